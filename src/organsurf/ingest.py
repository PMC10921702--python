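"""Protein-group quantification ingest.

Parses MaxQuant-style ``proteinGroups.txt`` tables, applies the standard
identification filters (drop decoys and contaminants, require >= 2 unique
peptides), log2-transforms iBAQ intensities, median-normalises each sample
on the log2 scale and imputes missing values with low draws. The fixed
pipeline order is: filter -> log2 -> normalise -> impute, with normalisation
statistics computed on observed values only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROTEIN_ID_COL = "Majority protein IDs"
UNIQUE_PEPTIDES_COL = "Unique peptides"
REVERSE_COL = "Reverse"
CONTAMINANT_COL = "Potential contaminant"
IBAQ_PREFIX = "iBAQ "

SAMPLE_SHEET_COLS = ("sample", "cell_line", "fraction", "replicate")


@dataclass
class RawQuantTable:
    """Linear-scale intensities plus identification metadata, pre-filtering."""

    intensities: pd.DataFrame     # protein x sample, linear iBAQ, NaN = missing
    samples: pd.DataFrame         # index sample id; cell_line, fraction, replicate
    unique_peptides: pd.Series
    reverse: pd.Series            # boolean decoy flag
    contaminant: pd.Series        # boolean contaminant flag
    filter_log: dict = field(default_factory=dict)


@dataclass
class QuantDataset:
    """Log2 abundance matrix with sample metadata and a missingness mask.

    ``values`` is protein x sample on the log2 scale; ``mask`` is True where
    the entry was originally missing (and hence NaN before imputation, an
    imputed low value after). ``samples`` carries cell_line / fraction /
    replicate per column; exactly one fraction label is the PM fraction.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    samples: pd.DataFrame
    pm_fraction: str = "PM"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate protein identifiers")
        if not self.values.columns.equals(self.mask.columns) or not self.values.index.equals(
            self.mask.index
        ):
            raise ValueError("values and mask are not aligned")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match matrix columns")
        keys = self.samples[["cell_line", "fraction", "replicate"]]
        if keys.duplicated().any():
            raise ValueError("(cell_line, fraction, replicate) must be unique")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def copy(self) -> "QuantDataset":
        return QuantDataset(
            self.values.copy(), self.mask.copy(), self.samples.copy(), self.pm_fraction
        )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "cell_line": str, "fraction": str})
    missing = set(SAMPLE_SHEET_COLS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet.set_index("sample")


def _flag_to_bool(col: pd.Series) -> pd.Series:
    # MaxQuant marks decoy/contaminant rows with "+"; anything non-empty counts.
    return col.fillna("").astype(str).str.strip().ne("")


def parse_protein_groups(path: str | Path, sample_sheet: str | Path) -> RawQuantTable:
    """Read a proteinGroups.txt-dialect TSV plus its sample sheet.

    Intensities are returned on the linear scale with zeros and blanks
    treated as missing (NaN). Every ``iBAQ <sample>`` column must be mapped
    by the sample sheet; other intensity columns are ignored.
    """
    table = pd.read_csv(path, sep="\t", low_memory=False)
    for col in (PROTEIN_ID_COL, UNIQUE_PEPTIDES_COL, REVERSE_COL, CONTAMINANT_COL):
        if col not in table.columns:
            raise ValueError(f"protein-groups table missing required column {col!r}")
    meta = read_sample_sheet(sample_sheet)

    ibaq_cols = [c for c in table.columns if c.startswith(IBAQ_PREFIX) and c != "iBAQ"]
    sample_of_col = {c: c[len(IBAQ_PREFIX):] for c in ibaq_cols}
    unmapped = [c for c, s in sample_of_col.items() if s not in meta.index]
    if unmapped:
        raise ValueError(f"iBAQ columns absent from sample sheet: {unmapped}")
    absent = set(meta.index) - set(sample_of_col.values())
    if absent:
        raise ValueError(f"sample sheet entries without an iBAQ column: {sorted(absent)}")

    # protein id = first entry of the majority-protein-IDs group
    ids = table[PROTEIN_ID_COL].astype(str).str.split(";").str[0]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise ValueError(f"duplicate protein identifiers, e.g. {list(dupes)}")

    intens = table[ibaq_cols].apply(pd.to_numeric, errors="coerce")
    intens = intens.rename(columns=sample_of_col)
    intens = intens.mask(intens <= 0)  # zero / blank = not quantified
    intens.index = ids
    intens = intens[list(meta.index)]  # sample-sheet order

    uniq = pd.to_numeric(table[UNIQUE_PEPTIDES_COL], errors="coerce").fillna(0).astype(int)
    uniq.index = ids
    rev = _flag_to_bool(table[REVERSE_COL])
    rev.index = ids
    cont = _flag_to_bool(table[CONTAMINANT_COL])
    cont.index = ids
    return RawQuantTable(intens, meta, uniq, rev, cont, {"n_parsed": len(table)})


def filter_identifications(raw: RawQuantTable, min_unique_peptides: int = 2) -> RawQuantTable:
    """Drop decoy and contaminant rows, then rows with < 2 unique peptides."""
    keep = ~(raw.reverse | raw.contaminant) & (raw.unique_peptides >= min_unique_peptides)
    log = dict(raw.filter_log)
    log.update(
        n_decoy=int(raw.reverse.sum()),
        n_contaminant=int((raw.contaminant & ~raw.reverse).sum()),
        n_below_min_peptides=int(
            (~(raw.reverse | raw.contaminant) & (raw.unique_peptides < min_unique_peptides)).sum()
        ),
        n_retained=int(keep.sum()),
    )
    return RawQuantTable(
        raw.intensities.loc[keep],
        raw.samples,
        raw.unique_peptides.loc[keep],
        raw.reverse.loc[keep],
        raw.contaminant.loc[keep],
        log,
    )


def log2_transform(raw: RawQuantTable, pm_fraction: str = "PM") -> QuantDataset:
    """Log2 linear intensities into a QuantDataset; missing entries stay NaN."""
    if (raw.intensities < 0).any().any():
        raise ValueError("negative intensities cannot be log-transformed")
    values = np.log2(raw.intensities)
    mask = raw.intensities.isna()
    return QuantDataset(values, mask, raw.samples, pm_fraction)


def median_normalize(ds: QuantDataset) -> QuantDataset:
    """Shift each sample so observed medians agree.

    Every sample's observed median is moved to the global median of the
    per-sample observed medians; within-sample differences are preserved
    exactly and the mask is untouched.
    """
    obs = ds.values.where(~ds.mask)
    medians = obs.median(axis=0)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no observed values: {bad}")
    target = float(medians.median())
    out = ds.copy()
    out.values = ds.values.add(target - medians, axis=1)
    return out


def impute_low(
    ds: QuantDataset,
    low: float = 1.0,
    high: float = 1.2,
    seed: int = 0,
    method: str = "uniform",
) -> QuantDataset:
    """Replace missing entries with low values on the log2 scale.

    ``uniform`` draws each imputed cell i.i.d. from U[low, high] (seeded);
    ``constant`` uses the midpoint. Observed entries are bit-identical to the
    input and the mask is retained for provenance.
    """
    if low > high:
        raise ValueError("low must not exceed high")
    if method not in ("uniform", "constant"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = ds.copy()
    m = ds.mask.to_numpy()
    n_missing = int(m.sum())
    vals = out.values.to_numpy()
    if n_missing:
        if method == "uniform":
            rng = np.random.default_rng(seed)
            fill = rng.uniform(low, high, n_missing)
        else:
            fill = np.full(n_missing, (low + high) / 2.0)
        vals[m] = fill
        out.values = pd.DataFrame(vals, index=ds.values.index, columns=ds.values.columns)
    return out


def run_ingest(
    protein_groups: str | Path,
    sample_sheet: str | Path,
    pm_fraction: str = "PM",
    low: float = 1.0,
    high: float = 1.2,
    seed: int = 0,
    impute_method: str = "uniform",
) -> tuple[QuantDataset, dict]:
    """Full ingest pipeline: parse -> filter -> log2 -> normalise -> impute."""
    raw = parse_protein_groups(protein_groups, sample_sheet)
    raw = filter_identifications(raw)
    ds = log2_transform(raw, pm_fraction=pm_fraction)
    ds = median_normalize(ds)
    ds = impute_low(ds, low=low, high=high, seed=seed, method=impute_method)
    return ds, raw.filter_log


def write_dataset(ds: QuantDataset, outdir: str | Path, log: dict | None = None) -> None:
    """Write the processed matrix, mask, sample sheet and processing log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.values.rename_axis("protein").to_csv(
        outdir / "matrix.tsv", sep="\t", float_format="%.10g", lineterminator="\n"
    )
    ds.mask.astype(int).rename_axis("protein").to_csv(
        outdir / "mask.tsv", sep="\t", lineterminator="\n"
    )
    ds.samples.rename_axis("sample").to_csv(outdir / "samples.tsv", sep="\t", lineterminator="\n")
    if log is not None:
        with open(outdir / "ingest_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_dataset(indir: str | Path, pm_fraction: str = "PM") -> QuantDataset:
    """Read back a matrix/mask/samples directory written by :func:`write_dataset`."""
    indir = Path(indir)
    values = pd.read_csv(indir / "matrix.tsv", sep="\t", index_col="protein")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample")
    samples.index = samples.index.astype(str)
    mask_path = indir / "mask.tsv"
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col="protein").astype(bool)
    else:
        mask = values.isna()
    return QuantDataset(values, mask, samples, pm_fraction)
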