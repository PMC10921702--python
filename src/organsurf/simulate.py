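"""Synthetic organellar-proteomics study generator.

Emulates the measured structure of a silica-bead PM capture plus
differential-ultracentrifugation fractionation experiment: four cell lines,
five organelle fractions in triplicate, log2 iBAQ-like abundances with a
home-compartment enrichment block structure, abundance-dependent (MNAR)
dropout, surface-annotation and cancer-panel tables with a planted
tumour-exclusive marker, four normal-tissue expression panels, and a
survival cohort with a planted upper-tertile hazard effect. Every output is
deterministic given the config seed, and the planted truth is returned so
downstream recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from organsurf.config import GroundTruth, SimConfig
from organsurf.ingest import (
    CONTAMINANT_COL,
    IBAQ_PREFIX,
    PROTEIN_ID_COL,
    REVERSE_COL,
    UNIQUE_PEPTIDES_COL,
    QuantDataset,
)
from organsurf.mining import AnnotationBundle

# independent RNG streams per generator stage, all derived from config.seed
_STREAM_QUANT = 0
_STREAM_ANNOT = 1
_STREAM_PANEL = 2
_STREAM_COHORT = 3
_STREAM_JUNK = 4


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def compartment_map(config: SimConfig) -> dict[str, tuple[str, ...]]:
    """Map each home compartment to the fraction(s) where it is enriched.

    With the default fraction set, mitochondria and microsome are treated as
    one mixed ``membrane`` compartment (co-elevated in both fractions), so
    the proteome falls into four classes: PM, cytosolic, membrane, nuclear.
    For non-default fraction lists every non-PM fraction is its own
    compartment.
    """
    comp = {"PM": (config.pm_fraction,)}
    others = [f for f in config.fractions if f != config.pm_fraction]
    if "mitochondria" in others and "microsome" in others:
        comp["membrane"] = ("mitochondria", "microsome")
        others = [f for f in others if f not in ("mitochondria", "microsome")]
    for f in others:
        comp[f] = (f,)
    return comp


def _protein_ids(config: SimConfig) -> list[str]:
    return [f"P{i:05d}" for i in range(config.n_proteins)]


def generate_quant_dataset(config: SimConfig) -> tuple[QuantDataset, GroundTruth]:
    """Simulate the log2 abundance tensor and its planted truth.

    log2 abundance of protein p in sample s is
    ``baseline(p) + delta_pm * [fraction(s) enriches home(p)] + N(0, sigma)``,
    masked missing with probability
    ``logistic(mnar_slope * (mnar_midpoint - abundance))``
    (``mnar_slope == 0`` disables missingness). Missing entries are NaN in
    ``values`` and True in ``mask``.
    """
    rng = _rng(config, _STREAM_QUANT)
    proteins = _protein_ids(config)
    n = config.n_proteins

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    planted_idx = np.sort(rng.choice(n, config.n_planted_pm, replace=False))
    exclusive_idx = np.sort(
        rng.choice(planted_idx, config.n_exclusive_markers, replace=False)
    )

    comp_map = compartment_map(config)
    bg_comps = [c for c in comp_map if c != "PM"]
    compartment = np.empty(n, dtype=object)
    compartment[:] = rng.choice(bg_comps, n) if bg_comps else "PM"
    compartment[planted_idx] = "PM"

    # elevation[p, f] = 1 if fraction f enriches protein p's home compartment
    frac_index = {f: j for j, f in enumerate(config.fractions)}
    elev_of_comp = {
        c: np.isin(np.array(config.fractions), fr).astype(float) for c, fr in comp_map.items()
    }
    elevation = np.stack([elev_of_comp[c] for c in compartment])  # n x n_fractions

    sample_rows = []
    cols = []
    for line in config.cell_lines:
        for frac in config.fractions:
            for rep in range(1, config.n_replicates + 1):
                sample_rows.append((f"{line}_{frac}_r{rep}", line, frac, rep))
                cols.append(frac_index[frac])
    sample_ids = [r[0] for r in sample_rows]
    mu = baseline[:, None] + config.delta_pm * elevation[:, cols]
    x = mu + rng.normal(0.0, config.sigma_noise, mu.shape) if config.sigma_noise > 0 else mu.copy()
    if config.mnar_slope > 0:
        p_miss = expit(config.mnar_slope * (config.mnar_midpoint - x))
        mask = rng.random(x.shape) < p_miss
    else:
        mask = np.zeros(x.shape, dtype=bool)
    x = np.where(mask, np.nan, x)

    samples = pd.DataFrame(
        sample_rows, columns=["sample", "cell_line", "fraction", "replicate"]
    ).set_index("sample")
    values = pd.DataFrame(x, index=pd.Index(proteins, name="protein"), columns=sample_ids)
    mask_df = pd.DataFrame(mask, index=values.index, columns=sample_ids)
    ds = QuantDataset(values, mask_df, samples, pm_fraction=config.pm_fraction)

    prot_arr = np.array(proteins)
    truth = GroundTruth(
        pm_protein_ids=frozenset(prot_arr[planted_idx]),
        compartment_of=dict(zip(proteins, compartment)),
        exclusive_marker_ids=frozenset(prot_arr[exclusive_idx]),
    )
    return ds, truth


def generate_annotation_bundle(config: SimConfig, truth: GroundTruth) -> AnnotationBundle:
    """Surface scores, cancer-panel detection and antibody availability.

    Planted PM proteins always pass the surface filter (GS >= 20, SPC in
    {3, 4}); a configured fraction of non-PM proteins also pass, to exercise
    false-positive filtering. Cancer-panel detection is Bernoulli per cell
    line with a low rate for exclusive markers and a higher rate otherwise.
    Exclusive markers always have a usable antibody (they are the planted
    recoverable target).
    """
    rng = _rng(config, _STREAM_ANNOT)
    proteins = list(truth.compartment_of)
    n = len(proteins)
    is_pm = np.array([p in truth.pm_protein_ids for p in proteins])
    is_excl = np.array([p in truth.exclusive_marker_ids for p in proteins])

    passes = is_pm | (rng.random(n) < config.annotation_noise)
    gs = np.where(passes, 20.0 + 60.0 * rng.random(n), 20.0 * rng.random(n))
    spc = np.where(passes, rng.integers(3, 5, n), rng.integers(0, 3, n))

    rate = np.where(is_excl, config.cancer_rate_exclusive, config.cancer_rate_background)
    detection = rng.random((n, config.n_cancer_lines)) < rate[:, None]
    antibody = (rng.random(n) < config.antibody_rate) | is_excl

    idx = pd.Index(proteins, name="protein")
    return AnnotationBundle(
        genie_score=pd.Series(gs, index=idx, name="genie_score"),
        spc=pd.Series(spc.astype(int), index=idx, name="spc"),
        cancer_detection=pd.DataFrame(
            detection, index=idx, columns=[f"CCL{j:03d}" for j in range(config.n_cancer_lines)]
        ),
        antibody_ok=pd.Series(antibody, index=idx, name="antibody_ok"),
    )


def generate_normal_panels(config: SimConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Four protein x tissue normal-expression panels.

    ``ihc`` holds ordinal staining levels 0-3 (0 = not detected); the two
    protein panels and the RNA panel hold linear log-normal abundances.
    Exclusive markers are entirely undetected (level 0 / value 0) in all
    four panels; everything else is background.
    """
    rng = _rng(config, _STREAM_PANEL)
    proteins = list(truth.compartment_of)
    n = len(proteins)
    tissues = [f"tissue{j:02d}" for j in range(config.n_tissues)]
    is_excl = np.array([p in truth.exclusive_marker_ids for p in proteins])

    idx = pd.Index(proteins, name="protein")
    ihc = rng.choice(len(config.ihc_level_probs), (n, config.n_tissues), p=config.ihc_level_probs)
    ihc[is_excl] = 0
    prot1 = rng.lognormal(config.panel_meanlog, config.panel_sdlog, (n, config.n_tissues))
    prot2 = rng.lognormal(config.panel_meanlog, config.panel_sdlog, (n, config.n_tissues))
    rna = rng.lognormal(config.rna_meanlog, config.rna_sdlog, (n, config.n_tissues))
    for arr in (prot1, prot2, rna):
        arr[is_excl] = 0.0
    return {
        "ihc": pd.DataFrame(ihc, index=idx, columns=tissues),
        "protein_ms_1": pd.DataFrame(prot1, index=idx, columns=tissues),
        "protein_ms_2": pd.DataFrame(prot2, index=idx, columns=tissues),
        "rna": pd.DataFrame(rna, index=idx, columns=tissues),
    }


def _calibrate_censor_horizon(times: np.ndarray, rate: float) -> float:
    """Horizon tau such that C ~ U(0, tau) censors the target fraction.

    P(C < T_i) = min(T_i / tau, 1); the mean over patients is monotone
    decreasing in tau, so the root is found by bisection. Censoring stays
    independent of the event times given tau.
    """

    def excess(tau: float) -> float:
        return float(np.minimum(times / tau, 1.0).mean()) - rate

    lo, hi = times.min() * 1e-6, times.max() * 1e6
    return float(brentq(excess, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_survival_cohort(
    config: SimConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth | None]:
    """Simulate the IHC patient cohort with a planted upper-tertile effect.

    Stain positivity is Beta(2, 5)-distributed (percent scale); PFI and OS
    event times are exponential with log-hazard
    ``log(true_hr) * I(upper tertile) + eor_log_hr * EOR + rt_log_hr * RT``;
    censoring is uniform with a horizon calibrated to ``censor_rate``.
    Returns the cohort table and, when ``truth`` is given, a copy with
    ``patient_risk_group`` filled in.
    """
    from organsurf.prognosis import tertile_split

    if config.n_patients < 9:
        raise ValueError("need n_patients >= 9 for well-defined tertiles")
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_patients
    patients = [f"PT{i:03d}" for i in range(n)]

    stain = rng.beta(2.0, 5.0, n) * 100.0
    eor = rng.integers(0, 2, n)
    rt = rng.integers(0, 2, n)
    site = rng.choice(["skull_base", "spine"], n)
    upper = tertile_split(stain) == "upper"

    lp = np.log(config.true_hr) * upper + config.eor_log_hr * eor + config.rt_log_hr * rt
    cohort = {"patient_id": patients, "stain_pct": stain, "eor": eor, "rt": rt, "site": site}
    for endpoint, lam0 in (("pfi", config.baseline_hazard_pfi), ("os", config.baseline_hazard_os)):
        t_event = rng.exponential(1.0 / (lam0 * np.exp(lp)))
        if config.censor_rate > 0:
            tau = _calibrate_censor_horizon(t_event, config.censor_rate)
            c = rng.uniform(0.0, tau, n)
            time = np.minimum(t_event, c)
            event = (t_event <= c).astype(int)
        else:
            time, event = t_event, np.ones(n, dtype=int)
        cohort[f"{endpoint}_time"] = time
        cohort[f"{endpoint}_event"] = event
    df = pd.DataFrame(cohort).set_index("patient_id")

    if truth is not None:
        risk = {p: ("upper" if u else "lower") for p, u in zip(patients, upper)}
        truth = dataclasses.replace(truth, patient_risk_group=risk)
    return df, truth


@dataclass
class SimBundle:
    """Everything one simulated study produces, plus its planted truth."""

    config: SimConfig
    dataset: QuantDataset
    truth: GroundTruth
    annotations: AnnotationBundle
    panels: dict[str, pd.DataFrame]
    cohort: pd.DataFrame


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage on independent seed streams."""
    ds, truth = generate_quant_dataset(config)
    annotations = generate_annotation_bundle(config, truth)
    panels = generate_normal_panels(config, truth)
    cohort, truth = generate_survival_cohort(config, truth)
    return SimBundle(config, ds, truth, annotations, panels, cohort)


def _junk_rows(
    config: SimConfig, sample_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Decoy / contaminant / single-peptide rows that ingestion must drop."""
    rows = []
    specs = (
        [(f"REV__Q{i:04d}", "+", "", int(rng.integers(2, 20))) for i in range(config.n_decoy_rows)]
        + [(f"CON__P{i:04d}", "", "+", int(rng.integers(2, 20)))
           for i in range(config.n_contaminant_rows)]
        + [(f"JUNK{i:04d}", "", "", 1) for i in range(config.n_single_peptide_rows)]
    )
    for pid, rev, cont, uniq in specs:
        intens = rng.lognormal(5.0, 1.0, len(sample_ids))
        rows.append([pid, uniq, rev, cont, *intens])
    cols = [PROTEIN_ID_COL, UNIQUE_PEPTIDES_COL, REVERSE_COL, CONTAMINANT_COL] + [
        IBAQ_PREFIX + s for s in sample_ids
    ]
    return pd.DataFrame(rows, columns=cols)


def protein_groups_frame(config: SimConfig, ds: QuantDataset) -> pd.DataFrame:
    """Render the dataset as a proteinGroups.txt-dialect table (linear iBAQ)."""
    rng = _rng(config, _STREAM_JUNK)
    uniq = rng.integers(2, 40, len(ds.proteins))
    linear = np.power(2.0, ds.values.to_numpy())
    linear = np.where(np.isnan(linear), 0.0, linear)
    body = pd.DataFrame(
        {
            PROTEIN_ID_COL: ds.proteins,
            UNIQUE_PEPTIDES_COL: uniq,
            REVERSE_COL: "",
            CONTAMINANT_COL: "",
        }
    )
    for j, s in enumerate(ds.values.columns):
        body[IBAQ_PREFIX + s] = linear[:, j]
    junk = _junk_rows(config, list(ds.values.columns), rng)
    return pd.concat([body, junk], ignore_index=True)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index=index, lineterminator="\n")


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Emit every pipeline input format plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(protein_groups_frame(bundle.config, bundle.dataset),
               outdir / "protein_groups.tsv", index=False)
    bundle.dataset.samples.rename_axis("sample").to_csv(
        outdir / "samples.tsv", sep="\t", lineterminator="\n"
    )
    ann = pd.DataFrame(
        {
            "genie_score": bundle.annotations.genie_score,
            "spc": bundle.annotations.spc,
            "antibody_ok": bundle.annotations.antibody_ok.astype(int),
        }
    )
    _write_tsv(ann.rename_axis("protein"), outdir / "annotations.tsv")
    _write_tsv(bundle.annotations.cancer_detection.astype(int), outdir / "cancer_panel.tsv")
    for name, panel in bundle.panels.items():
        _write_tsv(panel, outdir / f"panel_{name}.tsv")
    _write_tsv(bundle.cohort, outdir / "cohort.tsv")
    truth = {
        "pm_protein_ids": sorted(bundle.truth.pm_protein_ids),
        "exclusive_marker_ids": sorted(bundle.truth.exclusive_marker_ids),
        "compartment_of": dict(sorted(bundle.truth.compartment_of.items())),
        "patient_risk_group": dict(sorted(bundle.truth.patient_risk_group.items())),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
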