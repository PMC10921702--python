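"""Subtractive plasma-membrane enrichment calling.

Per cell line, the PM (silica-bead) fraction is tested against every other
organelle fraction with an unpaired Welch t-test; p-values are
Benjamini-Hochberg adjusted within each (cell line, fraction-pair) family;
a protein is called PM-enriched in a cell line when it passes
``q < fdr`` and ``log2FC > min_log2fc`` (signed, toward PM) against EVERY
non-PM fraction.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from organsurf.config import GroundTruth
from organsurf.ingest import QuantDataset


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpaired Welch t-test with Satterthwaite degrees of freedom.

    ``a`` and ``b`` are 1-D (one test) or 2-D (rows are independent tests
    over the trailing axis). Returns ``(t, df, p)`` with a two-sided p.
    Degenerate rows follow a fixed contract: zero variance in both groups
    with equal means gives ``t = 0, p = 1``; with unequal means ``p = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("welch_t needs at least 2 values per group")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate zero-variance rows are handled by the explicit contract below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=-1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)

    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    degen = (va == 0) & (vb == 0)
    if np.any(degen):
        equal = degen & (a.mean(axis=-1) == b.mean(axis=-1))
        unequal = degen & ~equal
        df_fallback = float(a.shape[-1] + b.shape[-1] - 2)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        df = np.where(degen, df_fallback, df)
        sign = np.sign(np.asarray(a.mean(axis=-1) - b.mean(axis=-1)))
        t = np.where(unequal, np.where(sign > 0, np.inf, -np.inf), t)
        p = np.where(unequal, 0.0, p)
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(list(pvals) if not isinstance(pvals, np.ndarray) else pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


def run_subtractive(
    ds: QuantDataset,
    fdr: float = 0.05,
    min_log2fc: float = 1.0,
    bh_family: str = "per-comparison",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test the PM fraction against every other fraction, per cell line.

    Returns ``(enrichment_table, pm_calls)``: a long table with one row per
    (protein, cell line, fraction-pair) holding log2FC (PM mean minus other
    mean), Welch p and BH q plus the per-comparison pass flag, and a
    protein x cell-line boolean call matrix (True when the protein passed
    against every non-PM fraction of that line).

    ``bh_family`` selects the BH adjustment family: ``per-comparison``
    (proteins within one cell line x fraction pair, the default) or
    ``per-cell-line`` (all fraction pairs of a line pooled). Cell lines
    missing the PM fraction, a non-PM fraction, or with fewer than two
    replicates of a needed fraction are skipped with a warning.
    """
    if bh_family not in ("per-comparison", "per-cell-line"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    if ds.values.isna().any().any():
        raise ValueError("run_subtractive requires an imputed (complete) matrix")
    pm = ds.pm_fraction
    others = [f for f in ds.samples["fraction"].unique() if f != pm]
    records: list[pd.DataFrame] = []
    call_cols: dict[str, pd.Series] = {}
    X = ds.values
    for line in ds.samples["cell_line"].unique():
        meta = ds.samples[ds.samples["cell_line"] == line]
        cols_of = {
            f: list(meta.index[meta["fraction"] == f]) for f in [pm] + others
        }
        if any(len(cols_of[f]) < 2 for f in [pm] + others):
            warnings.warn(f"cell line {line!r}: missing fraction or <2 replicates; skipped")
            continue
        a = X[cols_of[pm]].to_numpy()
        line_frames = []
        for frac in others:
            b = X[cols_of[frac]].to_numpy()
            t, df_, p = welch_t(a, b)
            line_frames.append(
                pd.DataFrame(
                    {
                        "protein": X.index,
                        "cell_line": line,
                        "fraction_vs": frac,
                        "log2FC": a.mean(axis=1) - b.mean(axis=1),
                        "t": t,
                        "df": df_,
                        "p": p,
                    }
                )
            )
        if bh_family == "per-comparison":
            for fr in line_frames:
                fr["q"] = bh_adjust(fr["p"].to_numpy())
        else:
            pooled = pd.concat(line_frames, ignore_index=True)
            pooled["q"] = bh_adjust(pooled["p"].to_numpy())
            line_frames = [g for _, g in pooled.groupby("fraction_vs", sort=False)]
        line_table = pd.concat(line_frames, ignore_index=True)
        line_table["passed"] = (line_table["q"] < fdr) & (line_table["log2FC"] > min_log2fc)
        n_passed = line_table.groupby("protein", sort=False)["passed"].sum()
        call_cols[line] = n_passed.reindex(X.index).eq(len(others))
        records.append(line_table)
    if not records:
        raise ValueError("no cell line had a complete fractionation design")
    enrichment = pd.concat(records, ignore_index=True)
    pm_calls = pd.DataFrame(call_cols, index=X.index).rename_axis("protein")
    return enrichment, pm_calls


def evaluate_pm_calls(
    pm_calls: pd.DataFrame, truth: GroundTruth, min_lines: int = 2
) -> dict[str, float]:
    """Score PM calls against planted truth at a >= min_lines call level.

    A protein counts as called when it is PM-enriched in at least
    ``min_lines`` cell lines. Sensitivity is the fraction of planted PM
    proteins called; the false-discovery proportion is the fraction of
    called proteins that were not planted.
    """
    n_lines = pm_calls.sum(axis=1)
    called = set(pm_calls.index[n_lines >= min_lines])
    planted = set(truth.pm_protein_ids)
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdp": (len(called) - tp) / len(called) if called else 0.0,
        "n_called": float(len(called)),
        "n_planted": float(len(planted)),
    }
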