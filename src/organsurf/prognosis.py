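"""Prognostic evaluation of a candidate marker in an IHC cohort.

Patients are dichotomised at the upper tertile of stain positivity; survival
is compared by Kaplan-Meier curves with a log-rank test and by univariable
and multivariable Cox proportional-hazards models (marker indicator plus
extent-of-resection and radiotherapy covariates, Efron tie handling);
stain positivity between tumour sites is compared by Wilcoxon's rank-sum
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

ENDPOINTS = ("pfi", "os")


def tertile_split(stain_pct) -> np.ndarray:
    """Label patients above the 2/3 quantile of stain positivity as "upper".

    The cut point is the linear-interpolation 66.67th percentile
    (``numpy.quantile(..., 2/3, method="linear")``); patients strictly above
    it are "upper", everyone else "lower". Labels depend only on the order
    statistics of the input. All-equal inputs yield all "lower" with a
    warning.
    """
    x = np.asarray(stain_pct, dtype=float)
    if x.size < 3:
        raise ValueError("tertile_split needs at least 3 values")
    if np.all(x == x[0]):
        warnings.warn("all stain values equal; no upper tertile")
        return np.full(x.shape, "lower", dtype=object)
    cut = np.quantile(x, 2.0 / 3.0, method="linear")
    return np.where(x > cut, "upper", "lower").astype(object)


def _check_endpoint(cohort: pd.DataFrame, endpoint: str) -> tuple[pd.Series, pd.Series]:
    endpoint = endpoint.lower()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    time = cohort[f"{endpoint}_time"]
    event = cohort[f"{endpoint}_event"]
    if (time < 0).any():
        raise ValueError("negative survival times")
    if not event.isin((0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return time, event


def km_logrank(
    cohort: pd.DataFrame, group: np.ndarray | pd.Series, endpoint: str = "pfi"
) -> dict:
    """Kaplan-Meier curves per group plus a two-sided log-rank test.

    Returns ``{"curves": {label: DataFrame}, "logrank_p": float | None}``;
    each curve table holds the product-limit estimate over the event
    timeline. With a single group only curves are returned (p undefined).
    """
    time, event = _check_endpoint(cohort, endpoint)
    if int(event.sum()) < 1:
        raise ValueError("need at least one event")
    group = pd.Series(np.asarray(group, dtype=object), index=cohort.index)
    curves = {}
    for label, idx in group.groupby(group).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[idx], event.loc[idx], label=str(label))
        curves[str(label)] = kmf.survival_function_.rename_axis("time")
    labels = sorted(curves)
    if len(labels) < 2:
        return {"curves": curves, "logrank_p": None}
    if len(labels) != 2:
        raise ValueError("km_logrank compares exactly two groups")
    m = group == labels[0]
    res = logrank_test(time[m], time[~m], event[m], event[~m])
    return {"curves": curves, "logrank_p": float(res.p_value)}


@dataclass
class CoxResult:
    """Hazard ratio, 95% CI and Wald p per fitted term."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    term: str
    summary: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def cox_fit(
    cohort: pd.DataFrame,
    endpoint: str = "pfi",
    covariates: tuple[str, ...] = (),
    marker_col: str = "stain_pct",
) -> CoxResult:
    """Proportional-hazards fit of the upper-tertile marker indicator.

    The marker column is dichotomised with :func:`tertile_split`;
    ``covariates`` (e.g. ``("eor", "rt")``) are added as-is for the
    multivariable model. Partial likelihood with Efron handling of tied
    event times (the lifelines default). Reports HR, 95% CI and Wald p for
    the marker term; the full per-term summary table is attached.
    Non-convergence or separation raises with an explicit message.
    """
    time, event = _check_endpoint(cohort, endpoint)
    design = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "marker_upper": (tertile_split(cohort[marker_col]) == "upper").astype(int),
        },
        index=cohort.index,
    )
    for cov in covariates:
        design[cov] = pd.to_numeric(cohort[cov])
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model for {endpoint} did not converge (possible separation): {err}"
        ) from err
    s = cph.summary
    row = s.loc["marker_upper"]
    return CoxResult(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        term="marker_upper",
        summary=s,
    )


def site_compare(stain_pct, site) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) of stain by tumour site.

    Returns ``(U, p)`` for the first site label vs the second; the exact
    distribution is used for small samples without ties (scipy's default).
    """
    stain = np.asarray(stain_pct, dtype=float)
    site = np.asarray(site, dtype=object)
    labels = sorted(set(site))
    if len(labels) != 2:
        raise ValueError("site_compare needs exactly two non-empty site groups")
    x = stain[site == labels[0]]
    y = stain[site == labels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both site groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def evaluate_cohort(cohort: pd.DataFrame, marker_col: str = "stain_pct") -> dict:
    """Full prognostic report: per endpoint, log-rank p plus univariable and
    multivariable (EOR + RT) Cox results; plus the site rank-sum test."""
    group = tertile_split(cohort[marker_col])
    out: dict = {}
    for endpoint in ENDPOINTS:
        uni = cox_fit(cohort, endpoint, covariates=(), marker_col=marker_col)
        multi = cox_fit(cohort, endpoint, covariates=("eor", "rt"), marker_col=marker_col)
        km = km_logrank(cohort, group, endpoint)
        out[endpoint] = {
            "logrank_p": km["logrank_p"],
            "univariable": {"hr": uni.hr, "ci": [uni.ci_low, uni.ci_high], "p": uni.p},
            "multivariable": {"hr": multi.hr, "ci": [multi.ci_low, multi.ci_high], "p": multi.p},
        }
    if "site" in cohort.columns and cohort["site"].nunique() == 2:
        u, p = site_compare(cohort[marker_col], cohort["site"])
        out["site_test"] = {"U": u, "p": p}
    return out
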