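"""Surface-candidate mining funnel.

PM-enriched proteins are filtered by surface-prediction scores
(GenieScore >= 20 and Surface Prediction Consensus >= 3), cross-cell-line
consistency (enriched in >= 2 lines), cancer-cell-line exclusivity
(detected in <= 5 of a 142-line panel) and antibody availability, then
prioritised by the rank sum of four normal-tissue expression rankings
(IHC detection, two protein-abundance panels, one RNA panel). Lower rank
sum means more tumour-restricted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_NAMES = ("ihc", "protein_ms_1", "protein_ms_2", "rna")


@dataclass
class AnnotationBundle:
    """Per-protein surface scores, cancer-panel detection and antibody flag."""

    genie_score: pd.Series
    spc: pd.Series
    cancer_detection: pd.DataFrame   # protein x cancer cell line, boolean
    antibody_ok: pd.Series

    def __post_init__(self) -> None:
        if not self.spc.isin(range(5)).all():
            raise ValueError("SPC scores must lie in 0..4")


def surface_filter(
    pm_calls: pd.DataFrame,
    bundle: AnnotationBundle,
    gs_min: float = 20.0,
    spc_min: int = 3,
    min_lines: int = 2,
) -> list[str]:
    """Surface-confidence filter: GS >= gs_min, SPC >= spc_min, enriched in
    >= min_lines cell lines (all thresholds inclusive).

    Proteins with PM calls but no annotation are excluded with a warning.
    """
    if pm_calls.shape[1] < min_lines:
        raise ValueError(f"need PM calls for at least {min_lines} cell lines")
    enriched = pm_calls.index[pm_calls.sum(axis=1) >= min_lines]
    missing = enriched.difference(bundle.genie_score.index)
    if len(missing):
        warnings.warn(f"{len(missing)} enriched proteins missing annotation; excluded")
        enriched = enriched.intersection(bundle.genie_score.index)
    gs_ok = bundle.genie_score.loc[enriched] >= gs_min
    spc_ok = bundle.spc.loc[enriched] >= spc_min
    return sorted(enriched[(gs_ok & spc_ok).to_numpy()])


def exclusivity_filter(
    candidates: list[str], cancer_detection: pd.DataFrame, max_lines: int = 5
) -> list[str]:
    """Keep candidates detected in at most ``max_lines`` cancer cell lines."""
    counts = cancer_detection.reindex(candidates).astype("boolean").fillna(False).sum(axis=1)
    return sorted(counts.index[counts <= max_lines])


def antibody_filter(candidates: list[str], antibody_ok: pd.Series) -> list[str]:
    """Keep candidates with a usable antibody."""
    ok = antibody_ok.reindex(candidates).astype("boolean").fillna(False).astype(bool)
    return sorted(ok.index[ok.to_numpy()])


def _panel_metric(
    candidates: list[str], panel: pd.DataFrame, kind: str, missing_policy: str
) -> pd.Series:
    """Per-candidate panel statistic (before ranking).

    IHC: proportion of tissues at level 0 (not detected) — higher is better,
    so its NEGATIVE is returned and all panels rank ascending. Continuous
    panels: median across tissues. A candidate absent from the panel gets
    the best ("not detected") value, the worst value, or is excluded,
    per ``missing_policy``.
    """
    present = [c for c in candidates if c in panel.index]
    absent = [c for c in candidates if c not in panel.index]
    if kind == "ihc":
        stat = -(panel.loc[present] == 0).mean(axis=1)
        best, worst = -1.0, 0.0
    else:
        stat = panel.loc[present].median(axis=1)
        best, worst = 0.0, np.inf
    if absent:
        if missing_policy == "exclude":
            return stat
        fill = best if missing_policy == "best" else worst
        warnings.warn(f"{len(absent)} candidates absent from a panel; treated as {missing_policy}")
        stat = pd.concat([stat, pd.Series(fill, index=absent)])
    return stat.loc[[c for c in candidates if c in stat.index]]


def rank_normal_tissue(
    candidates: list[str],
    ihc_panel: pd.DataFrame,
    prot_panel_1: pd.DataFrame,
    prot_panel_2: pd.DataFrame,
    rna_panel: pd.DataFrame,
    missing_policy: str = "best",
) -> pd.DataFrame:
    """Four-panel normal-tissue rank-sum prioritisation.

    Candidates are ranked in each panel (average ranks on ties): descending
    by the proportion of tissues with IHC level 0, and ascending by the
    across-tissue median of each protein panel and of the RNA panel. The
    rank sum orders the final list ascending, ties broken by candidate id.
    """
    if missing_policy not in ("best", "worst", "exclude"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    panels = {
        "ihc": (ihc_panel, "ihc"),
        "prot1": (prot_panel_1, "continuous"),
        "prot2": (prot_panel_2, "continuous"),
        "rna": (rna_panel, "continuous"),
    }
    metrics = {
        name: _panel_metric(candidates, panel, kind, missing_policy)
        for name, (panel, kind) in panels.items()
    }
    if missing_policy == "exclude":
        keep = set(candidates)
        for m in metrics.values():
            keep &= set(m.index)
        metrics = {name: m.loc[sorted(keep)] for name, m in metrics.items()}
    ranking = pd.DataFrame(
        {f"rank_{name}": m.rank(method="average") for name, m in metrics.items()}
    ).rename_axis("protein")
    ranking["rank_sum"] = ranking.sum(axis=1)
    ranking = ranking.sort_values(["rank_sum", "protein"], kind="mergesort")
    ranking["final_rank"] = np.arange(1, len(ranking) + 1)
    return ranking


@dataclass
class FunnelReport:
    """Stage-by-stage survivors of the candidate-mining funnel."""

    stage_counts: dict[str, int]
    survivors: dict[str, list[str]]
    ranking: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def top_candidate(self) -> str | None:
        return None if self.ranking.empty else str(self.ranking.index[0])


def run_funnel(
    pm_calls: pd.DataFrame,
    bundle: AnnotationBundle,
    panels: dict[str, pd.DataFrame],
    gs_min: float = 20.0,
    spc_min: int = 3,
    min_lines: int = 2,
    max_cancer_lines: int = 5,
    missing_policy: str = "best",
) -> FunnelReport:
    """Apply the full mining funnel and rank the survivors.

    Stages: surface filter -> cancer-panel exclusivity -> antibody
    availability -> four-panel rank sum. An empty survivor set at any stage
    yields a valid empty report with the stage counts recorded.
    """
    missing = [n for n in PANEL_NAMES if n not in panels]
    if missing:
        raise ValueError(f"panels missing: {missing}")
    s1 = surface_filter(pm_calls, bundle, gs_min=gs_min, spc_min=spc_min, min_lines=min_lines)
    s2 = exclusivity_filter(s1, bundle.cancer_detection, max_lines=max_cancer_lines)
    s3 = antibody_filter(s2, bundle.antibody_ok)
    ranking = (
        rank_normal_tissue(
            s3,
            panels["ihc"],
            panels["protein_ms_1"],
            panels["protein_ms_2"],
            panels["rna"],
            missing_policy=missing_policy,
        )
        if s3
        else pd.DataFrame()
    )
    counts = {
        "surface": len(s1),
        "exclusivity": len(s2),
        "antibody": len(s3),
        "ranked": len(ranking),
    }
    return FunnelReport(counts, {"surface": s1, "exclusivity": s2, "antibody": s3}, ranking)
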