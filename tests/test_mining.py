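"""Candidate-funnel filters and the four-panel rank-sum prioritisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from organsurf.enrichment import run_subtractive
from organsurf.mining import (
    AnnotationBundle,
    antibody_filter,
    exclusivity_filter,
    rank_normal_tissue,
    run_funnel,
    surface_filter,
)


def _bundle(proteins, gs, spc, det_counts, ab, n_lines=10):
    idx = pd.Index(proteins, name="protein")
    det = np.zeros((len(proteins), n_lines), bool)
    for i, c in enumerate(det_counts):
        det[i, :c] = True
    return AnnotationBundle(
        genie_score=pd.Series(gs, index=idx),
        spc=pd.Series(spc, index=idx),
        cancer_detection=pd.DataFrame(det, index=idx),
        antibody_ok=pd.Series(ab, index=idx),
    )


def _calls(proteins, n_lines_enriched, total_lines=4):
    m = np.zeros((len(proteins), total_lines), bool)
    for i, c in enumerate(n_lines_enriched):
        m[i, :c] = True
    return pd.DataFrame(m, index=pd.Index(proteins, name="protein"),
                        columns=[f"CL{j}" for j in range(total_lines)])


class TestFilters:
    def test_surface_thresholds_inclusive(self):
        prots = ["a", "b", "c", "d"]
        calls = _calls(prots, [2, 2, 2, 1])
        bundle = _bundle(prots, gs=[20.0, 19.9, 20.0, 50.0], spc=[3, 4, 2, 4],
                         det_counts=[0] * 4, ab=[True] * 4)
        kept = surface_filter(calls, bundle)
        assert kept == ["a"]  # b fails GS, c fails SPC, d enriched in 1 line only

    def test_unannotated_protein_excluded_with_warning(self):
        prots = ["a", "b"]
        calls = _calls(prots, [2, 2])
        bundle = _bundle(["a"], gs=[30.0], spc=[4], det_counts=[0], ab=[True])
        with pytest.warns(UserWarning, match="missing annotation"):
            assert surface_filter(calls, bundle) == ["a"]

    def test_exclusivity_boundary_five_kept_six_dropped(self):
        prots = ["five", "six", "none"]
        bundle = _bundle(prots, [30] * 3, [4] * 3, det_counts=[5, 6, 0], ab=[True] * 3)
        kept = exclusivity_filter(prots, bundle.cancer_detection)
        assert kept == ["five", "none"]

    def test_antibody_filter_counts(self):
        prots = [f"p{i:02d}" for i in range(15)]
        ab = [i % 4 != 0 for i in range(15)]  # 4 of 15 lack an antibody
        bundle = _bundle(prots, [30] * 15, [4] * 15, [0] * 15, ab)
        assert len(antibody_filter(prots, bundle.antibody_ok)) == 11

    def test_exclusivity_and_antibody_commute(self, rng):
        prots = [f"p{i:02d}" for i in range(30)]
        det = rng.integers(0, 10, 30)
        ab = rng.random(30) < 0.5
        bundle = _bundle(prots, [30] * 30, [4] * 30, det, ab)
        ab_then_ex = exclusivity_filter(
            antibody_filter(prots, bundle.antibody_ok), bundle.cancer_detection
        )
        ex_then_ab = antibody_filter(
            exclusivity_filter(prots, bundle.cancer_detection), bundle.antibody_ok
        )
        assert ab_then_ex == ex_then_ab


def rank_oracle(values_by_panel, higher_better):
    """Brute-force per-panel sort with average ties, then summation."""
    candidates = sorted(next(iter(values_by_panel.values())))
    ranks = {}
    for panel, vals in values_by_panel.items():
        keyed = [(-vals[c] if higher_better[panel] else vals[c]) for c in candidates]
        r = {}
        for i, c in enumerate(candidates):
            less = sum(1 for k in keyed if k < keyed[i])
            equal = sum(1 for k in keyed if k == keyed[i])
            r[c] = less + (equal + 1) / 2.0
        ranks[panel] = r
    sums = {c: sum(ranks[p][c] for p in values_by_panel) for c in candidates}
    order = sorted(candidates, key=lambda c: (sums[c], c))
    return ranks, sums, order


class TestRankSum:
    def _panels(self, table):
        """table: candidate -> (ihc_frac_zero, med1, med2, med_rna) rendered
        as protein x tissue matrices over 10 tissues."""
        n_t = 10
        panels = {k: {} for k in ("ihc", "p1", "p2", "rna")}
        for c, (frac0, m1, m2, mr) in table.items():
            n0 = int(round(frac0 * n_t))
            panels["ihc"][c] = [0] * n0 + [2] * (n_t - n0)
            panels["p1"][c] = [m1] * n_t
            panels["p2"][c] = [m2] * n_t
            panels["rna"][c] = [mr] * n_t
        return {k: pd.DataFrame.from_dict(v, orient="index") for k, v in panels.items()}

    def test_universal_winner_ranks_first_everywhere(self):
        table = {"win": (1.0, 0.0, 0.0, 0.0)}
        table.update({f"bg{i}": (0.2, 5.0 + i, 4.0 + i, 3.0 + i) for i in range(6)})
        p = self._panels(table)
        r = rank_normal_tissue(sorted(table), p["ihc"], p["p1"], p["p2"], p["rna"])
        assert r.index[0] == "win"
        assert r.loc["win", ["rank_ihc", "rank_prot1", "rank_prot2", "rank_rna"]].eq(1.0).all()
        assert r.loc["win", "final_rank"] == 1

    def test_identical_candidates_tie_broken_by_id(self):
        table = {"zz": (0.5, 2.0, 2.0, 2.0), "aa": (0.5, 2.0, 2.0, 2.0),
                 "mm": (0.1, 9.0, 9.0, 9.0)}
        p = self._panels(table)
        r = rank_normal_tissue(sorted(table), p["ihc"], p["p1"], p["p2"], p["rna"])
        assert r.loc["aa", "rank_sum"] == r.loc["zz", "rank_sum"]
        assert list(r.index[:2]) == ["aa", "zz"]

    def test_fifteen_candidate_fixture_matches_bruteforce_oracle(self, rng):
        # hand-enumerable values with deliberate ties in every panel
        cands = [f"c{i:02d}" for i in range(15)]
        table = {
            c: (
                float(rng.choice([0.0, 0.2, 0.5, 0.5, 1.0])),
                float(rng.choice([1.0, 2.0, 2.0, 7.0])),
                float(rng.choice([0.5, 3.0, 3.0, 4.0])),
                float(rng.choice([0.0, 1.0, 1.0, 6.0])),
            )
            for c in cands
        }
        p = self._panels(table)
        r = rank_normal_tissue(cands, p["ihc"], p["p1"], p["p2"], p["rna"])
        oracle_ranks, oracle_sums, oracle_order = rank_oracle(
            {
                "ihc": {c: table[c][0] for c in cands},
                "p1": {c: table[c][1] for c in cands},
                "p2": {c: table[c][2] for c in cands},
                "rna": {c: table[c][3] for c in cands},
            },
            higher_better={"ihc": True, "p1": False, "p2": False, "rna": False},
        )
        for c in cands:
            assert r.loc[c, "rank_ihc"] == oracle_ranks["ihc"][c]
            assert r.loc[c, "rank_prot1"] == oracle_ranks["p1"][c]
            assert r.loc[c, "rank_sum"] == oracle_sums[c]
        assert list(r.index) == oracle_order

    def test_tie_ranks_sum_to_triangular_number(self, rng):
        cands = [f"c{i}" for i in range(12)]
        table = {c: tuple(float(rng.choice([0.0, 0.5, 1.0])) for _ in range(4)) for c in cands}
        p = self._panels(table)
        r = rank_normal_tissue(cands, p["ihc"], p["p1"], p["p2"], p["rna"])
        n = len(cands)
        for col in ("rank_ihc", "rank_prot1", "rank_prot2", "rank_rna"):
            assert r[col].sum() == n * (n + 1) / 2

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.1, 100, allow_nan=False), min_size=4, max_size=10, unique=True))
    def test_monotone_transform_invariance(self, vals):
        cands = [f"c{i}" for i in range(len(vals))]
        base = {c: (0.5, v, v, v) for c, v in zip(cands, vals)}
        trans = {c: (0.5, np.log(v), np.log(v), np.log(v)) for c, v in zip(cands, vals)}
        p1 = self._panels(base)
        p2 = self._panels(trans)
        r1 = rank_normal_tissue(cands, p1["ihc"], p1["p1"], p1["p2"], p1["rna"])
        r2 = rank_normal_tissue(cands, p2["ihc"], p2["p1"], p2["p2"], p2["rna"])
        assert list(r1.index) == list(r2.index)
        pd.testing.assert_frame_equal(r1, r2.loc[r1.index])

    def test_missing_candidate_policies(self):
        table = {"present": (0.2, 5.0, 5.0, 5.0), "also": (0.4, 4.0, 4.0, 4.0)}
        p = self._panels(table)
        cands = ["absent", "also", "present"]
        with pytest.warns(UserWarning):
            r = rank_normal_tissue(cands, p["ihc"], p["p1"], p["p2"], p["rna"],
                                   missing_policy="best")
        assert r.index[0] == "absent"
        r2 = rank_normal_tissue(cands, p["ihc"], p["p1"], p["p2"], p["rna"],
                                missing_policy="exclude")
        assert "absent" not in r2.index


@pytest.fixture(scope="module")
def strong_run(strong_bundle, strong_dataset):
    _, calls = run_subtractive(strong_dataset)
    return strong_bundle, calls


class TestFunnel:
    def test_top_candidate_is_planted_exclusive_marker(self, strong_run):
        bundle, calls = strong_run
        report = run_funnel(calls, bundle.annotations, bundle.panels)
        assert report.top_candidate in bundle.truth.exclusive_marker_ids

    def test_stage_counts_non_increasing(self, strong_run):
        bundle, calls = strong_run
        report = run_funnel(calls, bundle.annotations, bundle.panels)
        c = report.stage_counts
        assert c["surface"] >= c["exclusivity"] >= c["antibody"] >= c["ranked"]

    def test_disabled_filters_rank_all_enriched(self, strong_run):
        bundle, calls = strong_run
        report = run_funnel(
            calls, bundle.annotations, bundle.panels,
            gs_min=-np.inf, spc_min=0, min_lines=1,
            max_cancer_lines=10**9,
        )
        enriched = set(calls.index[calls.sum(axis=1) >= 1])
        assert set(report.survivors["surface"]) == enriched
        assert len(report.ranking) == len(report.survivors["antibody"])

    def test_empty_survivors_yield_valid_report(self, strong_run):
        bundle, calls = strong_run
        report = run_funnel(calls, bundle.annotations, bundle.panels, gs_min=10**9)
        assert report.stage_counts["surface"] == 0
        assert report.top_candidate is None
        assert report.ranking.empty
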