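import numpy as np
import pandas as pd
import pytest

from organsurf import SimConfig, simulate
from organsurf.ingest import impute_low, median_normalize


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small but realistic study: 300 proteins, 12 planted, default design."""
    return SimConfig(n_proteins=300, n_planted_pm=12, n_exclusive_markers=2, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate.simulate_all(small_config)


@pytest.fixture(scope="session")
def strong_config() -> SimConfig:
    """Separability-limit variant (large effect, low noise, no dropout) for
    recovery unit tests that exercise logic rather than statistical power."""
    return SimConfig(
        n_proteins=400, n_planted_pm=15, n_exclusive_markers=1,
        delta_pm=5.0, sigma_noise=0.2, mnar_slope=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def strong_bundle(strong_config):
    return simulate.simulate_all(strong_config)


@pytest.fixture(scope="session")
def strong_dataset(strong_bundle, strong_config):
    return impute_low(
        median_normalize(strong_bundle.dataset), seed=strong_config.seed
    )


def make_protein_groups(tmp_path, rows, samples):
    """Write a tiny proteinGroups-dialect TSV plus its sample sheet.

    ``rows`` are dicts with keys id, uniq, rev, cont and per-sample
    intensities (None = blank); ``samples`` are (sample, line, fraction,
    replicate) tuples.
    """
    sample_ids = [s[0] for s in samples]
    recs = []
    for r in rows:
        rec = {
            "Majority protein IDs": r["id"],
            "Unique peptides": r["uniq"],
            "Reverse": r.get("rev", ""),
            "Potential contaminant": r.get("cont", ""),
        }
        for sid, v in zip(sample_ids, r["intens"]):
            rec[f"iBAQ {sid}"] = "" if v is None else v
        recs.append(rec)
    pg = tmp_path / "protein_groups.tsv"
    pd.DataFrame(recs).to_csv(pg, sep="\t", index=False)
    ss = tmp_path / "samples.tsv"
    pd.DataFrame(samples, columns=["sample", "cell_line", "fraction", "replicate"]).to_csv(
        ss, sep="\t", index=False
    )
    return pg, ss


DEFAULT_SAMPLES = [
    ("A_PM_r1", "A", "PM", 1),
    ("A_PM_r2", "A", "PM", 2),
    ("A_cyt_r1", "A", "cytosol", 1),
    ("A_cyt_r2", "A", "cytosol", 2),
]


@pytest.fixture()
def tiny_quant_files(tmp_path):
    rows = [
        {"id": "P1", "uniq": 5, "intens": [1024.0, 1024.0, 2.0, 2.0]},
        {"id": "P2", "uniq": 3, "intens": [8.0, None, 16.0, 32.0]},
        {"id": "P3", "uniq": 2, "intens": [4.0, 4.0, 4.0, 4.0]},
    ]
    return make_protein_groups(tmp_path, rows, DEFAULT_SAMPLES)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
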