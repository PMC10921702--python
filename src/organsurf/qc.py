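"""Quality-control views of the fractionation experiment.

PCA of the sample proteomes (fractions should dominate cell lines),
per-protein z-scoring, Ward hierarchical clustering of proteins into
compartment clusters, and per-cluster annotation composition summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.decomposition import PCA

from organsurf.ingest import QuantDataset


def pca_samples(ds: QuantDataset, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the principal axes of the protein-centred matrix.

    Returns per-sample scores and the explained-variance ratios
    (non-increasing, summing to at most 1). Requires a complete (imputed)
    matrix.
    """
    if ds.values.isna().any().any():
        raise ValueError("pca_samples requires an imputed (complete) matrix")
    X = ds.values.to_numpy().T  # samples x proteins
    max_rank = min(X.shape)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=ds.values.columns, columns=cols).rename_axis("sample"),
        pca.explained_variance_ratio_,
    )


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score: (x - row mean) / row SD; constant rows become 0."""
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(arr - mean, sd, out=np.zeros_like(arr), where=sd > 0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


@dataclass
class ClusterResult:
    """Hierarchical clustering of proteins on their z-scored profiles."""

    cluster_of: pd.Series          # protein -> cluster id in 1..k
    linkage_matrix: np.ndarray     # scipy merge history
    zmatrix: pd.DataFrame

    @property
    def k(self) -> int:
        return int(self.cluster_of.nunique())


def cluster_proteins(
    ds: QuantDataset, k: int = 4, method: str = "ward", metric: str = "euclidean"
) -> ClusterResult:
    """Agglomerative clustering of z-scored protein profiles cut at k clusters.

    Ward linkage on Euclidean distances by default, matching the standard
    treatment of z-scored abundance heatmaps. Deterministic for fixed input.
    """
    if ds.values.isna().any().any():
        raise ValueError("cluster_proteins requires an imputed (complete) matrix")
    n = len(ds.values)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    z = zscore_rows(ds.values)
    lm = scipy_linkage(z.to_numpy(), method=method, metric=metric)
    labels = fcluster(lm, t=k, criterion="maxclust")
    return ClusterResult(
        cluster_of=pd.Series(labels, index=z.index, name="cluster"),
        linkage_matrix=lm,
        zmatrix=z,
    )


def summarize_cluster_annotations(
    result: ClusterResult, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster counts and fractions of each boolean annotation flag.

    ``annotations`` is protein x flag (boolean-like). Proteins unknown to
    the clustering are ignored with a warning; clustered proteins absent
    from the table count as un-annotated.
    """
    unknown = annotations.index.difference(result.cluster_of.index)
    if len(unknown):
        warnings.warn(f"{len(unknown)} annotated proteins not in the clustering; ignored")
    ann = annotations.reindex(result.cluster_of.index).astype("boolean").fillna(False).astype(bool)
    out = []
    for cid, members in result.cluster_of.groupby(result.cluster_of):
        sub = ann.loc[members.index]
        row: dict[str, float] = {"cluster": int(cid), "n_proteins": len(sub)}
        for col in ann.columns:
            row[f"n_{col}"] = int(sub[col].sum())
            row[f"frac_{col}"] = sub[col].mean() if len(sub) else 0.0
        out.append(row)
    return pd.DataFrame(out).set_index("cluster")
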