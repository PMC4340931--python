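"""Transcript clustering and eigengene summarization.

Standardized transcripts are partitioned by K-means (Lloyd's algorithm,
k-means++ seeding, many restarts) and each cluster is summarized by its first
eigengene: the leading left singular vector of the samples x member-genes
submatrix, i.e. the cluster's principal axis of variation across samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data_io import standardize

__all__ = [
    "ClusterAssignment",
    "Eigengene",
    "kmeans_cluster",
    "extract_eigengene",
    "eigengene_matrix",
    "cluster_summary",
    "write_membership",
]


@dataclass
class ClusterAssignment:
    """Per-gene cluster labels in 1..K plus the restart-minimized objective."""

    labels: np.ndarray
    K: int
    objective: float
    n_init: int
    seed: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K + 1)[1:]


@dataclass
class Eigengene:
    """First eigengene of one cluster: a per-sample score vector plus diagnostics.

    ``scores`` is the unit-norm leading left singular vector (length n_samples);
    ``explained_fraction`` is D(1)^2 / sum D(i)^2; ``member_r2`` is each member
    gene's squared Pearson correlation with the eigengene.
    """

    cluster_id: int
    scores: np.ndarray
    explained_fraction: float
    member_r2: np.ndarray


def kmeans_cluster(
    values: np.ndarray, K: int, n_init: int = 1000, seed: int = 0
) -> ClusterAssignment:
    """K-means over genes (rows) with ``n_init`` random restarts.

    Returns the assignment minimizing within-cluster sum of squares over all
    restarts; deterministic for a fixed seed. Labels are 1-based cluster ids
    and every cluster is non-empty.
    """
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    if not 1 <= K <= n_genes:
        raise ValueError(f"K={K} must lie in 1..{n_genes} (number of genes)")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels0 = km.fit_predict(values)
    sizes = np.bincount(labels0, minlength=K)
    if (sizes == 0).any():  # sklearn relocates empty clusters; guard anyway
        raise RuntimeError(f"empty cluster(s) after K-means: {np.flatnonzero(sizes == 0)}")
    return ClusterAssignment(
        labels=labels0 + 1, K=K, objective=float(km.inertia_), n_init=n_init, seed=seed
    )


def extract_eigengene(Y_cluster: np.ndarray, cluster_id: int = 0) -> Eigengene:
    """First eigengene of one cluster from the samples x member-genes submatrix.

    SVD gives Y^j = U D V^T; the eigengene is U(:,1). Its sign is fixed so the
    eigengene correlates positively with the majority of member genes (ties
    broken by positive correlation with the lowest-index member), which makes
    downstream edge signs reproducible.
    """
    Y = np.asarray(Y_cluster, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("cluster submatrix must be 2-D samples x members")
    if not np.any(Y):
        raise ValueError("all-zero cluster submatrix has no eigengene")
    U, D, _ = np.linalg.svd(Y, full_matrices=False)
    scores = U[:, 0]
    explained = float(D[0] ** 2 / np.sum(D**2))

    centered = Y - Y.mean(axis=0)
    s_centered = scores - scores.mean()
    denom = np.linalg.norm(centered, axis=0) * np.linalg.norm(s_centered)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, centered.T @ s_centered / denom, 0.0)
    n_pos, n_neg = int(np.sum(corr > 0)), int(np.sum(corr < 0))
    if n_neg > n_pos or (n_neg == n_pos and corr[0] < 0):
        scores = -scores
        corr = -corr
    return Eigengene(
        cluster_id=cluster_id,
        scores=scores,
        explained_fraction=explained,
        member_r2=np.clip(corr**2, 0.0, 1.0),
    )


def eigengene_matrix(
    values_genes_by_samples: np.ndarray, assignment: ClusterAssignment
) -> tuple[np.ndarray, list[Eigengene]]:
    """Extract all K eigengenes and return them re-standardized as n_samples x K.

    Each eigengene is re-scaled to mean 0 / variance 1 across samples before it
    enters regression or the heatmap, matching the treatment of the condition
    variables.
    """
    Y = np.asarray(values_genes_by_samples, dtype=float)
    eigengenes: list[Eigengene] = []
    cols = []
    for cid in range(1, assignment.K + 1):
        members = assignment.members(cid)
        eg = extract_eigengene(Y[members, :].T, cluster_id=cid)
        eigengenes.append(eg)
        cols.append(eg.scores)
    E = np.column_stack(cols)
    E = standardize(E, axis="columns")
    return E, eigengenes


def cluster_summary(
    assignment: ClusterAssignment, eigengenes: list[Eigengene]
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster size and mean member R^2, plus global diagnostics.

    The global ``mean_r2`` is the mean over all genes (clusters weighted by
    size), the coherence diagnostic reported for the full pipeline.
    """
    sizes = assignment.sizes()
    per_cluster = pd.DataFrame(
        {
            "cluster": np.arange(1, assignment.K + 1),
            "size": sizes,
            "mean_r2": [float(np.mean(eg.member_r2)) for eg in eigengenes],
            "explained_fraction": [eg.explained_fraction for eg in eigengenes],
        }
    )
    all_r2 = np.concatenate([eg.member_r2 for eg in eigengenes])
    global_stats = {
        "n_clusters": int(assignment.K),
        "n_genes": int(sizes.sum()),
        "median_size": float(np.median(sizes)),
        "sd_size": float(np.std(sizes, ddof=1)) if assignment.K > 1 else 0.0,
        "min_size": int(sizes.min()),
        "max_size": int(sizes.max()),
        "mean_r2": float(np.mean(all_r2)),
        "objective": float(assignment.objective),
    }
    return per_cluster, global_stats


def write_membership(
    gene_ids: list[str],
    assignment: ClusterAssignment,
    eigengenes: list[Eigengene],
    path,
    delimiter: str = "\t",
) -> None:
    """Write gene id, cluster id, and member R^2 as a membership table."""
    r2 = np.empty(len(gene_ids))
    for eg in eigengenes:
        members = assignment.members(eg.cluster_id)
        r2[members] = eg.member_r2
    pd.DataFrame(
        {"gene": gene_ids, "cluster": assignment.labels, "member_r2": r2}
    ).to_csv(path, sep=delimiter, index=False)
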