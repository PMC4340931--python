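"""Soft-thresholded correlation network baseline (WGCNA-style).

Builds candidate networks G^eta = |cor(Z)|^eta over the combined gene +
condition matrix Z = [Y, X], selects the power whose weighted degree
distribution is most scale-free, and clusters variables with partitioning
around medoids (PAM) on the induced distance 1 - G^eta. This captures strong
*marginal* dependencies, the comparison point for the conditional-dependence
network the main pipeline infers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusterAssignment

__all__ = [
    "SoftNetwork",
    "soft_threshold",
    "scale_free_r2",
    "select_power",
    "pam_cluster",
    "OverlapReport",
    "compare_memberships",
    "neighborhood_genes",
]


@dataclass
class SoftNetwork:
    eta: int
    adjacency: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]
    scale_free_r2: float


def soft_threshold(Z: np.ndarray, eta: int) -> SoftNetwork:
    """Adjacency |cor(Z)|^eta over the columns of the samples x variables matrix."""
    if eta < 1:
        raise ValueError("eta must be >= 1")
    Z = np.asarray(Z, dtype=float)
    adjacency = np.abs(np.corrcoef(Z.T)) ** eta
    np.fill_diagonal(adjacency, 1.0)
    return SoftNetwork(eta=int(eta), adjacency=adjacency, scale_free_r2=scale_free_r2(adjacency))


def scale_free_r2(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) vs log10(connectivity) over log-binned degrees.

    Connectivity is the weighted degree (row sum minus the diagonal). Degrees
    are discretized into ``n_bins`` equal-width bins; each occupied bin
    contributes its mean connectivity and occupancy fraction, and the fit is
    an ordinary least-squares line of log10(frequency) on log10(mean k).
    Equal-width (rather than logarithmic) bins keep single-hub tail bins from
    flattening the fit. Returns 0 when fewer than 3 occupied bins remain.
    """
    k = adjacency.sum(axis=1) - np.diag(adjacency)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) < 1e-12:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            xs.append(np.log10(np.mean(k[sel])))
            ys.append(np.log10(np.mean(sel)))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def select_power(Z: np.ndarray, powers=range(1, 11)) -> int:
    """Return the eta in ``powers`` maximizing the scale-free R^2 (ties -> smallest)."""
    best_eta, best_r2 = None, -np.inf
    for eta in powers:
        r2 = soft_threshold(Z, eta).scale_free_r2
        if r2 > best_r2 + 1e-12:
            best_eta, best_r2 = eta, r2
    return int(best_eta)


def pam_cluster(distance: np.ndarray, K: int, max_swaps: int = 200) -> ClusterAssignment:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Deterministic: BUILD seeds medoids greedily (first medoid minimizes total
    distance, subsequent ones maximize cost reduction); SWAP applies the best
    improving (medoid, non-medoid) exchange until none improves or
    ``max_swaps`` is reached. Objective: total distance of points to their
    nearest medoid.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise ValueError("distance must have a zero diagonal")
    if not 1 <= K <= n:
        raise ValueError(f"K={K} out of range 1..{n}")

    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < K:
        gains = np.sum(np.maximum(nearest[:, None] - D, 0.0), axis=0)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, D[:, new])

    def total_cost(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    for _ in range(max_swaps):
        best = (0.0, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = total_cost(trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        cost += best[0]

    labels = np.argmin(D[:, medoids], axis=1) + 1
    return ClusterAssignment(labels=labels, K=K, objective=cost, n_init=1, seed=0)


@dataclass
class OverlapReport:
    intersection: set[str]
    only_a: set[str]
    only_b: set[str]


def compare_memberships(genes_a: set[str], genes_b: set[str]) -> OverlapReport:
    """Overlap between the gene sets two methods attach to a focus variable."""
    a, b = set(genes_a), set(genes_b)
    return OverlapReport(intersection=a & b, only_a=a - b, only_b=b - a)


def neighborhood_genes(
    graph, cluster_labels: np.ndarray, gene_ids: list[str], focus: str
) -> set[str]:
    """Genes belonging to clusters adjacent to ``focus`` in a called network.

    ``graph`` is a SpineGraph whose eigengene node ids follow the C<j>
    convention; cluster j's genes are those with label j.
    """
    neighbors = set()
    for e in graph.edges:
        if e.node_a == focus:
            neighbors.add(e.node_b)
        elif e.node_b == focus:
            neighbors.add(e.node_a)
    out: set[str] = set()
    for node in neighbors:
        if node.startswith("C") and node[1:].isdigit():
            j = int(node[1:])
            out |= {gene_ids[g] for g in np.flatnonzero(cluster_labels == j)}
    return out
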