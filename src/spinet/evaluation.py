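"""End-to-end evaluation harnesses over synthetic datasets with known truth.

These helpers run the full pipeline (clustering -> eigengenes -> network) on
a generated dataset, map the estimated clusters back onto the planted ones by
maximum-overlap assignment, and score the called edges against the planted
precision-matrix supports. They back both the test suite and the
reproducibility script.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import cluster, network
from .data_io import standardize_conditions
from .simulate import SyntheticDataset

__all__ = ["EdgeMetrics", "pipeline_edge_sets", "edge_metrics", "null_edge_count"]


@dataclass
class EdgeMetrics:
    precision: float
    recall: float
    n_called: int
    n_true: int
    true_positives: int


def pipeline_edge_sets(
    dataset: SyntheticDataset,
    kmeans_inits: int = 20,
    vbsr_restarts: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[set, set]:
    """Run clustering + network inference; return (called, planted) edge sets.

    Edges are canonical tuples: ("zz", j, k) with j < k for eigengene pairs and
    ("zx", cluster, condition) for condition links, all 1-based and expressed
    in the *planted* cluster numbering (estimated clusters are matched to
    planted ones by maximum-overlap linear assignment).
    """
    truth = dataset.truth
    K = truth.theta_zz.shape[0]
    assignment = cluster.kmeans_cluster(
        dataset.expression.values, K=K, n_init=kmeans_inits, seed=seed
    )
    E, _ = cluster.eigengene_matrix(dataset.expression.values, assignment)
    contingency = np.zeros((K, K))
    for true_label, est_label in zip(truth.labels, assignment.labels):
        contingency[true_label - 1, est_label - 1] += 1
    rows, cols = linear_sum_assignment(-contingency)
    est_to_true = {c + 1: r + 1 for r, c in zip(rows, cols)}

    X = standardize_conditions(dataset.conditions)
    model = network.fit_all_neighborhoods(
        E,
        X,
        condition_ids=dataset.conditions.variable_ids,
        n_restarts=vbsr_restarts,
        seed=seed,
        alpha=alpha,
    )
    graph = network.call_edges(model)
    called: set = set()
    for e in graph.edges:
        if e.kind == "eigengene-eigengene":
            a = est_to_true[int(e.node_a[1:])]
            b = est_to_true[int(e.node_b[1:])]
            called.add(("zz", min(a, b), max(a, b)))
        else:
            cond = dataset.conditions.variable_ids.index(e.node_a) + 1
            called.add(("zx", est_to_true[int(e.node_b[1:])], cond))
    planted = {("zz", j, k) for j, k in truth.zz_edges()} | {
        ("zx", j, l) for j, l in truth.zx_edges()
    }
    return called, planted


def edge_metrics(called: set, planted: set) -> EdgeMetrics:
    tp = len(called & planted)
    return EdgeMetrics(
        precision=tp / len(called) if called else 1.0,
        recall=tp / len(planted) if planted else 1.0,
        n_called=len(called),
        n_true=len(planted),
        true_positives=tp,
    )


def null_edge_count(dataset: SyntheticDataset, **kwargs) -> int:
    """Number of edges the full pipeline calls on a (null) dataset."""
    called, _ = pipeline_edge_sets(dataset, **kwargs)
    return len(called)
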