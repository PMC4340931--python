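"""Sparse eigengene network assembly by neighborhood selection.

Every eigengene is regressed (vbsr) on the other K-1 eigengenes plus all C
condition variables; condition variables are predictors only, never responses.
Eigengene-pair evidence from the two regression directions is combined by
geometric averaging of p-values, condition->eigengene evidence is single
direction, and edges are called at a Bonferroni threshold alpha / n_tests with
n_tests = (K + C) * K.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .vbsr import PenaltyConfig, compute_penalty, pvalue_from_z, vbsr_fit

__all__ = [
    "SpineModel",
    "SpineEdge",
    "SpineGraph",
    "fit_all_neighborhoods",
    "combine_bidirectional",
    "call_edges",
    "network_stats",
    "write_edges",
    "read_edges",
    "write_nodes",
]

P_FLOOR = 1e-300


@dataclass
class SpineModel:
    """Directed Z-statistics and aggregated p-values for the full neighborhood fit.

    ``z_matrix`` is K x (K + C): row j holds the Z-statistics of regression of
    eigengene j on predictors ordered [eigengenes, conditions]; the j-th
    eigengene column of row j is NaN (a variable never predicts itself).
    """

    eigengene_ids: list[str]
    condition_ids: list[str]
    z_matrix: np.ndarray
    p_directed: np.ndarray
    p_avg: np.ndarray
    condition_p: np.ndarray
    alpha: float
    n_tests: int
    penalty: PenaltyConfig

    @property
    def K(self) -> int:
        return len(self.eigengene_ids)

    @property
    def C(self) -> int:
        return len(self.condition_ids)

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests


@dataclass
class SpineEdge:
    node_a: str
    node_b: str
    kind: str  # "eigengene-eigengene" or "condition-eigengene"
    sign: int
    p_value: float
    discordant: bool = False


@dataclass
class SpineGraph:
    """Undirected edge list over eigengene and condition nodes, with attributes."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[SpineEdge] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for nid, attrs in self.nodes.items():
            g.add_node(nid, **attrs)
        for e in self.edges:
            g.add_edge(
                e.node_a, e.node_b, kind=e.kind, sign=e.sign,
                p_value=e.p_value, discordant=e.discordant,
            )
        return g

    def connected_node_ids(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.node_a)
            out.add(e.node_b)
        return out


def _regression_seed(seed: int, j: int) -> int:
    """Derive a per-regression seed deterministically from the master seed."""
    return int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31 - 1))


def fit_all_neighborhoods(
    E: np.ndarray,
    X: np.ndarray | None,
    eigengene_ids: list[str] | None = None,
    condition_ids: list[str] | None = None,
    penalty: PenaltyConfig | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> SpineModel:
    """Run one vbsr regression per eigengene against all other variables.

    ``E`` is n x K standardized eigengenes, ``X`` n x C standardized condition
    variables (or None for a conditions-free network). The penalty defaults to
    ``compute_penalty(m = K - 1 + C, n)`` — the per-regression predictor count.
    """
    E = np.asarray(E, dtype=float)
    X = None if X is None else np.asarray(X, dtype=float)
    n, K = E.shape
    if K < 2:
        raise ValueError("need at least two eigengenes")
    C = 0 if X is None else X.shape[1]
    if X is not None and X.shape[0] != n:
        raise ValueError("E and X sample counts differ")
    if eigengene_ids is None:
        eigengene_ids = [f"C{j + 1}" for j in range(K)]
    if condition_ids is None:
        condition_ids = [f"X{l + 1}" for l in range(C)]
    if penalty is None:
        penalty = compute_penalty(m=K - 1 + C, n=n)

    # Warn (not fail) on duplicated eigengene columns: vbsr tolerates collinearity.
    corr = np.corrcoef(E.T)
    dup = np.argwhere(np.triu(np.abs(corr), 1) > 1 - 1e-10)
    if dup.size:
        import warnings

        warnings.warn(f"near-duplicate eigengene pairs: {dup.tolist()}", stacklevel=2)

    z = np.full((K, K + C), np.nan)
    for j in range(K):
        others = [k for k in range(K) if k != j]
        pred = E[:, others] if X is None else np.column_stack([E[:, others], X])
        fit = vbsr_fit(
            E[:, j], pred, penalty=penalty,
            n_restarts=n_restarts, seed=_regression_seed(seed, j),
        )
        z[j, others] = fit.z_stat[: K - 1]
        if C:
            z[j, K:] = fit.z_stat[K - 1 :]

    p_directed = np.full_like(z, np.nan)
    finite = np.isfinite(z)
    p_directed[finite] = pvalue_from_z(z[finite])
    p_avg = np.full((K, K), np.nan)
    for j in range(K):
        for k in range(j + 1, K):
            p_avg[j, k] = p_avg[k, j] = combine_bidirectional(
                p_directed[j, k], p_directed[k, j]
            )
    condition_p = p_directed[:, K:] if C else np.empty((K, 0))
    return SpineModel(
        eigengene_ids=list(eigengene_ids),
        condition_ids=list(condition_ids),
        z_matrix=z,
        p_directed=p_directed,
        p_avg=p_avg,
        condition_p=condition_p,
        alpha=alpha,
        n_tests=(K + C) * K,
        penalty=penalty,
    )


def combine_bidirectional(p_jk: float, p_kj: float) -> float:
    """Geometric mean of the two directed p-values: 10^(mean of log10 p).

    Equals sqrt(p_jk * p_kj); symmetric and idempotent. Zero p-values are
    floored at 1e-300 before taking logs.
    """
    pj = max(float(p_jk), P_FLOOR)
    pk = max(float(p_kj), P_FLOOR)
    if not (0.0 < pj <= 1.0 and 0.0 < pk <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(10.0 ** (0.5 * (np.log10(pj) + np.log10(pk))))


def call_edges(
    model: SpineModel,
    alpha: float | None = None,
    node_attrs: dict[str, dict] | None = None,
) -> SpineGraph:
    """Call network edges at the Bonferroni threshold alpha / n_tests.

    Eigengene pairs: edge iff the geometrically averaged p <= threshold, with
    sign taken from the more significant direction's Z (discordant directed
    signs are kept but flagged). Condition->eigengene: edge iff the single
    directed p <= threshold, equivalently |Z| > Z_crit.
    """
    if alpha is None:
        alpha = model.alpha
    threshold = alpha / model.n_tests
    K, C = model.K, model.C
    graph = SpineGraph()
    for j, nid in enumerate(model.eigengene_ids):
        graph.nodes[nid] = {"kind": "eigengene", **(node_attrs or {}).get(nid, {})}
    for l, nid in enumerate(model.condition_ids):
        graph.nodes[nid] = {"kind": "condition", **(node_attrs or {}).get(nid, {})}

    for j in range(K):
        for k in range(j + 1, K):
            p = model.p_avg[j, k]
            if p <= threshold:
                zjk, zkj = model.z_matrix[j, k], model.z_matrix[k, j]
                primary = zjk if model.p_directed[j, k] <= model.p_directed[k, j] else zkj
                sign = 1 if primary >= 0 else -1
                discordant = bool(np.sign(zjk) * np.sign(zkj) < 0)
                graph.edges.append(
                    SpineEdge(
                        model.eigengene_ids[j], model.eigengene_ids[k],
                        "eigengene-eigengene", sign, float(p), discordant,
                    )
                )
    for j in range(K):
        for l in range(C):
            p = model.condition_p[j, l]
            if p <= threshold:
                sign = 1 if model.z_matrix[j, K + l] >= 0 else -1
                graph.edges.append(
                    SpineEdge(
                        model.condition_ids[l], model.eigengene_ids[j],
                        "condition-eigengene", sign, float(p),
                    )
                )
    return graph


def network_stats(graph: SpineGraph, total_variables: int | None = None) -> dict:
    """Connectedness summary: node counts, mean degrees, components.

    ``total_variables`` is the number of variables that entered the model
    (K + C); isolated variables are those with no called edge. Mean degrees are
    computed over connected nodes only, overall and restricted to condition
    nodes, matching how the network is usually reported.
    """
    g = graph.to_networkx()
    connected = graph.connected_node_ids()
    if total_variables is None:
        total_variables = len(graph.nodes)
    degrees = dict(g.degree())
    conn_deg = [degrees[n] for n in connected]
    cond_conn = [n for n in connected if graph.nodes.get(n, {}).get("kind") == "condition"]
    sub = g.subgraph(connected)
    return {
        "n_edges": len(graph.edges),
        "n_connected_nodes": len(connected),
        "n_isolated_variables": int(total_variables) - len(connected),
        "mean_degree": float(np.mean(conn_deg)) if conn_deg else 0.0,
        "condition_mean_degree": (
            float(np.mean([degrees[n] for n in cond_conn])) if cond_conn else 0.0
        ),
        "n_connected_condition_nodes": len(cond_conn),
        "n_components": nx.number_connected_components(sub) if connected else 0,
    }


def write_edges(graph: SpineGraph, path, delimiter: str = "\t") -> None:
    pd.DataFrame(
        [
            {
                "node_a": e.node_a, "node_b": e.node_b, "edge_kind": e.kind,
                "sign": e.sign, "p_avg": e.p_value, "discordant": e.discordant,
            }
            for e in graph.edges
        ],
        columns=["node_a", "node_b", "edge_kind", "sign", "p_avg", "discordant"],
    ).to_csv(path, sep=delimiter, index=False)


def read_edges(path, delimiter: str = "\t") -> SpineGraph:
    df = pd.read_csv(path, sep=delimiter)
    graph = SpineGraph()
    for _, row in df.iterrows():
        e = SpineEdge(
            str(row["node_a"]), str(row["node_b"]), str(row["edge_kind"]),
            int(row["sign"]), float(row["p_avg"]), bool(row["discordant"]),
        )
        graph.edges.append(e)
        a_kind, b_kind = ("condition", "eigengene") if e.kind.startswith("condition") else (
            "eigengene", "eigengene"
        )
        graph.nodes.setdefault(e.node_a, {"kind": a_kind})
        graph.nodes.setdefault(e.node_b, {"kind": b_kind})
    return graph


def write_nodes(graph: SpineGraph, path, delimiter: str = "\t") -> None:
    rows = []
    for nid, attrs in graph.nodes.items():
        rows.append({"id": nid, **attrs})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
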