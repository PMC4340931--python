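import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinet.data_io import standardize
from spinet.network import (
    SpineEdge,
    SpineGraph,
    SpineModel,
    call_edges,
    combine_bidirectional,
    fit_all_neighborhoods,
    network_stats,
    read_edges,
    write_edges,
)
from spinet.vbsr import compute_penalty


class TestCombineBidirectional:
    def test_identities(self):
        assert combine_bidirectional(0.3, 0.3) == pytest.approx(0.3)
        assert combine_bidirectional(1e-4, 1e-8) == pytest.approx(1e-6)
        assert combine_bidirectional(1.0, 0.04) == pytest.approx(0.2)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=1e-280, max_value=1.0),
        st.floats(min_value=1e-280, max_value=1.0),
    )
    def test_symmetric_and_bounded(self, p1, p2):
        combined = combine_bidirectional(p1, p2)
        assert combined == combine_bidirectional(p2, p1)
        assert min(p1, p2) * (1 - 1e-12) <= combined <= max(p1, p2) * (1 + 1e-12)

    def test_zero_floored(self):
        out = combine_bidirectional(0.0, 1e-10)
        assert out == pytest.approx(np.sqrt(1e-300 * 1e-10))


def _null_model(K=3, C=1):
    z = np.full((K, K + C), 0.1)
    np.fill_diagonal(z[:, :K], np.nan)
    p = np.full_like(z, 0.92)
    p_avg = np.full((K, K), 0.92)
    np.fill_diagonal(p_avg, np.nan)
    return SpineModel(
        eigengene_ids=[f"C{j+1}" for j in range(K)],
        condition_ids=[f"X{l+1}" for l in range(C)],
        z_matrix=z, p_directed=p, p_avg=p_avg, condition_p=p[:, K:],
        alpha=0.05, n_tests=(K + C) * K, penalty=compute_penalty(K - 1 + C, 10),
    )


def test_all_null_gives_empty_graph():
    graph = call_edges(_null_model())
    assert graph.edges == []


def test_bonferroni_divisor_convention():
    model = _null_model(K=3, C=1)
    assert model.n_tests == 12
    assert model.threshold == pytest.approx(0.05 / 12)


def test_strong_pair_detected_both_directions(rng):
    n = 200
    z1 = rng.standard_normal(n)
    z2 = 0.9 * z1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
    E = standardize(np.column_stack([z1, z2]), "columns")
    model = fit_all_neighborhoods(E, None, n_restarts=5, seed=0)
    assert model.p_directed[0, 1] < 0.05
    assert model.p_directed[1, 0] < 0.05
    graph = call_edges(model)
    assert [(e.node_a, e.node_b) for e in graph.edges] == [("C1", "C2")]
    assert graph.edges[0].sign == 1


def test_chain_cascade_filtered(rng):
    """z1 -> z2 -> z3: the z1-z3 marginal correlation is a cascade artifact;
    conditioning on z2 must remove it in at least 90% of replicates."""
    spurious = 0
    reps = 100
    for rep in range(reps):
        r = np.random.default_rng([17, rep])
        n = 200
        z1 = r.standard_normal(n)
        z2 = 0.9 * z1 + np.sqrt(1 - 0.81) * r.standard_normal(n)
        z3 = 0.9 * z2 + np.sqrt(1 - 0.81) * r.standard_normal(n)
        E = standardize(np.column_stack([z1, z2, z3]), "columns")
        model = fit_all_neighborhoods(E, None, n_restarts=3, seed=rep)
        graph = call_edges(model)
        pairs = {(e.node_a, e.node_b) for e in graph.edges}
        spurious += ("C1", "C3") in pairs
    assert spurious / reps <= 0.10


def test_conditions_are_predictors_only(rng):
    E = standardize(rng.standard_normal((60, 4)), "columns")
    X = standardize(rng.standard_normal((60, 3)), "columns")
    model = fit_all_neighborhoods(E, X, n_restarts=3, seed=1)
    assert model.z_matrix.shape == (4, 7)  # one row per eigengene only
    graph = call_edges(model, alpha=1e6)  # force every test into an edge
    kinds = {(graph.nodes[e.node_a]["kind"], graph.nodes[e.node_b]["kind"])
             for e in graph.edges}
    assert ("condition", "condition") not in kinds


def test_p_avg_symmetric_and_diag_nan(rng):
    E = standardize(rng.standard_normal((50, 5)), "columns")
    model = fit_all_neighborhoods(E, None, n_restarts=3, seed=2)
    off = ~np.eye(5, dtype=bool)
    np.testing.assert_allclose(model.p_avg, model.p_avg.T, equal_nan=True)
    assert np.isnan(np.diag(model.p_avg)).all()
    assert np.isnan(np.diag(model.z_matrix[:, :5])).all()
    assert np.isfinite(model.z_matrix[:, :5][off]).all()


def test_sample_permutation_invariance(rng):
    n = 80
    E = standardize(rng.standard_normal((n, 4)), "columns")
    X = standardize(rng.standard_normal((n, 2)), "columns")
    E[:, 1] = 0.7 * E[:, 0] + 0.3 * E[:, 1]
    E = standardize(E, "columns")
    perm = rng.permutation(n)
    m1 = fit_all_neighborhoods(E, X, n_restarts=5, seed=3)
    m2 = fit_all_neighborhoods(E[perm], X[perm], n_restarts=5, seed=3)
    np.testing.assert_allclose(m1.z_matrix, m2.z_matrix, atol=1e-8, equal_nan=True)
    e1 = {(e.node_a, e.node_b, e.sign) for e in call_edges(m1).edges}
    e2 = {(e.node_a, e.node_b, e.sign) for e in call_edges(m2).edges}
    assert e1 == e2


def test_network_stats_single_edge():
    graph = SpineGraph(
        nodes={"C1": {"kind": "eigengene"}, "C2": {"kind": "eigengene"}},
        edges=[SpineEdge("C1", "C2", "eigengene-eigengene", 1, 1e-9)],
    )
    stats = network_stats(graph, total_variables=5)
    assert stats["n_connected_nodes"] == 2
    assert stats["n_isolated_variables"] == 3
    assert stats["mean_degree"] == pytest.approx(1.0)
    assert stats["n_components"] == 1


def test_network_stats_known_degree_sequence(rng):
    """Star over 4 eigengenes plus one condition pendant: exact mean degrees."""
    edges = [
        SpineEdge("C1", "C2", "eigengene-eigengene", 1, 1e-9),
        SpineEdge("C1", "C3", "eigengene-eigengene", -1, 1e-9),
        SpineEdge("C1", "C4", "eigengene-eigengene", 1, 1e-9),
        SpineEdge("X1", "C1", "condition-eigengene", 1, 1e-9),
    ]
    nodes = {f"C{j}": {"kind": "eigengene"} for j in range(1, 5)}
    nodes["X1"] = {"kind": "condition"}
    stats = network_stats(SpineGraph(nodes=nodes, edges=edges), total_variables=7)
    assert stats["mean_degree"] == pytest.approx(8 / 5)
    assert stats["condition_mean_degree"] == pytest.approx(1.0)
    assert stats["n_isolated_variables"] == 2


def test_edge_list_round_trip(tmp_path):
    graph = SpineGraph(
        nodes={"C1": {"kind": "eigengene"}, "C2": {"kind": "eigengene"},
               "X1": {"kind": "condition"}},
        edges=[
            SpineEdge("C1", "C2", "eigengene-eigengene", -1, 2.5e-8, True),
            SpineEdge("X1", "C2", "condition-eigengene", 1, 1e-12),
        ],
    )
    path = tmp_path / "edges.tsv"
    write_edges(graph, path)
    back = read_edges(path)
    assert [(e.node_a, e.node_b, e.sign, e.kind, e.discordant) for e in back.edges] == [
        (e.node_a, e.node_b, e.sign, e.kind, e.discordant) for e in graph.edges
    ]
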