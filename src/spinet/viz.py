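"""Network export (SIF / GraphML / TSV) and the ordered eigengene heatmap."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage

from .network import SpineGraph, write_edges

__all__ = ["export_graph", "ordered_heatmap", "row_blocks_from_linkage"]


def export_graph(graph: SpineGraph, path, format: str = "sif") -> None:
    """Write the network for external graph viewers.

    ``sif``: one ``node_a <edge_kind> node_b`` line per edge. ``graphml``:
    node attributes (kind, member_count, annotation proportions when present)
    and edge attributes (sign, p_value) so that negative relationships stay
    distinguishable (sign = -1) after import. ``tsv``: the audit edge list.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "sif":
        lines = [f"{e.node_a}\t{e.kind}\t{e.node_b}" for e in graph.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = graph.to_networkx()
        for _, _, attrs in g.edges(data=True):
            attrs["sign"] = int(attrs.get("sign", 1))
            attrs["discordant"] = int(bool(attrs.get("discordant", False)))
        nx.write_graphml(g, path)
    elif fmt in ("tsv", "edge-tsv"):
        write_edges(graph, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def row_blocks_from_linkage(link: np.ndarray, leaf_order: list[int], gap_fraction: float):
    """Split dendrogram leaves (in display order) into blocks.

    Leaves whose merge happens above ``gap_fraction * max merge height`` fall
    into different blocks; with gap_fraction = 1.0 everything stays in one
    block. Returns a list of lists of leaf indices in display order.
    """
    heights = link[:, 2]
    threshold = gap_fraction * float(heights.max()) if heights.size else 0.0
    flat = fcluster(link, t=threshold, criterion="distance")
    blocks: list[list[int]] = []
    prev = None
    for leaf in leaf_order:
        if prev is None or flat[leaf] != prev:
            blocks.append([leaf])
        else:
            blocks[-1].append(leaf)
        prev = flat[leaf]
    return blocks


def ordered_heatmap(
    variables_by_samples: np.ndarray,
    variable_ids: list[str],
    sample_ids: list[str],
    path=None,
    gap_fraction: float = 0.9,
    method: str = "complete",
    metric: str = "euclidean",
):
    """Hierarchically ordered heatmap of standardized variables x experiments.

    Rows (variables) and columns (experiments) are each ordered by
    agglomerative clustering (Euclidean distance, complete linkage by
    default). Rows are segregated into blocks — rendered with white gaps —
    wherever the merge height separating adjacent ordered groups exceeds
    ``gap_fraction`` times the maximum merge height. The diverging color
    scale runs blue (negative) through white to red (positive).

    Returns (row_order, col_order, row_blocks); writes the figure when
    ``path`` is given.
    """
    M = np.asarray(variables_by_samples, dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 variables and 2 samples")
    row_link = linkage(M, method=method, metric=metric)
    col_link = linkage(M.T, method=method, metric=metric)
    row_order = dendrogram(row_link, no_plot=True)["leaves"]
    col_order = dendrogram(col_link, no_plot=True)["leaves"]
    blocks = row_blocks_from_linkage(row_link, row_order, gap_fraction)

    if path is not None:
        # interleave NaN gap rows between blocks; NaN renders as background
        gap = np.full((1, M.shape[1]), np.nan)
        pieces, labels = [], []
        for i, block in enumerate(blocks):
            if i:
                pieces.append(gap)
                labels.append("")
            pieces.append(M[np.ix_(block, col_order)])
            labels.extend(variable_ids[r] for r in block)
        stacked = np.vstack(pieces)
        vmax = np.nanmax(np.abs(stacked))
        fig, ax = plt.subplots(
            figsize=(max(6.0, 0.18 * M.shape[1]), max(4.0, 0.12 * stacked.shape[0]))
        )
        im = ax.imshow(stacked, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=4)
        ax.set_xticks(range(M.shape[1]))
        ax.set_xticklabels([sample_ids[c] for c in col_order], fontsize=4, rotation=90)
        fig.colorbar(im, ax=ax, shrink=0.5)
        fig.tight_layout()
        fig.savefig(path, dpi=200)
        plt.close(fig)
    return row_order, col_order, blocks
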