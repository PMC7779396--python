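"""Anatomical summaries of a predictive edge set.

Maps an edge set (0-based node-index pairs) onto an atlas lookup table to
produce label-by-label edge-count matrices (at the macroscale-region or
canonical-network level), node degrees, and a ranked top-k node report in
the usual "coordinate, lobe, degree" table layout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Edge, InvalidParameterError, NodeAtlas, RegionEdgeCounts


def _ordered_labels(values: np.ndarray) -> list[str]:
    """Labels in order of first appearance in the atlas."""
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(str(v), None)
    return list(seen)


def region_edge_counts(
    edges: set[Edge] | list[Edge],
    atlas: NodeAtlas,
    level: str = "region",
) -> RegionEdgeCounts:
    """Count edges within and between each pair of labels.

    Each edge increments the cell for its endpoint-label pair; within-label
    edges land on the diagonal, between-label edges symmetrically on both
    off-diagonal cells. The diagonal plus one off-diagonal triangle always
    totals the number of input edges.
    """
    if level not in ("region", "network"):
        raise InvalidParameterError(f"level must be 'region' or 'network', got {level!r}")
    node_labels = atlas.regions() if level == "region" else atlas.networks()
    labels = _ordered_labels(node_labels)
    pos = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    n = atlas.n_nodes
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise InvalidParameterError(f"edge node {max(i, j)} not in the {n}-node atlas")
        a, b = pos[str(node_labels[i])], pos[str(node_labels[j])]
        if a == b:
            counts[a, a] += 1
        else:
            counts[a, b] += 1
            counts[b, a] += 1
    return RegionEdgeCounts(labels=labels, counts=counts)


def node_degree(edges: set[Edge] | list[Edge], n_nodes: int) -> np.ndarray:
    """Number of selected edges incident to each node (handshake: sums to 2|E|)."""
    deg = np.zeros(n_nodes, dtype=int)
    for i, j in edges:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise InvalidParameterError(f"edge ({i},{j}) outside {n_nodes} nodes")
        deg[i] += 1
        deg[j] += 1
    return deg


def top_nodes(degrees: np.ndarray, k: int, atlas: NodeAtlas) -> pd.DataFrame:
    """The k highest-degree nodes with their anatomical labels.

    Ties are broken deterministically by ascending node index; the ``tied``
    column flags nodes whose degree is shared with at least one other node,
    so a reader can see when the k-th place was not unique.
    """
    degrees = np.asarray(degrees)
    n = degrees.size
    if k > n:
        raise InvalidParameterError(f"k={k} exceeds n_nodes={n}")
    if n != atlas.n_nodes:
        raise InvalidParameterError("degree vector and atlas disagree on node count")
    order = np.lexsort((np.arange(n), -degrees))[:k]
    counts = pd.Series(degrees).value_counts()
    rows = atlas.table.iloc[order].copy()
    rows["degree"] = degrees[order]
    rows["tied"] = [counts[d] > 1 for d in degrees[order]]
    cols = ["node_id"]
    for c in ("x", "y", "z"):
        if c in rows.columns:
            cols.append(c)
    cols += ["region", "network", "degree", "tied"]
    return rows[cols].reset_index(drop=True)
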