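"""Alternative null models used as comparison foils.

Two simpler shuffling schemes that, unlike SET, ignore the relationship
between cell size/shape and neighbor count: re-marking cell identities on a
honeycomb grid of identical hexagons, and re-marking identities on the
original segmentation's adjacency graph.  Both are known to be biased when
the two populations differ in size or shape; they are provided to reproduce
that bias, not as recommended analyses.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .stats import NullDistribution, empirical_pvalue

__all__ = ["hex_grid_graph", "hex_shuffle_null", "segmentation_shuffle_null"]


def hex_grid_graph(n_cells: int) -> nx.Graph:
    """Near-square honeycomb of exactly ``n_cells`` pointy-top hexagons.

    Cells fill row-major on an odd-r offset grid; edges join hexagons
    sharing a side (up to 6 neighbors each).
    """
    if n_cells < 7:
        raise ValueError("need at least 7 hexagons for any interior cell")
    cols = max(2, round(math.sqrt(n_cells)))
    rows = math.ceil(n_cells / cols)
    idx = {}
    k = 0
    for r in range(rows):
        for c in range(cols):
            if k >= n_cells:
                break
            idx[(r, c)] = k
            k += 1
    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    even = [(+1, 0), (-1, 0), (0, +1), (0, -1), (+1, -1), (-1, -1)]
    odd = [(+1, 0), (-1, 0), (0, +1), (0, -1), (+1, +1), (-1, +1)]
    for (r, c), i in idx.items():
        for dr, dc in (odd if r % 2 else even):
            j = idx.get((r + dr, c + dc))
            if j is not None:
                g.add_edge(i, j)
    return g


def _marked_edge_samples(g: nx.Graph, nodes, n_marked: int, B: int, seed: int):
    nodes = np.asarray(nodes)
    if not 0 < n_marked <= len(nodes):
        raise ValueError("n_marked out of range")
    rng = np.random.default_rng(seed)
    A = nx.to_scipy_sparse_array(g, nodelist=nodes.tolist(), format="csr")
    out = np.empty(B, dtype=int)
    for b in range(B):
        mark = np.zeros(len(nodes), dtype=bool)
        mark[rng.choice(len(nodes), size=n_marked, replace=False)] = True
        out[b] = int(A[mark][:, mark].sum() // 2)
    return out


def hex_shuffle_null(
    n_cells: int,
    n_marked: int,
    B: int = 1000,
    seed: int = 0,
    observed: float | None = None,
    tail: str = "greater",
) -> NullDistribution:
    """Same-type contact counts under random marking of a honeycomb grid
    with the observed cell-type ratio."""
    if not 0 < n_marked < n_cells:
        raise ValueError("need 0 < n_marked < n_cells")
    g = hex_grid_graph(n_cells)
    samples = _marked_edge_samples(g, list(g.nodes), n_marked, B, seed)
    p = empirical_pvalue(samples, observed, tail) if observed is not None else float("nan")
    return NullDistribution(
        feature="hex-shuffle same-type contacts", samples=samples.astype(float),
        observed=float("nan") if observed is None else float(observed),
        p_value=p, tail=tail, method="empirical", seeds=[seed],
    )


def segmentation_shuffle_null(
    graph: nx.Graph,
    n_marked: int,
    B: int = 1000,
    seed: int = 0,
    observed: float | None = None,
    tail: str = "greater",
) -> NullDistribution:
    """Same-type contact counts under random re-marking of interior cells of
    the original segmentation's adjacency graph (cell shapes preserved,
    size/type relationship discarded)."""
    interior = [n for n, d in graph.nodes(data=True) if not d.get("is_border", False)]
    if n_marked > len(interior):
        raise ValueError("n_marked must not exceed the interior node count")
    sub = graph.subgraph(interior)
    samples = _marked_edge_samples(sub, interior, n_marked, B, seed)
    p = empirical_pvalue(samples, observed, tail) if observed is not None else float("nan")
    return NullDistribution(
        feature="segmentation-shuffle same-type contacts",
        samples=samples.astype(float),
        observed=float("nan") if observed is None else float(observed),
        p_value=p, tail=tail, method="empirical", seeds=[seed],
    )
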