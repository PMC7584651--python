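"""Cell-relationship features, null distributions and p-values.

Spatial features (contact counts between cell classes, neighbor counts,
rank-wise organelle-orientation angles) are computed on the cell adjacency
graph of a tessellation.  Their null distribution is sampled by recomputing
the same feature on many random SETs — shuffled tessellations of the exact
same cells — and the observed value is taken on the reconstruction of the
original image, which by construction is one more (non-random) sample of
the same generative process.

Border cells are excluded from every feature: they are incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .fitting import touches_border
from .tessellation import Tessellation, partial_set, random_set, run_lloyd

__all__ = [
    "NullDistribution",
    "adjacency_graph",
    "contact_count",
    "neighbor_counts",
    "cell_centroids",
    "rank_angle_feature",
    "empirical_pvalue",
    "gaussian_pvalue",
    "build_null",
]


@dataclass
class NullDistribution:
    """Feature samples over shuffled tessellations plus the observed value."""

    feature: str
    samples: np.ndarray
    observed: float
    p_value: float
    tail: str = "greater"
    method: str = "empirical"
    seeds: list[int] = field(default_factory=list)
    n_failed: int = 0

    @property
    def B(self) -> int:
        return len(self.samples)

    def plot(self, ax=None, bins=30):
        """Histogram of the null samples with the observed value marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.samples, bins=bins, color="steelblue", alpha=0.7,
                label=f"null (B={self.B})")
        if np.isfinite(self.observed):
            ax.axvline(self.observed, color="seagreen", lw=2,
                       label=f"observed (p={self.p_value:.3g})")
        ax.set_xlabel(self.feature)
        ax.set_ylabel("count")
        ax.legend(frameon=False)
        return ax


def adjacency_graph(labels: np.ndarray, classes: dict[int, str] | None = None) -> nx.Graph:
    """Cell-contact graph of a label raster.

    Two cells are adjacent iff a pixel of one is 4-adjacent to a pixel of
    the other (diagonal-only touching is not contact: SET rasters carry no
    membrane pixels and 8-adjacency would manufacture corner contacts).
    Edges carry the shared boundary length in pixel-pair units; nodes carry
    ``is_border`` and, if given, ``cls``.
    """
    a = np.concatenate([labels[:, :-1].ravel(), labels[:-1, :].ravel()])
    b = np.concatenate([labels[:, 1:].ravel(), labels[1:, :].ravel()])
    m = a != b
    lo, hi = np.minimum(a[m], b[m]), np.maximum(a[m], b[m])
    pairs, counts = np.unique(np.column_stack([lo, hi]), axis=0, return_counts=True)
    g = nx.Graph()
    for cid in np.unique(labels):
        g.add_node(int(cid), is_border=touches_border(labels, int(cid)))
    for (u, v), c in zip(pairs, counts):
        g.add_edge(int(u), int(v), contact_length=int(c))
    if classes is not None:
        nx.set_node_attributes(g, {int(k): v for k, v in classes.items()}, "cls")
    return g


def _interior(g: nx.Graph):
    return [n for n, d in g.nodes(data=True) if not d.get("is_border", False)]


def contact_count(
    g: nx.Graph, class_map: dict[int, str], class_a: str, class_b: str | None = None
) -> int:
    """Number of contacts between two cell classes among interior cells.

    With ``class_b`` omitted or equal to ``class_a``: edges with both
    endpoints in the class; otherwise edges with one endpoint in each.
    """
    known = set(class_map.values())
    if class_b is None:
        class_b = class_a
    for c in (class_a, class_b):
        if c not in known:
            raise ValueError(f"unknown class {c!r}")
    interior = set(_interior(g))
    n = 0
    for u, v in g.edges():
        if u not in interior or v not in interior:
            continue
        cu, cv = class_map.get(u), class_map.get(v)
        if class_a == class_b:
            n += cu == class_a and cv == class_a
        else:
            n += {cu, cv} == {class_a, class_b}
    return n


def neighbor_counts(g: nx.Graph) -> dict[int, int]:
    """Degree of every interior cell (border neighbors still count)."""
    return {n: g.degree(n) for n in _interior(g)}


def cell_centroids(labels: np.ndarray) -> dict[int, np.ndarray]:
    ids = np.unique(labels)
    out = {}
    for cid in ids:
        rows, cols = np.nonzero(labels == cid)
        out[int(cid)] = np.array([cols.mean(), rows.mean()])
    return out


def rank_angle_feature(
    labels: np.ndarray,
    organelles: pd.DataFrame,
    rank: int = 1,
    return_per_cell: bool = False,
):
    """Image-level mean absolute angle between centroid->organelle vectors
    of cells at graph distance exactly ``rank``.

    Per interior cell: the mean over its rank-r cells of the absolute angle
    (in [0, 180] degrees) between the two cells' centroid->organelle
    vectors; then the unweighted mean over interior cells.  Cells whose
    organelle sits on the centroid (zero vector) are skipped.
    """
    import warnings

    if rank < 1:
        raise ValueError("rank must be >= 1")
    g = adjacency_graph(labels)
    cent = cell_centroids(labels)
    vec = {}
    for _, rec in organelles.iterrows():
        cid = int(rec["cell_id"])
        if cid not in cent:
            continue
        v = np.array([rec["x"], rec["y"]]) - cent[cid]
        if np.linalg.norm(v) < 1e-9:
            warnings.warn(f"cell {cid}: organelle at centroid, skipped")
            continue
        vec[cid] = np.arctan2(v[1], v[0])
    interior = [n for n in _interior(g) if n in vec]
    per_cell = {}
    for n in interior:
        dist = nx.single_source_shortest_path_length(g, n, cutoff=rank)
        ring = [m for m, r in dist.items() if r == rank and m in vec]
        if not ring:
            continue
        diffs = np.array([vec[m] for m in ring]) - vec[n]
        deg = np.degrees(np.abs(np.mod(diffs + np.pi, 2 * np.pi) - np.pi))
        per_cell[n] = float(deg.mean())
    if not per_cell:
        raise ValueError("no interior cell with a rank-%d neighborhood" % rank)
    if return_per_cell:
        return per_cell
    return float(np.mean(list(per_cell.values())))


def empirical_pvalue(samples, observed: float, tail: str = "greater") -> float:
    """Empirical p: fraction of shuffles at least as extreme as observed.

    Non-strict comparison; floored at 1/B so an observation outside all B
    samples reports p = 1/B rather than 0.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty sample set")
    B = s.size
    pg = max(int(np.count_nonzero(s >= observed)), 1) / B
    pl = max(int(np.count_nonzero(s <= observed)), 1) / B
    if tail == "greater":
        return pg
    if tail == "less":
        return pl
    if tail == "two-sided":
        return min(1.0, 2.0 * min(pg, pl))
    raise ValueError(f"unknown tail {tail!r}")


def gaussian_pvalue(samples, observed: float, tail: str = "greater") -> float:
    """Normal-approximation p (CLT): fit N(mean, sd) to the samples and take
    the tail beyond the observed value."""
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples to fit a Gaussian")
    mu, sd = s.mean(), s.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in null samples")
    z = (observed - mu) / sd
    if tail == "greater":
        return float(norm.sf(z))
    if tail == "less":
        return float(norm.cdf(z))
    if tail == "two-sided":
        return float(2 * norm.sf(abs(z)))
    raise ValueError(f"unknown tail {tail!r}")


def build_null(
    labels: np.ndarray,
    params,
    feature_fn,
    B: int = 1000,
    seed0: int = 0,
    movable="all",
    tail: str = "greater",
    method: str = "empirical",
    max_iter: int = 200,
    feature_name: str = "feature",
    observed_tess: Tessellation | None = None,
) -> NullDistribution:
    """Sample a feature over B seeded shuffles and attach a p-value.

    ``feature_fn(tess)`` must be a pure function of a tessellation.  The
    observed value is computed on the reconstruction (Lloyd from the fitted
    positions — pass ``observed_tess`` to reuse one).  ``movable="all"``
    shuffles every interior cell; a collection of cell ids shuffles only
    those (partial SET).  Shuffles that hit the iteration cap without
    stabilizing are excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    dims = labels.shape
    if observed_tess is None:
        observed_tess = run_lloyd(params, dims, max_iter=max_iter)
    observed = float(feature_fn(observed_tess))
    samples, seeds, n_failed = [], [], 0
    for b in range(B):
        seed = seed0 + b
        if movable == "all":
            tess = random_set(params, dims, seed=seed, max_iter=max_iter)
        else:
            tess = partial_set(params, dims, movable, "random", seed=seed,
                               max_iter=max_iter)
        if not tess.converged and tess.n_iterations >= max_iter:
            n_failed += 1
            continue
        samples.append(float(feature_fn(tess)))
        seeds.append(seed)
    samples = np.asarray(samples)
    pfun = empirical_pvalue if method == "empirical" else gaussian_pvalue
    p = pfun(samples, observed, tail)
    return NullDistribution(
        feature=feature_name, samples=samples, observed=observed, p_value=p,
        tail=tail, method=method, seeds=seeds, n_failed=n_failed,
    )
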