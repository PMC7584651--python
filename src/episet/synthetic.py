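"""Synthetic confluent epithelia with known ground truth.

The generator is deliberately independent of the AMAT machinery it is used
to test: cells are regions of a multiplicatively weighted (Euclidean)
Voronoi tessellation of blue-noise seed points, optionally anisotropic per
cell, so every pixel belongs to exactly one cell by construction.  On top
of the raster it can produce two-population labelings (clustered / random /
repulsed) and per-cell organelle points with controllable orientational
coherence — the engineered patterns used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "make_epithelium", "make_population", "make_polarity"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic epithelium.

    size_heterogeneity is the coefficient of variation of the per-cell
    Voronoi weights (0 = near-uniform areas); elongation stretches each
    cell's metric along a random axis; population_fraction / placement
    control the minority labeling; minority_area_factor scales the apical
    area of minority cells (1 = none, 0.1 = ten-fold smaller as in
    stem-vs-ependymal tissue); polarity_coherence in [0, 1] blends a smooth
    global orientation field with uniform noise.
    """

    dims: tuple[int, int] = (64, 64)
    n_cells: int = 60
    size_heterogeneity: float = 0.0
    elongation: float = 1.0
    population_fraction: float = 0.3
    placement: str = "random"  # clustered | random | repulsed
    minority_area_factor: float = 1.0
    n_minority_clusters: int = 1
    polarity_coherence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.population_fraction < 1:
            raise ValueError("population_fraction must be in (0, 1)")
        if not 0 <= self.polarity_coherence <= 1:
            raise ValueError("polarity_coherence must be in [0, 1]")
        if self.n_cells < 7:
            raise ValueError("need at least 7 cells")
        h, w = self.dims
        if h * w < 20 * self.n_cells:
            raise ValueError("dims too small: need >= 20 px per cell")


def _blue_noise_points(rng, dims, n, margin=1.5):
    """Dart-throwing with a shrinking exclusion radius; never fails."""
    h, w = dims
    d0 = 0.74 * np.sqrt(h * w / n)
    pts: list[np.ndarray] = []
    d = d0
    attempts = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
        if not pts or np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) >= d:
            pts.append(cand)
        attempts += 1
        if attempts > 200 * n:
            d *= 0.9
            attempts = 0
    return np.asarray(pts)


def _raster_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    """4-adjacent label pairs, written independently of episet.stats."""
    edges = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            edges.add((int(min(u, v)), int(max(u, v))))
    return edges


def make_epithelium(spec: FixtureSpec):
    """Generate a confluent label raster plus ground truth.

    Returns ``(labels, truth)`` where ``labels`` is an (h, w) int array with
    values 1..n_cells and ``truth`` has the seed points, per-cell areas,
    the raster adjacency edge set, and the minority class map (classes are
    only size-asymmetric when minority_area_factor != 1; the labeling
    itself comes from :func:`make_population` semantics applied to seeds).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.dims
    seeds = _blue_noise_points(rng, spec.dims, spec.n_cells)

    m = max(1, round(spec.population_fraction * spec.n_cells))
    minority = _select_minority_seeds(rng, seeds, m, spec.placement,
                                      spec.n_minority_clusters)

    # multiplicative weights: larger weight -> larger cell
    if spec.size_heterogeneity > 0:
        sigma = np.sqrt(np.log(1 + spec.size_heterogeneity**2))
        wgt = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=spec.n_cells)
    else:
        wgt = np.ones(spec.n_cells)
    if spec.minority_area_factor != 1.0:
        wgt[minority] *= np.sqrt(spec.minority_area_factor)

    phis = rng.uniform(0, np.pi, size=spec.n_cells)
    ys, xs = np.mgrid[0:h, 0:w]
    P = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    dmin = np.full(len(P), np.inf)
    lab = np.zeros(len(P), dtype=np.int32)
    e = spec.elongation
    for i in range(spec.n_cells):
        r = P - seeds[i]
        if e != 1.0:
            c, s = np.cos(phis[i]), np.sin(phis[i])
            u = r[:, 0] * c + r[:, 1] * s
            v = -r[:, 0] * s + r[:, 1] * c
            d = np.hypot(u / e, v * e)
        else:
            d = np.hypot(r[:, 0], r[:, 1])
        d = d / wgt[i]
        better = d < dmin
        dmin[better] = d[better]
        lab[better] = i + 1
    labels = lab.reshape(h, w)

    present = np.unique(labels)
    if len(present) < spec.n_cells:
        raise ValueError(
            f"infeasible density: {spec.n_cells - len(present)} cell(s) vanished; "
            "reduce heterogeneity or n_cells"
        )
    areas = {int(c): int(n) for c, n in
             zip(present, np.bincount(labels.ravel())[present])}
    if min(areas.values()) < 9:
        raise ValueError(
            "infeasible density: smallest cell below 9 px; "
            "reduce heterogeneity or n_cells"
        )
    classes = {int(i + 1): ("minority" if i in set(minority) else "majority")
               for i in range(spec.n_cells)}
    truth = {
        "seeds": seeds,
        "areas": areas,
        "adjacency": _raster_adjacency(labels),
        "classes": classes,
        "weights": wgt,
    }
    return labels, truth


def _select_minority_seeds(rng, seeds, m, placement, n_clusters):
    n = len(seeds)
    if placement == "random":
        return rng.choice(n, size=m, replace=False)
    if placement == "clustered":
        centers = rng.choice(n, size=n_clusters, replace=False)
        sizes = np.full(n_clusters, m // n_clusters)
        sizes[: m % n_clusters] += 1
        chosen: list[int] = []
        for c, k in zip(centers, sizes):
            d = np.linalg.norm(seeds - seeds[c], axis=1)
            take = [int(i) for i in np.argsort(d) if i not in chosen][:k]
            chosen.extend(take)
        return np.asarray(chosen[:m])
    if placement == "repulsed":
        chosen = [int(rng.integers(n))]
        while len(chosen) < m:
            d = np.min(
                np.linalg.norm(seeds[:, None] - seeds[chosen][None], axis=2), axis=1
            )
            d[chosen] = -1
            chosen.append(int(np.argmax(d)))
        return np.asarray(chosen)
    raise ValueError(f"unknown placement {placement!r}")


def make_population(
    labels: np.ndarray,
    fraction: float,
    mode: str,
    seed: int = 0,
    graph: nx.Graph | None = None,
) -> dict[int, str]:
    """Two-class labeling of the cells of a raster.

    clustered: the minority is one connected patch grown breadth-first from
    a random interior cell; random: a uniform sample of interior cells;
    repulsed: greedy max-min graph-distance selection.  Border cells are
    always majority.
    """
    from .stats import adjacency_graph

    if graph is None:
        graph = adjacency_graph(labels)
    rng = np.random.default_rng(seed)
    interior = sorted(
        n for n, d in graph.nodes(data=True) if not d.get("is_border", False)
    )
    m = max(1, round(fraction * len(interior)))
    sub = graph.subgraph(interior)
    if mode == "random":
        minority = set(rng.choice(interior, size=m, replace=False).tolist())
    elif mode == "clustered":
        start = int(rng.choice(interior))
        order = [start]
        seen = {start}
        queue = [start]
        while queue and len(order) < m:
            nxt = queue.pop(0)
            for nb in sorted(sub.neighbors(nxt)):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    queue.append(nb)
        minority = set(order[:m])
    elif mode == "repulsed":
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        big = len(interior) + 1
        chosen = [int(rng.choice(interior))]
        while len(chosen) < m:
            best, best_d = None, -1
            for cand in interior:
                if cand in chosen:
                    continue
                d = min(dist[cand].get(c, big) for c in chosen)
                if d > best_d:
                    best, best_d = cand, d
            chosen.append(best)
        minority = set(chosen)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        int(n): ("minority" if n in minority else "majority") for n in graph.nodes
    }


def make_polarity(labels: np.ndarray, coherence: float, seed: int = 0) -> pd.DataFrame:
    """One organelle point per cell with tunable orientation coherence.

    Each cell's organelle sits at u * s2 from the centroid (s2 = minor axis
    half-length from pixel moments, u drawn uniformly in [0.1, 0.8] per cell
    — like a centriole, anywhere between the cell center and the membrane)
    along an orientation that blends a
    smooth global field (weight = coherence) with uniform noise; coherence 0
    gives i.i.d. uniform orientations, coherence 1 the pure field.  The
    point is pulled toward the centroid until it lies on the cell's own
    pixels.
    """
    if not 0 <= coherence <= 1:
        raise ValueError("coherence must be in [0, 1]")
    from .fitting import moment_init

    rng = np.random.default_rng(seed)
    h, w = labels.shape
    theta0 = rng.uniform(0, 2 * np.pi)
    rows = []
    for cid in np.unique(labels):
        prm = moment_init(labels, int(cid))
        field_theta = theta0 + 0.5 * (prm.mu1 / w)  # slowly varying global field
        noise_theta = rng.uniform(0, 2 * np.pi)
        vx = coherence * np.cos(field_theta) + (1 - coherence) * np.cos(noise_theta)
        vy = coherence * np.sin(field_theta) + (1 - coherence) * np.sin(noise_theta)
        if np.hypot(vx, vy) < 1e-9:
            vx, vy = np.cos(noise_theta), np.sin(noise_theta)
        theta = np.arctan2(vy, vx)
        r = rng.uniform(0.1, 0.8) * prm.s2
        x, y = prm.mu1 + r * np.cos(theta), prm.mu2 + r * np.sin(theta)
        for _ in range(20):
            xi = int(np.clip(round(x), 0, w - 1))
            yi = int(np.clip(round(y), 0, h - 1))
            if labels[yi, xi] == cid:
                break
            x = prm.mu1 + 0.6 * (x - prm.mu1)
            y = prm.mu2 + 0.6 * (y - prm.mu2)
        else:
            x, y = prm.mu1, prm.mu2
        rows.append({"cell_id": int(cid), "label": "organelle", "x": x, "y": y})
    return pd.DataFrame(rows)
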