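"""Tessellation of the image plane by competing per-cell AMAT distances.

A modified Lloyd relaxation in which every cell carries its own metric:
(1) every pixel is assigned to the cell whose AMAT distance to it is
smallest; (2) the positional parameters (mu1, mu2, alpha) of every interior
cell are re-estimated on its current pixel set, the five shape parameters
staying fixed so each cell keeps its fitted shape.  The two steps alternate
until no pixel changes label.

Initializing positions at their fitted values reconstructs the original
image ("reconstruction by SET"); random initialization produces an
alternative tessellation of the exact same cells ("random SET") — one
sample of the null.  Border cells are fully fixed throughout so the frame
stays anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import CellShapeParams, amat_distance
from .fitting import fit_amat, moment_init, sample_contour

__all__ = [
    "Tessellation",
    "assign_pixels",
    "update_positions",
    "run_lloyd",
    "fit_cells",
    "reconstruct",
    "random_set",
    "partial_set",
]


@dataclass
class Tessellation:
    """A label raster produced by the Lloyd engine plus convergence metadata."""

    labels: np.ndarray
    params: list[CellShapeParams]
    n_iterations: int = 0
    n_pixels_changed: list[int] = field(default_factory=list)
    converged: bool = True
    seed: int | None = None
    n_reseeded: int = 0

    @property
    def n_pixels_changed_last(self) -> int:
        return self.n_pixels_changed[-1] if self.n_pixels_changed else 0


def _pixel_grid(dims: tuple[int, int]) -> np.ndarray:
    h, w = dims
    ys, xs = np.mgrid[0:h, 0:w]
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


#: A cell can only win pixels where its distance is below the current best;
#: distances above this cutoff are resolved in a global fallback pass.
_COVER_LEVEL = 2.0


def _window_halfwidth(prm: CellShapeParams) -> float | None:
    """Pixel half-width outside which the cell's distance exceeds the cover
    level, or None when no finite bound holds (asymmetric cells, whose
    level sets need not be bounded)."""
    if prm.a1 == 0.0 and prm.a2 == 0.0:
        # d = ||y||_p >= ||y||_inf and ||x - mu|| <= sqrt(2) s1 ||y||_inf
        return float(np.sqrt(2.0) * _COVER_LEVEL * prm.s1) + 1.0
    return None


def _distance_field(params: list[CellShapeParams], dims: tuple[int, int]):
    """Per-pixel nearest cell and its distance, exact argmin.

    Each cell is evaluated only on the window where its distance can be
    below the cover level; pixels whose best distance ends up above the
    cover level (e.g. far from every cell after a random initialization)
    are resolved by evaluating every cell on just those pixels.  Cells are
    visited in increasing cell_id with a strict '<' update, so ties
    deterministically go to the lowest cell_id.
    """
    h, w = dims
    dmin = np.full(dims, np.inf)
    lab = np.zeros(dims, dtype=np.int32)
    order = sorted(params, key=lambda q: q.cell_id)
    full = []
    for prm in order:
        hw = _window_halfwidth(prm)
        if hw is None:
            full.append(prm)
            continue
        c0 = max(int(prm.mu1 - hw), 0)
        c1 = min(int(prm.mu1 + hw) + 1, w)
        r0 = max(int(prm.mu2 - hw), 0)
        r1 = min(int(prm.mu2 + hw) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        ys, xs = np.mgrid[r0:r1, c0:c1]
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        d = amat_distance(prm, pts).reshape(r1 - r0, c1 - c0)
        win_d = dmin[r0:r1, c0:c1]
        better = d < win_d
        win_d[better] = d[better]
        lab[r0:r1, c0:c1][better] = prm.cell_id
    unresolved = dmin > _COVER_LEVEL
    if full:
        unresolved[:] = True
    if unresolved.any():
        rows, cols = np.nonzero(unresolved)
        pts = np.column_stack([cols, rows]).astype(float)
        sub_d = dmin[unresolved]
        sub_l = lab[unresolved]
        for prm in order:
            d = amat_distance(prm, pts)
            better = d < sub_d
            sub_d[better] = d[better]
            sub_l[better] = prm.cell_id
        dmin[unresolved] = sub_d
        lab[unresolved] = sub_l
    return lab, dmin


def assign_pixels(
    params: list[CellShapeParams], dims: tuple[int, int]
) -> np.ndarray:
    """Label every pixel of an (h, w) raster with its AMAT-closest cell."""
    if not params:
        raise ValueError("need at least one cell")
    lab, _ = _distance_field(params, dims)
    return lab


def _closed_form_position(xs, ys):
    """Centroid + principal covariance angle of a pixel set (Mahalanobis fast path)."""
    mx, my = xs.mean(), ys.mean()
    cxx = np.mean(xs * xs) - mx * mx + 1.0 / 12.0
    cyy = np.mean(ys * ys) - my * my + 1.0 / 12.0
    cxy = np.mean(xs * ys) - mx * my
    alpha = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy)
    return mx, my, alpha


#: Sub-pixel dead band on position updates.  Near the fixed point the
#: assignment and the moment-based update trade single boundary pixels back
#: and forth indefinitely; keeping a cell's position bitwise unchanged when
#: its update moves it less than this makes an exact fixed point reachable
#: without affecting the tessellation at pixel resolution.
_FREEZE_MU = 0.05  # px
_FREEZE_ALPHA = 0.005  # rad


def _snap(prm: CellShapeParams, mx: float, my: float, alpha: float) -> CellShapeParams:
    da = abs(float(np.mod(alpha, np.pi)) - prm.alpha)
    da = min(da, np.pi - da)
    if (abs(mx - prm.mu1) < _FREEZE_MU and abs(my - prm.mu2) < _FREEZE_MU
            and da < _FREEZE_ALPHA):
        return prm
    return prm.with_position(mx, my, alpha)


def update_positions(
    labels: np.ndarray, params: list[CellShapeParams]
) -> list[CellShapeParams]:
    """Re-estimate (mu1, mu2, alpha) of every interior cell on its pixels.

    Mahalanobis cells (a1 = a2 = 0, p = 2) use the closed form (pixel
    centroid and covariance angle); other cells minimize the summed AMAT
    distance over their pixel set by bounded quasi-Newton.  Border cells and
    cells that currently own no pixel are returned unchanged.
    """
    flat = labels.ravel()
    h, w = labels.shape
    xs_all = np.tile(np.arange(w, dtype=float), h)
    ys_all = np.repeat(np.arange(h, dtype=float), w)
    K = int(flat.max()) + 1
    cnt = np.bincount(flat, minlength=K).astype(float)
    sx = np.bincount(flat, weights=xs_all, minlength=K)
    sy = np.bincount(flat, weights=ys_all, minlength=K)
    sxx = np.bincount(flat, weights=xs_all * xs_all, minlength=K)
    syy = np.bincount(flat, weights=ys_all * ys_all, minlength=K)
    sxy = np.bincount(flat, weights=xs_all * ys_all, minlength=K)

    out = []
    for prm in params:
        cid = prm.cell_id
        if prm.is_border or cid >= K or cnt[cid] == 0:
            out.append(prm)  # fixed, or vanished (run_lloyd reseeds)
            continue
        if prm.a1 == 0.0 and prm.a2 == 0.0 and prm.p == 2.0:
            n = cnt[cid]
            mx, my = sx[cid] / n, sy[cid] / n
            cxx = sxx[cid] / n - mx * mx + 1.0 / 12.0
            cyy = syy[cid] / n - my * my + 1.0 / 12.0
            cxy = sxy[cid] / n - mx * my
            alpha = 0.5 * np.arctan2(2.0 * cxy, cxx - cyy)
            out.append(_snap(prm, mx, my, alpha))
        else:
            rows, cols = np.nonzero(labels == cid)
            xs, ys = cols.astype(float), rows.astype(float)
            pts = np.column_stack([xs, ys])

            def obj(v):
                q = prm.with_position(v[0], v[1], v[2])
                return float(np.sum(amat_distance(q, pts)))

            span = max(prm.s1, 4.0)
            v0 = np.array([prm.mu1, prm.mu2, prm.alpha])
            res = minimize(
                obj, v0, method="L-BFGS-B",
                bounds=[(v0[0] - span, v0[0] + span),
                        (v0[1] - span, v0[1] + span),
                        (v0[2] - np.pi, v0[2] + np.pi)],
                options={"maxiter": 60, "ftol": 1e-8},
            )
            v = res.x if res.fun <= obj(v0) else v0
            out.append(_snap(prm, v[0], v[1], v[2]))
    return out


def run_lloyd(
    params: list[CellShapeParams],
    dims: tuple[int, int],
    max_iter: int = 200,
    seed: int | None = None,
) -> Tessellation:
    """Alternate pixel assignment and position updates until stable.

    Terminates when zero pixels change label, on an exact revisit of a
    previous label raster (oscillation), or at ``max_iter``.  Cells that
    lose all their pixels are re-seeded at the pixel currently farthest
    from every cell and the relaxation continues.
    """
    params = list(params)
    n_reseeded = 0

    def _assign():
        nonlocal params, n_reseeded
        lab, dmin = _distance_field(params, dims)
        present = set(np.unique(lab).tolist())
        missing = [p for p in params if p.cell_id not in present and not p.is_border]
        for prm in missing:
            r, c = np.unravel_index(int(np.argmax(dmin)), dims)
            params = [
                q.with_position(float(c), float(r), q.alpha)
                if q.cell_id == prm.cell_id else q
                for q in params
            ]
            n_reseeded += 1
            lab, dmin = _distance_field(params, dims)
        return lab

    labels = _assign()
    history: list[int] = []
    seen = {labels.tobytes()}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        params = update_positions(labels, params)
        new_labels = _assign()
        changed = int(np.count_nonzero(new_labels != labels))
        history.append(changed)
        labels = new_labels
        if changed == 0:
            converged = True
            break
        key = labels.tobytes()
        if key in seen:
            break  # exact cycle: positional updates can no longer make progress
        seen.add(key)
    return Tessellation(
        labels=labels, params=params, n_iterations=it,
        n_pixels_changed=history, converged=converged, seed=seed,
        n_reseeded=n_reseeded,
    )


def fit_cells(
    labels: np.ndarray, mode: str = "five", n_points: int = 100
) -> list[CellShapeParams]:
    """Fit AMAT parameters to every cell of a fully-labeled image.

    Cells touching the image frame are flagged as border cells (all their
    parameters stay fixed downstream).  Unfittable cells are dropped with a
    warning.
    """
    import warnings

    out = []
    for cid in np.unique(labels):
        try:
            init = moment_init(labels, int(cid))
            if mode == "eight":
                contour = sample_contour(labels, int(cid), n_points)
                fitted, _ = fit_amat(contour, init, mode="eight")
                out.append(fitted)
            else:
                out.append(init)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"cell {cid} dropped: {exc}")
    if not out:
        raise ValueError("no fittable cell in image")
    return out


def reconstruct(
    labels: np.ndarray, mode: str = "five", n_points: int = 100, max_iter: int = 200
) -> Tessellation:
    """Reconstruction by SET: relax from the original fitted positions."""
    params = fit_cells(labels, mode=mode, n_points=n_points)
    return run_lloyd(params, labels.shape, max_iter=max_iter)


def _random_positions(
    params: list[CellShapeParams], dims: tuple[int, int], rng: np.random.Generator
) -> list[CellShapeParams]:
    h, w = dims
    out = []
    for prm in params:
        if prm.is_border:
            out.append(prm)
        else:
            mu1 = rng.uniform(2.0, w - 3.0)
            mu2 = rng.uniform(2.0, h - 3.0)
            alpha = rng.uniform(0.0, np.pi)
            out.append(prm.with_position(mu1, mu2, alpha))
    return out


def random_set(
    params: list[CellShapeParams],
    dims: tuple[int, int],
    seed: int,
    max_iter: int = 200,
) -> Tessellation:
    """Random SET: uniform random position/orientation for interior cells,
    shape parameters and border cells fixed, then Lloyd relaxation."""
    rng = np.random.default_rng(seed)
    init = _random_positions(params, dims, rng)
    tess = run_lloyd(init, dims, max_iter=max_iter, seed=seed)
    return tess


def partial_set(
    params: list[CellShapeParams],
    dims: tuple[int, int],
    movable_ids,
    init_positions: dict[int, tuple[float, float]] | str = "random",
    seed: int | None = None,
    max_iter: int = 200,
) -> Tessellation:
    """Shuffle (or pin) a subset of cells, letting all interior cells relax.

    Non-movable interior cells start at their original positions; movable
    cells start either at uniformly random positions ("random") or at the
    explicit positions given per cell id.  After initialization every
    interior cell is free to autoadjust during the relaxation.
    """
    h, w = dims
    movable = set(int(i) for i in movable_ids)
    interior = {p.cell_id for p in params if not p.is_border}
    if not movable <= interior:
        raise ValueError("movable_ids must be interior cells")
    rng = np.random.default_rng(seed)
    init = []
    for prm in params:
        if prm.cell_id not in movable:
            init.append(prm)
        elif init_positions == "random":
            init.append(
                prm.with_position(
                    rng.uniform(2.0, w - 3.0), rng.uniform(2.0, h - 3.0),
                    rng.uniform(0.0, np.pi),
                )
            )
        else:
            x, y = init_positions[prm.cell_id]
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"explicit position {(x, y)} outside image")
            init.append(prm.with_position(x, y, prm.alpha))
    return run_lloyd(init, dims, max_iter=max_iter, seed=seed)
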