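"""Estimation of per-cell AMAT parameters from a segmented label image.

Pipeline per cell: extract the boundary of its pixel set, resample it to N
equally spaced points (index 0 aligned with the major axis), initialize the
parameters from pixel moments, and — in eight-parameter mode — refine them by
bounded least squares on sum_i (d_AMAT(x_i) - 1)^2.

In five-parameter mode no optimization is needed: the Mahalanobis cell is
fully determined by the pixel centroid and the covariance diagonalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage import measure

from .geometry import PARAM_BOUNDS, CellShapeParams, amat_distance

__all__ = ["ContourSamples", "FitReport", "sample_contour", "moment_init", "fit_amat"]


@dataclass
class ContourSamples:
    """Ordered, equally-arc-length-spaced boundary samples of one cell.

    ``start_aligned`` marks that point 0 lies in the major-axis direction
    from the centroid, which is what the morphing step relies on to align a
    cell with its synthetic counterpart.
    """

    cell_id: int
    points: np.ndarray  # (N, 2) float, (x, y)
    start_aligned: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 4:
            raise ValueError("contour needs at least 4 (x, y) points")


@dataclass
class FitReport:
    sse: float
    n_iterations: int
    converged: bool


def _cell_pixels(labels: np.ndarray, cell_id: int) -> np.ndarray:
    rows, cols = np.nonzero(labels == cell_id)
    if rows.size == 0:
        raise ValueError(f"cell {cell_id} absent from label image")
    return np.column_stack([cols, rows]).astype(float)  # (x, y)


def _resample_closed(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points at equal arc-length spacing."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack(
        [np.interp(t, cum, closed[:, 0]), np.interp(t, cum, closed[:, 1])]
    )


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return poly[::-1].copy() if area2 < 0 else poly


def touches_border(labels: np.ndarray, cell_id: int) -> bool:
    return bool(
        np.any(labels[0, :] == cell_id)
        or np.any(labels[-1, :] == cell_id)
        or np.any(labels[:, 0] == cell_id)
        or np.any(labels[:, -1] == cell_id)
    )


def sample_contour(labels: np.ndarray, cell_id: int, n_points: int = 100) -> ContourSamples:
    """Extract ``n_points`` equally spaced boundary samples of one cell.

    The boundary is traced by marching squares on the cell mask at level 0.5,
    oriented counter-clockwise, and rotated so that index 0 is the point
    whose direction from the centroid is closest to the cell's major axis.
    """
    pix = _cell_pixels(labels, cell_id)
    if len(pix) < 4:
        raise ValueError(f"cell {cell_id} too small ({len(pix)} px) for a contour")
    mask = np.pad((labels == cell_id).astype(float), 1)
    contours = measure.find_contours(mask, 0.5)
    poly = max(contours, key=len)  # outer boundary in (row, col)
    poly = np.column_stack([poly[:, 1], poly[:, 0]]) - 1.0  # -> (x, y), unpad
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    poly = _ensure_ccw(poly)
    pts = _resample_closed(poly, n_points)

    init = moment_init(labels, cell_id)
    axis = np.array([np.cos(init.alpha), np.sin(init.alpha)])
    rel = pts - init.mu
    ang = rel @ axis / np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
    off = axis[0] * rel[:, 1] - axis[1] * rel[:, 0]  # signed offset from axis
    # closest direction to the +major axis: maximize cos, tie-break by |offset|
    k = int(np.lexsort((np.abs(off), -ang))[0])
    pts = np.roll(pts, -k, axis=0)
    return ContourSamples(cell_id=cell_id, points=pts, start_aligned=True)


def moment_init(labels: np.ndarray, cell_id: int) -> CellShapeParams:
    """Initial five-parameter (Mahalanobis) cell from pixel moments.

    mu is the pixel centroid; alpha the principal eigenvector angle of the
    pixel covariance; s_i = 2 sqrt(lambda_i), so that the level-1 ellipse of
    the p = 2 distance coincides with the boundary of a uniform elliptical
    pixel region (a uniform ellipse with semi-axes (A, B) has covariance
    eigenvalues (A^2/4, B^2/4)).
    """
    pix = _cell_pixels(labels, cell_id)
    if len(pix) < 3:
        raise ValueError(f"cell {cell_id} has fewer than 3 pixels")
    mu = pix.mean(axis=0)
    cov = np.cov(pix.T, bias=True) + np.eye(2) / 12.0  # pixel extent correction
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    s1 = 2.0 * np.sqrt(max(evals[0], 0.0))
    s2 = 2.0 * np.sqrt(max(evals[1], 0.0))
    if s2 < PARAM_BOUNDS["s_min"]:
        s2 = PARAM_BOUNDS["s_min"]
        s1 = max(s1, s2)
    alpha = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    border = touches_border(labels, cell_id)
    return CellShapeParams(
        cell_id=int(cell_id), mu1=float(mu[0]), mu2=float(mu[1]),
        alpha=alpha, s1=float(s1), s2=float(s2), is_border=border, mode="five",
    )


def contour_sse(params: CellShapeParams, points: np.ndarray) -> float:
    d = amat_distance(params, points)
    return float(np.sum((d - 1.0) ** 2))


def _pack(params: CellShapeParams) -> np.ndarray:
    return np.array(
        [params.mu1, params.mu2, params.alpha, params.s1, params.s2,
         params.a1, params.a2, params.p]
    )


def _unpack(v: np.ndarray, cell_id: int, is_border: bool) -> CellShapeParams:
    s1, s2 = max(v[3], v[4]), min(v[3], v[4])
    alpha = v[2] if v[3] >= v[4] else v[2] + np.pi / 2
    return CellShapeParams(
        cell_id=cell_id, mu1=v[0], mu2=v[1], alpha=alpha,
        s1=s1, s2=max(s2, PARAM_BOUNDS["s_min"]), a1=v[5], a2=v[6], p=v[7],
        is_border=is_border, mode="eight",
    )


def fit_amat(
    contour: ContourSamples,
    init: CellShapeParams,
    mode: str = "eight",
    max_iter: int = 500,
    diag: float | None = None,
) -> tuple[CellShapeParams, FitReport]:
    """Fit the AMAT level-1 set to a cell contour.

    In ``"five"`` mode the moment initialization is already the closed-form
    solution and is returned untouched.  In ``"eight"`` mode all eight
    parameters are refined by L-BFGS-B within the configured bounds,
    starting from ``init``; a second start with a squarish prior (p = 6)
    guards against the shallow local minimum at p = 2 for cornered cells.
    """
    pts = contour.points
    if mode == "five":
        return init, FitReport(sse=contour_sse(init, pts), n_iterations=0, converged=True)
    if mode != "eight":
        raise ValueError("mode must be 'five' or 'eight'")

    if diag is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        diag = float(np.hypot(*span)) * 4 + 10.0
    lo_a, hi_a = PARAM_BOUNDS["a"]
    lo_p, hi_p = PARAM_BOUNDS["p"]
    bounds = [
        (init.mu1 - diag, init.mu1 + diag),
        (init.mu2 - diag, init.mu2 + diag),
        (init.alpha - np.pi, init.alpha + np.pi),
        (PARAM_BOUNDS["s_min"], diag),
        (PARAM_BOUNDS["s_min"], diag),
        (lo_a, hi_a),
        (lo_a, hi_a),
        (lo_p, hi_p),
    ]

    def objective(v: np.ndarray) -> float:
        try:
            p = _unpack(v, init.cell_id, init.is_border)
        except ValueError:
            return 1e12
        return contour_sse(p, pts)

    best = None
    n_it = 0
    ok = False

    def _try(p0: float, a0: tuple[float, float]) -> None:
        nonlocal best, n_it, ok
        x0 = _pack(init)
        x0[5], x0[6], x0[7] = a0[0], a0[1], p0
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best, n_it, ok = res, res.nit, bool(res.success)

    for p0 in (2.0, 6.0):
        _try(p0, (0.0, 0.0))
    if best.fun > 1e-6 * len(pts):
        # strongly asymmetric low-p shapes have several basins; escalate
        for p0 in (1.5, 4.0):
            for a1 in (-0.5, 0.5):
                for a2 in (-0.5, 0.5):
                    _try(p0, (a1, a2))
    fitted = _unpack(best.x, init.cell_id, init.is_border)
    sse0 = contour_sse(init, pts)
    if best.fun > sse0:  # optimizer must not degrade the moment solution
        fitted = CellShapeParams(**{**init.__dict__, "mode": "eight"})
        return fitted, FitReport(sse=sse0, n_iterations=n_it, converged=ok)
    return fitted, FitReport(sse=float(best.fun), n_iterations=n_it, converged=ok)
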