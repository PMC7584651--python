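"""Parametric per-cell distance functions (MAT / AMAT).

Each cell of a confluent epithelium is modelled by a distance function whose
level-1 set approximates the cell contour.  The symmetric form (MAT) is an
affine transform of a Minkowski norm,

    d_MAT(x) = || (R S)^-1 (x - mu) ||_p ,

which contains the Mahalanobis distance (p = 2) and the classical L_p norms
(identity affine part) as special cases.  The asymmetric form (AMAT) adds two
exponential cross-weights a1, a2 that skew the level sets, allowing egg-like
and triangular cell shapes:

    y = (R S)^-1 (x - mu)
    d_AMAT(x) = ( e^{-a1 y2} |y1|^p + e^{-a2 y1} |y2|^p )^{1/p} .

Eight parameters per cell: position (mu1, mu2), orientation alpha, axis
lengths (s1 >= s2), asymmetries (a1, a2) and the Minkowski order p.

Coordinates are (x=column, y=row) in raster space; alpha is the angle of the
major axis from the +x axis, normalized to [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellShapeParams",
    "PARAM_BOUNDS",
    "to_canonical",
    "from_canonical",
    "mat_distance",
    "amat_distance",
    "level_one_contour",
    "rotation_matrix",
]

#: Fitting bounds for the free shape parameters.  Restricting (a1, a2, p)
#: keeps the level-1 set closed and simple; AMAT is not a metric for
#: arbitrary parameter combinations.
PARAM_BOUNDS = {
    "p": (1.0, 16.0),
    "a": (-1.5, 1.5),
    "s_min": 0.5,
}

#: Clamp on the exponent of the asymmetry weight.  Only distances near the
#: level-1 set matter for tessellation; far away the weight would overflow.
_EXP_CLAMP = 50.0


def rotation_matrix(alpha: float) -> np.ndarray:
    """CCW rotation by ``alpha`` (major axis direction)."""
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s], [s, c]])


@dataclass
class CellShapeParams:
    """The eight AMAT parameters of one cell plus bookkeeping.

    ``mode`` is ``"five"`` (a1 = a2 = 0, p = 2 fixed; Mahalanobis cell) or
    ``"eight"`` (all parameters free during fitting).
    """

    cell_id: int
    mu1: float
    mu2: float
    alpha: float
    s1: float
    s2: float
    a1: float = 0.0
    a2: float = 0.0
    p: float = 2.0
    is_border: bool = False
    mode: str = "five"

    def __post_init__(self) -> None:
        self.alpha = float(np.mod(self.alpha, np.pi))
        self.validate()

    def validate(self) -> None:
        if not (self.s1 >= self.s2 > 0):
            raise ValueError(
                f"cell {self.cell_id}: need s1 >= s2 > 0, got s1={self.s1}, s2={self.s2}"
            )
        if self.p <= 0:
            raise ValueError(f"cell {self.cell_id}: Minkowski order p must be > 0")
        if self.mode not in ("five", "eight"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "five" and not (self.a1 == self.a2 == 0.0 and self.p == 2.0):
            raise ValueError("five-parameter mode requires a1 = a2 = 0 and p = 2")

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2])

    def with_position(self, mu1: float, mu2: float, alpha: float) -> "CellShapeParams":
        """Copy with new positional parameters; shape parameters untouched."""
        return replace(self, mu1=float(mu1), mu2=float(mu2), alpha=float(alpha))

    @property
    def shape_key(self) -> tuple:
        return (self.s1, self.s2, self.a1, self.a2, self.p)


def _check_points(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input coordinates")
    return x


def to_canonical(params: CellShapeParams, x) -> np.ndarray:
    """Map raster points to the cell's canonical frame: y = (RS)^-1 (x - mu).

    ``x`` may be a single 2-vector or an (N, 2) batch; the output has the
    same shape.
    """
    x = _check_points(x)
    if params.s1 <= 0 or params.s2 <= 0:
        raise ValueError("degenerate scale: s1, s2 must be > 0")
    R = rotation_matrix(params.alpha)
    d = x - params.mu
    y = d @ R  # == (R.T @ d.T).T
    y /= np.array([params.s1, params.s2])
    return y


def from_canonical(params: CellShapeParams, y) -> np.ndarray:
    """Inverse of :func:`to_canonical`: x = R S y + mu."""
    y = _check_points(y)
    R = rotation_matrix(params.alpha)
    return (y * np.array([params.s1, params.s2])) @ R.T + params.mu


def _minkowski_sum(y: np.ndarray, p: float, a1: float, a2: float) -> np.ndarray:
    """sum_k w_k |y_k|^p with AMAT asymmetry weights, for (..., 2) arrays."""
    ay = np.abs(y)
    if p == 2.0:
        t = ay * ay
    else:
        t = ay**p
    if a1 != 0.0 or a2 != 0.0:
        e1 = np.exp(np.clip(-a1 * y[..., 1], -_EXP_CLAMP, _EXP_CLAMP))
        e2 = np.exp(np.clip(-a2 * y[..., 0], -_EXP_CLAMP, _EXP_CLAMP))
        return e1 * t[..., 0] + e2 * t[..., 1]
    return t[..., 0] + t[..., 1]


def amat_distance(params: CellShapeParams, x) -> np.ndarray | float:
    """AMAT distance of point(s) ``x`` to the cell.

    Reduces to :func:`mat_distance` when a1 = a2 = 0, and to the Mahalanobis
    distance when additionally p = 2.  Vectorized over an (N, 2) batch.
    """
    y = to_canonical(params, x)
    s = _minkowski_sum(np.atleast_2d(y), params.p, params.a1, params.a2)
    if params.p == 2.0:
        d = np.sqrt(s)
    else:
        d = s ** (1.0 / params.p)
    return float(d[0]) if np.asarray(x).ndim == 1 else d


def mat_distance(params: CellShapeParams, x) -> np.ndarray | float:
    """Symmetric (MAT) distance; requires a1 = a2 = 0."""
    if params.a1 != 0.0 or params.a2 != 0.0:
        raise ValueError("mat_distance requires a1 = a2 = 0")
    return amat_distance(params, x)


def level_one_contour(params: CellShapeParams, n_points: int = 100) -> np.ndarray:
    """Sample the level-1 set of the cell's AMAT distance.

    Casts ``n_points`` rays from mu and solves d(mu + t u) = 1 along each by
    bracketing + bisection (the AMAT distance is not radially homogeneous
    when a1 or a2 is nonzero).  Returns an (n_points, 2) closed polygon
    (first point not repeated).  Raises if a ray fails to bracket the level
    set, reporting the offending direction.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    thetas = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    for i, th in enumerate(thetas):
        u = np.array([np.cos(th), np.sin(th)])

        def f(t: float) -> float:
            return amat_distance(params, params.mu + t * u) - 1.0

        hi = max(params.s1, params.s2)
        for _ in range(60):
            if f(hi) > 0:
                break
            hi *= 1.5
        else:
            raise RuntimeError(
                f"level-1 set unbounded along ray theta={th:.4f} "
                f"(parameters outside the well-behaved range)"
            )
        lo = 0.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        out[i] = params.mu + 0.5 * (lo + hi) * u
    return out
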