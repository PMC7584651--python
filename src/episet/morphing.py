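"""Transport of intracellular content between corresponding cells.

A cell and its synthetic counterpart are near-congruent simple polygons once
both contours are resampled to the same number of points and start-aligned
to their major axes.  Mean value coordinates (Floater's generalized
barycentric weights, well-defined for arbitrary simple polygons) then morph
content smoothly between the two shapes: organelle points are transported
forward (weights computed in the source polygon, applied to the target
vertices); pixel textures are pulled backward (weights computed at each
target pixel, applied to the source vertices, followed by bilinear
interpolation in the source image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.draw import polygon as raster_polygon

from .fitting import ContourSamples, sample_contour

__all__ = [
    "MorphPair",
    "mean_value_coordinates",
    "transport_point",
    "morph_cell_texture",
    "transport_organelles",
    "morph_image",
]

_EPS = 1e-12


@dataclass
class MorphPair:
    """Source/target contour correspondence for one cell (equal N, both
    start-aligned to their respective major axes)."""

    cell_id: int
    source: ContourSamples
    target: ContourSamples

    def __post_init__(self) -> None:
        if len(self.source.points) != len(self.target.points):
            raise ValueError("source and target contours must have equal N")


def _mvc_weights_batch(poly: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Mean value coordinates of points Q (M, 2) w.r.t. polygon (N, 2).

    Uses the tan(half-angle) form t_i = (d_i d_{i+1} - dot_i) / (2 A_i);
    points on a vertex or an edge fall back to the exact one-hot / linear
    edge weights.
    """
    M, N = len(Q), len(poly)
    r = poly[None, :, :] - Q[:, None, :]  # (M, N, 2)
    d = np.linalg.norm(r, axis=2)  # (M, N)
    r_next = np.roll(r, -1, axis=1)
    d_next = np.roll(d, -1, axis=1)
    dot = np.sum(r * r_next, axis=2)
    cross = r[..., 0] * r_next[..., 1] - r[..., 1] * r_next[..., 0]
    denom = np.where(np.abs(cross) < _EPS, np.nan, 2.0 * 0.5 * cross)
    t = (d * d_next - dot) / denom  # tan(theta_i / 2)
    w = (np.roll(t, 1, axis=1) + t) / np.where(d < _EPS, np.nan, d)
    bad = ~np.isfinite(w).all(axis=1)
    total = np.nansum(w, axis=1, keepdims=True)
    W = w / total
    for m in np.nonzero(bad)[0]:
        W[m] = _mvc_weights_degenerate(poly, Q[m], d[m], dot[m], cross[m])
    return W


def _mvc_weights_degenerate(poly, q, d, dot, cross):
    N = len(poly)
    w = np.zeros(N)
    k = int(np.argmin(d))
    if d[k] < 1e-9:  # q coincides with a vertex
        w[k] = 1.0
        return w
    on_edge = (np.abs(cross) < _EPS) & (dot < 0)
    if on_edge.any():  # q lies on edge (i, i+1): linear interpolation
        i = int(np.nonzero(on_edge)[0][0])
        j = (i + 1) % N
        w[i] = d[j] / (d[i] + d[j])
        w[j] = d[i] / (d[i] + d[j])
        return w
    # collinear-but-outside segment: nudge q off the line and recompute
    return _mvc_weights_batch(poly, (q + 1e-7)[None, :])[0]


def mean_value_coordinates(polygon: np.ndarray, q) -> np.ndarray:
    """Mean value coordinates of a single point w.r.t. a simple polygon.

    The weights form a partition of unity and reproduce q exactly
    (sum_i w_i v_i = q, linear precision); they are nonnegative when the
    polygon is convex.  Raises if q lies strictly outside the polygon.
    """
    polygon = np.asarray(polygon, dtype=float)
    q = np.asarray(q, dtype=float)
    if not Polygon(polygon).buffer(1e-9).contains(Point(q)):
        raise ValueError("point lies outside the polygon")
    return _mvc_weights_batch(polygon, q[None, :])[0]


def transport_point(pair: MorphPair, q_source) -> np.ndarray:
    """Map a point of the source cell to the target cell (forward MVC)."""
    w = mean_value_coordinates(pair.source.points, q_source)
    return w @ pair.target.points


def morph_cell_texture(
    pair: MorphPair,
    source_image: np.ndarray,
    target_pixels: np.ndarray | None = None,
):
    """Fill the target cell with back-mapped source intensities.

    Each target-cell pixel gets MVC weights in the target polygon; the same
    weights applied to the source polygon give a floating-point location in
    the source image, read out by bilinear interpolation (locations falling
    off the raster are clamped to the nearest pixel).

    Returns ``(pixels, values, n_clamped)`` where ``pixels`` is an (M, 2)
    integer array of (x, y) target coordinates.
    """
    if target_pixels is None:
        tp = pair.target.points
        rr, cc = raster_polygon(tp[:, 1], tp[:, 0])
        target_pixels = np.column_stack([cc, rr])
    target_pixels = np.asarray(target_pixels)
    if len(target_pixels) == 0:
        return target_pixels, np.array([]), 0
    W = _mvc_weights_batch(pair.target.points, target_pixels.astype(float))
    src_xy = W @ pair.source.points  # (M, 2) float in source frame
    h, w_ = source_image.shape[:2]
    n_clamped = int(
        np.count_nonzero(
            (src_xy[:, 0] < 0) | (src_xy[:, 0] > w_ - 1)
            | (src_xy[:, 1] < 0) | (src_xy[:, 1] > h - 1)
        )
    )
    vals = ndimage.map_coordinates(
        source_image.astype(float), [src_xy[:, 1], src_xy[:, 0]],
        order=1, mode="nearest",
    )
    return target_pixels, vals, n_clamped


def _inside_pull(poly: Polygon, q: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Pull q toward the polygon centroid until strictly inside (contour
    resampling can leave a boundary organelle marginally outside)."""
    for _ in range(30):
        if poly.buffer(1e-9).contains(Point(q)):
            return q
        q = centroid + 0.8 * (q - centroid)
    return centroid.copy()


def build_morph_pairs(
    source_labels: np.ndarray, target_labels: np.ndarray, n_points: int = 100
) -> dict[int, MorphPair]:
    """One MorphPair per cell present (with >= 4 px) in both rasters."""
    src_ids = set(np.unique(source_labels).tolist())
    tgt_ids = set(np.unique(target_labels).tolist())
    pairs = {}
    for cid in sorted(src_ids & tgt_ids):
        try:
            s = sample_contour(source_labels, cid, n_points)
            t = sample_contour(target_labels, cid, n_points)
        except ValueError:
            continue
        pairs[cid] = MorphPair(cell_id=cid, source=s, target=t)
    return pairs


def transport_organelles(
    source_labels: np.ndarray,
    target_labels: np.ndarray,
    organelles: pd.DataFrame,
    n_points: int = 100,
) -> pd.DataFrame:
    """Transport per-cell organelle points from the original segmentation to
    a tessellation; cells absent from the target are dropped."""
    pairs = build_morph_pairs(source_labels, target_labels, n_points)
    rows = []
    for _, rec in organelles.iterrows():
        cid = int(rec["cell_id"])
        if cid not in pairs:
            continue
        pair = pairs[cid]
        poly = Polygon(pair.source.points)
        q = _inside_pull(poly, np.array([rec["x"], rec["y"]], dtype=float),
                         np.asarray(poly.centroid.coords[0]))
        out = transport_point(pair, q)
        row = dict(rec)
        row["x"], row["y"] = float(out[0]), float(out[1])
        rows.append(row)
    return pd.DataFrame(rows)


def morph_image(
    source_image: np.ndarray,
    source_labels: np.ndarray,
    target_labels: np.ndarray,
    n_points: int = 100,
) -> np.ndarray:
    """Morph a full intensity image cell by cell onto a tessellation."""
    out = np.zeros(target_labels.shape, dtype=float)
    pairs = build_morph_pairs(source_labels, target_labels, n_points)
    for cid, pair in pairs.items():
        rows, cols = np.nonzero(target_labels == cid)
        pix = np.column_stack([cols, rows])
        _, vals, _ = morph_cell_texture(pair, source_image, target_pixels=pix)
        out[rows, cols] = vals
    return out
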