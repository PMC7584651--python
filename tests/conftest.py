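import numpy as np
import pytest

from episet import FixtureSpec, make_epithelium


def disk_image(radius: int = 10, pad: int = 0) -> np.ndarray:
    """Single filled disk labeled 2 on a frame-filling background cell 1."""
    n = 2 * radius + 1 + 2 * pad
    ys, xs = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    lab = np.ones((n, n), dtype=np.int32)
    lab[(xs - c) ** 2 + (ys - c) ** 2 <= radius**2] = 2
    return lab


def ellipse_image(a: float, b: float, angle: float = 0.0, pad: int = 4) -> np.ndarray:
    """Filled ellipse (semi-axes a >= b, rotated by `angle`) labeled 2."""
    n = int(2 * a) + 2 * pad + 1
    ys, xs = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    dx, dy = xs - c, ys - c
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    lab = np.ones((n, n), dtype=np.int32)
    lab[(u / a) ** 2 + (v / b) ** 2 <= 1] = 2
    return lab


def hex_raster(n_rings_x: int = 6, n_rings_y: int = 6, r: float = 9.0) -> np.ndarray:
    """Honeycomb label raster: nearest-center Voronoi of a hex lattice."""
    centers = []
    for j in range(n_rings_y):
        for i in range(n_rings_x):
            x = r * np.sqrt(3) * (i + 0.5 * (j % 2)) + r
            y = 1.5 * r * j + r
            centers.append((x, y))
    centers = np.asarray(centers)
    w = int(centers[:, 0].max() + r)
    h = int(centers[:, 1].max() + r)
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (np.argmin(d2, axis=1) + 1).reshape(h, w).astype(np.int32)


def grid_raster(n: int = 4, cell: int = 8) -> np.ndarray:
    """n x n square cells of side `cell` px, labels 1..n^2 row-major."""
    lab = np.zeros((n * cell, n * cell), dtype=np.int32)
    for j in range(n):
        for i in range(n):
            lab[j * cell:(j + 1) * cell, i * cell:(i + 1) * cell] = j * n + i + 1
    return lab


@pytest.fixture(scope="session")
def small_epithelium():
    """60-cell, 64x64 near-uniform epithelium used across modules."""
    labels, truth = make_epithelium(FixtureSpec(dims=(64, 64), n_cells=60, seed=1))
    return labels, truth


@pytest.fixture(scope="session")
def hetero_epithelium():
    """100-cell, 160x160 size-heterogeneous epithelium (wide area range)."""
    labels, truth = make_epithelium(
        FixtureSpec(dims=(160, 160), n_cells=100, seed=2,
                    size_heterogeneity=0.5, elongation=1.25)
    )
    return labels, truth
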