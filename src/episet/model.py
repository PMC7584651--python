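"""High-level modelling interface.

``TissueModel`` wraps a segmented epithelium (label raster plus optional
cell classes and organelle points); ``fit()`` estimates the per-cell AMAT
distance parameters and returns a ``TissueFit`` from which reconstructions,
random SETs, content morphing and null-distribution tests are produced.

    >>> model = TissueModel(labels, classes=classes)
    >>> fit = model.fit(mode="five")
    >>> null = fit.test_contacts("minority", B=1000, seed=0)
    >>> null.p_value
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .geometry import CellShapeParams
from .morphing import transport_organelles
from .stats import (
    NullDistribution,
    adjacency_graph,
    build_null,
    contact_count,
    rank_angle_feature,
)
from .tessellation import Tessellation, fit_cells, partial_set, random_set, run_lloyd

__all__ = ["TissueModel", "TissueFit"]


class TissueModel:
    """A segmented, fully-confluent epithelium to be modelled.

    Parameters
    ----------
    labels : (h, w) integer array, every pixel labeled 1..K.
    classes : optional dict cell_id -> class name.
    organelles : optional DataFrame with columns cell_id, x, y.
    """

    def __init__(self, labels, classes: dict[int, str] | None = None,
                 organelles: pd.DataFrame | None = None):
        labels = np.asarray(labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be a 2D integer raster")
        if np.any(labels == 0):
            raise ValueError("confluence violated: zero-labeled pixels present")
        self.labels = labels
        self.classes = classes
        self.organelles = organelles

    @classmethod
    def from_image(cls, path, classes_csv=None, organelles_csv=None) -> "TissueModel":
        labels, _ = _io.read_label_image(path)
        classes = _io.read_classes_csv(classes_csv) if classes_csv else None
        org = _io.read_organelles_csv(organelles_csv) if organelles_csv else None
        return cls(labels, classes=classes, organelles=org)

    @property
    def dims(self) -> tuple[int, int]:
        return self.labels.shape

    def fit(self, mode: str = "five", n_points: int = 100) -> "TissueFit":
        """Estimate per-cell AMAT parameters (five- or eight-parameter)."""
        params = fit_cells(self.labels, mode=mode, n_points=n_points)
        return TissueFit(self, params, mode=mode, n_points=n_points)


@dataclass
class TissueFit:
    """Fitted per-cell distance parameters and everything built on them."""

    model: TissueModel
    cell_params: list[CellShapeParams]
    mode: str = "five"
    n_points: int = 100
    _reconstruction: Tessellation | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.DataFrame:
        """Per-cell parameter table (one row per cell)."""
        return _io.params_to_frame(self.cell_params)

    @property
    def n_cells(self) -> int:
        return len(self.cell_params)

    @property
    def n_border(self) -> int:
        return sum(p.is_border for p in self.cell_params)

    def reconstruct(self, max_iter: int = 200) -> Tessellation:
        """Reconstruction by SET: Lloyd relaxation from the fitted positions
        (cached)."""
        if self._reconstruction is None:
            self._reconstruction = run_lloyd(
                self.cell_params, self.model.dims, max_iter=max_iter
            )
        return self._reconstruction

    def random_set(self, seed: int, max_iter: int = 200) -> Tessellation:
        """One shuffled tessellation of the same cells (a null sample)."""
        return random_set(self.cell_params, self.model.dims, seed=seed,
                          max_iter=max_iter)

    def partial_set(self, movable_ids, init_positions="random", seed=None,
                    max_iter: int = 200) -> Tessellation:
        return partial_set(self.cell_params, self.model.dims, movable_ids,
                           init_positions, seed=seed, max_iter=max_iter)

    def transport_organelles(self, tess: Tessellation) -> pd.DataFrame:
        """Morph the model's organelle points onto a tessellation."""
        if self.model.organelles is None:
            raise ValueError("model carries no organelle points")
        return transport_organelles(
            self.model.labels, tess.labels, self.model.organelles, self.n_points
        )

    # ---- feature / test helpers -------------------------------------------------

    def simulate_null(self, feature_fn, B: int = 1000, seed: int = 0,
                      movable="all", tail: str = "greater",
                      method: str = "empirical",
                      feature_name: str = "feature") -> NullDistribution:
        """Null distribution of an arbitrary feature of a tessellation."""
        return build_null(
            self.model.labels, self.cell_params, feature_fn, B=B, seed0=seed,
            movable=movable, tail=tail, method=method,
            feature_name=feature_name, observed_tess=self.reconstruct(),
        )

    def test_contacts(self, class_a: str, class_b: str | None = None,
                      B: int = 1000, seed: int = 0, movable="all",
                      tail: str = "greater",
                      method: str = "empirical") -> NullDistribution:
        """Contact-count test between two cell classes (same class if
        class_b is omitted)."""
        if self.model.classes is None:
            raise ValueError("model carries no cell classes")
        classes = self.model.classes

        def feature(tess: Tessellation) -> float:
            g = adjacency_graph(tess.labels)
            return contact_count(g, classes, class_a, class_b)

        name = f"{class_a}-{class_b or class_a} contacts"
        return self.simulate_null(feature, B=B, seed=seed, movable=movable,
                                  tail=tail, method=method, feature_name=name)

    def test_rank_angle(self, rank: int = 1, B: int = 50, seed: int = 0,
                        tail: str = "less",
                        method: str = "empirical") -> NullDistribution:
        """Rank-r centroid->organelle angle test with content morphing."""
        if self.model.organelles is None:
            raise ValueError("model carries no organelle points")
        src = self.model.labels
        org = self.model.organelles
        npts = self.n_points

        def feature(tess: Tessellation) -> float:
            moved = transport_organelles(src, tess.labels, org, npts)
            return rank_angle_feature(tess.labels, moved, rank=rank)

        return self.simulate_null(feature, B=B, seed=seed, tail=tail,
                                  method=method,
                                  feature_name=f"rank-{rank} mean abs angle")

    def plot_tessellation(self, tess: Tessellation | None = None, ax=None):
        """Show a tessellation (default: the reconstruction) with the
        original cell boundaries overlaid."""
        import matplotlib.pyplot as plt

        if tess is None:
            tess = self.reconstruct()
        if ax is None:
            _, ax = plt.subplots()
        rng = np.random.default_rng(0)
        k = int(tess.labels.max()) + 1
        lut = rng.uniform(0.2, 1.0, (k, 3))
        ax.imshow(lut[tess.labels])
        edge = np.zeros(self.model.labels.shape, dtype=bool)
        lab = self.model.labels
        edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
        edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
        ys, xs = np.nonzero(edge)
        ax.scatter(xs, ys, s=0.3, c="white", alpha=0.6)
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary."""
        df = self.params
        interior = df[~df.is_border]
        lines = [
            "Tissue model fit (" + self.mode + "-parameter AMAT cells)",
            "=" * 56,
            f"image dims          : {self.model.dims[1]} x {self.model.dims[0]} px",
            f"cells               : {self.n_cells} ({self.n_border} border, fixed)",
            f"mean cell area      : {self.model.labels.size / self.n_cells:.1f} px",
            f"s1 (major half-axis): {interior.s1.mean():.2f} +/- {interior.s1.std():.2f} px",
            f"s2 (minor half-axis): {interior.s2.mean():.2f} +/- {interior.s2.std():.2f} px",
            f"aspect ratio s2/s1  : {(interior.s2 / interior.s1).mean():.3f}",
        ]
        if self.mode == "eight":
            lines += [
                f"Minkowski order p   : {interior.p.mean():.2f} "
                f"[{interior.p.min():.2f}, {interior.p.max():.2f}]",
                f"|a1|, |a2| mean     : {interior.a1.abs().mean():.3f}, "
                f"{interior.a2.abs().mean():.3f}",
            ]
        if self._reconstruction is not None:
            t = self._reconstruction
            lines.append(
                f"reconstruction      : {t.n_iterations} iterations, "
                f"converged={t.converged}"
            )
        return "\n".join(lines)
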