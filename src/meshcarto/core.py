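"""Domain types for mesh-scan analysis.

Conventions used throughout the package:

* Detector pixels are 0-based and continuous; ``x`` runs along the fast
  axis, ``y`` along the slow axis.
* The incident beam travels along +z in the lab frame; the detector plane
  is normal to the beam at ``detector_distance``.
* Grid nodes are addressed as ``(row, col)``, 0-based; images are acquired
  in row-major order and each row is its own small omega sweep restarting
  at ``omega_start``, so a node's goniometer angle is
  ``omega_start + col * omega_per_image`` (serpentine scanning is not
  assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "ExperimentGeometry",
    "Spot",
    "NodeRecord",
    "MeshScan",
    "AnalysisConfig",
]


@dataclass(frozen=True)
class ExperimentGeometry:
    """Geometry of a mesh-scan experiment.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Angstrom.
    detector_distance : float
        Sample-to-detector distance in mm.
    pixel_size : float
        Detector pixel size in mm (square pixels).
    beam_centre : tuple of float
        Direct-beam position on the detector ``(px, py)`` in pixels.
    detector_shape : tuple of int
        ``(n_fast, n_slow)`` detector dimensions in pixels.
    grid_shape : tuple of int
        ``(n_rows, n_cols)`` of the mesh-scan grid.
    omega_per_image : float
        Goniometer rotation increment per image, degrees.
    omega_start : float
        Goniometer angle of the first image, degrees.
    """

    wavelength: float
    detector_distance: float
    pixel_size: float
    beam_centre: tuple[float, float]
    detector_shape: tuple[int, int]
    grid_shape: tuple[int, int]
    omega_per_image: float = 0.0
    omega_start: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.detector_distance <= 0:
            raise ValueError("detector_distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape components must be >= 1")
        px, py = self.beam_centre
        nf, ns = self.detector_shape
        if not (0 <= px < nf and 0 <= py < ns):
            raise ValueError("beam_centre must lie inside detector bounds")

    @property
    def n_rows(self) -> int:
        return self.grid_shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid_shape[1]

    def omega_of(self, row: int, col: int) -> float:
        """Goniometer angle (degrees) of the image taken at a grid node.

        Each row of the mesh is acquired as its own small omega sweep that
        restarts at ``omega_start`` (detector readout is triggered by
        rotation), so omega depends on the column only.  Nodes in the same
        column therefore share the same orientation, which is what makes
        the omega-gated linkage able to connect a crystal across rows.
        """
        return self.omega_start + col * self.omega_per_image

    def edge_resolution(self) -> float:
        """Resolution (Angstrom) at the nearest detector edge."""
        px, py = self.beam_centre
        nf, ns = self.detector_shape
        half = min(px, nf - px, py, ns - py) * self.pixel_size
        two_theta = np.arctan2(half, self.detector_distance)
        return self.wavelength / (2.0 * np.sin(two_theta / 2.0))


@dataclass(frozen=True)
class Spot:
    """A diffraction spot on the detector (continuous pixel coordinates)."""

    x: float
    y: float
    intensity: float = 1.0


@dataclass
class NodeRecord:
    """Per-grid-node record: diffraction score, spot list and omega."""

    row: int
    col: int
    score: float
    spots: list[Spot] = field(default_factory=list)
    omega: float = 0.0

    def spot_array(self) -> np.ndarray:
        """Spots as an ``(n, 3)`` float array of (x, y, intensity)."""
        if not self.spots:
            return np.empty((0, 3))
        return np.array([(s.x, s.y, s.intensity) for s in self.spots])


class MeshScan:
    """A dense 2D grid of node records plus the experiment geometry."""

    def __init__(self, geometry: ExperimentGeometry, nodes: list[NodeRecord]):
        n_rows, n_cols = geometry.grid_shape
        if len(nodes) != n_rows * n_cols:
            raise ValueError(
                f"expected {n_rows * n_cols} nodes for grid "
                f"{geometry.grid_shape}, got {len(nodes)}"
            )
        grid: dict[tuple[int, int], NodeRecord] = {}
        for node in nodes:
            key = (node.row, node.col)
            if key in grid:
                raise ValueError(f"duplicate node {key}")
            if not (0 <= node.row < n_rows and 0 <= node.col < n_cols):
                raise ValueError(f"node {key} outside grid {geometry.grid_shape}")
            if node.score < 0:
                raise ValueError(f"node {key} has negative score")
            grid[key] = node
        self.geometry = geometry
        self._grid = grid

    def node(self, row: int, col: int) -> NodeRecord:
        return self._grid[(row, col)]

    def __iter__(self) -> Iterator[NodeRecord]:
        n_rows, n_cols = self.geometry.grid_shape
        for r in range(n_rows):
            for c in range(n_cols):
                yield self._grid[(r, c)]

    def __len__(self) -> int:
        return len(self._grid)

    def score_grid(self) -> np.ndarray:
        """Diffraction scores as an ``(n_rows, n_cols)`` array."""
        out = np.zeros(self.geometry.grid_shape)
        for node in self:
            out[node.row, node.col] = node.score
        return out


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    k_threshold : float
        Multi-pattern decision threshold on the K statistic, 1/Angstrom.
        Images with K above this are flagged as multi-crystal.
    ray_gate : float
        Maximum angle (degrees) between scattered rays for two spots to be
        considered the same reflection; unmatched spots contribute this
        value to the distance score, which is therefore capped at it.
    d_cutoff : float
        Dendrogram cut distance (degrees) separating distinct crystals.
    omega_gate : float
        Pairs of images whose goniometer angles differ by more than this
        (degrees) get zero weight in the average linkage.
    hist_bins : int
        Number of bins of the DDV-length histogram.
    hist_max : float
        Upper edge of the histogram range, 1/Angstrom.
    fit_range : tuple of float
        DDV-length window (1/Angstrom) used for the baseline fit.
    min_spots_for_k : int
        Below this spot count the K test is skipped (node treated as
        single-pattern).
    score_floor : float
        Scores strictly above this count as "diffraction present".
    penalty_weight : float
        Weight of zero-score nodes in the shape-fit objective.
    de_seed : int
        Seed of the differential-evolution optimizer.
    min_baseline_bins : int
        Minimum number of usable baseline bins for a valid slope fit.
    """

    k_threshold: float = 1.4e-4
    ray_gate: float = 0.1
    d_cutoff: float = 0.093
    omega_gate: float = 0.5
    hist_bins: int = 100
    hist_max: float = 1.0 / 25.0
    fit_range: tuple[float, float] = (1.0e-3, 40.0e-3)
    min_spots_for_k: int = 10
    score_floor: float = 0.0
    penalty_weight: float = 10.0
    de_seed: int = 0
    min_baseline_bins: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.d_cutoff <= self.ray_gate):
            raise ValueError("require 0 < d_cutoff <= ray_gate")
        if self.hist_bins < 10:
            raise ValueError("hist_bins must be >= 10")
        lo, hi = self.fit_range
        if not (0 <= lo < hi <= self.hist_max):
            raise ValueError("fit_range must lie within [0, hist_max]")
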