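"""Synthetic mesh-scan generator with known ground truth.

Still diffraction images are simulated with the Ewald construction: a
reciprocal-lattice node q diffracts when its angular offset from the Ewald
sphere (radius 1/wavelength, centred at -k_in) is below an excitation
half-width that lumps together mosaicity and bandwidth.  The scattered ray
k_out = q + k_in is projected onto a flat detector normal to the beam.

Crystals are laid out on the mesh as tilted ellipses; the per-node
diffraction score is the illuminated thickness of a semi-ellipsoid,
H * sqrt(max(0, 1 - u^2/a^2 - v^2/b^2)), evaluated at the node centre, so
the ground-truth score surface is exactly the shape the fitting stage
recovers.  Nodes covered by several crystals receive the concatenation of
the individual spot lists (no occlusion), which is all the K statistic
needs.  A crystal may carry a smooth orientation gradient along its major
axis to emulate gradually bent lattices.

Goniometer convention: omega rotates the sample about the lab y axis
(vertical, parallel to the slow detector axis); the image at grid node
(row, col) is taken at omega_start + (row*n_cols + col)*omega_per_image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import ExperimentGeometry, MeshScan, NodeRecord, Spot
from .multipattern import (
    ampd_local_minima,
    baseline_slope,
    ddv_histogram,
    ewald_cap_area,
    k_statistic,
    spots_to_reciprocal,
)

__all__ = [
    "CrystalSpec",
    "SimulationConfig",
    "GroundTruth",
    "reciprocal_basis",
    "lattice_points",
    "simulate_still_spots",
    "simulate_mesh",
    "calibration_curve_K",
    "typical_mx_geometry",
    "random_rotation",
]


@dataclass
class CrystalSpec:
    """Ground-truth description of one crystal on the mesh.

    centre is (row, col) in continuous grid units; semi_axes (a, b) are the
    major/minor ellipse semi-axes in grid units; tilt is the in-plane angle
    (degrees) of the major axis measured from the column direction;
    orientation is a rotation vector in degrees (axis * angle) fixing the
    lattice orientation; orientation_gradient adds a rotation (degrees per
    grid unit, about the goniometer axis) proportional to the position
    along the major axis.
    """

    centre: tuple[float, float]
    semi_axes: tuple[float, float]
    tilt: float = 0.0
    unit_cell: tuple[float, float, float, float, float, float] = (
        93.0,
        93.0,
        130.0,
        90.0,
        90.0,
        120.0,
    )
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_score: float = 10.0
    orientation_gradient: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if self.peak_score <= 0:
            raise ValueError("peak_score must be positive")

    def thickness(self, row: float, col: float) -> float:
        """Relative illuminated thickness at a mesh position (0 outside)."""
        u, v = self._axis_coords(row, col)
        a, b = self.semi_axes
        val = 1.0 - (u / a) ** 2 - (v / b) ** 2
        return float(np.sqrt(val)) if val > 0 else 0.0

    def _axis_coords(self, row: float, col: float) -> tuple[float, float]:
        phi = np.radians(self.tilt)
        dx = col - self.centre[1]
        dy = row - self.centre[0]
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return float(u), float(v)

    def rotation_at(self, row: float, col: float) -> Rotation:
        """Lattice orientation at a mesh position (gradient applied)."""
        base = Rotation.from_rotvec(np.radians(self.orientation))
        if self.orientation_gradient == 0.0:
            return base
        u, _ = self._axis_coords(row, col)
        extra = Rotation.from_euler(
            "y", self.orientation_gradient * u, degrees=True
        )
        return extra * base


@dataclass
class SimulationConfig:
    geometry: ExperimentGeometry
    crystals: list[CrystalSpec] = field(default_factory=list)
    excitation_halfwidth: float = 0.05  # degrees
    resolution_limit: float = 1.7  # Angstrom
    noise_spots_per_image: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.excitation_halfwidth <= 0:
            raise ValueError("excitation_halfwidth must be positive")
        if self.resolution_limit <= self.geometry.wavelength / 2.0:
            raise ValueError("resolution_limit must exceed wavelength/2")


@dataclass
class GroundTruth:
    """What the simulator knows: per-node contributors and true scores."""

    crystals: list[CrystalSpec]
    contributors: dict[tuple[int, int], list[int]]
    score: np.ndarray  # (n_rows, n_cols) exact semi-ellipsoid scores


def typical_mx_geometry(
    grid_shape: tuple[int, int] = (1, 1),
    wavelength: float = 1.0,
    edge_resolution: float = 1.7,
    detector_shape: tuple[int, int] = (1475, 1679),
    pixel_size: float = 0.172,
    omega_per_image: float = 0.0,
    omega_start: float = 0.0,
) -> ExperimentGeometry:
    """Geometry of a typical MX mesh scan (pixel-array detector).

    The detector distance is chosen so the nearest detector edge sits at
    ``edge_resolution`` Angstrom.
    """
    nf, ns = detector_shape
    half = min(nf, ns) / 2.0 * pixel_size
    two_theta = 2.0 * np.arcsin(wavelength / (2.0 * edge_resolution))
    distance = half / np.tan(two_theta)
    return ExperimentGeometry(
        wavelength=wavelength,
        detector_distance=float(distance),
        pixel_size=pixel_size,
        beam_centre=(nf / 2.0, ns / 2.0),
        detector_shape=detector_shape,
        grid_shape=grid_shape,
        omega_per_image=omega_per_image,
        omega_start=omega_start,
    )


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform random 3D rotation (via normalized random quaternion)."""
    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat))


def reciprocal_basis(
    unit_cell: tuple[float, float, float, float, float, float],
    orientation: Rotation | None = None,
) -> np.ndarray:
    """Reciprocal basis as a 3x3 matrix with columns a*, b*, c* (1/Angstrom).

    The direct cell is placed in the standard setting (a along x, b in the
    xy plane) and the optional orientation rotation is applied afterwards.
    Satisfies a_i . a*_j = delta_ij.
    """
    a, b, c, alpha, beta, gamma = unit_cell
    al, be, ga = np.radians([alpha, beta, gamma])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    v_sq = 1.0 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    if v_sq <= 1e-12 or min(a, b, c) <= 0:
        raise ValueError("degenerate unit cell")
    v = np.sqrt(v_sq)
    a_vec = np.array([a, 0.0, 0.0])
    b_vec = np.array([b * cos_ga, b * sin_ga, 0.0])
    c_vec = np.array(
        [c * cos_be, c * (cos_al - cos_be * cos_ga) / sin_ga, c * v / sin_ga]
    )
    direct = np.stack([a_vec, b_vec, c_vec])  # rows
    recip = np.linalg.inv(direct).T  # rows a*, b*, c*
    basis = recip.T  # columns
    if orientation is not None:
        basis = orientation.as_matrix() @ basis
    return basis


def _direct_cell_of(basis: np.ndarray) -> tuple[float, ...]:
    """Direct cell parameters (rounded) of a reciprocal basis — rotation
    invariant, used as the Miller-enumeration cache key."""
    direct = np.linalg.inv(basis)  # rows a, b, c (since A @ B = I)
    lengths = np.linalg.norm(direct, axis=1)
    cos = [
        direct[1] @ direct[2] / (lengths[1] * lengths[2]),
        direct[0] @ direct[2] / (lengths[0] * lengths[2]),
        direct[0] @ direct[1] / (lengths[0] * lengths[1]),
    ]
    angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    return tuple(round(float(x), 9) for x in (*lengths, *angles))


@lru_cache(maxsize=16)
def _hkl_within(cell: tuple[float, ...], q_max: float) -> np.ndarray:
    """Miller indices whose reciprocal vectors satisfy 0 < |q| <= q_max."""
    basis = reciprocal_basis(cell)
    lengths = np.array(cell[:3])
    bounds = np.ceil(q_max * lengths).astype(int)
    axes = [np.arange(-m, m + 1) for m in bounds]
    hkl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    q = hkl @ basis.T
    norm = np.linalg.norm(q, axis=1)
    keep = (norm > 0) & (norm <= q_max)
    return np.ascontiguousarray(hkl[keep])


def lattice_points(basis: np.ndarray, q_max: float) -> np.ndarray:
    """All reciprocal-lattice vectors with 0 < |q| <= q_max, shape (m, 3).

    Enumeration is cached per unit cell (rotation invariant), so rotating
    the same lattice across a mesh costs one matrix product per image.
    """
    hkl = _hkl_within(_direct_cell_of(basis), round(float(q_max), 9))
    return hkl @ basis.T


def simulate_still_spots(
    lattices: list[np.ndarray],
    geometry: ExperimentGeometry,
    omega: float = 0.0,
    excitation_halfwidth: float = 0.05,
    resolution_limit: float = 1.7,
    rng: np.random.Generator | None = None,
    noise_spots: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the spot list of one still image.

    Parameters
    ----------
    lattices : list of (3, 3) arrays
        Oriented reciprocal bases (columns a*, b*, c*), one per lattice.
    omega : float
        Goniometer angle in degrees (rotation about the lab y axis).
    excitation_halfwidth : float
        Angular half-width (degrees) of the excitation window: a node
        diffracts when | |q - c| - 1/wavelength | / |q| is below it, with
        c the Ewald-sphere centre.
    resolution_limit : float
        Only nodes with |q| <= 1/resolution_limit are considered.
    rng, noise_spots :
        If ``noise_spots`` > 0, a Poisson-distributed number of spurious
        spots uniform over the detector is appended (provenance id -1).

    Returns
    -------
    spots : (n, 3) array of (x_px, y_px, intensity)
    lattice_ids : (n,) int array, index into ``lattices`` (-1 for noise)
    """
    lam = geometry.wavelength
    q_max = 1.0 / resolution_limit
    half_rad = np.radians(excitation_halfwidth)
    rot = Rotation.from_euler("y", omega, degrees=True).as_matrix()
    centre = np.array([0.0, 0.0, -1.0 / lam])
    nf, ns = geometry.detector_shape
    px, py = geometry.beam_centre

    all_spots: list[np.ndarray] = []
    all_ids: list[np.ndarray] = []
    for idx, basis in enumerate(lattices):
        q = lattice_points(rot @ basis, q_max)
        if len(q) == 0:
            continue
        norm = np.linalg.norm(q, axis=1)
        offset = np.abs(np.linalg.norm(q - centre, axis=1) - 1.0 / lam)
        angular = offset / norm
        excited = angular <= half_rad
        if not excited.any():
            continue
        q_hit = q[excited]
        k_out = q_hit + np.array([0.0, 0.0, 1.0 / lam])
        forward = k_out[:, 2] > 0
        k_out = k_out[forward]
        partial = 1.0 - (angular[excited][forward] / half_rad) ** 2
        scale = geometry.detector_distance / k_out[:, 2]
        x = k_out[:, 0] * scale / geometry.pixel_size + px
        y = k_out[:, 1] * scale / geometry.pixel_size + py
        on_det = (x >= 0) & (x < nf) & (y >= 0) & (y < ns)
        spots = np.column_stack([x[on_det], y[on_det], partial[on_det]])
        all_spots.append(spots)
        all_ids.append(np.full(len(spots), idx, dtype=int))

    if noise_spots > 0:
        if rng is None:
            raise ValueError("noise_spots > 0 requires an rng")
        n_noise = rng.poisson(noise_spots)
        if n_noise:
            x = rng.uniform(0, nf, n_noise)
            y = rng.uniform(0, ns, n_noise)
            inten = rng.uniform(0.1, 1.0, n_noise)
            all_spots.append(np.column_stack([x, y, inten]))
            all_ids.append(np.full(n_noise, -1, dtype=int))

    if not all_spots:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.concatenate(all_spots), np.concatenate(all_ids)


def simulate_mesh(config: SimulationConfig) -> tuple[MeshScan, GroundTruth]:
    """Simulate a full mesh scan with ground truth; deterministic per seed."""
    geom = config.geometry
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = geom.grid_shape

    for k, spec in enumerate(config.crystals):
        covered = any(
            spec.thickness(r, c) > 0
            for r in range(n_rows)
            for c in range(n_cols)
        )
        if not covered:
            warnings.warn(
                f"crystal {k} does not cover any grid node", stacklevel=2
            )

    nodes: list[NodeRecord] = []
    contributors: dict[tuple[int, int], list[int]] = {}
    score = np.zeros((n_rows, n_cols))
    for row in range(n_rows):
        for col in range(n_cols):
            omega = geom.omega_of(row, col)
            bases = []
            ids = []
            for k, spec in enumerate(config.crystals):
                th = spec.thickness(row, col)
                if th <= 0:
                    continue
                score[row, col] += spec.peak_score * th
                rot = spec.rotation_at(row, col)
                bases.append(reciprocal_basis(spec.unit_cell, rot))
                ids.append(k)
            spots_arr, _ = simulate_still_spots(
                bases,
                geom,
                omega=omega,
                excitation_halfwidth=config.excitation_halfwidth,
                resolution_limit=config.resolution_limit,
                rng=rng,
                noise_spots=config.noise_spots_per_image,
            )
            contributors[(row, col)] = ids
            nodes.append(
                NodeRecord(
                    row=row,
                    col=col,
                    score=float(score[row, col]),
                    spots=[Spot(x, y, i) for x, y, i in spots_arr],
                    omega=omega,
                )
            )
    scan = MeshScan(geom, nodes)
    truth = GroundTruth(
        crystals=list(config.crystals), contributors=contributors, score=score
    )
    return scan, truth


def calibration_curve_K(
    spot_ratio_grid: list[float],
    replicates: int = 50,
    geometry: ExperimentGeometry | None = None,
    unit_cell: tuple[float, ...] = (93.0, 93.0, 130.0, 90.0, 90.0, 120.0),
    excitation_halfwidth: float = 0.05,
    resolution_limit: float = 1.7,
    seed: int = 0,
    hist_bins: int = 100,
    hist_max: float = 1.0 / 25.0,
    fit_range: tuple[float, float] = (1.0e-3, 40.0e-3),
    return_samples: bool = False,
):
    """Mean K versus satellite spot-ratio, from simulated superpositions.

    For each ratio r, simulates still images in which a satellite lattice
    contributes r times the main lattice's spot count (enforced by random
    subsampling of the satellite spot list) and computes the K statistic
    per replicate.  Baseline bins are AMPD minima of the cumulative
    histogram over the ratio's replicates: intra-lattice DDV lengths are
    distances between reciprocal-lattice nodes and hence orientation
    invariants, so the peaks line up across replicates just as they do
    across the images of a mesh scan.

    Returns a DataFrame with columns ratio, mean_k, sd_k, n_valid; with
    ``return_samples=True`` also a dict of per-replicate K values per ratio.
    """
    if geometry is None:
        geometry = typical_mx_geometry(edge_resolution=resolution_limit)
    rng = np.random.default_rng(seed)
    rows = []
    samples: dict[float, np.ndarray] = {}
    for ratio in spot_ratio_grid:
        if not (0.0 <= ratio <= 1.0):
            raise ValueError("spot ratios must lie in [0, 1]")
        replicate_data = []
        cumulative = None
        for _ in range(replicates):
            main_basis = reciprocal_basis(unit_cell, random_rotation(rng))
            main, _ = simulate_still_spots(
                [main_basis], geometry, 0.0, excitation_halfwidth, resolution_limit
            )
            parts = [main]
            if ratio > 0:
                sat_basis = reciprocal_basis(unit_cell, random_rotation(rng))
                sat, _ = simulate_still_spots(
                    [sat_basis], geometry, 0.0, excitation_halfwidth, resolution_limit
                )
                n_keep = min(len(sat), int(round(ratio * len(main))))
                if n_keep:
                    keep = rng.choice(len(sat), size=n_keep, replace=False)
                    parts.append(sat[keep])
            spots = np.concatenate(parts)
            if len(spots) < 10:
                continue
            q = spots_to_reciprocal(spots, geometry)
            hist = ddv_histogram(q, hist_bins, hist_max)
            s = ewald_cap_area(q, geometry.wavelength)
            replicate_data.append((hist, len(spots), s))
            cumulative = hist if cumulative is None else cumulative + hist
        ks = []
        if cumulative is not None and cumulative.counts.sum() > 0:
            minima = ampd_local_minima(cumulative.counts.astype(float))
            for hist, n_spots, s in replicate_data:
                k0 = baseline_slope(hist, minima, fit_range) if len(minima) else None
                if k0 is None:
                    continue
                ks.append(k_statistic(k0, n_spots, s))
        rows.append(
            {
                "ratio": ratio,
                "mean_k": float(np.mean(ks)) if ks else np.nan,
                "sd_k": float(np.std(ks, ddof=1)) if len(ks) > 1 else np.nan,
                "n_valid": len(ks),
            }
        )
        samples[ratio] = np.asarray(ks)
    table = pd.DataFrame(rows)
    if return_samples:
        return table, samples
    return table
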