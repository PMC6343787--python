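"""Pairwise image similarity and connected diffracting regions.

Two images from the same crystal at the same orientation show the same
spots in (almost) the same places.  Instrument-independence is obtained by
comparing scattered-ray directions: for each spot of the reference image
(the one with fewer spots) the nearest ray of the compared image is found;
deviations are capped at a gate (default 0.1 degrees, roughly the angular
size of a spot-integration box) and their RMS is the distance score D.
Identical patterns give D = 0 and completely unrelated patterns give
D = gate, so the score lives in [0, gate] regardless of spot counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import AnalysisConfig, ExperimentGeometry, MeshScan
from .multipattern import MultiPatternResult, scattered_ray_directions

__all__ = [
    "scattered_rays",
    "distance_score",
    "Region",
    "connected_regions",
    "region_distance_matrix",
]

NO_COMPARISON = None  # sentinel: a pair involving an empty spot list


def scattered_rays(spots: np.ndarray, geometry: ExperimentGeometry) -> np.ndarray:
    """Unit scattered-ray directions (n, 3) for a spot table."""
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    if spots.size == 0:
        return np.empty((0, 3))
    return scattered_ray_directions(spots, geometry)


def distance_score(
    spots_a: np.ndarray,
    spots_b: np.ndarray,
    geometry: ExperimentGeometry,
    ray_gate: float = 0.1,
) -> float | None:
    """Distance score D (degrees) between two images.

    The image with fewer spots is the reference (ties: the first
    argument).  Each reference spot contributes the angle to the nearest
    compared-image ray, capped at ``ray_gate``; D is the RMS of these.
    Returns None ("no comparison") when either image has no spots.

    Nearest-ray search uses a KD-tree on the unit vectors: for small
    angles the Euclidean chord 2*sin(delta/2) is monotone in the angle
    delta, so the chord-nearest ray is the angle-nearest ray.
    """
    spots_a = np.atleast_2d(np.asarray(spots_a, dtype=float))
    spots_b = np.atleast_2d(np.asarray(spots_b, dtype=float))
    n_a = len(spots_a) if spots_a.size else 0
    n_b = len(spots_b) if spots_b.size else 0
    if n_a == 0 or n_b == 0:
        return NO_COMPARISON
    if n_a <= n_b:
        ref, other = spots_a, spots_b
    else:
        ref, other = spots_b, spots_a
    rays_ref = scattered_rays(ref, geometry)
    rays_other = scattered_rays(other, geometry)
    tree = cKDTree(rays_other)
    chord, _ = tree.query(rays_ref, k=1)
    angle = np.degrees(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
    delta = np.minimum(angle, ray_gate)
    # RMS of capped deviations; guard the <= gate invariant against
    # floating-point round-up
    return float(min(np.sqrt(np.mean(delta**2)), ray_gate))


@dataclass
class Region:
    """A geometrically connected set of single-pattern diffracting nodes."""

    nodes: list[tuple[int, int]]
    omegas: np.ndarray
    condensed: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.nodes)


def connected_regions(
    mesh: MeshScan,
    multipattern: dict[tuple[int, int], MultiPatternResult],
    score_floor: float = 0.0,
    connectivity: int = 8,
) -> list[Region]:
    """Partition diffracting, non-multipattern nodes into connected regions.

    8-connectivity by default (diagonal neighbours connect); nodes flagged
    as multi-pattern are excluded from every region.
    """
    mask = mesh.score_grid() > score_floor
    for (row, col), res in multipattern.items():
        if res.is_multipattern:
            mask[row, col] = False
    structure = np.ones((3, 3), dtype=int) if connectivity == 8 else None
    labels, n_regions = ndimage.label(mask, structure=structure)
    regions = []
    for lab in range(1, n_regions + 1):
        rows, cols = np.nonzero(labels == lab)
        nodes = list(zip(rows.tolist(), cols.tolist()))
        omegas = np.array([mesh.geometry.omega_of(r, c) for r, c in nodes])
        regions.append(Region(nodes=nodes, omegas=omegas))
    return regions


def region_distance_matrix(
    region: Region,
    mesh: MeshScan,
    config: AnalysisConfig | None = None,
) -> Region:
    """Fill the region's condensed distance matrix over all node pairs.

    Pairs where a node has no spots ("no comparison") are assigned the
    maximally dissimilar value ``ray_gate``.
    """
    config = config or AnalysisConfig()
    n = len(region)
    spot_arrays = [mesh.node(r, c).spot_array() for r, c in region.nodes]
    condensed = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = distance_score(
                spot_arrays[i], spot_arrays[j], mesh.geometry, config.ray_gate
            )
            condensed[idx] = config.ray_gate if d is NO_COMPARISON else d
            idx += 1
    region.condensed = condensed
    return region
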