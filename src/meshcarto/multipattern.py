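"""Multi-pattern (multi-crystal) diffraction detection.

A still image of a single crystal only shows spots at reciprocal-lattice
nodes, so the lengths of difference diffraction vectors (DDVs) between the
observed reciprocal vectors pile up in discrete peaks.  When two or more
lattices are superposed in one image, the inter-lattice DDVs fill the gaps
between the peaks with an approximately linear baseline whose slope grows
with the number of cross-lattice pairs.  The statistic

    K = k0 * S / N**2        [1/Angstrom]

normalizes the fitted baseline slope k0 (counts per 1/Angstrom, i.e.
Angstrom) by the spot density N/S (N spots over an Ewald-sphere cap of
area S) and by N itself, making the multi-pattern decision independent of
how many spots an image contains.  Images with K above a fixed threshold
(default 1.4e-4 1/Angstrom) are flagged as multi-crystal.

Baseline regions — the histogram bins between the intra-lattice peaks —
are located as local minima of the mesh-wide cumulative DDV histogram with
the automatic multiscale peak-detection algorithm (AMPD), since peak
positions are a property of the lattice shared by all images of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import AnalysisConfig, ExperimentGeometry, MeshScan

__all__ = [
    "DDVHistogram",
    "MultiPatternResult",
    "spots_to_reciprocal",
    "ddv_histogram",
    "cumulative_histogram",
    "ampd_local_minima",
    "baseline_slope",
    "ewald_cap_area",
    "k_statistic",
    "classify_multipattern",
]


@dataclass
class DDVHistogram:
    """Histogram of DDV lengths over ``[0, hist_max)``."""

    bin_edges: np.ndarray  # hist_bins + 1 edges
    counts: np.ndarray  # hist_bins non-negative integers

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def __add__(self, other: "DDVHistogram") -> "DDVHistogram":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("histograms have different binning")
        return DDVHistogram(self.bin_edges, self.counts + other.counts)


@dataclass
class MultiPatternResult:
    """Per-node outcome of the multi-pattern test."""

    k0: float = 0.0
    n_spots: int = 0
    cap_area: float = 0.0
    k_stat: float = 0.0
    is_multipattern: bool = False
    valid: bool = False


def spots_to_reciprocal(spots: np.ndarray, geometry: ExperimentGeometry) -> np.ndarray:
    """Map detector spots to reciprocal-space vectors q (1/Angstrom).

    Parameters
    ----------
    spots : array, shape (n, >=2)
        Spot table whose first two columns are detector pixel coordinates
        (fast, slow).
    geometry : ExperimentGeometry

    Returns
    -------
    array, shape (n, 3)
        q = (s_hat - z_hat) / wavelength with s_hat the unit scattered-ray
        direction; |q| = 2 sin(theta) / wavelength.
    """
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    if spots.size == 0:
        return np.empty((0, 3))
    rays = scattered_ray_directions(spots, geometry)
    rays[:, 2] -= 1.0
    return rays / geometry.wavelength


def scattered_ray_directions(
    spots: np.ndarray, geometry: ExperimentGeometry
) -> np.ndarray:
    """Unit scattered-ray directions (lab frame) for detector spots."""
    spots = np.atleast_2d(np.asarray(spots, dtype=float))
    px, py = geometry.beam_centre
    lab = np.empty((len(spots), 3))
    lab[:, 0] = (spots[:, 0] - px) * geometry.pixel_size
    lab[:, 1] = (spots[:, 1] - py) * geometry.pixel_size
    lab[:, 2] = geometry.detector_distance
    return lab / np.linalg.norm(lab, axis=1, keepdims=True)


def ddv_histogram(
    q_vectors: np.ndarray, bins: int = 100, hist_max: float = 1.0 / 25.0
) -> DDVHistogram:
    """Histogram of pairwise |q_i - q_j| over all unordered pairs.

    Differences of ``hist_max`` or longer are discarded (not clamped); bin
    intervals are half-open ``[edge_i, edge_{i+1})``.
    """
    q_vectors = np.atleast_2d(np.asarray(q_vectors, dtype=float))
    edges = np.linspace(0.0, hist_max, bins + 1)
    if len(q_vectors) < 2:
        return DDVHistogram(edges, np.zeros(bins, dtype=np.int64))
    lengths = pdist(q_vectors)
    lengths = lengths[lengths < hist_max]
    # np.histogram closes the last bin; shrink its right edge below
    # hist_max so every interval is half-open.
    idx = np.floor(lengths / (hist_max / bins)).astype(np.int64)
    idx = np.clip(idx, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return DDVHistogram(edges, counts)


def cumulative_histogram(
    mesh: MeshScan, config: AnalysisConfig | None = None
) -> DDVHistogram:
    """Element-wise sum of per-node DDV histograms over the whole scan."""
    config = config or AnalysisConfig()
    edges = np.linspace(0.0, config.hist_max, config.hist_bins + 1)
    total = DDVHistogram(edges, np.zeros(config.hist_bins, dtype=np.int64))
    for node in mesh:
        arr = node.spot_array()
        if len(arr) < 2:
            continue
        q = spots_to_reciprocal(arr, mesh.geometry)
        total = total + ddv_histogram(q, config.hist_bins, config.hist_max)
    return total


def ampd_local_minima(signal: np.ndarray, max_scale: int | None = None) -> np.ndarray:
    """Local minima of a 1D signal via automatic multiscale peak detection.

    The multiscale local-extremum scalogram is built on the negated
    signal: entry (k, i) is 0 when sample i exceeds both its k-th
    neighbours and 1 (a deterministic penalty) otherwise.  The scale
    minimizing the row sum is selected, and indices that are extrema at
    every scale up to it are returned in ascending order.  Three
    adaptations for count histograms: ties (within a relative tolerance)
    count as extrema, so flat zero-count runs between peaks are recognized
    as baseline; comparisons that fall outside the signal are treated as
    satisfied so extrema near the edges survive large scales (the two
    endpoint samples are still never reported); the signal is not
    detrended, since for DDV histograms the trend is the baseline slope
    being measured.

    Parameters
    ----------
    signal : 1D array, length >= 5
    max_scale : int, optional
        Upper bound on the scale range (default: half the signal length).

    Returns
    -------
    array of int
        Indices of detected minima (empty for flat or monotonic input).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("signal must be 1D with length >= 5")
    n = len(x)
    span = float(np.ptp(x))
    tol = 1e-9 * max(1.0, span)
    if span <= tol:  # flat signal: no extrema
        return np.array([], dtype=int)
    # negate: minima of the signal are maxima of y
    y = -x

    scales = int(np.ceil(n / 2.0)) - 1
    if max_scale is not None:
        scales = min(scales, int(max_scale))
    scales = max(scales, 1)

    # Scale selection uses the canonical scalogram (strict comparisons,
    # out-of-range entries penalized); extraction uses a tolerant variant
    # where ties (within tol) count as extrema — so flat runs between
    # peaks are recognized as baseline — and out-of-range comparisons are
    # satisfied, letting extrema near the edges survive large scales.
    strict = np.ones((scales, n), dtype=np.int8)
    tolerant = np.ones((scales, n), dtype=np.int8)
    for k in range(1, scales + 1):
        left = y[k:] > y[:-k]
        right = y[:-k] > y[k:]
        interior = np.zeros(n, dtype=bool)
        interior[k : n - k] = left[: n - 2 * k] & right[k:]
        strict[k - 1, interior] = 0

        left_ok = np.ones(n, dtype=bool)
        right_ok = np.ones(n, dtype=bool)
        left_ok[k:] = y[k:] > y[:-k] - tol
        right_ok[:-k] = y[:-k] > y[k:] - tol
        tolerant[k - 1, left_ok & right_ok] = 0

    row_sums = strict.sum(axis=1)
    lam = int(np.argmin(row_sums)) + 1
    is_min = (tolerant[:lam] == 0).all(axis=0)
    is_min[0] = is_min[-1] = False
    return np.flatnonzero(is_min)


def baseline_slope(
    histogram: DDVHistogram,
    baseline_bins: np.ndarray,
    fit_range: tuple[float, float] = (1.0e-3, 40.0e-3),
    min_bins: int = 3,
) -> float | None:
    """OLS slope of counts vs DDV length over the baseline bins.

    Only baseline bins whose centres fall inside ``fit_range`` are used.
    The slope has units of counts per (1/Angstrom), i.e. Angstrom.
    Returns None when fewer than ``min_bins`` usable bins remain.
    """
    baseline_bins = np.asarray(baseline_bins, dtype=int)
    centres = histogram.bin_centres[baseline_bins]
    lo, hi = fit_range
    keep = (centres >= lo) & (centres <= hi)
    if keep.sum() < min_bins:
        return None
    xs = centres[keep]
    ys = histogram.counts[baseline_bins][keep].astype(float)
    slope, _ = np.polyfit(xs, ys, 1)
    return float(slope)


def ewald_cap_area(q_vectors: np.ndarray, wavelength: float) -> float:
    """Area (1/Angstrom^2) of the Ewald-sphere cap containing all spots.

    S = 2 pi (1/wavelength)^2 (1 - cos 2theta_max) with 2theta_max the
    largest scattering angle among the q vectors.
    """
    q_vectors = np.atleast_2d(np.asarray(q_vectors, dtype=float))
    if q_vectors.size == 0:
        raise ValueError("ewald_cap_area requires at least one vector")
    q_len = np.linalg.norm(q_vectors, axis=1)
    sin_theta = np.clip(q_len.max() * wavelength / 2.0, 0.0, 1.0)
    two_theta_max = 2.0 * np.arcsin(sin_theta)
    return float(2.0 * np.pi * (1.0 - np.cos(two_theta_max)) / wavelength**2)


def k_statistic(k0: float, n_spots: int, cap_area: float) -> float:
    """K = k0 * S / N^2 (1/Angstrom): baseline slope normalized by spot
    density N/S and spot count N."""
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    if cap_area <= 0:
        raise ValueError("cap_area must be positive")
    return float(k0 * cap_area / n_spots**2)


def baseline_bins_of(histogram: DDVHistogram) -> np.ndarray:
    """AMPD minima of a cumulative histogram: the baseline bin indices."""
    return ampd_local_minima(histogram.counts.astype(float))


def classify_multipattern(
    mesh: MeshScan, config: AnalysisConfig | None = None
) -> dict[tuple[int, int], MultiPatternResult]:
    """Flag every grid node whose image superposes several lattices.

    Baseline regions are determined once from the cumulative DDV histogram
    of the whole scan and reused for each per-image baseline fit.  Nodes
    without diffraction signal (score at or below ``score_floor``) or with
    fewer than ``min_spots_for_k`` spots are returned with
    ``valid=False`` and are never flagged.
    """
    config = config or AnalysisConfig()
    cumulative = cumulative_histogram(mesh, config)
    if cumulative.counts.sum() > 0:
        baseline = baseline_bins_of(cumulative)
    else:
        baseline = np.array([], dtype=int)

    results: dict[tuple[int, int], MultiPatternResult] = {}
    for node in mesh:
        res = MultiPatternResult(n_spots=len(node.spots))
        results[(node.row, node.col)] = res
        if node.score <= config.score_floor:
            continue
        if len(node.spots) < config.min_spots_for_k:
            continue
        q = spots_to_reciprocal(node.spot_array(), mesh.geometry)
        hist = ddv_histogram(q, config.hist_bins, config.hist_max)
        k0 = baseline_slope(
            hist, baseline, config.fit_range, config.min_baseline_bins
        ) if len(baseline) else None
        if k0 is None:
            continue
        s = ewald_cap_area(q, mesh.geometry.wavelength)
        res.k0 = k0
        res.cap_area = s
        res.k_stat = k_statistic(k0, res.n_spots, s)
        res.valid = True
        res.is_multipattern = res.k_stat > config.k_threshold
    return results


def multipattern_mask(
    results: dict[tuple[int, int], MultiPatternResult], grid_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean grid of nodes flagged as multi-pattern."""
    mask = np.zeros(grid_shape, dtype=bool)
    for (row, col), res in results.items():
        mask[row, col] = res.is_multipattern
    return mask
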