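"""End-to-end mesh-scan analysis: from bundle to ranked crystal map.

Stages, in order: flag multi-pattern nodes (K statistic) -> partition the
remaining diffracting nodes into connected regions -> pairwise distance
matrices -> omega-gated average-linkage clustering with a fixed cutoff ->
global crystal ids -> semi-ellipsoid shape fit per crystal -> ranking by
integral signal -> crystal map.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .clustering import assign_crystal_ids, cut_dendrogram, weighted_average_linkage
from .core import AnalysisConfig, MeshScan
from .multipattern import classify_multipattern, multipattern_mask
from .shapefit import CrystalFit, fit_crystal_shape, rank_crystals
from .similarity import connected_regions, region_distance_matrix

logger = logging.getLogger("meshcarto")

__all__ = ["CrystalMap", "run_pipeline", "render_map", "MULTIPATTERN", "NO_SIGNAL"]

MULTIPATTERN = -2
NO_SIGNAL = 0
N_PALETTE = 9  # crystal map colours cycle through a fixed 9-colour palette

# fixed 9-colour palette (RGB tuples) for crystal maps
PALETTE = [
    (0.122, 0.467, 0.706),
    (1.000, 0.498, 0.055),
    (0.173, 0.627, 0.173),
    (0.839, 0.153, 0.157),
    (0.580, 0.404, 0.741),
    (0.549, 0.337, 0.294),
    (0.890, 0.467, 0.761),
    (0.737, 0.741, 0.133),
    (0.090, 0.745, 0.812),
]


@dataclass
class CrystalMap:
    """Per-node label grid plus crystal overlays.

    Labels: -2 multi-pattern, 0 no signal, k >= 1 crystal id.  Colour
    index of crystal k is ``(k - 1) % 9 + 1``.
    """

    labels: np.ndarray
    fits: list[CrystalFit] = field(default_factory=list)

    def colour_index(self, crystal_id: int) -> int:
        return (crystal_id - 1) % N_PALETTE + 1


def run_pipeline(
    mesh: MeshScan, config: AnalysisConfig | None = None
) -> tuple[CrystalMap, list[CrystalFit]]:
    """Run the full analysis on a loaded mesh scan.

    Returns the crystal map and the crystal fits ranked by integral
    signal.  Deterministic for a given mesh and config.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    mp = classify_multipattern(mesh, config)
    n_grey = sum(res.is_multipattern for res in mp.values())
    logger.info("multipattern: %d grey nodes (%.2fs)", n_grey, time.perf_counter() - t0)

    t0 = time.perf_counter()
    regions = connected_regions(mesh, mp, config.score_floor)
    logger.info(
        "regions: %d connected regions, sizes %s (%.2fs)",
        len(regions),
        [len(r) for r in regions],
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    assignments = []
    for region in regions:
        if len(region) == 1:
            from .clustering import ClusterAssignment

            assignments.append((region, ClusterAssignment(np.array([1]))))
            continue
        region_distance_matrix(region, mesh, config)
        dendro = weighted_average_linkage(
            region.condensed, region.omegas, config.omega_gate, config.ray_gate
        )
        assignments.append((region, cut_dendrogram(dendro, config.d_cutoff)))
    crystals = assign_crystal_ids(assignments)
    logger.info(
        "clustering: %d crystals (%.2fs)", len(crystals), time.perf_counter() - t0
    )

    grid_shape = mesh.geometry.grid_shape
    labels = np.zeros(grid_shape, dtype=int)
    labels[multipattern_mask(mp, grid_shape)] = MULTIPATTERN
    for cid, nodes in crystals.items():
        for r, c in nodes:
            labels[r, c] = cid

    score = mesh.score_grid()
    t0 = time.perf_counter()
    fits = []
    for cid, nodes in crystals.items():
        scores = np.array([score[r, c] for r, c in nodes])
        zero_nodes = _neighbourhood_zero_nodes(nodes, labels, score, config, dilate=2)
        fits.append(
            fit_crystal_shape(
                cid, nodes, scores, zero_nodes, config, grid_shape=grid_shape
            )
        )
    ranked = rank_crystals(fits)
    logger.info("shapefit: %d fits (%.2fs)", len(fits), time.perf_counter() - t0)

    return CrystalMap(labels=labels, fits=ranked), ranked


def _neighbourhood_zero_nodes(
    nodes: list[tuple[int, int]],
    labels: np.ndarray,
    score: np.ndarray,
    config: AnalysisConfig,
    dilate: int = 2,
) -> list[tuple[int, int]]:
    """No-diffraction nodes in the crystal's dilated bounding box.

    Multi-pattern nodes and nodes of other crystals are excluded from the
    fit evaluation entirely.
    """
    rows = [r for r, _ in nodes]
    cols = [c for _, c in nodes]
    r_lo = max(min(rows) - dilate, 0)
    r_hi = min(max(rows) + dilate, labels.shape[0] - 1)
    c_lo = max(min(cols) - dilate, 0)
    c_hi = min(max(cols) + dilate, labels.shape[1] - 1)
    zero = []
    for r in range(r_lo, r_hi + 1):
        for c in range(c_lo, c_hi + 1):
            if labels[r, c] == NO_SIGNAL and score[r, c] <= config.score_floor:
                zero.append((r, c))
    return zero


def render_map(
    crystal_map: CrystalMap,
    path,
    png: bool = False,
    score: np.ndarray | None = None,
) -> None:
    """Write the label grid as CSV; optionally render a PNG crystal map.

    The raster shows crystal regions in the cycling 9-colour palette,
    tinted by diffraction score when given, multi-pattern zones in grey,
    and the fitted ellipse outline over each crystal.
    """
    from pathlib import Path

    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    np.savetxt(root / "labels.csv", crystal_map.labels, delimiter=",", fmt="%d")
    if not png:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse
    except Exception:  # pragma: no cover
        logger.warning("matplotlib unavailable; wrote labels.csv only")
        return

    labels = crystal_map.labels
    n_rows, n_cols = labels.shape
    rgb = np.ones((n_rows, n_cols, 3))
    rgb[labels == MULTIPATTERN] = (0.5, 0.5, 0.5)
    if score is not None and score.max() > 0:
        tint = 0.35 + 0.65 * score / score.max()
    else:
        tint = np.ones_like(labels, dtype=float)
    for cid in range(1, labels.max() + 1):
        mask = labels == cid
        colour = np.array(PALETTE[(cid - 1) % N_PALETTE])
        rgb[mask] = colour * tint[mask][:, None]

    fig, ax = plt.subplots(figsize=(max(4, n_cols / 4), max(3, n_rows / 4)))
    ax.imshow(rgb, origin="upper", interpolation="nearest")
    for fit in crystal_map.fits:
        ax.add_patch(
            Ellipse(
                (fit.x0, fit.y0),
                width=2 * fit.a,
                height=2 * fit.b,
                angle=fit.phi,
                fill=False,
                edgecolor="black",
                linewidth=1.0,
            )
        )
        ax.annotate(str(fit.rank), (fit.x0, fit.y0), color="black", fontsize=8)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.savefig(root / "crystal_map.png", dpi=150, bbox_inches="tight")
    plt.close(fig)
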