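"""Semi-ellipsoid crystal shape fitting and ranking.

Each crystal's diffraction scores, viewed as heights over the mesh plane,
are approximated by a semi-ellipsoid

    E(x, y) = H * sqrt(max(0, 1 - u^2/a^2 - v^2/b^2))
    u =  (x - x0) cos(phi) + (y - y0) sin(phi)
    v = -(x - x0) sin(phi) + (y - y0) cos(phi)

fitted by differential evolution on the weighted least-squares objective

    F(theta) = sum_i alpha_i * (E(x_i, y_i; theta) - score_i)^2

over the crystal's own nodes (alpha = 1) plus surrounding no-diffraction
nodes (score 0, alpha = penalty_weight, which penalizes nonzero fit where
nothing diffracts); nodes belonging to other crystals or to multi-pattern
zones are excluded.  The fitted integral diffraction signal
I = (2/3) pi a b H ranks the crystals for subsequent data collection.

Mesh coordinates: x = column index, y = row index (grid units); phi is the
in-plane angle of the major axis from the column direction, reported in
[0, 180) with a >= b (the (a, b, phi) <-> (b, a, phi+90) degeneracy is
canonicalized away).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from .core import AnalysisConfig

__all__ = ["CrystalFit", "semi_ellipsoid", "fit_crystal_shape", "rank_crystals"]


@dataclass
class CrystalFit:
    """Fitted semi-ellipsoid parameters of one crystal."""

    crystal_id: int
    height: float  # H, peak diffraction score
    x0: float  # centre, column grid units
    y0: float  # centre, row grid units
    a: float  # major semi-axis (grid units), a >= b
    b: float  # minor semi-axis (grid units)
    phi: float  # major-axis angle, degrees in [0, 180)
    fit_residual: float
    node_count: int
    rank: int = 0
    fallback: bool = False  # True when the optimizer failed

    @property
    def integral_signal(self) -> float:
        """I = (2/3) pi a b H, the crystal's total diffraction signal."""
        return (2.0 / 3.0) * np.pi * self.a * self.b * self.height

    def to_dict(self) -> dict:
        return {
            "id": self.crystal_id,
            "H": self.height,
            "x0": self.x0,
            "y0": self.y0,
            "a": self.a,
            "b": self.b,
            "phi": self.phi,
            "I": self.integral_signal,
            "rank": self.rank,
            "node_count": self.node_count,
            "fit_residual": self.fit_residual,
            "fallback": self.fallback,
        }


def semi_ellipsoid(
    x: np.ndarray, y: np.ndarray, params: tuple[float, ...]
) -> np.ndarray:
    """Evaluate the semi-ellipsoid surface at mesh coordinates (x, y).

    ``params`` is (H, x0, y0, a, b, phi_degrees).
    """
    h, x0, y0, a, b, phi = params
    rad = np.radians(phi)
    dx = np.asarray(x, dtype=float) - x0
    dy = np.asarray(y, dtype=float) - y0
    u = dx * np.cos(rad) + dy * np.sin(rad)
    v = -dx * np.sin(rad) + dy * np.cos(rad)
    val = 1.0 - (u / a) ** 2 - (v / b) ** 2
    return h * np.sqrt(np.maximum(val, 0.0))


def _canonicalize(params: np.ndarray) -> np.ndarray:
    """Report a >= b with phi folded into [0, 180)."""
    h, x0, y0, a, b, phi = params
    if b > a:
        a, b = b, a
        phi += 90.0
    phi %= 180.0
    return np.array([h, x0, y0, a, b, phi])


def fit_crystal_shape(
    crystal_id: int,
    nodes: list[tuple[int, int]],
    scores: np.ndarray,
    zero_nodes: list[tuple[int, int]],
    config: AnalysisConfig | None = None,
    grid_shape: tuple[int, int] | None = None,
    max_iter: int = 300,
) -> CrystalFit:
    """Fit a semi-ellipsoid to one crystal's score diagram.

    Parameters
    ----------
    nodes : list of (row, col)
        The crystal's own grid nodes.
    scores : array
        Diffraction score of each node, same order.
    zero_nodes : list of (row, col)
        No-diffraction nodes in the surrounding neighbourhood; they enter
        the objective with target 0 and weight ``penalty_weight``.
    grid_shape : optional
        Used to bound the semi-axes; defaults to the data extent.

    Notes
    -----
    Global optimization by differential evolution with a fixed seed
    (``config.de_seed``); bounds: centre within the node bounding box
    dilated by 2, semi-axes in (0.3, max grid dimension), H in
    (0, 2 * max score], phi in [0, 180).  If the optimizer fails, a
    bounding-box fallback fit is returned with ``fallback=True``.
    """
    config = config or AnalysisConfig()
    scores = np.asarray(scores, dtype=float)
    if len(nodes) == 0 or not (scores > 0).any():
        raise ValueError("need at least one node with positive score")

    ys = np.array([r for r, _ in nodes], dtype=float)
    xs = np.array([c for _, c in nodes], dtype=float)
    zy = np.array([r for r, _ in zero_nodes], dtype=float)
    zx = np.array([c for _, c in zero_nodes], dtype=float)
    ex = np.concatenate([xs, zx])
    ey = np.concatenate([ys, zy])
    target = np.concatenate([scores, np.zeros(len(zero_nodes))])
    weight = np.concatenate(
        [np.ones(len(nodes)), np.full(len(zero_nodes), config.penalty_weight)]
    )

    def objective(theta: np.ndarray) -> float:
        resid = semi_ellipsoid(ex, ey, theta) - target
        return float(np.sum(weight * resid**2))

    max_dim = float(max(grid_shape)) if grid_shape else max(
        xs.max() - xs.min(), ys.max() - ys.min(), 1.0
    ) + 2.0
    smax = scores.max()
    bounds = [
        (1e-6, 2.0 * smax),  # H
        (xs.min() - 2.0, xs.max() + 2.0),  # x0
        (ys.min() - 2.0, ys.max() + 2.0),  # y0
        (0.3, max_dim),  # a
        (0.3, max_dim),  # b
        (0.0, 180.0),  # phi
    ]
    try:
        result = differential_evolution(
            objective,
            bounds,
            seed=config.de_seed,
            maxiter=max_iter,
            popsize=20,
            tol=1e-10,
            polish=True,
        )
        params = _canonicalize(result.x)
        return CrystalFit(
            crystal_id=crystal_id,
            height=float(params[0]),
            x0=float(params[1]),
            y0=float(params[2]),
            a=float(params[3]),
            b=float(params[4]),
            phi=float(params[5]),
            fit_residual=float(result.fun),
            node_count=len(nodes),
        )
    except Exception:
        # bounding-box fallback: centre of mass + half-extent axes
        total = scores.sum()
        x0 = float((xs * scores).sum() / total)
        y0 = float((ys * scores).sum() / total)
        a = max(float(xs.max() - xs.min()) / 2.0, 0.5)
        b = max(float(ys.max() - ys.min()) / 2.0, 0.5)
        params = _canonicalize(np.array([smax, x0, y0, a, b, 0.0]))
        resid = semi_ellipsoid(ex, ey, params) - target
        return CrystalFit(
            crystal_id=crystal_id,
            height=float(params[0]),
            x0=float(params[1]),
            y0=float(params[2]),
            a=float(params[3]),
            b=float(params[4]),
            phi=float(params[5]),
            fit_residual=float(np.sum(weight * resid**2)),
            node_count=len(nodes),
            fallback=True,
        )


def rank_crystals(fits: list[CrystalFit]) -> list[CrystalFit]:
    """Sort crystals by descending integral signal I (stable on ties by
    crystal id) and stamp 1-based ranks."""
    ordered = sorted(fits, key=lambda f: (-f.integral_signal, f.crystal_id))
    for rank, fit in enumerate(ordered, start=1):
        fit.rank = rank
    return ordered
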