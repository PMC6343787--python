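"""Reading and writing mesh-scan bundles and crystal reports.

Bundle layout (one directory)::

    geometry.yaml          key-value experiment geometry
    scores.csv             n_rows x n_cols diffraction scores, row-major
    spots/r{row}_c{col}.tsv  per-node spot table, columns x, y, intensity

Report layout::

    crystals.json          ranked crystal table + run metadata
    labels.csv             per-node integer label grid

Omega angles are not stored per node: they are fully determined by
``omega_start`` and ``omega_per_image`` in the geometry (row-major image
order) and are reconstructed on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import yaml

from .core import AnalysisConfig, ExperimentGeometry, MeshScan, NodeRecord, Spot

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import CrystalMap
    from .shapefit import CrystalFit

__all__ = [
    "read_scan_bundle",
    "write_scan_bundle",
    "write_crystal_report",
    "read_crystal_report",
    "BundleFormatError",
    "BundleConsistencyError",
]


class BundleFormatError(ValueError):
    """Malformed geometry or spot table."""


class BundleConsistencyError(ValueError):
    """Bundle contents disagree with the declared geometry."""


_GEOMETRY_KEYS = {
    "wavelength",
    "detector_distance",
    "pixel_size",
    "beam_centre",
    "detector_shape",
    "grid_shape",
    "omega_per_image",
    "omega_start",
}


def _geometry_to_dict(geometry: ExperimentGeometry) -> dict:
    d = dataclasses.asdict(geometry)
    d["beam_centre"] = list(d["beam_centre"])
    d["detector_shape"] = list(d["detector_shape"])
    d["grid_shape"] = list(d["grid_shape"])
    return d


def _geometry_from_dict(d: dict) -> ExperimentGeometry:
    missing = _GEOMETRY_KEYS - {"omega_per_image", "omega_start"} - set(d)
    if missing:
        raise BundleFormatError(f"geometry is missing keys: {sorted(missing)}")
    try:
        return ExperimentGeometry(
            wavelength=float(d["wavelength"]),
            detector_distance=float(d["detector_distance"]),
            pixel_size=float(d["pixel_size"]),
            beam_centre=tuple(float(v) for v in d["beam_centre"]),
            detector_shape=tuple(int(v) for v in d["detector_shape"]),
            grid_shape=tuple(int(v) for v in d["grid_shape"]),
            omega_per_image=float(d.get("omega_per_image", 0.0)),
            omega_start=float(d.get("omega_start", 0.0)),
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise BundleFormatError(f"malformed geometry: {exc}") from exc


def _spot_path(root: Path, row: int, col: int) -> Path:
    return root / "spots" / f"r{row}_c{col}.tsv"


def write_scan_bundle(scan: MeshScan, path: str | Path) -> Path:
    """Write a mesh scan to a bundle directory; returns the directory."""
    root = Path(path)
    (root / "spots").mkdir(parents=True, exist_ok=True)
    with open(root / "geometry.yaml", "w") as fh:
        yaml.safe_dump(_geometry_to_dict(scan.geometry), fh, sort_keys=True)
    np.savetxt(root / "scores.csv", scan.score_grid(), delimiter=",", fmt="%.17g")
    for node in scan:
        arr = node.spot_array()
        with open(_spot_path(root, node.row, node.col), "w") as fh:
            fh.write("x\ty\tintensity\n")
            for x, y, i in arr:
                fh.write(f"{x:.17g}\t{y:.17g}\t{i:.17g}\n")
    return root


def read_scan_bundle(path: str | Path) -> MeshScan:
    """Load a mesh scan from a bundle directory.

    Raises
    ------
    BundleFormatError
        If the geometry file is missing or malformed.
    BundleConsistencyError
        If the score grid shape disagrees with the geometry or a per-node
        spot table is missing.
    """
    root = Path(path)
    geom_file = root / "geometry.yaml"
    if not geom_file.exists():
        raise BundleFormatError(f"no geometry.yaml in {root}")
    with open(geom_file) as fh:
        geometry = _geometry_from_dict(yaml.safe_load(fh))

    scores = np.loadtxt(root / "scores.csv", delimiter=",", ndmin=2)
    if scores.shape != geometry.grid_shape:
        raise BundleConsistencyError(
            f"score grid is {scores.shape} but geometry declares "
            f"{geometry.grid_shape}"
        )

    nodes = []
    for row in range(geometry.n_rows):
        for col in range(geometry.n_cols):
            spot_file = _spot_path(root, row, col)
            if not spot_file.exists():
                raise BundleConsistencyError(f"missing spot table {spot_file}")
            lines = spot_file.read_text().splitlines()
            if len(lines) > 1:
                table = np.loadtxt(spot_file, delimiter="\t", skiprows=1, ndmin=2)
                spots = [Spot(x, y, i) for x, y, i in table]
            else:
                spots = []
            nodes.append(
                NodeRecord(
                    row=row,
                    col=col,
                    score=float(scores[row, col]),
                    spots=spots,
                    omega=geometry.omega_of(row, col),
                )
            )
    return MeshScan(geometry, nodes)


def write_crystal_report(
    crystal_map: "CrystalMap",
    fits: list["CrystalFit"],
    path: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write crystals.json (ranked table + metadata) and labels.csv."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    table = [fit.to_dict() for fit in fits]
    meta: dict = {"seed": seed}
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
        meta["config"]["fit_range"] = list(config.fit_range)
    payload = {"crystals": table, "metadata": meta}
    with open(root / "crystals.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    np.savetxt(root / "labels.csv", crystal_map.labels, delimiter=",", fmt="%d")
    return root


def read_crystal_report(path: str | Path) -> tuple[np.ndarray, list[dict]]:
    """Reload a crystal report: (label grid, list of crystal dicts)."""
    root = Path(path)
    labels = np.loadtxt(root / "labels.csv", delimiter=",", ndmin=2).astype(int)
    with open(root / "crystals.json") as fh:
        payload = json.load(fh)
    return labels, payload["crystals"]
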