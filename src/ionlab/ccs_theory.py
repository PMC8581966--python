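"""Projection-approximation (PA) collision cross sections from 3-D
structures.

The PA treats the ion as a rigid union of hard spheres (atomic collision
radius + buffer-gas probe radius) and estimates CCS as the projected
shadow area averaged over uniformly random orientations:

    CCS = < area( union of projected disks ) >_orientations

Within each orientation the union area is estimated by Monte-Carlo
sampling of the 2-D bounding box; orientations are drawn as uniform random
rotations. The per-element collision radii for N2 drift gas are
configuration (an editable YAML shipped with the package), not ground
truth.

`grid_projection_ccs` is a deliberately independent brute-force
cross-check: it rasterises the projection on a fine fixed grid instead of
sampling it, and exists so the Monte-Carlo path can be validated against
it on small systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Union
import warnings

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "Geometry",
    "RadiiTable",
    "PAResult",
    "read_xyz",
    "write_xyz",
    "load_radii",
    "default_radii",
    "pa_ccs",
    "grid_projection_ccs",
    "XYZFormatError",
]


class XYZFormatError(ValueError):
    """Malformed XYZ file."""


@dataclass
class Geometry:
    symbols: List[str]
    coords: np.ndarray  # (N, 3) Å
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.symbols) == 0:
            raise ValueError("geometry must contain at least one atom")
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class RadiiTable:
    """Element -> collision radius (Å) vs the drift gas, plus probe radius."""

    radii: Dict[str, float]
    probe_radius: float = 1.0

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        for el, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"radius for {el} must be positive")

    def effective(self, symbols: List[str]) -> np.ndarray:
        out = []
        for s in symbols:
            if s not in self.radii:
                raise KeyError(f"no collision radius for element {s!r}")
            out.append(self.radii[s] + self.probe_radius)
        return np.asarray(out)


@dataclass
class PAResult:
    ccs_A2: float
    stderr_A2: float
    n_orientations: int
    n_samples: int
    seed: Optional[int] = None
    per_orientation: np.ndarray = field(default_factory=lambda: np.array([]))


def read_xyz(path: Union[str, Path]) -> Geometry:
    """Read a standard XYZ file (count line, comment line, atom rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: line 1: expected an atom count")
    rows = [ln for ln in lines[2 : 2 + n]]
    if len(rows) < n:
        raise XYZFormatError(f"{path}: header declares {n} atoms, found {len(rows)}")
    symbols, coords = [], []
    for i, ln in enumerate(rows, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: line {i}: expected 'El x y z'")
        symbols.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise XYZFormatError(f"{path}: line {i}: non-numeric coordinate")
    comment = lines[1].strip() if len(lines) > 1 else ""
    return Geometry(symbols, np.asarray(coords), label=comment or path.stem)


def write_xyz(geom: Geometry, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geom)}\n{geom.label}\n")
        for s, (x, y, z) in zip(geom.symbols, geom.coords):
            fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def load_radii(path: Union[str, Path]) -> RadiiTable:
    data = yaml.safe_load(Path(path).read_text())
    return RadiiTable(radii=dict(data["radii"]), probe_radius=float(data.get("probe_radius", 1.0)))


def default_radii() -> RadiiTable:
    """Packaged N2 collision-radius table (editable configuration)."""
    ref = resources.files("ionlab").joinpath("data/radii_n2.yaml")
    data = yaml.safe_load(ref.read_text())
    return RadiiTable(radii=dict(data["radii"]), probe_radius=float(data.get("probe_radius", 1.0)))


def _random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    return Rotation.random(n, random_state=rng)


def _projected_union_area_mc(
    xy: np.ndarray, radii: np.ndarray, n_samples: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo area of a union of disks in the plane."""
    lo = (xy - radii[:, None]).min(axis=0)
    hi = (xy + radii[:, None]).max(axis=0)
    box = np.prod(hi - lo)
    pts = rng.uniform(lo, hi, size=(n_samples, 2))
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    inside = (d2 <= radii[None, :] ** 2).any(axis=1)
    return float(box * inside.mean())


def pa_ccs(
    geom: Geometry,
    radii: RadiiTable,
    n_orientations: int = 300,
    n_samples: int = 4000,
    seed: Optional[int] = None,
) -> PAResult:
    """Orientation-averaged projection-approximation CCS (Å²).

    The Monte-Carlo standard error is the standard deviation of the
    per-orientation area estimates over sqrt(n_orientations); it therefore
    folds in both orientational variance and within-orientation sampling
    noise.
    """
    if n_orientations < 1:
        raise ValueError("need at least one orientation")
    eff = radii.effective(geom.symbols)
    rng = np.random.default_rng(seed)
    rots = _random_rotations(n_orientations, rng)
    areas = np.empty(n_orientations)
    coords = geom.coords - geom.coords.mean(axis=0)
    for i in range(n_orientations):
        xy = rots[i].apply(coords)[:, :2]
        areas[i] = _projected_union_area_mc(xy, eff, n_samples, rng)
    mean = float(areas.mean())
    se = float(areas.std(ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    if n_orientations > 1 and se > 0.05 * mean:
        warnings.warn(
            f"PA CCS standard error {se:.2f} exceeds 5% of the mean; "
            "increase n_orientations or n_samples",
            stacklevel=2,
        )
    return PAResult(mean, se, n_orientations, n_samples, seed, areas)


def grid_projection_ccs(
    geom: Geometry,
    radii: RadiiTable,
    grid_step: float = 0.01,
    n_orientations: int = 100,
    seed: Optional[int] = None,
) -> PAResult:
    """Brute-force PA CCS by fine-grid rasterisation of each projection.

    Independent of the Monte-Carlo path: for each random orientation the
    union-of-disks area is counted on a fixed rectangular grid of pitch
    `grid_step`. Accurate to O(grid_step * perimeter); intended as an
    oracle for validating `pa_ccs` on small geometries.
    """
    eff = radii.effective(geom.symbols)
    rng = np.random.default_rng(seed)
    rots = _random_rotations(n_orientations, rng)
    coords = geom.coords - geom.coords.mean(axis=0)
    areas = np.empty(n_orientations)
    cell = grid_step * grid_step
    for i in range(n_orientations):
        xy = rots[i].apply(coords)[:, :2]
        lo = (xy - eff[:, None]).min(axis=0) - grid_step
        hi = (xy + eff[:, None]).max(axis=0) + grid_step
        gx = np.arange(lo[0], hi[0], grid_step)
        gy = np.arange(lo[1], hi[1], grid_step)
        covered = np.zeros((gx.size, gy.size), dtype=bool)
        for (cx, cy), r in zip(xy, eff):
            # restrict the test to the disk's bounding sub-grid
            ix = slice(np.searchsorted(gx, cx - r), np.searchsorted(gx, cx + r))
            iy = slice(np.searchsorted(gy, cy - r), np.searchsorted(gy, cy + r))
            dx = gx[ix] - cx
            dy = gy[iy] - cy
            covered[ix, iy] |= dx[:, None] ** 2 + dy[None, :] ** 2 <= r * r
        areas[i] = covered.sum() * cell
    mean = float(areas.mean())
    se = float(areas.std(ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return PAResult(mean, se, n_orientations, 0, seed, areas)
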