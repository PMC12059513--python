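"""Dose-LET volume histograms (DLVH).

The DLVH index V(d, l) is the volume of a structure receiving a dose of at
least ``d`` Gy[RBE] *and* a dose-averaged LET of at least ``l`` keV/µm — a
joint cumulative histogram over the structure's voxels, tabulated on a
(dose, LETd) grid.  Both thresholds are closed (>=).  V is non-increasing
along both axes; normalized surfaces have V(0, 0) = 100% and reduce to the
ordinary cumulative DVH along l = 0 and to the LETd-volume histogram along
d = 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import find_contours

from .grids import (
    FormatError,
    ScalarField,
    StructureMask,
    ValidationError,
    check_alignment,
)

__all__ = [
    "DEFAULT_DOSE_GRID",
    "DEFAULT_LET_GRID",
    "DEFAULT_ISO_VOLUME_LEVELS",
    "default_dose_grid",
    "default_let_grid",
    "DLVHSurface",
    "ContourLine",
    "compute_dlvh",
    "query_index",
    "iso_volume_lines",
    "export_dlvh",
    "import_dlvh",
]

# Scan increments of 2 Gy[RBE] in dose and 0.2 keV/µm in LETd; upper bounds
# cover conventional chest-wall prescriptions (incl. boosts) and the LETd
# range seen at the distal falloff.
DEFAULT_DOSE_STEP = 2.0
DEFAULT_LET_STEP = 0.2
DEFAULT_DOSE_MAX = 70.0
DEFAULT_LET_MAX = 8.0
DEFAULT_ISO_VOLUME_LEVELS = (5.0, 20.0, 50.0, 80.0, 95.0)


def default_dose_grid(dose_max: float = DEFAULT_DOSE_MAX,
                      step: float = DEFAULT_DOSE_STEP) -> np.ndarray:
    return np.round(np.arange(0.0, dose_max + step / 2, step), 10)


def default_let_grid(let_max: float = DEFAULT_LET_MAX,
                     step: float = DEFAULT_LET_STEP) -> np.ndarray:
    return np.round(np.arange(0.0, let_max + step / 2, step), 10)


DEFAULT_DOSE_GRID = default_dose_grid()
DEFAULT_LET_GRID = default_let_grid()


@dataclass(frozen=True)
class DLVHSurface:
    """V(d, l) tabulated on a (dose, LETd) grid.

    ``volume[a, b]`` is V(dose_grid[a], let_grid[b]) in % of the structure
    volume if ``normalized`` else in cc.
    """

    dose_grid: np.ndarray
    let_grid: np.ndarray
    volume: np.ndarray
    normalized: bool
    total_volume_cc: float

    def __post_init__(self):
        object.__setattr__(self, "dose_grid", np.asarray(self.dose_grid, dtype=float))
        object.__setattr__(self, "let_grid", np.asarray(self.let_grid, dtype=float))
        object.__setattr__(self, "volume", np.asarray(self.volume, dtype=float))
        if self.volume.shape != (len(self.dose_grid), len(self.let_grid)):
            raise ValidationError("volume shape does not match grids")

    def same_grid(self, other: "DLVHSurface") -> bool:
        return (
            np.array_equal(self.dose_grid, other.dose_grid)
            and np.array_equal(self.let_grid, other.let_grid)
        )


@dataclass(frozen=True)
class ContourLine:
    """A level-set polyline in the (dose, LETd) plane."""

    level: float
    vertices: np.ndarray  # (n, 2) columns (dose, letd)


def _validate_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 1:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence")
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise ValidationError(f"{name} must be strictly increasing")
    if grid[0] != 0:
        raise ValidationError(f"{name} must start at 0, got {grid[0]:g}")
    return grid


def compute_dlvh(dose: ScalarField, letd: ScalarField, mask: StructureMask,
                 dose_grid=None, let_grid=None, normalized: bool = True) -> DLVHSurface:
    """Compute the DLVH surface of ``mask`` from paired dose/LETd fields.

    Exact at every grid node: V[a, b] counts the mask voxels with
    dose >= dose_grid[a] and letd >= let_grid[b] (times the voxel volume),
    computed by binning voxels once and tail-summing the 2-D histogram.
    """
    check_alignment(dose, letd, mask)
    if mask.n_voxels == 0:
        raise ValidationError(f"mask {mask.label!r} is empty")
    dose_grid = _validate_grid(
        DEFAULT_DOSE_GRID if dose_grid is None else dose_grid, "dose_grid")
    let_grid = _validate_grid(
        DEFAULT_LET_GRID if let_grid is None else let_grid, "let_grid")

    d_vox = dose.values[mask.values]
    l_vox = letd.values[mask.values]
    # voxel falls in bin a iff dose_grid[a] <= d < dose_grid[a+1]; the tail
    # sum over bins >= a then counts voxels with d >= dose_grid[a] exactly,
    # including voxels equal to a node value (closed thresholds).
    di = np.searchsorted(dose_grid, d_vox, side="right") - 1
    li = np.searchsorted(let_grid, l_vox, side="right") - 1
    counts = np.zeros((len(dose_grid), len(let_grid)))
    np.add.at(counts, (di, li), 1.0)
    tail = counts[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]

    total_cc = mask.volume_cc
    if normalized:
        volume = tail / mask.n_voxels * 100.0
    else:
        volume = tail * mask.voxel_volume_cc
    return DLVHSurface(dose_grid, let_grid, volume, normalized, total_cc)


def query_index(dose: ScalarField, letd: ScalarField, mask: StructureMask,
                d: float, l: float, normalized: bool = True) -> float:
    """V(d, l) recomputed exactly from the voxels (no grid interpolation)."""
    check_alignment(dose, letd, mask)
    if mask.n_voxels == 0:
        raise ValidationError(f"mask {mask.label!r} is empty")
    hit = int(((dose.values >= d) & (letd.values >= l) & mask.values).sum())
    if normalized:
        return hit / mask.n_voxels * 100.0
    return hit * mask.voxel_volume_cc


def iso_volume_lines(surface: DLVHSurface,
                     levels=DEFAULT_ISO_VOLUME_LEVELS) -> list[ContourLine]:
    """Iso-volume lines DLv% of a normalized surface in the (dose, LETd) plane.

    Marching-squares level sets with linear interpolation between grid
    nodes; levels outside the surface's value range yield no lines.
    """
    if not surface.normalized:
        raise ValidationError("iso-volume lines require a normalized (%) surface")
    lines: list[ContourLine] = []
    for level in levels:
        for contour in find_contours(surface.volume, level):
            vertices = np.column_stack([
                np.interp(contour[:, 0], np.arange(len(surface.dose_grid)),
                          surface.dose_grid),
                np.interp(contour[:, 1], np.arange(len(surface.let_grid)),
                          surface.let_grid),
            ])
            lines.append(ContourLine(level=float(level), vertices=vertices))
    return lines


# ---------------------------------------------------------------------------
# Long-format CSV export: metadata header, then one (d, l, V) row per node.
# ---------------------------------------------------------------------------

_DLVH_MAGIC = "# dlvhkit-dlvh v1"


def export_dlvh(surface: DLVHSurface, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_DLVH_MAGIC}\n")
        fh.write(f"# normalized={str(surface.normalized).lower()}\n")
        fh.write(f"# total_volume_cc={float(surface.total_volume_cc)!r}\n")
        fh.write("d,l,V\n")
        for a, d in enumerate(surface.dose_grid):
            for b, l in enumerate(surface.let_grid):
                fh.write(f"{float(d)!r},{float(l)!r},{float(surface.volume[a, b])!r}\n")


def import_dlvh(path) -> DLVHSurface:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _DLVH_MAGIC:
        raise FormatError(f"{path}: not a dlvhkit DLVH CSV (bad header)")
    meta = {}
    body_start = 0
    for n, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
        else:
            body_start = n
            break
    if "normalized" not in meta or "total_volume_cc" not in meta:
        raise FormatError(f"{path}: missing metadata header")
    import pandas as pd

    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    if list(df.columns) != ["d", "l", "V"] or df.empty:
        raise FormatError(f"{path}: expected non-empty columns d,l,V")
    dose_grid = np.unique(df["d"].to_numpy())
    let_grid = np.unique(df["l"].to_numpy())
    if len(df) != len(dose_grid) * len(let_grid):
        raise FormatError(f"{path}: incomplete (d, l) grid")
    volume = (
        df.sort_values(["d", "l"])["V"].to_numpy().reshape(len(dose_grid), len(let_grid))
    )
    return DLVHSurface(
        dose_grid=dose_grid, let_grid=let_grid, volume=volume,
        normalized=meta["normalized"] == "true",
        total_volume_cc=float(meta["total_volume_cc"]),
    )
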