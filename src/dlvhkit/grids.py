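"""Geometry-aware containers and I/O for paired dose/LETd volumes.

All gridded arrays in this package are indexed ``values[i, j, k]`` with
``(i, j, k)`` mapping to the ``(x, y, z)`` spatial axes; ``spacing`` and
``origin`` follow the same ``(x, y, z)`` order in millimetres.  Two fields
are *aligned* iff shape, spacing and origin agree exactly — misaligned
inputs are rejected, never resampled, because the downstream joint
histogram depends on voxel-level dose/LETd pairing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "DLVHError",
    "ValidationError",
    "AlignmentError",
    "FormatError",
    "ScalarField",
    "StructureMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_voxel_table",
    "check_alignment",
    "load_cohort_table",
    "validate_cohort_table",
]

AXIS_ORDER = "xyz"

_FORMAT_SUFFIXES = {"nrrd": (".nrrd",), "metaimage": (".mha", ".mhd")}


class DLVHError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(DLVHError, ValueError):
    """An input value violates a domain invariant."""


class AlignmentError(DLVHError, ValueError):
    """Two gridded volumes do not share geometry."""


class FormatError(DLVHError, ValueError):
    """A file does not parse under the named format."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"expected a length-3 tuple, got {x!r}")
    return t


@dataclass(frozen=True)
class ScalarField:
    """A 3-D gridded scalar (dose in Gy[RBE] or LETd in keV/µm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER

    def __post_init__(self):
        values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if values.ndim != 3:
            raise ValidationError(f"values must be 3-D, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.axis_order != AXIS_ORDER:
            raise ValidationError(f"axis_order must be {AXIS_ORDER!r}")
        if not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise ValidationError(f"values contain {n_bad} non-finite voxel(s)")
        if (values < 0).any():
            idx = np.unravel_index(int(np.argmin(values)), values.shape)
            raise ValidationError(
                f"negative value {values.min():g} at voxel {tuple(int(i) for i in idx)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def geometry(self) -> tuple:
        return (self.shape, self.spacing, self.origin)

    def aligned_with(self, other: "ScalarField | StructureMask") -> bool:
        return self.geometry() == other.geometry()


@dataclass(frozen=True)
class StructureMask:
    """A 3-D boolean mask sharing geometry with its companion fields."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "structure"
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self):
        values = np.ascontiguousarray(np.asarray(self.values))
        if values.dtype != bool:
            if not np.isin(values, (0, 1)).all():
                raise ValidationError("mask values must be boolean or 0/1")
            values = values.astype(bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if values.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    shape = ScalarField.shape
    voxel_volume_mm3 = ScalarField.voxel_volume_mm3
    voxel_volume_cc = ScalarField.voxel_volume_cc
    geometry = ScalarField.geometry
    aligned_with = ScalarField.aligned_with

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_cc


# ---------------------------------------------------------------------------
# Gridded-volume I/O (NRRD / MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def _check_format(path: Path, format: str | None) -> str:
    if format is None:
        for name, suffixes in _FORMAT_SUFFIXES.items():
            if path.suffix.lower() in suffixes:
                return name
        raise FormatError(f"cannot infer format from suffix {path.suffix!r}")
    if format not in _FORMAT_SUFFIXES:
        raise FormatError(
            f"unsupported format {format!r}; expected one of {sorted(_FORMAT_SUFFIXES)}"
        )
    return format


def read_volume(path, format: str | None = None) -> ScalarField:
    """Read a dose or LETd volume from NRRD or MetaImage.

    Values are returned unchanged (no resampling).  Negative or non-finite
    voxels raise :class:`ValidationError` naming the offending extremum.
    """
    path = Path(path)
    _check_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # malformed header
        raise FormatError(f"could not parse {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0).astype(np.float64))
    return ScalarField(values=values, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(field: ScalarField, path, format: str | None = None) -> None:
    """Write a field so that ``read_volume`` round-trips values and geometry."""
    path = Path(path)
    _check_format(path, format)
    img = sitk.GetImageFromArray(field.values.transpose(2, 1, 0))
    img.SetSpacing(field.spacing)
    img.SetOrigin(field.origin)
    try:
        sitk.WriteImage(img, str(path), useCompression=False)
    except RuntimeError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def read_mask(path, format: str | None = None, label: str = "structure") -> StructureMask:
    """Read a 0/1 volume as a boolean structure mask."""
    f = read_volume(path, format=format)
    if not np.isin(f.values, (0.0, 1.0)).all():
        raise ValidationError(f"{path} is not a 0/1 mask volume")
    return StructureMask(values=f.values.astype(bool), spacing=f.spacing,
                         origin=f.origin, label=label)


def write_mask(mask: StructureMask, path, format: str | None = None) -> None:
    f = ScalarField(values=mask.values.astype(np.float64), spacing=mask.spacing,
                    origin=mask.origin)
    write_volume(f, path, format=format)


# ---------------------------------------------------------------------------
# CSV voxel-table fixture dialect
# ---------------------------------------------------------------------------
#
#   # spacing=dx,dy,dz
#   i,j,k,dose,letd,in_mask
#   0,0,0,30.0,4.0,1
#
# Indices are 0-based; unlisted voxels within the bounding box of the listed
# indices get dose=0, letd=0, in_mask=false.

def read_voxel_table(path) -> tuple[ScalarField, ScalarField, StructureMask]:
    path = Path(path)
    spacing = None
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#") and "spacing=" in line:
            spec = line.split("spacing=", 1)[1]
            spacing = _as_triple(spec.split(","))
            break
        if line and not line.startswith("#"):
            break
    if spacing is None:
        raise FormatError(f"{path}: missing '# spacing=dx,dy,dz' header comment")
    df = pd.read_csv(io.StringIO(text), comment="#")
    required = {"i", "j", "k", "dose", "letd", "in_mask"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    ijk = df[["i", "j", "k"]].to_numpy()
    if not np.issubdtype(ijk.dtype, np.integer):
        raise FormatError(f"{path}: voxel indices must be integers")
    if df.duplicated(subset=["i", "j", "k"]).any():
        dup = df[df.duplicated(subset=["i", "j", "k"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate voxel index ({dup.i}, {dup.j}, {dup.k})"
        )
    lo = ijk.min(axis=0)
    hi = ijk.max(axis=0)
    shape = tuple(int(h - l + 1) for l, h in zip(lo, hi))
    origin = tuple(float(l * s) for l, s in zip(lo, spacing))
    dose = np.zeros(shape)
    letd = np.zeros(shape)
    in_mask = np.zeros(shape, dtype=bool)
    idx = tuple((ijk - lo).T)
    dose[idx] = df["dose"].to_numpy(dtype=float)
    letd[idx] = df["letd"].to_numpy(dtype=float)
    in_mask[idx] = df["in_mask"].to_numpy().astype(bool)
    return (
        ScalarField(dose, spacing, origin),
        ScalarField(letd, spacing, origin),
        StructureMask(in_mask, spacing, origin, label=path.stem),
    )


def check_alignment(
    dose: ScalarField, letd: ScalarField, mask: StructureMask
) -> tuple[ScalarField, ScalarField, StructureMask]:
    """Pass through iff all three volumes share geometry exactly."""
    for name, other in (("letd", letd), ("mask", mask)):
        for attr in ("shape", "spacing", "origin"):
            a, b = getattr(dose, attr), getattr(other, attr)
            if a != b:
                raise AlignmentError(
                    f"dose and {name} differ in {attr}: {a} vs {b}"
                )
    return dose, letd, mask


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

COHORT_REQUIRED_COLUMNS = (
    "patient_id", "set_id", "outcome", "total_dose", "n_fractions",
)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the matched case-control cohort table.

    Every matched set must contain exactly one case (``outcome == 1``) and
    at least one control; patient ids must be unique.
    """
    if missing := set(COHORT_REQUIRED_COLUMNS) - set(df.columns):
        raise ValidationError(f"cohort table missing columns {sorted(missing)}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["set_id"] = df["set_id"].astype(str)
    df["outcome"] = df["outcome"].astype(int)
    if not df["outcome"].isin((0, 1)).all():
        raise ValidationError("outcome must be binary (1 = fracture)")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")
    if (df["n_fractions"] <= 0).any():
        raise ValidationError("n_fractions must be positive")
    for set_id, grp in df.groupby("set_id"):
        n_case = int(grp["outcome"].sum())
        n_ctrl = len(grp) - n_case
        if n_case != 1 or n_ctrl < 1:
            raise ValidationError(
                f"set {set_id!r} has {n_case} case(s) and {n_ctrl} control(s); "
                "need exactly one case and at least one control"
            )
    return df


def load_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    return validate_cohort_table(pd.read_csv(path))
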