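"""Synthetic PBS chest-wall cohorts for end-to-end testing of the DLVH
pipeline without patient data.

Fields are parameterised along the beam depth axis z and extruded to 3-D:
the dose falls off sigmoidally at the end of range R while LETd rises from
a plateau value to its distal peak just beyond R — the characteristic
anti-correlation of pencil-beam-scanning fields in which moderate dose
co-locates with high LETd at the distal edge, and voxels with LETd above
~4 keV/µm sit below the prescription dose.  Per-patient jitter of the
range and plateau plus bounded multiplicative voxel noise create the
between-patient variation in V(d, l) that the regression sees.

Outcomes follow the conditional-logistic generating model
logit P(fracture) = alpha_i + beta_true * V(d*, l*); candidate sets are
redrawn until exactly one member is a case, reproducing the matched
case-control ascertainment (given one case per set, the probability that
member j is the case is exactly exp(beta x_j)/sum_k exp(beta x_k), so
fitting CLR at (d*, l*) recovers beta_true).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dlvh import query_index
from .grids import (
    ScalarField,
    StructureMask,
    ValidationError,
    validate_cohort_table,
    write_mask,
    write_volume,
)

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "simulate_patient_fields",
    "simulate_outcomes",
    "simulate_cohort",
    "generate_cohort",
    "summarize_cohort",
]

# Matched-set counts of the reference 7-case / 14-control design (one case
# matched 1:4, two 1:1, four 1:2).
REFERENCE_CONTROLS_PER_SET = (4, 1, 1, 2, 2, 2, 2)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic matched cohort.

    Beam-model defaults are chosen to reproduce the qualitative DLVH shape
    of chest-wall PBS fields (plateau dose at the prescription level, LETd
    rising through 4-8 keV/µm across the distal falloff); they are
    synthetic, not fitted to any measured field.
    """

    n_sets: int = 7
    controls_per_set: int | Sequence[int] = 2
    shape: tuple[int, int, int] = (8, 8, 30)
    spacing: tuple[float, float, float] = (4.0, 4.0, 2.0)  # mm
    prescription: float = 50.0     # Gy[RBE]
    n_fractions: int = 25
    plateau: float | None = None   # Gy[RBE]; defaults to prescription
    range_mm: float = 40.0         # distal falloff depth R
    sigma_d: float = 3.0           # falloff width (mm)
    let_plateau: float = 2.0       # L0, keV/µm
    let_max: float = 8.0           # Lmax, keV/µm
    sigma_l: float = 4.0           # LETd rise width (mm)
    let_offset: float = 3.0        # delta: LETd rise sits past the falloff (mm)
    mask_half_thickness: float = 12.0  # chest-wall slab extent about R (mm)
    jitter_range_mm: float = 2.0   # per-patient sd of the range shift
    jitter_plateau: float = 0.02   # per-patient relative sd of the plateau
    noise_amp: float = 0.03        # bounded multiplicative voxel noise (+/-)
    generating_index: tuple[float, float] = (30.0, 4.0)  # (d*, l*)
    beta_true: float = 0.0         # log-odds per % volume
    alpha0: float = -0.7           # baseline set intercept (see simulate_outcomes)
    rejection_cap: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValidationError("n_sets must be >= 1")
        if self.let_max <= self.let_plateau or self.let_plateau <= 0:
            raise ValidationError("need Lmax > L0 > 0")
        if self.sigma_d <= 0 or self.sigma_l <= 0:
            raise ValidationError("falloff widths must be positive")
        m = self.controls_per_set
        counts = (m,) * self.n_sets if np.isscalar(m) else tuple(int(x) for x in m)
        if len(counts) != self.n_sets or any(c < 1 for c in counts):
            raise ValidationError(
                "controls_per_set must be a positive int or one per set")
        object.__setattr__(self, "controls_per_set", counts)

    @property
    def set_sizes(self) -> tuple[int, ...]:
        return tuple(1 + m for m in self.controls_per_set)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("shape", "spacing", "controls_per_set", "generating_index"):
            d[key] = list(d[key])
        return d


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    dose: ScalarField
    letd: ScalarField
    mask: StructureMask


def _sigmoid(x):
    return expit(x)


def simulate_patient_fields(spec: CohortSpec, rng: np.random.Generator,
                            patient_id: str = "P0") -> SyntheticPatient:
    """Draw one patient's paired dose/LETd fields and chest-wall mask.

    Depth profiles (z in mm from the surface):

        dose(z) = plateau_i * sigmoid((R_i - z) / sigma_d)
        letd(z) = L0 + (Lmax - L0) * sigmoid((z - R_i + delta) / sigma_l)

    with R_i and plateau_i jittered per patient and independent bounded
    multiplicative noise per voxel.  The mask is a fixed slab of
    ``2 * mask_half_thickness`` mm about the nominal range, so masks align
    across patients while their fields differ.
    """
    nx, ny, nz = spec.shape
    dz = spec.spacing[2]
    z = (np.arange(nz) + 0.5) * dz
    plateau = spec.prescription if spec.plateau is None else spec.plateau
    r_i = spec.range_mm + rng.normal(0.0, spec.jitter_range_mm)
    plateau_i = plateau * (1.0 + rng.normal(0.0, spec.jitter_plateau))
    dose_z = plateau_i * _sigmoid((r_i - z) / spec.sigma_d)
    let_z = spec.let_plateau + (spec.let_max - spec.let_plateau) * _sigmoid(
        (z - r_i + spec.let_offset) / spec.sigma_l)

    dose = np.broadcast_to(dose_z, (nx, ny, nz)).copy()
    letd = np.broadcast_to(let_z, (nx, ny, nz)).copy()
    if spec.noise_amp > 0:
        a = spec.noise_amp
        dose *= 1.0 + rng.uniform(-a, a, size=spec.shape)
        letd *= 1.0 + rng.uniform(-a, a, size=spec.shape)

    slab = np.abs(z - spec.range_mm) <= spec.mask_half_thickness
    mask = np.broadcast_to(slab, (nx, ny, nz)).copy()
    return SyntheticPatient(
        patient_id=patient_id,
        dose=ScalarField(dose, spec.spacing),
        letd=ScalarField(letd, spec.spacing),
        mask=StructureMask(mask, spec.spacing, label="chest_wall"),
    )


def simulate_outcomes(set_values: Sequence[Sequence[float]], spec: CohortSpec,
                      rng: np.random.Generator) -> list[int]:
    """Draw one case index per candidate set from the generating model.

    ``set_values[i]`` holds the members' V(d*, l*) values (%).  Each
    member's fracture probability is expit(alpha_i + beta_true * V);
    Bernoulli draws are rejected until exactly one member is a case
    (``rejection_cap`` attempts per set).  The set intercept is centred,
    alpha_i = alpha0 - beta_true * mean(V_set): the conditional likelihood
    is invariant to alpha_i, and centring keeps rejection efficient.
    Returns the case's member index for each set.
    """
    case_indices = []
    for i, values in enumerate(set_values):
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValidationError(f"candidate set {i} needs >= 2 members")
        alpha_i = spec.alpha0 - spec.beta_true * v.mean()
        probs = expit(alpha_i + spec.beta_true * v)
        for _ in range(spec.rejection_cap):
            draws = rng.random(len(v)) < probs
            if draws.sum() == 1:
                case_indices.append(int(np.argmax(draws)))
                break
        else:
            raise RuntimeError(
                f"candidate set {i}: no draw with exactly one case within "
                f"{spec.rejection_cap} attempts; adjust alpha0 or beta_true"
            )
    return case_indices


_BOOST_OPTIONS = ("none", "SIB_chest_wall", "SIB_axilla", "sequential")
_LATERALITY = ("L", "R")


def simulate_cohort(spec: CohortSpec) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate patients and a validated matched cohort table in memory.

    Fully reproducible from ``spec`` (which includes the seed).  Matching
    covariates are drawn once per set so members match; grade and
    time-to-event are sampled for cases only, to exercise the cohort
    summary.
    """
    rng = np.random.default_rng(spec.seed)
    d_star, l_star = spec.generating_index

    patients: list[SyntheticPatient] = []
    set_values: list[list[float]] = []
    set_members: list[list[str]] = []
    pid = 0
    for i, size in enumerate(spec.set_sizes):
        members, values = [], []
        for _ in range(size):
            patient = simulate_patient_fields(spec, rng, patient_id=f"P{pid:03d}")
            patients.append(patient)
            members.append(patient.patient_id)
            values.append(query_index(patient.dose, patient.letd, patient.mask,
                                      d_star, l_star, normalized=True))
            pid += 1
        set_members.append(members)
        set_values.append(values)

    case_indices = simulate_outcomes(set_values, spec, rng)

    rows = []
    for i, (members, case_idx) in enumerate(zip(set_members, case_indices)):
        # matching covariates: identical within a set
        presc = spec.prescription
        boost = _BOOST_OPTIONS[rng.integers(len(_BOOST_OPTIONS))]
        recon = bool(rng.integers(2))
        lat = _LATERALITY[rng.integers(2)]
        thickness = float(np.round(rng.uniform(8.0, 25.0), 1))
        year = int(rng.integers(2015, 2021))
        for j, member in enumerate(members):
            is_case = j == case_idx
            rows.append({
                "patient_id": member,
                "set_id": f"S{i:02d}",
                "outcome": int(is_case),
                "total_dose": presc,
                "n_fractions": spec.n_fractions,
                "grade": int(rng.choice((1, 2), p=(0.7, 0.3))) if is_case else pd.NA,
                "time_to_event_months": (
                    float(np.round(rng.uniform(3.0, 18.0), 1)) if is_case else np.nan),
                "age": int(rng.integers(30, 71)),
                "prescription_dose": presc,
                "boost_location": boost,
                "reconstruction": recon,
                "laterality": lat,
                "chest_wall_thickness_mm": thickness,
                "treatment_year": year,
            })
    table = validate_cohort_table(pd.DataFrame(rows))
    return patients, table


def generate_cohort(spec: CohortSpec, outdir) -> Path:
    """End-to-end wrapper: write volumes, cohort CSV, and a manifest.

    The manifest records the spec, seed, and a SHA-256 per written file;
    the same spec yields a byte-identical manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients, table = simulate_cohort(spec)
    files = []
    for p in patients:
        for stem, writer, obj in ((f"{p.patient_id}_dose", write_volume, p.dose),
                                  (f"{p.patient_id}_letd", write_volume, p.letd),
                                  (f"{p.patient_id}_mask", write_mask, p.mask)):
            fpath = outdir / f"{stem}.nrrd"
            writer(obj, fpath)
            files.append(fpath)
    cohort_csv = outdir / "cohort.csv"
    table.to_csv(cohort_csv, index=False)
    files.append(cohort_csv)
    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def summarize_cohort(table: pd.DataFrame, n_screened: int | None = None) -> dict:
    """Cohort summary: counts, incidence, and case time/age statistics.

    Medians are the middle order statistic (odd n) or the mean of the two
    middle values (even n); percentages are rounded to one decimal.
    """
    if len(table) == 0:
        raise ValidationError("empty cohort table")
    table = validate_cohort_table(table)
    cases = table[table["outcome"] == 1]
    summary: dict = {
        "n_cases": int(len(cases)),
        "n_controls": int((table["outcome"] == 0).sum()),
    }
    if n_screened is not None:
        summary["incidence_pct"] = round(len(cases) / n_screened * 100.0, 1)
    if "time_to_event_months" in table.columns:
        t = cases["time_to_event_months"].dropna().to_numpy(dtype=float)
        if len(t):
            summary["time_to_event_months"] = {
                "median": float(np.median(t)),
                "range": (float(t.min()), float(t.max())),
            }
    if "age" in table.columns:
        ages = table.loc[table["outcome"] == 1, "age"].dropna().to_numpy(dtype=float)
        if len(ages):
            summary["age_years"] = {
                "median": float(np.median(ages)),
                "range": (float(ages.min()), float(ages.max())),
            }
    if "grade" in table.columns:
        grades = cases["grade"].dropna().astype(int)
        summary["grade_counts"] = {
            int(g): int(n) for g, n in grades.value_counts().sort_index().items()
        }
    return summary
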