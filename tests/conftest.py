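import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dlvhkit import ScalarField, StructureMask

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def four_voxel():
    """The canonical 4-voxel fixture: (dose, letd) pairs
    (10,1), (30,4), (30,5), (50,2) on a 2x2x1 unit-spacing grid."""
    dose = np.array([[[10.0], [30.0]], [[30.0], [50.0]]])
    letd = np.array([[[1.0], [4.0]], [[5.0], [2.0]]])
    mask = np.ones((2, 2, 1), dtype=bool)
    spacing = (1.0, 1.0, 1.0)
    return (ScalarField(dose, spacing), ScalarField(letd, spacing),
            StructureMask(mask, spacing, label="toy"))


def random_fields(rng, shape=(5, 5, 5), dose_max=70.0, let_max=8.0,
                  spacing=(2.0, 2.0, 2.0)):
    """Random paired fields with a random non-empty mask."""
    dose = rng.uniform(0, dose_max, size=shape)
    letd = rng.uniform(0, let_max, size=shape)
    mask = rng.random(shape) < 0.6
    if not mask.any():
        mask.flat[0] = True
    return (ScalarField(dose, spacing), ScalarField(letd, spacing),
            StructureMask(mask, spacing))


def brute_force_dlvh(dose, letd, mask, dose_grid, let_grid, normalized=True):
    """O(voxels x bins) reference for the DLVH surface."""
    d = dose.values[mask.values]
    l = letd.values[mask.values]
    out = np.empty((len(dose_grid), len(let_grid)))
    for a, dg in enumerate(dose_grid):
        for b, lg in enumerate(let_grid):
            out[a, b] = np.count_nonzero((d >= dg) & (l >= lg))
    if normalized:
        return out / mask.n_voxels * 100.0
    return out * mask.voxel_volume_cc


# The published 7-case cohort characteristics used as a printed-table input:
# per-case age, months to fracture, toxicity grade, and matched-control count.
TABLE1_AGES = (39, 63, 56, 32, 64, 33, 54)
TABLE1_MONTHS = (14, 11, 5, 14, 14, 11, 12)
TABLE1_GRADES = (1, 2, 1, 2, 1, 1, 1)
TABLE1_CONTROLS = (2, 4, 2, 2, 2, 1, 1)
TABLE1_N_SCREENED = 216


def table1_cohort() -> pd.DataFrame:
    """Cohort table built from the printed case characteristics, with
    anonymous controls filling out each matched set."""
    rows = []
    pid = 0
    for i, (age, months, grade, m) in enumerate(
            zip(TABLE1_AGES, TABLE1_MONTHS, TABLE1_GRADES, TABLE1_CONTROLS)):
        rows.append(dict(patient_id=f"case{i+1}", set_id=f"S{i+1}", outcome=1,
                         total_dose=50.0, n_fractions=25, grade=grade,
                         time_to_event_months=float(months), age=age))
        for _ in range(m):
            rows.append(dict(patient_id=f"ctrl{pid}", set_id=f"S{i+1}", outcome=0,
                             total_dose=50.0, n_fractions=25, grade=pd.NA,
                             time_to_event_months=np.nan, age=pd.NA))
            pid += 1
    return pd.DataFrame(rows)
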