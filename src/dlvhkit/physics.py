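"""Proton physics helpers: LETd spectral averaging, EQD2 conversion, and
derivation of the risk-associated structure from the prescription isodose.

Dose-averaged LET (LETd) at a point is the stopping-power-squared-weighted
over stopping-power-weighted average of the local proton energy spectrum:

    LETd = sum_j phi_j SP_j^2 dE_j / sum_j phi_j SP_j dE_j   [keV/µm]

with phi_j the fluence spectrum, SP_j the unrestricted stopping power to
medium at energy E_j, and dE_j the energy bin width.

EQD2 converts a fractionation scheme to the equi-effective total dose
delivered at 2 Gy per fraction under the linear-quadratic model:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

where d is the dose per fraction.  The default alpha/beta for bone/late
effects used throughout is 3 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ScalarField, StructureMask, ValidationError, check_alignment

__all__ = [
    "DEFAULT_ALPHA_BETA",
    "EnergySpectrum",
    "FractionationScheme",
    "read_spectrum",
    "letd_from_spectrum",
    "eqd2_convert",
    "eqd2_field",
    "derive_risk_structure",
]

DEFAULT_ALPHA_BETA = 3.0  # Gy


@dataclass(frozen=True)
class EnergySpectrum:
    """A binned proton energy spectrum with stopping powers.

    Attributes
    ----------
    energies : array, MeV, strictly increasing bin centres
    fluence : array, per-energy fluence values (arbitrary units, >= 0)
    bin_widths : array, MeV, > 0
    stopping_power : array, keV/µm, unrestricted stopping power to medium
    """

    energies: np.ndarray
    fluence: np.ndarray
    bin_widths: np.ndarray
    stopping_power: np.ndarray

    def __post_init__(self):
        arrays = {}
        for name in ("energies", "fluence", "bin_widths", "stopping_power"):
            arrays[name] = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arrays[name])
        n = len(self.energies)
        if any(len(a) != n for a in arrays.values()):
            raise ValidationError("spectrum sequences must have equal lengths")
        if n > 1 and not (np.diff(self.energies) > 0).all():
            raise ValidationError("energies must be strictly increasing")
        if (self.fluence < 0).any():
            raise ValidationError("fluence must be non-negative")
        if (self.bin_widths <= 0).any():
            raise ValidationError("bin widths must be positive")
        if (self.stopping_power <= 0).any():
            raise ValidationError(
                f"stopping power must be positive, got min {self.stopping_power.min():g}"
            )


def read_spectrum(path) -> EnergySpectrum:
    """Read a spectrum CSV with columns E, phi, dE, SP."""
    df = pd.read_csv(path, comment="#")
    if missing := {"E", "phi", "dE", "SP"} - set(df.columns):
        raise ValidationError(f"spectrum CSV missing columns {sorted(missing)}")
    return EnergySpectrum(df["E"], df["phi"], df["dE"], df["SP"])


def letd_from_spectrum(spectrum: EnergySpectrum) -> float:
    """Dose-averaged LET of a spectrum, in keV/µm.

    Invariant to uniform rescaling of the fluence; lies within
    [min SP, max SP] over bins with positive fluence.
    """
    w = spectrum.fluence * spectrum.stopping_power * spectrum.bin_widths
    denom = w.sum()
    if denom == 0:
        raise ValidationError("LETd undefined: all fluence values are zero")
    return float((w * spectrum.stopping_power).sum() / denom)


@dataclass(frozen=True)
class FractionationScheme:
    total_dose: float  # Gy[RBE]
    n_fractions: int
    alpha_beta: float = DEFAULT_ALPHA_BETA  # Gy

    def __post_init__(self):
        if self.n_fractions < 1 or int(self.n_fractions) != self.n_fractions:
            raise ValidationError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if self.total_dose < 0:
            raise ValidationError("total dose must be non-negative")
        if self.alpha_beta <= 0:
            raise ValidationError(f"alpha/beta must be positive, got {self.alpha_beta}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def eqd2_convert(scheme: FractionationScheme) -> float:
    """Equi-effective total dose at 2 Gy/fraction (Gy[RBE]).

    Equals ``total_dose`` when the scheme is already at 2 Gy/fraction.
    """
    d = scheme.dose_per_fraction
    return scheme.total_dose * (d + scheme.alpha_beta) / (2.0 + scheme.alpha_beta)


def eqd2_field(dose: ScalarField, n_fractions: int,
               alpha_beta: float = DEFAULT_ALPHA_BETA) -> ScalarField:
    """Voxel-wise EQD2 conversion of a dose field.

    Each voxel's dose per fraction is its own dose divided by
    ``n_fractions`` (not the prescription's), so non-uniform regions are
    converted consistently; geometry is preserved.
    """
    if n_fractions < 1 or int(n_fractions) != n_fractions:
        raise ValidationError(f"n_fractions must be a positive integer, got {n_fractions}")
    if alpha_beta <= 0:
        raise ValidationError(f"alpha/beta must be positive, got {alpha_beta}")
    d = dose.values / n_fractions
    eqd2 = dose.values * (d + alpha_beta) / (2.0 + alpha_beta)
    return ScalarField(eqd2, dose.spacing, dose.origin)


def derive_risk_structure(dose: ScalarField, anatomy: StructureMask,
                          prescription: float, fraction: float = 0.5) -> StructureMask:
    """Restrict an anatomical mask to the region enclosed by a prescription
    isodose (by default the 50% line): ``anatomy AND dose >= fraction * Rx``.

    The threshold is closed (>=).  An empty result sets a warning flag on
    the returned mask rather than raising.
    """
    if prescription <= 0:
        raise ValidationError(f"prescription must be positive, got {prescription}")
    if fraction < 0:
        raise ValidationError(f"isodose fraction must be non-negative, got {fraction}")
    check_alignment(dose, dose, anatomy)
    threshold = fraction * prescription
    values = anatomy.values & (dose.values >= threshold)
    warning = None
    if not values.any():
        warning = (
            f"risk structure is empty: no {anatomy.label!r} voxel reaches "
            f"{threshold:g} Gy[RBE]"
        )
    return StructureMask(
        values=values, spacing=anatomy.spacing, origin=anatomy.origin,
        label=f"{anatomy.label} & dose>={threshold:g}Gy[RBE]", warning=warning,
    )
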