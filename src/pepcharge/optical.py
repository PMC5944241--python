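"""Optical (solvent-free) surface mass from LSPR shifts, and mass accounting.

Localized surface plasmon resonance (LSPR) sensing reports the shift of the
extinction maximum, Delta lambda_max (nm), which tracks the local refractive
index within the evanescent field of the plasmonic discs.  The de Feijter
relation, combined with a single-exponential evanescent decay of length L,
converts the shift into the optical areal mass of an adlayer of thickness d:

    Delta Gamma = (Delta lambda_max / S') * d / [ (dn/dC) * (1 - exp(-d/L)) ]

with S' the refractive-index sensitivity (nm/RIU, in the presence of the
bilayer) and dn/dC the refractive index increment of the analyte.  For
d << L this reduces to Delta lambda_max * L / (S' * dn/dC), which is the
default when the adlayer thickness is unknown.

Because the optical mass excludes solvent while the acoustic (QCM-D) mass
includes dynamically coupled water, their comparison yields the film's water
content; the optical mass further converts to molecular coverage, to the
charge density the film would carry if every ionizable sidechain were
charged, and to fractional surface occupancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ELEMENTARY_CHARGE, N_A
from .peptides import PeptideDescriptor

__all__ = [
    "OpticalParams",
    "LSPRTrace",
    "defeijter_mass",
    "water_content",
    "molecular_coverage",
    "full_ionization_charge_density",
    "surface_occupancy",
]


@dataclass(frozen=True)
class OpticalParams:
    """Constants of the de Feijter / evanescent-decay conversion.

    sensitivity: S', nm per refractive-index unit (with bilayer present)
    decay_length: L, nm
    dn_dc: refractive index increment, cm^3 g^-1 (0.182 is the standard
        protein value)
    thickness: octamer adlayer thickness d, nm; ``None`` selects the
        thin-film (d << L) limit
    n_solution, n_octamer: refractive indices (validated, not used by the
        operative formula, whose (n_octamer - n_solution)/(dn/dC) factor is
        absorbed into the thickness convention)
    """

    sensitivity: float = 110.0
    decay_length: float = 20.0
    dn_dc: float = 0.182
    thickness: float | None = None
    n_solution: float = 1.334
    n_octamer: float = 1.5

    def __post_init__(self) -> None:
        if min(self.sensitivity, self.decay_length, self.dn_dc) <= 0:
            raise ValueError("sensitivity, decay_length and dn_dc must be positive")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be positive (or None for the thin-film limit)")
        if self.n_octamer <= self.n_solution:
            raise ValueError("n_octamer must exceed n_solution")


@dataclass
class LSPRTrace:
    """Time series of the extinction-maximum wavelength shift (nm)."""

    time: np.ndarray  # s, strictly increasing
    dlambda: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dlambda = np.asarray(self.dlambda, dtype=float)
        if len(self.time) != len(self.dlambda):
            raise ValueError("time and dlambda must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def window_mean(self, t0: float, t1: float) -> float:
        m = (self.time >= t0) & (self.time <= t1)
        if not m.any():
            raise ValueError("window contains no samples")
        return float(np.mean(self.dlambda[m]))


def defeijter_mass(
    dlambda: float, params: OpticalParams | None = None, noise: float = 0.0
) -> float:
    """Optical surface mass density (ng cm^-2) from Delta lambda_max (nm).

    A shift more negative than ``-noise`` is flagged (desorption below the
    baseline) with a warning; the linear conversion is still returned.
    """
    params = params or OpticalParams()
    if dlambda < -abs(noise):
        warnings.warn(
            f"dlambda = {dlambda:g} nm below baseline beyond noise: desorption?",
            stacklevel=2,
        )
    if params.thickness is None:
        geometric_nm = params.decay_length
    else:
        geometric_nm = params.thickness / (1.0 - math.exp(-params.thickness / params.decay_length))
    # nm -> cm (1e-7), g/cm^2 -> ng/cm^2 (1e9): net factor 100
    return (dlambda / params.sensitivity) * geometric_nm * 100.0 / params.dn_dc


def water_content(acoustic_mass: float, optical_mass: float) -> float:
    """Percent of acoustic mass attributable to dynamically coupled water.

    100*(acoustic - optical)/acoustic; results are clipped to [0, 100] with
    a warning when the optical mass exceeds the acoustic mass.
    """
    if acoustic_mass <= 0:
        raise ValueError("acoustic mass must be positive")
    pct = 100.0 * (acoustic_mass - optical_mass) / acoustic_mass
    if optical_mass > acoustic_mass:
        warnings.warn(
            "optical mass exceeds acoustic mass; water content clipped to 0%",
            stacklevel=2,
        )
        return 0.0
    return min(pct, 100.0)


def molecular_coverage(optical_mass: float, peptide: PeptideDescriptor) -> float:
    """Molecules per cm^2 from optical mass (ng cm^-2) and molar mass."""
    if optical_mass < 0:
        raise ValueError("optical mass must be non-negative")
    return optical_mass * 1e-9 * N_A / peptide.molar_mass


def full_ionization_charge_density(coverage: float, z_max: int) -> float:
    """Charge density (C m^-2) if every sidechain is charged.

    ``coverage`` in molecules cm^-2; the 1e4 factor converts to m^-2.
    """
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    return coverage * 1e4 * z_max * ELEMENTARY_CHARGE


def surface_occupancy(coverage: float, footprint: float) -> float:
    """Percent of bilayer area occupied by peptides lying flat.

    ``coverage`` in molecules cm^-2, ``footprint`` in nm^2 per molecule
    (1 cm^2 = 1e14 nm^2).  Occupancies above 100% are flagged.
    """
    if footprint <= 0:
        raise ValueError("footprint must be positive")
    pct = 100.0 * coverage * footprint / 1e14
    if pct > 100.0:
        warnings.warn(f"occupancy {pct:.1f}% exceeds a full monolayer", stacklevel=2)
    return pct
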