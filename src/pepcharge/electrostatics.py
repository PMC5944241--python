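"""Interfacial electrostatics of simulation-derived charge-density profiles.

Post-processing of z-binned charge densities rho(z) from membrane
simulations (z = 0 at the bilayer center, bins uniform):

* cumulative charge density sigma(z) = integral_0^z rho(z') dz'
  (trapezoid rule);
* electrostatic potential by double integration of the 1D Poisson equation
  with the vacuum permittivity (all explicit charges, including water, live
  in rho):  phi(z) = -(1/eps_0) int_0^z dz' int_0^z' rho(z'') dz'',
  shifted so that phi -> 0 in bulk solvent;
* the Grahame equation sigma(phi) = sqrt(8 eps_r eps_0 k_B T n_0)
  * sinh(e phi / 2 k_B T) — the exact inverse of the Gouy-Chapman surface
  potential — and a one-parameter fit of (phi(z), sigma(z)) pairs near the
  phosphate plane for the apparent interfacial dielectric constant;
* counting of membrane-bound cationic sidechains: a monomer is bound when
  the minimum-image distance from its representative atom (CZ for Arg, NZ
  for Lys) to any lipid phosphorus is within the first-RDF-peak cutoff
  (5.5 / 4.5 Angstrom; boundary inclusive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator

from .constants import ANGSTROM, ELEMENTARY_CHARGE, EPSILON_0, K_B
from .exceptions import DegenerateFitError, NonUniformGridError
from .isotherm import GCParams, gc_potential

__all__ = [
    "ChargeDensityProfile",
    "PotentialProfile",
    "GrahameFit",
    "BindingGeometry",
    "BindingCounts",
    "ApparentDielectricFit",
    "integrate_charge",
    "poisson_potential",
    "grahame_sigma",
    "fit_apparent_dielectric",
    "bound_monomer_count",
    "minimum_image_distances",
    "DEFAULT_CUTOFFS",
]

#: First-RDF-peak binding cutoffs, Angstrom, per residue type.
DEFAULT_CUTOFFS = {"ARG": 5.5, "LYS": 4.5}

#: Default medium for Grahame fitting of simulation profiles: the
#: simulation salt (0.15 M) and production temperature (303.15 K).
SIMULATION_MEDIUM = dict(temperature=303.15, electrolyte_M=0.15)


@dataclass
class ChargeDensityProfile:
    """z-binned, component-resolved charge density.

    ``z`` are uniform bin centers in Angstrom (z = 0 at the bilayer
    center); ``densities`` maps component labels (e.g. water, lipid, ions,
    peptide) to charge density arrays in C m^-3.  The special key "total"
    is always available: stored values are validated against the component
    sum, otherwise the sum is computed on demand.
    """

    z: np.ndarray  # Angstrom, uniform
    densities: dict  # label -> C m^-3
    area: float | None = None  # box cross-section, Angstrom^2

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.densities = {k: np.asarray(v, dtype=float) for k, v in self.densities.items()}
        if len(self.z) < 2:
            raise ValueError("profile needs at least 2 bins")
        dz = np.diff(self.z)
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
            raise NonUniformGridError("z grid is not uniform; resample required")
        for k, v in self.densities.items():
            if len(v) != len(self.z):
                raise ValueError(f"component {k!r} length mismatch")
        if "total" in self.densities:
            comp = [k for k in self.densities if k != "total"]
            if comp:
                s = sum(self.densities[k] for k in comp)
                scale = max(np.max(np.abs(s)), np.max(np.abs(self.densities["total"])), 1e-30)
                if not np.allclose(self.densities["total"], s, atol=1e-6 * scale):
                    raise ValueError("'total' is not the sum of the components")

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def components(self) -> list:
        return [k for k in self.densities if k != "total"]

    def density(self, components=("total",)) -> np.ndarray:
        """Summed charge density of the selected components, C m^-3."""
        if isinstance(components, str):
            components = (components,)
        if list(components) == ["total"] and "total" not in self.densities:
            components = self.components
        out = np.zeros_like(self.z)
        for k in components:
            out = out + self.densities[k]
        return out


@dataclass
class PotentialProfile:
    """Electrostatic potential phi(z), referenced to zero in bulk solvent."""

    z: np.ndarray  # Angstrom
    phi: np.ndarray  # V
    boundary_field_residual: float = 0.0  # V/m left at the far boundary

    def window(self, z0: float, z1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.z >= z0) & (self.z <= z1)
        return self.z[m], self.phi[m]


def integrate_charge(profile: ChargeDensityProfile, components=("total",)) -> np.ndarray:
    """Cumulative charge density sigma(z) (C m^-2) from z = 0 (first bin).

    Trapezoid rule; for the total component of a neutral box sigma(z_max)
    vanishes.
    """
    rho = profile.density(components)
    return cumulative_trapezoid(rho, profile.z * ANGSTROM, initial=0.0)


def poisson_potential(
    profile: ChargeDensityProfile,
    components=("total",),
    bulk_fraction: float = 0.05,
    neutrality_rtol: float = 1e-6,
) -> PotentialProfile:
    """Potential phi(z) by double trapezoid integration of Poisson's equation.

    Uses the vacuum permittivity — the explicit solvent charges are part of
    rho.  The result is shifted so the mean over the last ``bulk_fraction``
    of the grid (bulk solvent) is zero.  A non-neutral selection leaves a
    residual field at the boundary, which is reported and warned about.
    """
    sigma = integrate_charge(profile, components)
    scale = max(
        (abs(integrate_charge(profile, (k,))[-1]) for k in profile.components),
        default=abs(sigma[-1]),
    )
    if abs(sigma[-1]) > neutrality_rtol * max(scale, 1e-30):
        warnings.warn(
            f"selection is not neutral: residual sigma = {sigma[-1]:.3e} C/m^2 "
            f"(field {sigma[-1] / EPSILON_0:.3e} V/m at the boundary)",
            stacklevel=2,
        )
    phi = -cumulative_trapezoid(sigma, profile.z * ANGSTROM, initial=0.0) / EPSILON_0
    n_bulk = max(int(round(bulk_fraction * len(phi))), 1)
    phi = phi - float(np.mean(phi[-n_bulk:]))
    return PotentialProfile(profile.z.copy(), phi, float(sigma[-1] / EPSILON_0))


def grahame_sigma(
    phi,
    electrolyte_M: float = 0.15,
    temperature: float = 303.15,
    epsilon_r: float = 78.2,
):
    """Grahame surface charge density (C m^-2) for potential phi (V).

    sigma = sqrt(8 eps_r eps_0 k_B T n_0) * sinh(e phi / 2 k_B T); exact
    inverse of :func:`pepcharge.isotherm.gc_potential`.
    """
    params = GCParams(temperature, electrolyte_M, epsilon_r)
    phi = np.asarray(phi, dtype=float)
    out = params.sigma_star * np.sinh(
        ELEMENTARY_CHARGE * phi / (2.0 * K_B * temperature)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class GrahameFit:
    """Apparent-dielectric fit result over a z window."""

    z_window: tuple
    epsilon_app: float
    epsilon_stderr: float
    residuals: np.ndarray
    n_points: int


class ApparentDielectricFit(BaseEstimator):
    """One-parameter Grahame fit for the apparent interfacial dielectric.

    Given matched (phi(z), sigma(z)) pairs, minimizes
    sum_z [sigma(z) - grahame_sigma(phi(z); eps)]^2 over eps.  Because the
    Grahame equation is linear in sqrt(eps), the minimizer is closed-form.

    Attributes: ``epsilon_`` (the apparent dielectric constant),
    ``stderr_``, ``residuals_``.
    """

    def __init__(self, electrolyte_M: float = 0.15, temperature: float = 303.15):
        self.electrolyte_M = electrolyte_M
        self.temperature = temperature

    def fit(self, X, y):
        """X: potentials phi (V); y: integrated charge densities (C m^-2)."""
        phi = np.asarray(X, dtype=float).reshape(-1)
        sigma = np.asarray(y, dtype=float).reshape(-1)
        if len(phi) != len(sigma):
            raise ValueError("phi and sigma lengths differ")
        if len(phi) < 3:
            raise DegenerateFitError("need at least 3 (phi, sigma) pairs")
        g = grahame_sigma(phi, self.electrolyte_M, self.temperature, epsilon_r=1.0)
        gg = float(g @ g)
        if gg <= 0 or not np.any(sigma):
            raise DegenerateFitError("phi and sigma carry no signal; fit is degenerate")
        s = float(g @ sigma) / gg  # sqrt(eps)
        if s <= 0:
            raise DegenerateFitError("sigma and phi have inconsistent signs")
        self.epsilon_ = s * s
        self.residuals_ = sigma - s * g
        dof = max(len(phi) - 1, 1)
        s2 = float(self.residuals_ @ self.residuals_) / dof
        var_s = s2 / gg
        self.stderr_ = 2.0 * s * math.sqrt(var_s)  # d(eps)/d(sqrt eps) = 2 sqrt(eps)
        if self.epsilon_ <= 1.0:
            warnings.warn(
                f"apparent dielectric {self.epsilon_:.3g} <= 1 is unphysical", stacklevel=2
            )
        return self

    def predict(self, X):
        phi = np.asarray(X, dtype=float)
        return grahame_sigma(phi, self.electrolyte_M, self.temperature, self.epsilon_)


def fit_apparent_dielectric(
    potential: PotentialProfile,
    sigma: np.ndarray,
    z_window: tuple[float, float] = (18.0, 24.0),
    electrolyte_M: float = 0.15,
    temperature: float = 303.15,
) -> GrahameFit:
    """Fit the apparent dielectric constant over a z window (Angstrom).

    ``sigma`` is the cumulative charge from :func:`integrate_charge`, on the
    same grid as ``potential``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if len(sigma) != len(potential.z):
        raise ValueError("sigma and potential grids differ")
    m = (potential.z >= z_window[0]) & (potential.z <= z_window[1])
    if int(m.sum()) < 3:
        raise ValueError("z window contains fewer than 3 grid points")
    est = ApparentDielectricFit(electrolyte_M, temperature)
    est.fit(potential.phi[m], sigma[m])
    return GrahameFit(
        z_window=tuple(z_window),
        epsilon_app=est.epsilon_,
        epsilon_stderr=est.stderr_,
        residuals=est.residuals_,
        n_points=int(m.sum()),
    )


@dataclass
class BindingGeometry:
    """Representative-atom coordinates for binding-site counting.

    All coordinates in Angstrom; ``box`` is the orthorhombic box (lx, ly,
    lz).  ``sidechain_type`` holds residue labels keyed into ``cutoffs``;
    ``peptide_id`` maps each sidechain to its peptide.
    """

    sidechain_xyz: np.ndarray  # (N, 3)
    sidechain_type: np.ndarray  # (N,) str labels, e.g. "ARG"/"LYS"
    peptide_id: np.ndarray  # (N,) int
    phosphorus_xyz: np.ndarray  # (M, 3)
    box: np.ndarray  # (3,)
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self) -> None:
        self.sidechain_xyz = np.asarray(self.sidechain_xyz, dtype=float).reshape(-1, 3)
        self.sidechain_type = np.asarray(self.sidechain_type)
        self.peptide_id = np.asarray(self.peptide_id)
        self.phosphorus_xyz = np.asarray(self.phosphorus_xyz, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box dimensions must be positive")
        n = len(self.sidechain_xyz)
        if len(self.sidechain_type) != n or len(self.peptide_id) != n:
            raise ValueError("sidechain metadata length mismatch (missing membership mapping?)")
        if any(v <= 0 for v in self.cutoffs.values()):
            raise ValueError("cutoffs must be positive")


def minimum_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances (len(a) x len(b)) in an orthorhombic box.

    Computed in float64 so that exact boundary placements compare exactly
    against the inclusive cutoff.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    box = np.asarray(box, dtype=float).reshape(3)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta * delta, axis=-1))


@dataclass
class BindingCounts:
    """Per-peptide bound-sidechain counts and their distribution."""

    per_peptide: dict  # peptide id -> count
    histogram: np.ndarray  # counts of peptides with 0..max_monomers bound
    n_bound_peptides: int  # peptides with >= 1 bound sidechain

    @property
    def mean_bound(self) -> float:
        counts = np.fromiter(self.per_peptide.values(), dtype=float)
        return float(counts.mean()) if len(counts) else 0.0


def bound_monomer_count(geom: BindingGeometry, max_monomers: int = 8) -> BindingCounts:
    """Count membrane-bound sidechains per peptide.

    A sidechain is bound iff its minimum-image distance to any phosphorus is
    <= the cutoff for its residue type (boundary inclusive); a peptide is
    bound iff it has at least one bound sidechain.  Returns per-peptide
    counts and the histogram over 0..``max_monomers``.
    """
    peptides = np.unique(geom.peptide_id)
    if len(geom.sidechain_xyz) == 0 or len(peptides) == 0:
        return BindingCounts({}, np.zeros(max_monomers + 1, dtype=int), 0)
    unknown = set(np.unique(geom.sidechain_type)) - set(geom.cutoffs)
    if unknown:
        raise KeyError(f"no cutoff declared for residue type(s) {sorted(unknown)}")
    if len(geom.phosphorus_xyz) == 0:
        bound = np.zeros(len(geom.sidechain_xyz), dtype=bool)
    else:
        d = minimum_image_distances(geom.sidechain_xyz, geom.phosphorus_xyz, geom.box)
        dmin = d.min(axis=1)
        cut = np.array([geom.cutoffs[str(t)] for t in geom.sidechain_type])
        bound = dmin <= cut
    per = {int(p): int(bound[geom.peptide_id == p].sum()) for p in peptides}
    hist = np.zeros(max_monomers + 1, dtype=int)
    for v in per.values():
        hist[min(v, max_monomers)] += 1
    return BindingCounts(per, hist, int(sum(1 for v in per.values() if v > 0)))
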