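"""Hill/Gouy-Chapman modelling of surface-potential-sensitive SHG isotherms.

Second harmonic generation (SHG) from a charged interface contains a
third-order term proportional to the interfacial potential Phi_0 (the
Eisenthal chi(3) "optical voltmeter"): E_SHG ~ A + B*Phi_0.  As cationic
peptides adsorb to a negatively charged bilayer they add charge density
Delta sigma, Phi_0 relaxes toward zero, and the normalized SHG E-field

    E_norm(c) = [A + B*Phi_0(sigma_0 + theta(c)*Delta sigma)]
                / [A + B*Phi_0(sigma_0)]

decreases with bulk peptide concentration c.  Fractional coverage follows
the Hill isotherm theta = (K*c)^n / (1 + (K*c)^n) (n = 1 recovers Langmuir),
and the surface potential follows Gouy-Chapman theory for a symmetric 1:1
electrolyte,

    Phi_0 = (2 k_B T / e) * asinh(sigma / sqrt(8 eps_r eps_0 k_B T n_0)),

with n_0 the bulk ion number density.  Fitting E_norm(c) yields the
adsorption constant K_ads, the Hill coefficient n, and the peptide-added
charge density Delta sigma; the standard-state free energy is
Delta G = -R T ln(55.5 M * K_ads).

Because experimental isotherms rarely reach saturation, the analysis
supports appending one extrapolated point at high concentration (mean of
the last k measured points) and a +/-10% sensitivity scan on that point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import ELEMENTARY_CHARGE, EPSILON_0, GAS_CONSTANT, K_B, N_A
from .exceptions import DegenerateNormalizationError, InsufficientDataError

__all__ = [
    "GCParams",
    "IsothermData",
    "HillGCFit",
    "HillGouyChapmanIsotherm",
    "gc_potential",
    "hill_coverage",
    "model_efield",
    "augment_extrapolated_point",
    "fit_isotherm",
    "sensitivity_scan",
    "free_energy",
    "additive_expectation",
    "percent_ionization",
]

#: Molar concentration of pure water, used as the standard-state reference.
WATER_MOLARITY = 55.5


@dataclass(frozen=True)
class GCParams:
    """Gouy-Chapman medium parameters for a symmetric 1:1 electrolyte."""

    temperature: float = 298.15  # K
    electrolyte_M: float = 0.1  # mol/L total 1:1 electrolyte
    epsilon_r: float = 78.2

    def __post_init__(self) -> None:
        if min(self.temperature, self.electrolyte_M, self.epsilon_r) <= 0:
            raise ValueError("temperature, electrolyte_M, epsilon_r must be positive")

    @property
    def ion_density(self) -> float:
        """Bulk number density n_0 of each ion species, m^-3."""
        return 1000.0 * N_A * self.electrolyte_M

    @property
    def sigma_star(self) -> float:
        """Charge-density scale sqrt(8 eps_r eps_0 k_B T n_0), C m^-2."""
        return math.sqrt(
            8.0 * self.epsilon_r * EPSILON_0 * K_B * self.temperature * self.ion_density
        )

    @property
    def thermal_voltage(self) -> float:
        """k_B T / e, V."""
        return K_B * self.temperature / ELEMENTARY_CHARGE


def gc_potential(sigma, params: GCParams | None = None):
    """Gouy-Chapman surface potential Phi_0 (V) for charge density sigma.

    Odd and strictly increasing in sigma; linear with slope
    2 k_B T/(e sigma*) for |sigma| << sigma*.
    """
    params = params or GCParams()
    sigma = np.asarray(sigma, dtype=float)
    phi = 2.0 * params.thermal_voltage * np.arcsinh(sigma / params.sigma_star)
    return float(phi) if phi.ndim == 0 else phi


def hill_coverage(concentration, k_ads: float, n: float):
    """Hill fractional coverage theta = (K c)^n / (1 + (K c)^n)."""
    if k_ads <= 0 or n <= 0:
        raise ValueError("k_ads and n must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    x = np.power(k_ads * c, n, where=c > 0, out=np.zeros_like(c))
    theta = x / (1.0 + x)
    return float(theta) if theta.ndim == 0 else theta


def model_efield(
    concentration,
    a: float,
    b: float,
    k_ads: float,
    n: float,
    delta_sigma: float,
    sigma0: float,
    params: GCParams | None = None,
):
    """Normalized SHG E-field E_norm(c) of the combined Hill/GC model.

    E_norm(0) = 1 exactly; raises if the bare-bilayer normalization
    denominator A + B*Phi_0(sigma_0) is numerically zero.
    """
    params = params or GCParams()
    denom = a + b * gc_potential(sigma0, params)
    scale = max(abs(a), abs(b) * abs(gc_potential(sigma0, params)), 1e-30)
    if abs(denom) < 1e-12 * scale:
        raise DegenerateNormalizationError("A + B*Phi_0(sigma_0) is numerically zero")
    theta = hill_coverage(concentration, k_ads, n)
    return (a + b * gc_potential(sigma0 + theta * delta_sigma, params)) / denom


@dataclass
class IsothermData:
    """Concentration vs normalized SHG E-field with per-point uncertainty.

    ``extrapolated`` marks appended high-concentration anchor points that
    were not measured.
    """

    concentration: np.ndarray  # mol/L, strictly increasing
    e_norm: np.ndarray
    sigma_e: np.ndarray | None = None
    extrapolated: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.e_norm = np.asarray(self.e_norm, dtype=float)
        if self.sigma_e is None:
            self.sigma_e = np.full_like(self.e_norm, np.nan)
        else:
            self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(len(self.e_norm), dtype=bool)
        else:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if not (len(self.concentration) == len(self.e_norm) == len(self.sigma_e) == len(self.extrapolated)):
            raise ValueError("all isotherm columns must have equal length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")
        if len(self.concentration) > 1 and not np.all(np.diff(self.concentration) > 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.concentration)

    @property
    def measured(self) -> "IsothermData":
        m = ~self.extrapolated
        return IsothermData(
            self.concentration[m], self.e_norm[m], self.sigma_e[m], self.extrapolated[m]
        )

    def weights(self) -> np.ndarray:
        """Least-squares weights 1/sigma_E, or 1 where no uncertainty given."""
        w = np.ones_like(self.e_norm)
        ok = np.isfinite(self.sigma_e) & (self.sigma_e > 0)
        w[ok] = 1.0 / self.sigma_e[ok]
        return w


def augment_extrapolated_point(
    iso: IsothermData, c_extrap: float = 0.1, k: int = 3
) -> IsothermData:
    """Append one extrapolated point at ``c_extrap`` (mol/L).

    Its E_norm is the mean of the last ``k`` measured values; the point is
    flagged extrapolated.  Augmenting an already-augmented isotherm is
    rejected.
    """
    if iso.extrapolated.any():
        raise ValueError("isotherm already contains an extrapolated point")
    if len(iso) < k:
        raise InsufficientDataError(f"need at least k={k} measured points")
    if c_extrap <= iso.concentration[-1]:
        raise ValueError("c_extrap must exceed the largest measured concentration")
    e_val = float(np.mean(iso.e_norm[-k:]))
    sig = iso.sigma_e[-k:]
    s_val = float(np.mean(sig)) if np.all(np.isfinite(sig)) else np.nan
    return IsothermData(
        np.append(iso.concentration, c_extrap),
        np.append(iso.e_norm, e_val),
        np.append(iso.sigma_e, s_val),
        np.append(iso.extrapolated, True),
    )


@dataclass
class HillGCFit:
    """Result of the combined Hill/Gouy-Chapman isotherm fit."""

    a: float
    b: float  # V^-1 (lumped chi2/chi3 response)
    k_ads: float  # M^-1
    n: float
    sigma0: float  # C m^-2, fixed
    delta_sigma: float  # C m^-2, peptide-added
    covariance: np.ndarray  # 4x4 over (b, k_ads, n, delta_sigma)
    stderr: dict
    residual_norm: float
    converged: bool
    params: GCParams

    @property
    def free_energy(self) -> float:
        """Delta G_ads (kJ/mol) at the 55.5 M reference state."""
        return free_energy(self.k_ads, self.params.temperature)


class HillGouyChapmanIsotherm(RegressorMixin, BaseEstimator):
    """Weighted nonlinear least-squares fit of the Hill/GC isotherm model.

    The bare-bilayer charge density sigma_0 is fixed (taken from prior
    work), and A is fixed at 1 because E_norm is invariant under joint
    rescaling of A and B; free parameters are (B, log10 K_ads, ln n,
    Delta sigma), optimized from multiple deterministic starts.

    Because B and Delta sigma are nearly scale-degenerate in this model
    family (both deepen the plateau), Delta sigma carries a very large
    uncertainty when B is free — the reason for the extrapolated-point and
    sensitivity-scan procedures.  When an independent calibration of the
    chi(3) response is available (the usual "optical voltmeter" usage),
    pass it as ``fix_b`` to hold B and recover (K_ads, n, Delta sigma)
    sharply.

    Attributes (after fit)
    ----------------------
    A_, B_, K_ads_, n_, delta_sigma_ : point estimates.
    covariance_ : 4x4 covariance over (B, K_ads, n, delta_sigma) in linear
        space; ``covariance_rank_deficient_`` flags a singular fit.
    stderr_ : 1-sigma uncertainties.
    converged_ : optimizer success flag (never silently False).
    """

    def __init__(
        self,
        sigma0: float = -0.1,
        temperature: float = 298.15,
        electrolyte_M: float = 0.1,
        epsilon_r: float = 78.2,
        a: float = 1.0,
        fix_b: float | None = None,
        n_starts: int = 5,
        random_state: int = 0,
        require_span_decades: float = 2.0,
        min_points: int = 5,
    ):
        self.sigma0 = sigma0
        self.temperature = temperature
        self.electrolyte_M = electrolyte_M
        self.epsilon_r = epsilon_r
        self.a = a
        self.fix_b = fix_b
        self.n_starts = n_starts
        self.random_state = random_state
        self.require_span_decades = require_span_decades
        self.min_points = min_points

    def _gc_params(self) -> GCParams:
        return GCParams(self.temperature, self.electrolyte_M, self.epsilon_r)

    def _unpack(self, p):
        if self.fix_b is None:
            b, log10k, ln_n, dsig = p
        else:
            b = self.fix_b
            log10k, ln_n, dsig = p
        return b, 10.0 ** log10k, math.exp(min(ln_n, 50.0)), dsig

    def _residual(self, p, c, y, w, gc):
        b, k, n, dsig = self._unpack(p)
        model = model_efield(c, self.a, b, k, n, dsig, self.sigma0, gc)
        return (model - y) * w

    def _starts(self, c, y, gc):
        phi0 = gc_potential(self.sigma0, gc)
        e_min = float(np.min(y))
        # B that would explain the observed plateau by full charge neutralization
        if abs(phi0) > 0 and 0 < e_min < 1:
            b_guess = (1.0 / e_min - 1.0) / phi0
        else:
            b_guess = -1.0 / phi0 if phi0 != 0 else -1.0
        # concentration of half signal drop as a K guess
        e_half = 0.5 * (1.0 + e_min)
        below = np.nonzero(y <= e_half)[0]
        c_half = c[below[0]] if len(below) else np.median(c[c > 0])
        log10k_guess = -math.log10(max(c_half, 1e-12))
        rng = np.random.default_rng(self.random_state)
        base = []
        b_options = (b_guess, 0.5 * b_guess, 2.0 * b_guess) if self.fix_b is None else (None,)
        for bb in b_options:
            for nn in (0.5, 1.0):
                for ds in (-self.sigma0, -0.5 * self.sigma0):
                    head = [] if bb is None else [bb]
                    base.append(head + [log10k_guess, math.log(nn), ds])
        starts = base[: max(self.n_starts, 1)]
        extra = max(self.n_starts - len(starts), 0)
        jitter = [0.5, 0.3, 0.02]
        if self.fix_b is None:
            jitter = [0.3 * abs(b_guess) + 1e-3] + jitter
        for i in range(extra):
            p = np.array(base[i % len(base)], dtype=float)
            p += rng.normal(0, jitter)
            starts.append(list(p))
        return starts

    def fit(self, X, y, sample_weight=None):
        """Fit the isotherm. X: concentrations (n,) or (n,1); y: E_norm."""
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(c) != len(y):
            raise ValueError("X and y lengths differ")
        if len(c) < self.min_points:
            raise InsufficientDataError(
                f"need at least {self.min_points} points to fit the isotherm"
            )
        pos = c[c > 0]
        if len(pos) and math.log10(pos.max() / pos.min()) < self.require_span_decades:
            warnings.warn(
                "concentrations span fewer than "
                f"{self.require_span_decades:g} decades; fit may be ill-conditioned",
                stacklevel=2,
            )
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        gc = self._gc_params()
        best = None
        for p0 in self._starts(c, y, gc):
            try:
                res = optimize.least_squares(
                    self._residual, p0, args=(c, y, w, gc), method="lm", max_nfev=5000
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("isotherm fit failed from every start point")
        b, k, n, dsig = self._unpack(best.x)
        self.A_, self.B_, self.K_ads_, self.n_, self.delta_sigma_ = self.a, b, k, n, dsig
        self.converged_ = bool(best.success)
        if not self.converged_:
            warnings.warn("isotherm fit did not converge; result flagged", stacklevel=2)
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self.cost_ = float(best.cost)
        n_free = 3 if self.fix_b is not None else 4
        dof = max(len(y) - n_free, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        cond = np.linalg.cond(jtj)
        self.covariance_rank_deficient_ = bool(cond > 1e12)
        if self.covariance_rank_deficient_:
            warnings.warn("isotherm fit covariance is rank deficient", stacklevel=2)
            cov_p = s2 * np.linalg.pinv(jtj)
        else:
            cov_p = s2 * np.linalg.inv(jtj)
        # chain rule to linear space: K = 10^q, n = exp(m)
        grad = np.diag([k * math.log(10.0), n, 1.0])
        if self.fix_b is None:
            grad = np.block([
                [np.ones((1, 1)), np.zeros((1, 3))],
                [np.zeros((3, 1)), grad],
            ])
        cov = grad @ cov_p @ grad.T
        if self.fix_b is not None:  # pad the fixed-B row/column with zeros
            full = np.zeros((4, 4))
            full[1:, 1:] = cov
            cov = full
        self.covariance_ = cov
        err = np.sqrt(np.maximum(np.diag(self.covariance_), 0.0))
        self.stderr_ = {"b": err[0], "k_ads": err[1], "n": err[2], "delta_sigma": err[3]}
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return model_efield(
            c, self.A_, self.B_, self.K_ads_, self.n_, self.delta_sigma_,
            self.sigma0, self._gc_params(),
        )

    def result_(self) -> HillGCFit:
        """Bundle fitted attributes into a :class:`HillGCFit` record."""
        return HillGCFit(
            a=self.A_, b=self.B_, k_ads=self.K_ads_, n=self.n_,
            sigma0=self.sigma0, delta_sigma=self.delta_sigma_,
            covariance=self.covariance_, stderr=self.stderr_,
            residual_norm=self.residual_norm_, converged=self.converged_,
            params=self._gc_params(),
        )


def fit_isotherm(
    iso: IsothermData,
    params: GCParams | None = None,
    sigma0: float = -0.1,
    **estimator_kwargs,
) -> HillGCFit:
    """Fit the combined Hill/GC model to an isotherm (wrapper)."""
    params = params or GCParams()
    est = HillGouyChapmanIsotherm(
        sigma0=sigma0,
        temperature=params.temperature,
        electrolyte_M=params.electrolyte_M,
        epsilon_r=params.epsilon_r,
        **estimator_kwargs,
    )
    est.fit(iso.concentration, iso.e_norm, sample_weight=iso.weights())
    return est.result_()


def sensitivity_scan(
    iso: IsothermData,
    params: GCParams | None = None,
    sigma0: float = -0.1,
    perturbation: float = 0.10,
    **estimator_kwargs,
) -> dict:
    """Refit with the extrapolated point scaled by (1 +/- perturbation).

    Returns ``{"delta_sigma": (lo, hi), "k_ads": (lo, hi), "n": (lo, hi),
    "fits": {...}}`` where the ranges cover the central and both perturbed
    fits.  Requires the isotherm to contain an extrapolated point.
    """
    if not iso.extrapolated.any():
        raise ValueError("isotherm contains no extrapolated point to perturb")
    fits = {}
    for label, factor in (("central", 1.0), ("minus", 1.0 - perturbation), ("plus", 1.0 + perturbation)):
        e = iso.e_norm.copy()
        e[iso.extrapolated] *= factor
        branch = IsothermData(iso.concentration, e, iso.sigma_e, iso.extrapolated)
        try:
            fits[label] = fit_isotherm(branch, params, sigma0, **estimator_kwargs)
        except Exception as exc:  # propagated fit errors flagged per branch
            warnings.warn(f"sensitivity branch {label!r} failed: {exc}", stacklevel=2)
            fits[label] = None
    ok = [f for f in fits.values() if f is not None]
    if not ok:
        raise RuntimeError("all sensitivity branches failed")
    out = {"fits": fits}
    for name in ("delta_sigma", "k_ads", "n"):
        vals = [getattr(f, name) for f in ok]
        out[name] = (min(vals), max(vals))
    return out


def free_energy(k_ads: float, temperature: float = 298.15, reference: float = WATER_MOLARITY) -> float:
    """Standard-state adsorption free energy, kJ/mol.

    Delta G = -R T ln(reference * K_ads) with the 55.5 M (molarity of
    water) reference convention.
    """
    if k_ads <= 0:
        raise ValueError("k_ads must be positive")
    return -GAS_CONSTANT * temperature * math.log(reference * k_ads) / 1000.0


def additive_expectation(per_residue: float = -5.9, n_residues: int = 8) -> float:
    """Purely additive free-energy expectation: per-residue value x length."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return per_residue * n_residues


def percent_ionization(sigma_fit: float, sigma_full: float) -> float:
    """Percent of ionizable groups charged: 100 * sigma_fit / sigma_full."""
    if sigma_full <= 0:
        raise ValueError("sigma_full must be positive")
    return 100.0 * sigma_fit / sigma_full
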