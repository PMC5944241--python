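"""Acoustic surface mass from QCM-D frequency/dissipation responses.

A quartz crystal microbalance with dissipation monitoring (QCM-D) reports,
per odd harmonic nu, the shift in resonance frequency (Delta f_nu, Hz) and in
energy dissipation (Delta D_nu, dimensionless) relative to a baseline.  For
rigid, low-dissipation films the areal mass follows from the Sauerbrey
relation

    Delta Gamma = -C * Delta f_nu / nu

with C the mass sensitivity constant (18 ng cm^-2 Hz^-1 at f1 = 4.95 MHz).
Films with Delta D_nu / (-Delta f_nu / nu) above ~0.4e-6 Hz^-1 are too
dissipative for Sauerbrey; their mass is obtained by fitting a Kelvin-Voigt
viscoelastic layer (shear modulus mu, shear viscosity eta, density rho,
thickness h) under a semi-infinite Newtonian liquid to the Delta f / Delta D
response of several harmonics.

The Kelvin-Voigt response implemented here is the small-load approximation
with the exact one-layer acoustic load impedance: the film has complex shear
modulus G = mu + i*omega*eta, shear impedance Z_f = sqrt(rho*G), and the load
seen by the crystal under bulk liquid of impedance Z_l = sqrt(i*omega*rho_l*eta_l)
is

    Z_load = Z_f * (Z_l + Z_f*tanh(gamma*h)) / (Z_f + Z_l*tanh(gamma*h)),
    gamma = i*omega*sqrt(rho/G),

from which the complex frequency shift is Delta f* = i*f1*Z_load/(pi*Z_q)
with Z_q = 2*f1*(rho_q*h_q) the quartz shear-wave impedance; Delta f is its
real part and Delta D = 2*Im(Delta f*)/f.  In the stiff-film limit this
reduces to the Sauerbrey relation, and for h -> 0 to the Newtonian-liquid
(Kanazawa) loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import NG_CM2_TO_KG_M2
from .exceptions import (
    InsufficientDataError,
    InvalidHarmonicError,
    UndefinedRatioError,
)

__all__ = [
    "QuartzSensor",
    "BulkFluid",
    "ViscoelasticLayer",
    "HarmonicTrace",
    "RigidityResult",
    "KelvinVoigtFilm",
    "sauerbrey_mass",
    "rigidity_ratio",
    "kelvin_voigt_forward",
    "kelvin_voigt_fit",
    "harmonic_endpoints",
    "initial_attachment_rate",
    "RIGIDITY_THRESHOLD",
]

#: Operative rigidity criterion, Hz^-1: ratios below this are "rigid".
RIGIDITY_THRESHOLD = 0.4e-6

VALID_HARMONICS = (1, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class QuartzSensor:
    """AT-cut quartz sensor: fundamental frequency and mass sensitivity."""

    f1: float = 4.95e6  # Hz
    mass_sensitivity: float = 18.0  # C, ng cm^-2 Hz^-1

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.mass_sensitivity <= 0:
            raise ValueError("sensor parameters must be positive")

    @property
    def areal_mass_quartz(self) -> float:
        """rho_q * h_q of the crystal in kg m^-2 (= C_SI * f1)."""
        return self.mass_sensitivity * NG_CM2_TO_KG_M2 * self.f1

    @property
    def shear_impedance(self) -> float:
        """Quartz shear-wave impedance Z_q = 2 f1 rho_q h_q, kg m^-2 s^-1."""
        return 2.0 * self.f1 * self.areal_mass_quartz


@dataclass(frozen=True)
class BulkFluid:
    """Newtonian bulk liquid above the film (water-like defaults)."""

    density: float = 1000.0  # kg m^-3
    viscosity: float = 0.001  # kg m^-1 s^-1

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid parameters must be positive")


@dataclass(frozen=True)
class ViscoelasticLayer:
    """Kelvin-Voigt film: thickness h (m), density (kg/m^3), eta, mu."""

    thickness: float
    density: float
    shear_viscosity: float  # kg m^-1 s^-1
    shear_modulus: float  # Pa

    def __post_init__(self) -> None:
        if min(self.thickness, self.density, self.shear_viscosity, self.shear_modulus) <= 0:
            raise ValueError("all layer parameters must be positive")

    @property
    def areal_mass(self) -> float:
        """Acoustic mass Delta Gamma = rho*h in ng cm^-2."""
        return self.density * self.thickness / NG_CM2_TO_KG_M2


@dataclass
class HarmonicTrace:
    """Time series of Delta f and Delta D for one odd harmonic.

    ``dissipation`` is stored dimensionless (absolute, not x1e-6);
    ``frequency_shift`` is the raw (non harmonic-normalized) shift in Hz.
    """

    time: np.ndarray  # s, strictly increasing
    harmonic: int
    frequency_shift: np.ndarray  # Hz
    dissipation: np.ndarray  # dimensionless

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.frequency_shift = np.asarray(self.frequency_shift, dtype=float)
        self.dissipation = np.asarray(self.dissipation, dtype=float)
        _check_harmonic(self.harmonic)
        if not (len(self.time) == len(self.frequency_shift) == len(self.dissipation)):
            raise ValueError("time, frequency_shift, dissipation must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def window(self, t0: float, t1: float) -> "HarmonicTrace":
        m = (self.time >= t0) & (self.time <= t1)
        return HarmonicTrace(self.time[m], self.harmonic, self.frequency_shift[m], self.dissipation[m])


def _check_harmonic(nu: int) -> None:
    if not isinstance(nu, (int, np.integer)) or nu < 1 or nu % 2 == 0:
        raise InvalidHarmonicError(f"harmonic must be an odd positive integer, got {nu!r}")


def sauerbrey_mass(frequency_shift: float, harmonic: int, sensor: QuartzSensor | None = None) -> float:
    """Sauerbrey areal mass (ng cm^-2) from Delta f_nu of harmonic nu.

    A negative frequency shift corresponds to positive adsorbed mass.
    """
    _check_harmonic(harmonic)
    sensor = sensor or QuartzSensor()
    return -sensor.mass_sensitivity * frequency_shift / harmonic


@dataclass(frozen=True)
class RigidityResult:
    """Dissipation-to-normalized-frequency ratio and its classification."""

    ratio: float  # Hz^-1
    classification: str  # "rigid" | "viscoelastic"
    borderline: bool
    threshold: float = RIGIDITY_THRESHOLD

    @property
    def rigid(self) -> bool:
        return self.classification == "rigid"


def rigidity_ratio(
    trace: HarmonicTrace,
    window: tuple[float, float] | None = None,
    threshold: float = RIGIDITY_THRESHOLD,
    borderline_band: float = 0.25,
) -> RigidityResult:
    """Mean Delta D_nu / (-Delta f_nu/nu) over a window, with rigid flag.

    The "much less than" of the criterion is operationalized as a strict
    ``<`` against ``threshold``; ratios within ``borderline_band`` (relative)
    of the threshold are flagged borderline rather than silently classified.
    """
    t = trace if window is None else trace.window(*window)
    if len(t.time) < 1:
        raise InsufficientDataError("window contains no samples")
    norm = -t.frequency_shift / t.harmonic
    if np.any(norm == 0):
        raise UndefinedRatioError("zero normalized frequency shift in window")
    ratio = float(np.mean(t.dissipation / norm))
    classification = "rigid" if ratio < threshold else "viscoelastic"
    borderline = abs(ratio - threshold) < borderline_band * threshold
    return RigidityResult(ratio, classification, borderline, threshold)


def _complex_frequency_shift(
    h: float,
    density: float,
    eta: float,
    mu: float,
    fluid: BulkFluid,
    sensor: QuartzSensor,
    harmonics: np.ndarray,
) -> np.ndarray:
    """Complex Delta f* per harmonic for a KV film under Newtonian liquid."""
    f = harmonics * sensor.f1
    omega = 2.0 * np.pi * f
    z_liq = np.sqrt(1j * omega * fluid.density * fluid.viscosity)
    if h > 0:
        g_film = mu + 1j * omega * eta
        z_film = np.sqrt(density * g_film)
        gamma = 1j * omega * np.sqrt(density / g_film)
        t = np.tanh(gamma * h)
        z_load = z_film * (z_liq + z_film * t) / (z_film + z_liq * t)
    else:
        z_load = z_liq
    return 1j * sensor.f1 * z_load / (np.pi * sensor.shear_impedance)


def kelvin_voigt_forward(
    layer: ViscoelasticLayer | None,
    fluid: BulkFluid | None = None,
    sensor: QuartzSensor | None = None,
    harmonics: tuple[int, ...] = (7, 9, 11),
    include_liquid: bool = True,
) -> dict[int, tuple[float, float]]:
    """Per-harmonic (Delta f_nu, Delta D_nu) of a Kelvin-Voigt film.

    With ``include_liquid=True`` the returned shifts are referenced to the
    unloaded crystal (so ``layer=None`` or h->0 gives the Newtonian-liquid
    baseline); with ``include_liquid=False`` they are referenced to the
    liquid-loaded baseline, i.e. the film-only response measured in an
    adsorption experiment.
    """
    fluid = fluid or BulkFluid()
    sensor = sensor or QuartzSensor()
    for nu in harmonics:
        _check_harmonic(nu)
    nus = np.asarray(harmonics, dtype=float)
    if layer is None:
        dfc = _complex_frequency_shift(0.0, 1.0, 1.0, 1.0, fluid, sensor, nus)
    else:
        dfc = _complex_frequency_shift(
            layer.thickness, layer.density, layer.shear_viscosity, layer.shear_modulus,
            fluid, sensor, nus,
        )
    if not include_liquid:
        dfc = dfc - _complex_frequency_shift(0.0, 1.0, 1.0, 1.0, fluid, sensor, nus)
    f = nus * sensor.f1
    df = dfc.real
    dd = 2.0 * dfc.imag / f
    return {int(nu): (float(a), float(b)) for nu, a, b in zip(nus, df, dd)}


class KelvinVoigtFilm(RegressorMixin, BaseEstimator):
    """Fit a one-layer Kelvin-Voigt film to per-harmonic (Delta f, Delta D).

    The film density is fixed (QTools-style); free parameters are
    (h, eta, mu), optimized in log space by weighted least squares over the
    joint Delta f / Delta D residuals of all supplied harmonics.  Input
    shifts must be referenced to the liquid-loaded baseline (the usual
    experimental convention).

    Parameters
    ----------
    film_density : assumed film density, kg m^-3 (default 1050).
    fluid_density, fluid_viscosity : Newtonian bulk liquid.
    sensor_f1, sensor_c : quartz fundamental (Hz) and sensitivity
        (ng cm^-2 Hz^-1).
    noise_df, noise_dd : per-channel noise estimates used as residual
        weights (Hz and dimensionless dissipation); ideally taken from the
        baseline window of the traces.
    n_starts : number of deterministic multi-starts.
    random_state : seed for start-point jitter.

    Attributes
    ----------
    layer_ : fitted :class:`ViscoelasticLayer`.
    areal_mass_ : acoustic mass Delta Gamma = rho*h, ng cm^-2.
    thickness_, shear_viscosity_, shear_modulus_ : fitted parameters.
    stderr_ : dict of 1-sigma uncertainties of (thickness, shear_viscosity,
        shear_modulus, areal_mass).
    residual_norm_ : weighted residual 2-norm at the optimum.
    converged_ : False flags a non-converged fit (never silent).
    """

    def __init__(
        self,
        film_density: float = 1050.0,
        fluid_density: float = 1000.0,
        fluid_viscosity: float = 0.001,
        sensor_f1: float = 4.95e6,
        sensor_c: float = 18.0,
        noise_df: float = 0.5,
        noise_dd: float = 0.05e-6,
        n_starts: int = 6,
        random_state: int = 0,
    ):
        self.film_density = film_density
        self.fluid_density = fluid_density
        self.fluid_viscosity = fluid_viscosity
        self.sensor_f1 = sensor_f1
        self.sensor_c = sensor_c
        self.noise_df = noise_df
        self.noise_dd = noise_dd
        self.n_starts = n_starts
        self.random_state = random_state

    def _components(self) -> tuple[BulkFluid, QuartzSensor]:
        return (
            BulkFluid(self.fluid_density, self.fluid_viscosity),
            QuartzSensor(self.sensor_f1, self.sensor_c),
        )

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must have shape (n_harmonics, 2): columns (df_Hz, dD)")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 2:
            raise InsufficientDataError("need at least 2 harmonics to fit a Kelvin-Voigt film")
        for nu in X:
            _check_harmonic(int(nu))
        return X, y

    def _residual(self, p_log, nus, y, fluid, sensor):
        # clip to avoid float overflow during optimizer excursions
        h, eta, mu = np.exp(np.clip(p_log, -230.0, 230.0))
        base = _complex_frequency_shift(0.0, 1.0, 1.0, 1.0, fluid, sensor, nus)
        dfc = _complex_frequency_shift(h, self.film_density, eta, mu, fluid, sensor, nus) - base
        df = dfc.real
        dd = 2.0 * dfc.imag / (nus * sensor.f1)
        return np.concatenate([(df - y[:, 0]) / self.noise_df, (dd - y[:, 1]) / self.noise_dd])

    def fit(self, X, y):
        """Fit the film. X: harmonic orders (n,); y: (n, 2) of (df_Hz, dD)."""
        nus, y = self._validate(X, y)
        fluid, sensor = self._components()
        # Sauerbrey-mass-based thickness guess from the mean normalized shift
        mean_norm = float(np.mean(-y[:, 0] / nus))
        gamma_guess = max(sensor.mass_sensitivity * mean_norm, 1.0)  # ng/cm^2 floor
        h0 = gamma_guess * NG_CM2_TO_KG_M2 / self.film_density
        rng = np.random.default_rng(self.random_state)
        starts = []
        for eta0 in (1.5e-3, 4e-3):
            for mu0 in (1e4, 1e5, 1e6, 1e8):
                starts.append(np.log([h0, eta0, mu0]))
        starts = starts[: max(self.n_starts, 1)] + [
            s + rng.normal(0, 0.2, 3) for s in starts[: max(self.n_starts // 2, 1)]
        ]
        best = None
        for p0 in starts:
            try:
                res = optimize.least_squares(
                    self._residual, p0, args=(nus, y, fluid, sensor), method="lm",
                    max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("Kelvin-Voigt fit failed from every start point")
        h, eta, mu = np.exp(best.x)
        self.layer_ = ViscoelasticLayer(h, self.film_density, eta, mu)
        self.thickness_, self.shear_viscosity_, self.shear_modulus_ = h, eta, mu
        self.areal_mass_ = self.layer_.areal_mass
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self.converged_ = bool(best.success)
        if not self.converged_:
            warnings.warn("Kelvin-Voigt fit did not converge; result flagged", stacklevel=2)
        self.n_harmonics_ = len(nus)
        self._harmonics = nus
        # covariance in log space -> linear-space 1-sigma via delta method
        dof = max(best.fun.size - 3, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
            self.covariance_rank_deficient_ = False
        except np.linalg.LinAlgError:
            cov_log = s2 * np.linalg.pinv(jtj)
            self.covariance_rank_deficient_ = True
        scale = np.array([h, eta, mu])
        self.covariance_ = cov_log * np.outer(scale, scale)
        err = np.sqrt(np.maximum(np.diag(self.covariance_), 0.0))
        self.stderr_ = {
            "thickness": err[0],
            "shear_viscosity": err[1],
            "shear_modulus": err[2],
            "areal_mass": err[0] * self.film_density / NG_CM2_TO_KG_M2,
        }
        return self

    def predict(self, X):
        """Film-only (df_Hz, dD) at the fitted layer for harmonics X."""
        nus = np.asarray(X, dtype=float).reshape(-1)
        fluid, sensor = self._components()
        out = kelvin_voigt_forward(
            self.layer_, fluid, sensor, tuple(int(n) for n in nus), include_liquid=False
        )
        return np.array([out[int(n)] for n in nus])


def harmonic_endpoints(
    traces: dict[int, HarmonicTrace], window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state (X, y) arrays for fitting: window-mean df/dD per harmonic."""
    nus, rows = [], []
    for nu in sorted(traces):
        t = traces[nu].window(*window)
        if len(t.time) == 0:
            raise InsufficientDataError(f"window contains no samples for harmonic {nu}")
        nus.append(nu)
        rows.append([float(np.mean(t.frequency_shift)), float(np.mean(t.dissipation))])
    return np.asarray(nus, dtype=float), np.asarray(rows)


def kelvin_voigt_fit(
    traces: dict[int, HarmonicTrace] | tuple[np.ndarray, np.ndarray],
    window: tuple[float, float] | None = None,
    film_density: float = 1050.0,
    fluid: BulkFluid | None = None,
    sensor: QuartzSensor | None = None,
    **estimator_kwargs,
) -> KelvinVoigtFilm:
    """Convenience wrapper: fit a Kelvin-Voigt film from traces or arrays.

    ``traces`` may be a dict harmonic -> HarmonicTrace (a steady-state window
    is then required) or a pre-extracted ``(harmonics, y)`` pair as produced
    by :func:`harmonic_endpoints`.
    """
    if isinstance(traces, dict):
        if window is None:
            raise ValueError("window required when passing traces")
        X, y = harmonic_endpoints(traces, window)
    else:
        X, y = traces
    fluid = fluid or BulkFluid()
    sensor = sensor or QuartzSensor()
    est = KelvinVoigtFilm(
        film_density=film_density,
        fluid_density=fluid.density,
        fluid_viscosity=fluid.viscosity,
        sensor_f1=sensor.f1,
        sensor_c=sensor.mass_sensitivity,
        **estimator_kwargs,
    )
    return est.fit(X, y)


def initial_attachment_rate(
    time: np.ndarray,
    mass: np.ndarray,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Initial attachment rate (ng cm^-2 min^-1) and its standard error.

    Ordinary linear fit of surface mass density vs time over the declared
    early-time window (time in seconds).
    """
    time = np.asarray(time, dtype=float)
    mass = np.asarray(mass, dtype=float)
    m = (time >= window[0]) & (time <= window[1])
    if int(m.sum()) < 3:
        raise InsufficientDataError("need at least 3 points in the rate window")
    res = stats.linregress(time[m], mass[m])
    return float(res.slope * 60.0), float(res.stderr * 60.0)
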