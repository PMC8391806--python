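"""15N spin-relaxation processing.

Mono-exponential fitting of R1/R1rho decay series with Monte-Carlo errors,
tilt-angle offset correction of R1rho to R2, rigid-rotor R2 prediction from
dipolar and CSA contributions, and Stokes-Einstein scaling of the rotational
correlation time across temperature/viscosity (water-glycerol mixtures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RelaxationSeries",
    "RateEstimate",
    "OffsetGeometry",
    "TumblingModel",
    "fit_decay",
    "offset_correct",
    "predict_rigid_r2",
    "viscosity_water_glycerol",
    "scale_tauc",
    "popavg_r2",
    "R1RHO_DELAYS_S",
    "R1_DELAYS_S",
]

# Gyromagnetic ratios (CODATA), rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126180e7
#: |gamma_N / gamma_H| — 15N Larmor frequency as a fraction of the 1H frequency
GAMMA_RATIO_N_H = abs(GAMMA_N / GAMMA_H)  # ~0.101396
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1e-7  # T^2 J^-1 m^3

#: Standard pseudo-3D delay schedules (s): 10 interleaved points plus a
#: repeat of the 70 ms (R1rho) / 0.6 s (R1) point for error assessment.
R1RHO_DELAYS_S = (0.070, 0.130, 0.010, 0.090, 0.230, 0.030, 0.210, 0.050,
                  0.170, 0.001, 0.070)
R1_DELAYS_S = (0.0, 0.6, 0.08, 1.6, 0.4, 1.8, 1.04, 0.8, 0.2, 0.6)


@dataclass
class RelaxationSeries:
    """Delay-vs-intensity decay for one residue (R1 or R1rho)."""

    residue: int
    delays: np.ndarray  # s
    intensities: np.ndarray  # arbitrary units
    intensity_errors: np.ndarray | None = None  # same units, from plane noise
    rate_type: str = "R1rho"  # {"R1", "R1rho"}

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensity_errors is not None:
            self.intensity_errors = np.asarray(self.intensity_errors, dtype=float)
            if np.any(self.intensity_errors <= 0):
                raise ValueError("intensity errors must be > 0 when provided")
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have equal length")
        if np.any(self.delays < 0):
            raise ValueError("negative delay")
        if np.unique(self.delays).size < 3:
            raise ValueError("need at least 3 distinct delays")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")
        if self.rate_type not in ("R1", "R1rho"):
            raise ValueError(f"unknown rate_type {self.rate_type!r}")


@dataclass
class RateEstimate:
    """A fitted relaxation rate with its Monte-Carlo error."""

    residue: int
    rate: float  # s^-1
    rate_error: float  # s^-1
    rate_type: str
    i0: float = float("nan")
    converged: bool = True


@dataclass
class OffsetGeometry:
    """Spin-lock geometry for the R1rho -> R2 tilt-angle correction.

    ``delta_omega`` is the offset of the residue's resonance from the 15N
    carrier (Hz, either sign); ``theta`` is folded into (0, pi/2] so the
    correction is sign-safe on both sides of the carrier.
    """

    omega1: float  # spin-lock field strength, Hz
    delta_omega: float  # resonance offset from carrier, Hz
    theta: float = field(init=False)  # tilt angle, rad

    def __post_init__(self):
        if self.omega1 <= 0:
            raise ValueError("omega1 must be > 0")
        if self.delta_omega == 0.0:
            self.theta = math.pi / 2
        else:
            self.theta = math.atan(abs(self.omega1 / self.delta_omega))


@dataclass
class TumblingModel:
    """Rigid isotropic rotor for backbone amide 15N relaxation.

    Defaults rNH = 1.02 A and Delta-sigma = -170 ppm are the conventional
    effective bond length and 15N CSA for backbone amides.
    """

    tau_c: float  # ns
    field_1H: float  # MHz
    temperature: float = 298.15  # K
    viscosity: float = 0.89  # mPa s
    glycerol_vv: float = 0.0
    r_NH: float = 1.02  # Angstrom
    csa: float = -170.0  # ppm

    def __post_init__(self):
        if self.tau_c <= 0 or self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("tau_c, temperature and viscosity must be > 0")


def _expdecay(t, i0, rate):
    return i0 * np.exp(-rate * t)


def fit_decay(series: RelaxationSeries, n_mc: int = 1000,
              seed: int | None = None) -> RateEstimate:
    """Fit I(t) = I0 exp(-R t) by least squares; error by Monte Carlo.

    Duplicate delays (schedule repeats) all enter the fit as independent
    observations.  The rate error is the standard deviation of the rate over
    ``n_mc`` refits with intensities resampled from their errors; if the
    series carries no intensity errors the residual RMS is used as a
    homoscedastic error estimate.
    """
    t, y = series.delays, series.intensities
    if np.allclose(y, y[0]):
        raise ValueError("all intensities equal: no decay to fit")
    # log-linear start values; guard against non-positive intensities
    ypos = np.clip(y, 1e-12 * np.max(np.abs(y)), None)
    slope, intercept = np.polyfit(t, np.log(ypos), 1)
    p0 = (math.exp(intercept), max(-slope, 1e-3))
    try:
        popt, _ = curve_fit(_expdecay, t, y, p0=p0, maxfev=10000)
    except RuntimeError:
        return RateEstimate(series.residue, float("nan"), float("nan"),
                            series.rate_type, converged=False)
    i0, rate = popt
    if rate <= 0 or not np.isfinite(rate):
        return RateEstimate(series.residue, float(rate), float("nan"),
                            series.rate_type, i0=float(i0), converged=False)

    if series.intensity_errors is not None:
        sigma = series.intensity_errors
    else:
        resid = y - _expdecay(t, *popt)
        dof = max(len(y) - 2, 1)
        sigma = np.full_like(y, math.sqrt(float(resid @ resid) / dof))

    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_mc):
        y_mc = y + rng.normal(scale=sigma)
        try:
            p_mc, _ = curve_fit(_expdecay, t, y_mc, p0=popt, maxfev=2000)
        except RuntimeError:
            continue
        rates.append(p_mc[1])
    rate_error = float(np.std(rates)) if rates else float("nan")
    return RateEstimate(series.residue, float(rate), rate_error,
                        series.rate_type, i0=float(i0))


def offset_correct(r1rho: RateEstimate, r1: RateEstimate,
                   geom: OffsetGeometry) -> RateEstimate:
    """R2 = (R1rho - R1 cos^2(theta)) / sin^2(theta), errors propagated."""
    if r1rho.rate_type != "R1rho" or r1.rate_type != "R1":
        raise ValueError("expected an R1rho and an R1 estimate")
    if r1rho.residue != r1.residue:
        raise ValueError(
            f"residue mismatch: {r1rho.residue} vs {r1.residue}")
    s2 = math.sin(geom.theta) ** 2
    c2 = math.cos(geom.theta) ** 2
    if s2 == 0.0:
        raise ValueError("theta = 0: offset correction unbounded")
    r2 = (r1rho.rate - r1.rate * c2) / s2
    err = math.hypot(r1rho.rate_error / s2, r1.rate_error * c2 / s2)
    return RateEstimate(r1rho.residue, r2, err, "R2")


def _j(omega: float, tau_c_s: float) -> float:
    """Reduced spectral density of a rigid isotropic rotor, J(w) (s/rad)."""
    return 0.4 * tau_c_s / (1.0 + (omega * tau_c_s) ** 2)


def predict_rigid_r2(model: TumblingModel) -> float:
    """Amide 15N R2 of a rigid rotor: dipolar (1H-15N) + 15N CSA terms.

    R2 = (d^2/8)[4J(0) + J(wH-wN) + 3J(wN) + 6J(wH) + 6J(wH+wN)]
       + (c^2/6)[4J(0) + 3J(wN)]
    with d = (mu0/4pi) hbar gH gN / r^3 and c = wN * Dsigma / sqrt(3).
    """
    tau_c = model.tau_c * 1e-9
    omega_h = 2 * math.pi * model.field_1H * 1e6
    omega_n = omega_h * GAMMA_RATIO_N_H
    r = model.r_NH * 1e-10
    d = MU0_OVER_4PI * HBAR * abs(GAMMA_H * GAMMA_N) / r**3  # rad/s
    c = omega_n * abs(model.csa) * 1e-6 / math.sqrt(3.0)  # rad/s
    jd = (4 * _j(0.0, tau_c) + _j(omega_h - omega_n, tau_c)
          + 3 * _j(omega_n, tau_c) + 6 * _j(omega_h, tau_c)
          + 6 * _j(omega_h + omega_n, tau_c))
    jc = 4 * _j(0.0, tau_c) + 3 * _j(omega_n, tau_c)
    return d**2 / 8.0 * jd + c**2 / 6.0 * jc


#: Density of glycerol (g/mL), used to convert % v/v to mass fraction.
GLYCEROL_DENSITY = 1.261


def _water_density(t_celsius: float) -> float:
    # Kell-type polynomial, g/mL; adequate over 0-100 C
    t = t_celsius
    return (999.83952 + 16.945176 * t - 7.9870401e-3 * t**2
            - 46.170461e-6 * t**3 + 105.56302e-9 * t**4
            - 280.54253e-12 * t**5) / (1 + 16.897850e-3 * t) / 1000.0


def viscosity_water_glycerol(temperature: float, glycerol_vv: float) -> float:
    """Viscosity (mPa s) of a water-glycerol mixture.

    Empirical exponential-mixing correlation: component viscosities
    mu_w(T), mu_g(T) combined as mu = mu_w^alpha * mu_g^(1-alpha) with a
    temperature- and composition-dependent weighting exponent.  The % v/v
    glycerol fraction is converted to a mass fraction via the glycerol
    density (1.261 g/mL).  Pure water at 25 C evaluates to ~0.89 mPa s.
    """
    if not (273.0 < temperature < 373.0):
        raise ValueError("temperature outside the supported 273-373 K range")
    if not (0.0 <= glycerol_vv < 0.5):
        raise ValueError("glycerol fraction must be in [0, 0.5)")
    t = temperature - 273.15  # correlation is parameterized in Celsius
    mu_w = 1.790 * math.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))
    if glycerol_vv == 0.0:
        return mu_w
    mu_g = 12100.0 * math.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))
    mass_g = glycerol_vv * GLYCEROL_DENSITY
    mass_w = (1.0 - glycerol_vv) * _water_density(t)
    cm = mass_g / (mass_g + mass_w)
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a**2.5
    alpha = 1.0 - cm + a * b * cm * (1.0 - cm) / (a * cm + b * (1.0 - cm))
    return mu_w**alpha * mu_g ** (1.0 - alpha)


def scale_tauc(tau_ref: float, T_ref: float, eta_ref: float,
               T: float, eta: float) -> float:
    """Stokes-Einstein scaling: tau_c = tau_ref * (eta/eta_ref) * (T_ref/T)."""
    if min(tau_ref, T_ref, eta_ref, T, eta) <= 0:
        raise ValueError("all arguments must be positive")
    return tau_ref * (eta / eta_ref) * (T_ref / T)


def popavg_r2(p_bound: float, r2_free: float, r2_bound: float) -> float:
    """Fast-exchange population-weighted R2: (1-p) R2_free + p R2_bound."""
    if not 0.0 <= p_bound <= 1.0:
        raise ValueError("p_bound must be in [0, 1]")
    return (1.0 - p_bound) * r2_free + p_bound * r2_bound
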