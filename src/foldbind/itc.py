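"""Isothermal titration calorimetry: 1:1 isotherm simulation, fitting and
thermodynamic dissection.

The binding model is n identical and independent sites.  Injection heats
are computed with displaced-volume ("effective concentration") bookkeeping
for a perfusion cell: each injection instantaneously mixes into the cell,
an equal volume of mixed solution overflows, and the heat of the injection
is the enthalpy of the net complex formed inside the cell after overflow.
Free energies dissect as dG = R T ln(K_D) and -TdS = dG - dH.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import complex_concentration

__all__ = [
    "ITCExperiment",
    "ThermoResult",
    "simulate_isotherm",
    "fit_isotherm",
    "dissect",
    "hbond_equivalent",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant, kcal mol^-1 K^-1 (standard state 1 M).
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass
class ITCExperiment:
    """Injection scheme and integrated heats of one titration.

    ``heats`` are raw heats per injection in kcal; ``heats_per_mole`` gives
    the conventional kcal per mole of injectant.
    """

    cell_conc: float  # M, macromolecule in the cell
    syringe_conc: float  # M, titrant
    cell_volume: float  # L
    injection_volumes: np.ndarray  # L
    heats: np.ndarray | None = None  # kcal per injection
    temperature: float = 293.15  # K

    def __post_init__(self):
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        self.injection_volumes = np.asarray(self.injection_volumes, float)
        if self.injection_volumes.size < 1:
            raise ValueError("need at least one injection")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be > 0")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.size != self.injection_volumes.size:
                raise ValueError("heats and injection volumes differ in length")

    @property
    def heats_per_mole(self) -> np.ndarray:
        """Heats normalized per mole of injected titrant (kcal/mol)."""
        return self.heats / (self.syringe_conc * self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant:macromolecule ratio in the cell per injection."""
        m, x = _cell_concentrations(self)
        return x / m


@dataclass
class ThermoResult:
    """Fitted/derived 1:1 binding thermodynamics at ``temperature``."""

    K_D: float  # M
    dH: float  # kcal/mol
    N: float  # stoichiometry
    temperature: float  # K
    K_D_error: float = 0.0
    dH_error: float = 0.0
    N_error: float = 0.0
    dG: float = field(init=False)  # kcal/mol
    minusTdS: float = field(init=False)  # kcal/mol
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.K_D <= 0:
            raise ValueError("K_D must be > 0")
        self.dG = GAS_CONSTANT_KCAL * self.temperature * math.log(self.K_D)
        self.minusTdS = self.dG - self.dH

    @property
    def entropy_favorable(self) -> bool:
        """True when the entropic contribution (-TdS) favors binding."""
        return self.minusTdS < 0


def _cell_concentrations(exp: ITCExperiment):
    """Total (M, X) concentrations in the cell after each injection.

    Displaced-volume convention: injection dV mixes into V0 + dV, then dV
    of the mixed solution overflows, restoring V0.
    """
    v0 = exp.cell_volume
    m = np.empty(exp.injection_volumes.size)
    x = np.empty_like(m)
    mc, xc = exp.cell_conc, 0.0
    for i, dv in enumerate(exp.injection_volumes):
        f = v0 / (v0 + dv)
        mc = mc * f
        xc = (xc * v0 + exp.syringe_conc * dv) / (v0 + dv)
        m[i] = mc
        x[i] = xc
    return m, x


def _isotherm_heats(K_D, dH, N, exp: ITCExperiment, q_dil=0.0) -> np.ndarray:
    """Raw heat (kcal) of each injection under n identical independent sites."""
    v0 = exp.cell_volume
    m, x = _cell_concentrations(exp)
    heats = np.empty_like(m)
    pl_prev = 0.0
    for i, dv in enumerate(exp.injection_volumes):
        pl = complex_concentration(N * m[i], x[i], K_D)
        # complex carried over from before the injection, after overflow
        carried = pl_prev * v0 / (v0 + dv)
        heats[i] = dH * (pl - carried) * v0 + q_dil
        pl_prev = pl
    return heats


def simulate_isotherm(truth: tuple[float, float, float],
                      experiment: ITCExperiment) -> ITCExperiment:
    """Forward-simulate injection heats for ground-truth (K_D, dH, N).

    Warns (but still computes) when the cumulative injected volume exceeds
    the cell volume.
    """
    K_D, dH, N = truth
    if K_D <= 0 or N <= 0:
        raise ValueError("K_D and N must be > 0")
    if float(np.sum(experiment.injection_volumes)) > experiment.cell_volume:
        warnings.warn("cumulative injected volume exceeds the cell volume",
                      stacklevel=2)
    heats = _isotherm_heats(K_D, dH, N, experiment)
    return ITCExperiment(experiment.cell_conc, experiment.syringe_conc,
                         experiment.cell_volume, experiment.injection_volumes,
                         heats, experiment.temperature)


def fit_isotherm(exp: ITCExperiment, init: dict | None = None,
                 seed: int | None = None, fit_dilution: bool = False) -> ThermoResult:
    """Least-squares fit of (K_D, dH, N) to the injection heats.

    Parameter errors come from the Jacobian covariance at the optimum.
    The Wiseman c-value N*[cell]/K_D is checked: outside [1, 1000] the
    isotherm carries little shape information and the result is flagged
    (``low_information`` for small c, ``KD_upper_bound`` for the
    stoichiometric regime of very large c).
    """
    if exp.heats is None:
        raise ValueError("experiment carries no heats")
    informative = np.sum(np.abs(exp.heats) > 1e-3 * np.max(np.abs(exp.heats)))
    if informative < 6:
        raise ValueError("need at least 6 informative injections")

    init = dict(init or {})
    total_q = float(np.sum(exp.heats))
    dh0 = init.get("dH", total_q / (exp.cell_conc * exp.cell_volume))
    kd0 = init.get("K_D", exp.cell_conc / 10.0)
    n0 = init.get("N", 1.0)

    # fit on the per-mole-of-injectant scale (kcal/mol, O(1-10)) so the
    # optimizer tolerances are meaningful; raw heats are O(1e-9 kcal)
    inj_moles = exp.syringe_conc * exp.injection_volumes

    def residuals(x):
        kd, dh, n = x[:3]
        qd = x[3] if fit_dilution else 0.0
        model = _isotherm_heats(math.exp(kd), dh, n, exp, qd)
        return (model - exp.heats) / inj_moles

    x0 = [math.log(kd0), dh0, n0] + ([0.0] if fit_dilution else [])
    lo = [math.log(1e-15), -1e3, 0.05] + ([-1.0] if fit_dilution else [])
    hi = [math.log(1.0), 1e3, 20.0] + ([1.0] if fit_dilution else [])
    sol = least_squares(residuals, x0, bounds=(lo, hi), ftol=1e-14,
                        xtol=1e-14, gtol=1e-14, max_nfev=2000)
    if sol.status <= 0:
        raise RuntimeError(f"isotherm fit did not converge: {sol.message}")
    kd, dh, n = math.exp(sol.x[0]), sol.x[1], sol.x[2]

    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(sol.x.size, np.nan)
    kd_err = kd * perr[0]  # delta-method from log K_D

    flags = []
    c = n * exp.cell_conc / kd
    if c < 1.0:
        flags.append("low_information")
    elif c > 1000.0:
        flags.append("KD_upper_bound")
    res = ThermoResult(kd, dh, n, exp.temperature, kd_err, perr[1], perr[2])
    res.flags = flags
    return res


def dissect(K_D: float, dH: float, T: float = 293.15) -> ThermoResult:
    """dG = R T ln(K_D); -TdS = dG - dH (kcal/mol at temperature T)."""
    return ThermoResult(K_D, dH, N=1.0, temperature=T)


def hbond_equivalent(ddH: float, e_min: float = 1.5,
                     e_max: float = 2.25) -> tuple[int, int]:
    """Hydrogen-bond count range equivalent to an enthalpy difference.

    Divides ddH by a per-bond enthalpy window (default 1.5-2.25 kcal/mol)
    and rounds inward to integers: 4.5 kcal/mol -> (2, 3).
    """
    if ddH < 0:
        raise ValueError("ddH must be >= 0")
    if not 0 < e_min <= e_max:
        raise ValueError("invalid per-bond enthalpy window")
    return (math.ceil(ddH / e_max - 1e-9), math.floor(ddH / e_min + 1e-9))
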