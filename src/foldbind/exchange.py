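"""Two-site chemical-exchange models: CEST and CPMG.

Forward simulation of 15N CEST profiles by Bloch-McConnell propagation
(matrix exponential over the saturation period) and of CPMG relaxation
dispersion by the Carver-Richards closed form; global least-squares fitting
of the exchange rate constant kEX and bound population p_bound shared
across residues; per-residue extraction of free/bound chemical-shift
differences (delta-omega) at fixed exchange parameters.

Conventions
-----------
* ppm -> rad/s uses the 15N Larmor frequency = field_1H * |gammaN/gammaH|.
* delta_omega = delta_B - delta_A; positive means the bound state resonates
  downfield of the free state.
* Detailed balance: k_AB = p_bound * kEX, k_BA = (1 - p_bound) * kEX.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import least_squares

from .relax import GAMMA_RATIO_N_H

__all__ = [
    "TwoSiteExchangeModel",
    "CESTProfile",
    "CPMGProfile",
    "ExchangeFitResult",
    "DwEstimate",
    "simulate_cest",
    "simulate_cest_numeric",
    "simulate_cpmg",
    "simulate_cpmg_numeric",
    "fit_global",
    "extract_dw",
]


def rad_per_ppm(field_1H: float) -> float:
    """rad/s per ppm on the 15N axis at a given 1H field (MHz)."""
    return 2.0 * math.pi * field_1H * GAMMA_RATIO_N_H


@dataclass
class TwoSiteExchangeModel:
    """Global two-site exchange parameters plus one residue's spin parameters.

    kEX = k_AB + k_BA is the total exchange rate constant and p_bound the
    fractional population of the bound (minor) state B.  Chemical shifts are
    on the 15N ppm axis relative to the carrier.
    """

    kEX: float  # s^-1
    p_bound: float
    delta_A: float = 0.0  # ppm, free state
    delta_B: float = 0.0  # ppm, bound state
    R1_A: float = 1.0  # s^-1
    R1_B: float | None = None  # defaults to R1_A (tied)
    R2_A: float = 5.0  # s^-1
    R2_B: float = 69.0  # s^-1

    def __post_init__(self):
        if self.kEX <= 0:
            raise ValueError("kEX must be > 0")
        if not 0.0 < self.p_bound < 1.0:
            raise ValueError("p_bound must be in (0, 1)")
        if self.R1_B is None:
            self.R1_B = self.R1_A
        for r in (self.R1_A, self.R1_B, self.R2_A, self.R2_B):
            if r < 0:
                raise ValueError("relaxation rates must be >= 0")

    @property
    def dw(self) -> float:
        """delta_omega = delta_B - delta_A (ppm)."""
        return self.delta_B - self.delta_A

    @property
    def k_AB(self) -> float:
        return self.p_bound * self.kEX

    @property
    def k_BA(self) -> float:
        return (1.0 - self.p_bound) * self.kEX


@dataclass
class CESTProfile:
    """One residue's CEST dataset: saturation offsets vs I/I0."""

    residue: int
    field_1H: float  # MHz
    B1: float  # Hz
    T_sat: float  # s
    offsets: np.ndarray  # ppm on the 15N axis
    intensity_ratio: np.ndarray | None = None
    error: np.ndarray | None = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.size == 0:
            raise ValueError("offsets must be non-empty")
        if self.T_sat <= 0:
            raise ValueError("T_sat must be > 0")
        if self.B1 < 0:
            raise ValueError("B1 must be >= 0")
        if self.intensity_ratio is not None:
            self.intensity_ratio = np.asarray(self.intensity_ratio, float)
            if not np.all(np.isfinite(self.intensity_ratio)):
                raise ValueError("non-finite intensity ratio")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)

    @property
    def carrier_MHz(self) -> float:
        """15N carrier frequency (MHz)."""
        return self.field_1H * GAMMA_RATIO_N_H


@dataclass
class CPMGProfile:
    """One residue's CPMG relaxation dispersion: nu_CPMG vs R2,eff."""

    residue: int
    field_1H: float  # MHz
    nu_cpmg: np.ndarray  # Hz
    r2_eff: np.ndarray | None = None  # s^-1
    error: np.ndarray | None = None
    T_relax: float = 0.04  # s, constant-time relaxation delay

    def __post_init__(self):
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg must be > 0")
        if self.r2_eff is not None:
            self.r2_eff = np.asarray(self.r2_eff, dtype=float)
            if not np.all(np.isfinite(self.r2_eff)):
                raise ValueError("non-finite R2,eff")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def _bm_matrices(model: TwoSiteExchangeModel, offsets_ppm: np.ndarray,
                 B1: float, field_1H: float) -> np.ndarray:
    """Stack of 6x6 Bloch-McConnell evolution matrices, one per offset.

    Basis (MxA, MyA, MzA, MxB, MyB, MzB), B1 applied along +x in the frame
    rotating at the saturation offset.  Homogeneous form: magnetization
    relaxes toward zero during saturation (no equilibrium-recovery term).
    """
    scale = rad_per_ppm(field_1H)
    w1 = 2.0 * math.pi * B1
    om_a = (model.delta_A - offsets_ppm) * scale
    om_b = (model.delta_B - offsets_ppm) * scale
    kab, kba = model.k_AB, model.k_BA
    n = offsets_ppm.size
    L = np.zeros((n, 6, 6))
    # state A block
    L[:, 0, 0] = -(model.R2_A + kab)
    L[:, 0, 1] = -om_a
    L[:, 1, 0] = om_a
    L[:, 1, 1] = -(model.R2_A + kab)
    L[:, 1, 2] = w1
    L[:, 2, 1] = -w1
    L[:, 2, 2] = -(model.R1_A + kab)
    # state B block
    L[:, 3, 3] = -(model.R2_B + kba)
    L[:, 3, 4] = -om_b
    L[:, 4, 3] = om_b
    L[:, 4, 4] = -(model.R2_B + kba)
    L[:, 4, 5] = w1
    L[:, 5, 4] = -w1
    L[:, 5, 5] = -(model.R1_B + kba)
    # exchange coupling
    idx = np.arange(3)
    L[:, idx, idx + 3] = kba
    L[:, idx + 3, idx] = kab
    return L


def _cest_from_matrices(L: np.ndarray, p_bound: float, T_sat: float) -> np.ndarray:
    prop = sla.expm(L * T_sat)
    m0 = np.array([0.0, 0.0, 1.0 - p_bound, 0.0, 0.0, p_bound])
    mz_a = prop @ m0
    return mz_a[:, 2] / (1.0 - p_bound)


def simulate_cest(model: TwoSiteExchangeModel, profile: CESTProfile) -> CESTProfile:
    """Simulate a CEST profile by Bloch-McConnell matrix-exponential propagation.

    For each saturation offset the 6-dimensional two-site magnetization is
    propagated for ``T_sat``; I/I0 = MzA(T_sat)/MzA(0) with initial
    longitudinal magnetization at the equilibrium populations.
    """
    L = _bm_matrices(model, profile.offsets, profile.B1, profile.field_1H)
    ratio = _cest_from_matrices(L, model.p_bound, profile.T_sat)
    if not np.all(np.isfinite(ratio)):
        raise FloatingPointError("non-finite Bloch-McConnell propagation")
    return CESTProfile(profile.residue, profile.field_1H, profile.B1,
                       profile.T_sat, profile.offsets, ratio,
                       error=profile.error)


def simulate_cest_numeric(model: TwoSiteExchangeModel, profile: CESTProfile,
                          dt: float = 1e-5) -> np.ndarray:
    """Brute-force RK4 integration of the same Bloch-McConnell ODE.

    Independent cross-check for :func:`simulate_cest`; O(T_sat/dt) work.
    """
    L = _bm_matrices(model, profile.offsets, profile.B1, profile.field_1H)
    n_steps = int(round(profile.T_sat / dt))
    dt = profile.T_sat / n_steps
    m = np.tile(np.array([0, 0, 1 - model.p_bound, 0, 0, model.p_bound]),
                (profile.offsets.size, 1))[..., None]
    for _ in range(n_steps):
        k1 = L @ m
        k2 = L @ (m + 0.5 * dt * k1)
        k3 = L @ (m + 0.5 * dt * k2)
        k4 = L @ (m + dt * k3)
        m = m + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return m[:, 2, 0] / (1.0 - model.p_bound)


def simulate_cpmg(model: TwoSiteExchangeModel, nu_cpmg, field_1H: float,
                  residue: int | None = None, T_relax: float = 0.04) -> CPMGProfile:
    """R2,eff(nu_CPMG) from the Carver-Richards closed form.

    nu_CPMG = 1/(2 delta) with delta the spacing between successive
    refocusing pulses.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be > 0")
    pa, pb = 1.0 - model.p_bound, model.p_bound
    kex = model.kEX
    dw = model.dw * rad_per_ppm(field_1H)  # rad/s
    r2a, r2b = model.R2_A, model.R2_B
    if dw == 0.0:
        r2eff = np.full_like(nu, pa * r2a + pb * r2b)
    else:
        dr = r2a - r2b - pa * kex + pb * kex
        psi = dr**2 - dw**2 + 4.0 * pa * pb * kex**2
        zeta = 2.0 * dw * dr
        root = np.hypot(psi, zeta)
        dplus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
        dminus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
        tau_cp = 1.0 / (2.0 * nu)
        eta_p = tau_cp / math.sqrt(2.0) * np.sqrt(np.maximum(root + psi, 0.0))
        eta_m = tau_cp / math.sqrt(2.0) * np.sqrt(np.maximum(root - psi, 0.0))
        # arccosh(D+ cosh(eta+) - D- cos(eta-)), log-space for large eta+
        small = eta_p < 30.0
        arg = dplus * np.cosh(np.where(small, eta_p, 0.0)) - dminus * np.cos(eta_m)
        ach = np.where(small,
                       np.arccosh(np.maximum(arg, 1.0)),
                       eta_p + np.log(np.maximum(dplus, 1e-300)))
        r2eff = 0.5 * (r2a + r2b + kex - ach / tau_cp)
    res = residue if residue is not None else -1
    return CPMGProfile(res, field_1H, nu, r2eff, T_relax=T_relax)


def simulate_cpmg_numeric(model: TwoSiteExchangeModel, nu_cpmg, field_1H: float,
                          T_relax: float = 0.04) -> np.ndarray:
    """R2,eff by explicit propagation of the CPMG echo train.

    The transverse magnetization (M+_A, M+_B) evolves under the 2x2 complex
    Bloch-McConnell matrix for delta/2 and is conjugated by each 180 pulse.
    The effective rate is measured from the decay of the A-state signal
    between T_relax and 2*T_relax, which isolates the steady-state echo
    decay rate (the quantity the Carver-Richards closed form expresses)
    from the initial-projection transient.  Serves as the independent
    oracle for :func:`simulate_cpmg`.
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    dw = model.dw * rad_per_ppm(field_1H)
    kab, kba = model.k_AB, model.k_BA
    A = np.array([
        [-model.R2_A - kab + 0j, kba],
        [kab, -model.R2_B - kba + 1j * dw],
    ])
    pa = 1.0 - model.p_bound
    out = np.empty_like(nu)
    for i, v in enumerate(nu):
        n_echo = max(int(round(2.0 * v * T_relax)), 1)
        t_block = n_echo / (2.0 * v)  # duration of n_echo full echoes
        tau = 1.0 / (4.0 * v)  # delta/2: half the interpulse spacing
        U = sla.expm(A * tau)
        m = np.array([pa + 0j, model.p_bound + 0j])
        for _ in range(n_echo):
            m = U @ np.conj(U @ m)  # tau - 180x - tau
        a1 = abs(m[0])
        for _ in range(n_echo):
            m = U @ np.conj(U @ m)
        out[i] = -math.log(abs(m[0]) / a1) / t_block
    return out


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------

@dataclass
class DwEstimate:
    """Per-residue chemical-shift difference from an exchange fit."""

    residue: int
    dw: float  # ppm
    dw_error: float  # ppm
    flagged: bool = False  # True when only an upper bound is supported
    note: str = ""


@dataclass
class ExchangeFitResult:
    kEX: float
    kEX_error: float
    p_bound: float
    p_bound_error: float
    dw: dict[int, DwEstimate]
    chi2: float
    n_points: int
    n_params: int
    residuals: np.ndarray | None = None
    boundary_pinned: list[str] = dc_field(default_factory=list)

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / max(self.n_points - self.n_params, 1)


def _default_errors_cest(profile: CESTProfile) -> np.ndarray:
    if profile.error is not None and np.all(profile.error > 0):
        return profile.error
    # baseline scatter: spread of the flat far-offset region
    y = profile.intensity_ratio
    n = max(len(y) // 5, 3)
    base = np.concatenate([y[:n], y[-n:]])
    sd = float(np.std(np.diff(base))) / math.sqrt(2.0)
    return np.full_like(y, max(sd, 1e-4))


def _default_errors_cpmg(profile: CPMGProfile) -> np.ndarray:
    if profile.error is not None and np.all(profile.error > 0):
        return profile.error
    return np.full_like(profile.r2_eff, max(0.02 * np.mean(profile.r2_eff), 1e-3))


def detect_cest_dips(profile: CESTProfile) -> tuple[float, float | None]:
    """Locate the major dip and, if present, a minor dip (ppm positions).

    Minima of the lightly smoothed profile; the deepest is the free state.
    Returns (major, minor-or-None).
    """
    y = profile.intensity_ratio
    k = np.ones(3) / 3.0
    ys = np.convolve(y, k, mode="same")
    ys[0], ys[-1] = y[0], y[-1]
    order = np.argsort(profile.offsets)
    x, ys = profile.offsets[order], ys[order]
    mins = [i for i in range(1, len(ys) - 1)
            if ys[i] <= ys[i - 1] and ys[i] <= ys[i + 1]]
    if not mins:
        return float(x[np.argmin(ys)]), None
    mins.sort(key=lambda i: ys[i])
    major = float(x[mins[0]])
    base = float(np.median(ys))
    noise = float(np.std(np.diff(ys))) / math.sqrt(2.0)
    for i in mins[1:]:
        if abs(x[i] - major) > 0.3 and base - ys[i] > 4.0 * noise:
            return major, float(x[i])
    return major, None


class _ParamLayout:
    """Index bookkeeping for the global parameter vector.

    x = [kEX, p_bound] followed by per-residue blocks.  When a residue's
    free-state shift is supplied (``free_shifts``) the block is
    [dw, R1_A, R2_A, R2_B]; otherwise delta_A is fitted too and the block is
    [delta_A, dw, R1_A, R2_A, R2_B].
    """

    def __init__(self, residues: list[int],
                 free_shifts: dict[int, float] | None = None):
        self.residues = residues
        self.fixed_da = dict(free_shifts or {})
        self.index: dict[int, int] = {}
        self.width: dict[int, int] = {}
        j = 2
        for r in residues:
            self.index[r] = j
            self.width[r] = 4 if r in self.fixed_da else 5
            j += self.width[r]
        self.n_total = j

    @property
    def n(self) -> int:
        return self.n_total

    def dw_index(self, residue: int) -> int:
        return self.index[residue] + (0 if residue in self.fixed_da else 1)

    def model_for(self, x: np.ndarray, residue: int) -> TwoSiteExchangeModel:
        j = self.index[residue]
        if residue in self.fixed_da:
            da = self.fixed_da[residue]
            dw, r1a, r2a, r2b = x[j:j + 4]
        else:
            da, dw, r1a, r2a, r2b = x[j:j + 5]
        return TwoSiteExchangeModel(
            kEX=x[0], p_bound=x[1], delta_A=da, delta_B=da + dw,
            R1_A=r1a, R2_A=r2a, R2_B=r2b)


def _collect(profiles) -> tuple[list[CESTProfile], list[CPMGProfile]]:
    cest = [p for p in profiles if isinstance(p, CESTProfile)]
    cpmg = [p for p in profiles if isinstance(p, CPMGProfile)]
    return cest, cpmg


def _residuals_factory(cest, cpmg, layout):
    cest_err = [_default_errors_cest(p) for p in cest]
    cpmg_err = [_default_errors_cpmg(p) for p in cpmg]
    # batch all CEST offsets into a single stacked expm call per evaluation
    def fun(x):
        res = []
        if cest:
            mats = []
            for p in cest:
                m = layout.model_for(x, p.residue)
                mats.append(_bm_matrices(m, p.offsets, p.B1, p.field_1H))
            ratios = _cest_from_matrices(np.concatenate(mats), x[1],
                                         cest[0].T_sat)
            start = 0
            for p, e in zip(cest, cest_err):
                stop = start + p.offsets.size
                res.append((ratios[start:stop] - p.intensity_ratio) / e)
                start = stop
        for p, e in zip(cpmg, cpmg_err):
            m = layout.model_for(x, p.residue)
            sim = simulate_cpmg(m, p.nu_cpmg, p.field_1H).r2_eff
            res.append((sim - p.r2_eff) / e)
        return np.concatenate(res)
    return fun


def _jac_sparsity(cest, cpmg, layout):
    rows = sum(p.offsets.size for p in cest) + sum(p.nu_cpmg.size for p in cpmg)
    S = np.zeros((rows, layout.n), dtype=bool)
    S[:, :2] = True
    r0 = 0
    for p in cest:
        j = layout.index[p.residue]
        S[r0:r0 + p.offsets.size, j:j + layout.width[p.residue]] = True
        r0 += p.offsets.size
    for p in cpmg:
        j = layout.index[p.residue]
        S[r0:r0 + p.nu_cpmg.size, j:j + layout.width[p.residue]] = True
        r0 += p.nu_cpmg.size
    return S


DW_MULTISTART_PPM = (0.5, -0.5, 1.5, -1.5, 3.0, -3.0, 5.0, -5.0)


def _initial_guess(cest, cpmg, layout, init):
    init = dict(init or {})
    x0 = np.empty(layout.n)
    x0[0] = init.get("kEX", 150.0)
    x0[1] = init.get("p_bound", 0.05)
    per_res_cest = {p.residue: p for p in cest}
    dw_inits = init.get("dw", {})
    for r in layout.residues:
        j = layout.index[r]
        da, dw = layout.fixed_da.get(r, 0.0), dw_inits.get(r, 1.5)
        r2a = 5.0
        if r in per_res_cest:
            p = per_res_cest[r]
            major, minor = detect_cest_dips(p)
            if r in layout.fixed_da:
                major = da
            else:
                da = major
            if r not in dw_inits and minor is not None:
                dw = minor - major
        else:
            pcp = next(q for q in cpmg if q.residue == r)
            r2a = float(np.min(pcp.r2_eff))
        block = (dw, init.get("R1_A", 1.5), r2a, init.get("R2_B", 69.0))
        if r not in layout.fixed_da:
            block = (da,) + block
        x0[j:j + layout.width[r]] = block
    return x0


def _bounds(layout, cest):
    lo = np.empty(layout.n)
    hi = np.empty(layout.n)
    lo[:2] = (1.0, 1e-4)
    hi[:2] = (5000.0, 0.5)
    if cest:
        off_lo = min(float(np.min(p.offsets)) for p in cest)
        off_hi = max(float(np.max(p.offsets)) for p in cest)
    else:
        off_lo, off_hi = -20.0, 20.0
    for r in layout.residues:
        j = layout.index[r]
        blo, bhi = (-12.0, 0.05, 0.2, 20.0), (12.0, 10.0, 150.0, 2000.0)
        if r not in layout.fixed_da:
            blo, bhi = (off_lo,) + blo, (off_hi,) + bhi
        lo[j:j + layout.width[r]] = blo
        hi[j:j + layout.width[r]] = bhi
    return lo, hi


def _run_lsq(fun, x0, bounds, sparsity, layout):
    # characteristic parameter scales: [kEX, pB] + per-residue blocks
    x_scale = np.empty_like(x0)
    x_scale[:2] = (50.0, 0.02)
    for r in layout.residues:
        j = layout.index[r]
        blk = (0.2, 0.5, 2.0, 20.0)
        if r not in layout.fixed_da:
            blk = (0.2,) + blk
        x_scale[j:j + layout.width[r]] = blk
    return least_squares(
        fun, x0, bounds=bounds, jac_sparsity=sparsity, tr_solver="lsmr",
        x_scale=x_scale, ftol=1e-9, xtol=1e-9, max_nfev=300)


def _covariance(jac, cost, m, n):
    J = np.asarray(jac.todense()) if hasattr(jac, "todense") else jac
    dof = max(m - n, 1)
    s2 = 2.0 * cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_global(profiles, residue_subset=None, init=None,
               seed: int | None = None,
               free_shifts: dict[int, float] | None = None) -> ExchangeFitResult:
    """Global two-site exchange fit: shared (kEX, p_bound), local shifts/rates.

    ``profiles`` mixes :class:`CESTProfile` and :class:`CPMGProfile` objects;
    all points are weighted by their per-point errors (estimated from
    baseline scatter when absent).  When ``free_shifts`` supplies a
    residue's free-state 15N shift (known from the assigned free-protein
    spectrum) delta_A is held there and only delta-omega, R1 and R2 are
    fitted for that residue.  Initial delta-omega values come from CEST dip
    detection, falling back to a sign/magnitude multi-start for CPMG-only
    residues (dw sign degeneracy).  Parameter errors are taken from the
    Jacobian covariance at the optimum.
    """
    cest, cpmg = _collect(profiles)
    if residue_subset is not None:
        subset = set(residue_subset)
        cest = [p for p in cest if p.residue in subset]
        cpmg = [p for p in cpmg if p.residue in subset]
    residues = sorted({p.residue for p in cest} | {p.residue for p in cpmg})
    if len(residues) < 2:
        raise ValueError("need >= 2 residues for a global exchange fit")
    layout = _ParamLayout(residues, free_shifts)
    fun = _residuals_factory(cest, cpmg, layout)
    sparsity = _jac_sparsity(cest, cpmg, layout)
    bounds = _bounds(layout, cest)
    x0 = _initial_guess(cest, cpmg, layout, init)

    # CPMG-only residues have a dw sign/magnitude degeneracy: multi-start.
    # CEST residues are anchored by their dip positions even when no minor
    # dip is detectable, so a single start suffices there.
    need_scan = [r for r in residues if not any(p.residue == r for p in cest)]
    if need_scan and not (init and "dw" in init):
        best = None
        for dw0 in DW_MULTISTART_PPM:
            x_try = x0.copy()
            for r in need_scan:
                x_try[layout.index[r] + 1] = dw0
            sol = _run_lsq(fun, x_try, bounds, sparsity, layout)
            if best is None or sol.cost < best.cost:
                best = sol
        sol = best
    else:
        sol = _run_lsq(fun, x0, bounds, sparsity, layout)

    if sol.status < 0 or (sol.status == 0 and not np.isfinite(sol.cost)):
        raise RuntimeError(f"global exchange fit did not converge: {sol.message}")

    chi2 = float(2.0 * sol.cost)
    m = sol.fun.size
    errs = _covariance(sol.jac, sol.cost, m, layout.n)

    # unidentifiable when no residue carries exchange information
    dws = np.array([sol.x[layout.dw_index(r)] for r in residues])
    dwe = np.array([errs[layout.dw_index(r)] for r in residues])
    if np.all((np.abs(dws) < 0.05) | (np.abs(dws) < 2.0 * dwe)):
        raise ValueError(
            "fit unidentifiable: no residue shows a significant delta-omega")

    pinned = []
    for name, j in (("kEX", 0), ("p_bound", 1)):
        if math.isclose(sol.x[j], bounds[0][j]) or math.isclose(sol.x[j], bounds[1][j]):
            pinned.append(name)

    dw_map = {}
    for r in residues:
        j = layout.dw_index(r)
        flag = abs(sol.x[j]) < 2.0 * errs[j]
        dw_map[r] = DwEstimate(r, float(sol.x[j]), float(errs[j]), flagged=flag,
                               note="below sensitivity" if flag else "")
    return ExchangeFitResult(
        kEX=float(sol.x[0]), kEX_error=float(errs[0]),
        p_bound=float(sol.x[1]), p_bound_error=float(errs[1]),
        dw=dw_map, chi2=chi2, n_points=m, n_params=layout.n,
        residuals=sol.fun, boundary_pinned=pinned)


def extract_dw(profiles, fixed_kEX: float, fixed_pbound: float,
               free_shifts: dict[int, float] | None = None) -> dict[int, DwEstimate]:
    """Per-residue delta-omega at fixed global exchange parameters.

    Each residue is fitted independently with (dw, R1_A, R2_A, R2_B) free —
    plus delta_A unless supplied via ``free_shifts`` — while (kEX, p_bound)
    are clamped to the globally determined values.  The sign of dw is
    resolved from the CEST minor-dip position when one is detectable;
    residues whose profile shows no minor dip are returned flagged, with
    the fitted |dw| to be read as an upper bound.
    """
    cest, cpmg = _collect(profiles)
    fixed_da = dict(free_shifts or {})
    residues = sorted({p.residue for p in cest} | {p.residue for p in cpmg})
    out: dict[int, DwEstimate] = {}
    for r in residues:
        my_cest = [p for p in cest if p.residue == r]
        my_cpmg = [p for p in cpmg if p.residue == r]
        cest_err = [_default_errors_cest(p) for p in my_cest]
        cpmg_err = [_default_errors_cpmg(p) for p in my_cpmg]
        fix_da = fixed_da.get(r)

        def fun(x, _cest=my_cest, _cpmg=my_cpmg, _ce=cest_err, _pe=cpmg_err,
                _fix=fix_da):
            if _fix is None:
                da, dw, r1a, r2a, r2b = x
            else:
                da, (dw, r1a, r2a, r2b) = _fix, x
            m = TwoSiteExchangeModel(fixed_kEX, fixed_pbound, da, da + dw,
                                     r1a, R2_A=r2a, R2_B=r2b)
            res = []
            if _cest:
                # one stacked matrix-exponential call across all profiles
                mats = np.concatenate([
                    _bm_matrices(m, p.offsets, p.B1, p.field_1H)
                    for p in _cest])
                ratios = _cest_from_matrices(mats, fixed_pbound,
                                             _cest[0].T_sat)
                start = 0
                for p, e in zip(_cest, _ce):
                    stop = start + p.offsets.size
                    res.append((ratios[start:stop] - p.intensity_ratio) / e)
                    start = stop
            for p, e in zip(_cpmg, _pe):
                sim = simulate_cpmg(m, p.nu_cpmg, p.field_1H).r2_eff
                res.append((sim - p.r2_eff) / e)
            return np.concatenate(res)

        da0, dw0, has_dip = fix_da or 0.0, None, False
        if my_cest:
            major, minor = detect_cest_dips(my_cest[0])
            if fix_da is None:
                da0 = major
            if minor is not None:
                dw0, has_dip = minor - da0, True
        r2a0 = float(np.min(my_cpmg[0].r2_eff)) if my_cpmg else 5.0
        lo = np.array([-12.0, 0.05, 0.2, 20.0])
        hi = np.array([12.0, 10.0, 150.0, 2000.0])
        if fix_da is None:
            lo, hi = np.r_[da0 - 3.0, lo], np.r_[da0 + 3.0, hi]
        if has_dip:
            starts = [dw0]
        else:
            # coarse sign/magnitude scan, then refine from the two best
            grid_cost = []
            for s in DW_MULTISTART_PPM:
                x_try = np.array([s, 1.5, r2a0, 69.0])
                if fix_da is None:
                    x_try = np.r_[da0, x_try]
                resid = fun(np.clip(x_try, lo, hi))
                grid_cost.append((float(resid @ resid), s))
            grid_cost.sort()
            starts = [s for _, s in grid_cost[:2]]
        best = None
        for s in starts:
            x0 = np.array([s, 1.5, r2a0, 69.0])
            if fix_da is None:
                x0 = np.r_[da0, x0]
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(fun, x0, bounds=(lo, hi),
                                ftol=1e-8, xtol=1e-8, max_nfev=100)
            if best is None or sol.cost < best.cost:
                best = sol
        errs = _covariance(best.jac, best.cost, best.fun.size, best.x.size)
        k = 1 if fix_da is None else 0
        dw_fit, dw_err = float(best.x[k]), float(errs[k])
        if not has_dip and my_cest:
            bound = max(abs(dw_fit), 2.0 * dw_err)
            out[r] = DwEstimate(r, dw_fit, dw_err, flagged=True,
                                note=f"no minor dip; |dw| <~ {bound:.2f} ppm")
        else:
            out[r] = DwEstimate(r, dw_fit, dw_err)
    return out
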