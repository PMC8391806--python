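"""Synthetic data generation for every pipeline input.

A :class:`SyntheticScenario` bundles the ground truth of one IDP:kinase
complex — global exchange parameters, per-residue chemical shifts and
shift differences, binding thermodynamics and the acquisition scheme — and
the generators emulate the corresponding measurements: CEST profiles and
CPMG dispersions from the two-site forward models, mono-exponential
relaxation decays, slow-exchange HSQC titration intensities, ITC
thermograms and chemical-shift tables.  All noise is Gaussian and
homoscedastic per table, drawn from per-table substreams of a single
scenario seed, so a fixed seed reproduces every table bitwise.

Two presets mirror the study conditions of the MKK4 regulatory domain
binding its two MAPK partners: a JNK1-like slow-exchange complex
(kEX = 99 s^-1, p_bound = 8.7%, K_D = 1.3 uM) whose docking motif folds
helically upon binding, and a p38alpha-like complex (kEX = 219 s^-1,
p_bound = 6.2%, K_D = 4.1 uM) that binds extended.  The docking-motif
segment (40-48, KRKALKLNF) and the residue types the study names are
real; the remaining sequence positions are synthetic disordered filler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exchange as ex
from . import itc as itc_mod
from .helicity import HELIX_N15_SECONDARY_SHIFT, ShiftTable
from .kinetics import TitrationPoint, complex_concentration
from .relax import R1_DELAYS_S, R1RHO_DELAYS_S, RelaxationSeries

__all__ = [
    "SyntheticScenario",
    "jnk1_scenario",
    "p38a_scenario",
    "gen_cest_dataset",
    "gen_cpmg_dataset",
    "gen_relaxation_decays",
    "gen_titration_intensities",
    "gen_itc_thermogram",
    "gen_shift_table",
    "gen_free_shift_table",
    "DEFAULT_OFFSETS_PPM",
    "DEFAULT_NU_CPMG_HZ",
    "TITRATION_SERIES",
]

#: Approximate random-coil amide 15N shifts per residue type (ppm).  These
#: are synthetic stand-ins for neighbor-corrected predictor output: the
#: pipeline consumes whatever random-coil table it is given, so only their
#: realistic magnitudes matter here.
RANDOM_COIL_N15 = {
    "A": 123.8, "C": 118.8, "D": 120.4, "E": 120.2, "F": 120.3,
    "G": 108.8, "H": 118.2, "I": 119.9, "K": 120.4, "L": 121.8,
    "M": 119.6, "N": 118.7, "P": 135.0, "Q": 119.8, "R": 120.5,
    "S": 115.7, "T": 113.6, "V": 119.2, "W": 121.3, "Y": 120.3,
}

#: Default CEST offset grid (ppm, relative to the 15N carrier at 119 ppm).
#: Asymmetric: the amide region extends ~10 ppm upfield (glycines).
DEFAULT_OFFSETS_PPM = tuple(np.round(np.arange(-14.0, 8.01, 0.25), 4))

#: Default CPMG pulsing-frequency grid (Hz).
DEFAULT_NU_CPMG_HZ = (50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 300.0,
                      400.0, 500.0, 650.0, 800.0, 1000.0)

#: HSQC titration series: (labeled conc M, partner conc M, n_scans).
TITRATION_SERIES = (
    (120e-6, 0.0, 8),
    (120e-6, 24e-6, 8),
    (120e-6, 48e-6, 8),
    (68e-6, 46e-6, 16),
    (50e-6, 45e-6, 16),
)

# Documented segment of the regulatory domain: docking motif 40-48
# (KRKALKLNF) with its flanks and the two downstream residues named in the
# dispersion analysis.  Positions not listed here get synthetic filler.
_KNOWN_RESIDUES = {
    38: "Q", 39: "G", 40: "K", 41: "R", 42: "K", 43: "A", 44: "L",
    45: "K", 46: "L", 47: "N", 48: "F", 49: "A", 50: "N", 53: "F", 54: "K",
}
_FILLER = "SEGTDKASEQTPGSDELKSTAGSDE"  # disordered-like composition


def _default_residues(first: int = 12, last: int = 86) -> list[tuple[int, str]]:
    out = []
    for i in range(first, last + 1):
        aa = _KNOWN_RESIDUES.get(i, _FILLER[i % len(_FILLER)])
        out.append((i, aa))
    return out


@dataclass
class SyntheticScenario:
    """Ground truth and acquisition scheme for one synthetic complex."""

    seed: int
    name: str = "complex"
    residues: list[tuple[int, str]] = field(default_factory=_default_residues)
    motif_span: tuple[int, int] = (40, 48)
    kEX: float = 99.0  # s^-1
    pbound: float = 0.087
    dw_profile: dict[int, float] = field(default_factory=dict)  # ppm
    noise_sd: float = 0.01  # fraction of reference intensity
    cest_fields: tuple[float, ...] = (700.0, 850.0)  # MHz
    field_1H: float = 700.0  # MHz, principal field
    B1: float = 21.0  # Hz
    Tsat: float = 0.3  # s
    # (cell conc M, syringe conc M, cell volume L, injection volume L, count)
    itc_scheme: tuple[float, float, float, float, int] = (
        42e-6, 570e-6, 200e-6, 1.5e-6, 26)
    itc_temperature: float = 293.15  # K
    ground_truth: tuple[float, float, float] = (1.3e-6, -9.5, 1.0)  # KD M, dH kcal/mol, N
    # spin parameters of the free/bound states
    r1_free: float = 1.4  # s^-1
    r2_free: float = 5.0  # s^-1
    r2_bound: float = 69.0  # s^-1
    carrier_ppm: float = 119.0  # absolute 15N position of the carrier

    def __post_init__(self):
        if not 0.0 < self.pbound < 1.0:
            raise ValueError("pbound must be in (0, 1)")
        if self.kEX <= 0:
            raise ValueError("kEX must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.itc_scheme[4] < 1:
            raise ValueError("injection count must be >= 1")
        indices = {i for i, _ in self.residues}
        lo, hi = self.motif_span
        if lo > hi or lo not in indices or hi not in indices:
            raise ValueError("motif_span must lie within the residue range")
        bad = set(self.dw_profile) - indices
        if bad:
            raise ValueError(f"dw_profile references unknown residues: {sorted(bad)}")

    # -- derived per-residue tables -------------------------------------

    @property
    def aa(self) -> dict[int, str]:
        return dict(self.residues)

    def free_shifts_abs(self) -> dict[int, float]:
        """Absolute free-state 15N shifts: random-coil value + small
        deterministic jitter (the synthetic stand-in for real dispersion)."""
        rng = np.random.default_rng([self.seed, 0xF5])
        jitter = rng.uniform(-0.4, 0.4, len(self.residues))
        return {i: RANDOM_COIL_N15[a] + float(j)
                for (i, a), j in zip(self.residues, jitter)}

    def free_shifts_rel(self) -> dict[int, float]:
        """Free-state shifts relative to the 15N carrier (ppm)."""
        return {i: v - self.carrier_ppm for i, v in self.free_shifts_abs().items()}

    def dw(self, residue: int) -> float:
        return self.dw_profile.get(residue, 0.0)

    def model_for(self, residue: int) -> ex.TwoSiteExchangeModel:
        da = self.free_shifts_rel()[residue]
        return ex.TwoSiteExchangeModel(
            kEX=self.kEX, p_bound=self.pbound, delta_A=da,
            delta_B=da + self.dw(residue), R1_A=self.r1_free,
            R2_A=self.r2_free, R2_B=self.r2_bound)

    def contact_weight(self, residue: int) -> float:
        """Titration broadening weight: 1 inside the docking motif,
        exponential decay with sequence distance outside, floor 0.1."""
        lo, hi = self.motif_span
        if lo <= residue <= hi:
            return 1.0
        dist = min(abs(residue - lo), abs(residue - hi))
        return max(math.exp(-dist / 8.0), 0.1)

    def rng(self, stream: int) -> np.random.Generator:
        """Per-table substream of the scenario seed."""
        return np.random.default_rng([self.seed, stream])

    def observable_residues(self) -> list[int]:
        """Residues visible in amide-detected experiments (no prolines)."""
        return [i for i, a in self.residues if a != "P"]


def _helix_dw(aa: str, fraction: float) -> float:
    return fraction * HELIX_N15_SECONDARY_SHIFT[aa]


def jnk1_scenario(seed: int = 0) -> SyntheticScenario:
    """Slow-exchange complex whose motif folds helically upon binding.

    The bound-state shift differences of residues 40-45 are helix
    secondary shifts (90% formed); flanking residues carry environment
    perturbations of either sign, decaying away from the motif.
    """
    sc = SyntheticScenario(seed=seed, name="jnk1", kEX=99.0, pbound=0.087,
                           ground_truth=(1.3e-6, -9.5, 1.0))
    aa = sc.aa
    dw = {}
    for r in range(40, 46):  # helical turn K40-K45
        dw[r] = round(_helix_dw(aa[r], 0.9), 3)
    # binding-environment shifts at the motif flanks: downfield (positive),
    # so they carry no spurious helix signature on the 15N axis
    dw.update({38: 1.9, 39: 2.3, 46: 2.1, 47: 1.8, 48: 2.0, 49: 1.7,
               50: 1.6, 51: 0.8, 52: -0.6, 53: 0.5, 54: 0.4,
               37: 0.6, 35: 0.3})
    sc.dw_profile = dw
    return sc


def p38a_scenario(seed: int = 0) -> SyntheticScenario:
    """Intermediate-exchange complex binding in an extended conformation.

    Shift differences are smaller than in the helical complex and carry no
    helix signature; the residues with the largest dispersion amplitudes
    (41, 45, 49, 53, 54) anchor the CPMG analysis.
    """
    sc = SyntheticScenario(seed=seed, name="p38a", kEX=219.0, pbound=0.062,
                           ground_truth=(4.1e-6, -5.0, 1.0))
    sc.dw_profile = {
        38: 0.6, 39: 0.7, 40: 1.2, 41: 1.8, 42: 1.3, 43: 1.1,
        44: 1.4, 45: 1.7, 46: 1.0, 47: 0.8, 48: 1.2, 49: 1.5,
        50: 0.9, 51: 0.5, 52: -0.4, 53: 1.6, 54: 1.4, 37: 0.3, 35: -0.3,
    }
    return sc


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_cest_dataset(scenario: SyntheticScenario,
                     offsets=DEFAULT_OFFSETS_PPM,
                     residues=None) -> list[ex.CESTProfile]:
    """CEST profiles for every residue at every configured field.

    Forward Bloch-McConnell simulation plus homoscedastic Gaussian noise of
    ``noise_sd`` (fraction of the reference intensity); bitwise
    reproducible for a fixed scenario seed.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must be non-empty")
    picks = scenario.observable_residues() if residues is None else list(residues)
    out = []
    for k, fld in enumerate(scenario.cest_fields):
        rng = scenario.rng(0x10 + k)
        for r in picks:
            spec = ex.CESTProfile(r, fld, scenario.B1, scenario.Tsat, offsets)
            prof = ex.simulate_cest(scenario.model_for(r), spec)
            if scenario.noise_sd > 0:
                prof.intensity_ratio = (prof.intensity_ratio
                                        + rng.normal(0.0, scenario.noise_sd,
                                                     offsets.size))
                prof.error = np.full(offsets.size, scenario.noise_sd)
            out.append(prof)
    return out


def gen_cpmg_dataset(scenario: SyntheticScenario,
                     nu_cpmg=DEFAULT_NU_CPMG_HZ,
                     field_1H: float = 600.0,
                     T_relax: float = 0.04,
                     residues=None) -> list[ex.CPMGProfile]:
    """CPMG dispersions from the Carver-Richards forward model plus noise.

    The R2,eff error follows from propagating the intensity noise through
    R2,eff = -ln(I/I0)/T: sigma_R2 ~ (noise_sd / T) * exp(R2,eff * T).
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if nu.size == 0:
        raise ValueError("nu_cpmg must be non-empty")
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be > 0")
    picks = scenario.observable_residues() if residues is None else list(residues)
    rng = scenario.rng(0x20)
    out = []
    for r in picks:
        prof = ex.simulate_cpmg(scenario.model_for(r), nu, field_1H,
                                residue=r, T_relax=T_relax)
        if scenario.noise_sd > 0:
            sd = scenario.noise_sd / T_relax * np.exp(prof.r2_eff * T_relax)
            prof.r2_eff = prof.r2_eff + rng.normal(0.0, 1.0, nu.size) * sd
            prof.error = sd
        out.append(prof)
    return out


def gen_relaxation_decays(scenario: SyntheticScenario, rate_type: str,
                          delays=None, molar_ratio_bound: float = 0.0,
                          spin_lock_hz: float = 1500.0,
                          residues=None) -> list[RelaxationSeries]:
    """Mono-exponential decay series I(t) = I0 exp(-R t) + noise.

    Duplicate delays (schedule repeats) receive independent noise.  For
    R1rho the underlying rate is R2 sin^2(theta) + R1 cos^2(theta) with a
    small per-residue offset from the carrier and, when a bound fraction
    is given, a population-weighted R2.
    """
    if rate_type not in ("R1", "R1rho"):
        raise ValueError("rate_type must be 'R1' or 'R1rho'")
    if delays is None:
        delays = R1_DELAYS_S if rate_type == "R1" else R1RHO_DELAYS_S
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("negative delay")
    picks = scenario.observable_residues() if residues is None else list(residues)
    rel = scenario.free_shifts_rel()
    rng = scenario.rng(0x30 if rate_type == "R1" else 0x31)
    out = []
    for r in picks:
        if rate_type == "R1":
            rate = scenario.r1_free
        else:
            r2 = ((1.0 - molar_ratio_bound) * scenario.r2_free
                  + molar_ratio_bound * scenario.r2_bound)
            dnu = rel[r] * ex.rad_per_ppm(scenario.field_1H) / (2 * math.pi)
            theta = math.pi / 2 if dnu == 0 else math.atan(abs(spin_lock_hz / dnu))
            rate = (r2 * math.sin(theta) ** 2
                    + scenario.r1_free * math.cos(theta) ** 2)
        i0 = 100.0
        y = i0 * np.exp(-rate * delays)
        if scenario.noise_sd > 0:
            y = y + rng.normal(0.0, scenario.noise_sd * i0, delays.size)
        err = np.full(delays.size, max(scenario.noise_sd, 1e-4) * i0)
        out.append(RelaxationSeries(r, delays, y, err, rate_type))
    return out


def gen_titration_intensities(scenario: SyntheticScenario,
                              molar_ratios=None, KD: float | None = None,
                              series=TITRATION_SERIES) -> list[TitrationPoint]:
    """Slow-exchange HSQC titration: free-peak intensities per point.

    The free-peak intensity ratio is 1 - w_r * [PL]/[P]tot with the
    per-residue contact weight w_r (1 inside the motif, decaying outside).
    Raw intensities are scaled by concentration and scan count so that the
    normalization stage has real work to do.
    """
    kd = scenario.ground_truth[0] if KD is None else KD
    pts = list(series)
    if molar_ratios is not None:
        for ratio in molar_ratios:
            if not 0.0 <= ratio <= 1.0:
                raise ValueError("molar ratios must be in [0, 1]")
        base = series[0]
        pts = [(base[0], ratio * base[0], base[2]) for ratio in molar_ratios]
    rng = scenario.rng(0x40)
    out = []
    for conc_p, conc_l, scans in pts:
        pl = complex_concentration(conc_p, conc_l, kd)
        fb = pl / conc_p if conc_p else 0.0
        intens = {}
        for r in scenario.observable_residues():  # prolines: missing, not 0
            ratio = max(1.0 - scenario.contact_weight(r) * fb, 0.0)
            raw = ratio * conc_p * scans  # signal scales with conc and scans
            if scenario.noise_sd > 0:
                raw += rng.normal(0.0, scenario.noise_sd * conc_p * scans)
            intens[r] = raw
        out.append(TitrationPoint(conc_p, conc_l, scans, intens))
    return out


def gen_itc_thermogram(scenario: SyntheticScenario) -> itc_mod.ITCExperiment:
    """ITC injection heats from the 1:1 isotherm forward model plus noise.

    Noise is ``noise_sd`` of the largest injection heat, homoscedastic
    across injections.
    """
    cell, syringe, v0, dv, n = scenario.itc_scheme
    if cell <= 0:
        raise ValueError("cell concentration must be > 0")
    geom = itc_mod.ITCExperiment(cell, syringe, v0, np.full(n, dv),
                                 temperature=scenario.itc_temperature)
    exp = itc_mod.simulate_isotherm(scenario.ground_truth, geom)
    if scenario.noise_sd > 0:
        rng = scenario.rng(0x50)
        scale = scenario.noise_sd * float(np.max(np.abs(exp.heats)))
        exp.heats = exp.heats + rng.normal(0.0, scale, n)
    return exp


def gen_shift_table(scenario: SyntheticScenario,
                    helical_span: tuple[int, int] | None = None,
                    helicity: float = 0.0) -> ShiftTable:
    """Observed-shift table with the random-coil and helix references.

    delta_obs = delta_rc + helicity * (delta_helix - delta_rc) inside the
    helical span, delta_rc outside.  No noise: chemical shifts are measured
    to far higher precision than intensities.
    """
    if not 0.0 <= helicity <= 1.0:
        raise ValueError("helicity must be in [0, 1]")
    indices = {i for i, _ in scenario.residues}
    if helical_span is not None:
        lo, hi = helical_span
        if lo > hi or lo not in indices or hi not in indices:
            raise ValueError("helical span outside the residue range")
    rows = []
    for i, a in scenario.residues:
        rc = RANDOM_COIL_N15[a]
        helix = rc + HELIX_N15_SECONDARY_SHIFT[a]
        obs = rc
        if helical_span is not None and helical_span[0] <= i <= helical_span[1]:
            obs = rc + helicity * (helix - rc)
        rows.append((i, a, obs, rc, helix))
    df = pd.DataFrame(rows, columns=["residue", "aa", "delta_obs",
                                     "delta_rc", "delta_helix"])
    return ShiftTable(df)


def gen_free_shift_table(scenario: SyntheticScenario) -> ShiftTable:
    """Free-state observed shifts (coil plus the scenario's jitter)."""
    abs_shifts = scenario.free_shifts_abs()
    rows = []
    for i, a in scenario.residues:
        rc = RANDOM_COIL_N15[a]
        rows.append((i, a, abs_shifts[i], rc, rc + HELIX_N15_SECONDARY_SHIFT[a]))
    df = pd.DataFrame(rows, columns=["residue", "aa", "delta_obs",
                                     "delta_rc", "delta_helix"])
    return ShiftTable(df)
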