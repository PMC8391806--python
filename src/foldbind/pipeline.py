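"""End-to-end orchestration: config, staged execution, comparison report.

A pipeline run processes one or two complexes (e.g. the same IDP bound to
two homologous kinases).  Per complex the stages are: titration
normalization -> relaxation fitting and offset correction -> global
two-site exchange fit on an informative residue subset -> fixed-parameter
delta-omega extraction -> kinetic dissection (koff, and kon when ITC data
exist) -> ITC fit and thermodynamic dissection -> helicity profiling of
the free and bound states.  The combined report compares the complexes:
enthalpy difference (with its hydrogen-bond equivalent), affinity ratio,
off/on-rates and helicity summaries.

Configuration is a TOML file; inputs are either paths to delimited-text
tables or, when absent, simulated from a named synthetic scenario preset.
Every run is deterministic for a fixed seed, and the report embeds the
config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from . import synthetic as syn
from .exchange import ExchangeFitResult, extract_dw, fit_global
from .helicity import HelicityProfile, ShiftTable, bound_shifts, helical_propensity
from .itc import ThermoResult, fit_isotherm, hbond_equivalent
from .kinetics import KineticRates, derive_koff, derive_kon, normalize_titration
from .relax import (GAMMA_RATIO_N_H, OffsetGeometry, TumblingModel, fit_decay,
                    offset_correct, predict_rigid_r2, scale_tauc,
                    viscosity_water_glycerol)

__all__ = ["PipelineConfig", "ComplexResult", "ComparisonReport",
           "run_pipeline", "load_config", "DEFAULT_FIT_SUBSETS"]

logger = logging.getLogger("foldbind")

#: Residue subsets with the clearest exchange signatures, per preset.
DEFAULT_FIT_SUBSETS = {
    "jnk1": (38, 39, 42, 43, 44, 45, 46, 47, 49, 50),
    "p38a": (41, 45, 49, 53, 54),
}

#: Residue window simulated/analyzed for exchange by default (the
#: docking-motif region and flanks; far residues carry no exchange signal).
DEFAULT_EXCHANGE_WINDOW = (33, 57)


@dataclass
class ComplexConfig:
    name: str
    preset: str = "jnk1"
    seed: int = 0
    fit_subset: tuple[int, ...] = ()
    use_cpmg: bool = False
    exchange_window: tuple[int, int] = DEFAULT_EXCHANGE_WINDOW
    inputs: dict[str, str] = field(default_factory=dict)  # kind -> path
    helical_reference_span: tuple[int, int] | None = None

    def scenario(self) -> syn.SyntheticScenario:
        maker = {"jnk1": syn.jnk1_scenario, "p38a": syn.p38a_scenario}
        if self.preset not in maker:
            raise ValueError(f"unknown scenario preset {self.preset!r}")
        return maker[self.preset](seed=self.seed)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("foldbind_out")
    complexes: list[ComplexConfig] = field(default_factory=list)
    n_mc: int = 100  # Monte-Carlo refits for relaxation errors
    # rigid-rotor / tumbling constants
    tau_c_ref_ns: float = 21.8
    tau_c_ref_T: float = 298.15
    glycerol_vv: float = 0.05
    temperature: float = 278.15
    field_1H: float = 600.0
    r_NH: float = 1.02
    csa: float = -170.0
    config_hash: str = "unconfigured"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)


def load_config(path) -> PipelineConfig:
    """Parse a TOML pipeline configuration."""
    text = Path(path).read_bytes()
    data = tomllib.loads(text.decode())
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        out_dir=Path(data.get("out_dir", "foldbind_out")),
        n_mc=int(data.get("fit", {}).get("n_mc", 100)),
        config_hash=hashlib.sha256(text).hexdigest()[:16],
    )
    const = data.get("constants", {})
    for key in ("tau_c_ref_ns", "tau_c_ref_T", "glycerol_vv", "temperature",
                "field_1H", "r_NH", "csa"):
        if key in const:
            setattr(cfg, key, float(const[key]))
    for name, sec in data.get("complexes", {}).items():
        preset = sec.get("preset", name)
        subset = tuple(sec.get("fit_subset",
                               DEFAULT_FIT_SUBSETS.get(preset, ())))
        window = tuple(sec.get("exchange_window", DEFAULT_EXCHANGE_WINDOW))
        inputs = {k: sec[k] for k in
                  ("cest", "cpmg", "itc", "shifts", "titration",
                   "r1_decays", "r1rho_decays") if k in sec}
        cc = ComplexConfig(name=name, preset=preset,
                           seed=int(sec.get("seed", cfg.seed)),
                           fit_subset=subset,
                           use_cpmg=bool(sec.get("use_cpmg", preset == "p38a")),
                           exchange_window=window, inputs=inputs)
        if "helical_reference_span" in sec:
            cc.helical_reference_span = tuple(sec["helical_reference_span"])
        cfg.complexes.append(cc)
    if not cfg.complexes:
        cfg.complexes = [
            ComplexConfig("jnk1", "jnk1", cfg.seed,
                          DEFAULT_FIT_SUBSETS["jnk1"]),
            ComplexConfig("p38a", "p38a", cfg.seed,
                          DEFAULT_FIT_SUBSETS["p38a"], use_cpmg=True),
        ]
    return cfg


def default_config(seed: int = 0, out_dir="foldbind_out") -> PipelineConfig:
    """Two-complex default: helical slow-exchange vs extended intermediate."""
    cfg = PipelineConfig(seed=seed, out_dir=Path(out_dir))
    cfg.complexes = [
        ComplexConfig("jnk1", "jnk1", seed, DEFAULT_FIT_SUBSETS["jnk1"]),
        ComplexConfig("p38a", "p38a", seed, DEFAULT_FIT_SUBSETS["p38a"],
                      use_cpmg=True),
    ]
    cfg.config_hash = hashlib.sha256(f"default:{seed}".encode()).hexdigest()[:16]
    return cfg


@dataclass
class ComplexResult:
    name: str
    exchange: ExchangeFitResult
    kinetics: KineticRates
    thermo: ThermoResult | None
    helicity_free: HelicityProfile
    helicity_bound: HelicityProfile
    titration: pd.DataFrame
    r2_rates: list
    dw_all: dict


@dataclass
class ComparisonReport:
    seed: int
    config_hash: str
    version: str
    complexes: list[ComplexResult]
    ddH: float | None = None  # kcal/mol
    affinity_ratio: float | None = None
    hbond_range: tuple[int, int] | None = None

    def text(self) -> str:
        lines = [
            "two-complex folding-upon-binding comparison",
            f"package version : {self.version}",
            f"seed            : {self.seed}",
            f"config hash     : {self.config_hash}",
            "",
        ]
        for c in self.complexes:
            k = c.kinetics
            lines.append(f"[{c.name}]")
            lines.append(f"  kEX      = {c.exchange.kEX:.1f} +- "
                         f"{c.exchange.kEX_error:.1f} s-1")
            lines.append(f"  p_bound  = {100 * c.exchange.p_bound:.2f} +- "
                         f"{100 * c.exchange.p_bound_error:.2f} %")
            lines.append(f"  k_off    = {k.k_off:.0f} s-1")
            if k.k_on is not None:
                lines.append(f"  k_on     = {k.k_on:.3g} M-1s-1")
            else:
                lines.append("  k_on     = unavailable (no ITC input)")
            if c.thermo is not None:
                t = c.thermo
                lines.append(f"  K_D      = {t.K_D * 1e6:.2f} uM (N = {t.N:.2f})")
                lines.append(f"  dG       = {t.dG:.2f} kcal/mol")
                lines.append(f"  dH       = {t.dH:.2f} kcal/mol")
                lines.append(f"  -TdS     = {t.minusTdS:.2f} kcal/mol "
                             f"({'favorable' if t.minusTdS < 0 else 'unfavorable'})")
            smoothed = c.helicity_bound.data["propensity_smoothed"]
            resids = c.helicity_bound.data["residue"]
            helical = resids[smoothed > 0.5].tolist()
            lines.append(f"  bound-state helicity > 0.5 at residues: "
                         f"{helical if helical else 'none'}")
            lines.append("")
        if self.ddH is not None:
            lines.append(f"ddH             = {self.ddH:.1f} kcal/mol")
            if self.hbond_range is not None:
                lines.append(f"H-bond equiv.   = {self.hbond_range[0]}-"
                             f"{self.hbond_range[1]} bonds")
        if self.affinity_ratio is not None:
            lines.append(f"affinity ratio  = {self.affinity_ratio:.1f}")
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    """An error in a named pipeline stage, with the offending context."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}': {detail}")
        self.stage = stage


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as err:
        logger.error("stage=%s error=%s", name, err)
        raise StageError(name, str(err)) from err
    logger.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
    return out


def _gather_inputs(cc: ComplexConfig, out_dir: Path):
    """Load input tables where paths are configured, simulate the rest."""
    sc = cc.scenario()
    lo, hi = cc.exchange_window
    window = [i for i, _ in sc.residues if lo <= i <= hi]
    sim_dir = out_dir / cc.name / "inputs"

    def load_or(kind, simulate, reader, writer):
        if kind in cc.inputs:
            return reader(cc.inputs[kind])
        obj = simulate()
        writer(sim_dir / f"{kind}.csv", obj)
        return obj

    cest = load_or("cest", lambda: syn.gen_cest_dataset(sc, residues=window),
                   fio.read_cest, fio.write_cest)
    cpmg = None
    if cc.use_cpmg:
        cpmg = load_or("cpmg", lambda: syn.gen_cpmg_dataset(sc, residues=window),
                       fio.read_cpmg, fio.write_cpmg)
    titr = load_or("titration", lambda: syn.gen_titration_intensities(sc),
                   fio.read_titration, fio.write_titration)
    r1 = load_or("r1_decays", lambda: syn.gen_relaxation_decays(sc, "R1"),
                 fio.read_decays, fio.write_decays)
    r1rho = load_or("r1rho_decays",
                    lambda: syn.gen_relaxation_decays(
                        sc, "R1rho", molar_ratio_bound=0.0),
                    fio.read_decays, fio.write_decays)
    # `itc = false` in the config disables the stage (graceful degradation)
    if cc.inputs.get("itc", True) is False:
        itc = None
    else:
        itc = load_or("itc", lambda: syn.gen_itc_thermogram(sc),
                      fio.read_itc, fio.write_itc)
    shifts = load_or("shifts", lambda: syn.gen_free_shift_table(sc),
                     fio.read_shifts, fio.write_shifts)
    return sc, cest, cpmg, titr, r1, r1rho, itc, shifts


def run_complex(cc: ComplexConfig, cfg: PipelineConfig) -> ComplexResult:
    out_dir = cfg.out_dir
    sc, cest, cpmg, titr, r1_series, r1rho_series, itc_exp, shifts = _stage(
        f"{cc.name}/inputs", _gather_inputs, cc, out_dir)
    cdir = out_dir / cc.name
    free_abs = dict(zip(shifts.data["residue"], shifts.data["delta_obs"]))
    carrier = sc.carrier_ppm
    free_rel = {r: v - carrier for r, v in free_abs.items()}

    # 1. titration normalization
    reference = min(titr, key=lambda p: p.conc_partner)
    titr_table = _stage(f"{cc.name}/titration", normalize_titration,
                        titr, reference)
    titr_table.to_csv(cdir / "titration_normalized.csv")

    # 2. relaxation: decay fits, offset correction to R2
    def fit_rates():
        rng = np.random.default_rng([cfg.seed, 0x7E])
        r1_fit = {s.residue: fit_decay(s, n_mc=cfg.n_mc,
                                       seed=int(rng.integers(2**31)))
                  for s in r1_series}
        r2 = []
        for s in r1rho_series:
            r1rho = fit_decay(s, n_mc=cfg.n_mc, seed=int(rng.integers(2**31)))
            if not r1rho.converged or s.residue not in r1_fit:
                continue
            # residue offset from the 15N carrier in Hz at the 1H field
            dnu_hz = free_rel.get(s.residue, 0.0) * sc.field_1H * GAMMA_RATIO_N_H
            geom = OffsetGeometry(omega1=1500.0, delta_omega=dnu_hz)
            r2.append(offset_correct(r1rho, r1_fit[s.residue], geom))
        return r2

    r2_rates = _stage(f"{cc.name}/relaxation", fit_rates)
    fio.write_rates(cdir / "r2_rates.csv", r2_rates)

    # 3. global exchange fit on the informative subset
    subset = cc.fit_subset or None
    profiles = list(cest) + list(cpmg or [])
    exch = _stage(f"{cc.name}/exchange-fit", fit_global, profiles,
                  residue_subset=subset, free_shifts=free_rel)

    # 4. per-residue delta-omega at fixed (kEX, p_bound)
    dw_all = _stage(f"{cc.name}/extract-dw", extract_dw, profiles,
                    exch.kEX, exch.p_bound, free_shifts=free_rel)
    fio.write_dw(cdir / "dw.csv", dw_all,
                 {"kEX_s-1": exch.kEX, "p_bound": exch.p_bound})

    # 5. kinetics
    koff, koff_err = derive_koff(exch.kEX, exch.p_bound,
                                 exch.kEX_error, exch.p_bound_error)
    thermo = None
    kon = kon_err = kd = None
    if itc_exp is not None and itc_exp.heats is not None:
        thermo = _stage(f"{cc.name}/itc", fit_isotherm, itc_exp)
        kd = thermo.K_D
        kon, kon_err = derive_kon(koff, kd, koff_err, thermo.K_D_error)
    kinetics = KineticRates(k_off=koff, k_on=kon, K_D=kd, kEX=exch.kEX,
                            p_bound=exch.p_bound, k_off_error=koff_err,
                            k_on_error=kon_err or 0.0)

    # 6. helicity: free state and bound state (free shifts + extracted dw)
    hel_free = _stage(f"{cc.name}/helicity-free", helical_propensity,
                      shifts, state="free")
    dw_map = {r: d.dw for r, d in dw_all.items()}
    full_dw = {r: dw_map.get(r, 0.0) for r in free_abs}
    bshifts = bound_shifts(free_abs, full_dw)
    btable = shifts.data.copy()
    btable["delta_obs"] = btable["residue"].map(bshifts)
    hel_bound = _stage(f"{cc.name}/helicity-bound", helical_propensity,
                       ShiftTable(btable), state=f"bound-{cc.name}")
    hel_free.data.assign(state="free").to_csv(cdir / "helicity_free.csv",
                                              index=False)
    hel_bound.data.assign(state=hel_bound.state).to_csv(
        cdir / "helicity_bound.csv", index=False)

    return ComplexResult(cc.name, exch, kinetics, thermo, hel_free,
                         hel_bound, titr_table, r2_rates, dw_all)


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    """Execute all stages for every configured complex and compare."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        results = [run_complex(cc, config) for cc in config.complexes]
        report = ComparisonReport(config.seed, config.config_hash,
                                  __version__, results)
        thermos = [r.thermo for r in results if r.thermo is not None]
        if len(thermos) == 2:
            report.ddH = abs(thermos[0].dH - thermos[1].dH)
            report.hbond_range = hbond_equivalent(report.ddH)
            report.affinity_ratio = max(thermos[0].K_D, thermos[1].K_D) / \
                min(thermos[0].K_D, thermos[1].K_D)
        (config.out_dir / "report.txt").write_text(report.text())
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def rigid_r2_prediction(cfg: PipelineConfig) -> tuple[float, float]:
    """(tau_c scaled to the experimental conditions, predicted rigid R2).

    Stokes-Einstein scaling of the reference correlation time to the
    experimental temperature and glycerol content, then the dipolar+CSA
    rigid-rotor R2 at the configured field.
    """
    eta_ref = viscosity_water_glycerol(cfg.tau_c_ref_T, 0.0)
    eta = viscosity_water_glycerol(cfg.temperature, cfg.glycerol_vv)
    tau_c = scale_tauc(cfg.tau_c_ref_ns, cfg.tau_c_ref_T, eta_ref,
                       cfg.temperature, eta)
    r2 = predict_rigid_r2(TumblingModel(
        tau_c=tau_c, field_1H=cfg.field_1H, temperature=cfg.temperature,
        viscosity=eta, glycerol_vv=cfg.glycerol_vv, r_NH=cfg.r_NH,
        csa=cfg.csa))
    return tau_c, r2
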