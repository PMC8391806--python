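"""Delimited-text table formats and input validation.

Every table is comma-separated with an optional leading metadata block of
``# key = value`` lines.  The formats:

cest       residue, offset_ppm, intensity_ratio, error
           meta: field_1H_MHz, B1_Hz, Tsat_s
cpmg       residue, nu_cpmg_Hz, r2eff_s-1, error
           meta: field_1H_MHz, T_relax_s
decays     residue, delay_s, intensity, intensity_error
           meta: rate_type
rates      residue, rate_s-1, error_s-1, type
titration  conc_labeled_M, conc_partner_M, n_scans, residue, intensity
itc        injection_volume_L, heat_kcal
           meta: cell_conc_M, syringe_conc_M, cell_volume_L, temperature_K
shifts     residue, aa, delta_obs_ppm, delta_rc_ppm, delta_helix_ppm
dw         residue, dw_ppm, error_ppm, flagged, note
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import CESTProfile, CPMGProfile, DwEstimate
from .helicity import ShiftTable
from .itc import ITCExperiment
from .kinetics import TitrationPoint
from .relax import RateEstimate, RelaxationSeries

__all__ = [
    "read_table", "write_table",
    "write_cest", "read_cest",
    "write_cpmg", "read_cpmg",
    "write_decays", "read_decays",
    "write_rates", "read_rates",
    "write_titration", "read_titration",
    "write_itc", "read_itc",
    "write_shifts", "read_shifts",
    "write_dw", "read_dw",
    "validate_inputs",
]


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a CSV with a '#'-prefixed ``key = value`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v!r}\n" if isinstance(v, str) else f"# {k} = {v}\n")
        # %.17g: lossless (bit-exact) float round-trip
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    meta: dict = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    v = v.strip()
                    if v.startswith("'") and v.endswith("'"):
                        meta[k.strip()] = v[1:-1]
                    else:
                        try:
                            meta[k.strip()] = int(v)
                        except ValueError:
                            try:
                                meta[k.strip()] = float(v)
                            except ValueError:
                                meta[k.strip()] = v
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)),
                     float_precision="round_trip")
    return df, meta


# -- per-format wrappers ----------------------------------------------------

def write_cest(path, profiles: list[CESTProfile]) -> None:
    p0 = profiles[0]
    rows = []
    for p in profiles:
        err = p.error if p.error is not None else np.full(p.offsets.size, np.nan)
        for o, y, e in zip(p.offsets, p.intensity_ratio, err):
            rows.append((p.residue, p.field_1H, o, y, e))
    df = pd.DataFrame(rows, columns=["residue", "field_1H_MHz", "offset_ppm",
                                     "intensity_ratio", "error"])
    write_table(path, df, {"B1_Hz": p0.B1, "Tsat_s": p0.T_sat})


def read_cest(path) -> list[CESTProfile]:
    df, meta = read_table(path)
    out = []
    for (res, fld), grp in df.groupby(["residue", "field_1H_MHz"], sort=True):
        err = grp["error"].to_numpy()
        out.append(CESTProfile(
            int(res), float(fld), float(meta["B1_Hz"]), float(meta["Tsat_s"]),
            grp["offset_ppm"].to_numpy(), grp["intensity_ratio"].to_numpy(),
            None if np.isnan(err).all() else err))
    return out


def write_cpmg(path, profiles: list[CPMGProfile]) -> None:
    p0 = profiles[0]
    rows = []
    for p in profiles:
        err = p.error if p.error is not None else np.full(p.nu_cpmg.size, np.nan)
        for v, y, e in zip(p.nu_cpmg, p.r2_eff, err):
            rows.append((p.residue, v, y, e))
    df = pd.DataFrame(rows, columns=["residue", "nu_cpmg_Hz", "r2eff_s-1", "error"])
    write_table(path, df, {"field_1H_MHz": p0.field_1H, "T_relax_s": p0.T_relax})


def read_cpmg(path) -> list[CPMGProfile]:
    df, meta = read_table(path)
    out = []
    for res, grp in df.groupby("residue", sort=True):
        err = grp["error"].to_numpy()
        out.append(CPMGProfile(
            int(res), float(meta["field_1H_MHz"]), grp["nu_cpmg_Hz"].to_numpy(),
            grp["r2eff_s-1"].to_numpy(),
            None if np.isnan(err).all() else err,
            T_relax=float(meta.get("T_relax_s", 0.04))))
    return out


def write_decays(path, series: list[RelaxationSeries]) -> None:
    rows = []
    for s in series:
        err = (s.intensity_errors if s.intensity_errors is not None
               else np.full(s.delays.size, np.nan))
        for t, y, e in zip(s.delays, s.intensities, err):
            rows.append((s.residue, t, y, e))
    df = pd.DataFrame(rows, columns=["residue", "delay_s", "intensity",
                                     "intensity_error"])
    write_table(path, df, {"rate_type": series[0].rate_type})


def read_decays(path) -> list[RelaxationSeries]:
    df, meta = read_table(path)
    out = []
    for res, grp in df.groupby("residue", sort=True):
        err = grp["intensity_error"].to_numpy()
        out.append(RelaxationSeries(
            int(res), grp["delay_s"].to_numpy(), grp["intensity"].to_numpy(),
            None if np.isnan(err).all() else err,
            rate_type=str(meta["rate_type"])))
    return out


def write_rates(path, rates: list[RateEstimate]) -> None:
    df = pd.DataFrame(
        [(r.residue, r.rate, r.rate_error, r.rate_type) for r in rates],
        columns=["residue", "rate_s-1", "error_s-1", "type"])
    write_table(path, df)


def read_rates(path) -> list[RateEstimate]:
    df, _ = read_table(path)
    return [RateEstimate(int(r.residue), float(r["rate_s-1"]),
                         float(r["error_s-1"]), str(r["type"]))
            for _, r in df.iterrows()]


def write_titration(path, points: list[TitrationPoint]) -> None:
    rows = []
    for pt in points:
        for res, i in sorted(pt.intensities.items()):
            rows.append((pt.conc_labeled, pt.conc_partner, pt.n_scans, res, i))
    df = pd.DataFrame(rows, columns=["conc_labeled_M", "conc_partner_M",
                                     "n_scans", "residue", "intensity"])
    write_table(path, df)


def read_titration(path) -> list[TitrationPoint]:
    df, _ = read_table(path)
    out = []
    keys = ["conc_labeled_M", "conc_partner_M", "n_scans"]
    for (cl, cp, ns), grp in df.groupby(keys, sort=False):
        intens = dict(zip(grp["residue"].astype(int), grp["intensity"]))
        out.append(TitrationPoint(float(cl), float(cp), int(ns), intens))
    out.sort(key=lambda p: p.molar_ratio)
    return out


def write_itc(path, exp: ITCExperiment) -> None:
    heats = exp.heats if exp.heats is not None else np.full(
        exp.injection_volumes.size, np.nan)
    df = pd.DataFrame({"injection_volume_L": exp.injection_volumes,
                       "heat_kcal": heats})
    write_table(path, df, {
        "cell_conc_M": exp.cell_conc, "syringe_conc_M": exp.syringe_conc,
        "cell_volume_L": exp.cell_volume, "temperature_K": exp.temperature})


def read_itc(path) -> ITCExperiment:
    df, meta = read_table(path)
    heats = df["heat_kcal"].to_numpy()
    return ITCExperiment(
        float(meta["cell_conc_M"]), float(meta["syringe_conc_M"]),
        float(meta["cell_volume_L"]), df["injection_volume_L"].to_numpy(),
        None if np.isnan(heats).all() else heats,
        temperature=float(meta.get("temperature_K", 293.15)))


_SHIFT_COLS = {"residue": "residue", "aa": "aa", "delta_obs_ppm": "delta_obs",
               "delta_rc_ppm": "delta_rc", "delta_helix_ppm": "delta_helix"}


def write_shifts(path, table: ShiftTable, meta: dict | None = None) -> None:
    df = table.data.rename(columns={v: k for k, v in _SHIFT_COLS.items()})
    write_table(path, df[list(_SHIFT_COLS)], meta)


def read_shifts(path) -> ShiftTable:
    df, _ = read_table(path)
    return ShiftTable(df.rename(columns=_SHIFT_COLS))


def write_dw(path, dw: dict[int, DwEstimate], meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [(d.residue, d.dw, d.dw_error, d.flagged, d.note) for d in dw.values()],
        columns=["residue", "dw_ppm", "error_ppm", "flagged", "note"])
    write_table(path, df.sort_values("residue"), meta)


def read_dw(path) -> dict[int, DwEstimate]:
    df, _ = read_table(path)
    df["note"] = df["note"].fillna("")
    return {int(r.residue): DwEstimate(int(r.residue), float(r.dw_ppm),
                                       float(r.error_ppm), bool(r.flagged),
                                       str(r.note))
            for _, r in df.iterrows()}


# -- validation -------------------------------------------------------------

_SCHEMAS = {
    "cest": ["residue", "field_1H_MHz", "offset_ppm", "intensity_ratio"],
    "cpmg": ["residue", "nu_cpmg_Hz", "r2eff_s-1"],
    "decays": ["residue", "delay_s", "intensity"],
    "rates": ["residue", "rate_s-1", "error_s-1", "type"],
    "titration": ["conc_labeled_M", "conc_partner_M", "n_scans", "residue",
                  "intensity"],
    "itc": ["injection_volume_L", "heat_kcal"],
    "shifts": ["residue", "aa", "delta_obs_ppm", "delta_rc_ppm"],
    "dw": ["residue", "dw_ppm", "error_ppm"],
}


def _sniff_kind(df: pd.DataFrame) -> str | None:
    for kind, cols in _SCHEMAS.items():
        if set(cols) <= set(df.columns):
            return kind
    return None


def validate_inputs(paths: dict[str, str] | list[str]) -> list[str]:
    """Schema and sanity checks; returns a list of violation strings.

    Checks: file existence, recognized column schema, numeric columns
    parse as numbers (offending rows are reported 1-based, excluding the
    header and metadata lines), ppm offsets within ±60 ppm of the carrier,
    non-negative rates, duplicated residues in shift tables.
    """
    if isinstance(paths, dict):
        items = list(paths.items())
    else:
        items = [(None, p) for p in paths]
    violations: list[str] = []
    for declared, path in items:
        path = Path(path)
        if not path.exists():
            violations.append(f"{path}: file not found")
            continue
        try:
            df, _meta = read_table(path)
        except Exception as err:  # malformed beyond row level
            violations.append(f"{path}: unreadable ({err})")
            continue
        kind = declared or _sniff_kind(df)
        if kind not in _SCHEMAS:
            violations.append(f"{path}: unrecognized table layout "
                              f"(columns: {list(df.columns)})")
            continue
        missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
        if missing:
            violations.append(f"{path}: missing columns {missing}")
            continue
        for col in _SCHEMAS[kind]:
            if col in ("aa", "type", "note"):
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()]
            for i in bad:
                violations.append(
                    f"{path}: non-numeric value {df[col][i]!r} in column "
                    f"'{col}' at data row {i + 1}")
            df[col] = vals
        if kind == "cest" and df["offset_ppm"].abs().max() > 60:
            violations.append(f"{path}: offsets outside a plausible ppm range")
        if kind == "rates" and (df["rate_s-1"] < 0).any():
            violations.append(f"{path}: negative relaxation rate")
        if kind == "cpmg" and (df["nu_cpmg_Hz"] <= 0).any():
            violations.append(f"{path}: non-positive nu_cpmg")
        if kind == "shifts" and df["residue"].duplicated().any():
            dups = sorted(set(df.loc[df["residue"].duplicated(), "residue"]))
            violations.append(f"{path}: duplicated residue indices {dups}")
    return violations
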