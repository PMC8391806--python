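"""Per-residue alpha-helical propensity from amide 15N chemical shifts.

Neighbor-corrected random-coil shifts (an input, e.g. from a random-coil
predictor run at the experimental temperature and pH) and full-helix
reference shifts bracket the observed shift; the raw propensity

    f = (delta_obs - delta_rc) / (delta_helix - delta_rc)

is clipped to [0, 1] and smoothed with a short sliding window.  Bound-state
shifts are built from the free-state shifts plus the exchange-derived
chemical-shift differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ShiftTable",
    "HelicityProfile",
    "HELIX_N15_SECONDARY_SHIFT",
    "helical_propensity",
    "bound_shifts",
]

#: Full-helix 15N secondary shifts (ppm) per residue type: the expected
#: offset delta_helix - delta_rc of a residue inside a fully formed
#: alpha-helix.  Amide 15N moves upfield in helices; values are in the
#: conventional -2.5 to -5.5 ppm range with per-type variation.
HELIX_N15_SECONDARY_SHIFT: dict[str, float] = {
    "A": -3.6, "C": -4.2, "D": -3.6, "E": -4.0, "F": -4.6,
    "G": -3.0, "H": -4.2, "I": -5.4, "K": -4.2, "L": -4.0,
    "M": -4.0, "N": -3.4, "Q": -4.0, "R": -4.2, "S": -3.8,
    "T": -5.0, "V": -5.4, "W": -4.4, "Y": -4.6,
    # proline has no amide 15N H; entry kept for completeness, excluded anyway
    "P": 0.0,
}

#: Residues with |delta_helix - delta_rc| below this (ppm) carry no usable
#: helicity information and are excluded.
MIN_REFERENCE_SEPARATION = 0.2


@dataclass
class ShiftTable:
    """Per-residue observed, random-coil and full-helix 15N shifts (ppm)."""

    data: pd.DataFrame  # columns: residue, aa, delta_obs, delta_rc[, delta_helix]

    REQUIRED = ("residue", "aa", "delta_obs", "delta_rc")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"shift table missing columns: {missing}")
        if self.data["residue"].duplicated().any():
            dup = self.data.loc[self.data["residue"].duplicated(), "residue"]
            raise ValueError(f"duplicated residue indices: {sorted(set(dup))}")
        if "delta_helix" not in self.data.columns:
            offsets = self.data["aa"].map(HELIX_N15_SECONDARY_SHIFT)
            if offsets.isna().any():
                bad = self.data.loc[offsets.isna(), "aa"].unique()
                raise ValueError(f"unknown residue types: {list(bad)}")
            self.data = self.data.assign(
                delta_helix=self.data["delta_rc"] + offsets)


@dataclass
class HelicityProfile:
    """Raw and window-averaged helical propensity along the chain."""

    data: pd.DataFrame  # residue, propensity, propensity_smoothed
    state: str = "free"
    excluded: list[int] = field(default_factory=list)


def helical_propensity(table: ShiftTable, window: int = 3,
                       state: str = "free") -> HelicityProfile:
    """Fractional helicity per residue, clipped to [0, 1] and smoothed.

    The sliding-window mean (default width 3) shrinks to the available
    neighbors at the chain termini rather than padding.  Prolines and
    residues whose helix/coil references are closer than 0.2 ppm are
    excluded (they carry no signal on this axis).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    df = table.data.sort_values("residue").reset_index(drop=True)
    sep = df["delta_helix"] - df["delta_rc"]
    usable = (df["aa"] != "P") & (sep.abs() >= MIN_REFERENCE_SEPARATION)
    excluded = df.loc[~usable, "residue"].tolist()
    df = df[usable].reset_index(drop=True)
    raw = (df["delta_obs"] - df["delta_rc"]) / (df["delta_helix"] - df["delta_rc"])
    raw = raw.clip(0.0, 1.0)
    half = window // 2
    smoothed = raw.rolling(window, center=True, min_periods=half + 1).mean()
    out = pd.DataFrame({
        "residue": df["residue"],
        "propensity": raw,
        "propensity_smoothed": smoothed,
    })
    return HelicityProfile(out, state=state, excluded=excluded)


def bound_shifts(free_shifts: pd.Series | dict[int, float],
                 dw: pd.Series | dict[int, float]) -> pd.Series:
    """Bound-state shifts: delta_bound = delta_free + delta_omega.

    ``delta_omega`` follows the exchange-model sign convention (positive =
    bound state downfield).  Raises when the residue sets differ, listing
    the unmatched residues.
    """
    free = pd.Series(free_shifts, dtype=float)
    dws = pd.Series(dw, dtype=float)
    only_free = sorted(set(free.index) - set(dws.index))
    only_dw = sorted(set(dws.index) - set(free.index))
    if only_free or only_dw:
        raise ValueError(
            "residue mismatch between free shifts and delta-omega: "
            f"missing dw for {only_free}; missing shifts for {only_dw}")
    return free + dws.reindex(free.index)
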