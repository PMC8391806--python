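"""Binding kinetics and titration intensity processing.

Dissects two-site exchange parameters (kEX, p_bound) and an ITC dissociation
constant into off- and on-rates, solves the 1:1 binding mass balance, and
normalizes HSQC peak-intensity titrations for concentration and scan count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticRates",
    "TitrationPoint",
    "derive_koff",
    "derive_kon",
    "complex_concentration",
    "normalize_titration",
]


@dataclass
class KineticRates:
    """Off/on-rate dissection of a two-state binding equilibrium.

    k_off = (1 - p_bound) * kEX for pseudo-first-order two-site binding
    (the escape rate from the bound state), k_on = k_off / K_D.
    """

    k_off: float  # s^-1
    k_on: float | None  # M^-1 s^-1, None when no K_D is available
    K_D: float | None  # M
    kEX: float  # s^-1
    p_bound: float
    k_off_error: float = 0.0
    k_on_error: float = 0.0

    def __post_init__(self):
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")


def derive_koff(kEX: float, p_bound: float, kEX_error: float = 0.0,
                p_bound_error: float = 0.0) -> tuple[float, float]:
    """k_off = (1 - p_bound) * kEX, with first-order error propagation."""
    if not 0.0 < p_bound < 1.0:
        raise ValueError("p_bound must be in (0, 1)")
    if kEX <= 0:
        raise ValueError("kEX must be > 0")
    koff = (1.0 - p_bound) * kEX
    err = math.hypot((1.0 - p_bound) * kEX_error, kEX * p_bound_error)
    return koff, err


def derive_kon(k_off: float, K_D: float, k_off_error: float = 0.0,
               K_D_error: float = 0.0) -> tuple[float, float]:
    """k_on = k_off / K_D, with first-order error propagation."""
    if K_D <= 0:
        raise ValueError("K_D must be > 0")
    if k_off <= 0:
        raise ValueError("k_off must be > 0")
    kon = k_off / K_D
    err = kon * math.hypot(
        k_off_error / k_off if k_off else 0.0,
        K_D_error / K_D if K_D else 0.0)
    return kon, err


def complex_concentration(P_tot: float, L_tot: float, K_D: float) -> float:
    """1:1 complex concentration from the binding quadratic.

    Physical root of [PL]^2 - (P + L + K_D)[PL] + P*L = 0, clamped to
    [0, min(P, L)].  Numerically stable form (no catastrophic cancellation
    for K_D << concentrations).
    """
    if min(P_tot, L_tot, K_D) < 0:
        raise ValueError("concentrations and K_D must be >= 0")
    if P_tot == 0.0 or L_tot == 0.0:
        return 0.0
    b = P_tot + L_tot + K_D
    disc = math.sqrt(b * b - 4.0 * P_tot * L_tot)
    # smaller root via the product form: r1*r2 = P*L, r2 = (b+sqrt)/2
    pl = 2.0 * P_tot * L_tot / (b + disc)
    return min(max(pl, 0.0), min(P_tot, L_tot))


@dataclass
class TitrationPoint:
    """One HSQC titration point: concentrations, scans, raw intensities."""

    conc_labeled: float  # M
    conc_partner: float  # M
    n_scans: int
    intensities: dict[int, float] = field(default_factory=dict)  # residue -> I

    def __post_init__(self):
        if self.conc_labeled < 0 or self.conc_partner < 0:
            raise ValueError("concentrations must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")

    @property
    def molar_ratio(self) -> float:
        return self.conc_partner / self.conc_labeled if self.conc_labeled else 0.0


def normalize_titration(points: list[TitrationPoint],
                        reference: TitrationPoint) -> pd.DataFrame:
    """Per-residue I/I0 table, corrected for concentration and scan count.

    I/I0 = (I / I_ref) * (conc_ref / conc) * (scans_ref / scans).  Residues
    missing at any point (overlap, prolines) carry NaN; residues whose
    reference intensity is zero are flagged NaN rather than propagating an
    infinity.
    """
    if reference.conc_partner != 0.0:
        raise ValueError("reference point must have partner concentration 0")
    residues = sorted(reference.intensities)
    cols = {}
    for pt in points:
        factor = ((reference.conc_labeled / pt.conc_labeled)
                  * (reference.n_scans / pt.n_scans))
        col = []
        for r in residues:
            i_ref = reference.intensities.get(r)
            i = pt.intensities.get(r)
            if i_ref is None or i is None or i_ref == 0.0:
                col.append(np.nan)
            else:
                col.append(i / i_ref * factor)
        cols[round(pt.molar_ratio, 4)] = col
    df = pd.DataFrame(cols, index=pd.Index(residues, name="residue"))
    df.columns.name = "molar_ratio"
    return df
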