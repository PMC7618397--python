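"""Kir4.1 current kinetics: Nernst reversal, current-density law, I-V curves.

The astrocytic inward-rectifier current density is modelled as

    I_Kir = g_Kir * V_f(V1) * [K+]_out^(1/2) * (1 + exp(V_f(V2)/V3))^(-1/2)

with the driving-force terms V_f(V_i) = V_m - A_K * E_K - V_i, where E_K is
the Nernst reversal potential for K+ and A_K is a dimensionless normalization
factor chosen so that the current vanishes at resting conditions
([K+]_out = 2.5 mM, V_m = -80 mV).  Sign convention: inward current is
negative, in uA/cm^2 for g in mS/cm^2 and voltages in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FARADAY",
    "AVOGADRO",
    "ELEMENTARY_CHARGE",
    "KirParams",
    "MembraneState",
    "nernst_potential",
    "kir_current_density",
    "normalization_factor",
    "whole_cell_current",
    "iv_curve",
    "rectification_index",
]

FARADAY = 96485.33212  # C/mol
AVOGADRO = 6.02214076e23  # 1/mol
ELEMENTARY_CHARGE = FARADAY / AVOGADRO  # C


@dataclass(frozen=True)
class KirParams:
    """Constants of the Kir4.1 current law and Nernst computation.

    Defaults are the fitted CA1-astrocyte values: conductance density
    g_kir = 0.175 mS/cm^2, voltage parameters V1 = -14.83, V2 = -105.82,
    V3 = 19.23 mV, normalization A_K = 0.6891, intracellular K+ 110 mM and
    thermal voltage RT/F = 25 mV.  The passive-leak parameters (g_pas,
    e_pas) are carried for completeness; the reduced dynamics here do not
    evolve membrane potential.
    """

    g_kir: float = 0.175  # mS/cm^2
    v1: float = -14.83  # mV
    v2: float = -105.82  # mV
    v3: float = 19.23  # mV
    a_k: float = 0.6891  # dimensionless
    k_in: float = 110.0  # mM
    rt_over_f: float = 25.0  # mV
    faraday: float = FARADAY  # C/mol
    avogadro: float = AVOGADRO  # 1/mol
    g_pas: float = 0.001  # mS/cm^2, recorded, unused by the reduced model
    e_pas: float = -80.0  # mV, recorded, unused

    def __post_init__(self) -> None:
        if self.g_kir < 0:
            raise ValueError(f"g_kir must be >= 0, got {self.g_kir}")
        if self.k_in <= 0:
            raise ValueError(f"k_in must be > 0, got {self.k_in}")
        if self.rt_over_f <= 0:
            raise ValueError(f"rt_over_f must be > 0, got {self.rt_over_f}")

    def with_g_kir(self, g_kir: float) -> "KirParams":
        return replace(self, g_kir=g_kir)


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous membrane potential (mV) and extracellular K+ (mM)."""

    v_m: float
    k_out: float

    def __post_init__(self) -> None:
        if self.k_out <= 0:
            raise ValueError(f"k_out must be > 0, got {self.k_out}")


def nernst_potential(k_out, k_in: float = 110.0, rt_over_f: float = 25.0):
    """Nernst reversal potential E_K = (RT/F) ln([K+]_out/[K+]_in), in mV.

    Strictly increasing in ``k_out``; antisymmetric under exchange of the
    two concentrations.  Accepts scalars or arrays for ``k_out``.
    """
    k_out = np.asarray(k_out, dtype=float)
    if np.any(k_out <= 0) or k_in <= 0:
        raise ValueError("concentrations must be strictly positive")
    e_k = rt_over_f * np.log(k_out / k_in)
    return float(e_k) if e_k.ndim == 0 else e_k


def _current_density(v_m, k_out, params: KirParams):
    """Vectorized current-density kernel (uA/cm^2, inward negative)."""
    e_k = params.rt_over_f * np.log(np.asarray(k_out, dtype=float) / params.k_in)
    shifted = np.asarray(v_m, dtype=float) - params.a_k * e_k
    vf1 = shifted - params.v1
    vf2 = shifted - params.v2
    gate = 1.0 / np.sqrt(1.0 + np.exp(vf2 / params.v3))
    return params.g_kir * vf1 * np.sqrt(k_out) * gate


def kir_current_density(state: MembraneState, params: KirParams = KirParams()) -> float:
    """Kir4.1 current density (uA/cm^2) at the given membrane state.

    Linear in ``g_kir``; zero exactly on the manifold
    V_m = A_K * E_K(k_out) + V1.
    """
    if state.k_out <= 0:
        raise ValueError("k_out must be strictly positive")
    return float(_current_density(state.v_m, state.k_out, params))


def normalization_factor(
    v_rest: float, k_out_rest: float, params: KirParams = KirParams()
) -> float:
    """Unique A_K that zeroes the current at rest: (v_rest - V1)/E_K(rest).

    Raises on E_K = 0 (equal concentrations), where no finite factor exists
    unless v_rest = V1.
    """
    e_k = nernst_potential(k_out_rest, params.k_in, params.rt_over_f)
    if e_k == 0.0:
        if v_rest == params.v1:
            return 0.0
        raise ValueError("reversal potential is zero: normalization degenerate")
    return (v_rest - params.v1) / e_k


def whole_cell_current(
    state: MembraneState, params: KirParams = KirParams(), area: float = 20_000.0
) -> float:
    """Whole-cell Kir current in nA for a membrane ``area`` in um^2.

    uA/cm^2 * (area in cm^2) * 1e3 -> nA; sign preserved (inward negative).
    """
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    area_cm2 = area * 1e-8
    return kir_current_density(state, params) * area_cm2 * 1e3


def iv_curve(
    v_grid: Sequence[float], k_out: float, params: KirParams = KirParams()
) -> pd.DataFrame:
    """Pointwise I-V table with columns ``v_mV`` and ``i_uA_per_cm2``."""
    v = np.asarray(v_grid, dtype=float)
    if v.size == 0:
        raise ValueError("voltage grid must be non-empty")
    if k_out <= 0:
        raise ValueError("k_out must be strictly positive")
    i = _current_density(v, k_out, params)
    return pd.DataFrame({"v_mV": v, "i_uA_per_cm2": np.atleast_1d(i)})


def rectification_index(iv: pd.DataFrame, offset: float = 40.0) -> float:
    """Chord-conductance rectification index of an I-V relation.

    Locates the zero-current voltage V0 by sign change + linear
    interpolation, then returns
    RI = |I(V0 - offset)/(−offset)| / |I(V0 + offset)/offset|,
    the ratio of chord conductances at symmetric offsets.  RI = 1 for ohmic
    data; RI > 1 indicates inward rectification.  Requires the table to
    bracket the zero crossing and to cover both offset voltages.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    v = np.asarray(iv["v_mV"], dtype=float)
    i = np.asarray(iv["i_uA_per_cm2"], dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    sign = np.sign(i)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise ValueError("I-V data do not bracket a zero-current crossing")
    j = crossings[0]
    if i[j] == 0.0:
        v0 = v[j]
    else:
        v0 = v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j])
    lo, hi = v0 - offset, v0 + offset
    if lo < v[0] or hi > v[-1]:
        raise ValueError("offset voltages fall outside the I-V range")
    i_lo = np.interp(lo, v, i)
    i_hi = np.interp(hi, v, i)
    if i_hi == 0.0:
        raise ValueError("outward chord current is zero; RI undefined")
    return abs(i_lo / offset) / abs(i_hi / offset)
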