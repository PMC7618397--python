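"""Well-mixed whole-cell K+ uptake approximation and ion-budget arithmetic.

A CA1 astrocyte is reduced to a single compartment: ~20,000 um^2 of membrane,
~5e3 um^3 of cytosol at 110 mM K+, occupying ~10% of tissue volume while the
extracellular space occupies ~20%, so one territory overlies ~1e4 um^3 of
extracellular lumen.  Local K+ challenges are converted through the Kir4.1
current law into transported charge, ions, and concentration changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .kir_kinetics import (
    AVOGADRO,
    ELEMENTARY_CHARGE,
    FARADAY,
    KirParams,
    MembraneState,
    kir_current_density,
    whole_cell_current,
)

__all__ = [
    "CellGeometry",
    "UptakeEvent",
    "territory_ecs_volume",
    "charge_to_ions",
    "ions_to_concentration",
    "local_uptake_event",
    "ecs_decay_curve",
    "fit_first_order_tau",
]

UM3_TO_L = 1e-15


@dataclass(frozen=True)
class CellGeometry:
    """Whole-cell surface/volume figures and tissue volume fractions."""

    surface_area: float = 20_000.0  # um^2
    cell_volume: float = 5e3  # um^3
    svr_soma: float = 7.0  # um^-1, near the cell body
    svr_periphery: float = 22.0  # um^-1, average in fine processes
    astro_tissue_fraction: float = 0.10
    ecs_tissue_fraction: float = 0.20
    k_in_rest: float = 110.0  # mM

    def __post_init__(self) -> None:
        for name in ("surface_area", "cell_volume", "svr_soma", "svr_periphery", "k_in_rest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("astro_tissue_fraction", "ecs_tissue_fraction"):
            frac = getattr(self, name)
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {frac}")


@dataclass(frozen=True)
class UptakeEvent:
    """A transient local [K+]_out elevation challenging the astrocyte.

    Defaults: [K+]_out raised from 2.5 to 5 mM inside a 10-um-diameter
    sphere for 5 s, membrane clamped at -80 mV.
    """

    sphere_diameter: float = 10.0  # um
    delta_k: float = 2.5  # mM above rest
    duration: float = 5.0  # s
    v_m: float = -80.0  # mV
    k_rest: float = 2.5  # mM

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0 or self.duration < 0:
            raise ValueError("sphere_diameter must be > 0 and duration >= 0")


def territory_ecs_volume(geom: CellGeometry = CellGeometry()) -> float:
    """Extracellular lumen per astrocyte territory, um^3.

    The territory tissue volume is cell_volume / astro_tissue_fraction; the
    ECS share of it is ecs_tissue_fraction, hence
    cell_volume * (ecs_fraction / astro_fraction).  Defaults give 1e4 um^3.
    """
    return geom.cell_volume * geom.ecs_tissue_fraction / geom.astro_tissue_fraction


def charge_to_ions(charge: float) -> float:
    """Number of monovalent ions carrying ``charge`` coulombs."""
    if charge < 0:
        raise ValueError("charge must be non-negative")
    return charge / ELEMENTARY_CHARGE


def ions_to_concentration(n_ions: float, volume: float) -> float:
    """Concentration (mM) of ``n_ions`` ions dissolved in ``volume`` um^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    moles = n_ions / AVOGADRO
    return moles / (volume * UM3_TO_L) * 1e3


def local_uptake_event(
    event: UptakeEvent = UptakeEvent(),
    geom: CellGeometry = CellGeometry(),
    params: KirParams = KirParams(),
) -> float:
    """Peak fractional change of whole-cell [K+]_in (%) from a local event.

    The astrocyte membrane inside the event sphere is svr_periphery times
    the astrocytic share of the sphere volume.  The Kir flux at the elevated
    [K+]_out (constant-flux approximation, V_m held fixed) is integrated
    over the event duration and the transported moles are distributed into
    the whole cell volume.  Linear in duration and in g_kir.
    """
    radius = event.sphere_diameter / 2.0
    sphere_vol = 4.0 / 3.0 * np.pi * radius**3  # um^3
    membrane_um2 = geom.svr_periphery * geom.astro_tissue_fraction * sphere_vol
    density = kir_current_density(
        MembraneState(v_m=event.v_m, k_out=event.k_rest + event.delta_k), params
    )  # uA/cm^2
    current_a = abs(density) * 1e-6 * membrane_um2 * 1e-8  # A
    moles = current_a * event.duration / FARADAY
    delta_mM = moles / (geom.cell_volume * UM3_TO_L) * 1e3
    return 100.0 * delta_mM / geom.k_in_rest


def ecs_decay_curve(
    geom: CellGeometry = CellGeometry(),
    params: KirParams = KirParams(),
    k_start: float = 5.0,
    t_grid=None,
    k_ss: float = 2.5,
    v_m: float = -80.0,
) -> pd.DataFrame:
    """Decay of territory-average [K+]_out under whole-cell Kir uptake.

    Integrates the coupled budget
        d[K+]_out/dt = I(t) / (F * V_ecs)
        d[K+]_in/dt  = -I(t) / (F * V_cell)
    with I the whole-cell Kir current (negative = inward) at fixed V_m over
    ``geom.surface_area``, so every mole leaving the extracellular lumen is
    credited to the cell pool.  Columns: t_s, k_out_mM, k_in_mM.
    """
    if k_start < k_ss:
        raise ValueError("k_start must be >= the steady-state concentration")
    if t_grid is None:
        t_grid = np.linspace(0.0, 120.0, 601)
    t_grid = np.asarray(t_grid, dtype=float)
    v_ecs_l = territory_ecs_volume(geom) * UM3_TO_L
    v_cell_l = geom.cell_volume * UM3_TO_L

    def rhs(_t, y):
        k_out = max(y[0], 1e-9)
        i_na = whole_cell_current(MembraneState(v_m=v_m, k_out=k_out), params, geom.surface_area)
        mol_per_s = i_na * 1e-9 / FARADAY  # negative = efflux from ECS
        return [mol_per_s / v_ecs_l * 1e3, -mol_per_s / v_cell_l * 1e3]

    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        [k_start, geom.k_in_rest],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ECS decay integration failed: {sol.message}")
    return pd.DataFrame({"t_s": sol.t, "k_out_mM": sol.y[0], "k_in_mM": sol.y[1]})


def fit_first_order_tau(t, y=None, k_ss: float | None = None) -> float:
    """Least-squares first-order time constant of a decaying series, in s.

    Fits y(t) = k_ss + A exp(-t/tau) (asymptote fitted unless ``k_ss`` is
    given).  Accepts a DataFrame with columns t_s/k_out_mM or two arrays.
    Raises on non-decaying input.
    """
    if y is None:
        frame = t
        t = np.asarray(frame["t_s"], dtype=float)
        y = np.asarray(frame["k_out_mM"], dtype=float)
    else:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples to fit a time constant")
    tail = y[-max(3, t.size // 10):].mean()
    if y[0] <= tail + 1e-12:
        raise ValueError("series does not decay toward an asymptote")

    t0 = t - t[0]
    span = t[-1] - t[0]
    if k_ss is None:
        def model(tt, a, tau, c):
            return c + a * np.exp(-tt / tau)
        p0 = (y[0] - tail, max(span / 5.0, 1e-6), tail)
        popt, _ = curve_fit(model, t0, y, p0=p0, maxfev=20000)
        tau = popt[1]
    else:
        def model(tt, a, tau):
            return k_ss + a * np.exp(-tt / tau)
        p0 = (y[0] - k_ss, max(span / 5.0, 1e-6))
        popt, _ = curve_fit(model, t0, y, p0=p0, maxfev=20000)
        tau = popt[1]
    if tau <= 0:
        raise ValueError("fitted time constant is non-positive")
    return float(tau)
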