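"""Reduced 3D voxel model of extracellular K+ dynamics around an astrocyte.

Extracellular [K+] evolves on a regular voxel grid by explicit forward-Euler
integration of

    d[K+]_out/dt = D * laplacian([K+]_out) - k(r) * ([K+]_out - [K+]_ss)

with zero-flux (Neumann) boundaries.  The first-order relaxation term is the
lumped proxy for Kir4.1-mediated uptake: background rate 1/tau everywhere
(tau = 40 s for the reference conductance density 0.175 mS/cm^2), scaled by
``g_ratio`` inside the central astrocyte territory (2.0 = over-expressing,
0.5 = under-expressing, 1.0 = control).  Inside the territory, intracellular
K+ mirrors the local extracellular depletion,

    [K+]_in(r, t) = 110 + 2 * ([K+]_out(r, 0) - [K+]_out(r, t))  [mM],

the factor 2 being the extracellular/intracellular volume-fraction ratio.
Intracellular diffusion is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DynamicsConfig",
    "FieldState",
    "Trajectory",
    "IntegrationError",
    "build_uptake_field",
    "laplacian_neumann",
    "step",
    "run",
    "boundary_sensitivity",
]

K_IN_REST = 110.0  # mM


class IntegrationError(RuntimeError):
    """Raised when the explicit integration produces NaN or negative K+."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Arena geometry, grid, and dynamical parameters of the reduced model.

    Defaults reproduce the reference simulation: a 130 x 150 x 42 um^3 arena
    centered at (2, -1, -3) um, discretized 19 x 28 x 15, extracellular
    diffusion D = 0.6 um^2/ms (tortuosity included), uptake time constant
    tau = 40 s toward steady state 2.5 mM from uniform initial 5 mM,
    dt = 1 ms over 20 s.  Construction enforces the explicit-scheme
    stability bound 2*D*dt*(1/hx^2 + 1/hy^2 + 1/hz^2) <= 1.
    """

    arena: tuple[float, float, float] = (130.0, 150.0, 42.0)  # um
    center: tuple[float, float, float] = (2.0, -1.0, -3.0)  # um
    grid: tuple[int, int, int] = (19, 28, 15)
    d: float = 0.6  # um^2/ms
    tau: float = 40.0  # s
    k_ss: float = 2.5  # mM
    k0: float = 5.0  # mM
    dt: float = 1.0  # ms
    duration: float = 20.0  # s
    g_ratio: float = 1.0  # territory Kir conductance relative to background
    territory_radius: float = 23.0  # um
    snapshot_every: float = 1000.0  # ms
    # optional box (lengths, center) clipping the territory mask; used when
    # the arena is enlarged but the astrocyte must stay identical
    territory_clip: Optional[tuple[tuple[float, float, float],
                                   tuple[float, float, float]]] = field(default=None)

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.grid):
            raise ValueError("each axis needs at least 2 voxels")
        if any(length <= 0 for length in self.arena):
            raise ValueError("arena lengths must be positive")
        if self.dt <= 0 or self.duration <= 0 or self.tau <= 0:
            raise ValueError("dt, duration and tau must be positive")
        if self.g_ratio < 0:
            raise ValueError(f"g_ratio must be >= 0, got {self.g_ratio}")
        if self.territory_radius <= 0:
            raise ValueError("territory_radius must be positive")
        crit = 2.0 * self.d * self.dt * sum(1.0 / h**2 for h in self.pitches)
        if crit > 1.0:
            raise ValueError(
                "explicit-scheme stability violated: "
                f"2*D*dt*sum(1/h^2) = {crit:.4g} > 1; reduce dt or coarsen grid"
            )

    @property
    def pitches(self) -> tuple[float, float, float]:
        """Voxel pitch per axis, um (arena length / voxel count)."""
        return tuple(length / n for length, n in zip(self.arena, self.grid))

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates per axis, arena-centered as configured."""
        out = []
        for length, n, c in zip(self.arena, self.grid, self.center):
            h = length / n
            out.append(c - length / 2.0 + h * (np.arange(n) + 0.5))
        return tuple(out)

    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    def territory_mask(self) -> np.ndarray:
        """Boolean field: voxels whose center lies in the astrocyte sphere."""
        x, y, z = self.axis_coords()
        dx = x[:, None, None] - self.center[0]
        dy = y[None, :, None] - self.center[1]
        dz = z[None, None, :] - self.center[2]
        mask = dx**2 + dy**2 + dz**2 <= self.territory_radius**2
        if self.territory_clip is not None:
            (lx, ly, lz), (cx, cy, cz) = self.territory_clip
            mask &= (np.abs(x[:, None, None] - cx) <= lx / 2.0)
            mask &= (np.abs(y[None, :, None] - cy) <= ly / 2.0)
            mask &= (np.abs(z[None, None, :] - cz) <= lz / 2.0)
        return mask


@dataclass
class FieldState:
    """Simulation state: time (s), [K+]_out field, mirrored [K+]_in, mask."""

    t: float
    k_out: np.ndarray  # mM, shape = grid
    k_in: np.ndarray  # mM, NaN outside the territory mask
    mask: np.ndarray  # bool


@dataclass
class Trajectory:
    """Snapshots plus summary time series of a territory-model run."""

    config: DynamicsConfig
    snapshots: list[FieldState]
    summary: pd.DataFrame  # t_s, mean_kout_mM, interior_kout_mM, exterior_kout_mM, mean_kin_mM


def initial_state(config: DynamicsConfig) -> FieldState:
    mask = config.territory_mask()
    k_out = np.full(config.grid, config.k0, dtype=float)
    k_in = np.where(mask, K_IN_REST, np.nan)
    return FieldState(t=0.0, k_out=k_out, k_in=k_in, mask=mask)


def build_uptake_field(config: DynamicsConfig) -> np.ndarray:
    """Uptake rate constants k(r) in 1/s: 1/tau outside, g_ratio/tau inside."""
    rate = np.full(config.grid, 1.0 / config.tau, dtype=float)
    rate[config.territory_mask()] = config.g_ratio / config.tau
    return rate


def laplacian_neumann(field: np.ndarray, pitches, out: Optional[np.ndarray] = None) -> np.ndarray:
    """7-point Laplacian with zero-flux boundaries (mirrored ghost voxels).

    The mirrored ghost makes every boundary second difference telescope, so
    the voxel sum of the result is zero for any field (discrete mass
    conservation of the pure-diffusion operator).
    """
    if field.ndim != 3:
        raise ValueError("field must be 3D")
    if any(n < 2 for n in field.shape):
        raise ValueError("each axis needs at least 2 voxels")
    if out is None:
        out = np.zeros_like(field)
    else:
        out.fill(0.0)
    for axis, h in enumerate(pitches):
        inv_h2 = 1.0 / (h * h)
        sl = [slice(None)] * 3

        def take(s):
            sl[axis] = s
            return tuple(sl)

        mid, up, down = take(slice(1, -1)), take(slice(2, None)), take(slice(None, -2))
        out[mid] += (field[up] - 2.0 * field[mid] + field[down]) * inv_h2
        first, second = take(0), take(1)
        out[first] += (field[second] - field[first]) * inv_h2
        last, penult = take(-1), take(-2)
        out[last] += (field[penult] - field[last]) * inv_h2
    return out


def step(state: FieldState, uptake_field: np.ndarray, config: DynamicsConfig,
         _lap_buf: Optional[np.ndarray] = None) -> FieldState:
    """Advance the state one forward-Euler step of length ``config.dt`` ms."""
    lap = laplacian_neumann(state.k_out, config.pitches, out=_lap_buf)
    rate_per_ms = uptake_field * 1e-3  # 1/s -> 1/ms
    k_out = state.k_out + config.dt * (
        config.d * lap - rate_per_ms * (state.k_out - config.k_ss)
    )
    if not np.all(np.isfinite(k_out)) or np.any(k_out < 0):
        raise IntegrationError("non-finite or negative [K+]_out; integration failed")
    k_in = np.where(state.mask, K_IN_REST + 2.0 * (config.k0 - k_out), np.nan)
    return FieldState(t=state.t + config.dt * 1e-3, k_out=k_out, k_in=k_in, mask=state.mask)


def run(config: DynamicsConfig) -> Trajectory:
    """Integrate the reduced model over ``config.duration`` seconds.

    Deterministic.  Snapshots (including t = 0) are stored every
    ``config.snapshot_every`` ms; the summary holds the spatial mean,
    territory-interior mean and exterior mean of [K+]_out and the mask-mean
    [K+]_in at each snapshot time.
    """
    mask = config.territory_mask()
    interior = mask
    exterior = ~mask
    uptake = build_uptake_field(config)
    rate_per_ms = uptake * 1e-3
    k_out = np.full(config.grid, config.k0, dtype=float)
    lap = np.empty_like(k_out)

    snap_stride = max(1, int(round(config.snapshot_every / config.dt)))
    n_steps = config.n_steps()
    snapshots: list[FieldState] = []
    rows = []

    def record(t_s: float, field: np.ndarray) -> None:
        k_in = np.where(mask, K_IN_REST + 2.0 * (config.k0 - field), np.nan)
        snapshots.append(FieldState(t=t_s, k_out=field.copy(), k_in=k_in, mask=mask))
        rows.append(
            (
                t_s,
                float(field.mean()),
                float(field[interior].mean()) if interior.any() else np.nan,
                float(field[exterior].mean()) if exterior.any() else np.nan,
                float(k_in[mask].mean()) if mask.any() else np.nan,
            )
        )

    record(0.0, k_out)
    dt = config.dt
    for n in range(1, n_steps + 1):
        laplacian_neumann(k_out, config.pitches, out=lap)
        k_out += dt * (config.d * lap - rate_per_ms * (k_out - config.k_ss))
        if n % snap_stride == 0 or n == n_steps:
            if not np.all(np.isfinite(k_out)) or np.any(k_out < 0):
                raise IntegrationError("non-finite or negative [K+]_out during run")
            record(n * dt * 1e-3, k_out)

    summary = pd.DataFrame(
        rows,
        columns=["t_s", "mean_kout_mM", "interior_kout_mM", "exterior_kout_mM", "mean_kin_mM"],
    )
    return Trajectory(config=config, snapshots=snapshots, summary=summary)


def boundary_sensitivity(config: DynamicsConfig, scale: float = 2.0) -> float:
    """Max relative [K+]_out deviation (%) near the territory when the arena
    is enlarged ``scale``-fold at unchanged voxel pitch.

    The enlarged run keeps the identical astrocyte (mask clipped to the
    original arena box) so only the boundary location changes; its fields,
    linearly interpolated to the base voxel centers, serve as reference.
    Deviations are measured over all snapshot times at voxels whose centers
    lie within 15 um of the territory-sphere surface, relative to the local
    reference departure from steady state.
    """
    if scale <= 1.0:
        if scale == 1.0:
            return 0.0
        raise ValueError("scale must be >= 1")
    big = replace(
        config,
        arena=tuple(length * scale for length in config.arena),
        grid=tuple(int(round(n * scale)) for n in config.grid),
        territory_clip=(config.arena, config.center),
    )
    base_traj = run(config)
    big_traj = run(big)

    x, y, z = config.axis_coords()
    pts = np.stack(np.meshgrid(x, y, z, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.sqrt(
        (pts[:, 0] - config.center[0]) ** 2
        + (pts[:, 1] - config.center[1]) ** 2
        + (pts[:, 2] - config.center[2]) ** 2
    )
    shell = np.abs(r - config.territory_radius) <= 15.0

    worst = 0.0
    for small_state, big_state in zip(base_traj.snapshots[1:], big_traj.snapshots[1:]):
        interp = RegularGridInterpolator(big.axis_coords(), big_state.k_out, method="linear")
        ref = interp(pts[shell])
        small = small_state.k_out.reshape(-1)[shell]
        denom = ref - config.k_ss
        ok = np.abs(denom) > 1e-12
        if not ok.any():
            continue
        dev = np.abs(small[ok] - ref[ok]) / np.abs(denom[ok])
        worst = max(worst, float(dev.max()))
    return 100.0 * worst
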