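"""Seeded generators emulating the recordings the estimators consume.

Each generator is a bit-reproducible function of its parameters and seed and
returns the data plus a truth dictionary with the generating parameters, so
estimator-recovery round trips can be tested without any download.  Defaults
are the study conditions: first/second-pulse release probabilities
0.46/0.69, transient decay 1.85 s, calibration truth (9340, 2.74), paired
stimuli 50 ms apart.

Noise models: additive Gaussian for current/fluorescence traces,
multiplicative Gaussian for calibration ratios (matching the respective
measurement physics).  Synthetic paired-pulse responses use alpha-function
kinetics, f(t) = (t/tau_r) * exp(1 - t/tau_r), which peaks at exactly
t = tau_r with value 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .estimators import TraceSeries

__all__ = [
    "SynthSpec",
    "generate",
    "gen_quantal_trials",
    "gen_transient",
    "gen_calibration_points",
    "gen_paired_dff",
]

KINDS = ("quantal", "transient", "calibration", "paired_dff")


@dataclass(frozen=True)
class SynthSpec:
    """Declarative generator request: kind, seed, per-kind truth parameters."""

    kind: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


def generate(spec: SynthSpec):
    """Dispatch a :class:`SynthSpec` to the matching generator."""
    fn = {
        "quantal": gen_quantal_trials,
        "transient": gen_transient,
        "calibration": gen_calibration_points,
        "paired_dff": gen_paired_dff,
    }[spec.kind]
    return fn(seed=spec.seed, **spec.parameters)


def gen_quantal_trials(
    p1: float = 0.46,
    p2: float = 0.69,
    n_trials: int = 20,
    n_boutons: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Bernoulli success/failure table for paired-pulse quantal release.

    Independent outcomes per pulse per trial with probabilities (p1, p2);
    columns bouton_id, trial, success1, success2.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if n_trials < 1 or n_boutons < 1:
        raise ValueError("n_trials and n_boutons must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_boutons):
        s1 = rng.random(n_trials) < p1
        s2 = rng.random(n_trials) < p2
        for k in range(n_trials):
            rows.append((b, k, int(s1[k]), int(s2[k])))
    table = pd.DataFrame(rows, columns=["bouton_id", "trial", "success1", "success2"])
    truth = {"p1": p1, "p2": p2, "ppr": (p2 / p1 if p1 > 0 else np.nan),
             "n_trials": n_trials, "n_boutons": n_boutons, "seed": seed}
    return table, truth


def gen_transient(
    tau: float = 1.85,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.02,
    fs: float = 1000.0,
    onset: float = 0.5,
    duration: float = 12.0,
    seed: int = 0,
) -> tuple[TraceSeries, dict[str, Any]]:
    """Noisy mono-exponential transient: step to ``amplitude`` at ``onset``
    decaying with time constant ``tau`` (s), sampled at ``fs`` Hz."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / fs)
    clean = baseline + np.where(t >= onset, amplitude * np.exp(-(t - onset) / tau), 0.0)
    values = clean + rng.normal(0.0, noise_sd, size=t.size)
    truth = {"tau": tau, "amplitude": amplitude, "baseline": baseline,
             "noise_sd": noise_sd, "fs": fs, "onset": onset, "seed": seed}
    return TraceSeries(t=t, values=values, meta=dict(truth)), truth


def gen_calibration_points(
    a: float = 9340.0,
    b: float = 2.74,
    k_grid=None,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Ratiometric calibration points ratio = a*ln(k + b)*(1 + eps),
    eps ~ N(0, noise_cv), on a [K+]_out grid (default 8 points, 0.1-10 mM)."""
    if k_grid is None:
        k_grid = np.geomspace(0.1, 10.0, 8)
    k = np.asarray(k_grid, dtype=float)
    if k.size < 2 or np.unique(k).size < 2:
        raise ValueError("k grid must contain at least 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    clean = a * np.log(k + b)
    ratio = clean * (1.0 + rng.normal(0.0, noise_cv, size=k.size))
    points = pd.DataFrame({"k_out_mM": k, "ratio": ratio})
    truth = {"a": a, "b": b, "noise_cv": noise_cv, "seed": seed}
    return points, truth


def gen_paired_dff(
    peak1: float = 0.2,
    peak2: float = 0.3,
    isi: float = 0.05,
    rise_tau: float = 0.005,
    noise_sd: float = 0.0,
    fs: float = 2000.0,
    pre: float = 0.1,
    post: float = 0.15,
    seed: int = 0,
) -> tuple[TraceSeries, dict[str, Any]]:
    """dF/F0 trace of two alpha-function responses ``isi`` seconds apart.

    Stimulus markers at (pre, pre + isi); true PPR = peak2/peak1 in the
    truth dict.  The trace must extend one inter-stimulus interval past the
    second stimulus (required by the PPR window convention).
    """
    if isi <= 0:
        raise ValueError("isi must be positive")
    if post < 2 * isi:
        raise ValueError("trace too short: need post >= 2*isi after the first stimulus")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, pre + post, 1.0 / fs)
    s1, s2 = pre, pre + isi

    def alpha(t0, peak):
        dt = t - t0
        resp = np.where(dt > 0, (dt / rise_tau) * np.exp(1.0 - dt / rise_tau), 0.0)
        return peak * resp

    values = alpha(s1, peak1) + alpha(s2, peak2)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    truth = {"peak1": peak1, "peak2": peak2, "ppr": peak2 / peak1, "isi": isi,
             "rise_tau": rise_tau, "noise_sd": noise_sd, "fs": fs, "seed": seed}
    return TraceSeries(t=t, values=values, stim_times=np.array([s1, s2]),
                       meta=dict(truth)), truth
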