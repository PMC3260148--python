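"""Synthetic TMRM StDev traces: plateau, stochastic flicker, logistic collapse.

Under polarized conditions the TMRM dye is concentrated in mitochondria, so
the per-cell spatial standard deviation (StDev) of the signal is high; loss of
membrane potential redistributes the dye and the StDev falls.  Each synthetic
trace is a noiseless logistic collapse

    v(t) = min + (max - min) / (1 + exp((t - t0) / tau))

parameterized directly by the time ``t_half_s`` at which it crosses
``max_level / 2`` (so downstream parameter extraction is a genuine
parameter-recovery problem), overlaid with transient multiplicative flicker
dips and additive Gaussian noise.  Non-collapsing conditions (e.g. adenine
nucleotide translocator inhibition) set ``t_half_s = None``.

Traces are sampled at 1 Hz for 301 samples (t = 0..300 s), matching a
5-minute acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TracePreset:
    """Condition-level parameters of the synthetic StDev trace model."""

    name: str
    max_level: float  # plateau StDev, a.u.
    min_level: float  # post-collapse StDev, a.u.
    t_half_s: float | None  # time of crossing max_level/2; None = no collapse
    collapse_steepness_s: float = 12.0  # logistic time constant tau
    flicker_rate_hz: float = 0.05
    flicker_depth_frac: float = 0.15
    noise_sd: float = 0.8
    t_half_jitter_s: float = 8.0  # per-cell spread of the crossing time
    duration_s: int = 300
    sample_hz: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_level < self.max_level:
            raise ValueError("require 0 <= min_level < max_level")
        if self.t_half_s is not None:
            if not 0 < self.t_half_s < self.duration_s:
                raise ValueError("t_half_s must lie within (0, duration_s)")
            if self.min_level >= self.max_level / 2:
                raise ValueError(
                    "inconsistent preset: min_level >= max_level/2, the trace "
                    "can never cross half of its initial value"
                )


#: Condition presets.  Timing and plateau levels follow the published
#: qualitative grouping: controls collapse late (full medium at ~232 s),
#: death-receptor/bioenergetic drugs sensitize (earlier collapse), uncoupler /
#: calcium stress conditions are already collapsed at acquisition onset, the
#: permeability-pore inhibitor cyclosporine A delays collapse and bongkrekic
#: acid blocks it.
TRACE_PRESETS: dict[str, TracePreset] = {
    "FM": TracePreset("FM", 40.0, 8.0, 232.0),
    "BSS": TracePreset("BSS", 38.0, 8.0, 185.0),
    "ceramide": TracePreset("ceramide", 28.0, 7.0, 268.0, flicker_depth_frac=0.1),
    "CsA": TracePreset("CsA", 38.0, 8.0, 252.0),
    "BA": TracePreset("BA", 38.0, 8.0, None),
    "TNFa": TracePreset("TNFa", 36.0, 7.0, 118.0),
    "TRAIL": TracePreset("TRAIL", 37.0, 7.0, 142.0),
    "camptothecin": TracePreset("camptothecin", 35.0, 7.0, 108.0),
    "oligomycin": TracePreset("oligomycin", 34.0, 7.0, 130.0),
    "CCCP": TracePreset("CCCP", 7.0, 4.0, None, noise_sd=0.5, flicker_rate_hz=0.0),
    "thapsigargin": TracePreset("thapsigargin", 8.0, 4.5, None, noise_sd=0.5, flicker_rate_hz=0.0),
}


def make_trace_preset(name: str) -> TracePreset:
    try:
        return TRACE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown trace preset {name!r}; valid names: {sorted(TRACE_PRESETS)}"
        ) from None


def noiseless_trace(preset: TracePreset, t_half_s: float | None = None) -> np.ndarray:
    """The underlying noiseless curve sampled on the preset's time grid."""
    t = np.arange(0, preset.duration_s + 1, 1.0 / preset.sample_hz)
    th = preset.t_half_s if t_half_s is None else t_half_s
    if th is None:
        return np.full_like(t, preset.max_level)
    # position the logistic so it crosses max_level/2 exactly at th
    s_star = (preset.max_level / 2 - preset.min_level) / (preset.max_level - preset.min_level)
    t0 = th - preset.collapse_steepness_s * np.log((1.0 - s_star) / s_star)
    s = 1.0 / (1.0 + np.exp((t - t0) / preset.collapse_steepness_s))
    return preset.min_level + (preset.max_level - preset.min_level) * s


def generate_tmrm_traces(
    preset: TracePreset | str,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` per-cell StDev traces; long table (cell_id, t, value)."""
    if isinstance(preset, str):
        preset = make_trace_preset(preset)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(0, preset.duration_s + 1, 1.0 / preset.sample_hz)
    frames = []
    for cell in range(1, n + 1):
        th = preset.t_half_s
        if th is not None and preset.t_half_jitter_s > 0:
            th = float(
                np.clip(
                    rng.normal(th, preset.t_half_jitter_s), 1.0, preset.duration_s - 1.0
                )
            )
        v = noiseless_trace(preset, th).copy()
        # transient multiplicative flicker dips (~3 s wide)
        if preset.flicker_rate_hz > 0:
            n_flicks = rng.poisson(preset.flicker_rate_hz * preset.duration_s)
            for _ in range(n_flicks):
                center = rng.uniform(0, preset.duration_s)
                depth = rng.uniform(0.3, 1.0) * preset.flicker_depth_frac
                width = rng.uniform(1.5, 3.5)
                v = v * (1.0 - depth * np.exp(-0.5 * ((t - center) / width) ** 2))
        if preset.noise_sd > 0:
            v = v + rng.normal(0.0, preset.noise_sd, size=v.shape)
        frames.append(
            pd.DataFrame({"cell_id": cell, "t": t, "value": np.clip(v, 0.0, None)})
        )
    return pd.concat(frames, ignore_index=True)


def generate_condition_traces(
    n_per_condition: int,
    seed: int = 0,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Traces for several condition presets, with a ``condition`` column."""
    names = conditions if conditions is not None else list(TRACE_PRESETS)
    rng = np.random.default_rng(seed)
    out = []
    for name in names:
        df = generate_tmrm_traces(name, n_per_condition, seed=int(rng.integers(2**31)))
        df.insert(0, "condition", name)
        out.append(df)
    return pd.concat(out, ignore_index=True)
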