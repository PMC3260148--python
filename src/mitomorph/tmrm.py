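"""Membrane-potential kinetics from TMRM StDev traces.

Polarized mitochondria concentrate the TMRM dye, so the spatial standard
deviation of the signal inside a cell is high; depolarization redistributes
the dye and the StDev collapses.  Each per-cell trace is summarized by three
parameters:

* ``MAX`` — initial StDev level (median of the first 10 samples);
* ``Y_spread`` — total StDev decrease, ``MAX - MIN`` with ``MIN`` the median
  of the last 10 samples;
* ``t_half_decay`` — first time the trace falls to half of its initial value
  (linearly interpolated between samples), or censored if it never does.

Condition-level profiles (mean StDev per time point) are compared by
agglomerative hierarchical clustering with Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage


@dataclass
class Trace:
    cell_id: int
    times: np.ndarray  # seconds
    values: np.ndarray  # StDev, a.u.

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class TraceParams:
    """Extracted kinetic parameters for one trace."""

    cell_id: int
    MAX: float
    MIN: float
    Y_spread: float
    t_half_decay: float | None
    censored: bool


def stdev_trace(frames: np.ndarray, cell_mask: np.ndarray, sample_hz: float = 1.0) -> Trace:
    """Per-frame population StDev of pixel values inside a fixed cell mask."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (time, y, x) stack")
    if frames.shape[0] < 20:
        raise ValueError("need at least 20 frames")
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    values = frames[:, mask].std(axis=1)  # population StDev over ROI pixels
    times = np.arange(frames.shape[0]) / sample_hz
    return Trace(cell_id=0, times=times, values=values)


def extract_trace_params(
    trace: Trace | tuple[np.ndarray, np.ndarray],
    halflife_mode: str = "half_max",
    persistence_samples: int = 5,
    cell_id: int = 0,
) -> TraceParams:
    """Extract (MAX, MIN, Y_spread, t_half_decay) from a StDev trace.

    ``halflife_mode='half_max'`` reads "half of its initial value" literally
    (threshold = MAX/2); ``'midpoint'`` uses (MAX+MIN)/2 instead.  The
    crossing is the first downward crossing after which the trace stays at or
    below threshold for at least ``persistence_samples`` samples, suppressing
    transient flicker dips; the crossing time is linearly interpolated
    between the bracketing samples.
    """
    if isinstance(trace, Trace):
        t, v = trace.times, trace.values
        cell_id = trace.cell_id
    else:
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if v.size < 20:
        raise ValueError("need at least 20 samples")
    vmax = float(np.median(v[:10]))
    vmin = float(np.median(v[-10:]))
    if halflife_mode == "half_max":
        threshold = vmax / 2.0
    elif halflife_mode == "midpoint":
        threshold = (vmax + vmin) / 2.0
    else:
        raise ValueError("halflife_mode must be 'half_max' or 'midpoint'")

    below = v <= threshold
    t_half: float | None = None
    for i in np.flatnonzero(below):
        run_end = min(i + persistence_samples, v.size)
        if below[i:run_end].all():
            if i == 0:
                t_half = float(t[0])
            else:
                # linear interpolation between the bracketing samples
                v0, v1 = v[i - 1], v[i]
                frac = (v0 - threshold) / (v0 - v1) if v0 != v1 else 1.0
                t_half = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            break
    return TraceParams(
        cell_id=cell_id,
        MAX=vmax,
        MIN=vmin,
        Y_spread=vmax - vmin,
        t_half_decay=t_half,
        censored=t_half is None,
    )


def extract_params_table(
    traces: pd.DataFrame, halflife_mode: str = "half_max"
) -> pd.DataFrame:
    """Run :func:`extract_trace_params` per cell of a long trace table.

    ``traces`` columns: ``cell_id``, ``t``, ``value`` and optionally
    ``condition`` (preserved in the output).
    """
    rows = []
    keys = ["condition", "cell_id"] if "condition" in traces.columns else ["cell_id"]
    for key, g in traces.groupby(keys, sort=False):
        g = g.sort_values("t")
        p = extract_trace_params(
            (g["t"].to_numpy(), g["value"].to_numpy()), halflife_mode=halflife_mode
        )
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            MAX=p.MAX, MIN=p.MIN, Y_spread=p.Y_spread,
            t_half_decay=p.t_half_decay, censored=p.censored,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def condition_profiles(traces: pd.DataFrame) -> pd.DataFrame:
    """Mean StDev per condition per time point (rows = conditions)."""
    if "condition" not in traces.columns:
        raise ValueError("traces need a 'condition' column")
    prof = traces.pivot_table(index="condition", columns="t", values="value", aggfunc="mean", sort=False)
    return prof


def plot_heatmap(profiles: pd.DataFrame, path, vmin: float = 0.0, vmax: float = 50.0) -> None:
    """Save the condition x time profile matrix as a heatmap (0-50 a.u. scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.45 * len(profiles) + 1.5))
    im = ax.imshow(profiles.to_numpy(), aspect="auto", vmin=vmin, vmax=vmax, cmap="viridis")
    ax.set_yticks(range(len(profiles)), profiles.index)
    ax.set_xlabel("time (s)")
    fig.colorbar(im, ax=ax, label="StDev (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_conditions(profiles: pd.DataFrame, method: str = "average") -> dict:
    """Agglomerative clustering of condition profiles (Euclidean distance).

    Returns the scipy linkage matrix, the dendrogram leaf order (condition
    names) and a ``cut(k)`` helper mapping conditions to cluster ids.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 conditions")
    X = profiles.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("profiles of unequal length (NaNs after alignment)")
    Z = linkage(X, method=method, metric="euclidean")
    order = [profiles.index[i] for i in leaves_list(Z)]

    def cut(k: int) -> dict[str, int]:
        assignment = fcluster(Z, t=k, criterion="maxclust")
        return dict(zip(profiles.index, (int(a) for a in assignment)))

    return {"linkage": Z, "leaf_order": order, "labels": list(profiles.index), "cut": cut}
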