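"""Condition-level tables with a planted causal chain.

Generates per-condition summary tables over the seven pipeline variables
(Bax %, N/F/S morphology-class %, and the membrane-potential kinetics
parameters MAX, t1/2_decay, Y_spread) in which a known directed chain —
by default Bax -> Fragmented -> Y_spread — drives downstream variables
through monotone saturating (Hill-type) link functions plus noise.

Saturation is the key design ingredient: it makes the forward mapping a
well-defined function while the reverse mapping is ill-conditioned near the
plateau, so a mirror-model comparison (fit both directions, keep the smaller
error) can recover the planted direction.  Non-chain variables are filled
from independent marginal distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ("Bax", "N", "F", "S", "MAX", "t1_2_decay", "Y_spread")


@dataclass(frozen=True)
class HillLink:
    """Monotone saturating link y = ymin + (ymax-ymin) * x^h / (K^h + x^h)."""

    ymin: float
    ymax: float
    K: float
    h: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), 0.0, None)
        return self.ymin + (self.ymax - self.ymin) * x**self.h / (self.K**self.h + x**self.h)


@dataclass(frozen=True)
class CausalTableSpec:
    """Specification of a planted-chain condition table.

    The default reflects the study conditions: nine drug/control conditions,
    chain Bax -> F -> Y_spread, Hill links with half-saturation well inside
    the driver's range (so several conditions sit on the plateau), and
    moderate condition-level noise.
    """

    n_conditions: int = 9
    chain: tuple[str, ...] = ("Bax", "F", "Y_spread")
    link_functions: dict[str, HillLink] = field(
        default_factory=lambda: {
            "F": HillLink(ymin=12.0, ymax=68.0, K=25.0, h=2.0),
            "Y_spread": HillLink(ymin=5.0, ymax=38.0, K=30.0, h=3.0),
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"F": 3.0, "Y_spread": 2.0}
    )
    variable_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Bax": (2.0, 95.0),
            "MAX": (8.0, 42.0),
            "t1_2_decay": (80.0, 280.0),
            "Y_spread": (4.0, 40.0),
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.chain) - set(COLUMNS)
        if unknown:
            raise ValueError(f"chain references unknown variable(s): {sorted(unknown)}")
        for v in self.chain[1:]:
            if v not in self.link_functions:
                raise ValueError(f"no link function declared for chain variable {v!r}")


def _stratified_uniform(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """One draw per equal-width stratum: spreads values over the full range."""
    edges = np.linspace(lo, hi, n + 1)
    vals = rng.uniform(edges[:-1], edges[1:])
    return rng.permutation(vals)


def generate_condition_table(
    spec: CausalTableSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a condition table (rows = conditions, columns = :data:`COLUMNS`).

    The chain root is drawn stratified-uniform over its range (guaranteeing
    coverage of the saturating regime); each downstream chain variable is its
    link function of the parent plus Gaussian noise.  N and S are filled so
    that N + F + S = 100 exactly per row; remaining variables come from their
    uniform marginals.
    """
    spec = spec or CausalTableSpec()
    if spec.n_conditions < 5:
        raise ValueError("n_conditions must be >= 5 (minimum rows for model fitting)")
    rng = np.random.default_rng(seed)
    n = spec.n_conditions
    data: dict[str, np.ndarray] = {}

    root = spec.chain[0]
    lo, hi = spec.variable_ranges.get(root, (0.0, 100.0))
    data[root] = _stratified_uniform(lo, hi, n, rng)
    for parent, child in zip(spec.chain[:-1], spec.chain[1:]):
        y = spec.link_functions[child](data[parent])
        sd = spec.noise_sd.get(child, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n)
        data[child] = y

    # morphology simplex: split the non-fragmented remainder between N and S
    if "F" in data:
        f = np.clip(data["F"], 0.0, 100.0)
        share = rng.uniform(0.55, 0.75, size=n)  # networked share of the remainder
        data["F"] = f
        data["N"] = (100.0 - f) * share
        data["S"] = 100.0 - f - data["N"]
    for col in COLUMNS:
        if col in data:
            continue
        lo, hi = spec.variable_ranges.get(col, (0.0, 100.0))
        data[col] = rng.uniform(lo, hi, size=n)

    df = pd.DataFrame({c: data[c] for c in COLUMNS})
    df.insert(0, "condition", [f"cond_{i+1:02d}" for i in range(n)])
    return df
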