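"""Sugeno SISO fuzzy models and mirror-model directionality inference.

Each candidate interaction between two measured variables is encoded as a
single-input single-output (SISO) Sugeno fuzzy system with two Gaussian input
membership functions ("low", "high"; peak fixed at 1) and linear rule
outputs, so the inferred output is

    y(x) = sum_i w_i(x) * (p_i * x + r_i) / sum_i w_i(x),
    w_i(x) = exp(-(x - c_i)^2 / (2 * sigma_i^2)).

Two rules (= number of input membership functions) suffice to approximate a
smooth monotone nonlinearity piecewise-linearly.  Training is hybrid: the
four consequent parameters are solved exactly by least squares at each epoch
(the output is linear in them), and the four premise parameters
(c, sigma per membership) follow a gradient step with rollback-and-halve on
any SSE increase, so training SSE is non-increasing.

Directionality between variable groups is inferred by an exhaustive search:
one model per ordered cross-group variable pair (30 models for the default
grouping {Bax} x {N, F, S} x {MAX, t1/2_decay, Y_spread}); models with
training RMSE above a threshold (default 15 a.u.) are discarded, and within
each surviving mirror pair (A->B vs B->A) the direction with the smaller
RMSE is retained as an edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("Bax",),
    ("N", "F", "S"),
    ("MAX", "t1_2_decay", "Y_spread"),
)

#: Hypothesis tags for the six cross-group direction families:
#: morphology->Bax, Bax->morphology, Bax->potential, potential->Bax,
#: morphology->potential, potential->morphology.
_HYPOTHESES = {
    (1, 0): "H1",
    (0, 1): "H2",
    (0, 2): "H3",
    (2, 0): "H4",
    (1, 2): "H5",
    (2, 1): "H6",
}

RMSE_THRESHOLD = 15.0


@dataclass
class MembershipParams:
    """Gaussian membership function; degree of membership peaks at 1 at c."""

    c: float
    sigma: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_dom(x, mf: MembershipParams):
    """Degree of membership exp(-(x-c)^2 / (2 sigma^2)), in [0, 1]."""
    if mf.sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - mf.c) ** 2) / (2.0 * mf.sigma**2))
    return float(out) if out.ndim == 0 else out


@dataclass
class SISOModel:
    """Two-rule Sugeno model for one directed variable pair."""

    input_var: str
    output_var: str
    premises: tuple[MembershipParams, MembershipParams]
    consequents: np.ndarray  # shape (2, 2): rows (p_i, r_i)
    rmse: float = np.nan
    hypothesis: str | None = None
    training_meta: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.premises)


def siso_infer(model: SISOModel, x):
    """Sugeno weighted-average inference; vectorized over x."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    w = np.stack([gaussian_dom(x, mf) for mf in model.premises])  # (2, n)
    rule_out = np.stack(
        [p * x + r for p, r in np.asarray(model.consequents, dtype=float)]
    )
    wsum = w.sum(axis=0)
    degenerate = wsum < 1e-300
    if degenerate.any():
        warnings.warn("membership weights underflowed; using unweighted rule mean", stacklevel=2)
        wsum = np.where(degenerate, 1.0, wsum)
        w = np.where(degenerate[None, :], 0.5, w)
    y = (w * rule_out).sum(axis=0) / wsum
    return float(y[0]) if scalar else y


def _solve_consequents(x, y, premises) -> np.ndarray:
    """Exact least squares for (p1, r1, p2, r2) given fixed premises."""
    w = np.stack([gaussian_dom(x, mf) for mf in premises])
    wn = w / w.sum(axis=0, keepdims=True)
    A = np.column_stack([wn[0] * x, wn[0], wn[1] * x, wn[1]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef.reshape(2, 2)


def _sse(x, y, premises, consequents) -> float:
    model = SISOModel("", "", premises, consequents)
    r = y - siso_infer(model, x)
    return float((r**2).sum())


def train_siso(
    x,
    y,
    input_var: str = "x",
    output_var: str = "y",
    epochs: int = 200,
    learning_rate: float = 0.05,
    rel_tol: float = 1e-8,
    seed: int | None = None,
) -> SISOModel:
    """Hybrid training: exact consequent least squares + premise gradient steps.

    Premises are initialized at the data extremes (c_low = min x,
    c_high = max x, sigma = range/2), guaranteeing overlap and full-range
    coverage.  Each epoch solves the consequents exactly, then takes one
    gradient step on the premise parameters (numeric gradient, step scaled by
    the data range); a step that increases SSE is rolled back and the
    learning rate halved, so SSE is non-increasing across epochs.  The
    reported RMSE is the training-set root mean squared residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 (x, y) pairs")
    span = float(x.max() - x.min())
    if span == 0:
        raise ValueError("all x identical; premise widths undefined")

    theta = np.array([x.min(), span / 2.0, x.max(), span / 2.0])  # (c_lo, s_lo, c_hi, s_hi)
    min_sigma = max(span * 1e-3, 1e-9)

    def premises_of(t) -> tuple[MembershipParams, MembershipParams]:
        return (
            MembershipParams(c=t[0], sigma=max(t[1], min_sigma), label="low"),
            MembershipParams(c=t[2], sigma=max(t[3], min_sigma), label="high"),
        )

    lr = learning_rate
    consequents = _solve_consequents(x, y, premises_of(theta))
    sse = _sse(x, y, premises_of(theta), consequents)
    scale = np.array([span, span, span, span])
    for epoch in range(epochs):
        # numeric gradient of SSE w.r.t. premise parameters
        grad = np.zeros(4)
        h = 1e-5 * span
        for k in range(4):
            tp = theta.copy()
            tp[k] += h
            tm = theta.copy()
            tm[k] -= h
            grad[k] = (
                _sse(x, y, premises_of(tp), consequents)
                - _sse(x, y, premises_of(tm), consequents)
            ) / (2 * h)
        gmax = np.abs(grad).max()
        if gmax > 0:
            step = -lr * grad / gmax * scale * 0.1
            cand = theta + step
            cand_cons = _solve_consequents(x, y, premises_of(cand))
            cand_sse = _sse(x, y, premises_of(cand), cand_cons)
            if cand_sse <= sse:
                if sse > 0 and (sse - cand_sse) / sse < rel_tol:
                    theta, consequents, sse = cand, cand_cons, cand_sse
                    break
                theta, consequents, sse = cand, cand_cons, cand_sse
            else:
                lr *= 0.5  # rollback: keep previous theta
                if lr < 1e-6:
                    break
        else:
            break
    # final exact consequent solve at the settled premises
    consequents = _solve_consequents(x, y, premises_of(theta))
    sse = _sse(x, y, premises_of(theta), consequents)
    return SISOModel(
        input_var=input_var,
        output_var=output_var,
        premises=premises_of(theta),
        consequents=consequents,
        rmse=float(np.sqrt(sse / x.size)),
        training_meta={"epochs": epochs, "learning_rate": learning_rate, "seed": seed},
    )


def exhaustive_search(
    table: pd.DataFrame,
    groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS,
    normalize: bool = False,
    epochs: int = 200,
) -> list[SISOModel]:
    """Train one SISO model per ordered cross-group variable pair.

    With the default three groups (1 + 3 + 3 variables) this yields
    2*(1*3 + 1*3 + 3*3) = 30 models.  ``normalize`` min-max rescales every
    variable to 0-100 before fitting (mirror RMSE comparison across
    heterogeneous units is otherwise scale-sensitive).
    """
    for g in groups:
        missing = [v for v in g if v not in table.columns]
        if missing:
            raise ValueError(f"table missing column(s): {missing}")
    data = table.copy()
    if normalize:
        for g in groups:
            for v in g:
                col = data[v].astype(float)
                span = col.max() - col.min()
                data[v] = 100.0 * (col - col.min()) / (span if span > 0 else 1.0)
    models = []
    for gi, ga in enumerate(groups):
        for gj, gb in enumerate(groups):
            if gi == gj:
                continue
            for a in ga:
                for b in gb:
                    m = train_siso(
                        data[a].to_numpy(float),
                        data[b].to_numpy(float),
                        input_var=a,
                        output_var=b,
                        epochs=epochs,
                    )
                    m.hypothesis = _HYPOTHESES.get((gi, gj))
                    models.append(m)
    return models


@dataclass
class DirectionGraph:
    """Surviving directed edges with RMSEs, plus the discard list."""

    edges: list[tuple[str, str, float]]
    discarded: list[tuple[str, str, float]]
    threshold: float

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for a, b, r in self.edges:
            g.add_edge(a, b, rmse=r)
        return g

    def to_dot(self) -> str:
        lines = ["digraph directionality {"]
        for a, b, r in self.edges:
            lines.append(f'  "{a}" -> "{b}" [label="{r:.2f}"];')
        lines.append("}")
        return "\n".join(lines)

    def has_edge(self, a: str, b: str) -> bool:
        return any(e[0] == a and e[1] == b for e in self.edges)


def mirror_select(models: list[SISOModel], threshold: float = RMSE_THRESHOLD) -> DirectionGraph:
    """Discard high-RMSE models; keep the better direction of each mirror pair.

    Models must come in mirror pairs (A->B and B->A).  Any model with
    RMSE > threshold is discarded; among surviving pairs the direction with
    the smaller RMSE becomes an edge (if only one direction survives the
    threshold, it is the edge).  Pairs with both directions discarded
    contribute no edge.
    """
    by_pair: dict[frozenset, dict[tuple[str, str], SISOModel]] = {}
    for m in models:
        key = frozenset((m.input_var, m.output_var))
        by_pair.setdefault(key, {})[(m.input_var, m.output_var)] = m
    edges, discarded = [], []
    for key, pair in by_pair.items():
        if len(pair) != 2:
            (only,) = pair.values()
            raise ValueError(
                f"unpaired model {only.input_var}->{only.output_var}: "
                "mirror selection needs both directions"
            )
        surviving = {d: m for d, m in pair.items() if m.rmse <= threshold}
        for d, m in pair.items():
            if d not in surviving:
                discarded.append((d[0], d[1], float(m.rmse)))
        if not surviving:
            continue
        best_dir = min(surviving, key=lambda d: surviving[d].rmse)
        edges.append((best_dir[0], best_dir[1], float(surviving[best_dir].rmse)))
    return DirectionGraph(edges=edges, discarded=discarded, threshold=threshold)
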