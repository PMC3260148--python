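"""Random-forest degree-of-belonging classification of mitochondrial morphology.

A forest of CART trees is grown on per-cell feature vectors with bootstrap
samples stratified by (class, experimental batch), so every tree sees the
class/batch composition of the full training set.  A cell's *degree of
belonging* to each class is the fraction of trees voting for it (the RF
score); reducing to the majority class is used only for validation-style
accuracy figures.  Out-of-bag (OOB) votes give the generalization error, and
permutation of OOB columns yields Breiman-style mean-decrease-in-accuracy
(MDA) feature importance, computed per tree on that tree's own OOB cells and
averaged.

Tree induction is delegated to sklearn ``DecisionTreeClassifier``; the
bootstrap scheme, OOB bookkeeping, vote aggregation, MDA and the
MDA-cost-weighted representative tree are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

CLASS_ORDER = ("networked", "fragmented", "swollen")


@dataclass
class RFModel:
    """Trained forest with OOB bookkeeping."""

    trees: list
    feature_names: list[str]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    oob_error: float
    class_order: tuple[str, ...] = CLASS_ORDER
    training_meta: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _as_matrix(features: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return features[feature_names].to_numpy(dtype=float)


def _stratified_bootstrap(
    labels: np.ndarray, batches: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap preserving per-(class, batch) counts."""
    idx = []
    strata = pd.Series(range(len(labels))).groupby([pd.Series(labels), pd.Series(batches)], observed=True)
    for _, members in strata:
        members = members.to_numpy()
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def train_rf(
    features: pd.DataFrame,
    labels,
    batches=None,
    n_trees: int = 500,
    mtry: int | None = None,
    max_depth: int | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> RFModel:
    """Train the forest; OOB error from out-of-bootstrap majority votes.

    ``batches`` tags each cell's experimental origin; bootstraps are
    stratified by (class, batch).  When a batch is absent (or any stratum is
    empty) stratification falls back to class only, with a warning.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    unknown = set(classes) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    if feature_names is None:
        feature_names = [c for c in features.columns if features[c].dtype.kind in "fc" or c not in ("cell_id",)]
        feature_names = [c for c in feature_names if c not in ("cell_id", "image_id", "condition", "replicate")]
    X = _as_matrix(features, feature_names)
    n, p = X.shape
    if batches is None:
        batches = np.zeros(n, dtype=int)
    batches = np.asarray(batches)
    # a class entirely missing from some batch breaks per-stratum bootstraps
    counts = pd.crosstab(pd.Series(labels), pd.Series(batches))
    if (counts.to_numpy() == 0).any():
        warnings.warn(
            "some (class, batch) strata are empty; stratifying by class only",
            stacklevel=2,
        )
        batches = np.zeros(n, dtype=int)
    if mtry is None:
        mtry = max(int(np.sqrt(p)), 1)

    rng = np.random.default_rng(seed)
    trees, boot_list, oob_list = [], [], []
    class_to_col = {c: i for i, c in enumerate(CLASS_ORDER)}
    oob_votes = np.zeros((n, len(CLASS_ORDER)), dtype=int)
    for _ in range(n_trees):
        boot = _stratified_bootstrap(labels, batches, rng)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            max_depth=max_depth,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[boot], labels[boot])
        if oob.size:
            pred = tree.predict(X[oob])
            for i, c in zip(oob, pred):
                oob_votes[i, class_to_col[c]] += 1
        trees.append(tree)
        boot_list.append(boot)
        oob_list.append(oob)

    voted = oob_votes.sum(axis=1) > 0
    oob_pred = np.array(CLASS_ORDER)[np.argmax(oob_votes, axis=1)]
    oob_error = float(np.mean(oob_pred[voted] != labels[voted])) if voted.any() else np.nan
    return RFModel(
        trees=trees,
        feature_names=list(feature_names),
        bootstrap_indices=boot_list,
        oob_indices=oob_list,
        oob_error=oob_error,
        training_meta={
            "n_trees": n_trees,
            "mtry": mtry,
            "seed": seed,
            "class_counts": {str(c): int((labels == c).sum()) for c in classes},
        },
    )


def predict_scores(model: RFModel, features: pd.DataFrame) -> pd.DataFrame:
    """Vote fractions per cell: columns = class order, rows sum to 1 exactly."""
    X = _as_matrix(features, model.feature_names)
    votes = np.zeros((len(X), len(model.class_order)), dtype=int)
    col = {c: i for i, c in enumerate(model.class_order)}
    for tree in model.trees:
        for i, c in enumerate(tree.predict(X)):
            votes[i, col[c]] += 1
    scores = votes / votes.sum(axis=1, keepdims=True)
    out = pd.DataFrame(scores, columns=list(model.class_order), index=features.index)
    if "cell_id" in features.columns:
        out.insert(0, "cell_id", features["cell_id"].to_numpy())
    return out


def major_class(scores) -> np.ndarray | str:
    """Reduce score triple(s) to the majority class; ties break N > F > S."""
    arr = np.atleast_2d(np.asarray(scores if not isinstance(scores, pd.DataFrame) else scores[list(CLASS_ORDER)]))
    # argmax returns the first maximum, which is exactly the declared tie order
    out = np.array(CLASS_ORDER)[np.argmax(arr, axis=1)]
    return out if out.size > 1 else str(out[0])


def mda_importance(
    model: RFModel,
    features: pd.DataFrame,
    labels,
    n_repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance (mean decrease in accuracy, percentage points).

    For each tree, accuracy on its own OOB cells is compared with accuracy
    after permuting one feature column among those cells; the per-tree drops
    are averaged (and their spread reported), then scaled to percentage
    points.  Sorted descending.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    labels = np.asarray(labels)
    X = _as_matrix(features, model.feature_names)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    drops = np.full((model.n_trees, p), np.nan)
    for t, (tree, oob) in enumerate(zip(model.trees, model.oob_indices)):
        if oob.size == 0:
            continue
        base = np.mean(tree.predict(X[oob]) == labels[oob])
        Xo = X[oob]
        for j in range(p):
            acc = 0.0
            for _ in range(n_repeats):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xo)), j]
                acc += np.mean(tree.predict(Xp) == labels[oob])
            drops[t, j] = base - acc / n_repeats
    mda = np.nanmean(drops, axis=0) * 100.0
    sd = np.nanstd(drops, axis=0) * 100.0
    report = pd.DataFrame(
        {"feature": model.feature_names, "mda": mda, "mda_sd": sd}
    ).sort_values("mda", ascending=False, ignore_index=True)
    return report


def cross_validate(
    features: pd.DataFrame,
    labels,
    batches=None,
    folds: int = 10,
    repeats: int = 10,
    n_trees: int = 500,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> dict:
    """Repeated stratified k-fold CV with major-class reduction.

    Overall accuracy = mean over repeats of the pooled per-repeat fold
    accuracy.
    """
    labels = np.asarray(labels)
    smallest = min(np.bincount(pd.factorize(labels)[0]))
    if smallest < folds:
        raise ValueError(f"smallest class has {smallest} members; need >= {folds}")
    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        correct = 0
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            model = train_rf(
                features.iloc[train_idx],
                labels[train_idx],
                None if batches is None else np.asarray(batches)[train_idx],
                n_trees=n_trees,
                seed=int(rng.integers(2**31)),
                feature_names=feature_names,
            )
            scores = predict_scores(model, features.iloc[test_idx])
            pred = major_class(scores)
            correct += int(np.sum(np.atleast_1d(pred) == labels[test_idx]))
        per_repeat.append(correct / len(labels))
    return {
        "overall_accuracy": float(np.mean(per_repeat)),
        "per_repeat": per_repeat,
        "folds": folds,
        "repeats": repeats,
    }


# ---------------------------------------------------------------------------
# MDA-cost-weighted representative tree


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    prediction: str | None = None
    class_fractions: dict | None = None

    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _best_split(X, y_codes, n_classes, weights):
    """Best (feature, threshold) by MDA-weighted Gini gain."""
    n, p = X.shape
    parent_counts = np.bincount(y_codes, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best = (None, 0.0, -np.inf)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y_codes[order]
        left = np.zeros(n_classes)
        right = parent_counts.astype(float).copy()
        for i in range(n - 1):
            left[ys[i]] += 1
            right[ys[i]] -= 1
            if xs[i + 1] == xs[i]:
                continue
            nl, nr = i + 1, n - i - 1
            gain = parent_gini - (nl * _gini(left) + nr * _gini(right)) / n
            weighted = gain * weights[j]
            if weighted > best[2] + 1e-15:
                best = (j, 0.5 * (xs[i] + xs[i + 1]), weighted)
    return best


def representative_tree(
    features: pd.DataFrame,
    labels,
    importance: pd.DataFrame,
    max_depth: int = 4,
    feature_names: list[str] | None = None,
) -> TreeNode:
    """Single interpretable CART whose split gains are weighted by MDA.

    Splitting on a feature is 'cheap' in proportion to its importance: the
    Gini gain of a candidate split is multiplied by the feature's MDA
    (equivalently divided by its cost 1/MDA).  Non-positive MDAs are replaced
    by epsilon = (smallest positive MDA) / 10; if no MDA is positive the tree
    falls back to unweighted CART with a warning.  Depth-limited for
    interpretability; not intended for classification.
    """
    if feature_names is None:
        feature_names = list(importance["feature"])
    X = _as_matrix(features, feature_names)
    labels = np.asarray(labels)
    codes = np.array([list(CLASS_ORDER).index(c) for c in labels])
    mda_map = dict(zip(importance["feature"], importance["mda"]))
    missing = [f for f in feature_names if f not in mda_map]
    if missing:
        raise ValueError(f"importance missing for feature(s): {missing}")
    w = np.array([mda_map[f] for f in feature_names], dtype=float)
    pos = w[w > 0]
    if pos.size == 0:
        warnings.warn("all MDA <= 0; building unweighted tree", stacklevel=2)
        w = np.ones_like(w)
    else:
        w[w <= 0] = pos.min() / 10.0

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(codes[idx], minlength=len(CLASS_ORDER))
        node = TreeNode(
            prediction=CLASS_ORDER[int(np.argmax(counts))],
            class_fractions={c: float(counts[i] / counts.sum()) for i, c in enumerate(CLASS_ORDER)},
        )
        if depth >= max_depth or len(np.unique(codes[idx])) == 1 or idx.size < 2:
            return node
        j, thr, gain = _best_split(X[idx], codes[idx], len(CLASS_ORDER), w)
        if j is None or gain <= 0:
            return node
        mask = X[idx, j] <= thr
        node.feature = j
        node.threshold = float(thr)
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    tree = build(np.arange(len(labels)), 0)
    tree.feature_names = feature_names  # type: ignore[attr-defined]
    return tree


def tree_to_dict(node: TreeNode, feature_names: list[str] | None = None) -> dict:
    names = feature_names or getattr(node, "feature_names", None)
    if node.is_leaf():
        return {"prediction": node.prediction, "class_fractions": node.class_fractions}
    return {
        "feature": names[node.feature] if names else node.feature,
        "threshold": node.threshold,
        "left": tree_to_dict(node.left, names),
        "right": tree_to_dict(node.right, names),
        "prediction": node.prediction,
    }


# ---------------------------------------------------------------------------
# condition-level aggregation


def aggregate_condition(scores: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Population summaries per condition.

    ``scores`` must carry (or be joined with ``metadata`` on index to carry)
    ``condition`` and optionally ``replicate`` columns alongside the class
    score columns.  Returns, per condition: mean per-cell score (x100, %),
    s.e.m. across replicate means, and the intercellular StDev of per-cell
    scores (x100).
    """
    df = scores if metadata is None else pd.concat([scores.reset_index(drop=True), metadata.reset_index(drop=True)], axis=1)
    df = df.loc[:, ~df.columns.duplicated()]
    if "condition" not in df.columns:
        raise ValueError("scores need a 'condition' column (or metadata providing it)")
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    rows = []
    for cond, g in df.groupby("condition", sort=False):
        if len(g) == 0:
            warnings.warn(f"condition {cond!r} has no cells; omitted", stacklevel=2)
            continue
        row = {"condition": cond, "n_cells": len(g)}
        rep_means = g.groupby("replicate")[list(CLASS_ORDER)].mean()
        for c in CLASS_ORDER:
            row[f"{c}_mean_pct"] = float(g[c].mean() * 100.0)
            row[f"{c}_sem_pct"] = (
                float(rep_means[c].sem() * 100.0) if len(rep_means) > 1 else float("nan")
            )
            row[f"{c}_intercell_sd_pct"] = float(g[c].std(ddof=0) * 100.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: RFModel, path) -> None:
    """Serialize forest structure and metadata to JSON (portable, text-only)."""
    payload = {
        "class_order": list(model.class_order),
        "feature_names": model.feature_names,
        "oob_error": model.oob_error,
        "training_meta": model.training_meta,
        "trees": [
            {
                "children_left": t.tree_.children_left.tolist(),
                "children_right": t.tree_.children_right.tolist(),
                "feature": t.tree_.feature.tolist(),
                "threshold": t.tree_.threshold.tolist(),
                "value": t.tree_.value[:, 0, :].tolist(),
                "classes": [str(c) for c in t.classes_],
            }
            for t in model.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


class _ArrayTree:
    """Lightweight predictor reconstructed from serialized tree arrays."""

    def __init__(self, d: dict):
        self.left = np.asarray(d["children_left"])
        self.right = np.asarray(d["children_right"])
        self.feature = np.asarray(d["feature"])
        self.threshold = np.asarray(d["threshold"])
        self.value = np.asarray(d["value"])
        self.classes_ = np.asarray(d["classes"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=object)
        for i, x in enumerate(np.asarray(X, dtype=float)):
            node = 0
            while self.left[node] != -1:
                node = self.left[node] if x[self.feature[node]] <= self.threshold[node] else self.right[node]
            out[i] = self.classes_[int(np.argmax(self.value[node]))]
        return out


def model_from_json(path) -> RFModel:
    with open(path) as fh:
        payload = json.load(fh)
    trees = [_ArrayTree(d) for d in payload["trees"]]
    return RFModel(
        trees=trees,
        feature_names=payload["feature_names"],
        bootstrap_indices=[],
        oob_indices=[np.array([], dtype=int)] * len(trees),
        oob_error=payload["oob_error"],
        class_order=tuple(payload["class_order"]),
        training_meta=payload["training_meta"],
    )
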