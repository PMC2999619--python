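"""Survival decision trees for cut-point discovery on continuous scores.

Trees are grown by recursive binary splitting: at each node every candidate
threshold — the midpoint between consecutive sorted unique values of each
predictor — is scored by the two-sample log-rank chi-square statistic, and
the best admissible split (both children at least ``min_node_size``) wins.
Ties break toward the smaller threshold, then the predictor listed first.

Model selection follows a seeded k-fold protocol: one tree per fold trained
on the other k-1 folds, scored on the held-out fold by the concordance index
between terminal-node risk ordering and the held-out survival, with the
highest-scoring tree selected.

Variable importance is the per-predictor sum of split improvements (log-rank
statistics), normalised by the maximum so the top predictor scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index

DEFAULT_PREDICTORS = ("snas", "cytoplasmic_autoscore", "cnr")


def logrank_statistic(times, events, group) -> float:
    """Two-sample log-rank chi-square for ``group`` (bool) vs the rest.

    Returns 0.0 for degenerate cases (a group empty, no events, or zero
    variance).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all() or not events.any():
        return 0.0

    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order]
    uniq, start = np.unique(t, return_index=True)
    # deaths and at-risk counts per distinct time, overall and in group 1
    d = np.add.reduceat(e.astype(float), start)
    d1 = np.add.reduceat((e & g).astype(float), start)
    n_total = len(t)
    removed = np.add.reduceat(np.ones_like(t), start)
    removed1 = np.add.reduceat(g.astype(float), start)
    n_at = n_total - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    n1_at = g.sum() - np.concatenate([[0.0], np.cumsum(removed1)[:-1]])

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * n1_at / n_at
        var = d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / np.maximum(n_at - 1, 1)
    keep = (n_at > 0) & (d > 0)
    o_minus_e = float(np.sum(d1[keep] - expected[keep]))
    v = float(np.sum(var[keep]))
    if v <= 0:
        return 0.0
    return o_minus_e * o_minus_e / v


@dataclass
class TreeNode:
    """One node; internal nodes carry a split, terminal nodes a risk summary."""

    n: int
    n_events: int
    risk: float  # events per person-month in the node (exponential MLE)
    depth: int
    predictor: str | None = None
    threshold: float | None = None
    improvement: float = 0.0
    left: "TreeNode | None" = None  # predictor <= threshold
    right: "TreeNode | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None


@dataclass
class TreeModel:
    """A fitted survival tree."""

    root: TreeNode
    predictors: tuple[str, ...]
    max_depth: int
    min_node_size: int

    @property
    def root_predictor(self) -> str | None:
        return self.root.predictor

    @property
    def root_threshold(self) -> float | None:
        return self.root.threshold

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_terminal:
                stack.extend([node.left, node.right])

    def to_dict(self) -> dict:
        def rec(node: TreeNode) -> dict:
            out = {"n": node.n, "n_events": node.n_events, "risk": node.risk,
                   "depth": node.depth}
            if not node.is_terminal:
                out.update(predictor=node.predictor, threshold=node.threshold,
                           improvement=node.improvement,
                           left=rec(node.left), right=rec(node.right))
            return out

        return {"predictors": list(self.predictors), "max_depth": self.max_depth,
                "min_node_size": self.min_node_size, "root": rec(self.root),
                "importance": variable_importance(self)}


def _logrank_scan(vals: np.ndarray, times: np.ndarray, events: np.ndarray,
                  min_node_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square for every admissible midpoint threshold of one
    predictor, computed jointly.

    Returns (thresholds, statistics); inadmissible cuts (a child smaller than
    ``min_node_size``) are dropped.  Equivalent to looping
    :func:`logrank_statistic` over ``vals <= threshold`` — the loop form is
    kept as the reference oracle in the test suite.
    """
    n = len(vals)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    # candidate cut after position c-1: left = c smallest values
    boundary = np.flatnonzero(np.diff(sorted_vals) > 0) + 1
    if boundary.size == 0:
        return np.empty(0), np.empty(0)
    thresholds = (sorted_vals[boundary - 1] + sorted_vals[boundary]) / 2.0
    admissible = (boundary >= min_node_size) & (n - boundary >= min_node_size)
    boundary, thresholds = boundary[admissible], thresholds[admissible]
    if boundary.size == 0:
        return np.empty(0), np.empty(0)

    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    tau, inv = np.unique(times[events.astype(bool)], return_inverse=True)
    k = tau.size
    if k == 0:
        return thresholds, np.zeros_like(thresholds)

    # per distinct event time: at-risk and death indicators laid out by rank
    at_risk = times[None, :] >= tau[:, None]            # k x n (patient axis)
    death = (times[None, :] == tau[:, None]) & events[None, :].astype(bool)
    at_risk_by_rank = np.empty((k, n))
    death_by_rank = np.empty((k, n))
    at_risk_by_rank[:, rank] = at_risk
    death_by_rank[:, rank] = death

    n_at = at_risk.sum(axis=1).astype(float)            # overall at-risk
    d = death.sum(axis=1).astype(float)                 # overall deaths
    cum_risk = np.cumsum(at_risk_by_rank, axis=1)
    cum_death = np.cumsum(death_by_rank, axis=1)
    n1 = cum_risk[:, boundary - 1]                      # k x cuts, left-group at-risk
    d1 = cum_death[:, boundary - 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_at[:, None]
        expected = d[:, None] * frac
        var = d[:, None] * frac * (1 - frac) * ((n_at - d) / np.maximum(n_at - 1, 1))[:, None]
    o_minus_e = np.sum(d1 - expected, axis=0)
    v = np.sum(var, axis=0)
    stats = np.where(v > 0, o_minus_e * o_minus_e / np.where(v > 0, v, 1.0), 0.0)
    return thresholds, stats


def _best_split(x: np.ndarray, times: np.ndarray, events: np.ndarray,
                predictors: tuple[str, ...], min_node_size: int):
    """Exhaustive scan over (predictor, midpoint threshold) log-rank splits.

    Ties break toward the smaller threshold, then the predictor listed first
    (implicit in scan order).
    """
    best = None  # (stat, pred_index, threshold)
    for j, _ in enumerate(predictors):
        thresholds, stats = _logrank_scan(x[:, j], times, events, min_node_size)
        if thresholds.size == 0:
            continue
        i = int(np.argmax(stats))  # argmax takes the first (smallest threshold) tie
        if stats[i] <= 0:
            continue
        if best is None or stats[i] > best[0] + 1e-12:
            best = (float(stats[i]), j, float(thresholds[i]))
    return best


def _grow(x, times, events, predictors, max_depth, min_node_size, depth) -> TreeNode:
    n = len(times)
    n_events = int(np.sum(events))
    total_time = float(np.sum(times))
    node = TreeNode(n=n, n_events=n_events,
                    risk=n_events / total_time if total_time > 0 else 0.0,
                    depth=depth)
    if depth >= max_depth or n < 2 * min_node_size:
        return node
    best = _best_split(x, times, events, predictors, min_node_size)
    if best is None:
        return node
    stat, j, thr = best
    left = x[:, j] <= thr
    node.predictor = predictors[j]
    node.threshold = thr
    node.improvement = stat
    node.left = _grow(x[left], times[left], events[left], predictors,
                      max_depth, min_node_size, depth + 1)
    node.right = _grow(x[~left], times[~left], events[~left], predictors,
                       max_depth, min_node_size, depth + 1)
    return node


def fit_survival_tree(
    scores: pd.DataFrame,
    times,
    events,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    max_depth: int = 3,
    min_node_size: int = 20,
) -> TreeModel:
    """Grow a log-rank-splitting survival tree on per-patient scores."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(scores) != len(times) or len(times) != len(events):
        raise ValueError("scores, times and events disagree on length")
    if len(times) < 2 * min_node_size:
        raise ValueError(f"need at least {2 * min_node_size} patients")
    if not events.any():
        raise ValueError("cannot fit a survival tree with no events")
    x = scores.loc[:, list(predictors)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("predictor values contain NaN; exclude undefined records first")
    root = _grow(x, times, events, tuple(predictors), max_depth, min_node_size, 0)
    return TreeModel(root=root, predictors=tuple(predictors),
                     max_depth=max_depth, min_node_size=min_node_size)


def predict_risk(model: TreeModel, scores: pd.DataFrame) -> np.ndarray:
    """Terminal-node event rate for each row (higher = worse prognosis)."""
    x = scores.loc[:, list(model.predictors)].to_numpy(dtype=float)
    out = np.empty(len(x))
    for i, row in enumerate(x):
        node = model.root
        while not node.is_terminal:
            j = model.predictors.index(node.predictor)
            node = node.left if row[j] <= node.threshold else node.right
        out[i] = node.risk
    return out


def variable_importance(model: TreeModel) -> dict[str, float]:
    """Sum of log-rank improvements per predictor, normalised to max = 1."""
    if model.root is None:
        raise ValueError("model is not fitted")
    raw = {p: 0.0 for p in model.predictors}
    for node in model.nodes():
        if not node.is_terminal:
            raw[node.predictor] += node.improvement
    top = max(raw.values())
    if top <= 0:
        return {p: 0.0 for p in model.predictors}
    return {p: v / top for p, v in raw.items()}


@dataclass
class CVResult:
    """Outcome of seeded k-fold model selection."""

    fold_assignments: np.ndarray
    models: list  # TreeModel or None for skipped folds
    accuracies: list
    selected_index: int
    selected_model: TreeModel = field(repr=False, default=None)

    @property
    def selected_predictor(self) -> str | None:
        return self.selected_model.root_predictor

    @property
    def selected_threshold(self) -> float | None:
        return self.selected_model.root_threshold

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": range(len(self.accuracies)),
            "heldout_concordance": self.accuracies,
            "selected": [i == self.selected_index for i in range(len(self.accuracies))],
        })


def select_model_cv(
    cohort: pd.DataFrame,
    time_col: str = "bcss_time",
    event_col: str = "bcss_event",
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    k: int = 10,
    seed: int = 0,
    max_depth: int = 3,
    min_node_size: int = 20,
) -> CVResult:
    """k-fold cross-validated tree selection.

    Patients are randomly partitioned into ``k`` folds (sizes differing by at
    most one); each tree is trained on the other folds and scored on its
    held-out fold by concordance between terminal-node risk and survival.
    The highest-concordance tree is selected.  Training folds without events
    are skipped with a warning.
    """
    n = len(cohort)
    if n < 50:
        raise ValueError("cross-validated selection needs n >= 50")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f

    times = cohort[time_col].to_numpy(float)
    events = cohort[event_col].to_numpy(bool)
    scores = cohort.loc[:, list(predictors)].reset_index(drop=True)

    models, accs = [], []
    for f in range(k):
        heldout = folds == f
        train = ~heldout
        if not events[train].any():
            warnings.warn(f"fold {f}: training data has no events; fold skipped")
            models.append(None)
            accs.append(-np.inf)
            continue
        model = fit_survival_tree(scores[train], times[train], events[train],
                                  predictors=predictors, max_depth=max_depth,
                                  min_node_size=min_node_size)
        risk = predict_risk(model, scores[heldout])
        if np.ptp(risk) == 0 or not events[heldout].any():
            acc = 0.5
        else:
            acc = concordance_index(times[heldout], -risk, events[heldout])
        models.append(model)
        accs.append(float(acc))

    if all(m is None for m in models):
        raise ValueError("every fold was skipped; no events available")
    selected = int(np.argmax(accs))
    return CVResult(fold_assignments=folds, models=models, accuracies=accs,
                    selected_index=selected, selected_model=models[selected])
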