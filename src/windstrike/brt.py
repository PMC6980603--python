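"""Boosted regression trees for binary presence / pseudo-absence data.

A forward-stagewise ensemble of shallow regression trees fitted to the
negative gradient of the Bernoulli deviance (logit link).  Trees are
grown best-first on squared-error improvement with at most ``tc``
splits, each scaled by the learning rate; the tree count ``nt`` is
selected by stepped k-fold cross-validation, walking down a ladder of
learning rates until the selected ensemble holds at least ``min_trees``
trees.  Interpretation tools: relative influence from squared split
improvements, partial-dependence curves, a lattice-based pairwise
interaction statistic, and backward model simplification.
"""

from __future__ import annotations

import dataclasses
import heapq
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BRTConfig:
    """Calibration parameters of the boosting procedure.

    tc: number of splits per tree (bounds interaction order).
    lr: learning rate used when fitting with a fixed tree count.
    bf: bag fraction, the share of rows drawn (without replacement) per tree.
    lr_candidates: descending learning-rate ladder for the stepped scan.
    step_size: trees added per cross-validation step.
    min_trees: the scan accepts a learning rate only once the selected
        ensemble holds at least this many trees.
    patience_steps: stop a scan after this many steps without improvement
        of the cross-validated deviance.
    """

    tc: int = 12
    lr: float = 0.005
    bf: float = 0.5
    lr_candidates: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001, 0.0005)
    step_size: int = 50
    max_trees: int = 10000
    min_node: int = 10
    k_folds: int = 10
    min_trees: int = 1000
    patience_steps: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tc < 1:
            raise ValueError("tc must be >= 1")
        if not 0.0 < self.lr < 1.0:
            raise ValueError("lr must lie in (0, 1)")
        if not 0.0 < self.bf <= 1.0:
            raise ValueError("bf must lie in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def replace(self, **kw) -> "BRTConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Regression trees
# ---------------------------------------------------------------------------


@dataclass
class RegressionTree:
    """Array-encoded binary regression tree.

    feature[i] is the split variable of node i (-1 for leaves),
    threshold[i] the split point in signed metres, left/right the child
    node ids, value[i] the terminal value (link scale, leaves only) and
    improvement[i] the squared-error improvement of the split.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    improvement: np.ndarray

    @property
    def n_splits(self) -> int:
        return int((self.feature >= 0).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(len(X), dtype=np.intp)
        feature = self.feature
        active = np.flatnonzero(feature[idx] >= 0)
        while active.size:
            node = idx[active]
            go_left = X[active, feature[node]] <= self.threshold[node]
            idx[active] = np.where(go_left, self.left[node], self.right[node])
            active = active[feature[idx[active]] >= 0]
        return self.value[idx]


_MAX_LEAF_VALUE = 4.0


def _best_split(X, r, rows, min_node):
    """Best (gain, feature, threshold) for one node, or None.

    Exhaustive scan of midpoint thresholds, vectorized over all
    features; ties break to the lowest feature index, then the lowest
    threshold, for determinism.
    """
    n = rows.size
    if n < 2 * min_node:
        return None
    Xr = X[rows]
    rr = r[rows]
    order = np.argsort(Xr, axis=0, kind="stable")
    xs = np.take_along_axis(Xr, order, axis=0)
    csum = np.cumsum(rr[order], axis=0)[:-1]
    S = rr.sum()
    base = S * S / n
    nl = np.arange(1, n, dtype=float)[:, None]
    nr = n - nl
    valid = (xs[:-1] < xs[1:]) & (nl >= min_node) & (nr >= min_node)
    if not valid.any():
        return None
    with np.errstate(invalid="ignore"):
        gains = np.where(valid, csum * csum / nl + (S - csum) ** 2 / nr - base, -np.inf)
    # per-feature argmax takes the first (lowest-threshold) maximum
    pos = np.argmax(gains, axis=0)
    per_feature = gains[pos, np.arange(gains.shape[1])]
    j = int(np.argmax(per_feature))  # first maximum -> lowest feature index
    gain = float(per_feature[j])
    if gain <= 1e-12:
        return None
    i = int(pos[j])
    return (gain, j, float((xs[i, j] + xs[i + 1, j]) / 2.0))


def fit_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    rows: np.ndarray,
    tc: int,
    min_node: int = 10,
    hessian: np.ndarray | None = None,
) -> RegressionTree:
    """Fit one regression tree to gradient residuals on the sampled rows.

    Greedy best-first growth: the leaf with the largest squared-error
    improvement is split next, up to ``tc`` splits.  Terminal values are
    the (damped) Newton step for Bernoulli loss on the in-node residuals
    when a hessian is supplied, otherwise the in-node mean residual.
    """
    rows = np.asarray(rows, dtype=np.intp)
    feature = [-1]
    threshold = [np.nan]
    left = [-1]
    right = [-1]
    improvement = [0.0]
    node_rows = {0: rows}
    heap = []
    counter = 0

    def push(node_id):
        nonlocal counter
        cand = _best_split(X, residuals, node_rows[node_id], min_node)
        if cand is not None:
            gain, j, thr = cand
            heapq.heappush(heap, (-gain, counter, node_id, j, thr))
            counter += 1

    push(0)
    splits = 0
    while heap and splits < tc:
        neg_gain, _, node_id, j, thr = heapq.heappop(heap)
        rws = node_rows.pop(node_id)
        go_left = X[rws, j] <= thr
        l_id, r_id = len(feature), len(feature) + 1
        feature[node_id] = j
        threshold[node_id] = thr
        left[node_id] = l_id
        right[node_id] = r_id
        improvement[node_id] = -neg_gain
        for child, child_rows in ((l_id, rws[go_left]), (r_id, rws[~go_left])):
            feature.append(-1)
            threshold.append(np.nan)
            left.append(-1)
            right.append(-1)
            improvement.append(0.0)
            node_rows[child] = child_rows
        push(l_id)
        push(r_id)
        splits += 1

    value = np.zeros(len(feature))
    for node_id, rws in node_rows.items():
        num = residuals[rws].sum()
        if hessian is None:
            value[node_id] = num / rws.size if rws.size else 0.0
        else:
            den = hessian[rws].sum()
            v = num / den if den > 1e-10 else 0.0
            value[node_id] = float(np.clip(v, -_MAX_LEAF_VALUE, _MAX_LEAF_VALUE))
    return RegressionTree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=value,
        improvement=np.asarray(improvement, dtype=float),
    )


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

_P_EPS = 1e-12


def bernoulli_deviance(labels, probabilities) -> float:
    """Mean Bernoulli deviance, -2*mean(y log p + (1-y) log(1-p)).

    Probabilities at or beyond {0, 1} are clamped to 1e-12 with a warning.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("probabilities outside (0, 1) clamped to 1e-12", stacklevel=2)
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# Boosting
# ---------------------------------------------------------------------------


@dataclass
class BRTModel:
    """Intercept plus learning-rate-scaled regression trees.

    Prediction on the link scale is
    ``intercept + lr * sum(tree(x) for the first nt trees)``.
    metadata carries the training arrays and any cross-validation
    results, which the interpretation tools rely on.
    """

    intercept: float
    trees: list
    lr: float
    nt: int
    var_names: tuple[str, ...]
    config: BRTConfig
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def link(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=float)
        out = np.full(len(X), self.intercept)
        for tree in self.trees[: self.nt]:
            out += self.lr * tree.predict(X)
        return out


class _Booster:
    """Incrementally growable boosting state on a fixed training matrix."""

    def __init__(self, X, y, config: BRTConfig, lr: float, seed: int):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.config = config
        self.lr = lr
        self.rng = np.random.default_rng(seed)
        p = float(np.mean(self.y))
        p = min(max(p, _P_EPS), 1.0 - _P_EPS)
        self.intercept = float(np.log(p / (1.0 - p)))
        self.F = np.full(len(self.y), self.intercept)
        self.trees: list[RegressionTree] = []
        self.holdout_X: np.ndarray | None = None
        self.holdout_F: np.ndarray | None = None

    def track_holdout(self, X_hold) -> None:
        self.holdout_X = np.ascontiguousarray(X_hold, dtype=float)
        self.holdout_F = np.full(len(self.holdout_X), self.intercept)

    def grow(self, n_trees: int) -> None:
        cfg = self.config
        n = len(self.y)
        n_bag = max(2 * cfg.min_node, int(round(cfg.bf * n)))
        n_bag = min(n_bag, n)
        for _ in range(n_trees):
            p = expit(self.F)
            residual = self.y - p
            hessian = p * (1.0 - p)
            if n_bag < n:
                rows = self.rng.choice(n, size=n_bag, replace=False)
                rows.sort()
            else:
                rows = np.arange(n)
            tree = fit_tree(self.X, residual, rows, cfg.tc, cfg.min_node, hessian)
            self.F += self.lr * tree.predict(self.X)
            if self.holdout_X is not None:
                self.holdout_F += self.lr * tree.predict(self.holdout_X)
            self.trees.append(tree)


def _as_xy(training_set):
    """Accept a TrainingSet-like object or an (X, y[, names]) tuple."""
    if hasattr(training_set, "X") and hasattr(training_set, "y"):
        names = tuple(getattr(training_set, "feature_names"))
        return training_set.X, training_set.y, names
    X, y = training_set[0], training_set[1]
    names = tuple(training_set[2]) if len(training_set) > 2 else tuple(
        f"x{j}" for j in range(np.asarray(X).shape[1])
    )
    return np.asarray(X, dtype=float), np.asarray(y), names


def boost(training_set, config: BRTConfig, nt_fixed: int) -> BRTModel:
    """Fit a boosted ensemble with a fixed number of trees."""
    X, y, names = _as_xy(training_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    booster = _Booster(X, y, config, config.lr, config.seed)
    booster.grow(nt_fixed)
    return BRTModel(
        intercept=booster.intercept,
        trees=booster.trees,
        lr=config.lr,
        nt=nt_fixed,
        var_names=names,
        config=config,
        seed=config.seed,
        metadata={"X": booster.X, "y": booster.y},
    )


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per row, stratified by label."""
    fold = np.empty(len(y), dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def _scan_learning_rate(X, y, folds, config: BRTConfig, lr: float, seed: int):
    """Grow fold models step by step; return (nt, cv curve, cv link preds)."""
    k = config.k_folds
    boosters = []
    for f in range(k):
        train = folds != f
        b = _Booster(X[train], y[train], config, lr, seed + 101 * f)
        b.track_holdout(X[~train])
        boosters.append(b)
    dev_curve: list[float] = []
    pred_history: list[np.ndarray] = []
    best_dev = np.inf
    best_step = -1
    step = 0
    while (step + 1) * config.step_size <= config.max_trees:
        cv_link = np.empty(len(y))
        for f, b in enumerate(boosters):
            b.grow(config.step_size)
            cv_link[folds == f] = b.holdout_F
        dev = bernoulli_deviance(y, expit(cv_link))
        dev_curve.append(dev)
        pred_history.append(cv_link.copy())
        if dev < best_dev - 1e-12:
            best_dev = dev
            best_step = step
        step += 1
        if step - 1 - best_step >= config.patience_steps:
            break
    nt = (best_step + 1) * config.step_size
    return nt, np.asarray(dev_curve), pred_history[best_step]


def gbm_step(training_set, config: BRTConfig | None = None) -> BRTModel:
    """Select nt by stepped k-fold cross-validation over a learning-rate ladder.

    Trees are added ``step_size`` at a time; after each step the
    cross-validated predicted deviance is evaluated on folds fixed once
    per call, and nt is the arg-min of that curve.  If the selected nt
    falls short of ``min_trees``, the next smaller candidate learning
    rate is scanned; if none reaches it, the smallest rate is returned
    with a warning.  The returned model is refitted on the full data at
    the selected (lr, nt) and carries all cross-validation results in
    its metadata.
    """
    config = config or BRTConfig()
    X, y, names = _as_xy(training_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    min_rows = max(config.k_folds, 2 * config.min_node)
    if len(y) < min_rows:
        raise ValueError(
            f"{len(y)} rows is too few for k_folds={config.k_folds} "
            f"with min_node={config.min_node} (need >= {min_rows})"
        )
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(np.asarray(y), config.k_folds, rng)

    chosen_lr = config.lr_candidates[-1]
    result = None
    for i, lr in enumerate(config.lr_candidates):
        nt, curve, cv_link = _scan_learning_rate(X, y, folds, config, lr, config.seed + 17 * i)
        result = (lr, nt, curve, cv_link)
        if nt >= config.min_trees:
            chosen_lr = lr
            break
    else:
        chosen_lr = config.lr_candidates[-1]
        warnings.warn(
            f"no learning rate in {config.lr_candidates} reached "
            f"{config.min_trees} trees; returning lr={chosen_lr} "
            f"with nt={result[1]}",
            stacklevel=2,
        )
    lr, nt, curve, cv_link = result
    model = boost((X, y, names), config.replace(lr=lr), nt)

    cv_prob = expit(cv_link)
    null_p = np.full(len(y), np.mean(y))
    null_dev = bernoulli_deviance(y, null_p)
    cv_dev = bernoulli_deviance(y, cv_prob)
    fold_dev = np.array(
        [bernoulli_deviance(y[folds == f], cv_prob[folds == f]) for f in range(config.k_folds)]
    )
    fold_null = np.array(
        [bernoulli_deviance(y[folds == f], null_p[folds == f]) for f in range(config.k_folds)]
    )
    fold_dev_explained = 100.0 * (fold_null - fold_dev) / fold_null
    fold_auc = []
    for f in range(config.k_folds):
        yy = y[folds == f]
        if len(np.unique(yy)) == 2:
            fold_auc.append(roc_auc(yy, cv_prob[folds == f]))
    model.metadata.update(
        {
            "folds": folds,
            "cv_deviance_curve": curve,
            "cv_link": cv_link,
            "null_deviance": null_dev,
            "cv_deviance": cv_dev,
            "cv_dev_explained": 100.0 * (null_dev - cv_dev) / null_dev,
            "cv_dev_explained_se": float(
                np.std(fold_dev_explained, ddof=1) / np.sqrt(config.k_folds)
            ),
            "fold_deviances": fold_dev,
            "cv_auc_fold_mean": float(np.mean(fold_auc)) if fold_auc else np.nan,
            "cv_auc_pooled": roc_auc(y, cv_prob),
        }
    )
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(model: BRTModel, features, scale: str = "probability") -> np.ndarray:
    """Predict on the link or probability scale.

    features may be a DataFrame (columns selected by the model's
    variable names; a missing column raises KeyError naming it) or an
    array whose columns already match the model's variable order.
    """
    if scale not in ("link", "probability"):
        raise ValueError(f"unknown scale {scale!r}")
    if isinstance(features, pd.DataFrame):
        missing = [v for v in model.var_names if v not in features.columns]
        if missing:
            raise KeyError(f"missing feature columns: {', '.join(missing)}")
        X = features[list(model.var_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.var_names):
            raise ValueError(
                f"expected {len(model.var_names)} feature columns, got {X.shape[1]}"
            )
    link = model.link(X)
    return link if scale == "link" else expit(link)


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------


def relative_influence(model: BRTModel) -> pd.Series:
    """Relative influence (%) per variable from squared split improvements.

    Sums the squared-error improvement of every split over the first nt
    trees, per variable, and normalizes to percentages (sum 100).
    """
    totals = np.zeros(len(model.var_names))
    for tree in model.trees[: model.nt]:
        internal = tree.feature >= 0
        np.add.at(totals, tree.feature[internal], tree.improvement[internal])
    total = totals.sum()
    if total <= 0:
        raise ValueError("model has no splits; influence undefined")
    series = pd.Series(100.0 * totals / total, index=list(model.var_names), name="influence")
    return series.sort_values(ascending=False, kind="stable")


@dataclass
class PDPCurve:
    """Marginal fitted function of one variable on the link scale."""

    variable: str
    grid: np.ndarray
    values: np.ndarray


def _training_X(model: BRTModel) -> np.ndarray:
    X = model.metadata.get("X")
    if X is None:
        raise ValueError("model carries no training data; cannot marginalize")
    return X


def _quantile_grid(x: np.ndarray, n_grid: int) -> np.ndarray:
    grid = np.quantile(x, np.linspace(0.0, 1.0, n_grid))
    return np.unique(grid)


def partial_dependence(model: BRTModel, variable: str, n_grid: int = 100) -> PDPCurve:
    """Partial-dependence curve: training rows averaged, one variable swept.

    The grid holds ``n_grid`` equally spaced quantiles of the training
    values of the variable (deduplicated, strictly increasing); the
    value at each grid point is the mean link-scale prediction with the
    variable overwritten by that point.
    """
    if variable not in model.var_names:
        raise KeyError(f"unknown variable {variable!r}")
    X = _training_X(model)
    j = model.var_names.index(variable)
    grid = _quantile_grid(X[:, j], n_grid)
    Xmod = X.copy()
    values = np.empty(grid.size)
    for g_i, g in enumerate(grid):
        Xmod[:, j] = g
        values[g_i] = float(np.mean(model.link(Xmod)))
    return PDPCurve(variable, grid, values)


def interaction_size(
    model: BRTModel, var_i: str, var_j: str, grid_size: int = 15
) -> float:
    """Pairwise interaction statistic from an additive lattice fit.

    Computes the two-variable partial-dependence surface on a
    ``grid_size`` x ``grid_size`` lattice of training quantiles, fits
    the additive model value ~ a + f(level_i) + g(level_j) by least
    squares (one coefficient per lattice level, i.e. the two-way
    row/column-mean decomposition), and returns 1000 times the mean
    squared residual.  Zero for an exactly additive model; symmetric in
    its arguments.
    """
    if var_i == var_j:
        raise ValueError("interaction requires two distinct variables")
    for v in (var_i, var_j):
        if v not in model.var_names:
            raise KeyError(f"unknown variable {v!r}")
    X = _training_X(model)
    i = model.var_names.index(var_i)
    j = model.var_names.index(var_j)
    grid_i = _quantile_grid(X[:, i], grid_size)
    grid_j = _quantile_grid(X[:, j], grid_size)
    surface = np.empty((grid_i.size, grid_j.size))
    Xmod = X.copy()
    for a, gi in enumerate(grid_i):
        Xmod[:, i] = gi
        for b, gj in enumerate(grid_j):
            Xmod[:, j] = gj
            surface[a, b] = float(np.mean(model.link(Xmod)))
    # additive least-squares fit == row/column mean decomposition
    residual = (
        surface
        - surface.mean(axis=1, keepdims=True)
        - surface.mean(axis=0, keepdims=True)
        + surface.mean()
    )
    return float(1000.0 * np.mean(residual**2))


def simplify(
    model: BRTModel,
    training_set,
    max_drop: int,
    match_tc_to_predictors: bool = True,
):
    """Backward simplification: drop the least influential variables.

    Iteratively removes the currently least-influential variable and
    refits via :func:`gbm_step` on the retained set, up to ``max_drop``
    drops, recording the cross-validated deviance after each.  When the
    original tree complexity equals the predictor count (the convention
    of tying interaction depth to the number of variables),
    ``match_tc_to_predictors`` shrinks tc alongside.  Returns the final
    refit and a drop report DataFrame.
    """
    X, y, names = _as_xy(training_set)
    if tuple(names) != tuple(model.var_names):
        raise ValueError("training-set features do not match the model's variables")
    if max_drop >= len(names):
        raise ValueError(
            f"max_drop={max_drop} must be smaller than the number of variables"
        )
    report_rows = []
    current = model
    current_names = list(names)
    name_to_col = {n: k for k, n in enumerate(names)}
    for _ in range(max_drop):
        influence = relative_influence(current)
        weakest = influence.index[-1]
        current_names = [n for n in current_names if n != weakest]
        cols = [name_to_col[n] for n in current_names]
        cfg = current.config
        if match_tc_to_predictors and cfg.tc == len(current_names) + 1:
            cfg = cfg.replace(tc=len(current_names))
        current = gbm_step((X[:, cols], y, tuple(current_names)), cfg)
        report_rows.append(
            {
                "dropped": weakest,
                "n_retained": len(current_names),
                "cv_deviance": current.metadata["cv_deviance"],
                "nt": current.nt,
                "lr": current.lr,
            }
        )
    report = pd.DataFrame(report_rows)
    return current, report


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def roc_auc(labels, scores) -> float:
    """Rank-statistic AUC with ties counted half (Mann-Whitney)."""
    from scipy.stats import rankdata

    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Discrimination and calibration summary of a fitted model."""

    auc: float
    sensitivity: float
    one_minus_specificity: float
    threshold: float
    cv_dev_explained: float | None = None
    cv_dev_explained_se: float | None = None
    fold_deviances: list | None = None
    cv_auc_fold_mean: float | None = None
    cv_auc_pooled: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["fold_deviances"] is not None:
            d["fold_deviances"] = [float(v) for v in d["fold_deviances"]]
        return d


def evaluate(model: BRTModel, held_out, threshold_rule="youden") -> EvalReport:
    """Evaluate on a held-out set: AUC, sensitivity and 1-specificity.

    threshold_rule is "youden" (maximize sensitivity + specificity - 1)
    or a fixed probability threshold.  Cross-validation statistics are
    copied from the model's metadata when present.
    """
    X, y, names = _as_xy(held_out)
    if len(np.unique(y)) < 2:
        raise ValueError("held-out set contains a single class")
    prob = predict(model, (pd.DataFrame(X, columns=list(names)) if names != model.var_names else X))
    auc = roc_auc(y, prob)
    y = np.asarray(y)
    if threshold_rule == "youden":
        cands = np.unique(prob)
        best_t, best_j = cands[0], -np.inf
        n_pos = (y == 1).sum()
        n_neg = (y == 0).sum()
        for t in cands:
            pred = prob >= t
            sens = (pred & (y == 1)).sum() / n_pos
            spec = (~pred & (y == 0)).sum() / n_neg
            if sens + spec - 1.0 > best_j + 1e-12:
                best_j = sens + spec - 1.0
                best_t = t
        threshold = float(best_t)
    else:
        threshold = float(threshold_rule)
    pred = prob >= threshold
    sens = float((pred & (y == 1)).sum() / (y == 1).sum())
    spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
    md = model.metadata
    return EvalReport(
        auc=auc,
        sensitivity=sens,
        one_minus_specificity=1.0 - spec,
        threshold=threshold,
        cv_dev_explained=md.get("cv_dev_explained"),
        cv_dev_explained_se=md.get("cv_dev_explained_se"),
        fold_deviances=(
            list(md["fold_deviances"]) if "fold_deviances" in md else None
        ),
        cv_auc_fold_mean=md.get("cv_auc_fold_mean"),
        cv_auc_pooled=md.get("cv_auc_pooled"),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_json(model: BRTModel, path=None) -> str:
    """Serialize a model (trees, intercept, lr, nt, variables) to JSON."""
    payload = {
        "intercept": model.intercept,
        "lr": model.lr,
        "nt": model.nt,
        "var_names": list(model.var_names),
        "seed": model.seed,
        "config": dataclasses.asdict(model.config),
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": [None if np.isnan(v) else v for v in t.threshold],
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
                "improvement": t.improvement.tolist(),
            }
            for t in model.trees
        ],
    }
    text = json.dumps(payload)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def model_from_json(source) -> BRTModel:
    """Load a model serialized by :func:`model_to_json` (path or JSON text)."""
    try:
        with open(source) as fh:
            payload = json.load(fh)
    except (OSError, TypeError):
        payload = json.loads(source)
    cfg = payload["config"]
    cfg["lr_candidates"] = tuple(cfg["lr_candidates"])
    trees = [
        RegressionTree(
            feature=np.asarray(t["feature"], dtype=np.int32),
            threshold=np.asarray(
                [np.nan if v is None else v for v in t["threshold"]], dtype=float
            ),
            left=np.asarray(t["left"], dtype=np.int32),
            right=np.asarray(t["right"], dtype=np.int32),
            value=np.asarray(t["value"], dtype=float),
            improvement=np.asarray(t["improvement"], dtype=float),
        )
        for t in payload["trees"]
    ]
    return BRTModel(
        intercept=payload["intercept"],
        trees=trees,
        lr=payload["lr"],
        nt=payload["nt"],
        var_names=tuple(payload["var_names"]),
        config=BRTConfig(**cfg),
        seed=payload["seed"],
    )
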