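"""Recursive random-forest feature selection with balanced sampling.

High-dimensional screening stage: a random forest is grown on all current
features, each tree on a balanced bootstrap (minority-class-size stratified
resample) so that the rare asthma class is not ignored; out-of-bag (OOB)
votes give per-class misclassification rates and a permutation variable
importance measure (VIM, mean decrease in OOB accuracy).  The half of the
features with the smallest VIMs is dropped and the procedure repeats until
the case-class misclassification levels off; the feature set of the
levelling-off iteration is passed to the association stage.

Trees are sklearn ``DecisionTreeClassifier``s; bootstrapping, OOB vote
aggregation and the OOB permutation importance are implemented here
(sklearn's forest offers neither minority-size balanced bootstraps nor
per-tree OOB permutation importance).  OOB predictions traverse the fitted
tree arrays with a vectorized numpy walk, which keeps the permutation VIM
affordable at thousands of features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .data import MValueMatrix

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Random-forest and recursion settings.

    ``ntree`` and ``mtry_fraction`` default to the screening configuration
    used for 450k-scale data (7500 trees, 10% of current predictors per
    split).  ``level_off_tolerance`` is on the case-class misclassification
    scale: 0 selects the fewest-feature iteration attaining the minimum.
    """

    ntree: int = 7500
    mtry_fraction: float = 0.10
    balanced: bool = True
    vim_kind: str = "permutation_accuracy"  # or "gini"
    min_features: int = 10
    level_off_tolerance: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.mtry_fraction <= 1):
            raise ValueError("mtry_fraction must be in (0, 1]")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.vim_kind not in ("permutation_accuracy", "gini"):
            raise ValueError(f"unknown vim_kind {self.vim_kind!r}")


@dataclass
class ForestFit:
    """Aggregated OOB results of one forest."""

    oob_misclassification: float
    oob_by_class: dict[int, float]
    vim: np.ndarray
    n_trees: int
    n_never_oob: int = 0


@dataclass
class IterationRecord:
    iteration: int
    n_features: int
    oob_misclassification: float
    oob_case: float
    oob_control: float
    feature_ids: tuple[str, ...]
    vim: np.ndarray


@dataclass
class SelectionTrace:
    """Per-iteration record of the recursive selection."""

    iterations: list[IterationRecord] = field(default_factory=list)
    selected_iteration: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": it.iteration,
                    "n_features": it.n_features,
                    "oob_misclassification": it.oob_misclassification,
                    "oob_case": it.oob_case,
                    "oob_control": it.oob_control,
                    "selected": it.iteration == self.selected_iteration,
                }
                for it in self.iterations
            ]
        ).set_index("iteration")

    def vim_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            for fid, v in zip(it.feature_ids, it.vim):
                rows.append({"iteration": it.iteration, "feature_id": fid, "vim": v})
        return pd.DataFrame(rows)


def feature_count_schedule(n_start: int, iteration: int) -> int:
    """Feature count at a given iteration of the halving schedule.

    Iteration 1 is the full set; each following iteration keeps the better
    half, ``floor(n_start / 2^(iteration-1))`` (odd counts keep floor(n/2)).
    """
    if n_start < 1:
        raise ValueError("n_start must be >= 1")
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    count = n_start >> (iteration - 1) if iteration - 1 < n_start.bit_length() else 0
    if count == 0:
        raise ValueError(f"schedule exhausted at iteration {iteration} (n_start={n_start})")
    return count


def _tree_leaf_ids(tree, X: np.ndarray) -> np.ndarray:
    """Vectorized traversal: leaf node id for each row of X."""
    t = tree.tree_
    feature = t.feature
    threshold = t.threshold
    left = t.children_left
    right = t.children_right
    node = np.zeros(X.shape[0], dtype=np.intp)
    active = np.flatnonzero(feature[node] >= 0)
    while active.size:
        nd = node[active]
        go_left = X[active, feature[nd]] <= threshold[nd]
        node[active] = np.where(go_left, left[nd], right[nd])
        active = active[feature[node[active]] >= 0]
    return node


def grow_forest(X, y, config: RFConfig, rng: np.random.Generator | None = None) -> ForestFit:
    """Grow a balanced-bootstrap forest; return OOB errors and VIMs.

    Parameters
    ----------
    X : array (n_samples, n_features)
        Predictor matrix without missing values (mean-impute beforehand).
    y : array of {0, 1}
        Binary outcome; both classes must be present.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    if p == 0:
        raise ValueError("no features")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; mean-impute before growing the forest")
    classes = np.unique(y)
    if classes.size != 2 or set(classes) != {0, 1}:
        raise ValueError("y must contain both classes coded {0, 1}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n_min = min(idx0.size, idx1.size)
    mtry = max(1, int(np.floor(config.mtry_fraction * p)))

    votes = np.zeros((n, 2), dtype=np.int64)
    vim = np.zeros(p)
    in_bag = np.zeros(n, dtype=bool)
    for _ in range(config.ntree):
        if config.balanced:
            boot = np.concatenate(
                [
                    rng.choice(idx0, size=n_min, replace=True),
                    rng.choice(idx1, size=n_min, replace=True),
                ]
            )
        else:
            boot = rng.choice(n, size=n, replace=True)
        in_bag[:] = False
        in_bag[boot] = True
        oob = np.flatnonzero(~in_bag)
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if config.vim_kind == "gini":
            vim += tree.feature_importances_
        if oob.size == 0:
            continue
        t = tree.tree_
        leaf_class = tree.classes_[np.argmax(t.value[:, 0, :], axis=1)]
        X_oob = X[oob]
        pred = leaf_class[_tree_leaf_ids(tree, X_oob)]
        votes[oob, pred] += 1
        if config.vim_kind == "permutation_accuracy":
            acc_base = float(np.mean(pred == y[oob]))
            used = np.unique(t.feature[t.feature >= 0])
            if used.size:
                X_perm = X_oob.copy()
                for f in used:
                    saved = X_perm[:, f].copy()
                    X_perm[:, f] = saved[rng.permutation(oob.size)]
                    pred_f = leaf_class[_tree_leaf_ids(tree, X_perm)]
                    vim[f] += acc_base - float(np.mean(pred_f == y[oob]))
                    X_perm[:, f] = saved
    vim /= config.ntree

    voted = votes.sum(axis=1) > 0
    n_never = int(n - voted.sum())
    if n_never:
        logger.debug("%d samples never out-of-bag; excluded from OOB error", n_never)
    # deterministic tie-break: ties go to the control class (0)
    hard_pred = (votes[:, 1] > votes[:, 0]).astype(np.int64)
    wrong = (hard_pred != y) & voted
    overall = float(wrong.sum() / max(voted.sum(), 1))
    by_class = {}
    for c in (0, 1):
        mask = voted & (y == c)
        by_class[c] = float(wrong[mask].sum() / max(mask.sum(), 1))
    return ForestFit(
        oob_misclassification=overall,
        oob_by_class=by_class,
        vim=vim,
        n_trees=config.ntree,
        n_never_oob=n_never,
    )


def mean_impute(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace missing values by the per-feature mean; returns imputed count."""
    X = np.array(X, dtype=np.float64, copy=True)
    missing = np.isnan(X)
    n_imputed = int(missing.sum())
    if n_imputed:
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    return X, n_imputed


def recursive_select(
    X, y, config: RFConfig, feature_ids=None
) -> tuple[SelectionTrace, list[str]]:
    """Iterate grow -> rank by VIM -> keep the top half until levelling off.

    ``X`` may be an :class:`MValueMatrix`, DataFrame or ndarray (with
    ``feature_ids``).  Missing values are mean-imputed per feature before
    forest fitting (association models elsewhere remain complete-case).

    The selected iteration is the largest (fewest features) whose
    case-class OOB misclassification is within ``level_off_tolerance`` of
    the minimum over all iterations; its feature set is returned.
    VIM ties are broken by feature order (stable sort).
    """
    if isinstance(X, MValueMatrix):
        feature_ids = X.feature_ids
        X = X.values
    elif isinstance(X, pd.DataFrame):
        feature_ids = X.columns.tolist()
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(X.shape[1])]
    feature_ids = list(feature_ids)
    y = np.asarray(y, dtype=np.int64)
    X, n_imputed = mean_impute(X)
    if n_imputed:
        logger.info("mean-imputed %d missing values before forest fitting", n_imputed)

    rng = np.random.default_rng(config.rng_seed)
    n_start = X.shape[1]
    current = np.arange(n_start)
    trace = SelectionTrace()
    iteration = 0
    while current.size >= config.min_features:
        iteration += 1
        assert current.size == feature_count_schedule(n_start, iteration)
        fit = grow_forest(np.ascontiguousarray(X[:, current]), y, config, rng=rng)
        trace.iterations.append(
            IterationRecord(
                iteration=iteration,
                n_features=int(current.size),
                oob_misclassification=fit.oob_misclassification,
                oob_case=fit.oob_by_class[1],
                oob_control=fit.oob_by_class[0],
                feature_ids=tuple(feature_ids[i] for i in current),
                vim=fit.vim,
            )
        )
        keep = current.size // 2
        if keep < 1:
            break
        order = np.argsort(-fit.vim, kind="stable")  # ties -> feature order
        current = current[np.sort(order[:keep])]

    if not trace.iterations:
        raise ValueError("no iterations run; fewer features than min_features")
    case_errors = np.array([it.oob_case for it in trace.iterations])
    threshold = case_errors.min() + config.level_off_tolerance
    k_star = int(np.max(np.flatnonzero(case_errors <= threshold + 1e-12)))
    trace.selected_iteration = trace.iterations[k_star].iteration
    selected = list(trace.iterations[k_star].feature_ids)
    return trace, selected
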