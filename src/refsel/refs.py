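"""Recursive ensemble feature selection (REFS).

At each step of a geometric elimination schedule, eight heterogeneous
classifiers are fitted to the current feature set; each classifier's feature
importances (impurity-based for tree ensembles, absolute coefficient
magnitudes for linear models) are L1-normalized and averaged into one merged
score; the lowest-scoring 20% of features are dropped; and the step is
graded by stratified 10-fold cross-validated accuracy per classifier.  The
whole descent is repeated over several stochastic runs, the signature size
is the feature count maximizing mean accuracy (ties toward the smaller,
more parsimonious size), and the final signature is assembled from per-gene
selection frequencies across runs.

Two evaluation modes are provided.  The default ("protocol") mode scores and
eliminates on all samples and uses cross-validation only to grade each
feature count — accuracies at small counts are therefore optimistically
biased by feature selection.  With ``nested_selection=True`` the elimination
is refit inside each training fold and only out-of-fold accuracy is
recorded, giving an unbiased estimate of the whole procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, ConsistencyError, DegenerateDataError

logger = logging.getLogger("refsel")

#: The eight-classifier roster, in canonical order.
DEFAULT_ROSTER = (
    "gradient_boosting",
    "passive_aggressive",
    "logistic_regression",
    "linear_svc",
    "random_forest",
    "sgd",
    "ridge",
    "bagging",
)

TREE_KINDS = frozenset({"gradient_boosting", "random_forest", "bagging"})
COEF_KINDS = frozenset({"passive_aggressive", "logistic_regression", "linear_svc", "sgd", "ridge"})


@dataclass(frozen=True)
class RefsConfig:
    """REFS hyperparameters.

    ``first_cutoff`` is a single truncation applied before the geometric
    descent starts; ``step_rate`` is the fraction of features removed per
    step.  ``nested_selection`` switches to out-of-fold accuracy with
    per-fold elimination (see module docstring).  ``tree_importance``
    chooses between impurity-based importances (default) and a literal
    per-feature split count for the tree ensembles.
    """

    roster: tuple[str, ...] = DEFAULT_ROSTER
    first_cutoff: int = 1000
    step_rate: float = 0.2
    n_runs: int = 10
    n_folds: int = 10
    stratified: bool = True
    nested_selection: bool = False
    tree_importance: str = "impurity"
    seed: int = 0

    def __post_init__(self):
        if not self.roster:
            raise ConfigurationError("roster must not be empty")
        unknown = [k for k in self.roster if k not in TREE_KINDS | COEF_KINDS]
        if unknown:
            raise ConfigurationError(f"unknown classifier kind(s): {unknown}")
        if not 0.0 < self.step_rate < 1.0:
            raise ConfigurationError(f"step_rate must be in (0, 1), got {self.step_rate}")
        if self.first_cutoff < 1:
            raise ConfigurationError(f"first_cutoff must be >= 1, got {self.first_cutoff}")
        if self.n_folds < 2:
            raise ConfigurationError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_runs < 1:
            raise ConfigurationError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.tree_importance not in ("impurity", "split_count"):
            raise ConfigurationError(f"unknown tree_importance {self.tree_importance!r}")


@dataclass(frozen=True)
class FeatureScoreTable:
    """Per-classifier normalized importances and their merged mean."""

    per_classifier: pd.DataFrame  # features x classifier kinds, each column sums to 1
    merged: pd.Series  # mean over classifier columns

    @property
    def ranking(self) -> list[str]:
        """Feature ids best-first; ties broken by original feature order."""
        order = np.argsort(-self.merged.to_numpy(), kind="stable")
        return [self.merged.index[i] for i in order]


@dataclass(frozen=True)
class TraceStep:
    k: int
    kept_ids: tuple[str, ...]
    accuracies: dict[str, float]  # per classifier kind
    mean_accuracy: float
    #: merged scores that selected this step's kept set (None on the first step)
    scores: dict[str, float] | None = None


@dataclass(frozen=True)
class ReductionTrace:
    steps: tuple[TraceStep, ...]
    run_seed: int
    nested: bool = False

    @property
    def schedule(self) -> tuple[int, ...]:
        return tuple(s.k for s in self.steps)

    def step_at(self, k: int) -> TraceStep:
        for s in self.steps:
            if s.k == k:
                return s
        raise KeyError(f"no step with k={k} in this trace")


@dataclass(frozen=True)
class Signature:
    """Consensus signature: genes ordered by cross-run selection strength."""

    gene_ids: tuple[str, ...]
    selection_frequency: pd.Series  # over all genes seen at k_star in any run
    k_star: int


# ---------------------------------------------------------------------------
# classifier roster

# Ensemble sizes are desk-scale defaults chosen for tiny cohorts (tens of
# samples), where large forests add runtime but little signal; they can be
# overridden per kind via `classifier_overrides` in make_classifier.
_TREE_PARAMS = {
    "gradient_boosting": dict(n_estimators=8, max_depth=1),
    "random_forest": dict(n_estimators=8),
    "bagging": dict(n_estimators=4),
}


def make_classifier(kind: str, seed: int, overrides: dict | None = None):
    """Instantiate one roster classifier with a deterministic seed."""
    params = dict(_TREE_PARAMS.get(kind, {}))
    if overrides:
        params.update(overrides)
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "bagging":
        return BaggingClassifier(DecisionTreeClassifier(), random_state=seed, **params)
    if kind == "passive_aggressive":
        # the passive-aggressive update expressed through SGD (hinge loss,
        # no penalty, PA-I learning rate)
        return SGDClassifier(
            loss="hinge", penalty=None, learning_rate="pa1", eta0=1.0, random_state=seed, **params
        )
    if kind == "logistic_regression":
        return LogisticRegression(max_iter=200, solver="liblinear", random_state=seed, **params)
    if kind == "linear_svc":
        # linear kernel so coefficient-based feature scoring is defined
        return LinearSVC(max_iter=1000, **params)
    if kind == "sgd":
        return SGDClassifier(random_state=seed, **params)
    if kind == "ridge":
        return RidgeClassifier(**params)
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


def extract_importance(kind: str, model, n_features: int, method: str = "impurity") -> np.ndarray:
    """Raw (unnormalized) non-negative importance vector of a fitted model.

    Tree ensembles yield impurity-based importances (or literal split
    counts with ``method="split_count"``); linear models yield absolute
    coefficient magnitudes.
    """
    if kind in TREE_KINDS:
        if method == "split_count":
            imp = _split_counts(kind, model, n_features)
        elif kind == "bagging":
            imp = np.zeros(n_features)
            for est, feats in zip(model.estimators_, model.estimators_features_):
                imp[np.asarray(feats)] += est.feature_importances_
            imp /= len(model.estimators_)
        else:
            imp = np.asarray(model.feature_importances_, dtype=float)
    elif kind in COEF_KINDS:
        imp = np.abs(np.asarray(model.coef_, dtype=float)).ravel()
    else:
        raise ConfigurationError(f"unknown classifier kind {kind!r}")
    if imp.shape != (n_features,):
        raise ConsistencyError(
            f"{kind}: importance vector has shape {imp.shape}, expected ({n_features},)"
        )
    return imp


def _split_counts(kind: str, model, n_features: int) -> np.ndarray:
    counts = np.zeros(n_features)
    if kind == "gradient_boosting":
        trees = [t for row in model.estimators_ for t in row]
        feats_list = [None] * len(trees)
    else:
        trees = model.estimators_
        feats_list = getattr(model, "estimators_features_", [None] * len(trees))
    for tree, feats in zip(trees, feats_list):
        used = tree.tree_.feature
        used = used[used >= 0]
        if feats is not None:
            used = np.asarray(feats)[used]
        np.add.at(counts, used, 1.0)
    return counts


def _l1_normalize(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if not np.isfinite(total) or total <= 0:
        return np.full(v.shape, 1.0 / len(v))
    return v / total


# ---------------------------------------------------------------------------
# schedule

def reduction_schedule(n_features: int, cfg: RefsConfig) -> list[int]:
    """Feature counts visited by the descent, from ``n_features`` down to 1.

    If ``n_features`` exceeds the first cutoff, a single truncation to the
    cutoff precedes the geometric descent ``k -> max(1, floor((1-rate)*k))``
    (clamped to strictly decrease for tiny rates).
    """
    if n_features < 1:
        raise ConfigurationError(f"n_features must be >= 1, got {n_features}")
    schedule = [n_features]
    k = n_features
    if n_features > cfg.first_cutoff:
        k = cfg.first_cutoff
        schedule.append(k)
    while k > 1:
        k = max(1, min(k - 1, int(np.floor((1.0 - cfg.step_rate) * k))))
        schedule.append(k)
    return schedule


# ---------------------------------------------------------------------------
# scoring & cross-validation

def _check_two_classes(y: np.ndarray):
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("both classes must be present")


def _score_array(
    X: np.ndarray, y: np.ndarray, cfg: RefsConfig, seed: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Fit every roster classifier and return normalized + merged scores."""
    _check_two_classes(y)
    per: dict[str, np.ndarray] = {}
    n_features = X.shape[1]
    for kind in cfg.roster:
        clf = make_classifier(kind, seed)
        clf.fit(X, y)
        raw = extract_importance(kind, clf, n_features, method=cfg.tree_importance)
        per[kind] = _l1_normalize(raw)
    merged = np.mean(np.stack(list(per.values())), axis=0)
    return per, merged


def score_features(
    matrix: pd.DataFrame, y: Sequence[int], cfg: RefsConfig, run_seed: int
) -> FeatureScoreTable:
    """Merged ensemble importance scores for a genes x samples matrix."""
    y = np.asarray(y).astype(int)
    X = np.ascontiguousarray(matrix.to_numpy(dtype=float).T)
    with sklearn.config_context(assume_finite=True):
        per, merged = _score_array(X, y, cfg, run_seed)
    table = pd.DataFrame(per, index=matrix.index)
    return FeatureScoreTable(per_classifier=table, merged=pd.Series(merged, index=matrix.index))


def _make_splitter(cfg: RefsConfig, seed: int):
    cls = StratifiedKFold if cfg.stratified else KFold
    return cls(n_splits=cfg.n_folds, shuffle=True, random_state=seed)


def _check_foldable(y: np.ndarray, cfg: RefsConfig):
    if cfg.stratified:
        smallest = np.bincount(y).min()
        if smallest < cfg.n_folds:
            raise DegenerateDataError(
                f"smallest class has {smallest} members, fewer than n_folds="
                f"{cfg.n_folds}; use fewer folds"
            )


def _cv_array(X: np.ndarray, y: np.ndarray, cfg: RefsConfig, seed: int) -> dict[str, float]:
    """Per-classifier mean fold accuracy under a seeded k-fold split."""
    _check_two_classes(y)
    _check_foldable(y, cfg)
    folds = list(_make_splitter(cfg, seed).split(X, y))
    accs = {kind: 0.0 for kind in cfg.roster}
    for train_idx, test_idx in folds:
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        for kind in cfg.roster:
            clf = make_classifier(kind, seed)
            clf.fit(X_tr, y_tr)
            accs[kind] += float((clf.predict(X_te) == y_te).mean())
    return {kind: total / len(folds) for kind, total in accs.items()}


@dataclass(frozen=True)
class CvResult:
    accuracies: dict[str, float]
    mean_accuracy: float


def evaluate_cv(
    matrix: pd.DataFrame, y: Sequence[int], cfg: RefsConfig, run_seed: int
) -> CvResult:
    """Stratified k-fold accuracy per roster classifier plus their mean."""
    y = np.asarray(y).astype(int)
    X = np.ascontiguousarray(matrix.to_numpy(dtype=float).T)
    with sklearn.config_context(assume_finite=True):
        accs = _cv_array(X, y, cfg, run_seed)
    return CvResult(accuracies=accs, mean_accuracy=float(np.mean(list(accs.values()))))


# ---------------------------------------------------------------------------
# the descent

def _top_k(kept: np.ndarray, merged: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k positions by merged score, ties broken by original feature order."""
    order = np.argsort(-merged, kind="stable")[:k]
    order = np.sort(order)  # preserve original ordering within the kept set
    return kept[order], merged[order]


def run_refs_once(
    matrix: pd.DataFrame, y: Sequence[int], cfg: RefsConfig, run_seed: int
) -> ReductionTrace:
    """One full elimination descent; see the module docstring for the modes."""
    y = np.asarray(y).astype(int)
    if matrix.shape[1] != len(y):
        raise ConsistencyError(
            f"matrix has {matrix.shape[1]} samples but y has {len(y)} entries"
        )
    ids = np.asarray(matrix.index)
    X = np.ascontiguousarray(matrix.to_numpy(dtype=float).T)
    sched = reduction_schedule(len(ids), cfg)
    seeds = np.random.SeedSequence(run_seed).generate_state(2 * len(sched) + 1).astype(np.int64)
    seeds = (seeds % (2**31)).astype(int)
    with sklearn.config_context(assume_finite=True):
        if cfg.nested_selection:
            steps = _descend_nested(X, y, ids, sched, cfg, seeds)
        else:
            steps = _descend_protocol(X, y, ids, sched, cfg, seeds)
    return ReductionTrace(steps=tuple(steps), run_seed=run_seed, nested=cfg.nested_selection)


def _descend_protocol(X, y, ids, sched, cfg, seeds) -> list[TraceStep]:
    kept = np.arange(len(ids))
    steps: list[TraceStep] = []
    for i, k in enumerate(sched):
        scores = None
        if k < kept.size:
            _, merged = _score_array(X[:, kept], y, cfg, int(seeds[2 * i]))
            kept, kept_scores = _top_k(kept, merged, k)
            scores = dict(zip(ids[kept], kept_scores.astype(float)))
        accs = _cv_array(X[:, kept], y, cfg, int(seeds[2 * i + 1]))
        mean_acc = float(np.mean(list(accs.values())))
        logger.info("refs step: k=%d mean_cv_accuracy=%.4f", k, mean_acc)
        steps.append(
            TraceStep(
                k=k,
                kept_ids=tuple(ids[kept]),
                accuracies=accs,
                mean_accuracy=mean_acc,
                scores=scores,
            )
        )
    return steps


def _descend_nested(X, y, ids, sched, cfg, seeds) -> list[TraceStep]:
    """Per-fold elimination with out-of-fold accuracy; kept sets from full data."""
    _check_two_classes(y)
    _check_foldable(y, cfg)
    folds = list(_make_splitter(cfg, int(seeds[-1])).split(X, y))
    fold_seeds = np.random.SeedSequence(int(seeds[-1]) + 1).generate_state(
        len(folds) * len(sched)
    ).astype(np.int64) % (2**31)

    acc = {kind: np.zeros(len(sched)) for kind in cfg.roster}
    for f, (train_idx, test_idx) in enumerate(folds):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        kept = np.arange(len(ids))
        for i, k in enumerate(sched):
            if k < kept.size:
                _, merged = _score_array(
                    X_tr[:, kept], y_tr, cfg, int(fold_seeds[f * len(sched) + i])
                )
                kept, _ = _top_k(kept, merged, k)
            for kind in cfg.roster:
                clf = make_classifier(kind, int(fold_seeds[f * len(sched) + i]))
                clf.fit(X_tr[:, kept], y_tr)
                acc[kind][i] += float((clf.predict(X_te[:, kept]) == y_te).mean())
    for kind in acc:
        acc[kind] /= len(folds)

    # full-data elimination path provides the reported kept sets
    kept = np.arange(len(ids))
    steps: list[TraceStep] = []
    for i, k in enumerate(sched):
        scores = None
        if k < kept.size:
            _, merged = _score_array(X[:, kept], y, cfg, int(seeds[2 * i]))
            kept, kept_scores = _top_k(kept, merged, k)
            scores = dict(zip(ids[kept], kept_scores.astype(float)))
        accs = {kind: float(acc[kind][i]) for kind in cfg.roster}
        mean_acc = float(np.mean(list(accs.values())))
        logger.info("refs step (nested): k=%d mean_oof_accuracy=%.4f", k, mean_acc)
        steps.append(
            TraceStep(
                k=k,
                kept_ids=tuple(ids[kept]),
                accuracies=accs,
                mean_accuracy=mean_acc,
                scores=scores,
            )
        )
    return steps


def derive_run_seeds(seed: int, n_runs: int) -> list[int]:
    """Deterministic per-run seeds (< 2^31) derived from the ensemble seed."""
    return [
        int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        for r in range(n_runs)
    ]


def run_refs_ensemble(
    matrix: pd.DataFrame, y: Sequence[int], cfg: RefsConfig
) -> list[ReductionTrace]:
    """``cfg.n_runs`` independent descents with seeds derived from ``cfg.seed``."""
    traces = []
    for r, run_seed in enumerate(derive_run_seeds(cfg.seed, cfg.n_runs)):
        logger.info("refs run %d/%d (run_seed=%d)", r + 1, cfg.n_runs, run_seed)
        traces.append(run_refs_once(matrix, y, cfg, run_seed))
    return traces


# ---------------------------------------------------------------------------
# aggregation across runs

def select_optimal_size(traces: Sequence[ReductionTrace]) -> int:
    """Feature count maximizing mean CV accuracy over runs and classifiers.

    Exact ties are broken toward the smaller (more parsimonious) size.
    """
    if not traces:
        raise ConsistencyError("no traces given")
    sched = traces[0].schedule
    if any(t.schedule != sched for t in traces):
        raise ConsistencyError("traces do not share a common schedule")
    best_k, best_acc = None, -np.inf
    for i, k in enumerate(sched):
        acc = float(np.mean([t.steps[i].mean_accuracy for t in traces]))
        if acc >= best_acc:  # >= so later (smaller) k wins ties
            best_k, best_acc = k, acc
    return int(best_k)


def consensus_signature(traces: Sequence[ReductionTrace], k_star: int) -> Signature:
    """Top ``k_star`` genes by cross-run selection frequency at ``k_star``.

    Frequency ties are broken by mean merged score (over the runs where the
    gene was selected), then by original feature order.
    """
    if not traces:
        raise ConsistencyError("no traces given")
    feature_order = {g: i for i, g in enumerate(traces[0].steps[0].kept_ids)}
    counts: dict[str, int] = {}
    score_sums: dict[str, float] = {}
    score_counts: dict[str, int] = {}
    for t in traces:
        step = t.step_at(k_star)
        for g in step.kept_ids:
            counts[g] = counts.get(g, 0) + 1
            if step.scores is not None and g in step.scores:
                score_sums[g] = score_sums.get(g, 0.0) + step.scores[g]
                score_counts[g] = score_counts.get(g, 0) + 1

    def mean_score(g: str) -> float:
        return score_sums.get(g, 0.0) / score_counts[g] if score_counts.get(g) else 0.0

    genes = sorted(
        counts,
        key=lambda g: (-counts[g], -mean_score(g), feature_order.get(g, len(feature_order)), g),
    )
    freq = pd.Series({g: counts[g] / len(traces) for g in genes}, name="selection_frequency")
    return Signature(
        gene_ids=tuple(genes[:k_star]), selection_frequency=freq, k_star=int(k_star)
    )


# ---------------------------------------------------------------------------
# tidy exports

def traces_to_frame(traces: Sequence[ReductionTrace]) -> pd.DataFrame:
    """Tidy per-(run, k, classifier) accuracy table for export/plotting."""
    records = []
    for r, t in enumerate(traces):
        for step in t.steps:
            for kind, acc in step.accuracies.items():
                records.append({"run": r, "k": step.k, "classifier": kind, "accuracy": acc})
    return pd.DataFrame.from_records(records, columns=["run", "k", "classifier", "accuracy"])


def signature_to_frame(sig: Signature, traces: Sequence[ReductionTrace]) -> pd.DataFrame:
    """Signature export: gene, selection frequency, mean merged score."""
    score_sums: dict[str, float] = {}
    score_counts: dict[str, int] = {}
    for t in traces:
        step = t.step_at(sig.k_star)
        if step.scores:
            for g, s in step.scores.items():
                score_sums[g] = score_sums.get(g, 0.0) + s
                score_counts[g] = score_counts.get(g, 0) + 1
    rows = [
        {
            "gene_id": g,
            "frequency": float(sig.selection_frequency[g]),
            "mean_score": score_sums.get(g, 0.0) / score_counts[g] if score_counts.get(g) else 0.0,
        }
        for g in sig.gene_ids
    ]
    return pd.DataFrame.from_records(rows, columns=["gene_id", "frequency", "mean_score"])
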