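"""Baseline-relative concept encoding and boolean rule extraction.

The interpretable track of the pipeline turns expression values into binary
*concepts* — for each gene, "down" (below the healthy-control mean) or "up"
(its complement) — and then searches for a small disjunction of short
conjunctions of concepts (a DNF) that predicts responder status.  Candidate
concepts are screened by information gain, conjunctions up to a maximum
length are enumerated over the screened set, and rules are added greedily by
additional positive-class coverage subject to a minimum training precision.

This is a transparent, exhaustively checkable realization of the
concept-rule contract; a neural concept learner could be slotted in behind
the same interfaces (see :func:`extract_rules`'s ``candidate_generator``
hook).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import ConsistencyError, DegenerateDataError
from .io import CohortLabels

DOWN = "down"
UP = "up"


def concept_label(gene_id: str, direction: str) -> str:
    """Canonical column label for a (gene, direction) concept."""
    return f"{direction}({gene_id})"


def parse_concept(label: str) -> tuple[str, str | None]:
    """Invert :func:`concept_label`; plain concept names map to (name, None)."""
    for d in (DOWN, UP):
        if label.startswith(d + "(") and label.endswith(")"):
            return label[len(d) + 1 : -1], d
    return label, None


def concept_genes(labels: Iterable[str]) -> set[str]:
    return {parse_concept(c)[0] for c in labels}


@dataclass(frozen=True)
class LogicRule:
    """A conjunction of concept literals, e.g. down(G1) AND down(G2)."""

    literals: tuple[str, ...]

    def __post_init__(self):
        if not self.literals:
            raise ConsistencyError("a rule needs at least one literal")
        genes = [parse_concept(c)[0] for c in self.literals]
        if len(set(genes)) != len(genes):
            raise ConsistencyError(f"gene repeated within rule {self.literals}")

    def predict(self, concepts: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(concepts), dtype=bool)
        for lit in self.literals:
            mask &= concepts[lit].to_numpy(dtype=bool)
        return mask

    @property
    def genes(self) -> set[str]:
        return {parse_concept(c)[0] for c in self.literals}

    def __str__(self) -> str:
        return " AND ".join(self.literals)


@dataclass
class RuleSet:
    """A disjunction of conjunctive rules with its evaluation metrics."""

    rules: list[LogicRule] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def predict(self, concepts: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(concepts), dtype=bool)
        for rule in self.rules:
            out |= rule.predict(concepts)
        return out

    @property
    def genes(self) -> set[str]:
        return set().union(*(r.genes for r in self.rules)) if self.rules else set()

    @property
    def concepts(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            for lit in r.literals:
                seen.setdefault(lit)
        return list(seen)

    def __str__(self) -> str:
        if not self.rules:
            return "<empty rule set>"
        return "\n".join(f"IF {r} THEN responder" for r in self.rules)


def compute_baseline(matrix: pd.DataFrame, labels: CohortLabels) -> pd.Series:
    """Per-gene mean expression over the healthy-control samples."""
    controls = labels.control_ids
    if not controls:
        raise DegenerateDataError(
            "no control samples: the rule stage needs a healthy-control baseline"
        )
    return matrix[controls].mean(axis=1)


def binarize_concepts(
    matrix: pd.DataFrame, labels: CohortLabels, baseline: pd.Series
) -> pd.DataFrame:
    """Encode each patient sample as down/up concepts against the baseline.

    ``down(g)`` is 1 iff the sample's value for gene ``g`` is strictly below
    the control mean (a value exactly on the baseline counts as "up"); the
    ``up`` concept is its complement.  Controls are not encoded.
    """
    missing = matrix.index.difference(baseline.index)
    if len(missing):
        raise ConsistencyError(f"baseline missing for genes: {list(missing)[:10]}")
    patients = labels.patient_ids
    values = matrix.loc[:, patients].to_numpy(dtype=float)
    base = baseline.loc[matrix.index].to_numpy(dtype=float)[:, None]
    down = (values < base).T  # samples x genes
    cols: list[str] = []
    data = np.empty((down.shape[0], 2 * down.shape[1]), dtype=bool)
    for j, gene in enumerate(matrix.index):
        data[:, 2 * j] = down[:, j]
        data[:, 2 * j + 1] = ~down[:, j]
        cols.append(concept_label(gene, DOWN))
        cols.append(concept_label(gene, UP))
    return pd.DataFrame(data, index=patients, columns=cols)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(concept: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (bits) between a binary concept and the class."""
    concept = np.asarray(concept, dtype=bool)
    y = np.asarray(y)
    if concept.shape != y.shape:
        raise ConsistencyError("concept and class vectors must have equal length")
    n = len(y)
    h_y = _entropy(np.bincount(y.astype(int)) / n)
    h_cond = 0.0
    for v in (False, True):
        mask = concept == v
        if mask.any():
            h_cond += mask.mean() * _entropy(np.bincount(y[mask].astype(int)) / mask.sum())
    return h_y - h_cond


def _information_gain_columns(C: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized per-column information gain for a boolean matrix."""
    n = len(y)
    pos = y.astype(bool)
    n1 = C.sum(axis=0).astype(float)
    n0 = n - n1
    p1 = (C & pos[:, None]).sum(axis=0).astype(float)  # concept=1, y=1
    p0 = pos.sum() - p1  # concept=0, y=1

    def h(p, tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(tot > 0, p / np.maximum(tot, 1), 0.0)
            t1 = np.where((q > 0) & (q < 1), -q * np.log2(np.where(q > 0, q, 1)), 0.0)
            t2 = np.where((q > 0) & (q < 1), -(1 - q) * np.log2(np.where(q < 1, 1 - q, 1)), 0.0)
        return t1 + t2

    h_y = _entropy(np.bincount(y.astype(int)) / n)
    cond = (n1 / n) * h(p1, n1) + (n0 / n) * h(p0, n0)
    return h_y - cond


def extract_rules(
    concepts: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_len: int = 3,
    top_k_concepts: int = 10,
    min_precision: float = 0.8,
    coverage_target: float = 0.95,
    split_seed: int = 0,
    test_fraction: float = 0.3,
    candidate_generator: Callable[[Sequence[str], int], Iterable[tuple[str, ...]]] | None = None,
) -> RuleSet:
    """Learn a DNF of concept conjunctions predicting the positive class.

    The concepts are screened to the ``top_k_concepts`` by information gain
    on the training split; all conjunctions of length <= ``max_len`` over the
    screened concepts (skipping contradictory same-gene pairs) are candidate
    rules; rules with training precision >= ``min_precision`` are added
    greedily by additional true-positive coverage until ``coverage_target``
    of the training positives is covered or no candidate helps.  Accuracy of
    the disjunction is reported on the training and held-out splits.

    ``candidate_generator`` replaces the exhaustive conjunction enumerator;
    it receives the screened concept labels and ``max_len`` and yields
    literal tuples, allowing an external concept learner to propose rules
    while keeping screening, greedy merging and metrics unchanged.
    """
    y = np.asarray(y).astype(int)
    if max_len < 1:
        raise ConsistencyError("max_len must be >= 1")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("both classes must be present to extract rules")

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=split_seed, stratify=y
    )
    C = concepts.to_numpy(dtype=bool)
    C_tr, y_tr = C[train_idx], y[train_idx]
    C_te, y_te = C[test_idx], y[test_idx]

    gains = _information_gain_columns(C_tr, y_tr)
    order = np.argsort(-gains, kind="stable")[:top_k_concepts]
    screened = [concepts.columns[i] for i in order]
    col_of = {c: i for i, c in enumerate(concepts.columns)}

    if candidate_generator is None:
        candidate_generator = _enumerate_conjunctions
    candidates: list[tuple[str, ...]] = []
    for lits in candidate_generator(screened, max_len):
        genes = [parse_concept(c)[0] for c in lits]
        if len(set(genes)) == len(genes):
            candidates.append(tuple(lits))

    masks_tr = np.stack(
        [np.logical_and.reduce(C_tr[:, [col_of[c] for c in lits]], axis=1) for lits in candidates]
    ) if candidates else np.zeros((0, len(y_tr)), dtype=bool)

    pos_tr = y_tr.astype(bool)
    n_pos = int(pos_tr.sum())
    covered = np.zeros(len(y_tr), dtype=bool)
    chosen: list[int] = []
    while True:
        best = None  # (gain, precision, -length, -index)
        for i, m in enumerate(masks_tr):
            if i in chosen:
                continue
            fired = int(m.sum())
            if fired == 0:
                continue
            precision = float((m & pos_tr).sum()) / fired
            if precision < min_precision:
                continue
            gain = int((m & pos_tr & ~covered).sum())
            if gain == 0:
                continue
            key = (gain, precision, -len(candidates[i]), -i)
            if best is None or key > best[0]:
                best = (key, i)
        if best is None:
            break
        chosen.append(best[1])
        covered |= masks_tr[best[1]] & pos_tr
        if n_pos and covered.sum() / n_pos >= coverage_target:
            break

    rules = [LogicRule(candidates[i]) for i in chosen]
    rs = RuleSet(rules=rules)
    if not rules:
        warnings.warn(
            "no candidate rule met the precision threshold; returning an empty rule set",
            UserWarning,
            stacklevel=2,
        )
    pred_tr = rs.predict(concepts.iloc[train_idx])
    pred_te = rs.predict(concepts.iloc[test_idx])
    rs.metrics = {
        "train_accuracy": float((pred_tr == y_tr.astype(bool)).mean()),
        "test_accuracy": float((pred_te == y_te.astype(bool)).mean()),
        "train_positive_coverage": float(covered.sum() / n_pos) if n_pos else 0.0,
        "per_rule": [
            _rule_metrics(masks_tr[i], pos_tr) for i in chosen
        ],
        "split_seed": split_seed,
    }
    return rs


def _enumerate_conjunctions(screened: Sequence[str], max_len: int):
    for length in range(1, max_len + 1):
        yield from itertools.combinations(screened, length)


def _rule_metrics(mask: np.ndarray, pos: np.ndarray) -> dict:
    fired = int(mask.sum())
    tp = int((mask & pos).sum())
    return {
        "precision": tp / fired if fired else 0.0,
        "coverage": tp / int(pos.sum()) if pos.sum() else 0.0,
    }


def evaluate_ruleset(
    rs: RuleSet,
    concepts: pd.DataFrame,
    y: np.ndarray | pd.Series,
    reference: np.ndarray | None = None,
) -> dict:
    """Accuracy, per-rule precision/coverage, and fidelity to a reference.

    An empty rule set predicts all-negative, so its accuracy equals one
    minus the positive-class prevalence.
    """
    y = np.asarray(y).astype(bool)
    pred = rs.predict(concepts)
    out = {
        "accuracy": float((pred == y).mean()),
        "per_rule": [_rule_metrics(r.predict(concepts), y) for r in rs.rules],
    }
    if reference is not None:
        out["fidelity"] = float((pred == np.asarray(reference).astype(bool)).mean())
    return out


def rulesets_equivalent(a: RuleSet, b: RuleSet) -> bool:
    """Exact logical equivalence of two DNFs by truth-table enumeration.

    Enumerates every assignment of the union of referenced concepts, so it
    is only suitable for small rule sets (<= ~20 distinct concepts).  Note
    that complementarity of down/up concepts for the same gene is *not*
    assumed: concepts are treated as free boolean variables.
    """
    names = sorted(set(a.concepts) | set(b.concepts))
    if len(names) > 20:
        raise ConsistencyError("too many concepts for truth-table comparison")
    n = len(names)
    assignments = np.array(
        [[(row >> i) & 1 for i in range(n)] for row in range(2**n)], dtype=bool
    )
    table = pd.DataFrame(assignments, columns=names)
    return bool(np.array_equal(a.predict(table), b.predict(table)))


def format_ruleset(rs: RuleSet) -> str:
    """Human-readable export: one rule per line plus a metrics block."""
    lines = [str(rs)]
    if rs.metrics:
        lines.append("")
        lines.append("metric\tvalue")
        for key in ("train_accuracy", "test_accuracy", "train_positive_coverage"):
            if key in rs.metrics:
                lines.append(f"{key}\t{rs.metrics[key]:.6f}")
        for i, m in enumerate(rs.metrics.get("per_rule", []), start=1):
            lines.append(f"rule{i}_precision\t{m['precision']:.6f}")
            lines.append(f"rule{i}_coverage\t{m['coverage']:.6f}")
    return "\n".join(lines) + "\n"
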