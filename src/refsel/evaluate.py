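"""ROC/AUC evaluation of a signature and cross-track comparison.

AUC is reported per roster classifier from out-of-fold decision scores
pooled across the stratified folds (one curve per classifier, matching the
deterministic "single pooled curve" convention rather than per-fold curve
averaging).  Scores are probability-like where the classifier provides one
and signed decision values otherwise; the kind used is recorded per
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import ConsistencyError, DegenerateDataError
from .io import GROUP_CONTROL, GROUP_NONRESPONDER, GROUP_RESPONDER, CohortLabels
from .refs import RefsConfig, Signature, _make_splitter, make_classifier


@dataclass(frozen=True)
class RocResult:
    """Per-classifier pooled-fold ROC curves and AUCs."""

    curves: dict[str, tuple[np.ndarray, np.ndarray]]  # kind -> (fpr, tpr)
    auc: dict[str, float]
    score_kind: dict[str, str]  # "probability" or "decision"


@dataclass(frozen=True)
class OverlapReport:
    refs_signature: tuple[str, ...]
    rule_genes: tuple[str, ...]
    intersection: tuple[str, ...]
    union: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "refs": len(self.refs_signature),
            "rules": len(self.rule_genes),
            "intersection": len(self.intersection),
            "union": len(self.union),
        }


def roc_auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """AUC: probability a random positive outranks a random negative (ties half)."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("AUC requires both classes to be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _decision_scores(clf, X: np.ndarray) -> tuple[np.ndarray, str]:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1], "probability"
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X), "decision"
    return clf.predict(X).astype(float), "prediction"


def pooled_cv_roc(
    matrix: pd.DataFrame, y: Sequence[int], cfg: RefsConfig, seed: int | None = None
) -> RocResult:
    """Out-of-fold scores pooled over the folds, then one ROC/AUC per classifier.

    ``matrix`` is the genes x samples expression matrix restricted to the
    signature genes (patient samples only, aligned with ``y``).
    """
    if matrix.shape[0] == 0:
        raise ConsistencyError("signature is empty; nothing to evaluate")
    y = np.asarray(y).astype(int)
    X = np.ascontiguousarray(matrix.to_numpy(dtype=float).T)
    if seed is None:
        seed = cfg.seed
    folds = list(_make_splitter(cfg, seed).split(X, y))
    curves, aucs, kinds = {}, {}, {}
    with sklearn.config_context(assume_finite=True):
        for kind in cfg.roster:
            oof = np.empty(len(y), dtype=float)
            used = "decision"
            for train_idx, test_idx in folds:
                clf = make_classifier(kind, seed)
                clf.fit(X[train_idx], y[train_idx])
                oof[test_idx], used = _decision_scores(clf, X[test_idx])
            fpr, tpr, _ = roc_curve(y, oof)
            curves[kind] = (fpr, tpr)
            aucs[kind] = float(roc_auc_score(y, oof))
            kinds[kind] = used
    return RocResult(curves=curves, auc=aucs, score_kind=kinds)


def signature_overlap(refs_sig: Signature | Sequence[str], rule_genes: Sequence[str]) -> OverlapReport:
    """Exact set intersection/union between the two discovery tracks."""
    refs_genes = list(refs_sig.gene_ids) if isinstance(refs_sig, Signature) else list(refs_sig)
    a, b = set(refs_genes), set(rule_genes)
    return OverlapReport(
        refs_signature=tuple(sorted(a)),
        rule_genes=tuple(sorted(b)),
        intersection=tuple(sorted(a & b)),
        union=tuple(sorted(a | b)),
    )


def export_signature_matrix(
    matrix: pd.DataFrame,
    labels: CohortLabels,
    signature: Signature | Sequence[str],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Signature-restricted matrix with samples grouped for heatmap plotting.

    Columns are ordered responders, then non-responders, then controls;
    rows are the signature genes in signature order.  Optionally written as
    a TSV.
    """
    genes = list(signature.gene_ids) if isinstance(signature, Signature) else list(signature)
    if not genes:
        raise ConsistencyError("signature is empty")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ConsistencyError(f"signature gene(s) not in matrix: {missing}")
    order = []
    for group in (GROUP_RESPONDER, GROUP_NONRESPONDER, GROUP_CONTROL):
        order.extend(labels.groups.index[labels.groups == group])
    out = matrix.loc[genes, order]
    if path is not None:
        out.to_csv(path, sep="\t", index_label="gene_id")
    return out


def roc_to_frames(result: RocResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy exports: (classifier, fpr, tpr) points and a (classifier, auc) summary."""
    records = []
    for kind, (fpr, tpr) in result.curves.items():
        for f, t in zip(fpr, tpr):
            records.append({"classifier": kind, "fpr": float(f), "tpr": float(t)})
    points = pd.DataFrame.from_records(records, columns=["classifier", "fpr", "tpr"])
    summary = pd.DataFrame(
        {
            "classifier": list(result.auc),
            "auc": [result.auc[k] for k in result.auc],
            "score_kind": [result.score_kind[k] for k in result.auc],
        }
    )
    return points, summary


def format_overlap(report: OverlapReport) -> str:
    """Key-value text export of an overlap report."""
    lines = [
        f"refs_signature\t{','.join(report.refs_signature)}",
        f"rule_genes\t{','.join(report.rule_genes)}",
        f"intersection\t{','.join(report.intersection)}",
        f"union\t{','.join(report.union)}",
    ]
    for key, value in report.counts.items():
        lines.append(f"n_{key}\t{value}")
    return "\n".join(lines) + "\n"
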