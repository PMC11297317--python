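"""Localization calls, F1, and the AUC/F1 evaluation report.

AUC is macro-averaged over the 7 categories: per-label ROC-AUC over
proteins, skipping labels without both a positive and a negative in the
truth (such labels are listed in the report).  F1 is micro-averaged over
all (protein, label) decisions at the model threshold.  Both conventions
are recorded in every report so results are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from locdiff.categories import CATEGORIES
from locdiff.locmodel.model import LocalizationCall, ProbVector


def call_localizations(prob: ProbVector, threshold: float) -> LocalizationCall:
    """Labels whose probability strictly exceeds the threshold (may be empty)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    labels = frozenset(c for c, p in zip(CATEGORIES, prob.p) if p > threshold)
    return LocalizationCall(prob.protein_id, prob.condition, labels, threshold)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall; 0 when precision+recall is 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    auc: float
    f1: float
    per_label: dict[str, dict] = field(default_factory=dict)
    skipped_labels: list[str] = field(default_factory=list)
    threshold: float = 0.5
    auc_averaging: str = "macro over labels"
    f1_averaging: str = "micro over (protein,label) decisions"
    provenance: dict = field(default_factory=dict)


def evaluate(probs: list[ProbVector], truth: dict[str, frozenset[str]],
             threshold: float = 0.5) -> EvalReport:
    """Score probability vectors against known label sets."""
    missing = [p.protein_id for p in probs if p.protein_id not in truth]
    if missing:
        raise ValueError(f"no truth labels for proteins: {missing[:5]}")
    P = np.array([p.p for p in probs], dtype=float)
    Y = np.array([[1.0 if c in truth[p.protein_id] else 0.0 for c in CATEGORIES]
                  for p in probs])
    per_label: dict[str, dict] = {}
    skipped: list[str] = []
    aucs = []
    for j, cat in enumerate(CATEGORIES):
        y = Y[:, j]
        entry: dict = {"n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum())}
        if 0 < y.sum() < len(y):
            entry["auc"] = float(roc_auc_score(y, P[:, j]))
            aucs.append(entry["auc"])
        else:
            skipped.append(cat)
        pred = P[:, j] > threshold
        entry["tp"] = int(np.sum(pred & (y == 1)))
        entry["fp"] = int(np.sum(pred & (y == 0)))
        entry["fn"] = int(np.sum(~pred & (y == 1)))
        entry["f1"] = f1_score(entry["tp"], entry["fp"], entry["fn"])
        per_label[cat] = entry
    tp = sum(e["tp"] for e in per_label.values())
    fp = sum(e["fp"] for e in per_label.values())
    fn = sum(e["fn"] for e in per_label.values())
    return EvalReport(
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        f1=f1_score(tp, fp, fn),
        per_label=per_label,
        skipped_labels=skipped,
        threshold=threshold,
    )
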