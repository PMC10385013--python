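"""DDI evaluation: per-class and micro P/R/F1 plus the 5x5 confusion matrix.

The headline metric follows the DDIExtraction2013 "detection and
classification" convention: micro-averaged precision/recall/F1 with
TP/FP/FN pooled over the four positive interaction classes only
(``mechanism``, ``effect``, ``advice``, ``int``); the ``negative`` class is
excluded from the pooling.  An all-class micro variant is also reported
for comparison.  The 0/0 convention maps undefined ratios to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .corpus_io import CLASS_ORDER

POSITIVE_CLASSES = tuple(c for c in CLASS_ORDER if c != "negative")


@dataclass
class EvalReport:
    per_class: pd.DataFrame        # rows = CLASS_ORDER, cols = P/R/F1/support
    micro_precision: float         # pooled over positive classes
    micro_recall: float
    micro_f1: float
    micro_f1_all: float            # pooled over all five classes
    confusion: pd.DataFrame        # counts, gold rows x predicted columns
    confusion_prop: pd.DataFrame   # row-normalized proportions

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class.to_dict(orient="index"),
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "micro_f1_all": self.micro_f1_all,
            "confusion": self.confusion.values.tolist(),
            "class_order": list(CLASS_ORDER),
        }

    def confusion_tsv(self) -> str:
        return self.confusion.to_csv(sep="\t")


def evaluate_predictions(pred: list[str], gold: list[str]) -> EvalReport:
    """Score predicted against gold labels over the five-class schema."""
    if len(pred) != len(gold):
        raise ValueError("prediction and gold lists differ in length")
    known = set(CLASS_ORDER)
    for lab in list(pred) + list(gold):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    labels = list(CLASS_ORDER)
    p, r, f, s = precision_recall_fscore_support(
        gold, pred, labels=labels, zero_division=0,
    )
    per_class = pd.DataFrame(
        {"precision": p, "recall": r, "f1": f, "support": s}, index=labels,
    )
    mp, mr, mf, _ = precision_recall_fscore_support(
        gold, pred, labels=list(POSITIVE_CLASSES), average="micro",
        zero_division=0,
    )
    _, _, mf_all, _ = precision_recall_fscore_support(
        gold, pred, labels=labels, average="micro", zero_division=0,
    )
    cm = confusion_matrix(gold, pred, labels=labels)
    conf = pd.DataFrame(cm, index=labels, columns=labels)
    row_sums = cm.sum(axis=1, keepdims=True)
    prop = np.divide(cm, np.where(row_sums == 0, 1, row_sums), dtype=float)
    return EvalReport(
        per_class=per_class,
        micro_precision=float(mp),
        micro_recall=float(mr),
        micro_f1=float(mf),
        micro_f1_all=float(mf_all),
        confusion=conf,
        confusion_prop=pd.DataFrame(prop, index=labels, columns=labels),
    )


def micro_f1(pred: list[str], gold: list[str]) -> float:
    """Micro-F1 pooled over the four positive classes (headline metric)."""
    return evaluate_predictions(pred, gold).micro_f1
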