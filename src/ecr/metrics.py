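"""Confusion-count bookkeeping, accuracy/MCC, and sub-sampling validation.

Conventions: FLIP is the positive class.  TP = FLIP predicted FLIP,
TN = FunC predicted FunC, FP = FunC predicted FLIP, FN = FLIP predicted
FunC.  Accuracy is (TP+TN)/total; the Matthews correlation coefficient is

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the common convention MCC = 0 when any factor of the denominator is
zero.  Percentages are displayed rounded half-up to one decimal and MCC to
two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import classify
from .exceptions import DegenerateDataError, InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_from_labels(
    true_labels: list[str], predicted: list[str], positive: str = classify.FLIP
) -> ConfusionCounts:
    if len(true_labels) != len(predicted):
        raise InputError("label/prediction length mismatch")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise DegenerateDataError("accuracy undefined for empty counts")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if c.total == 0:
        raise DegenerateDataError("MCC undefined for empty counts")
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(math.prod(factors))


def auxiliary_rates(c: ConfusionCounts) -> dict[str, float | None]:
    """Precision, sensitivity, specificity, NPV; None where undefined."""

    def rate(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return {
        "precision": rate(c.tp, c.tp + c.fp),
        "sensitivity": rate(c.tp, c.tp + c.fn),
        "specificity": rate(c.tn, c.tn + c.fp),
        "npv": rate(c.tn, c.tn + c.fn),
    }


def format_percent(fraction: float) -> str:
    """Round half-up to one decimal, e.g. 0.7625 -> '76.3%'."""
    q = Decimal(str(fraction * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def format_mcc(value: float) -> str:
    return str(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Two-round evaluation report


def two_round_report(
    round1: ConfusionCounts, round2: ConfusionCounts | None
) -> pd.DataFrame:
    """Per-round and total rows of accuracy/MCC from confusion counts.

    The total row combines FLIP predictions across rounds: TP/FP accumulate
    over both clusterings while FN/TN are the round-2 leftovers (round-1
    non-FLIP rows all proceed to round 2).
    """
    rows = []
    rows.append(("1st clustering", round1))
    if round2 is not None:
        rows.append(("2nd clustering", round2))
        total = ConfusionCounts(
            tp=round1.tp + round2.tp,
            fp=round1.fp + round2.fp,
            fn=round2.fn,
            tn=round2.tn,
        )
        rows.append(("Total", total))
    records = []
    for name, c in rows:
        records.append(
            {
                "round": name,
                "TP": c.tp,
                "FP": c.fp,
                "FN": c.fn,
                "TN": c.tn,
                "accuracy": accuracy(c),
                "mcc": mcc(c),
                "accuracy_pct": format_percent(accuracy(c)),
                "mcc_2dp": format_mcc(mcc(c)),
            }
        )
    return pd.DataFrame.from_records(records)


def round_confusions(
    model: classify.ClassificationModel, labels: list[str]
) -> tuple[ConfusionCounts, ConfusionCounts | None]:
    """Per-round confusion counts for a trained model against true labels.

    Round 1 counts treat FLIP-cluster membership as the FLIP prediction over
    all rows; round 2 counts cover only its own input rows.
    """
    n = len(labels)
    r1_pred = [classify.FUNC] * n
    for i in model.round1_member_idx:
        r1_pred[i] = classify.FLIP
    c1 = confusion_from_labels(labels, r1_pred)
    if model.round2 is None:
        return c1, None
    idx2 = model.round2_input_idx
    in_flip2 = model.round2.clustering.assignments == model.round2.flip_cluster
    r2_pred = [classify.FLIP if f else classify.FUNC for f in in_flip2]
    r2_true = [labels[i] for i in idx2]
    return c1, confusion_from_labels(r2_true, r2_pred)


# ---------------------------------------------------------------------------
# Random sub-sampling validation


def subsample_validation(
    matrix: classify.FeatureMatrix,
    fractions: list[float],
    replicates: int = 3,
    seed: int = classify.DEFAULT_SEED,
    restarts: int = classify.DEFAULT_RESTARTS,
) -> pd.DataFrame:
    """Retrain on random row subsets and record accuracy/MCC per draw.

    For each fraction and replicate a simple random sample of rows (no
    stratification, no replacement) is drawn, the two-round classifier is
    retrained on it, and its training accuracy/MCC against the true labels
    recorded.  Fraction 1.0 reproduces the full-training result exactly.
    Subsamples too small to train are recorded as NA with a reason.
    """
    if matrix.labels is None:
        raise InputError("sub-sampling validation requires labelled data")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise InputError(f"fraction {f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for fraction in fractions:
        for rep in range(replicates):
            k = int(round(fraction * matrix.n))
            idx = np.sort(rng.choice(matrix.n, size=k, replace=False))
            sub = matrix.subset(idx)
            rec = {"fraction": fraction, "replicate": rep + 1, "n": k}
            try:
                model = classify.train_two_round(sub, seed=seed, restarts=restarts)
                c = confusion_from_labels(sub.labels, model.predictions)
                rec.update(accuracy=accuracy(c), mcc=mcc(c), note="")
            except DegenerateDataError as exc:
                rec.update(accuracy=np.nan, mcc=np.nan, note=str(exc))
            records.append(rec)
    return pd.DataFrame.from_records(records)
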