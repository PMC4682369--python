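"""Evaluation machinery: confusion-matrix metrics, repeated stratified
k-fold cross-validation, homology filtering, and independent testing.

Metrics follow the usual definitions: Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total, and the Matthews correlation coefficient

    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

with MCC defined as 0 when any factor under the root vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .seq_windows import PeptideWindow


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsPanel:
    Sn: float
    Sp: float
    Acc: float
    MCC: float


def metrics(cm: ConfusionMatrix) -> MetricsPanel:
    """Sensitivity, specificity, accuracy, and MCC for one matrix."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    sn = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else float("nan")
    sp = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP else float("nan")
    acc = (cm.TP + cm.TN) / cm.total
    denom = (
        (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TP + cm.FP) * (cm.TN + cm.FN)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cm.TP * cm.TN - cm.FN * cm.FP) / math.sqrt(denom)
    return MetricsPanel(Sn=sn, Sp=sp, Acc=acc, MCC=mcc)


def confusion_from_calls(
    pos_calls: np.ndarray, neg_calls: np.ndarray
) -> ConfusionMatrix:
    """Build a matrix from boolean positive-calls on each true class."""
    pos_calls = np.asarray(pos_calls, dtype=bool)
    neg_calls = np.asarray(neg_calls, dtype=bool)
    return ConfusionMatrix(
        TP=int(pos_calls.sum()),
        FN=int((~pos_calls).sum()),
        FP=int(neg_calls.sum()),
        TN=int((~neg_calls).sum()),
    )


# ---------------------------------------------------------------------------
# Cross-validation

Trainer = Callable[[Sequence[PeptideWindow], Sequence[PeptideWindow]], object]


@dataclass
class CVResult:
    """Averaged panel plus one panel per evaluation fold and per round."""

    mean: MetricsPanel
    per_fold: list  # MetricsPanel per (round, fold)
    per_round: list  # MetricsPanel per round (folds pooled)
    confusion: ConfusionMatrix  # pooled over everything

    def report(self) -> pd.DataFrame:
        """Tabular report: one row per fold, per-round pooled rows, and
        the overall average (columns TP, FN, TN, FP, Sn, Sp, Acc, MCC)."""
        rows = []
        for k, (cm, panel) in enumerate(self.per_fold):
            rows.append(
                {
                    "round": k // self._folds_per_round,
                    "fold": k % self._folds_per_round,
                    "TP": cm.TP, "FN": cm.FN, "TN": cm.TN, "FP": cm.FP,
                    "Sn": panel.Sn, "Sp": panel.Sp,
                    "Acc": panel.Acc, "MCC": panel.MCC,
                }
            )
        cm = self.confusion
        rows.append(
            {
                "round": "mean", "fold": "",
                "TP": cm.TP, "FN": cm.FN, "TN": cm.TN, "FP": cm.FP,
                "Sn": self.mean.Sn, "Sp": self.mean.Sp,
                "Acc": self.mean.Acc, "MCC": self.mean.MCC,
            }
        )
        return pd.DataFrame(rows)

    _folds_per_round: int = 5


def stratified_kfold(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    trainer: Trainer,
    k: int = 5,
    repeats: int = 30,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of a full training procedure.

    Each repeat draws a fresh seeded partition; ``trainer`` receives the
    training positives/negatives only (so MDD, balancing, and the SVM
    are all re-fit inside the fold) and must return an object with a
    ``predict_windows(fragments) -> bool array`` method. Fold metrics
    are averaged over all ``k * repeats`` test folds; per-round panels
    pool the k folds of one repeat.
    """
    if min(len(positives), len(negatives)) < k:
        raise ValueError(f"each class needs at least k={k} members")
    X = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))

    per_fold = []
    per_round = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        round_cm = ConfusionMatrix(0, 0, 0, 0)
        for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
            tr_pos = [X[i] for i in tr_idx if y[i] == 1]
            tr_neg = [X[i] for i in tr_idx if y[i] == 0]
            te_pos = [X[i] for i in te_idx if y[i] == 1]
            te_neg = [X[i] for i in te_idx if y[i] == 0]
            model = trainer(tr_pos, tr_neg)
            cm = confusion_from_calls(
                model.predict_windows(te_pos), model.predict_windows(te_neg)
            )
            per_fold.append((cm, metrics(cm)))
            round_cm = round_cm + cm
            pooled = pooled + cm
        per_round.append(metrics(round_cm))

    panels = [p for _, p in per_fold]
    mean = MetricsPanel(
        Sn=float(np.mean([p.Sn for p in panels])),
        Sp=float(np.mean([p.Sp for p in panels])),
        Acc=float(np.mean([p.Acc for p in panels])),
        MCC=float(np.mean([p.MCC for p in panels])),
    )
    result = CVResult(mean=mean, per_fold=per_fold, per_round=per_round,
                      confusion=pooled)
    result._folds_per_round = k
    return result


# ---------------------------------------------------------------------------
# Independent testing

def fragment_identity(a: str, b: str) -> float:
    """Ungapped identity: matching positions / window length. A padding
    symbol matches only another padding symbol."""
    if len(a) != len(b):
        raise ValueError("fragments must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def homology_filter(
    test: Sequence[PeptideWindow],
    train: Sequence[PeptideWindow],
    identity_cutoff: float = 1.0,
) -> list[PeptideWindow]:
    """Drop test fragments with identity >= cutoff to any training fragment."""
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError("identity_cutoff must lie in (0, 1]")
    if not train:
        return list(test)
    train_frags = [t.fragment for t in train]
    if identity_cutoff == 1.0:
        train_set = set(train_frags)
        return [t for t in test if t.fragment not in train_set]
    out = []
    for t in test:
        if all(fragment_identity(t.fragment, tr) < identity_cutoff
               for tr in train_frags):
            out.append(t)
    return out


def independent_test(
    model,
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
) -> tuple[ConfusionMatrix, MetricsPanel]:
    """Score disjoint held-out fragments with a trained classifier."""
    if not positives:
        raise ValueError("positive test set is empty; Sn undefined")
    if not negatives:
        raise ValueError("negative test set is empty; Sp undefined")
    cm = confusion_from_calls(
        model.predict_windows(list(positives)),
        model.predict_windows(list(negatives)),
    )
    return cm, metrics(cm)


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Metrics report in the standard column order."""
    cols = ["model", "TP", "FN", "TN", "FP", "Sn", "Sp", "Acc", "MCC"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]
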