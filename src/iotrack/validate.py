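"""Diary alignment and agreement metrics.

Ground truth comes from an activity diary: segment start times (rounded
to the epoch grid) and the true mode of each segment.  Each epoch takes
the mode of the segment containing it, with half-open intervals
``[start, next_start)`` so boundaries are deterministic.

Agreement is summarised the way remote-sensing accuracy assessments are:
a confusion matrix of true class (rows) by predicted class (columns),
user's accuracy (precision — of the epochs predicted c, how many are c),
producer's accuracy (recall — of the truly-c epochs, how many were found)
and Cohen's unweighted kappa

    kappa = (p_o − p_e) / (1 − p_e),   p_e = Σ_c row_c · col_c / N²,

the observed agreement corrected for the agreement expected from the
marginals alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ConfusionSummary", "align_diary", "confusion", "two_class_view"]

CLASSES = ("indoor", "outdoor", "vehicle")


@dataclass
class ConfusionSummary:
    """Confusion matrix plus the derived accuracy metrics.

    Per-class accuracies are NaN (undefined), not zero, when the class is
    absent from the relevant margin.
    """

    matrix: pd.DataFrame  # rows: true class, columns: predicted class
    overall_acc: float
    users_acc: dict[str, float] = field(default_factory=dict)
    producers_acc: dict[str, float] = field(default_factory=dict)
    kappa: float = float("nan")

    @property
    def n(self) -> int:
        return int(self.matrix.to_numpy().sum())


def align_diary(diary: pd.DataFrame, track: pd.DataFrame) -> pd.Series:
    """True mode per epoch from diary segments (half-open intervals).

    Epochs before the first segment start get NA and a warning; epochs at
    or after the last start take the last segment's mode.
    """
    if len(diary) == 0:
        raise ValueError("diary has no segments")
    diary = diary.sort_values("start").reset_index(drop=True)
    t = pd.to_datetime(track["t"])
    starts = pd.to_datetime(diary["start"]).to_numpy()
    idx = np.searchsorted(starts, t.to_numpy(), side="right") - 1
    out = pd.Series(pd.NA, index=track.index, dtype="object")
    valid = idx >= 0
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} epochs precede the first diary segment; excluded from validation")
    out[valid] = diary["mode"].to_numpy()[idx[valid]]
    return out


def confusion(true_labels, pred_labels, classes=CLASSES) -> ConfusionSummary:
    """Tally the confusion matrix and compute accuracies and kappa.

    Pairs where either label is missing are dropped first.  Raises on an
    empty tally.
    """
    true_s = pd.Series(list(true_labels), dtype="object")
    pred_s = pd.Series(list(pred_labels), dtype="object")
    if len(true_s) != len(pred_s):
        raise ValueError("label sequences differ in length")
    keep = true_s.notna() & pred_s.notna()
    true_s, pred_s = true_s[keep], pred_s[keep]
    total = len(true_s)
    if total == 0:
        raise ValueError("no labelled epochs to validate")

    classes = list(classes)
    m = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for tr, pr in zip(true_s, pred_s):
        m[pos[tr], pos[pr]] += 1

    row = m.sum(axis=1).astype(float)
    col = m.sum(axis=0).astype(float)
    diag = np.diag(m).astype(float)
    overall = diag.sum() / total
    with np.errstate(invalid="ignore", divide="ignore"):
        users = {c: (diag[i] / col[i] if col[i] > 0 else float("nan")) for i, c in enumerate(classes)}
        producers = {c: (diag[i] / row[i] if row[i] > 0 else float("nan")) for i, c in enumerate(classes)}
    p_e = float((row * col).sum()) / total**2
    kappa = 1.0 if p_e == 1.0 else (overall - p_e) / (1.0 - p_e)

    return ConfusionSummary(
        matrix=pd.DataFrame(m, index=classes, columns=classes),
        overall_acc=float(overall),
        users_acc=users,
        producers_acc=producers,
        kappa=float(kappa),
    )


def two_class_view(true_labels, pred_labels) -> ConfusionSummary:
    """Indoor/outdoor confusion summary, dropping epochs that are vehicle
    in either the truth or the prediction."""
    true_s = pd.Series(list(true_labels), dtype="object")
    pred_s = pd.Series(list(pred_labels), dtype="object")
    keep = (true_s != "vehicle") & (pred_s != "vehicle")
    return confusion(true_s[keep], pred_s[keep], classes=("indoor", "outdoor"))
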