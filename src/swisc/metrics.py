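"""Evaluation statistics for scored hypnograms.

Per-state precision, recall and F1 (with macro and prevalence-weighted
averages), overall agreement, Cohen's kappa and the confusion matrix come
from scikit-learn. The area under the precision-recall curve is approximated
as a Riemann sum over 200 evenly spaced probability thresholds, per one-hot
state. The seizure false-alarm rate of a file is the signed difference
between classifier-detected and expert seizure run counts divided by the
file's duration in hours, averaged over files.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.metrics import (cohen_kappa_score, confusion_matrix,
                             precision_recall_fscore_support)

from .errors import ConfigError
from .io import StateLabels
from .postprocess import find_state_runs
from .states import N_STATES, SEIZURE, STATES, as_indices


@dataclasses.dataclass
class ClassificationReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1_micro: dict[str, float]
    f1_macro: float
    f1_weighted: float
    accuracy: float
    agreement_pct: float
    kappa: float
    confusion: np.ndarray  # (5, 5) counts, rows = true state
    support: dict[str, int]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d


def _as_idx(labels) -> np.ndarray:
    if isinstance(labels, StateLabels):
        return labels.indices
    return as_indices(labels)


def agreement(true, pred) -> float:
    """Percent of epochs where the two label sequences agree."""
    t, p = _as_idx(true), _as_idx(pred)
    if len(t) != len(p):
        raise ConfigError("label sequences differ in length")
    if len(t) == 0:
        raise ConfigError("agreement is undefined for empty input")
    return 100.0 * float((t == p).mean())


def report(true, pred) -> ClassificationReport:
    """Full per-state classification report over the five-state alphabet."""
    t, p = _as_idx(true), _as_idx(pred)
    if len(t) != len(p):
        raise ConfigError("label sequences differ in length")
    idx = np.arange(N_STATES)
    prec, rec, f1, support = precision_recall_fscore_support(
        t, p, labels=idx, zero_division=0)
    present = support > 0
    f1_macro = float(f1[present].mean()) if present.any() else 0.0
    f1_weighted = float((f1 * support).sum() / support.sum()) if support.sum() else 0.0
    cm = confusion_matrix(t, p, labels=idx)
    agree = 100.0 * float((t == p).mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class edge cases
        kappa = float(cohen_kappa_score(t, p, labels=idx)) if len(set(t) | set(p)) > 1 else 1.0
    return ClassificationReport(
        precision={STATES[i]: float(prec[i]) for i in idx},
        recall={STATES[i]: float(rec[i]) for i in idx},
        f1_micro={STATES[i]: float(f1[i]) for i in idx},
        f1_macro=f1_macro,
        f1_weighted=f1_weighted,
        accuracy=float((t == p).mean()),
        agreement_pct=agree,
        kappa=kappa,
        confusion=cm,
        support={STATES[i]: int(support[i]) for i in idx},
    )


def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aucpr(true_onehot: np.ndarray, probabilities: np.ndarray,
          n_thresholds: int = 200) -> dict[str, float]:
    """Per-state area under the precision-recall curve.

    Approximated as a Riemann sum of precision over recall evaluated at
    ``n_thresholds`` evenly spaced probability thresholds. States absent from
    the truth get NaN (undefined).
    """
    y = np.asarray(true_onehot) > 0.5
    p = np.asarray(probabilities, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ConfigError("probabilities must lie in [0, 1]")
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    out: dict[str, float] = {}
    for c in range(y.shape[1]):
        yc, pc = y[:, c], p[:, c]
        n_pos = int(yc.sum())
        if n_pos == 0:
            out[STATES[c]] = float("nan")
            continue
        desc = thresholds[::-1]  # descending: recall grows monotonically
        pred = pc[None, :] >= desc[:, None]  # (T, n)
        tp = (pred & yc[None, :]).sum(axis=1).astype(float)
        fp = (pred & ~yc[None, :]).sum(axis=1).astype(float)
        denom = tp + fp
        precision = np.where(denom > 0, tp / np.maximum(denom, 1), 1.0)
        recall = tp / n_pos
        r = np.concatenate([[0.0], recall])
        q = np.concatenate([[1.0], precision])
        out[STATES[c]] = float(np.sum(np.diff(r) * q[1:]))
    return out


def seizure_run_count(labels) -> int:
    """Number of maximal runs of contiguous seizure epochs."""
    if isinstance(labels, StateLabels):
        labels = labels.labels
    return sum(1 for state, _, _ in find_state_runs(labels) if state == SEIZURE)


def far(true_per_file, pred_per_file, hours_per_file, clamp: bool = False) -> float:
    """Mean seizure false-alarm rate per hour over files.

    Per file: FA = (# predicted seizure runs) - (# true seizure runs);
    FAR = FA / duration in hours. The signed difference is kept by default
    (under-detection gives a negative contribution); ``clamp`` floors each
    file's FA at zero.
    """
    rates = []
    for t, p, h in zip(true_per_file, pred_per_file, hours_per_file):
        if h <= 0:
            warnings.warn("skipping zero-duration file in FAR", stacklevel=2)
            continue
        fa = seizure_run_count(p) - seizure_run_count(t)
        if clamp:
            fa = max(fa, 0)
        rates.append(fa / h)
    if not rates:
        raise ConfigError("no usable files for FAR")
    return float(np.mean(rates))
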