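"""Training-set assembly: sequence windows, one-hot targets, class weights,
subject-level splits.

Class imbalance is handled with a two-step weighting. The "balanced" weight
for class C is SK_C = N / (T * N_C) over the T classes present; those raw
weights span orders of magnitude when seizure epochs are rare, so they are
log-smoothed and anchored on the wake class:

    Weight_C = ln(SK_C) - ln(SK_wake) + 1  =  ln(N_wake / N_C) + 1

which fixes Weight_wake = 1 exactly and preserves the relative ordering.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ConfigError, LeakageError
from .io import FeatureMatrix, StateLabels
from .states import N_STATES, STATES, WAKE, as_indices, as_names

SEQ_LENGTHS = (1, 3, 5, 7)


def make_sequences(features: FeatureMatrix | np.ndarray, seq_len: int) -> np.ndarray:
    """Center-aligned sliding windows: row T holds epochs T-k .. T+k.

    Boundary epochs are padded by edge replication of the first/last feature
    vector, so every input epoch yields exactly one output row.
    """
    if seq_len < 1 or seq_len % 2 == 0:
        raise ConfigError("sequence length must be odd and >= 1")
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    n = x.shape[0]
    k = (seq_len - 1) // 2
    idx = np.clip(np.arange(n)[:, None] + np.arange(-k, k + 1)[None, :], 0, n - 1)
    return x[idx]  # (n, seq_len, n_features)


def compute_class_weights(labels, floor: float | None = None) -> dict[str, float]:
    """Smoothed balanced class weights, anchored so weight(wake) = 1.

    ``labels`` may be a StateLabels, a sequence of state names, or a mapping
    {state: count}. Absent classes get no entry. Weights below zero (a class
    outnumbering wake by more than a factor of e) are kept but warned about
    unless ``floor`` is given.
    """
    if isinstance(labels, dict):
        counts = {s: int(c) for s, c in labels.items() if c > 0}
    else:
        if isinstance(labels, StateLabels):
            labels = labels.labels
        idx = as_indices(labels)
        binc = np.bincount(idx, minlength=N_STATES)
        counts = {STATES[i]: int(binc[i]) for i in range(N_STATES) if binc[i] > 0}
    if counts.get(WAKE, 0) == 0:
        raise ConfigError("wake count must be positive to anchor the weights")

    n_total = sum(counts.values())
    t = len(counts)
    sk = {s: n_total / (t * c) for s, c in counts.items()}
    weights = {s: float(np.log(sk[s]) - np.log(sk[WAKE]) + 1.0) for s in counts}
    negative = [s for s, w in weights.items() if w <= 0]
    if negative and floor is None:
        warnings.warn(f"non-positive class weights for {negative}; "
                      "consider the floor option", stacklevel=2)
    if floor is not None:
        weights = {s: max(w, floor) for s, w in weights.items()}
    return weights


def encode_onehot(labels) -> np.ndarray:
    """(n, 5) one-hot matrix in (wake, NREM, REM, seizure, postictal) order."""
    if isinstance(labels, StateLabels):
        return labels.onehot
    return np.eye(N_STATES, dtype=np.int64)[as_indices(labels)]


def decode(probabilities: np.ndarray, epoch_len_s: float = 20.0) -> StateLabels:
    """Argmax decoding of class probabilities; ties break to the lowest index."""
    probs = np.asarray(probabilities)
    if probs.ndim != 2 or probs.shape[1] != N_STATES:
        raise ConfigError(f"probabilities must be (n, {N_STATES})")
    return StateLabels(labels=as_names(np.argmax(probs, axis=1)),
                       epoch_len_s=epoch_len_s)


def split_by_subject(files_by_subject: dict, assignment: dict) -> dict[str, list]:
    """Partition files into train/val/test lists strictly by subject.

    ``assignment`` maps subject_id -> partition name. Every subject must go
    to exactly one partition; an empty partition is legal (with a warning).
    """
    partitions: dict[str, list] = {"train": [], "val": [], "test": []}
    seen: dict[str, str] = {}
    for subject, files in files_by_subject.items():
        if subject not in assignment:
            raise ConfigError(f"subject {subject!r} has no partition assignment")
        part = assignment[subject]
        if part not in partitions:
            raise ConfigError(f"unknown partition {part!r} for subject {subject!r}")
        if subject in seen and seen[subject] != part:
            raise LeakageError(f"subject {subject!r} assigned to two partitions")
        seen[subject] = part
        partitions[part].extend(files)
    # a subject listed twice in the assignment cannot happen with a dict; the
    # leakage check that matters is file-level overlap across partitions
    for a in ("train", "val", "test"):
        for b in ("train", "val", "test"):
            if a < b:
                overlap = set(map(str, partitions[a])) & set(map(str, partitions[b]))
                if overlap:
                    raise LeakageError(f"files shared between {a} and {b}: {sorted(overlap)}")
    for part, files in partitions.items():
        if not files:
            warnings.warn(f"partition {part!r} is empty", stacklevel=2)
    return partitions
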