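"""Scoring-rule layer: run decomposition, rule checking, and correction.

Two transition rules from rodent-adapted Rechtschaffen & Kales scoring are
enforced: REM may only follow NREM, and NREM is only legal in runs of two or
more consecutive epochs. Seizure and postictal epochs are transparent to the
layer — they are never relabeled, and for transition legality they count as
wake (so REM emerging straight out of a seizure/postictal block is flagged).

The correction policy relabels each violating run to the preceding
sleep-wake state (wake when the preceding state is seizure/postictal or the
run opens the file) and rescans until a fixed point; the label sequence can
change by at most one pass per remaining violation.
"""

from __future__ import annotations

import numpy as np

from .io import StateLabels
from .states import NREM, POSTICTAL, REM, SEIZURE, WAKE

RULE_REM_TRANSITION = "rem_transition"
RULE_LONE_NREM = "lone_nrem"


def _names(labels) -> list[str]:
    if isinstance(labels, StateLabels):
        return [str(s) for s in labels.labels]
    return [str(s) for s in np.asarray(labels, dtype=object)]


def find_state_runs(labels) -> list[tuple[str, int, int]]:
    """Maximal-run decomposition as (state, start_index, length) triples."""
    seq = _names(labels)
    runs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append((seq[start], start, i - start))
            start = i
    return runs


def _transition_state(state: str) -> str:
    """State as seen by the transition rules (ictal states count as wake)."""
    return WAKE if state in (SEIZURE, POSTICTAL) else state


def detect_rk_violations(labels) -> list[tuple[int, str]]:
    """Indices (first epoch of the offending run) and rule names of all
    violations. A REM run opening the file has no preceding state to judge
    and is not flagged."""
    runs = find_state_runs(labels)
    violations: list[tuple[int, str]] = []
    for k, (state, start, length) in enumerate(runs):
        if state == REM and k > 0:
            prev = _transition_state(runs[k - 1][0])
            if prev != NREM:
                violations.append((start, RULE_REM_TRANSITION))
        if state == NREM and length == 1:
            violations.append((start, RULE_LONE_NREM))
    return sorted(violations)


def apply_rk_correction(labels, max_passes: int | None = None):
    """Relabel violating runs until the sequence passes the rule detector.

    Seizure and postictal epochs are never altered. Idempotent on legal
    input; returns the same container type it was given.
    """
    seq = _names(labels)
    passes = max_passes if max_passes is not None else max(len(seq), 1)
    for _ in range(passes):
        violations = detect_rk_violations(seq)
        if not violations:
            break
        runs = find_state_runs(seq)
        start_to_run = {start: k for k, (_, start, _) in enumerate(runs)}
        for start, _rule in violations:
            k = start_to_run[start]
            state, s, length = runs[k]
            prev = runs[k - 1][0] if k > 0 else WAKE
            if prev in (SEIZURE, POSTICTAL):
                prev = WAKE
            replacement = prev
            if replacement == state:  # cannot happen for maximal runs, be safe
                replacement = WAKE
            seq[s:s + length] = [replacement] * length
    if isinstance(labels, StateLabels):
        return StateLabels(labels=np.array(seq, dtype=object),
                           epoch_len_s=labels.epoch_len_s)
    return np.array(seq, dtype=object)
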