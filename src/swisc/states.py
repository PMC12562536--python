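"""The five-state scoring alphabet and its canonical encoding.

Epochs are scored as one of five states; the one-hot index order is fixed so
that feature matrices, label files and model outputs all agree:
index 0 = wake, 1 = NREM, 2 = REM, 3 = seizure, 4 = postictal.
"""

from __future__ import annotations

import numpy as np

WAKE = "wake"
NREM = "NREM"
REM = "REM"
SEIZURE = "seizure"
POSTICTAL = "postictal"

STATES: tuple[str, ...] = (WAKE, NREM, REM, SEIZURE, POSTICTAL)
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

SLEEP_WAKE_STATES = (WAKE, NREM, REM)


def as_indices(labels) -> np.ndarray:
    """Map a sequence of state names to integer codes (wake=0 ... postictal=4)."""
    from .errors import VocabularyError

    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        if labels.size and (labels.min() < 0 or labels.max() >= N_STATES):
            raise VocabularyError("integer label outside 0..4")
        return labels.astype(np.int64)
    out = np.empty(labels.shape, dtype=np.int64)
    for i, lab in enumerate(labels.ravel()):
        try:
            out.ravel()[i] = STATE_INDEX[str(lab)]
        except KeyError:
            raise VocabularyError(f"unknown state label: {lab!r}") from None
    return out


def as_names(indices) -> np.ndarray:
    """Map integer codes back to state names."""
    idx = np.asarray(indices, dtype=np.int64)
    return np.array(STATES, dtype=object)[idx]
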