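"""Generate a short labeled synthetic recording and condition it.

Builds 18 minutes of 4-channel (ECoG, HPC-L, HPC-R, EMG) signal at 2 kHz
with wake/NREM/REM bouts and a couple of seizures, then runs the standard
conditioning: 1 Hz high-pass, anti-aliased decimation to 200 Hz, per-file
z-scoring, and 20 s epoching.
"""

import numpy as np

from swisc import PreprocessConfig, SynthConfig, preprocess_pipeline
from swisc.synth import generate_subject

cfg = SynthConfig(hours=0.3, seed=8, seizure_rate_per_h=6.0)
rec, track, labels = generate_subject(cfg, "demo", seed=8)

print(f"raw recording: {rec.signals.shape[0]} channels x "
      f"{rec.n_samples} samples @ {rec.rate:.0f} Hz ({rec.duration_s:.0f} s)")

epochs = preprocess_pipeline(rec, PreprocessConfig(epoch_len_s=20.0))
print(f"conditioned epochs: {epochs.data.shape} "
      "(epochs x channels x samples @ 200 Hz)")

counts = {s: int(n) for s, n in
          zip(("wake", "NREM", "REM", "seizure", "postictal"),
              np.bincount(labels.indices, minlength=5))}
print(f"epoch labels: {counts}")
# each 20 s epoch carries exactly one of the five state labels; the
# conditioned tensor is what feature extraction consumes next
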