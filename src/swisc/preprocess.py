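"""Signal conditioning: high-pass, anti-aliased decimation, z-scoring, epoching.

The stages run in a fixed order — high-pass filter the raw 2 kHz signal,
decimate to 200 Hz through a zero-phase IIR anti-aliasing filter, z-score each
channel over the whole file, then cut the file into fixed-length epochs. The
high-pass is a causal first-order Butterworth at 1 Hz; only the anti-aliasing
stage is zero-phase. The anti-aliasing filter is a Chebyshev type-I IIR with a
corner at 0.8x the post-decimation Nyquist, second order for ECoG and eighth
order for the hippocampal and EMG channels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataQualityError, DegenerateChannelError, FormatError
from .io import EpochArray, Recording

#: anti-aliasing filter order by channel role
DEFAULT_AA_ORDER = {"ECoG": 2, "HPC-L": 8, "HPC-R": 8, "EMG": 8}


@dataclasses.dataclass
class PreprocessConfig:
    """Tunable knobs of the conditioning pipeline.

    hp_cutoff/hp_order: high-pass corner (Hz) and Butterworth order.
    decim_factor: integer downsampling ratio (2 kHz -> 200 Hz by default).
    aa_order_by_role: anti-aliasing IIR order per channel role.
    epoch_len_s: scoring epoch length in seconds (20 or 4).
    """

    hp_cutoff: float = 1.0
    hp_order: int = 1
    decim_factor: int = 10
    aa_order_by_role: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_AA_ORDER))
    epoch_len_s: float = 20.0

    def __post_init__(self):
        if self.decim_factor < 1:
            raise ConfigError("decimation factor must be >= 1")


def highpass(x: np.ndarray, rate: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Causal Butterworth high-pass; attenuates DC and slow drift."""
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise DataQualityError("non-finite samples in input to high-pass")
    if rate <= 2 * cfg.hp_cutoff:
        raise ConfigError("sampling rate too low for the high-pass corner")
    sos = sps.butter(cfg.hp_order, cfg.hp_cutoff, btype="highpass", fs=rate,
                     output="sos")
    return sps.sosfilt(sos, x, axis=-1)


def decimate(x: np.ndarray, rate: float, role: str = "ECoG",
             cfg: PreprocessConfig | None = None) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation; zero-phase Chebyshev-I filter then subsample."""
    cfg = cfg or PreprocessConfig()
    q = cfg.decim_factor
    if rate % q != 0:
        raise ConfigError(f"decimation factor {q} does not divide rate {rate}")
    order = cfg.aa_order_by_role.get(role, 8)
    x = np.asarray(x, dtype=np.float64)
    if q == 1:
        return x, rate
    # same family/corner as scipy.signal.decimate's IIR default (cheby1,
    # 0.05 dB ripple, 0.8 x new Nyquist), applied forward-backward.
    sos = sps.cheby1(order, 0.05, 0.8 / q, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=-1)
    return y[..., ::q], rate / q


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit standard deviation over the whole file."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateChannelError("zero-variance channel cannot be z-scored")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def epoch(rec: Recording, epoch_len_s: float) -> EpochArray:
    """Cut a (post-decimation) recording into fixed-length epochs.

    A trailing partial epoch is discarded, never padded.
    """
    n_per = int(round(epoch_len_s * rec.rate))
    if abs(n_per - epoch_len_s * rec.rate) > 1e-9:
        raise ConfigError("epoch length must be an integer number of samples")
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise FormatError("recording shorter than one epoch")
    data = rec.signals[:, : n_epochs * n_per]
    data = data.reshape(len(rec.roles), n_epochs, n_per).transpose(1, 0, 2)
    return EpochArray(data=np.ascontiguousarray(data), epoch_len_s=epoch_len_s,
                      rate=rec.rate, roles=rec.roles)


def preprocess_recording(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Run high-pass -> decimate -> z-score, returning the conditioned recording."""
    cfg = cfg or PreprocessConfig()
    if not np.isfinite(rec.signals).all():
        raise DataQualityError("recording contains NaN/Inf samples")
    out = []
    new_rate = rec.rate
    for i, role in enumerate(rec.roles):
        y = highpass(rec.signals[i], rec.rate, cfg)
        y, new_rate = decimate(y, rec.rate, role, cfg)
        out.append(zscore(y))
    return Recording(signals=np.vstack(out), rate=new_rate, roles=rec.roles,
                     subject_id=rec.subject_id, start_time=rec.start_time)


def preprocess_pipeline(rec: Recording, cfg: PreprocessConfig | None = None) -> EpochArray:
    """Full conditioning pipeline: filter -> decimate -> z-score -> epoch."""
    cfg = cfg or PreprocessConfig()
    return epoch(preprocess_recording(rec, cfg), cfg.epoch_len_s)
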