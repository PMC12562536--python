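"""Per-epoch feature extraction and the four named feature sets.

Each channel contributes up to 20 features per epoch: six time-domain
statistics (mean, median, standard deviation, variance, skewness, kurtosis),
six normalized band powers plus a delta/low-theta ratio from the one-sided FFT
magnitude spectrum, and the same seven from the Welch power spectral density.
The EMG channel additionally contributes twenty 1 s RMS amplitude values.

Band powers are aggregated over half-open frequency intervals and normalized
to the 2-55 Hz broadband aggregate of the same spectrum; the 55-65 Hz interval
is excluded everywhere to keep line noise out of the feature space. With all
four channels present the sets are:

==========  =======================================================  ========
name        per-channel block                                        total
==========  =======================================================  ========
dt_rms      FFT ratio + PSD ratio                                         28
stat_rms    6 statistics                                                  44
fft_rms     6 FFT band powers + FFT ratio                                 48
full        6 stats + 6 FFT + ratio + 6 PSD + ratio                      100
==========  =======================================================  ========

(each including the 20-value RMS EMG block).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import ConfigError, DegenerateEpochError, LayoutError
from .io import EpochArray, FeatureMatrix, ROLES

RATIO_CAP = 1e6
RATIO_FLOOR = 1e-6

FEATURE_SETS = ("dt_rms", "stat_rms", "fft_rms", "full")
_SET_ALIASES = {
    "dt/rms": "dt_rms", "stat/rms": "stat_rms", "fft/rms": "fft_rms",
    "dt_rms": "dt_rms", "stat_rms": "stat_rms", "fft_rms": "fft_rms",
    "full": "full",
}

STAT_NAMES = ("mean", "median", "sd", "variance", "skewness", "kurtosis")


def canonical_set_name(name: str) -> str:
    try:
        return _SET_ALIASES[name.lower()]
    except KeyError:
        raise ConfigError(f"unknown feature set {name!r}; choose from {FEATURE_SETS}") from None


@dataclasses.dataclass(frozen=True)
class BandScheme:
    """Half-open EEG band edges in Hz; shared edges belong to the upper band."""

    bands: tuple = (
        ("delta", 2.0, 4.0),
        ("theta_low", 4.0, 7.0),
        ("theta_high", 7.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma_low", 30.0, 55.0),
        ("gamma_high", 65.0, 100.0),
    )
    broadband: tuple = (2.0, 55.0)
    excluded: tuple = (55.0, 65.0)

    @property
    def band_names(self) -> tuple:
        return tuple(name for name, _, _ in self.bands)


DEFAULT_SCHEME = BandScheme()


# ---------------------------------------------------------------------------
# elementary per-epoch quantities
# ---------------------------------------------------------------------------

def statistical_features(x: np.ndarray) -> np.ndarray:
    """Six time-domain statistics along the last axis.

    Order: mean, median, sd, variance, skewness, kurtosis (Fisher/excess,
    bias-uncorrected). Zero-variance segments get skewness = kurtosis = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 4:
        raise ConfigError("need at least 4 samples for the statistical features")
    mean = x.mean(axis=-1)
    median = np.median(x, axis=-1)
    var = x.var(axis=-1)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = spstats.skew(x, axis=-1)
        kurt = spstats.kurtosis(x, axis=-1)  # Fisher, excess
    skew = np.where(np.isfinite(skew), skew, 0.0)
    kurt = np.where(np.isfinite(kurt), kurt, 0.0)
    return np.stack([mean, median, sd, var, skew, kurt], axis=-1)


def _band_aggregate(power: np.ndarray, freqs: np.ndarray,
                    scheme: BandScheme) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sum ``power`` over each band and over the broadband interval."""
    sums = {}
    for name, lo, hi in scheme.bands:
        m = (freqs >= lo) & (freqs < hi)
        sums[name] = power[..., m].sum(axis=-1)
    lo, hi = scheme.broadband
    bb = power[..., (freqs >= lo) & (freqs < hi)].sum(axis=-1)
    stacked = np.stack([sums[n] for n in scheme.band_names], axis=-1)
    return stacked, bb, sums


def _ratio(delta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Delta / low-theta power ratio, clipped to [1e-6, 1e6] to stay finite."""
    delta = np.asarray(delta, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = delta / theta
    r = np.where(theta == 0, np.where(delta > 0, RATIO_CAP, RATIO_FLOOR), r)
    return np.clip(r, RATIO_FLOOR, RATIO_CAP)


def spectrum(x: np.ndarray, rate: float, method: str,
             scheme: BandScheme = DEFAULT_SCHEME) -> tuple[np.ndarray, np.ndarray]:
    """Return (freqs, power-like spectrum) along the last axis.

    ``fft_mag`` is the modulus of the one-sided real-input FFT; ``welch_psd``
    is a Welch density estimate with 1 s Hann segments at 50% overlap.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if method == "fft_mag":
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        return freqs, np.abs(np.fft.rfft(x, axis=-1))
    if method == "welch_psd":
        nperseg = min(int(rate), n)
        freqs, psd = sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2, scaling="density", axis=-1)
        return freqs, psd
    raise ConfigError(f"unknown spectral method {method!r}")


def band_powers(x: np.ndarray, rate: float, method: str = "fft_mag",
                scheme: BandScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Six broadband-normalized band powers plus the delta/low-theta ratio.

    Works on a single epoch (1-D) or batched along leading axes; the result
    appends a length-7 axis: (delta, theta_low, theta_high, beta, gamma_low,
    gamma_high, delta_theta_ratio).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2 * rate:
        raise ConfigError("epoch must be at least 2 s long to resolve 2 Hz")
    freqs, power = spectrum(x, rate, method, scheme)
    stacked, bb, sums = _band_aggregate(power, freqs, scheme)
    if np.any(bb == 0):
        raise DegenerateEpochError("epoch has zero broadband power")
    ratio = _ratio(sums["delta"], sums["theta_low"])
    return np.concatenate([stacked / bb[..., None], ratio[..., None]], axis=-1)


def rms_emg(x: np.ndarray, rate: float, epoch_len_s: float) -> np.ndarray:
    """Twenty 1 s RMS EMG amplitudes per epoch.

    For 20 s epochs this is one RMS per second. For 4 s epochs the four
    1 s RMS values are each repeated five times in order, so the feature
    block keeps its 20-slot layout across epoch lengths.
    """
    x = np.asarray(x, dtype=np.float64)
    n_bins = int(round(epoch_len_s))
    bin_len = int(round(rate))
    if epoch_len_s not in (4.0, 20.0, 4, 20):
        raise ConfigError("RMS EMG block is defined for 4 s and 20 s epochs only")
    if x.shape[-1] != n_bins * bin_len:
        raise ConfigError("epoch length must divide into whole 1 s bins")
    binned = x.reshape(*x.shape[:-1], n_bins, bin_len)
    rms = np.sqrt((binned ** 2).mean(axis=-1))
    if n_bins == 20:
        return rms
    return np.repeat(rms, 5, axis=-1)


# ---------------------------------------------------------------------------
# feature-set assembly
# ---------------------------------------------------------------------------

def _channel_block(kind: str, scheme: BandScheme) -> list[str]:
    if kind == "stat":
        return [f"stat:{n}" for n in STAT_NAMES]
    if kind == "fft":
        return [f"fft:{n}" for n in scheme.band_names] + ["fft:delta_theta_ratio"]
    if kind == "psd":
        return [f"psd:{n}" for n in scheme.band_names] + ["psd:delta_theta_ratio"]
    if kind == "dt":
        return ["fft:delta_theta_ratio", "psd:delta_theta_ratio"]
    raise ConfigError(kind)


_SET_BLOCKS = {
    "dt_rms": ("dt",),
    "stat_rms": ("stat",),
    "fft_rms": ("fft",),
    "full": ("stat", "fft", "psd"),
}


def manifest_for(feature_set: str, mask=None,
                 scheme: BandScheme = DEFAULT_SCHEME) -> list[str]:
    """Ordered feature names for a feature set and channel mask."""
    feature_set = canonical_set_name(feature_set)
    roles = tuple(mask) if mask is not None else ROLES
    roles = tuple(r for r in ROLES if r in roles)
    if not roles:
        raise ConfigError("channel mask is empty")
    names: list[str] = []
    for role in roles:
        for kind in _SET_BLOCKS[feature_set]:
            names.extend(f"{role}:{item}" for item in _channel_block(kind, scheme))
    if "EMG" in roles:
        names.extend(f"EMG:rms:{i + 1:02d}" for i in range(20))
    return names


def extract_features(epochs: EpochArray, feature_set: str = "full", mask=None,
                     scheme: BandScheme = DEFAULT_SCHEME) -> FeatureMatrix:
    """Assemble the per-epoch feature matrix for one of the four feature sets.

    ``mask`` restricts extraction to a subset of the canonical roles (the
    channel-dropping paradigm); when EMG is masked out the RMS block is
    omitted and the matrix shrinks accordingly.
    """
    feature_set = canonical_set_name(feature_set)
    roles = tuple(mask) if mask is not None else epochs.roles
    missing = [r for r in roles if r not in epochs.roles]
    if missing:
        raise LayoutError(f"mask requests roles absent from the epochs: {missing}")
    roles = tuple(r for r in ROLES if r in roles)
    if not roles:
        raise ConfigError("channel mask is empty")

    blocks: list[np.ndarray] = []
    needs = _SET_BLOCKS[feature_set]
    for role in roles:
        x = epochs.data[:, epochs.roles.index(role), :]  # (E, n)
        for kind in needs:
            if kind == "stat":
                blocks.append(statistical_features(x))
            elif kind == "fft":
                blocks.append(band_powers(x, epochs.rate, "fft_mag", scheme))
            elif kind == "psd":
                blocks.append(band_powers(x, epochs.rate, "welch_psd", scheme))
            elif kind == "dt":
                fft7 = band_powers(x, epochs.rate, "fft_mag", scheme)
                psd7 = band_powers(x, epochs.rate, "welch_psd", scheme)
                blocks.append(np.stack([fft7[..., -1], psd7[..., -1]], axis=-1))
    if "EMG" in roles:
        emg = epochs.data[:, epochs.roles.index("EMG"), :]
        blocks.append(rms_emg(emg, epochs.rate, epochs.epoch_len_s))

    values = np.concatenate(blocks, axis=-1)
    manifest = manifest_for(feature_set, roles, scheme)
    return FeatureMatrix(values=values, feature_set=feature_set,
                         manifest=manifest, epoch_len_s=epochs.epoch_len_s)
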