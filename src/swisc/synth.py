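"""Synthetic labeled 4-channel recordings with state-dependent spectra.

The generator emulates the electrographic signatures that human scorers use:
wake is broadband theta-through-gamma EEG with phasic EMG bursts; NREM has
high delta power, loss of beta/gamma and low muscle tone; REM shows
prominent hippocampal theta with muscle atonia; seizures are >=5 s trains of
rhythmic biphasic spikes whose fundamental frequency sweeps down and whose
amplitude grows; the postictal state is broadband amplitude suppression.

State dwell times follow a semi-Markov chain whose epoch-level structure
obeys the scoring rules by construction (REM entered only from NREM, NREM
bouts at least two epochs long); seizure/postictal events are superimposed
inside wake bouts, each seizure immediately followed by a postictal block.
Sleep-state transitions are aligned to epoch boundaries; seizure onsets fall
at arbitrary seconds so the majority/override epoch-labeling rules are
exercised.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import ROLES, Recording, StateLabels
from .states import (NREM, POSTICTAL, REM, SEIZURE, STATE_INDEX, STATES, WAKE,
                     as_names)

BAND_ORDER = ("delta", "theta_low", "theta_high", "beta", "gamma_low", "gamma_high")
_BAND_EDGES = {
    "delta": (2.0, 4.0), "theta_low": (4.0, 7.0), "theta_high": (7.0, 13.0),
    "beta": (13.0, 30.0), "gamma_low": (30.0, 55.0), "gamma_high": (65.0, 100.0),
}

_W = STATE_INDEX[WAKE]
_N = STATE_INDEX[NREM]
_R = STATE_INDEX[REM]
_S = STATE_INDEX[SEIZURE]
_P = STATE_INDEX[POSTICTAL]


@dataclasses.dataclass
class StateProfile:
    """Spectral weights and EMG behavior of one state.

    ``eeg_bands``/``hpc_bands`` weight the six canonical bands for the ECoG
    and hippocampal channels; ``amplitude`` scales the channel RMS in the
    recording's arbitrary units; ``emg_tone`` is the EMG RMS level and
    ``emg_burst_rate`` the rate (per second) of phasic EMG bursts.
    """

    eeg_bands: dict
    hpc_bands: dict
    amplitude: float = 1.0
    emg_tone: float = 0.5
    emg_burst_rate: float = 0.0


def default_profiles() -> dict[str, StateProfile]:
    wake_eeg = dict(delta=0.35, theta_low=0.8, theta_high=1.2, beta=1.0,
                    gamma_low=0.7, gamma_high=0.35)
    nrem_eeg = dict(delta=2.6, theta_low=0.6, theta_high=0.4, beta=0.15,
                    gamma_low=0.08, gamma_high=0.04)
    rem_ecog = dict(delta=0.25, theta_low=1.2, theta_high=1.3, beta=0.5,
                    gamma_low=0.35, gamma_high=0.2)
    rem_hpc = dict(delta=0.2, theta_low=2.2, theta_high=2.6, beta=0.4,
                   gamma_low=0.3, gamma_high=0.15)
    return {
        WAKE: StateProfile(wake_eeg, dict(wake_eeg), amplitude=1.0,
                           emg_tone=0.8, emg_burst_rate=0.6),
        NREM: StateProfile(nrem_eeg, dict(nrem_eeg), amplitude=1.25,
                           emg_tone=0.3, emg_burst_rate=0.0),
        REM: StateProfile(rem_ecog, rem_hpc, amplitude=0.9,
                          emg_tone=0.08, emg_burst_rate=0.0),
        # postictal spectra are wake-shaped but globally suppressed; the
        # suppression factor is applied from SynthConfig at synthesis time
        POSTICTAL: StateProfile(dict(wake_eeg), dict(wake_eeg), amplitude=1.0,
                                emg_tone=0.1, emg_burst_rate=0.0),
    }


@dataclasses.dataclass
class SynthConfig:
    """Study-design knobs of the synthetic corpus."""

    hours: float = 2.0
    rate: float = 2000.0
    epoch_len_s: float = 20.0
    # semi-Markov mean bout durations (seconds) and minimums (epochs)
    mean_wake_s: float = 280.0
    mean_nrem_s: float = 220.0
    mean_rem_s: float = 90.0
    p_nrem_to_rem: float = 0.5
    # seizure/postictal events
    seizure_rate_per_h: float = 1.0
    seizure_dur_range: tuple = (12.0, 40.0)
    spike_freq_sweep: tuple = (8.0, 3.0)   # Hz, start -> end of each seizure
    spike_amp_range: tuple = (4.0, 12.0)   # amplitude ramp across the seizure
    postictal_dur_range: tuple = (60.0, 120.0)
    postictal_suppression: float = 0.3
    # epilepsy-severity knob: scales interictal spiking, attenuates theta
    severity: float = 0.0
    # corpus layout
    n_subjects: int = 6
    n_seizure_subjects: int = 4
    seed: int = 0

    def __post_init__(self):
        assert self.seizure_dur_range[0] >= 5.0, "seizures must last >= 5 s"


# ---------------------------------------------------------------------------
# state track
# ---------------------------------------------------------------------------

def _draw_epochs(rng, mean_s, epoch_len_s, min_epochs):
    dur = rng.exponential(mean_s)
    return max(min_epochs, int(np.ceil(dur / epoch_len_s)))


def sample_state_track(config: SynthConfig, rng=None,
                       with_seizures: bool = True) -> np.ndarray:
    """Per-second state codes for one recording.

    Sleep-state transitions land on epoch boundaries; seizure events (each
    followed by its postictal block) are carved out of sufficiently long wake
    bouts at arbitrary second offsets.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total_s = int(round(config.hours * 3600))
    ep = int(round(config.epoch_len_s))
    n_epochs = total_s // ep

    chain: list[int] = []
    state = _W
    while len(chain) < n_epochs:
        if state == _W:
            k = _draw_epochs(rng, config.mean_wake_s, ep, 1)
            nxt = _N
        elif state == _N:
            k = _draw_epochs(rng, config.mean_nrem_s, ep, 2)
            nxt = _R if rng.random() < config.p_nrem_to_rem else _W
        else:  # REM
            k = _draw_epochs(rng, config.mean_rem_s, ep, 1)
            nxt = _W
        chain.extend([state] * k)
        state = nxt
    track = np.repeat(np.asarray(chain[:n_epochs], dtype=np.int8), ep)
    track = track[:total_s]

    if with_seizures and config.seizure_rate_per_h > 0:
        n_events = rng.poisson(config.seizure_rate_per_h * config.hours)
        occupied = np.zeros(total_s, dtype=bool)
        for _ in range(n_events):
            dur = rng.uniform(*config.seizure_dur_range)
            pi = rng.uniform(*config.postictal_dur_range)
            need = int(np.ceil(dur + pi)) + 2
            placed = False
            for _attempt in range(20):
                # wake runs long enough to contain the whole event
                wake = (track == _W) & ~occupied
                # candidate start seconds: wake and the whole window free/wake
                starts = np.flatnonzero(wake[: total_s - need])
                if starts.size == 0:
                    break
                s0 = int(rng.choice(starts))
                window = slice(s0, s0 + need)
                if np.all(track[window] == _W) and not occupied[window].any():
                    d = int(round(dur))
                    p = int(round(pi))
                    track[s0:s0 + d] = _S
                    track[s0 + d:s0 + d + p] = _P
                    occupied[window] = True
                    placed = True
                    break
            if not placed:
                continue
    return track


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _shaped_noise(rng, n: int, rate: float, band_weights: dict,
                  background: float = 0.15) -> np.ndarray:
    """Unit-RMS noise whose spectrum follows the band-weight envelope plus a
    1/f-ish broadband floor."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = background / np.sqrt(1.0 + freqs)
    for band, w in band_weights.items():
        lo, hi = _BAND_EDGES[band]
        amp = amp + w * ((freqs >= lo) & (freqs < hi))
    shaped = np.fft.irfft(spec * amp, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / rms if rms > 0 else shaped


def _spike_kernel(rate: float, width_s: float = 0.03) -> np.ndarray:
    """Biphasic (Ricker) spike waveform."""
    half = int(round(3 * width_s * rate))
    t = np.arange(-half, half + 1) / rate
    u = t / width_s
    k = (1.0 - 2.0 * u ** 2) * np.exp(-(u ** 2))
    return k / np.abs(k).max()


def _seizure_waveform(rng, n: int, rate: float, config: SynthConfig) -> np.ndarray:
    """Rhythmic spike train with linearly swept fundamental and growing
    amplitude, riding on low background noise."""
    f0, f1 = config.spike_freq_sweep
    a0, a1 = config.spike_amp_range
    t_frac = np.arange(n) / max(n - 1, 1)
    inst_freq = f0 + (f1 - f0) * t_frac
    phase = np.cumsum(inst_freq) / rate
    impulses = np.zeros(n)
    crossings = np.flatnonzero(np.diff(np.floor(phase)) > 0)
    impulses[crossings] = a0 + (a1 - a0) * t_frac[crossings]
    wave = np.convolve(impulses, _spike_kernel(rate), mode="same")
    wave += 0.4 * rng.standard_normal(n)
    return wave


def _interictal_spikes(rng, n: int, rate: float, severity: float) -> np.ndarray:
    if severity <= 0:
        return np.zeros(n)
    rate_per_s = 0.2 * severity
    n_spikes = rng.poisson(rate_per_s * n / rate)
    out = np.zeros(n)
    if n_spikes == 0:
        return out
    kernel = _spike_kernel(rate)
    centers = rng.integers(0, n, size=n_spikes)
    imp = np.zeros(n)
    imp[centers] += rng.uniform(3.0, 6.0, size=n_spikes)
    return np.convolve(imp, kernel, mode="same")


def _attenuate_theta(bands: dict, severity: float) -> dict:
    if severity <= 0:
        return bands
    factor = max(0.0, 1.0 - 0.3 * severity)
    out = dict(bands)
    out["theta_low"] = out["theta_low"] * factor
    out["theta_high"] = out["theta_high"] * factor
    return out


def synthesize_recording(track: np.ndarray, config: SynthConfig, rng=None,
                         subject_id: str = "synth",
                         profiles: dict | None = None) -> Recording:
    """Render the per-second state track into a 4-channel 2 kHz recording."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    profiles = profiles or default_profiles()
    rate = config.rate
    n_total = int(len(track) * rate)
    signals = np.zeros((4, n_total), dtype=np.float32)

    # maximal runs of the per-second track
    change = np.flatnonzero(np.diff(track)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(track)]])

    for s0, s1 in zip(starts, ends):
        state = int(track[s0])
        n = int((s1 - s0) * rate)
        lo = int(s0 * rate)
        sl = slice(lo, lo + n)
        if state == _S:
            base = _seizure_waveform(rng, n, rate, config)
            signals[0, sl] = 0.7 * base + 0.3 * rng.standard_normal(n)
            for ch in (1, 2):
                signals[ch, sl] = _seizure_waveform(rng, n, rate, config)
            signals[3, sl] = 1.5 * rng.standard_normal(n) + 0.3 * np.abs(base)
            continue
        prof = profiles[STATES[state]]
        amp = prof.amplitude
        if state == _P:
            amp = amp * config.postictal_suppression
        eeg_b = _attenuate_theta(prof.eeg_bands, config.severity)
        hpc_b = _attenuate_theta(prof.hpc_bands, config.severity)
        signals[0, sl] = amp * _shaped_noise(rng, n, rate, eeg_b)
        for ch in (1, 2):
            sig = amp * _shaped_noise(rng, n, rate, hpc_b)
            if state in (_W, _N, _R):
                sig = sig + _interictal_spikes(rng, n, rate, config.severity)
            signals[ch, sl] = sig

        emg = prof.emg_tone * _shaped_noise(
            rng, n, rate, dict(beta=0.6, gamma_low=1.0, gamma_high=1.0),
            background=0.3)
        if state == _P:
            emg = emg * config.postictal_suppression
        if prof.emg_burst_rate > 0:
            n_bursts = rng.poisson(prof.emg_burst_rate * (s1 - s0))
            env = np.ones(n)
            for _ in range(n_bursts):
                b0 = rng.integers(0, n)
                blen = int(rng.uniform(0.2, 0.8) * rate)
                env[b0:b0 + blen] = 4.0
            emg = emg * env
        signals[3, sl] = emg

    return Recording(signals=signals, rate=rate, roles=ROLES,
                     subject_id=subject_id)


# ---------------------------------------------------------------------------
# epoch labeling
# ---------------------------------------------------------------------------

def label_epochs(track: np.ndarray, epoch_len_s: float) -> StateLabels:
    """Majority epoch labels with the seizure override.

    An epoch takes the state occupying at least half of it (ties go to the
    state present in the epoch's first second). Any epoch containing more
    than 5 s of seizure is labeled seizure; a seizure too short/straddled to
    give any epoch >5 s labels the epoch holding its largest share.
    """
    ep = int(round(epoch_len_s))
    n_epochs = len(track) // ep
    track = np.asarray(track[: n_epochs * ep], dtype=np.int64)
    windows = track.reshape(n_epochs, ep)

    labels = np.empty(n_epochs, dtype=np.int64)
    for i, w in enumerate(windows):
        counts = np.bincount(w, minlength=5)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            labels[i] = tied[0]
        else:
            # earliest-appearing tied state wins
            first_pos = {int(s): int(np.argmax(w == s)) for s in tied}
            labels[i] = min(tied, key=lambda s: first_pos[int(s)])

    seiz_per_epoch = (windows == _S).sum(axis=1)
    labels[seiz_per_epoch > 5] = _S
    # guarantee every seizure run is represented
    in_run = False
    run_start = 0
    for s in list(np.flatnonzero(np.diff(np.concatenate([[0], (track == _S).astype(int), [0]])))):
        if not in_run:
            run_start, in_run = s, True
        else:
            run_end, in_run = s, False
            e0, e1 = run_start // ep, (run_end - 1) // ep
            if not np.any(labels[e0:e1 + 1] == _S):
                shares = [(min(run_end, (e + 1) * ep) - max(run_start, e * ep), e)
                          for e in range(e0, e1 + 1)]
                best = max(shares, key=lambda t: (t[0], -t[1]))
                labels[best[1]] = _S
    return StateLabels(labels=as_names(labels), epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# corpus convenience
# ---------------------------------------------------------------------------

def generate_subject(config: SynthConfig, subject_id: str, seed,
                     with_seizures: bool = True,
                     profiles: dict | None = None):
    """One subject's (recording, per-second truth, 20 s epoch labels)."""
    rng = np.random.default_rng(seed)
    track = sample_state_track(config, rng, with_seizures=with_seizures)
    rec = synthesize_recording(track, config, rng, subject_id=subject_id,
                               profiles=profiles)
    labels = label_epochs(track, config.epoch_len_s)
    return rec, track, labels


def generate_corpus(config: SynthConfig, seed: int | None = None):
    """Yield (subject_id, with_seizures, recording, track, labels) for the
    configured corpus; the first ``n_seizure_subjects`` are epileptic."""
    base = config.seed if seed is None else seed
    for i in range(config.n_subjects):
        sid = f"synth{i:02d}"
        with_sz = i < config.n_seizure_subjects
        rec, track, labels = generate_subject(
            config, sid, seed=[base, i], with_seizures=with_sz)
        yield sid, with_sz, rec, track, labels
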