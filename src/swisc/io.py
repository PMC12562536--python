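"""Recording, epoch-array, feature-matrix and label I/O.

The native on-disk container is a flat ``.npy`` array next to a JSON sidecar
that carries the metadata (sampling rate, channel roles, subject id, shapes).
EDF and MAT v7.3 imports are provided as optional readers for lab data; the
rest of the pipeline only ever sees the validated in-memory containers below.

Channel order is canonicalized to (ECoG, HPC-L, HPC-R, EMG) on read so that
feature-vector layout is fixed no matter how the source file orders channels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataQualityError, FormatError, LayoutError, VocabularyError
from .states import N_STATES, STATES, as_indices, as_names

#: Canonical channel roles, in canonical order.
ROLES: tuple[str, ...] = ("ECoG", "HPC-L", "HPC-R", "EMG")


def _require_finite(arr: np.ndarray, what: str) -> None:
    if not np.isfinite(arr).all():
        raise DataQualityError(f"{what} contains NaN or Inf values")


def _canonical_roles(roles) -> tuple[str, ...]:
    roles = tuple(str(r) for r in roles)
    unknown = [r for r in roles if r not in ROLES]
    if unknown:
        raise LayoutError(f"unknown channel roles: {unknown}")
    if len(set(roles)) != len(roles):
        raise LayoutError("duplicate channel roles")
    return roles


@dataclasses.dataclass
class Recording:
    """A multichannel continuous recording with role-tagged channels.

    ``signals`` has shape (n_channels, n_samples); ``roles[i]`` names channel
    ``i``. After :func:`Recording.validate` the channels are sorted into the
    canonical (ECoG, HPC-L, HPC-R, EMG) order (or the canonical order of the
    declared subset for reduced montages).
    """

    signals: np.ndarray
    rate: float
    roles: tuple[str, ...]
    subject_id: str = ""
    start_time: str | None = None

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals))
        self.roles = _canonical_roles(self.roles)
        self.validate()

    def validate(self) -> "Recording":
        if self.rate <= 0:
            raise FormatError("sampling rate must be positive")
        if self.signals.shape[0] != len(self.roles):
            raise LayoutError(
                f"{self.signals.shape[0]} channels but {len(self.roles)} roles"
            )
        _require_finite(self.signals, "recording")
        order = sorted(range(len(self.roles)), key=lambda i: ROLES.index(self.roles[i]))
        if order != list(range(len(self.roles))):
            self.signals = self.signals[order]
            self.roles = tuple(self.roles[i] for i in order)
        return self

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.signals[self.roles.index(role)]
        except ValueError:
            raise LayoutError(f"recording has no {role} channel") from None


@dataclasses.dataclass
class EpochArray:
    """Epoched signal tensor of shape (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    epoch_len_s: float
    rate: float
    roles: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError("epoch array must be 3-dimensional")
        self.roles = _canonical_roles(self.roles)
        expected = int(round(self.epoch_len_s * self.rate))
        if self.data.shape[2] != expected:
            raise FormatError(
                f"epoch has {self.data.shape[2]} samples, expected "
                f"{expected} = {self.epoch_len_s} s x {self.rate} Hz"
            )
        _require_finite(self.data, "epoch array")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclasses.dataclass
class StateLabels:
    """Per-epoch categorical labels over the five-state alphabet."""

    labels: np.ndarray  # state names, dtype=object
    epoch_len_s: float = 20.0

    def __post_init__(self):
        idx = as_indices(self.labels)
        self.labels = as_names(idx)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def indices(self) -> np.ndarray:
        return as_indices(self.labels)

    @property
    def onehot(self) -> np.ndarray:
        """(n_epochs, 5) binary matrix in (wake, NREM, REM, seizure, postictal) order."""
        return np.eye(N_STATES, dtype=np.int64)[self.indices]


@dataclasses.dataclass
class FeatureMatrix:
    """Per-epoch feature vectors plus the ordered feature-name manifest."""

    values: np.ndarray
    feature_set: str
    manifest: list[str]
    epoch_len_s: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError("feature matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.manifest):
            raise FormatError("manifest length does not match feature count")
        _require_finite(self.values, "feature matrix")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# native container: .npy + .json sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    p = Path(path)
    return p if p.suffix == ".json" else p.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
    side = _sidecar_path(path)
    npy = side.with_suffix(".npy")
    np.save(npy, rec.signals)
    side.write_text(json.dumps({
        "kind": "recording",
        "data": npy.name,
        "rate": rec.rate,
        "roles": list(rec.roles),
        "subject_id": rec.subject_id,
        "start_time": rec.start_time,
        "dtype": str(rec.signals.dtype),
        "shape": list(rec.signals.shape),
    }, indent=1))
    return side


def read_recording(path, layout: dict | None = None, strict: bool = True) -> Recording:
    """Read a native-container recording.

    Parameters
    ----------
    layout
        Optional mapping from file channel names to canonical roles; by
        default the sidecar's own role names are used.
    strict
        When True, require all four canonical roles to be present; set False
        for deliberately reduced montages (channel-dropping studies).
    """
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"no sidecar found at {side}")
    meta = json.loads(side.read_text())
    signals = np.load(side.parent / meta["data"])
    roles = [str(r) for r in meta["roles"]]
    if layout:
        roles = [layout.get(r, r) for r in roles]
    missing = [r for r in ROLES if r not in roles]
    if strict and missing:
        raise LayoutError(f"recording is missing required roles: {missing}")
    return Recording(
        signals=signals,
        rate=float(meta["rate"]),
        roles=tuple(roles),
        subject_id=str(meta.get("subject_id", "")),
        start_time=meta.get("start_time"),
    )


def write_epochs(epochs: EpochArray, path) -> Path:
    side = _sidecar_path(path)
    npy = side.with_suffix(".npy")
    np.save(npy, epochs.data)
    side.write_text(json.dumps({
        "kind": "epochs",
        "data": npy.name,
        "rate": epochs.rate,
        "roles": list(epochs.roles),
        "epoch_len_s": epochs.epoch_len_s,
        "dtype": str(epochs.data.dtype),
        "shape": list(epochs.data.shape),
    }, indent=1))
    return side


def read_epochs(path) -> EpochArray:
    side = _sidecar_path(path)
    meta = json.loads(side.read_text())
    data = np.load(side.parent / meta["data"])
    return EpochArray(data=data, epoch_len_s=float(meta["epoch_len_s"]),
                      rate=float(meta["rate"]), roles=tuple(meta["roles"]))


def write_features(fm: FeatureMatrix, path) -> Path:
    side = _sidecar_path(path)
    npy = side.with_suffix(".npy")
    np.save(npy, fm.values)
    side.write_text(json.dumps({
        "kind": "features",
        "data": npy.name,
        "feature_set": fm.feature_set,
        "manifest": fm.manifest,
        "epoch_len_s": fm.epoch_len_s,
    }, indent=1))
    return side


def read_features(path) -> FeatureMatrix:
    side = _sidecar_path(path)
    meta = json.loads(side.read_text())
    values = np.load(side.parent / meta["data"])
    return FeatureMatrix(values=values, feature_set=meta["feature_set"],
                         manifest=list(meta["manifest"]),
                         epoch_len_s=float(meta["epoch_len_s"]))


# ---------------------------------------------------------------------------
# label CSV: dense, 0-based, one row per epoch
# ---------------------------------------------------------------------------

def write_labels(labels: StateLabels, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"epoch_index": np.arange(len(labels)),
                       "state": labels.labels})
    df.to_csv(path, index=False)
    return path


def read_labels(path, epoch_len_s: float = 20.0) -> StateLabels:
    df = pd.read_csv(path)
    if not {"epoch_index", "state"}.issubset(df.columns):
        raise FormatError("label CSV must have columns (epoch_index, state)")
    idx = df["epoch_index"].to_numpy()
    if len(idx) == 0:
        raise FormatError("label CSV is empty")
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError("epoch indices must be dense and 0-based")
    states = df["state"].astype(str).to_numpy()
    bad = sorted(set(states) - set(STATES))
    if bad:
        raise VocabularyError(f"unknown states in label CSV: {bad}")
    return StateLabels(labels=states, epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# optional importers for lab formats
# ---------------------------------------------------------------------------

def read_edf(path, layout: dict, subject_id: str = "") -> Recording:
    """Import a recording from EDF using MNE (optional dependency).

    ``layout`` maps EDF channel names to canonical roles.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - depends on environment
        raise ImportError("EDF import requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [name for name in raw.ch_names if name in layout]
    if not picks:
        raise LayoutError("no EDF channels matched the provided layout")
    data = raw.get_data(picks=picks)
    roles = tuple(layout[name] for name in picks)
    return Recording(signals=data, rate=float(raw.info["sfreq"]),
                     roles=roles, subject_id=subject_id)


def read_mat73(path, layout: dict, rate: float, subject_id: str = "") -> Recording:
    """Import channels from a MAT v7.3 (HDF5) file; ``layout`` maps dataset
    names to canonical roles."""
    import h5py

    signals, roles = [], []
    with h5py.File(path, "r") as f:
        for name, role in layout.items():
            if name not in f:
                raise LayoutError(f"dataset {name!r} not found in {path}")
            signals.append(np.asarray(f[name]).squeeze())
            roles.append(role)
    return Recording(signals=np.vstack(signals), rate=rate,
                     roles=tuple(roles), subject_id=subject_id)
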