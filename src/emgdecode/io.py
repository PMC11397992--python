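"""Reading and preparing paired sEMG-envelope / joint-angle recordings.

The on-disk convention follows the Ninapro DB1 layout: a MAT (v5) file per
subject holding an ``emg`` matrix (T x C rectified envelope channels), a
``glove`` matrix (T x 22 joint angles from a CyberGlove), a per-sample
movement ``stimulus`` vector and a ``repetition`` vector, all sampled at
100 Hz.  One :class:`SignalRecord` is produced per movement present in the
file; the rest plateaus between repetitions of a movement are kept inside
the record so that downstream windowing sees the full trace, troughs
included.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

__all__ = [
    "SignalRecord",
    "read_ninapro_mat",
    "select_target_angle",
    "normalize_angle",
    "denormalize_angle",
    "save_processed",
    "load_processed",
]

DEFAULT_FS = 100.0
#: Default DB1-style movement labels for the three wrist movements.  The
#: stimulus indices are dataset-configuration values, not universal truths;
#: override them when your files use a different numbering.
MOVEMENT_LABELS = {"WF": 13, "WUD": 15, "WECH": 21}


@dataclass
class SignalRecord:
    """One subject/movement recording: EMG envelopes plus an angle trace.

    Attributes
    ----------
    emg : ndarray, shape (T, C)
        Non-negative rectified envelope amplitudes, one column per electrode.
    angle : ndarray, shape (T,)
        The target joint angle (degrees raw, or dimensionless in [0, 1] once
        ``normalized`` is set).
    fs : float
        Sampling rate in Hz; EMG and glove share it.
    subject_id, movement_id : int
        Metadata carried through to the metrics tables.
    repetition : ndarray, shape (T,)
        1-based repetition index per sample, 0 during rest.
    normalized : bool
        Whether ``angle`` has been mapped to [0, 1].
    """

    emg: np.ndarray
    angle: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: int = 0
    movement_id: int = 0
    repetition: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float).ravel()
        if self.emg.ndim != 2:
            raise ValueError(f"emg must be 2-D (T x C), got shape {self.emg.shape}")
        if self.repetition is None:
            self.repetition = np.zeros(len(self.angle), dtype=int)
        self.repetition = np.asarray(self.repetition).ravel().astype(int)
        t_emg, t_ang, t_rep = len(self.emg), len(self.angle), len(self.repetition)
        if not (t_emg == t_ang == t_rep):
            raise ValueError(
                f"length mismatch: emg has {t_emg} samples, angle {t_ang}, "
                f"repetition {t_rep}"
            )
        if t_emg < 1 or self.emg.shape[1] < 1:
            raise ValueError("record must have T >= 1 samples and C >= 1 channels")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if np.any(self.emg < 0):
            raise ValueError("emg envelopes must be non-negative (rectified input)")
        if self.normalized and (self.angle.min() < 0 or self.angle.max() > 1):
            raise ValueError("normalized record has angle values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]


def _require_numeric(name: str, arr: object) -> np.ndarray:
    a = np.asarray(arr)
    if not np.issubdtype(a.dtype, np.number):
        raise TypeError(f"MAT variable {name!r} is not numeric (dtype {a.dtype})")
    return a.astype(float)


def read_ninapro_mat(
    path,
    *,
    emg_key: str = "emg",
    glove_key: str = "glove",
    label_key: str = "stimulus",
    repetition_key: str = "repetition",
    sensor_index: int = 0,
    fs: float = DEFAULT_FS,
    subject_id: int = 0,
) -> list[SignalRecord]:
    """Read a DB1-style MAT file into one :class:`SignalRecord` per movement.

    Each movement label ``m > 0`` present in the stimulus vector yields one
    record spanning from its first to its last sample, so the rest segments
    that separate repetitions of the same movement remain inside the record.

    Parameters
    ----------
    sensor_index : int
        Which glove column is the target angle.  The CyberGlove has 22
        sensors and the wrist sensor index is a dataset decision, so it is an
        explicit argument rather than a trusted default.
    """
    mat = scipy.io.loadmat(str(path))
    arrays = {}
    for role, key in [
        ("emg", emg_key),
        ("glove", glove_key),
        ("label", label_key),
        ("repetition", repetition_key),
    ]:
        if key not in mat:
            raise KeyError(
                f"MAT file {path} has no variable {key!r} (needed for {role})"
            )
        arrays[role] = _require_numeric(key, mat[key])

    emg = np.atleast_2d(arrays["emg"])
    glove = np.atleast_2d(arrays["glove"])
    labels = arrays["label"].ravel().astype(int)
    reps = arrays["repetition"].ravel().astype(int)

    lengths = {
        "emg": emg.shape[0],
        "glove": glove.shape[0],
        "labels": len(labels),
        "repetition": len(reps),
    }
    if len(set(lengths.values())) != 1:
        raise ValueError(f"ragged MAT arrays, per-variable lengths: {lengths}")

    angle = select_target_angle(glove, sensor_index)
    records = []
    for m in sorted(set(labels[labels > 0])):
        idx = np.flatnonzero(labels == m)
        lo, hi = idx[0], idx[-1] + 1  # keep inter-repetition rest inside
        records.append(
            SignalRecord(
                emg=emg[lo:hi].copy(),
                angle=angle[lo:hi].copy(),
                fs=fs,
                subject_id=subject_id,
                movement_id=int(m),
                repetition=np.where(labels[lo:hi] == m, reps[lo:hi], 0),
            )
        )
    return records


def select_target_angle(glove: np.ndarray, sensor_index: int) -> np.ndarray:
    """Pick the scalar target-angle trace (one glove column) out of T x A."""
    glove = np.atleast_2d(np.asarray(glove, dtype=float))
    n_sensors = glove.shape[1]
    if not 0 <= sensor_index < n_sensors:
        raise IndexError(
            f"sensor_index {sensor_index} out of range for {n_sensors} glove sensors"
        )
    return glove[:, sensor_index].copy()


def normalize_angle(record: SignalRecord, min_val: float, max_val: float) -> SignalRecord:
    """Map the angle trace to [0, 1] with a fixed affine transform, clipping.

    ``min_val``/``max_val`` must come from the TRAINING portion of the trace
    only; passing them in (rather than computing them here) keeps test-set
    statistics out of the transform.
    """
    if not max_val > min_val:
        raise ValueError(f"max_val ({max_val}) must exceed min_val ({min_val})")
    scaled = np.clip((record.angle - min_val) / (max_val - min_val), 0.0, 1.0)
    return dataclasses.replace(record, angle=scaled, normalized=True)


def denormalize_angle(record: SignalRecord, min_val: float, max_val: float) -> SignalRecord:
    """Inverse of :func:`normalize_angle` for in-range values."""
    if not max_val > min_val:
        raise ValueError(f"max_val ({max_val}) must exceed min_val ({min_val})")
    raw = record.angle * (max_val - min_val) + min_val
    return dataclasses.replace(record, angle=raw, normalized=False)


def save_processed(path, *, features, targets, window_starts, config: dict) -> None:
    """Write a processed dataset (feature matrix + targets) with a JSON sidecar."""
    path = Path(path)
    np.savez(
        path,
        features=np.asarray(features, dtype=float),
        targets=np.asarray(targets, dtype=float),
        window_starts=np.asarray(window_starts, dtype=int),
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(config, indent=2, sort_keys=True))


def load_processed(path):
    """Read back a processed dataset written by :func:`save_processed`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    sidecar = path.with_suffix(".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return data["features"], data["targets"], data["window_starts"], config
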