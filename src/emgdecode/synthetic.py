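"""Synthetic paired sEMG-envelope / wrist-angle generator.

Real recordings of this kind are rectified, low-pass-filtered EMG envelopes
sampled at 100 Hz alongside a glove angle, with muscle activation leading the
measured motion by the electromechanical delay (roughly 50-100 ms).  The
generator reproduces exactly that structure with known ground truth:

* the angle trace is a train of raised-cosine bursts (smooth peaks, like
  repeated flexion movements) separated by rest plateaus at zero;
* each EMG channel is ``baseline + weight * activation`` where the
  activation is the angle shifted *earlier* by ``lead_ms``;
* noise is multiplicative, ``|1 + eps|`` with Gaussian ``eps``, which keeps
  envelopes non-negative without clipping bias and preserves the monotone
  weight -> MAV relationship used for parameter-recovery checks.

It emulates repetition timing, activation lead, and channel coupling; it does
not model motor-unit biophysics, electrode shift, or fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

from .io import DEFAULT_FS, SignalRecord

__all__ = ["SyntheticConfig", "generate_angle_trajectory", "generate_record", "export_mat"]


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic subject/movement recording."""

    n_channels: int = 10
    fs: float = DEFAULT_FS
    n_repetitions: int = 10
    rep_duration_s: float = 5.0  # DB1 acquisition protocol: 5 s movement,
    rest_duration_s: float = 3.0  # 3 s rest, 10 repetitions
    lead_ms: float = 75.0  # electromechanical delay: activation precedes motion
    channel_weights: np.ndarray | None = None
    baseline: float = 0.05
    noise_sd: float = 0.05
    seed: int = 0
    subject_id: int = 1
    movement_id: int = 1

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.rep_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.lead_ms < 0:
            raise ValueError("lead_ms must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_weights is None:
            # distinct couplings so channels are informative but not identical
            self.channel_weights = 0.5 + np.linspace(0.0, 1.5, self.n_channels)
        self.channel_weights = np.asarray(self.channel_weights, dtype=float).ravel()
        if len(self.channel_weights) != self.n_channels:
            raise ValueError(
                f"channel_weights has length {len(self.channel_weights)}, "
                f"expected n_channels={self.n_channels}"
            )
        if np.any(self.channel_weights < 0):
            raise ValueError("channel_weights must be non-negative")


def _segment_lengths(config: SyntheticConfig) -> tuple[int, int]:
    rep = int(round(config.rep_duration_s * config.fs))
    rest = int(round(config.rest_duration_s * config.fs))
    return rep, rest


def generate_angle_trajectory(config: SyntheticConfig) -> np.ndarray:
    """Rest plateaus at 0 interleaved with raised-cosine bursts peaking at 1.

    Layout: rest, burst, rest, burst, ..., rest — ``n_repetitions`` bursts
    with a rest segment before, between, and after.  Values lie in [0, 1] and
    the trace is deterministic (no noise enters the kinematics).
    """
    rep_n, rest_n = _segment_lengths(config)
    burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(rep_n) / rep_n))
    parts = [np.zeros(rest_n)]
    for _ in range(config.n_repetitions):
        parts.append(burst)
        parts.append(np.zeros(rest_n))
    return np.concatenate(parts)


def repetition_vector(config: SyntheticConfig) -> np.ndarray:
    """1-based repetition index per sample, 0 on rest plateaus."""
    rep_n, rest_n = _segment_lengths(config)
    parts = [np.zeros(rest_n, dtype=int)]
    for r in range(1, config.n_repetitions + 1):
        parts.append(np.full(rep_n, r, dtype=int))
        parts.append(np.zeros(rest_n, dtype=int))
    return np.concatenate(parts)


def generate_record(config: SyntheticConfig) -> SignalRecord:
    """Generate one seeded :class:`SignalRecord` with known structure.

    The muscle activation is the angle advanced by ``lead_ms`` (edge-padded),
    so the envelopes rise before the angle does, as real EMG does.
    """
    angle = generate_angle_trajectory(config)
    lead = int(round(config.lead_ms * config.fs / 1000.0))
    if lead > 0:
        activation = np.concatenate([angle[lead:], np.full(lead, angle[-1])])
    else:
        activation = angle.copy()

    rng = np.random.default_rng(config.seed)
    clean = config.baseline + np.outer(activation, config.channel_weights)
    eps = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
    emg = clean * np.abs(1.0 + eps)

    return SignalRecord(
        emg=emg,
        angle=angle,
        fs=config.fs,
        subject_id=config.subject_id,
        movement_id=config.movement_id,
        repetition=repetition_vector(config),
        normalized=True,
    )


def export_mat(
    record: SignalRecord,
    path,
    *,
    sensor_index: int = 0,
    n_glove_sensors: int = 22,
) -> None:
    """Write a record as a DB1-style MAT v5 file.

    The glove matrix is T x 22 with the angle in ``sensor_index`` and zeros
    elsewhere.  The stimulus vector carries the movement label over the whole
    trace (rest plateaus are distinguished by repetition == 0) so that the
    reader, which trims to the labelled span, round-trips the record exactly,
    leading and trailing rest included.
    """
    path = Path(path)
    glove = np.zeros((record.n_samples, n_glove_sensors))
    glove[:, sensor_index] = record.angle
    stimulus = np.full(record.n_samples, record.movement_id, dtype=int)
    scipy.io.savemat(
        str(path),
        {
            "emg": record.emg,
            "glove": glove,
            "stimulus": stimulus.reshape(-1, 1),
            "repetition": record.repetition.reshape(-1, 1),
        },
    )
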