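"""Sliding-window segmentation and per-channel EMG features.

A recording is cut into overlapping windows (default 100 ms with 10 ms
overlap at 100 Hz, i.e. 10-sample windows advancing by 9); the sample
immediately after each window is its regression target, so a model trained
on the windows predicts the *next* angle sample and never sees the future.

Features are computed per channel per window and concatenated channel-major
(all features of channel 0, then channel 1, ...).  The two defaults are the
time-domain pair MAV and RMS; VAR and the periodogram-based spectral trio
MNP / MNF / MDF are available for feature-comparison sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "WindowConfig",
    "FeatureSequence",
    "FEATURE_NAMES",
    "make_windows",
    "mav",
    "rms",
    "extra_features",
    "compute_feature",
    "split_half",
]

FEATURE_NAMES = ("MAV", "RMS", "VAR", "MNP", "MNF", "MDF")


@dataclass(frozen=True)
class WindowConfig:
    """Windowing and feature-set parameters (durations in milliseconds)."""

    window_ms: float = 100.0
    overlap_ms: float = 10.0
    feature_set: tuple[str, ...] = ("MAV", "RMS")

    def __post_init__(self) -> None:
        if not self.window_ms > self.overlap_ms >= 0:
            raise ValueError(
                f"need window_ms > overlap_ms >= 0, got {self.window_ms} / {self.overlap_ms}"
            )
        object.__setattr__(self, "feature_set", tuple(self.feature_set))
        unknown = [f for f in self.feature_set if f not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown features {unknown}; choose from {FEATURE_NAMES}")
        if not self.feature_set:
            raise ValueError("feature_set must be nonempty")

    def samples(self, fs: float) -> tuple[int, int]:
        """Window and overlap lengths in samples; errors on fractional counts."""
        w = self.window_ms * fs / 1000.0
        o = self.overlap_ms * fs / 1000.0
        if abs(w - round(w)) > 1e-9 or abs(o - round(o)) > 1e-9:
            raise ValueError(
                f"window/overlap of {self.window_ms}/{self.overlap_ms} ms are not "
                f"whole samples at fs={fs} Hz"
            )
        w, o = int(round(w)), int(round(o))
        if w < 1:
            raise ValueError("window shorter than one sample")
        return w, o


@dataclass
class FeatureSequence:
    """Time-ordered window features plus next-sample angle targets."""

    features: np.ndarray  # (N, C*F), channel-major
    targets: np.ndarray  # (N,)
    window_starts: np.ndarray  # (N,) 0-based sample indices
    config: WindowConfig
    fs: float = 100.0
    subject_id: int = 0
    movement_id: int = 0

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        self.window_starts = np.asarray(self.window_starts).ravel().astype(int)
        n = len(self.features)
        if not (n == len(self.targets) == len(self.window_starts)):
            raise ValueError(
                f"row mismatch: {n} feature rows, {len(self.targets)} targets, "
                f"{len(self.window_starts)} window starts"
            )

    def __len__(self) -> int:
        return len(self.targets)


def mav(window: np.ndarray) -> float:
    """Mean absolute value, ``(1/W) * sum |x_i|``."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(window)))


def rms(window: np.ndarray) -> float:
    """Root mean square, ``sqrt((1/W) * sum x_i^2)``."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(window**2)))


def extra_features(window: np.ndarray, fs: float) -> tuple[float, float, float, float]:
    """(VAR, MNP, MNF, MDF) of one window.

    VAR is the unbiased sample variance.  The spectral features come from a
    plain one-sided periodogram of the raw window with the DC bin included in
    total power (rectified envelopes carry most of their power at DC, so
    excluding it would be a different dialect): MNP is the mean periodogram
    power, MNF the power-weighted mean frequency, and MDF the lowest
    frequency at which cumulative power reaches half the total (ties resolve
    to the lower bin).
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("spectral and variance features need W >= 2")
    var = float(np.var(window, ddof=1))
    freqs, power = periodogram(window, fs=fs, detrend=False)
    total = power.sum()
    mnp = float(power.mean())
    if total <= 0:
        return var, mnp, 0.0, 0.0
    mnf = float((freqs * power).sum() / total)
    mdf = float(freqs[np.searchsorted(np.cumsum(power), 0.5 * total)])
    return var, mnp, mnf, mdf


def compute_feature(name: str, window: np.ndarray, fs: float) -> float:
    """Evaluate one named feature on one single-channel window."""
    if name == "MAV":
        return mav(window)
    if name == "RMS":
        return rms(window)
    if name in ("VAR", "MNP", "MNF", "MDF"):
        return extra_features(window, fs)[("VAR", "MNP", "MNF", "MDF").index(name)]
    raise ValueError(f"unknown feature {name!r}")


def make_windows(record, config: WindowConfig) -> FeatureSequence:
    """Segment a record into windows with next-sample targets.

    Windows start at 0 and advance by ``stride = W - O`` samples; the last
    window is the one with the largest start such that ``start + W <= T - 1``
    (one sample must remain to serve as the target), giving
    ``N = floor((T - W - 1) / stride) + 1`` windows with
    ``target[i] = angle[start_i + W]``.
    """
    w, o = config.samples(record.fs)
    stride = w - o
    t = record.n_samples
    if t < w + 1:
        raise ValueError(
            f"record of {t} samples too short for {w}-sample windows plus a target"
        )
    starts = np.arange(0, t - w, stride)
    emg = record.emg
    n_windows, n_channels = len(starts), emg.shape[1]
    feats = np.empty((n_windows, n_channels * len(config.feature_set)))
    for i, s in enumerate(starts):
        seg = emg[s : s + w]
        col = 0
        for c in range(n_channels):
            spectral_cache = None
            for name in config.feature_set:
                if name == "MAV":
                    feats[i, col] = np.mean(np.abs(seg[:, c]))
                elif name == "RMS":
                    feats[i, col] = np.sqrt(np.mean(seg[:, c] ** 2))
                else:
                    if spectral_cache is None:
                        spectral_cache = extra_features(seg[:, c], record.fs)
                    feats[i, col] = spectral_cache[("VAR", "MNP", "MNF", "MDF").index(name)]
                col += 1
    return FeatureSequence(
        features=feats,
        targets=record.angle[starts + w],
        window_starts=starts,
        config=config,
        fs=record.fs,
        subject_id=record.subject_id,
        movement_id=record.movement_id,
    )


def split_half(sequence: FeatureSequence) -> tuple[FeatureSequence, FeatureSequence]:
    """Chronological 1:1 split: first ceil(N/2) windows train, the rest test.

    No shuffling — the held-out half is a continuous trace, so predictions on
    it can be plotted against the true angle as one unbroken curve.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError(f"need at least 2 windows to split, got {n}")
    cut = (n + 1) // 2

    def _slice(lo: int, hi: int) -> FeatureSequence:
        return replace(
            sequence,
            features=sequence.features[lo:hi],
            targets=sequence.targets[lo:hi],
            window_starts=sequence.window_starts[lo:hi],
        )

    return _slice(0, cut), _slice(cut, n)
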