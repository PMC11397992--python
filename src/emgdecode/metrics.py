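"""Regression metrics and the one-way ANOVA used for model comparison."""

from __future__ import annotations

import numpy as np
import scipy.stats

__all__ = ["rmse", "r_squared", "one_way_anova"]

ALPHA = 0.05


def _paired(y_pred, y_true) -> tuple[np.ndarray, np.ndarray]:
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    y_true = np.asarray(y_true, dtype=float).ravel()
    if len(y_pred) != len(y_true):
        raise ValueError(f"length mismatch: {len(y_pred)} predictions vs {len(y_true)} truths")
    if len(y_true) == 0:
        raise ValueError("empty vectors")
    return y_pred, y_true


def rmse(y_pred, y_true) -> float:
    """Root mean square error, ``sqrt(mean((y_pred - y_true)^2))``."""
    y_pred, y_true = _paired(y_pred, y_true)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_pred, y_true) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``.

    1 is a perfect fit and 0 matches the mean predictor; undefined (raises)
    when the truth is constant.
    """
    y_pred, y_true = _paired(y_pred, y_true)
    if len(y_true) < 2:
        raise ValueError("r_squared needs at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined: y_true is constant (zero total variance)")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - ss_res / ss_tot


def one_way_anova(groups: list) -> tuple[float, float, bool]:
    """Classic one-way ANOVA across groups of values.

    Returns ``(F, p, significant)`` with significance judged at 0.05.
    """
    clean = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(clean):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    f_stat, p_value = scipy.stats.f_oneway(*clean)
    return float(f_stat), float(p_value), bool(p_value < ALPHA)
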