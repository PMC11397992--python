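"""Published per-subject wrist-angle benchmark results shipped as data.

These are the reference per-subject RMSE and R² grids for the TCN, LSTM and
hybrid TCN-LSTM decoders on the public Ninapro-DB1 wrist task (8 intact
subjects; movements: wrist flexion WF, wrist ulnar deviation WUD, wrist
extension with closed hand WECH; normalized angle scale).  They exist so
the table-arithmetic layer — column means, grand means, spreads, percent
reductions, ANOVA — can be exercised and audited against known printed
values without downloading the underlying recordings.
"""

from __future__ import annotations

import numpy as np

from .tables import MetricsTable

__all__ = [
    "SUBJECTS",
    "MOVEMENTS",
    "MODELS",
    "RMSE_GRID",
    "R2_GRID",
    "reference_metrics_table",
]

SUBJECTS = (1, 2, 3, 4, 5, 6, 7, 8)
MOVEMENTS = ("WF", "WUD", "WECH")
MODELS = ("TCN", "LSTM", "TCN-LSTM")

#: RMSE per subject (rows) and movement (columns WF, WUD, WECH), per model.
RMSE_GRID = {
    "TCN": np.array([
        [0.092, 0.122, 0.088],
        [0.110, 0.109, 0.109],
        [0.094, 0.098, 0.074],
        [0.095, 0.128, 0.117],
        [0.148, 0.166, 0.166],
        [0.150, 0.139, 0.118],
        [0.092, 0.062, 0.088],
        [0.088, 0.097, 0.067],
    ]),
    "LSTM": np.array([
        [0.128, 0.131, 0.147],
        [0.144, 0.124, 0.156],
        [0.130, 0.137, 0.133],
        [0.148, 0.155, 0.141],
        [0.151, 0.163, 0.126],
        [0.164, 0.157, 0.166],
        [0.129, 0.122, 0.077],
        [0.092, 0.095, 0.113],
    ]),
    "TCN-LSTM": np.array([
        [0.051, 0.058, 0.049],
        [0.061, 0.078, 0.091],
        [0.067, 0.052, 0.049],
        [0.073, 0.056, 0.070],
        [0.079, 0.098, 0.065],
        [0.049, 0.091, 0.075],
        [0.076, 0.049, 0.055],
        [0.056, 0.045, 0.046],
    ]),
}

#: R² per subject and movement, per model (same layout as RMSE_GRID).
R2_GRID = {
    "TCN": np.array([
        [0.768, 0.861, 0.885],
        [0.891, 0.794, 0.831],
        [0.879, 0.926, 0.946],
        [0.912, 0.873, 0.860],
        [0.561, 0.555, 0.557],
        [0.752, 0.848, 0.844],
        [0.889, 0.821, 0.842],
        [0.868, 0.784, 0.952],
    ]),
    "LSTM": np.array([
        [0.579, 0.828, 0.685],
        [0.827, 0.787, 0.656],
        [0.890, 0.885, 0.832],
        [0.855, 0.748, 0.797],
        [0.590, 0.590, 0.836],
        [0.695, 0.748, 0.693],
        [0.823, 0.759, 0.880],
        [0.850, 0.641, 0.863],
    ]),
    "TCN-LSTM": np.array([
        [0.883, 0.930, 0.963],
        [0.966, 0.919, 0.882],
        [0.939, 0.944, 0.976],
        [0.946, 0.964, 0.950],
        [0.877, 0.860, 0.880],
        [0.913, 0.913, 0.936],
        [0.948, 0.935, 0.939],
        [0.957, 0.915, 0.976],
    ]),
}


def reference_metrics_table() -> MetricsTable:
    """The full reference benchmark as one :class:`MetricsTable` (72 rows)."""
    rows = []
    for model in MODELS:
        for i, s in enumerate(SUBJECTS):
            for j, m in enumerate(MOVEMENTS):
                rows.append({
                    "subject_id": s,
                    "movement_id": m,
                    "model": model,
                    "rmse": float(RMSE_GRID[model][i, j]),
                    "r2": float(R2_GRID[model][i, j]),
                })
    return MetricsTable(rows)
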