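"""Experiment orchestration: model comparison, sweeps, and report rendering.

Every run is fully determined by (configuration, seed list, input data); a
plain-text manifest written next to the outputs records all three so a run
can be replayed byte-identically.  Sweep cells share no mutable state, so
permuting their execution order cannot change results.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import LSTMRegressor, TCNLSTMRegressor, TCNRegressor, evaluate
from .features import FeatureSequence, WindowConfig, make_windows, split_half
from .io import SignalRecord, normalize_angle
from .metrics import one_way_anova
from .synthetic import SyntheticConfig, generate_record
from .tables import MetricsTable

__all__ = [
    "MODEL_FACTORIES",
    "SweepSpec",
    "prepare_sequences",
    "synthetic_dataset",
    "run_model_comparison",
    "run_sweep",
    "render_report",
]

logger = logging.getLogger("emgdecode")

MODEL_FACTORIES = {
    "TCN": TCNRegressor,
    "LSTM": LSTMRegressor,
    "TCN-LSTM": TCNLSTMRegressor,
}

SWEEP_AXES = ("window_ms", "kernel_size", "channels", "feature_set", "model")


@dataclass
class SweepSpec:
    """One hyperparameter axis to sweep, with replicate seeds."""

    axis: str
    values: list
    replicate_seeds: list[int] = field(default_factory=lambda: [0])
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"unknown sweep axis {self.axis!r}; choose from {SWEEP_AXES}")
        if not self.values:
            raise ValueError("sweep values must be nonempty")
        if self.axis == "model":
            bad = [v for v in self.values if v not in MODEL_FACTORIES]
            if bad:
                raise ValueError(f"unknown models {bad}")
        if self.axis == "feature_set":
            self.values = [tuple(v) for v in self.values]
        if not self.replicate_seeds:
            raise ValueError("replicate_seeds must be nonempty")


def prepare_sequences(
    record: SignalRecord, window: WindowConfig
) -> tuple[FeatureSequence, FeatureSequence]:
    """Normalize -> window -> chronological 1:1 split for one record.

    The angle min/max come from the training (first) half of the trace only,
    so no test-set statistic leaks into the transform.
    """
    half = record.n_samples // 2
    train_angle = record.angle[:half]
    lo, hi = float(train_angle.min()), float(train_angle.max())
    if hi > lo:
        record = normalize_angle(record, lo, hi)
    seq = make_windows(record, window)
    return split_half(seq)


def synthetic_dataset(
    n_subjects: int = 2,
    *,
    seed: int = 0,
    noise_sd: float = 0.05,
    n_channels: int = 10,
    n_repetitions: int = 10,
    movement_id: int = 1,
) -> list[SignalRecord]:
    """Seeded cohort of synthetic subjects (one movement each)."""
    return [
        generate_record(
            SyntheticConfig(
                n_channels=n_channels,
                n_repetitions=n_repetitions,
                noise_sd=noise_sd,
                seed=seed * 100 + sid,
                subject_id=sid,
                movement_id=movement_id,
            )
        )
        for sid in range(1, n_subjects + 1)
    ]


def _make_estimator(name: str, seed: int, overrides: dict | None = None):
    overrides = dict(overrides or {})
    cls = MODEL_FACTORIES[name]
    valid = cls().get_params()
    kwargs = {k: v for k, v in overrides.items() if k in valid}
    kwargs["random_state"] = seed
    return cls(**kwargs)


def run_model_comparison(
    records: list[SignalRecord],
    models: tuple[str, ...] = ("TCN", "LSTM", "TCN-LSTM"),
    *,
    window: WindowConfig | None = None,
    seed: int = 0,
    estimator_overrides: dict | None = None,
    collect_traces: bool = False,
):
    """Train and evaluate each model on identical splits and seeds.

    Returns ``(table, anova)`` — a :class:`MetricsTable` with one row per
    (subject, movement, model), and the one-way ANOVA of per-subject mean
    RMSE across models (None when fewer than 2 subjects).  Failures in a
    single cell are recorded and the run continues.
    """
    window = window or WindowConfig()
    table = MetricsTable()
    traces: dict = {}
    failures: list[str] = []
    splits = [(rec, *prepare_sequences(rec, window)) for rec in records]
    for name in models:
        if name not in MODEL_FACTORIES:
            raise ValueError(f"unknown model {name!r}")
        for rec, train_seq, test_seq in splits:
            try:
                est = _make_estimator(name, seed, estimator_overrides)
                est.fit(train_seq.features, train_seq.targets)
                cell_rmse, cell_r2, trace = evaluate(est, test_seq)
                table.add(rec.subject_id, rec.movement_id, name, cell_rmse, cell_r2)
                if collect_traces:
                    traces[(rec.subject_id, rec.movement_id, name)] = trace
                logger.info(
                    "comparison %s subject=%s movement=%s rmse=%.6f r2=%.6f",
                    name, rec.subject_id, rec.movement_id, cell_rmse, cell_r2,
                )
            except Exception as exc:  # cell failure must not kill the run
                failures.append(f"{name}/s{rec.subject_id}/m{rec.movement_id}: {exc}")
                logger.warning("comparison cell failed: %s", failures[-1])
    anova = None
    if len(table) and len(records) >= 2 and len(models) >= 2:
        groups = [table.subject_means(m, "rmse").to_numpy() for m in models]
        anova = one_way_anova(groups)
    result = {"table": table, "anova": anova, "failures": failures}
    if collect_traces:
        result["traces"] = traces
    return result


def run_sweep(records: list[SignalRecord], spec: SweepSpec):
    """Mean +/- spread of test RMSE/R² per swept value, over replicate seeds."""
    rows = []
    for value in spec.values:
        cell_rmse, cell_r2 = [], []
        for rep_seed in spec.replicate_seeds:
            window = WindowConfig(
                window_ms=value if spec.axis == "window_ms"
                else spec.fixed.get("window_ms", 100.0),
                overlap_ms=spec.fixed.get("overlap_ms", 10.0),
                feature_set=value if spec.axis == "feature_set"
                else spec.fixed.get("feature_set", ("MAV", "RMS")),
            )
            model = value if spec.axis == "model" else spec.fixed.get("model", "TCN-LSTM")
            overrides = dict(spec.fixed.get("estimator", {}))
            if spec.axis == "kernel_size":
                overrides["kernel_size"] = int(value)
            elif spec.axis == "channels":
                overrides["channels"] = int(value)
            per_subject_rmse, per_subject_r2 = [], []
            for rec in records:
                train_seq, test_seq = prepare_sequences(rec, window)
                est = _make_estimator(model, rep_seed, overrides)
                est.fit(train_seq.features, train_seq.targets)
                r, r2, _ = evaluate(est, test_seq)
                per_subject_rmse.append(r)
                per_subject_r2.append(r2)
            cell_rmse.append(float(np.mean(per_subject_rmse)))
            cell_r2.append(float(np.mean(per_subject_r2)))
        rows.append({
            "value": value if not isinstance(value, tuple) else "+".join(value),
            "rmse_mean": float(np.mean(cell_rmse)),
            "rmse_sd": float(np.std(cell_rmse, ddof=1)) if len(cell_rmse) > 1 else 0.0,
            "r2_mean": float(np.mean(cell_r2)),
            "r2_sd": float(np.std(cell_r2, ddof=1)) if len(cell_r2) > 1 else 0.0,
            "n_seeds": len(spec.replicate_seeds),
        })
        logger.info("sweep %s=%s rmse=%.6f", spec.axis, value, rows[-1]["rmse_mean"])
    summary = pd.DataFrame(rows)
    best = summary.loc[summary["rmse_mean"].idxmin(), "value"]
    return {"axis": spec.axis, "summary": summary, "best_value": best}


def run_grid_sweep(
    records: list[SignalRecord],
    kernel_sizes=range(5, 41, 5),
    channel_counts=range(5, 41, 5),
    *,
    replicate_seeds=(0,),
    fixed: dict | None = None,
):
    """Kernel-size x channel-count grid of hybrid test RMSE (surface data)."""
    rows = []
    for k in kernel_sizes:
        for c in channel_counts:
            vals = []
            for rep_seed in replicate_seeds:
                per_subject = []
                for rec in records:
                    train_seq, test_seq = prepare_sequences(
                        rec, WindowConfig(**(fixed or {}).get("window", {}))
                    )
                    overrides = dict((fixed or {}).get("estimator", {}))
                    overrides.update(kernel_size=int(k), channels=int(c))
                    est = _make_estimator("TCN-LSTM", rep_seed, overrides)
                    est.fit(train_seq.features, train_seq.targets)
                    r, _, _ = evaluate(est, test_seq)
                    per_subject.append(r)
                vals.append(float(np.mean(per_subject)))
            rows.append({
                "kernel_size": int(k), "channels": int(c),
                "rmse_mean": float(np.mean(vals)),
                "rmse_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            })
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["rmse_mean"].idxmin(), ["kernel_size", "channels"]]
    return {"grid": grid, "best_kernel_size": int(best["kernel_size"]),
            "best_channels": int(best["channels"])}


def render_report(tables: dict, out_dir, *, manifest: dict | None = None,
                  traces: dict | None = None) -> list[Path]:
    """Write tab-separated tables, optional trace files/plots, and a manifest.

    ``tables`` maps name -> :class:`MetricsTable` or DataFrame.  Raises on an
    empty input rather than writing a partial report.
    """
    if not tables:
        raise ValueError("no tables to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        if isinstance(table, MetricsTable):
            if not len(table):
                raise ValueError(f"table {name!r} is empty")
            table.df.to_csv(path, sep="\t", index=False)
            for metric in ("rmse", "r2"):
                wide = out_dir / f"{name}_{metric}_wide.tsv"
                table.pivot(metric).to_csv(wide, sep="\t")
                written.append(wide)
        else:
            if len(table) == 0:
                raise ValueError(f"table {name!r} is empty")
            pd.DataFrame(table).to_csv(path, sep="\t", index=False)
        written.append(path)
    if traces:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for (sid, mid, model), trace in traces.items():
            stem = f"trace_s{sid}_m{mid}_{model}"
            np.savetxt(
                out_dir / f"{stem}.tsv", trace, delimiter="\t",
                header="actual\tpredicted", comments="",
            )
            written.append(out_dir / f"{stem}.tsv")
            fig, ax = plt.subplots(figsize=(8, 3))
            ax.plot(trace[:, 0], label="actual")
            ax.plot(trace[:, 1], label="predicted")
            ax.set_xlabel("test window")
            ax.set_ylabel("normalized angle")
            ax.set_title(f"subject {sid}, movement {mid}, {model}")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / f"{stem}.png", dpi=100)
            plt.close(fig)
            written.append(out_dir / f"{stem}.png")
    manifest = dict(manifest or {})
    manifest.setdefault("python", platform.python_version())
    manifest.setdefault("numpy", np.__version__)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(manifest_path)
    return written
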