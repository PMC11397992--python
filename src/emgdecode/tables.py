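"""Per-subject metrics tables with the aggregation used for model comparison.

A :class:`MetricsTable` holds one row per (subject, movement, model) with
that cell's RMSE and R².  Aggregation reproduces the standard benchmark
layout: per-movement column means over subjects ("Average" row), grand means
over movements per model, subject spread (both SD and SEM are reported —
published "±" values are often ambiguous between the two), and percent
change between models with the larger/baseline model as reference:

    reduction(%) = (mean_baseline - mean_other) / mean_baseline * 100
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MetricsTable"]

_COLUMNS = ["subject_id", "movement_id", "model", "rmse", "r2"]


class MetricsTable:
    def __init__(self, rows: pd.DataFrame | list[dict] | None = None) -> None:
        if rows is None:
            df = pd.DataFrame(columns=_COLUMNS)
        elif isinstance(rows, pd.DataFrame):
            df = rows.copy()
        else:
            df = pd.DataFrame(rows)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metrics table missing columns {missing}")
        if len(df) and (df["rmse"] < 0).any():
            raise ValueError("rmse must be non-negative")
        if len(df) and (df["r2"] > 1 + 1e-12).any():
            raise ValueError("r2 cannot exceed 1")
        self.df = df[_COLUMNS].reset_index(drop=True)

    def add(self, subject_id, movement_id, model, rmse, r2) -> None:
        row = pd.DataFrame(
            [{"subject_id": subject_id, "movement_id": movement_id,
              "model": model, "rmse": float(rmse), "r2": float(r2)}]
        )
        if rmse < 0:
            raise ValueError("rmse must be non-negative")
        if r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        self.df = pd.concat([self.df, row], ignore_index=True) if len(self.df) else row

    def __len__(self) -> int:
        return len(self.df)

    def _select(self, model=None, movement_id=None) -> pd.DataFrame:
        sel = self.df
        if model is not None:
            sel = sel[sel["model"] == model]
        if movement_id is not None:
            sel = sel[sel["movement_id"] == movement_id]
        if sel.empty:
            raise ValueError(
                f"empty selection for model={model!r}, movement={movement_id!r}"
            )
        return sel

    def column_mean(self, model, movement_id, metric: str = "rmse") -> float:
        """Mean over subjects for one model x movement cell (an 'Average' entry)."""
        return float(self._select(model, movement_id)[metric].mean())

    def grand_mean(self, model, metric: str = "rmse") -> float:
        """Mean of the per-movement column means for one model."""
        sel = self._select(model)
        return float(sel.groupby("movement_id")[metric].mean().mean())

    def subject_means(self, model, metric: str = "rmse") -> pd.Series:
        """Per-subject means over movements (the ANOVA unit of analysis)."""
        return self._select(model).groupby("subject_id")[metric].mean()

    def spread(self, model, metric: str = "rmse") -> dict[str, float]:
        """SD and SEM of the per-subject means for one model."""
        means = self.subject_means(model, metric)
        if len(means) < 2:
            raise ValueError("spread needs at least 2 subjects")
        sd = float(means.std(ddof=1))
        return {"sd": sd, "sem": sd / np.sqrt(len(means))}

    def percent_change(self, baseline_model, model, metric: str = "rmse") -> float:
        """Percent reduction of ``model`` relative to ``baseline_model``."""
        base = self.grand_mean(baseline_model, metric)
        if base == 0:
            raise ValueError("baseline grand mean is zero; percent change undefined")
        return (base - self.grand_mean(model, metric)) / base * 100.0

    def pivot(self, metric: str = "rmse") -> pd.DataFrame:
        """Benchmark-style layout: subject rows, (model, movement) columns, Average row."""
        if self.df.empty:
            raise ValueError("empty table")
        wide = self.df.pivot_table(
            index="subject_id", columns=["model", "movement_id"], values=metric
        )
        wide.loc["Average"] = wide.mean(axis=0)
        return wide

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetricsTable":
        return cls(pd.read_csv(Path(path)))

    @classmethod
    def from_arrays(cls, values: np.ndarray, *, subjects, movements, model,
                    metric: str = "rmse") -> "MetricsTable":
        """Build a table from a (subjects x movements) value grid for one model.

        The complementary metric column is filled with a neutral placeholder
        (0 for rmse, so tables built from a published grid of one metric can
        still aggregate that metric).
        """
        values = np.asarray(values, dtype=float)
        rows = []
        for i, s in enumerate(subjects):
            for j, m in enumerate(movements):
                cell = {"subject_id": s, "movement_id": m, "model": model,
                        "rmse": 0.0, "r2": 0.0}
                cell[metric] = values[i, j]
                rows.append(cell)
        return cls(rows)

    def merged(self, other: "MetricsTable") -> "MetricsTable":
        return MetricsTable(pd.concat([self.df, other.df], ignore_index=True))
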