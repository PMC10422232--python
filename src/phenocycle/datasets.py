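"""Labelled collections of NDVI series and their CSV round-trip.

The on-disk layout is one row per pixel: ``pixel_id, t0..t{T-1}[, label]``,
with missing observations as empty cells.  The same layout is used for raw,
reconstructed and labelled sample sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import NDVISeries

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """A collection of NDVI series with one class label per series."""

    series: list[NDVISeries]
    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.series) != len(self.labels):
            raise ValueError("one label per series required")
        if self.class_names:
            present = set(np.unique(self.labels).tolist())
            declared = set(self.class_names)
            if not present <= declared:
                raise ValueError(
                    f"labels {sorted(present - declared)} missing from class_names"
                )

    def __len__(self) -> int:
        return len(self.series)

    def class_counts(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            series=[self.series[i] for i in idx],
            labels=self.labels[idx],
            class_names=dict(self.class_names),
        )

    def to_frame(self) -> pd.DataFrame:
        t_len = len(self.series[0]) if self.series else 0
        rows = []
        for s, lab in zip(self.series, self.labels):
            row = {"pixel_id": s.pixel_id}
            for t in range(t_len):
                row[f"t{t}"] = np.nan if s.missing[t] else s.values[t]
            row["label"] = int(lab)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, class_names=None) -> "LabeledDataset":
        t_cols = sorted(
            (c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        series = []
        for _, row in df.iterrows():
            series.append(
                NDVISeries.from_values(
                    row[t_cols].to_numpy(dtype=float),
                    pixel_id=str(row.get("pixel_id", "")),
                )
            )
        labels = (
            df["label"].to_numpy(dtype=int)
            if "label" in df
            else np.zeros(len(series), dtype=int)
        )
        return cls(series=series, labels=labels, class_names=class_names or {})

    @classmethod
    def from_csv(cls, path, class_names=None) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path), class_names=class_names)
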