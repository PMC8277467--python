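"""Comparative statistics over per-event localization residuals.

Given a table of best residuals per event for the five method/modality
combinations (deterministic acoustic/seismic, probabilistic
acoustic/seismic, probabilistic joint), compute the column means and
standard deviations, the pairwise Pearson correlations that quantify
agreement between the two independent solvers, and the count of events
where the seismic residual beats the acoustic one under both frameworks.

Also includes the interaural-delay arithmetic that translates array-scale
TDOAs to the arrival-time differences available across a listening animal's
two ears (~1 m apart).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RESIDUAL_COLUMNS",
    "ResidualTable",
    "SummaryStats",
    "summarize",
    "interaural_delay",
    "load_field_residuals",
]

RESIDUAL_COLUMNS = (
    "det_acoustic",
    "det_seismic",
    "prob_acoustic",
    "prob_seismic",
    "prob_joint",
)

PEARSON_PAIRS = (
    ("det_acoustic", "prob_acoustic"),
    ("det_seismic", "prob_seismic"),
    ("prob_joint", "prob_seismic"),
    ("prob_joint", "prob_acoustic"),
)


@dataclass
class ResidualTable:
    """Per-event residuals (m) for the five method/modality combinations."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESIDUAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"residual table missing columns: {missing}")
        vals = self.data[list(RESIDUAL_COLUMNS)].to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("residuals must be finite and >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResidualTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def n_events(self) -> int:
        return len(self.data)


@dataclass
class SummaryStats:
    """Column means/s.d. (m), labelled Pearson r, and the seismic win count."""

    mean: dict
    sd: dict
    pearson: dict
    seismic_win_count: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "mean_m": self.mean,
            "sd_m": self.sd,
            "pearson": {f"{a}~{b}": r for (a, b), r in self.pearson.items()},
            "seismic_win_count": self.seismic_win_count,
        }

    def to_text(self) -> str:
        lines = ["Residual summary (m)", f"  events: {self.n_events}", ""]
        lines.append(f"  {'column':<16}{'mean':>8}{'s.d.':>8}")
        for c in RESIDUAL_COLUMNS:
            lines.append(f"  {c:<16}{self.mean[c]:>8.2f}{self.sd[c]:>8.2f}")
        lines.append("")
        for (a, b), r in self.pearson.items():
            lines.append(f"  Pearson r {a} ~ {b}: {r:.4f}")
        lines.append(
            f"  events where seismic beats acoustic in both frameworks: "
            f"{self.seismic_win_count}/{self.n_events}"
        )
        return "\n".join(lines)


def summarize(table: ResidualTable) -> SummaryStats:
    """Sample means, n-1 standard deviations, Pearson agreement, win count.

    The win count tallies events whose seismic residual is strictly smaller
    than the acoustic one under *both* the deterministic and probabilistic
    frameworks.
    """
    if table.n_events < 2:
        raise ValueError("need at least 2 events to summarize")
    df = table.data
    mean = {c: float(df[c].mean()) for c in RESIDUAL_COLUMNS}
    sd = {c: float(df[c].std(ddof=1)) for c in RESIDUAL_COLUMNS}
    pearson = {
        (a, b): float(np.corrcoef(df[a], df[b])[0, 1]) for a, b in PEARSON_PAIRS
    }
    wins = int(
        ((df["det_seismic"] < df["det_acoustic"]) & (df["prob_seismic"] < df["prob_acoustic"])).sum()
    )
    return SummaryStats(
        mean=mean, sd=sd, pearson=pearson, seismic_win_count=wins, n_events=table.n_events
    )


def interaural_delay(separation: float, v: float) -> float:
    """Worst-case (end-on incidence) arrival-time difference across two
    receivers ``separation`` metres apart: separation / v, in seconds."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if v <= 0:
        raise ValueError("wavespeed must be > 0")
    return separation / v


def load_field_residuals() -> ResidualTable:
    """The published nine-event residual table bundled with the package.

    Best residuals (m) per event from a four-station seismo-acoustic field
    deployment, for all five method/modality combinations; the reference
    data set for the summary statistics.
    """
    with resources.files("rumbleloc.data").joinpath("field_residuals.csv").open() as fh:
        return ResidualTable(pd.read_csv(fh))
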