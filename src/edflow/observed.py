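"""Synthetic patient-level "observed" dataset.

Stands in for the study hospital's one-year electronic extract: daily
admitted-patient counts follow a truncated normal (the printed mean/SD pair
is incompatible with the printed range for an untruncated normal, so the
range wins and the realized SD undershoots), and per-patient subprocess
durations follow the moment-matched triangular laws.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PATHWAY, ModelConfig, load_default_config
from .stochastic import RandomStreamConfig, fit_triangular_from_moments

__all__ = [
    "ObservedDataset",
    "generate_observed",
    "export_observed",
    "export_daily_counts",
    "read_observed",
    "DAILY_MEAN",
    "DAILY_SD",
    "DAILY_RANGE",
]

DAILY_MEAN = 52.0
DAILY_SD = 28.0
DAILY_RANGE = (28, 79)

_DURATION_COLUMNS = list(PATHWAY)


@dataclass
class ObservedDataset:
    """One row per admitted patient: admission date, per-stage minutes, total."""

    patients: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "date", "total_pet", *_DURATION_COLUMNS}
        missing = required - set(self.patients.columns)
        if missing:
            raise ValueError(f"observed dataset missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.patients)

    def durations(self, subprocess: str) -> np.ndarray:
        return self.patients[subprocess].to_numpy(dtype=float)

    @property
    def total_pet(self) -> np.ndarray:
        return self.patients["total_pet"].to_numpy(dtype=float)

    def daily_counts(self) -> pd.Series:
        return self.patients.groupby("date").size()

    def equals(self, other: "ObservedDataset") -> bool:
        return self.patients.equals(other.patients)


def generate_observed(
    year_days: int = 365,
    seed: int = 0,
    config: ModelConfig | None = None,
    start_date: str = "2019-01-01",
    daily_mean: float = DAILY_MEAN,
    daily_sd: float = DAILY_SD,
    daily_range: tuple = DAILY_RANGE,
) -> ObservedDataset:
    """Generate the synthetic one-year observed dataset.

    Daily admitted counts are truncated-normal(mean, sd) clipped to the
    stated range and rounded to integers; each patient's seven durations are
    drawn from the fitted triangular distributions.  Fixed seeds regenerate
    byte-identical datasets.
    """
    if year_days < 1:
        raise ValueError("year_days must be >= 1")
    config = config or load_default_config()
    lo, hi = daily_range
    a = (lo - daily_mean) / daily_sd
    b = (hi - daily_mean) / daily_sd
    counts_rng = RandomStreamConfig(seed, "observed:daily_counts").rng()
    counts = np.rint(
        stats.truncnorm.rvs(
            a, b, loc=daily_mean, scale=daily_sd, size=year_days,
            random_state=counts_rng,
        )
    ).astype(int)
    n_total = int(counts.sum())

    day0 = _dt.date.fromisoformat(start_date)
    dates = np.repeat(
        [(day0 + _dt.timedelta(days=int(d))).isoformat() for d in range(year_days)],
        counts,
    )
    data = {"patient_id": np.arange(n_total), "date": dates}
    for sp in config.subprocesses:
        dist = fit_triangular_from_moments(sp.observed_mean, sp.observed_sd)
        rng = RandomStreamConfig(seed, f"observed:{sp.name}").rng()
        data[sp.name] = np.asarray(dist.sample(rng, n_total), dtype=float)
    df = pd.DataFrame(data)
    df["total_pet"] = df[_DURATION_COLUMNS].sum(axis=1)
    return ObservedDataset(patients=df)


def export_observed(dataset: ObservedDataset, path) -> None:
    """Write one CSV row per patient; floats round-trip losslessly."""
    dataset.patients.to_csv(path, index=False)


def export_daily_counts(dataset: ObservedDataset, path) -> None:
    """Write one CSV row per day: date, admitted-patient count."""
    counts = dataset.daily_counts().rename("admitted").rename_axis("date")
    counts.to_csv(path)


def read_observed(path) -> ObservedDataset:
    df = pd.read_csv(
        path, dtype={"date": str}, float_precision="round_trip"
    )
    if df.empty:
        df = df.reindex(
            columns=["patient_id", "date", *_DURATION_COLUMNS, "total_pet"]
        )
    return ObservedDataset(patients=df)
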