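"""Replication protocol, PET summary statistics, subprocess shares,
simulated-vs-observed validation and the scenario comparison table."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import des
from .model import PATHWAY, ModelConfig, apply_scenario, build_base_model

__all__ = [
    "ReplicationProtocol",
    "ReplicationResult",
    "run_replications",
    "replication_metrics",
    "summarize_replications",
    "compute_shares",
    "truncate_one_decimal",
    "validate_against_observed",
    "compare_scenarios",
    "bed_expansion_search",
    "AnalysisError",
]

SIX_HOUR_TARGET_MIN = 360.0


class AnalysisError(ValueError):
    """Raised when an analysis precondition fails (e.g. empty population)."""


@dataclass(frozen=True)
class ReplicationProtocol:
    """How many independent runs to make and how long each one is."""

    replications: int = 10
    horizon_days: float = 180.0
    warmup_days: float = 7.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not self.horizon_days > self.warmup_days >= 0:
            raise ValueError("need horizon > warmup >= 0")

    def seed_for(self, replication: int) -> int:
        # replication r of every scenario shares a seed: common random numbers
        return self.master_seed + replication


@dataclass
class ReplicationResult:
    """Summary metrics of one replication (post-warm-up patients only)."""

    subprocess_means: dict
    pet_mean: float
    pet_sd: float
    pet_median: float
    pet_iqr: tuple
    admitted_count: int
    frac_under_six_hours: float
    per_patient_durations: dict = field(default_factory=dict, repr=False)


def run_replications(
    config: ModelConfig,
    mode: str,
    protocol: ReplicationProtocol,
    scenario=None,
) -> list:
    """Run the protocol and return one event log per replication."""
    cfg = apply_scenario(config, scenario) if scenario is not None else config
    logs = []
    for r in range(protocol.replications):
        net = build_base_model(cfg, mode)
        logs.append(
            des.run(
                net,
                horizon=protocol.horizon_days,
                warmup=protocol.warmup_days,
                master_seed=protocol.seed_for(r),
            )
        )
    return logs


def replication_metrics(log: des.EventLog, keep_durations: bool = False
                        ) -> ReplicationResult:
    completed = log.completed_patients()
    if not completed:
        raise AnalysisError("no completed post-warm-up patients in this run")
    pets = np.array([p.pet for p in completed])
    sub_means = {}
    durations = {}
    for name in log.station_names:
        vals = np.array(
            [
                s
                for p in log.post_warmup_patients()
                if (s := p.sojourn(name)) is not None
            ]
        )
        sub_means[name] = float(vals.mean()) if vals.size else float("nan")
        if keep_durations:
            durations[name] = vals
    q1, med, q3 = np.percentile(pets, [25, 50, 75])
    return ReplicationResult(
        subprocess_means=sub_means,
        pet_mean=float(pets.mean()),
        pet_sd=float(pets.std(ddof=1)) if pets.size > 1 else 0.0,
        pet_median=float(med),
        pet_iqr=(float(q1), float(q3)),
        admitted_count=int(pets.size),
        frac_under_six_hours=float((pets < SIX_HOUR_TARGET_MIN).mean()),
        per_patient_durations=durations,
    )


def _t_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    return float(
        stats.t.ppf(0.5 + level / 2.0, n - 1) * values.std(ddof=1) / math.sqrt(n)
    )


def summarize_replications(logs: list, protocol: ReplicationProtocol | None = None
                           ) -> dict:
    """Across-replication mean and 95% t-based half-width for every metric."""
    if not logs:
        raise AnalysisError("at least one completed event log is required")
    reps = [replication_metrics(log) for log in logs]
    out = {"replications": len(reps), "metrics": {}}

    def agg(metric: str, values: list) -> None:
        arr = np.asarray(values, dtype=float)
        out["metrics"][metric] = {
            "mean": float(arr.mean()),
            "ci95_halfwidth": _t_halfwidth(arr),
        }

    agg("pet_mean", [r.pet_mean for r in reps])
    agg("pet_sd", [r.pet_sd for r in reps])
    agg("pet_median", [r.pet_median for r in reps])
    agg("pet_iqr_low", [r.pet_iqr[0] for r in reps])
    agg("pet_iqr_high", [r.pet_iqr[1] for r in reps])
    agg("admitted_count", [r.admitted_count for r in reps])
    agg("frac_under_six_hours", [r.frac_under_six_hours for r in reps])
    for name in logs[0].station_names:
        agg(f"sojourn:{name}", [r.subprocess_means[name] for r in reps])
    out["per_replication"] = reps
    return out


def truncate_one_decimal(x: float) -> float:
    """Truncate (not round) to one decimal; tiny epsilon guards float dust."""
    return math.floor(x * 10.0 + 1e-9) / 10.0


def compute_shares(means) -> dict:
    """Percentage of total PET attributable to each stage, truncated to 0.1%.

    Accepts a mapping name -> mean or a sequence of means; shares before
    truncation sum to exactly 100.
    """
    if isinstance(means, dict):
        items = list(means.items())
    else:
        items = list(enumerate(means))
    if any(v < 0 for _, v in items):
        raise AnalysisError("subprocess means must be non-negative")
    total = sum(v for _, v in items)
    if total <= 0:
        raise AnalysisError("total of subprocess means must be positive")
    return {k: truncate_one_decimal(100.0 * v / total) for k, v in items}


def validate_against_observed(simulated: dict, observed) -> pd.DataFrame:
    """Per-subprocess Welch two-sample t-test of simulated vs observed durations.

    *simulated* maps subprocess name to an array of per-patient durations;
    *observed* is an ObservedDataset or an equivalent mapping.  Zero-variance
    pairs degenerate to an exact mean comparison.  The pass flag marks
    p >= 0.05 (no detectable difference at the 5% level).
    """
    if hasattr(observed, "durations"):
        obs_map = {name: observed.durations(name) for name in simulated}
    else:
        obs_map = observed
    rows = []
    for name in simulated:
        sim = np.asarray(simulated[name], dtype=float)
        obs = np.asarray(obs_map[name], dtype=float)
        if sim.size < 2 or obs.size < 2:
            raise AnalysisError(
                f"need >= 2 values per sample for {name!r} "
                f"(got {sim.size} simulated, {obs.size} observed)"
            )
        if sim.std(ddof=1) == 0.0 and obs.std(ddof=1) == 0.0:
            equal = math.isclose(sim.mean(), obs.mean())
            t, p = (0.0, 1.0) if equal else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_ind(sim, obs, equal_var=False)
        rows.append(
            {
                "subprocess": name,
                "simulated_mean": float(sim.mean()),
                "observed_mean": float(obs.mean()),
                "t_statistic": float(t),
                "p_value": float(p),
                "passes": bool(p >= 0.05),
            }
        )
    return pd.DataFrame(rows)


def compare_scenarios(results: dict, base_id: str = "0") -> pd.DataFrame:
    """Improvements versus the base scenario, with ranks (1 = largest).

    *results* maps scenario id to a mean total PET in minutes (or to a
    summary dict carrying ``metrics.pet_mean.mean``).  Percent decreases are
    truncated to one decimal; the base row carries no rank.
    """

    def mean_pet(v) -> float:
        if isinstance(v, dict):
            return float(v["metrics"]["pet_mean"]["mean"])
        return float(v)

    if base_id not in results:
        raise AnalysisError(f"base scenario {base_id!r} missing from results")
    base = mean_pet(results[base_id])
    rows = []
    for sid, v in results.items():
        pet = mean_pet(v)
        improvement = base - pet
        rows.append(
            {
                "scenario": sid,
                "mean_pet_min": pet,
                "improvement_min": improvement,
                "improvement_pct": truncate_one_decimal(100.0 * improvement / base),
            }
        )
    df = pd.DataFrame(rows)
    others = df[df["scenario"] != base_id].sort_values(
        ["improvement_min", "scenario"], ascending=[False, True]
    )
    ranks = {sid: i + 1 for i, sid in enumerate(others["scenario"])}
    df["rank"] = pd.array(
        [ranks.get(sid) if sid != base_id else None for sid in df["scenario"]],
        dtype="Int64",
    )
    return df.sort_values("scenario").reset_index(drop=True)


def bed_expansion_search(
    config: ModelConfig,
    mode: str = "queueing",
    step: int = 10,
    max_added: int = 60,
    target: float = SIX_HOUR_TARGET_MIN,
    companion_scenario=None,
    protocol: ReplicationProtocol | None = None,
) -> dict:
    """Sweep ward-bed additions and find the smallest one meeting the target.

    Runs with common random numbers across bed counts.  An unreachable
    target is a valid result (``minimal_added_beds`` is None).
    """
    protocol = protocol or ReplicationProtocol()
    base = (
        apply_scenario(config, companion_scenario)
        if companion_scenario is not None
        else config
    )
    curve = []
    minimal = None
    for added in range(0, max_added + 1, step):
        cfg = base.copy()
        cfg.bed_pool("ward").bed_count += added
        logs = run_replications(cfg, mode, protocol)
        mean_pet = float(np.mean([replication_metrics(l).pet_mean for l in logs]))
        curve.append({"added_ward_beds": added, "mean_pet_min": mean_pet})
        if minimal is None and mean_pet <= target:
            minimal = added
    return {
        "target_min": target,
        "curve": curve,
        "minimal_added_beds": minimal,
        "reachable": minimal is not None,
    }
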