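"""The concrete admission-flow model: seven-stage pathway, resource pools,
bed pools, routing, service-time calibration and scenario application.

Two execution modes are exposed:

``direct``
    Each subprocess consumes a sampled triangular sojourn moment-matched to
    the observed per-stage means and SDs; no resource contention is modeled.
    This is the validated base model: total PET is the sum of seven draws.

``queueing``
    Each subprocess is a multi-server FIFO station.  The intrinsic service
    time is the same fitted triangular scaled by a per-station multiplier,
    chosen by :func:`calibrate_service_times` so that base-staffing
    steady-state sojourns (waiting + service) reproduce the observed stage
    means.  Scenarios act on this mode by adding servers, beds, or the
    pooled admitting team.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import des
from .stochastic import (
    DailyProfileArrival,
    ExponentialArrival,
    RandomStreamConfig,
    fit_triangular_from_moments,
)

__all__ = [
    "PATHWAY",
    "SubprocessSpec",
    "BedPoolSpec",
    "RoutingSpec",
    "ScenarioSpec",
    "ModelConfig",
    "load_default_config",
    "load_config",
    "load_scenarios",
    "build_base_model",
    "apply_scenario",
    "allocate_bed",
    "calibrate_service_times",
    "CalibrationError",
]

PATHWAY = (
    "registration",
    "triage",
    "assessment",
    "referral_to_medicine",
    "decision_to_admit",
    "room_allocation",
    "physical_transfer",
)

MINUTES_PER_DAY = 1440.0


class CalibrationError(RuntimeError):
    """Service-time calibration could not reach its sojourn target."""


@dataclass
class SubprocessSpec:
    """One pathway stage: observed sojourn moments and its resource pool.

    ``per_shift_servers`` (optional) staffs shifts unevenly — a zero means
    the stage pauses on that shift and work accumulates until the next one.
    """

    name: str
    observed_mean: float
    observed_sd: float
    servers: int | None  # None = ample (capacity never binds)
    pathway_order: int
    resource: str = ""
    per_shift_servers: list | None = None

    def __post_init__(self) -> None:
        if self.name not in PATHWAY:
            raise ValueError(f"unknown subprocess {self.name!r}")
        if not 1 <= self.pathway_order <= len(PATHWAY):
            raise ValueError(f"pathway_order out of range: {self.pathway_order}")
        if self.per_shift_servers is not None:
            if max(self.per_shift_servers) < 1:
                raise ValueError(f"{self.name}: at least one shift must be staffed")

    def shift_counts(self, shifts_per_day: int) -> tuple:
        if self.per_shift_servers is not None:
            if len(self.per_shift_servers) != shifts_per_day:
                raise ValueError(
                    f"{self.name}: per_shift_servers length "
                    f"{len(self.per_shift_servers)} != shifts_per_day {shifts_per_day}"
                )
            return tuple(int(c) for c in self.per_shift_servers)
        if self.servers is None:
            return tuple([None] * shifts_per_day)
        return tuple([int(self.servers)] * shifts_per_day)

    def add_servers(self, delta: int) -> None:
        """Apply a scenario staffing delta (staffed shifts only).

        Adding staff to an ample-capacity stage is a no-op: its capacity
        already never binds.
        """
        if self.servers is None:
            return
        self.servers += delta
        if self.per_shift_servers is not None:
            self.per_shift_servers = [
                c + delta if c > 0 else 0 for c in self.per_shift_servers
            ]


@dataclass
class BedPoolSpec:
    pool: str
    bed_count: int
    admission_share: float


@dataclass
class RoutingSpec:
    """Patient funnel: ED visits -> referrals -> admissions."""

    ed_boarding_capacity: int = 250
    annual_visits: int = 386_889
    annual_referrals: int = 30_185
    annual_admissions: int = 19_058

    @property
    def referral_fraction(self) -> float:
        return self.annual_referrals / self.annual_visits

    @property
    def admit_fraction(self) -> float:
        return self.annual_admissions / self.annual_referrals


@dataclass(frozen=True)
class ScenarioSpec:
    """A named intervention: staffing deltas, bed deltas, admitting team."""

    id: str
    server_deltas: tuple = ()  # ((station, delta), ...)
    bed_deltas: tuple = ()  # ((pool, delta), ...)
    admitting_team: bool = False
    description: str = ""

    @classmethod
    def from_mapping(cls, scenario_id: str, raw: dict) -> "ScenarioSpec":
        return cls(
            id=str(scenario_id),
            server_deltas=tuple(sorted((raw.get("server_deltas") or {}).items())),
            bed_deltas=tuple(sorted((raw.get("bed_deltas") or {}).items())),
            admitting_team=bool(raw.get("admitting_team", False)),
            description=raw.get("description", ""),
        )

    @property
    def server_delta_map(self) -> dict:
        return dict(self.server_deltas)

    @property
    def bed_delta_map(self) -> dict:
        return dict(self.bed_deltas)


@dataclass
class ModelConfig:
    """Full parameterisation of the admission-flow network."""

    subprocesses: list
    routing: RoutingSpec
    bed_pools: list
    los_means: dict  # pool -> mean length of stay, minutes
    admitting_team_size: int = 1
    admitting_team: bool = False
    admitting_team_policy: str = "round_robin"
    admitting_team_efficiency: float = 0.5
    admitting_team_shifts: list | None = None  # default: decision's staffed shifts
    shifts_per_day: int = 3
    arrival_preset: str = "admitted_only"
    full_mean_interarrival: float = 5.78
    admissions_per_day: float = 52.0
    peak_start_hour: float | None = 8.0
    peak_end_hour: float | None = 20.0
    peak_share: float | None = 0.7
    multipliers: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def subprocess(self, name: str) -> SubprocessSpec:
        for sp in self.subprocesses:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def bed_pool(self, name: str) -> BedPoolSpec:
        for bp in self.bed_pools:
            if bp.pool == name:
                return bp
        raise KeyError(name)

    @property
    def mean_interarrival(self) -> float:
        if self.arrival_preset == "admitted_only":
            return MINUTES_PER_DAY / self.admissions_per_day
        if self.arrival_preset == "full":
            return self.full_mean_interarrival
        raise ValueError(f"unknown arrival preset {self.arrival_preset!r}")

    @property
    def observed_means(self) -> dict:
        return {sp.name: sp.observed_mean for sp in self.subprocesses}


def _data_text(filename: str) -> str:
    return resources.files("edflow.data").joinpath(filename).read_text()


def load_default_config() -> ModelConfig:
    """Load the shipped defaults (observed moments, staffing, beds, funnel)."""
    return _parse_config(yaml.safe_load(_data_text("defaults.yaml")))


def load_config(path=None) -> ModelConfig:
    """Load a config file with the defaults schema; None means the defaults."""
    if path is None:
        return load_default_config()
    with open(path) as fh:
        return _parse_config(yaml.safe_load(fh))


def _parse_config(raw: dict) -> ModelConfig:
    subs = [
        SubprocessSpec(
            name=row["name"],
            observed_mean=float(row["observed_mean"]),
            observed_sd=float(row["observed_sd"]),
            servers=(None if row.get("servers") is None else int(row["servers"])),
            pathway_order=i + 1,
            resource=row.get("resource", ""),
            per_shift_servers=row.get("per_shift_servers"),
        )
        for i, row in enumerate(raw["subprocesses"])
    ]
    if tuple(sp.name for sp in subs) != PATHWAY:
        raise ValueError("defaults.yaml subprocess order does not match the pathway")
    routing = RoutingSpec(
        ed_boarding_capacity=int(raw["routing"]["ed_boarding_capacity"]),
        annual_visits=int(raw["routing"]["annual_visits"]),
        annual_referrals=int(raw["routing"]["annual_referrals"]),
        annual_admissions=int(raw["routing"]["annual_admissions"]),
    )
    pools = [
        BedPoolSpec(
            pool=row["pool"],
            bed_count=int(row["bed_count"]),
            admission_share=float(row["admission_share"]),
        )
        for row in raw["bed_pools"]
    ]
    los = {k: float(v) * 60.0 for k, v in raw["length_of_stay_hours"].items()}
    return ModelConfig(
        subprocesses=subs,
        routing=routing,
        bed_pools=pools,
        los_means=los,
        admitting_team_size=int(raw["admitting_team_size"]),
        admitting_team_efficiency=float(raw.get("admitting_team_efficiency", 0.5)),
        admitting_team_policy=str(raw.get("admitting_team_policy", "fifo")),
        admitting_team_shifts=raw.get("admitting_team_shifts"),
        shifts_per_day=int(raw["shifts_per_day"]),
        arrival_preset=raw["arrivals"]["preset"],
        full_mean_interarrival=float(raw["arrivals"]["full"]["mean_interarrival"]),
        admissions_per_day=float(
            raw["arrivals"]["admitted_only"]["admissions_per_day"]
        ),
        peak_start_hour=raw["arrivals"]["admitted_only"].get("peak_start_hour"),
        peak_end_hour=raw["arrivals"]["admitted_only"].get("peak_end_hour"),
        peak_share=raw["arrivals"]["admitted_only"].get("peak_share"),
        multipliers={sp.name: 1.0 for sp in subs},
        protocol=dict(raw["protocol"]),
    )


def load_scenarios() -> dict:
    """Load the shipped scenario library keyed by scenario id (string)."""
    raw = yaml.safe_load(_data_text("scenarios.yaml"))
    return {
        str(sid): ScenarioSpec.from_mapping(str(sid), spec or {})
        for sid, spec in raw.items()
    }


def apply_scenario(config: ModelConfig, scenario: ScenarioSpec | str) -> ModelConfig:
    """Return a new config with the scenario's deltas applied; base unchanged."""
    if isinstance(scenario, str):
        library = load_scenarios()
        if scenario not in library:
            raise KeyError(
                f"unknown scenario {scenario!r}; valid ids: {sorted(library)}"
            )
        scenario = library[scenario]
    out = config.copy()
    for station, delta in scenario.server_deltas:
        out.subprocess(station).add_servers(delta)
    for pool, delta in scenario.bed_deltas:
        out.bed_pool(pool).bed_count += delta
    if scenario.admitting_team:
        out.admitting_team = True
    return out


def allocate_bed(shares: dict, stream: RandomStreamConfig, n: int = 1) -> list:
    """Draw bed-pool dispositions from the admission shares.

    This is the same cumulative-share draw the engine applies per patient;
    waiting for a free bed when the drawn pool is full is enforced by the
    room-allocation station inside the engine.
    """
    tot = sum(shares.values())
    if not math.isclose(tot, 1.0, abs_tol=1e-9):
        raise ValueError(f"shares must sum to 1, got {tot}")
    rng = stream.rng()
    out = []
    items = list(shares.items())
    for u in rng.uniform(size=n):
        acc = 0.0
        chosen = items[-1][0]
        for pool, share in items:
            acc += share
            if u <= acc:
                chosen = pool
                break
        out.append(chosen)
    return out


def build_base_model(
    config: ModelConfig,
    mode: str = "direct",
    ample_from: int | None = None,
) -> des.Network:
    """Assemble the network for one of the two execution modes.

    *ample_from* overrides staffing to unbounded for stations at pathway
    position >= that index (used internally by calibration: stations
    downstream of the one being tuned cannot influence its sojourn, but at
    their un-calibrated service times they would saturate and jam the
    entry gate).
    """
    if mode not in ("direct", "queueing"):
        raise ValueError(f"mode must be 'direct' or 'queueing', got {mode!r}")
    subs = config.subprocesses
    dists = {
        sp.name: fit_triangular_from_moments(sp.observed_mean, sp.observed_sd)
        for sp in subs
    }
    if config.arrival_preset == "admitted_only" and config.peak_share is not None:
        arrival = DailyProfileArrival(
            config.mean_interarrival,
            peak_start_hour=float(config.peak_start_hour),
            peak_end_hour=float(config.peak_end_hour),
            peak_share=float(config.peak_share),
        )
    else:
        arrival = ExponentialArrival(config.mean_interarrival)
    exit_probs = {}
    if config.arrival_preset == "full":
        exit_probs = {
            "assessment": 1.0 - config.routing.referral_fraction,
            "decision_to_admit": 1.0 - config.routing.admit_fraction,
        }
        exit_probs = {k: v for k, v in exit_probs.items() if k in dists}

    if mode == "direct":
        stations = [_direct_station(sp) for sp in subs]
        return des.Network(
            stations=stations,
            arrival_process=arrival,
            service_dists=dists,
            exit_probs=exit_probs,
        )

    shared = None
    if config.admitting_team:
        # the team follows the medical service's staffing pattern: it works
        # the shifts on which admission decisions are made
        if config.admitting_team_shifts is not None:
            team_counts = tuple(
                config.admitting_team_size if staffed else 0
                for staffed in config.admitting_team_shifts
            )
        else:
            decision_counts = config.subprocess("decision_to_admit").shift_counts(
                config.shifts_per_day
            )
            team_counts = tuple(
                config.admitting_team_size if c > 0 else 0 for c in decision_counts
            )
        shared = des.ServerPool(
            "admitting_team",
            des.ShiftSchedule(
                shifts_per_day=config.shifts_per_day,
                shift_length=MINUTES_PER_DAY / config.shifts_per_day,
                per_shift_counts=team_counts,
            ),
            policy=config.admitting_team_policy,
            efficiency=config.admitting_team_efficiency,
        )
    names = {sp.name for sp in subs}
    stations = []
    for i, sp in enumerate(subs):
        ample = ample_from is not None and i >= ample_from
        stations.append(
            des.Station(
                sp.name,
                server_count=None if ample else sp.servers,
                shift_schedule=des.ShiftSchedule(
                    shifts_per_day=config.shifts_per_day,
                    shift_length=MINUTES_PER_DAY / config.shifts_per_day,
                    per_shift_counts=(
                        tuple([None] * config.shifts_per_day)
                        if ample
                        else sp.shift_counts(config.shifts_per_day)
                    ),
                ),
                shared_pool=(
                    shared
                    if sp.name in ("referral_to_medicine", "decision_to_admit")
                    and shared is not None
                    else None
                ),
                needs_bed=(sp.name == "room_allocation"),
                multiplier=float(config.multipliers.get(sp.name, 1.0)),
            )
        )
    has_beds = "room_allocation" in names
    return des.Network(
        stations=stations,
        arrival_process=arrival,
        service_dists=dists,
        exit_probs=exit_probs,
        gate_capacity=config.routing.ed_boarding_capacity,
        bed_station="room_allocation" if has_beds else None,
        bed_pools=(
            [des.BedPool(bp.pool, bp.bed_count) for bp in config.bed_pools]
            if has_beds
            else None
        ),
        disposition_shares=(
            {bp.pool: bp.admission_share for bp in config.bed_pools}
            if has_beds
            else None
        ),
        los_means=config.los_means if has_beds else None,
    )


def _direct_station(sp: SubprocessSpec) -> des.Station:
    """Unbounded-capacity station: sojourn equals the sampled duration."""
    return des.Station(sp.name, server_count=None)


def _mean_sojourn(log: des.EventLog, station: str) -> float:
    vals = [
        p.sojourn(station)
        for p in log.post_warmup_patients()
        if p.sojourn(station) is not None
    ]
    if not vals:
        # fully saturated: nobody finished the stage; treat as unbounded sojourn
        return float("inf")
    return float(np.mean(vals))


def calibrate_service_times(
    config: ModelConfig,
    targets: dict | None = None,
    tol: float = 5.0,
    max_iter: int = 30,
    horizon_days: float = 120.0,
    warmup_days: float = 7.0,
    replications: int = 2,
    master_seed: int = 12345,
    min_multiplier: float = 1e-3,
) -> tuple:
    """Find per-station service-time multipliers for queueing mode.

    For each station, in pathway order, a scalar multiplier on the fitted
    triangular service distribution is found by monotone bisection so that
    the simulated steady-state mean sojourn at base staffing is within *tol*
    minutes of the observed target.  A station's sojourn depends only on
    stations upstream of it — except for a weak feedback through bed-holding
    (beds release a length of stay after the *last* stage) — so a pass in
    pathway order over the full network is followed by a verification pass
    that re-tunes any station pushed off target.  Evaluations run under
    fixed seeds; common random numbers make the objective monotone in the
    multiplier.

    Returns ``(calibrated_config, report)``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    targets = dict(targets or config.observed_means)
    work = config.copy()
    work.multipliers = {sp.name: 1.0 for sp in work.subprocesses}
    lam = 1.0 / work.mean_interarrival
    report = {}

    def run_network(ample_from: int | None = None) -> list:
        logs = []
        for r in range(replications):
            net = build_base_model(work, "queueing", ample_from=ample_from)
            # same seed derivation as ReplicationProtocol.seed_for, so a
            # post-calibration evaluation under the same protocol reproduces
            # the calibrated sojourns exactly
            logs.append(
                des.run(
                    net, horizon=horizon_days, warmup=warmup_days,
                    master_seed=master_seed + r,
                )
            )
        return logs

    order = {sp.name: i for i, sp in enumerate(work.subprocesses)}

    def evaluate(station: str, m: float, ample_downstream: bool) -> float:
        work.multipliers[station] = m
        ample_from = order[station] + 1 if ample_downstream else None
        logs = run_network(ample_from=ample_from)
        return float(np.mean([_mean_sojourn(log, station) for log in logs]))

    def tune(sp: SubprocessSpec, ample_downstream: bool = True) -> None:
        name = sp.name
        target = targets[name]
        f_hi = evaluate(name, 1.0, ample_downstream)
        entry = {"target": target, "iterations": 1}
        if f_hi <= target + tol:
            # waiting is negligible at this staffing; sojourn ~ service time
            work.multipliers[name] = 1.0
            entry.update(multiplier=1.0, achieved=f_hi, converged=True)
            report[name] = entry
            return
        lo, hi = min_multiplier, 1.0
        f_lo = evaluate(name, lo, ample_downstream)
        entry["iterations"] = 2
        if f_lo > target + tol:
            util = lam * lo * sp.observed_mean / (sp.servers or 1)
            raise CalibrationError(
                f"station {name!r}: sojourn {f_lo:.1f} min at the minimum "
                f"multiplier {lo} already exceeds target {target} min "
                f"(utilization ~{util:.2f}); target is infeasible"
            )
        achieved, mid = f_lo, lo
        converged = False
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            achieved = evaluate(name, mid, ample_downstream)
            entry["iterations"] += 1
            if abs(achieved - target) <= tol:
                converged = True
                break
            if achieved < target:
                lo = mid
            else:
                hi = mid
        work.multipliers[name] = mid
        entry.update(
            multiplier=mid,
            achieved=achieved,
            converged=converged,
            utilization=lam * mid * sp.observed_mean / (sp.servers or 1),
        )
        report[name] = entry
        if not converged:
            raise CalibrationError(
                f"station {name!r}: bisection did not reach target "
                f"{target} +/- {tol} min in {max_iter} iterations "
                f"(last sojourn {achieved:.1f} min, multiplier {mid:.4f}, "
                f"utilization ~{entry['utilization']:.2f})"
            )

    for sp in work.subprocesses:
        tune(sp)

    # verification: bed-holding couples stations across the pathway order;
    # re-tune anything the later stations pushed off target
    for _ in range(2):
        logs = run_network()
        off_target = [
            sp
            for sp in work.subprocesses
            if abs(
                float(np.mean([_mean_sojourn(log, sp.name) for log in logs]))
                - targets[sp.name]
            )
            > tol
        ]
        if not off_target:
            break
        for sp in off_target:
            tune(sp, ample_downstream=False)
    else:
        raise CalibrationError(
            "verification pass could not bring all stations within tolerance; "
            f"still off target: {[sp.name for sp in off_target]}"
        )
    return work, report
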