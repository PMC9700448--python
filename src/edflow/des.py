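"""Generic discrete-event engine for tandem queueing networks.

A :class:`Network` is an ordered line of FIFO multi-server :class:`Station`
objects through which patient entities flow.  The engine supports

* shift-scheduled server counts (constant 24/7 staffing by default),
* an optional entry gate with finite capacity (ED boarding beds),
* an optional shared overflow server pool serving several stations,
* optional bed pools seized at a designated station and held until a
  per-patient length-of-stay elapses after delivery,
* per-station exit probabilities (patients leaving the pathway early).

All random variates a patient will ever need are drawn at the moment the
patient is created, from named per-station substreams, in arrival order.
Because the draw order depends only on the arrival sequence — never on
staffing levels — two runs with the same master seed but different server
counts use common random numbers, which is what scenario comparison relies
on.

Time is measured in minutes on a continuous clock; ties in the future-event
list are broken by insertion order, so runs are bit-reproducible.
"""

from __future__ import annotations

import csv
import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .stochastic import RandomStreamConfig

__all__ = [
    "ShiftSchedule",
    "ServerPool",
    "Station",
    "BedPool",
    "PatientEntity",
    "Network",
    "EventLog",
    "run",
    "conservation_check",
    "InstabilityError",
    "EngineInvariantError",
]

MINUTES_PER_DAY = 1440.0


class InstabilityError(RuntimeError):
    """A station's queue exceeded the configured cap (system is saturated)."""


class EngineInvariantError(AssertionError):
    """An internal conservation or ordering invariant was violated."""


@dataclass(frozen=True)
class ShiftSchedule:
    """Server counts by shift-of-day; shifts tile the 24-hour day exactly."""

    shifts_per_day: int
    shift_length: float
    per_shift_counts: tuple

    def __post_init__(self) -> None:
        if self.shifts_per_day < 1:
            raise ValueError("shifts_per_day must be >= 1")
        if not math.isclose(
            self.shifts_per_day * self.shift_length, MINUTES_PER_DAY
        ):
            raise ValueError(
                "shifts_per_day * shift_length must equal 1440 minutes, got "
                f"{self.shifts_per_day} * {self.shift_length}"
            )
        if len(self.per_shift_counts) != self.shifts_per_day:
            raise ValueError("per_shift_counts length must equal shifts_per_day")
        for c in self.per_shift_counts:
            if c is not None and (not isinstance(c, int) or c < 0):
                raise ValueError(f"per-shift count must be a non-negative int, got {c}")

    @classmethod
    def constant(cls, count, shifts_per_day: int = 3) -> "ShiftSchedule":
        """Identical staffing on every shift (the model default)."""
        return cls(
            shifts_per_day=shifts_per_day,
            shift_length=MINUTES_PER_DAY / shifts_per_day,
            per_shift_counts=tuple([count] * shifts_per_day),
        )

    @property
    def is_constant(self) -> bool:
        return len(set(self.per_shift_counts)) == 1

    def count_at(self, t: float):
        """Active server count at absolute time *t* (None means unbounded)."""
        idx = int((t % MINUTES_PER_DAY) // self.shift_length) % self.shifts_per_day
        return self.per_shift_counts[idx]


class ServerPool:
    """A group of interchangeable servers drawn on by one or more stations.

    Pools serving several stations choose the next patient either by
    earliest queue entry across members (``fifo``) or by cycling through the
    member stations (``round_robin``, which models a team alternating
    between its duties and therefore dedicating only a fraction of its
    capacity to each station).
    """

    def __init__(self, name: str, schedule: ShiftSchedule, policy: str = "fifo",
                 efficiency: float = 1.0):
        if policy not in ("fifo", "round_robin"):
            raise ValueError(f"unknown dispatch policy {policy!r}")
        if not 0.0 < efficiency <= 1.0:
            raise ValueError("efficiency must lie in (0, 1]")
        self.name = name
        self.schedule = schedule
        self.policy = policy
        # fraction of a server's time that is net station throughput; service
        # taken through this pool is stretched by 1/efficiency
        self.efficiency = efficiency
        self.busy = 0
        self.members: list[Station] = []
        self._rr_index = 0

    def capacity_at(self, t: float):
        return self.schedule.count_at(t)

    def has_free(self, t: float) -> bool:
        cap = self.capacity_at(t)
        return cap is None or self.busy < cap


class Station:
    """A FIFO multi-server service stage in the pathway."""

    def __init__(
        self,
        name: str,
        server_count=1,
        shift_schedule: ShiftSchedule | None = None,
        shared_pool: ServerPool | None = None,
        needs_bed: bool = False,
        multiplier: float = 1.0,
    ):
        if shift_schedule is None:
            shift_schedule = ShiftSchedule.constant(server_count)
        self.name = name
        self.pool = ServerPool(f"{name}:primary", shift_schedule)
        self.pool.members.append(self)
        self.shared_pool = shared_pool
        if shared_pool is not None:
            shared_pool.members.append(self)
        self.needs_bed = needs_bed
        self.multiplier = multiplier
        self.queue: deque[PatientEntity] = deque()
        self.arrivals = 0
        self.departures = 0
        self.in_service = 0

    @property
    def server_count(self):
        counts = self.pool.schedule.per_shift_counts
        return counts[0] if self.pool.schedule.is_constant else counts

    def __repr__(self) -> str:  # pragma: no cover
        return f"Station({self.name!r}, servers={self.server_count})"


@dataclass
class BedPool:
    """A ward bed pool with hard capacity; beds are held for a length of stay."""

    name: str
    capacity: int
    occupied: int = 0

    def has_free(self) -> bool:
        return self.occupied < self.capacity


@dataclass
class PatientEntity:
    """One patient flowing through the pathway, with its full timestamp set."""

    id: int
    arrival_time: float
    service: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # name -> {queue_entry,start,end}
    disposition: str | None = None
    los: float | None = None
    admitted_flag: bool = False
    exited_after: str | None = None
    delivery_time: float | None = None
    _exit_draws: dict = field(default_factory=dict, repr=False)

    @property
    def completed(self) -> bool:
        return self.delivery_time is not None

    @property
    def pet(self) -> float | None:
        """Total patient experience time: arrival to bed delivery, minutes."""
        if self.delivery_time is None:
            return None
        return self.delivery_time - self.arrival_time

    def sojourn(self, station: str) -> float | None:
        st = self.stages.get(station)
        if st is None or "end" not in st:
            return None
        return st["end"] - st["queue_entry"]


class Network:
    """A tandem line of stations plus arrival, routing, gate and bed wiring."""

    def __init__(
        self,
        stations: list[Station],
        arrival_process,
        service_dists: dict,
        exit_probs: dict | None = None,
        gate_capacity: int | None = None,
        bed_station: str | None = None,
        bed_pools: list[BedPool] | None = None,
        disposition_shares: dict | None = None,
        los_means: dict | None = None,
        max_queue: int = 1_000_000,
    ):
        self.stations = stations
        self.arrival_process = arrival_process
        self.service_dists = service_dists
        self.exit_probs = exit_probs or {}
        self.gate_capacity = gate_capacity
        self.bed_station = bed_station
        self.bed_pools = {p.name: p for p in (bed_pools or [])}
        self.disposition_shares = disposition_shares or {}
        self.los_means = los_means or {}
        self.max_queue = max_queue
        names = [s.name for s in stations]
        if len(set(names)) != len(names):
            raise ValueError("station names must be unique")
        missing = [n for n in names if n not in service_dists]
        if missing:
            raise ValueError(f"no service distribution for stations {missing}")
        if bed_station is not None and bed_station not in names:
            raise ValueError(f"bed_station {bed_station!r} is not a station")
        if self.disposition_shares:
            tot = sum(self.disposition_shares.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(f"disposition shares must sum to 1, got {tot}")


@dataclass
class EventLog:
    """Ordered event records plus the patient entities that produced them."""

    records: list  # (time, patient_id, station, kind)
    patients: list
    horizon: float  # minutes
    warmup: float  # minutes
    station_names: list
    final_state: dict  # station -> {"queue": int, "in_service": int}

    def completed_patients(self, include_warmup: bool = False) -> list:
        out = []
        for p in self.patients:
            if not p.completed:
                continue
            if not include_warmup and p.arrival_time < self.warmup:
                continue
            out.append(p)
        return out

    def post_warmup_patients(self) -> list:
        return [p for p in self.patients if p.arrival_time >= self.warmup]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.records, columns=["time", "patient_id", "station", "kind"]
        )

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for time, pid, station, kind in self.records:
                fh.write(
                    json.dumps(
                        {"time": time, "patient_id": pid, "station": station,
                         "kind": kind},
                        separators=(",", ":"),
                    )
                    + "\n"
                )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time", "patient_id", "station", "kind"])
            writer.writerows(self.records)


# event kind codes for the future-event list
_ARRIVAL = 0
_END_SERVICE = 1
_SHIFT = 2
_BED_FREE = 3


class _Sim:
    """One run's mutable state; see :func:`run` for the public entry point."""

    def __init__(self, network: Network, horizon_min: float, warmup_min: float,
                 master_seed: int):
        self.net = network
        self.horizon = horizon_min
        self.warmup = warmup_min
        self.heap: list = []
        self.seq = 0
        self.now = 0.0
        self.records: list = []
        self.patients: list = []
        self.gate_occupancy = 0
        self.gate_queue: deque = deque()
        self.arrival_rng = RandomStreamConfig(master_seed, "arrivals").rng()
        self.routing_rng = RandomStreamConfig(master_seed, "routing").rng()
        self.service_rngs = {
            s.name: RandomStreamConfig(master_seed, f"service:{s.name}").rng()
            for s in network.stations
        }
        self.station_index = {s.name: i for i, s in enumerate(network.stations)}
        # reset mutable station/pool/bed state so a Network can be re-run
        for s in network.stations:
            s.queue.clear()
            s.arrivals = s.departures = s.in_service = 0
            s.pool.busy = 0
            s.pool._rr_index = 0
            if s.shared_pool is not None:
                s.shared_pool.busy = 0
                s.shared_pool._rr_index = 0
        for b in network.bed_pools.values():
            b.occupied = 0

    # -- future-event list ------------------------------------------------
    def push(self, t: float, kind: int, payload) -> None:
        heapq.heappush(self.heap, (t, self.seq, kind, payload))
        self.seq += 1

    def log(self, pid: int, station: str, kind: str) -> None:
        self.records.append((self.now, pid, station, kind))

    # -- patient creation -------------------------------------------------
    def new_patient(self) -> PatientEntity:
        net = self.net
        p = PatientEntity(id=len(self.patients), arrival_time=self.now)
        for st in net.stations:
            p.service[st.name] = float(
                net.service_dists[st.name].sample(self.service_rngs[st.name])
            )
        if net.exit_probs or net.bed_pools:
            # disposition/LOS drawn first so they are identical whether the
            # pathway is run whole or truncated (calibration); exit draws are
            # per-station with a fixed count per patient (CRN)
            u_disp = float(self.routing_rng.uniform())
            e_los = float(self.routing_rng.exponential())
            for st in net.stations:
                p._exit_draws[st.name] = float(self.routing_rng.uniform())
            if net.disposition_shares:
                acc = 0.0
                for pool_name, share in net.disposition_shares.items():
                    acc += share
                    if u_disp <= acc:
                        p.disposition = pool_name
                        break
                else:  # guard against float round-off at the top edge
                    p.disposition = pool_name
                p.los = e_los * float(net.los_means.get(p.disposition, 0.0))
        self.patients.append(p)
        return p

    # -- flow --------------------------------------------------------------
    def handle_arrival(self) -> None:
        p = self.new_patient()
        if (
            self.net.gate_capacity is not None
            and self.gate_occupancy >= self.net.gate_capacity
        ):
            self.gate_queue.append(p)
        else:
            self.gate_occupancy += 1
            self.enter_station(p, 0)
        nxt = self.now + float(self.arrival_process_draw())
        if nxt <= self.horizon:
            self.push(nxt, _ARRIVAL, None)

    def arrival_process_draw(self) -> float:
        ap = self.net.arrival_process
        if hasattr(ap, "next_interarrival"):
            return ap.next_interarrival(self.now, self.arrival_rng)
        return ap.sample(self.arrival_rng)

    def enter_station(self, p: PatientEntity, idx: int) -> None:
        st = self.net.stations[idx]
        st.queue.append(p)
        st.arrivals += 1
        if len(st.queue) > self.net.max_queue:
            raise InstabilityError(
                f"queue at station {st.name!r} exceeded {self.net.max_queue} "
                f"waiting entities at t={self.now:.1f} min"
            )
        p.stages[st.name] = {"queue_entry": self.now}
        self.log(p.id, st.name, "arrive")
        self.dispatch(st.pool)
        if st.shared_pool is not None:
            self.dispatch(st.shared_pool)

    def _startable(self, st: Station):
        """Earliest-queued patient at *st* who could start now, else None."""
        if not st.queue:
            return None
        if not st.needs_bed:
            return st.queue[0]
        for p in st.queue:  # FIFO among bed-feasible patients
            pool = self.net.bed_pools.get(p.disposition)
            if pool is None or pool.has_free():
                return p
        return None

    def dispatch(self, pool: ServerPool) -> None:
        while pool.has_free(self.now):
            chosen = None
            if pool.policy == "round_robin" and len(pool.members) > 1:
                n = len(pool.members)
                for k in range(n):
                    st = pool.members[(pool._rr_index + k) % n]
                    p = self._startable(st)
                    if p is not None:
                        chosen = (st, p)
                        pool._rr_index = (pool._rr_index + k + 1) % n
                        break
            else:
                best = None
                for st in pool.members:
                    p = self._startable(st)
                    if p is None:
                        continue
                    key = (p.stages[st.name]["queue_entry"], p.id)
                    if best is None or key < best[0]:
                        best = (key, st, p)
                if best is not None:
                    chosen = (best[1], best[2])
            if chosen is None:
                return
            self.start_service(chosen[0], chosen[1], pool)

    def start_service(self, st: Station, p: PatientEntity, pool: ServerPool) -> None:
        st.queue.remove(p)
        pool.busy += 1
        st.in_service += 1
        if st.needs_bed and p.disposition in self.net.bed_pools:
            self.net.bed_pools[p.disposition].occupied += 1
        p.stages[st.name]["start"] = self.now
        self.log(p.id, st.name, "start_service")
        dur = st.multiplier * p.service[st.name] / pool.efficiency
        self.push(self.now + dur, _END_SERVICE, (p, st, pool))

    def handle_end_service(self, p: PatientEntity, st: Station,
                           pool: ServerPool) -> None:
        p.stages[st.name]["end"] = self.now
        self.log(p.id, st.name, "end_service")
        st.departures += 1
        st.in_service -= 1
        pool.busy -= 1
        self.dispatch(pool)
        idx = self.station_index[st.name]
        exit_prob = self.net.exit_probs.get(st.name, 0.0)
        if exit_prob > 0.0 and p._exit_draws.get(st.name, 1.0) < exit_prob:
            p.exited_after = st.name
            self.leave_system(p)
        elif idx + 1 < len(self.net.stations):
            self.enter_station(p, idx + 1)
        else:
            p.admitted_flag = True
            p.delivery_time = self.now
            if p.disposition in self.net.bed_pools and p.los is not None:
                self.push(self.now + p.los, _BED_FREE, p.disposition)
            self.leave_system(p)

    def leave_system(self, p: PatientEntity) -> None:
        if self.net.gate_capacity is not None:
            self.gate_occupancy -= 1
            if self.gate_queue:
                q = self.gate_queue.popleft()
                self.gate_occupancy += 1
                self.enter_station(q, 0)

    def handle_bed_free(self, pool_name: str) -> None:
        self.net.bed_pools[pool_name].occupied -= 1
        if self.net.bed_station is not None:
            st = self.net.stations[self.station_index[self.net.bed_station]]
            self.dispatch(st.pool)
            if st.shared_pool is not None:
                self.dispatch(st.shared_pool)

    def schedule_shift_changes(self) -> None:
        pools = {id(s.pool): s.pool for s in self.net.stations}
        for s in self.net.stations:
            if s.shared_pool is not None:
                pools[id(s.shared_pool)] = s.shared_pool
        for pool in pools.values():
            sched = pool.schedule
            if sched.is_constant:
                continue
            t = sched.shift_length
            while t <= self.horizon:
                self.push(t, _SHIFT, pool)
                t += sched.shift_length

    def run(self) -> EventLog:
        self.schedule_shift_changes()
        self.push(float(self.arrival_process_draw()), _ARRIVAL, None)
        heap = self.heap
        while heap:
            t, _, kind, payload = heapq.heappop(heap)
            if t > self.horizon:
                break
            self.now = t
            if kind == _ARRIVAL:
                self.handle_arrival()
            elif kind == _END_SERVICE:
                self.handle_end_service(*payload)
            elif kind == _BED_FREE:
                self.handle_bed_free(payload)
            else:  # _SHIFT: capacity may have risen; try to start work
                self.dispatch(payload)
        final_state = {
            s.name: {"queue": len(s.queue), "in_service": s.in_service}
            for s in self.net.stations
        }
        return EventLog(
            records=self.records,
            patients=self.patients,
            horizon=self.horizon,
            warmup=self.warmup,
            station_names=[s.name for s in self.net.stations],
            final_state=final_state,
        )


def run(
    network: Network,
    horizon: float,
    warmup: float = 0.0,
    master_seed: int = 0,
) -> EventLog:
    """Execute *network* for *horizon* days and return the event log.

    Patients arriving before the end of the *warmup* period (days) are kept in
    the log but excluded from downstream statistics.  Events scheduled past
    the horizon are left unprocessed, so the log covers exactly [0, horizon].
    """
    if not horizon > warmup:
        raise ValueError(f"horizon ({horizon} d) must exceed warmup ({warmup} d)")
    if warmup < 0:
        raise ValueError("warmup must be >= 0")
    sim = _Sim(
        network,
        horizon_min=horizon * MINUTES_PER_DAY,
        warmup_min=warmup * MINUTES_PER_DAY,
        master_seed=master_seed,
    )
    return sim.run()


def conservation_check(log: EventLog) -> dict:
    """Verify arrivals = departures + in-system, per station and globally.

    Arrival/departure counts are recounted from the raw event records and
    compared with the engine's final queue/in-service state; a mismatch means
    an engine bug, raised as :class:`EngineInvariantError`.
    """
    arrive: dict = {}
    depart: dict = {}
    for _, _, station, kind in log.records:
        if kind == "arrive":
            arrive[station] = arrive.get(station, 0) + 1
        elif kind == "end_service":
            depart[station] = depart.get(station, 0) + 1
    report = {"stations": {}, "ok": True}
    for name in log.station_names:
        a = arrive.get(name, 0)
        d = depart.get(name, 0)
        state = log.final_state[name]
        in_system = state["queue"] + state["in_service"]
        ok = a == d + in_system
        report["stations"][name] = {
            "arrivals": a, "departures": d, "in_system": in_system, "ok": ok,
        }
        if not ok:
            report["ok"] = False
    total_a = sum(v["arrivals"] for v in report["stations"].values())
    total_d = sum(v["departures"] for v in report["stations"].values())
    total_in = sum(v["in_system"] for v in report["stations"].values())
    report["global"] = {
        "arrivals": total_a, "departures": total_d, "in_system": total_in,
    }
    if not report["ok"]:
        bad = [n for n, v in report["stations"].items() if not v["ok"]]
        raise EngineInvariantError(
            f"flow conservation violated at stations {bad}; this is an engine bug"
        )
    return report
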