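import json
import math

import numpy as np
import pytest

from edflow.des import (
    BedPool,
    EngineInvariantError,
    EventLog,
    InstabilityError,
    Network,
    ServerPool,
    ShiftSchedule,
    Station,
    conservation_check,
    run,
)
from edflow.stochastic import ExponentialArrival, TriangularDist


class FixedArrivals:
    """Deterministic inter-arrival sequence for hand-checkable examples."""

    def __init__(self, interarrivals, then=1e12):
        self._seq = list(interarrivals)
        self._then = then

    def sample(self, rng):
        return self._seq.pop(0) if self._seq else self._then


def single_station_net(server_count=1, service=None, arrivals=None, **kw):
    st = Station("svc", server_count=server_count)
    return Network(
        stations=[st],
        arrival_process=arrivals or ExponentialArrival(2.0),
        service_dists={"svc": service or ExponentialArrival(1.0)},
        **kw,
    )


def erlang_c(c: int, a: float) -> float:
    """Probability of waiting in an M/M/c queue with offered load a."""
    rho = a / c
    s = sum(a**k / math.factorial(k) for k in range(c))
    top = a**c / math.factorial(c)
    return top / ((1 - rho) * s + top)


class TestShiftSchedule:
    def test_constant(self):
        sched = ShiftSchedule.constant(4)
        assert sched.shifts_per_day == 3
        assert sched.shift_length == 480.0
        assert sched.per_shift_counts == (4, 4, 4)
        assert sched.is_constant

    def test_day_must_tile_exactly(self):
        with pytest.raises(ValueError):
            ShiftSchedule(3, 500.0, (1, 1, 1))
        with pytest.raises(ValueError):
            ShiftSchedule(3, 480.0, (1, 1))
        with pytest.raises(ValueError):
            ShiftSchedule(3, 480.0, (1, 1, -1))

    def test_count_at(self):
        sched = ShiftSchedule(3, 480.0, (0, 2, 1))
        assert sched.count_at(0.0) == 0
        assert sched.count_at(479.999) == 0
        assert sched.count_at(480.0) == 2
        assert sched.count_at(900.0) == 2
        assert sched.count_at(960.0) == 1
        assert sched.count_at(1440.0 + 10.0) == 0  # wraps daily

    def test_unbounded_counts(self):
        sched = ShiftSchedule.constant(None)
        assert sched.count_at(123.0) is None


class TestHandCheckableCases:
    def test_two_patient_fifo_wait(self):
        # service exactly 10 min; arrivals at t=0 and t=1
        net = single_station_net(
            server_count=1,
            service=TriangularDist(10, 10, 10),
            arrivals=FixedArrivals([0.0, 1.0]),
        )
        log = run(net, horizon=1.0, master_seed=0)
        p0, p1 = log.patients
        assert p0.stages["svc"]["start"] == 0.0
        assert p0.stages["svc"]["end"] == 10.0
        assert p1.stages["svc"]["queue_entry"] == 1.0
        assert p1.stages["svc"]["start"] == 10.0  # waited 9 minutes
        assert p1.stages["svc"]["end"] == 20.0
        report = conservation_check(log)
        assert report["global"] == {"arrivals": 2, "departures": 2, "in_system": 0}

    def test_two_servers_no_wait(self):
        net = single_station_net(
            server_count=2,
            service=TriangularDist(10, 10, 10),
            arrivals=FixedArrivals([0.0, 1.0]),
        )
        log = run(net, horizon=1.0, master_seed=0)
        assert log.patients[1].stages["svc"]["start"] == 1.0

    def test_night_shift_gap_delays_start(self):
        st = Station("svc", shift_schedule=ShiftSchedule(3, 480.0, (0, 1, 1)))
        net = Network(
            stations=[st],
            arrival_process=FixedArrivals([100.0]),
            service_dists={"svc": TriangularDist(10, 10, 10)},
        )
        log = run(net, horizon=1.0, master_seed=0)
        p = log.patients[0]
        assert p.stages["svc"]["queue_entry"] == 100.0
        assert p.stages["svc"]["start"] == 480.0  # first staffed minute
        assert p.stages["svc"]["end"] == 490.0

    def test_gate_capacity_blocks_entry(self):
        net = single_station_net(
            server_count=1,
            service=TriangularDist(10, 10, 10),
            arrivals=FixedArrivals([0.0, 1.0]),
            gate_capacity=1,
        )
        log = run(net, horizon=1.0, master_seed=0)
        # second patient enters the station only when the first leaves
        assert log.patients[1].stages["svc"]["queue_entry"] == 10.0


class TestQueueingOracles:
    def test_mm1_sojourn_closed_form(self):
        # M/M/1: lambda=0.5/min, mu=1/min -> W = 1/(mu-lambda) = 2 min
        net = single_station_net(
            server_count=1,
            service=ExponentialArrival(1.0),
            arrivals=ExponentialArrival(2.0),
        )
        log = run(net, horizon=40.0, warmup=3.0, master_seed=42)
        soj = [p.sojourn("svc") for p in log.completed_patients()]
        # ~4 sigma for a correlated M/M/1 mean-sojourn estimate at this n
        assert np.mean(soj) == pytest.approx(2.0, abs=0.2)

    def test_mmc_waiting_time_erlang_c(self):
        # M/M/2: lambda=0.75/min, mean service 2 min -> a=1.5, rho=0.75
        lam, s, c = 0.75, 2.0, 2
        wq_oracle = erlang_c(c, lam * s) / (c / s - lam)
        waits = []
        for seed in (1, 2, 3):
            net = single_station_net(
                server_count=c,
                service=ExponentialArrival(s),
                arrivals=ExponentialArrival(1.0 / lam),
            )
            log = run(net, horizon=30.0, warmup=3.0, master_seed=seed)
            waits.extend(
                p.stages["svc"]["start"] - p.stages["svc"]["queue_entry"]
                for p in log.completed_patients()
            )
        assert np.mean(waits) == pytest.approx(wq_oracle, abs=0.3)

    def test_more_servers_never_increase_mean_wait(self):
        def mean_wait(c):
            net = single_station_net(
                server_count=c,
                service=ExponentialArrival(1.8),
                arrivals=ExponentialArrival(1.0),
            )
            log = run(net, horizon=20.0, warmup=2.0, master_seed=11)
            return np.mean(
                [
                    p.stages["svc"]["start"] - p.stages["svc"]["queue_entry"]
                    for p in log.completed_patients()
                ]
            )

        w2, w3, w4 = mean_wait(2), mean_wait(3), mean_wait(4)
        assert w2 >= w3 >= w4

    def test_determinism_bit_identical_logs(self):
        def one():
            net = single_station_net(
                server_count=2,
                service=ExponentialArrival(1.5),
                arrivals=ExponentialArrival(1.0),
            )
            return run(net, horizon=5.0, master_seed=9)

        a, b = one(), one()
        assert a.records == b.records


class TestSharedPool:
    def _tandem_with_shared(self, policy="fifo"):
        shared = ServerPool("shared", ShiftSchedule.constant(1), policy=policy)
        st1 = Station("a", server_count=1, shared_pool=shared)
        st2 = Station("b", server_count=1, shared_pool=shared)
        return Network(
            stations=[st1, st2],
            arrival_process=ExponentialArrival(1.0),
            service_dists={
                "a": ExponentialArrival(1.5),
                "b": ExponentialArrival(1.5),
            },
        )

    @pytest.mark.parametrize("policy", ["fifo", "round_robin"])
    def test_concurrency_never_exceeds_pooled_capacity(self, policy):
        log = run(self._tandem_with_shared(policy), horizon=3.0, master_seed=5)
        in_service = {"a": 0, "b": 0}
        peak = 0
        for _, _, station, kind in log.records:
            if kind == "start_service":
                in_service[station] += 1
            elif kind == "end_service":
                in_service[station] -= 1
            assert in_service["a"] <= 2 and in_service["b"] <= 2  # primary+shared
            assert in_service["a"] + in_service["b"] <= 3
            peak = max(peak, in_service["a"] + in_service["b"])
        assert peak == 3  # the shared server actually gets used

    def test_shared_pool_reduces_waits(self):
        def total_wait(net):
            log = run(net, horizon=10.0, master_seed=3)
            return sum(
                p.stages[s]["start"] - p.stages[s]["queue_entry"]
                for p in log.completed_patients(include_warmup=True)
                for s in ("a", "b")
                if s in p.stages and "start" in p.stages[s]
            )

        shared = total_wait(self._tandem_with_shared())
        st1 = Station("a", server_count=1)
        st2 = Station("b", server_count=1)
        plain = total_wait(
            Network(
                stations=[st1, st2],
                arrival_process=ExponentialArrival(1.0),
                service_dists={
                    "a": ExponentialArrival(1.5),
                    "b": ExponentialArrival(1.5),
                },
            )
        )
        assert shared < plain

    def test_pool_efficiency_stretches_service(self):
        shared = ServerPool("shared", ShiftSchedule.constant(1), efficiency=0.5)
        st = Station("a", server_count=0,
                     shift_schedule=ShiftSchedule.constant(0),
                     shared_pool=shared)
        net = Network(
            stations=[st],
            arrival_process=FixedArrivals([0.0]),
            service_dists={"a": TriangularDist(10, 10, 10)},
        )
        log = run(net, horizon=1.0, master_seed=0)
        p = log.patients[0]
        assert p.stages["a"]["end"] - p.stages["a"]["start"] == 20.0


class TestBedPools:
    def test_bed_capacity_never_exceeded(self):
        st = Station("alloc", server_count=None, needs_bed=True)
        net = Network(
            stations=[st],
            arrival_process=ExponentialArrival(5.0),
            service_dists={"alloc": TriangularDist(1, 1, 1)},
            bed_station="alloc",
            bed_pools=[BedPool("w", capacity=2)],
            disposition_shares={"w": 1.0},
            los_means={"w": 60.0},
        )
        log = run(net, horizon=2.0, master_seed=8)
        # bed held from service start until delivery + LOS
        intervals = [
            (p.stages["alloc"]["start"], p.delivery_time + p.los)
            for p in log.patients
            if p.completed
        ]
        events = sorted(
            [(t, +1) for t, _ in intervals] + [(t, -1) for _, t in intervals]
        )
        occ = 0
        for _, delta in events:
            occ += delta
            assert occ <= 2

    def test_full_pools_make_patients_wait(self):
        st = Station("alloc", server_count=None, needs_bed=True)
        net = Network(
            stations=[st],
            arrival_process=FixedArrivals([0.0, 1.0, 2.0]),
            service_dists={"alloc": TriangularDist(1, 1, 1)},
            bed_station="alloc",
            bed_pools=[BedPool("w", capacity=1)],
            disposition_shares={"w": 1.0},
            los_means={"w": 100.0},
        )
        log = run(net, horizon=0.5, master_seed=0)
        p0, p1 = log.patients[0], log.patients[1]
        assert p0.stages["alloc"]["start"] == 0.0
        # bed frees at p0's delivery (t=1) plus p0's sampled length of stay
        assert p1.stages["alloc"]["start"] == pytest.approx(1.0 + p0.los)


class TestRunContract:
    def test_horizon_must_exceed_warmup(self):
        with pytest.raises(ValueError):
            run(single_station_net(), horizon=5.0, warmup=5.0)

    def test_instability_error_names_station(self):
        net = single_station_net(
            server_count=1,
            service=ExponentialArrival(10.0),
            arrivals=ExponentialArrival(1.0),
            max_queue=50,
        )
        with pytest.raises(InstabilityError, match="svc"):
            run(net, horizon=10.0, master_seed=0)

    def test_empty_log_conserves(self):
        net = single_station_net(arrivals=FixedArrivals([], then=1e9))
        log = run(net, horizon=1.0, master_seed=0)
        report = conservation_check(log)
        assert report["global"] == {"arrivals": 0, "departures": 0, "in_system": 0}

    def test_conservation_detects_corruption(self):
        net = single_station_net()
        log = run(net, horizon=2.0, master_seed=1)
        log.records.append((0.0, 999, "svc", "arrive"))  # fake arrival
        with pytest.raises(EngineInvariantError):
            conservation_check(log)

    def test_timestamps_monotone_per_patient(self):
        net = single_station_net(server_count=2)
        log = run(net, horizon=5.0, master_seed=4)
        for p in log.completed_patients(include_warmup=True):
            st = p.stages["svc"]
            assert p.arrival_time <= st["queue_entry"] <= st["start"] <= st["end"]
            assert p.pet >= 0

    def test_warmup_filtering(self):
        net = single_station_net()
        log = run(net, horizon=4.0, warmup=2.0, master_seed=6)
        assert all(p.arrival_time >= 2880.0 for p in log.completed_patients())
        assert any(
            p.arrival_time < 2880.0 for p in log.completed_patients(include_warmup=True)
        )


class TestEventLogExport:
    def test_jsonl_round_trip(self, tmp_path):
        net = single_station_net()
        log = run(net, horizon=1.0, master_seed=2)
        path = tmp_path / "events.jsonl"
        log.to_jsonl(path)
        rows = [json.loads(line) for line in path.read_text().splitlines()]
        assert len(rows) == len(log.records)
        assert rows[0]["kind"] == log.records[0][3]

    def test_csv_and_dataframe(self, tmp_path):
        net = single_station_net()
        log = run(net, horizon=1.0, master_seed=2)
        path = tmp_path / "events.csv"
        log.to_csv(path)
        assert len(path.read_text().splitlines()) == len(log.records) + 1
        df = log.to_dataframe()
        assert list(df.columns) == ["time", "patient_id", "station", "kind"]
        assert len(df) == len(log.records)
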