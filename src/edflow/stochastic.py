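"""Seeded random-variate generation and moment-based distribution fitting.

All stochastic inputs of the admission-flow model are driven from a single
master seed through named substreams, so that scenario comparisons can use
common random numbers: changing the staffing of one station never perturbs
the variates drawn anywhere else.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TriangularDist",
    "ExponentialArrival",
    "DailyProfileArrival",
    "RandomStreamConfig",
    "fit_triangular_from_moments",
    "sample_duration",
    "sample_interarrivals",
]

_SQRT6 = math.sqrt(6.0)


class ParameterError(ValueError):
    """Raised for distribution parameters outside their domain."""


@dataclass(frozen=True)
class TriangularDist:
    """Three-parameter triangular duration distribution, in minutes.

    Satisfies ``lower <= mode <= upper`` with ``lower >= 0``.  The analytic
    moments are

    * mean = (lower + mode + upper) / 3
    * variance = (lower^2 + mode^2 + upper^2
      - lower*mode - lower*upper - mode*upper) / 18
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.mode <= self.upper):
            raise ParameterError(
                f"triangular parameters must satisfy 0 <= lower <= mode <= upper, "
                f"got ({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0

    @property
    def variance(self) -> float:
        a, m, b = self.lower, self.mode, self.upper
        v = (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
        return max(v, 0.0)  # guard float dust for degenerate triangles

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    @property
    def is_degenerate(self) -> bool:
        return self.lower == self.upper

    def sample(self, rng: np.random.Generator, n: int | None = None):
        """Draw variates; scalar when *n* is None, else an ndarray of length n."""
        if self.is_degenerate:
            if n is None:
                return self.mode
            return np.full(n, self.mode)
        return rng.triangular(self.lower, self.mode, self.upper, size=n)


@dataclass(frozen=True)
class ExponentialArrival:
    """Memoryless arrival process parameterised by its mean inter-arrival time."""

    mean_interarrival: float

    def __post_init__(self) -> None:
        if not self.mean_interarrival > 0:
            raise ParameterError(
                f"mean inter-arrival must be positive, got {self.mean_interarrival}"
            )

    def sample(self, rng: np.random.Generator, n: int | None = None):
        return rng.exponential(self.mean_interarrival, size=n)


@dataclass(frozen=True)
class DailyProfileArrival:
    """Non-homogeneous Poisson arrivals with a piecewise-constant daily cycle.

    The overall mean inter-arrival time is preserved; *peak_share* of each
    day's arrivals fall inside the window ``[peak_start_hour, peak_end_hour)``.
    One unit-exponential draw is consumed per arrival, so runs with the same
    stream use common random numbers regardless of the profile shape.
    """

    mean_interarrival: float
    peak_start_hour: float = 8.0
    peak_end_hour: float = 20.0
    peak_share: float = 0.7

    def __post_init__(self) -> None:
        if not self.mean_interarrival > 0:
            raise ParameterError("mean inter-arrival must be positive")
        if not 0.0 <= self.peak_start_hour < self.peak_end_hour <= 24.0:
            raise ParameterError("need 0 <= peak_start < peak_end <= 24 hours")
        if not 0.0 < self.peak_share < 1.0:
            raise ParameterError("peak_share must lie strictly between 0 and 1")

    def _rates(self) -> tuple:
        """(peak rate, off-peak rate) in arrivals per minute."""
        daily = 1440.0 / self.mean_interarrival
        peak_min = (self.peak_end_hour - self.peak_start_hour) * 60.0
        off_min = 1440.0 - peak_min
        return (
            daily * self.peak_share / peak_min,
            daily * (1.0 - self.peak_share) / off_min,
        )

    def rate_at(self, t: float) -> float:
        lo = self.peak_start_hour * 60.0
        hi = self.peak_end_hour * 60.0
        r_peak, r_off = self._rates()
        tod = t % 1440.0
        return r_peak if lo <= tod < hi else r_off

    def next_interarrival(self, t: float, rng: np.random.Generator) -> float:
        """Time to the next arrival after *t*, by piecewise hazard inversion."""
        target = rng.exponential()
        lo = self.peak_start_hour * 60.0
        hi = self.peak_end_hour * 60.0
        r_peak, r_off = self._rates()
        now = t
        while True:
            tod = now % 1440.0
            if tod < lo:
                rate, seg_end = r_off, now + (lo - tod)
            elif tod < hi:
                rate, seg_end = r_peak, now + (hi - tod)
            else:
                rate, seg_end = r_off, now + (1440.0 - tod) + lo
            hazard = rate * (seg_end - now)
            if hazard >= target:
                return now + target / rate - t
            target -= hazard
            now = seg_end


@dataclass(frozen=True)
class RandomStreamConfig:
    """A named, reproducible substream of a master seed.

    Identical ``(master_seed, stream_id)`` pairs always yield identical
    variate sequences.  The stream id is hashed with CRC32 so the mapping is
    stable across processes and platforms.
    """

    master_seed: int
    stream_id: str

    def rng(self) -> np.random.Generator:
        key = zlib.crc32(self.stream_id.encode("utf-8"))
        return np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(key,))
        )


def fit_triangular_from_moments(mean: float, sd: float) -> TriangularDist:
    """Fit the symmetric triangular distribution matching a (mean, sd) pair.

    The symmetric triangle with ``mode = mean`` and half-width ``sd * sqrt(6)``
    is the unique symmetric triangular distribution with these two moments.
    If the implied lower bound would be negative it is clipped to zero and the
    upper bound re-set to ``3*mean - mode - lower`` so the mean is preserved
    (the variance then undershoots; a warning is emitted).
    """
    if not mean > 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ParameterError(f"sd must be non-negative, got {sd}")
    half_width = sd * _SQRT6
    lower = mean - half_width
    upper = mean + half_width
    mode = mean
    if lower < 0:
        warnings.warn(
            f"symmetric triangular fit to mean={mean}, sd={sd} implies a negative "
            "lower bound; clipping to 0 (fitted variance will undershoot)",
            stacklevel=2,
        )
        lower = 0.0
        upper = 3.0 * mean - mode - lower
    return TriangularDist(lower=lower, mode=mode, upper=upper)


def sample_duration(
    dist: TriangularDist, stream: RandomStreamConfig, n: int
) -> np.ndarray:
    """Draw *n* independent triangular duration variates from a named stream."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = stream.rng()
    out = dist.sample(rng, n)
    return np.asarray(out, dtype=float)


def sample_interarrivals(
    arr: ExponentialArrival, stream: RandomStreamConfig, n: int
) -> np.ndarray:
    """Draw *n* exponential inter-arrival times from a named stream."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = stream.rng()
    return np.asarray(arr.sample(rng, n), dtype=float)
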