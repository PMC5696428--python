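"""Wet/dry logger emulation: from continuous flights to interval records.

Immersion loggers store, per aggregation interval of length tau, whether any
saltwater contact occurred.  A flight (a continuous dry period) is therefore
observed as the number ``j`` of *completely dry* intervals it covers: the two
intervals containing take-off and landing are wet-contaminated and lost.  For
a flight of duration ``t`` starting at a uniformly random phase within an
interval, ``j = max(floor(u + t/tau) - 1, 0)`` with ``u ~ U(0, 1)``; flights
with ``j = 0`` never appear in the record and are discarded.

Two emulators are provided: a fast per-flight kernel sampler
(:func:`emulate_record`) and a full alternating wet/dry timeline
(:func:`emulate_timeline`) that serves as an independent cross-check; the two
agree in distribution whenever wet gaps keep flights separated in the
aggregated stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distributions import FlightDistribution, ParameterGrid

__all__ = [
    "ObservationScheme",
    "TrueFlightSet",
    "ObservedRecord",
    "WetModel",
    "observation_kernel",
    "sample_flights",
    "emulate_record",
    "emulate_timeline",
    "simulate_study",
    "SCHEME_10S",
    "SCHEME_30S",
    "SCHEME_1H",
]


@dataclass(frozen=True)
class ObservationScheme:
    """A logger generation's aggregation rule.

    ``interval_s`` is the aggregation interval tau; ``segment_s`` is the
    wet/dry measurement segment (equal to the interval for high-resolution
    devices, shorter for coarse ones).  Only the timeline emulator looks at
    the segment.
    """

    interval_s: float
    segment_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        seg = self.segment_s if self.segment_s is not None else self.interval_s
        if seg <= 0 or (self.interval_s / seg) % 1.0 > 1e-9:
            raise ValueError("segment_s must be positive and divide interval_s")
        object.__setattr__(self, "segment_s", seg)

    @property
    def tau_h(self) -> float:
        """Aggregation interval in hours."""
        return self.interval_s / 3600.0


#: High-resolution scheme of the most recent loggers (10 s sampling).
SCHEME_10S = ObservationScheme(10.0, label="10s")
#: Alternative fine scheme (30 s).
SCHEME_30S = ObservationScheme(30.0, label="30s")
#: Coarse scheme of the first-generation loggers (1 h aggregation, 3 s segments).
SCHEME_1H = ObservationScheme(3600.0, 3.0, label="1h")


@dataclass(frozen=True)
class TrueFlightSet:
    """Continuous flight durations (hours) drawn from a known law."""

    durations: np.ndarray
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))

    def __len__(self) -> int:
        return self.durations.size


def sample_flights(dist: FlightDistribution, n: int, seed: int) -> TrueFlightSet:
    """Draw ``n`` true flights from ``dist`` (inverse-CDF, reproducible)."""
    return TrueFlightSet(dist.sample(n, seed), source=dist.label(), seed=seed)


@dataclass
class ObservedRecord:
    """The record: counts ``d_j`` of flights lasting ``j`` whole dry intervals."""

    counts: Mapping[int, int]
    interval_s: float
    n_discarded: int = 0
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = {int(j): int(d) for j, d in sorted(self.counts.items()) if d > 0}
        if any(j < 1 for j in self.counts):
            raise ValueError("observed lengths j must be >= 1")
        if any(d < 0 for d in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @property
    def n_flights(self) -> int:
        return sum(self.counts.values())

    @property
    def j_max(self) -> int:
        return max(self.counts) if self.counts else 0

    @property
    def tau_h(self) -> float:
        return self.interval_s / 3600.0

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Observed lengths and their counts as aligned integer arrays."""
        j = np.fromiter(self.counts.keys(), dtype=np.int64, count=len(self.counts))
        d = np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))
        return j, d

    def durations_h(self) -> np.ndarray:
        """Recorded dry durations j*tau (hours), expanded by counts, sorted."""
        j, d = self.arrays()
        return np.repeat(j, d) * self.tau_h

    # -- plain-text round trip ----------------------------------------------
    def to_csv(self, path) -> None:
        j, d = self.arrays()
        header = (
            f"interval_s={self.interval_s} n_flights={self.n_flights} "
            f"n_discarded={self.n_discarded} seed={self.seed} label={self.label}\nj,count"
        )
        np.savetxt(path, np.column_stack([j, d]), fmt="%d", delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path) -> "ObservedRecord":
        meta: dict[str, str] = {}
        with open(path) as fh:
            first = fh.readline().lstrip("# ").strip()
            for tok in first.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        data = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2, dtype=np.int64)
        counts = {int(j): int(d) for j, d in data}
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        return cls(
            counts,
            float(meta["interval_s"]),
            n_discarded=int(meta.get("n_discarded", 0)),
            label=meta.get("label", ""),
            seed=seed,
        )


@dataclass(frozen=True)
class WetModel:
    """Law of wet-landing gaps between flights (timeline emulator only).

    Defaults to exponential gaps with mean ``2 * tau`` of the scheme in use,
    which keeps consecutive flights separated in the aggregated stream.
    """

    law: str = "exponential"
    mean_s: float | None = None

    def sample_gaps_h(self, n: int, scheme: ObservationScheme, rng: np.random.Generator):
        mean_s = self.mean_s if self.mean_s is not None else 2.0 * scheme.interval_s
        if self.law != "exponential":
            raise ValueError(f"unsupported wet-gap law {self.law!r}")
        gaps = rng.exponential(mean_s / 3600.0, size=n)
        return np.maximum(gaps, 1e-12)  # gaps are strictly positive


def observation_kernel(j, t, tau):
    """P(observe j complete dry intervals | true duration t), uniform phase.

    ``K(0|t) = clamp(2 - t/tau, 0, 1)``; for j >= 1 a triangular tent on
    ``[j*tau, (j+2)*tau]`` peaking at ``(j+1)*tau``:
    ``K(j|t) = max(0, min(t/tau - j, (j+2) - t/tau))``.
    """
    j = np.asarray(j)
    t = np.asarray(t, dtype=float)
    x = t / tau
    tent = np.maximum(0.0, np.minimum(x - j, (j + 2) - x))
    zero = np.clip(2.0 - x, 0.0, 1.0)
    out = np.where(j == 0, zero, tent)
    return out if out.ndim else float(out)


def _counts_from_j(j: np.ndarray) -> dict[int, int]:
    vals, cnt = np.unique(j, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnt)}


def emulate_record(
    flights: TrueFlightSet, scheme: ObservationScheme, seed: int
) -> ObservedRecord:
    """Observe each flight with an independent uniform phase on the grid."""
    t = flights.durations
    if t.size == 0:
        raise ValueError("flight set is empty")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=t.size)
    # clip before the integer cast: heavy-tailed draws can exceed int64 range
    jf = np.clip(np.floor(u + t / scheme.tau_h), 0.0, 2.0**62)
    j = jf.astype(np.int64) - 1
    kept = j >= 1
    return ObservedRecord(
        _counts_from_j(j[kept]),
        scheme.interval_s,
        n_discarded=int((~kept).sum()),
        label=scheme.label or f"{scheme.interval_s:g}s",
        seed=seed,
    )


def emulate_timeline(
    flights: TrueFlightSet,
    wet: WetModel,
    scheme: ObservationScheme,
    seed: int,
) -> ObservedRecord:
    """Independent oracle: build the full wet/dry timeline and aggregate it.

    The stream alternates wet gap, flight, wet gap, ...; every interval that
    overlaps any wetness is marked wet and maximal runs of fully dry intervals
    become observed flights.  Runs touching the record boundary cannot occur
    because the stream starts and ends wet.
    """
    t = flights.durations
    rng = np.random.default_rng(seed)
    if t.size == 0:
        return ObservedRecord({}, scheme.interval_s, label=scheme.label, seed=seed)
    gaps = wet.sample_gaps_h(t.size + 1, scheme, rng)
    # interleave: gap_0, flight_0, gap_1, flight_1, ..., gap_n
    spans = np.empty(2 * t.size + 1)
    spans[0::2] = gaps
    spans[1::2] = t
    edges = np.concatenate([[0.0], np.cumsum(spans)])
    tau = scheme.tau_h
    starts = edges[1:-1:2]  # flight start times
    ends = edges[2::2]      # flight end times
    # complete dry intervals inside each flight; neighbours are wet because
    # every gap has positive length and so contaminates the adjacent intervals
    j = np.floor(ends / tau + 1e-12).astype(np.int64) - np.ceil(
        starts / tau - 1e-12
    ).astype(np.int64)
    kept = j >= 1
    return ObservedRecord(
        _counts_from_j(j[kept]),
        scheme.interval_s,
        n_discarded=int((~kept).sum()),
        label=scheme.label or f"{scheme.interval_s:g}s",
        seed=seed,
    )


@dataclass(frozen=True)
class SimulatedRecord:
    generator: str
    scale_target: float
    replicate: int
    scheme: ObservationScheme
    n_true: int
    record: ObservedRecord
    truth: FlightDistribution


def simulate_study(
    grid: ParameterGrid,
    n_flights: int = 3000,
    n_reps: int = 10,
    schemes: Sequence[ObservationScheme] = (SCHEME_10S, SCHEME_1H),
    base_seed: int = 0,
) -> list[SimulatedRecord]:
    """Simulate the full study: every generator x replicate x scheme.

    Each (generator, replicate) pair draws one set of true flights which is
    then observed under every scheme, so the default 16-generator grid with
    10 replicates and two schemes yields 320 records of length <= n_flights.
    Seeds are derived reproducibly from ``base_seed``.
    """
    if n_flights < 1 or n_reps < 1 or not schemes:
        raise ValueError("n_flights, n_reps and schemes must be positive/nonempty")
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(grid) * n_reps)
    out: list[SimulatedRecord] = []
    idx = 0
    for entry in grid:
        for rep in range(n_reps):
            child = children[idx]
            idx += 1
            flight_seed, *obs_seeds = child.generate_state(1 + len(schemes)) % (2**31)
            fl = sample_flights(entry.distribution, n_flights, int(flight_seed))
            for scheme, oseed in zip(schemes, obs_seeds):
                rec = emulate_record(fl, scheme, int(oseed))
                out.append(
                    SimulatedRecord(
                        entry.label, entry.scale_target, rep, scheme,
                        n_flights, rec, entry.distribution,
                    )
                )
    return out
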