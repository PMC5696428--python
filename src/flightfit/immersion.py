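"""Real wet/dry immersion-logger records: parsing, flight extraction, analysis.

A leg-mounted immersion logger stores, per aggregation interval, the number
of wet measurement segments (or a binary wet/dry state).  Flights are
recovered by merging maximal runs of completely dry intervals; runs touching
a record boundary are censored (their true length is unknown) and dropped.
The pooled histogram of run lengths is then fit with all four candidate
flight laws under the exact multinomial likelihood, ranked by BIC, and
checked with a quantile-quantile table against the best fit.

The input schema is a plain CSV with columns ``deployment_id, timestamp,
interval_s, wet_count`` (dialect ``counts``) or ``deployment_id, timestamp,
interval_s, state`` with values wet/dry (dialect ``state``); timestamps mark
interval starts and must advance by exactly ``interval_s`` within a
deployment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import FAMILIES
from .emulator import ObservationScheme, ObservedRecord
from .inference import FitOptions, FitResult, fit_record
from .selection import ModelComparison, rank_models

__all__ = [
    "WetDryLog",
    "QQTable",
    "DatasetAnalysis",
    "read_wetdry",
    "extract_flights",
    "pool_records",
    "analyze_dataset",
    "qq_points",
    "KNOWN_INTERVALS_S",
]

#: Aggregation intervals of the deployed logger generations (seconds).
KNOWN_INTERVALS_S = (10.0, 15.0, 600.0, 720.0, 3600.0)


@dataclass
class WetDryLog:
    """One deployment's per-interval wet/dry series."""

    deployment_id: str
    interval_s: float
    wet_counts: np.ndarray  # integer >= 0 per interval; 0 means fully dry
    species: str = ""
    start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        wc = np.asarray(self.wet_counts, dtype=np.int64)
        if np.any(wc < 0):
            raise ValueError(f"{self.deployment_id}: wet counts must be nonnegative")
        self.wet_counts = wc
        if self.interval_s not in KNOWN_INTERVALS_S:
            import warnings

            warnings.warn(
                f"{self.deployment_id}: interval {self.interval_s} s does not match "
                "a known logger generation", stacklevel=2,
            )

    def __len__(self) -> int:
        return self.wet_counts.size


class WetDryFormatError(ValueError):
    """Malformed wet/dry input; message carries deployment and line numbers."""


def read_wetdry(path, dialect: str = "counts") -> list[WetDryLog]:
    """Parse a wet/dry CSV into one validated log per deployment."""
    if dialect not in ("counts", "state"):
        raise ValueError("dialect must be 'counts' or 'state'")
    value_col = "wet_count" if dialect == "counts" else "state"
    df = pd.read_csv(path)
    required = {"deployment_id", "timestamp", "interval_s", value_col}
    missing = required - set(df.columns)
    if missing:
        raise WetDryFormatError(f"{path}: missing columns {sorted(missing)}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    logs: list[WetDryLog] = []
    for dep, grp in df.groupby("deployment_id", sort=True):
        ivals = grp["interval_s"].unique()
        if len(ivals) != 1:
            raise WetDryFormatError(
                f"deployment {dep}: mixed interval_s values {sorted(ivals)}"
            )
        interval = float(ivals[0])
        ts = pd.to_datetime(grp["timestamp"])
        steps = ts.diff().dt.total_seconds().to_numpy()[1:]
        bad = np.nonzero(np.abs(steps - interval) > 1e-6)[0]
        if bad.size:
            line = int(grp["_line"].iloc[bad[0] + 1])
            raise WetDryFormatError(
                f"deployment {dep}, line {line}: timestamps must advance by "
                f"{interval} s (gap or reordering detected)"
            )
        if dialect == "counts":
            vals = grp[value_col].to_numpy()
            if not np.all(np.equal(np.mod(vals, 1), 0)) or np.any(vals < 0):
                line = int(grp["_line"].iloc[int(np.argmax((np.mod(vals, 1) != 0) | (vals < 0)))])
                raise WetDryFormatError(
                    f"deployment {dep}, line {line}: wet_count must be a "
                    "nonnegative integer"
                )
            wet = vals.astype(np.int64)
        else:
            states = grp[value_col].astype(str).str.strip().str.lower()
            unknown = ~states.isin(["wet", "dry"])
            if unknown.any():
                line = int(grp.loc[unknown, "_line"].iloc[0])
                raise WetDryFormatError(
                    f"deployment {dep}, line {line}: state must be 'wet' or 'dry'"
                )
            wet = (states == "wet").to_numpy().astype(np.int64)
        species = str(grp["species"].iloc[0]) if "species" in grp.columns else ""
        logs.append(WetDryLog(str(dep), interval, wet, species=species, start=ts.iloc[0]))
    return logs


def _dry_runs(wet: np.ndarray) -> tuple[np.ndarray, int]:
    """Lengths of interior maximal dry runs; boundary runs counted censored."""
    dry = wet == 0
    if dry.size == 0:
        return np.empty(0, dtype=np.int64), 0
    padded = np.concatenate([[0], dry.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    lengths = ends - starts
    censored = (starts == 0) | (ends == dry.size)
    return lengths[~censored], int(censored.sum())


def extract_flights(log: WetDryLog) -> ObservedRecord:
    """Merge consecutive completely dry intervals into observed flights.

    Runs touching the start or end of the record are censored — their true
    extent is unknown — and are dropped rather than truncated.
    """
    lengths, n_censored = _dry_runs(log.wet_counts)
    vals, cnt = np.unique(lengths, return_counts=True)
    return ObservedRecord(
        {int(v): int(c) for v, c in zip(vals, cnt)},
        log.interval_s,
        n_discarded=n_censored,
        label=log.deployment_id,
    )


def pool_records(records: Iterable[ObservedRecord], label: str = "pooled") -> ObservedRecord:
    """Sum flight-length counts across deployments sharing one interval."""
    records = list(records)
    if not records:
        raise ValueError("no records to pool")
    intervals = {r.interval_s for r in records}
    if len(intervals) != 1:
        raise ValueError(f"cannot pool records with mixed intervals {sorted(intervals)}")
    counts: dict[int, int] = {}
    discarded = 0
    for r in records:
        discarded += r.n_discarded
        for j, d in r.counts.items():
            counts[j] = counts.get(j, 0) + d
    return ObservedRecord(counts, intervals.pop(), n_discarded=discarded, label=label)


@dataclass
class QQTable:
    """Theoretical vs observed quantiles (hours) of a fitted flight law."""

    table: pd.DataFrame  # columns: plotting_position, theoretical_h, observed_h

    def __post_init__(self) -> None:
        th = self.table["theoretical_h"].to_numpy()
        ob = self.table["observed_h"].to_numpy()
        if np.any(np.diff(th) < -1e-12) or np.any(np.diff(ob) < -1e-12):
            raise ValueError("quantile columns must be nondecreasing")

    def max_abs_deviation(self) -> float:
        return float(
            np.max(np.abs(self.table["theoretical_h"] - self.table["observed_h"]))
        )


def qq_points(fit: FitResult, record: ObservedRecord) -> QQTable:
    """Q-Q table: fitted-law quantiles at positions (i - 0.5)/N vs j*tau."""
    if not fit.converged:
        raise ValueError("cannot build a Q-Q table from a non-converged fit")
    obs = record.durations_h()
    n = obs.size
    pos = (np.arange(1, n + 1) - 0.5) / n
    theo = fit.distribution.quantile(pos)
    return QQTable(
        pd.DataFrame(
            {"plotting_position": pos, "theoretical_h": theo, "observed_h": obs}
        )
    )


@dataclass
class DatasetAnalysis:
    """Full analysis of one pooled data set: fits, ranking, gamma report, Q-Q."""

    fits: dict[str, FitResult]
    comparison: ModelComparison
    qq: QQTable
    gamma_report: dict[str, float]

    @property
    def best_family(self) -> str:
        return self.comparison.best_family


def analyze_dataset(
    record: ObservedRecord,
    scheme: ObservationScheme | None = None,
    families: Sequence[str] = FAMILIES,
    options: FitOptions = FitOptions(),
) -> DatasetAnalysis:
    """Fit all candidate families (exact likelihood), rank by BIC, and
    report the gamma parameter summary and a Q-Q table for the best model."""
    if scheme is not None and abs(scheme.interval_s - record.interval_s) > 1e-9:
        raise ValueError("scheme interval does not match the record")
    fits = {fam: fit_record(record, fam, "exact", options) for fam in families}
    ok = [f for f in fits.values() if f.converged and np.isfinite(f.loglik)]
    comparison = rank_models(ok)
    gamma_report: dict[str, float] = {}
    gfit = fits.get("gamma")
    if gfit is not None and gfit.converged:
        mom = gfit.distribution.moments()
        gamma_report = {
            "shape": gfit.params["shape"], "rate": gfit.params["rate"],
            "mean_h": mom["mean"], "variance_h2": mom["variance"],
        }
    qq = qq_points(fits[comparison.best_family], record)
    return DatasetAnalysis(fits, comparison, qq, gamma_report)
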