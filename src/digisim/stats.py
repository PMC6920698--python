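"""Population statistics for flow-cytometry event tables.

Implements the benchmark summaries: per-condition median fluorescence,
coefficient of variation as a percentage (CV*100), a "no-fluorescence"
gate drawn from the promoterless control population, and the fraction of
events above that gate (fraction ON).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CytometrySummary",
    "SUMMARY_COLUMNS",
    "median_fluorescence",
    "cv100",
    "gate_threshold",
    "fraction_on",
    "summarize",
    "MissingControlError",
]

SUMMARY_COLUMNS = (
    "construct", "dose_nM", "time_min", "n_events",
    "median_au", "mean_au", "sd_au", "cv100", "frac_on",
)


class MissingControlError(ValueError):
    """Raised when a promoterless control population is absent for a time."""


@dataclass(frozen=True)
class CytometrySummary:
    construct: str
    dose_nM: float
    time_min: float
    n_events: int
    median_au: float
    mean_au: float
    sd_au: float
    cv100: float
    frac_on: float


def _events(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("events must be a non-empty 1-D array")
    return arr


def median_fluorescence(events) -> float:
    """Sample median (mean of the middle two values for even n)."""
    return float(np.median(_events(events)))


def cv100(events) -> float:
    """Coefficient of variation as a percentage: 100 * SD / mean.

    SD is the sample standard deviation (n-1 denominator).  The higher the
    value, the less homogeneous the population.
    """
    arr = _events(events)
    if arr.size < 2:
        raise ValueError("cv100 requires at least 2 events")
    m = arr.mean()
    if m <= 0:
        raise ValueError("cv100 requires a positive mean")
    return float(100.0 * arr.std(ddof=1) / m)


def gate_threshold(control_events, q: float = 0.995) -> float:
    """No-fluorescence gate: empirical q-quantile of the control population.

    The control must be the promoterless (autofluorescence-only)
    construct.  Uses the linear-interpolation quantile definition
    (numpy's default), so a constant control returns that constant and
    q=0.5 coincides with the median.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(_events(control_events), q))


def fraction_on(events, threshold: float) -> float:
    """Proportion of events strictly above the gate threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = _events(events)
    return float(np.mean(arr > threshold))


def summarize(table: pd.DataFrame, gate_q: float = 0.995) -> pd.DataFrame:
    """Per-(construct, dose, time) summary of an event table.

    The no-fluorescence gate is computed per time point from the pooled
    promoterless control events at that time; dead cells are excluded from
    all statistics.  Raises :class:`MissingControlError` naming the time
    point if the control is absent.
    """
    required = {"construct", "dose_nM", "time_min", "fluorescence_au", "alive"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    live = table[table["alive"].astype(bool)]
    gates: dict[float, float] = {}
    for t in sorted(live["time_min"].unique()):
        ctrl = live[(live["construct"] == "promoterless") & (live["time_min"] == t)]
        if ctrl.empty:
            raise MissingControlError(
                f"no promoterless control events at time_min={t}"
            )
        gates[t] = gate_threshold(ctrl["fluorescence_au"].to_numpy(), gate_q)
    rows = []
    for (construct, dose, t), grp in live.groupby(
        ["construct", "dose_nM", "time_min"], sort=True
    ):
        au = grp["fluorescence_au"].to_numpy()
        rows.append(
            CytometrySummary(
                construct=str(construct),
                dose_nM=float(dose),
                time_min=float(t),
                n_events=int(au.size),
                median_au=median_fluorescence(au),
                mean_au=float(au.mean()),
                sd_au=float(au.std(ddof=1)) if au.size > 1 else 0.0,
                cv100=cv100(au) if au.size > 1 and au.mean() > 0 else 0.0,
                frac_on=fraction_on(au, gates[float(t)]),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows], columns=SUMMARY_COLUMNS)


def onset_time(summary: pd.DataFrame, construct: str, dose: float,
               level: float = 0.5) -> float:
    """First summarised time at which frac_on reaches ``level``.

    Returns +inf if the level is never reached.
    """
    sub = summary[
        (summary["construct"] == construct) & (summary["dose_nM"] == dose)
    ].sort_values("time_min")
    hit = sub[sub["frac_on"] >= level]
    return float(hit["time_min"].iloc[0]) if not hit.empty else float("inf")
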