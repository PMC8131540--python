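"""Summary kinetics from bottle time series: denitrification rate, completion
and lag times, exponential growth rate and yield coefficients.

The overall denitrification rate is defined operationally as the initial NO3-
divided by the time at which every oxidized N species (NO3-, NO2-, N2O) has
fallen below its detection limit; with 0.862 mmol/L consumed in 2 days this
gives 0.431 mmol L-1 d-1.  Growth rates come from a log-linear least-squares
fit of OD600 over an explicit exponential window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress


@dataclass(frozen=True)
class GrowthRecord:
    time: float  # days
    od600: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.od600 < 0:
            raise ValueError("od600 must be >= 0")


@dataclass(frozen=True)
class KineticSummary:
    denitrification_rate: float | None  # mmol L-1 d-1, None if not completed
    completion_time: float | None  # days
    lag_time: float | None  # days
    mu: float | None  # d-1
    max_od: float | None
    yield_value: float | None
    yield_definition: str = "n2_per_no3"


def completion_time(
    times: Sequence[float],
    no3: Sequence[float],
    no2: Sequence[float],
    n2o: Sequence[float],
    detection_limit: float = 0.001,
) -> float | None:
    """First sampling time at which NO3-, NO2- and N2O are all below detection.

    Returns None when the series never reaches completion.  Censored values
    (recorded as 0) count as below detection.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty series")
    below = (
        (np.asarray(no3, dtype=float) < detection_limit)
        & (np.asarray(no2, dtype=float) < detection_limit)
        & (np.asarray(n2o, dtype=float) < detection_limit)
    )
    idx = np.flatnonzero(below)
    return float(times[idx[0]]) if idx.size else None


def denitrification_rate(no3_initial: float, completion: float | None) -> float | None:
    """Overall rate = initial NO3- / time to completion, mmol L-1 d-1."""
    if completion is None:
        return None
    if completion <= 0:
        raise ValueError("completion time must be positive")
    if no3_initial < 0:
        raise ValueError("initial NO3- must be >= 0")
    return no3_initial / completion


def exponential_window(records: Sequence[GrowthRecord]) -> tuple[int, int]:
    """Default window: the maximal run of strictly increasing OD ending at the
    series maximum.  Returns (start, stop) indices, stop exclusive."""
    od = np.array([r.od600 for r in records], dtype=float)
    i_max = int(np.argmax(od))
    start = i_max
    while start > 0 and od[start - 1] < od[start]:
        start -= 1
    return start, i_max + 1


def exponential_growth_rate(
    records: Sequence[GrowthRecord],
    window: tuple[float, float] | None = None,
) -> float:
    """Slope of ln(OD600) vs time (d-1) over the exponential window.

    `window` is an explicit (t_start, t_end) time interval; when omitted the
    maximal increasing run before the OD maximum is used.  Requires >= 3
    usable points with OD > 0; a constant series returns 0.
    """
    records = sorted(records, key=lambda r: r.time)
    positive = [r.od600 for r in records if r.od600 > 0]
    if len(positive) >= 3 and np.ptp(np.log(positive)) == 0.0:
        return 0.0
    if window is None:
        start, stop = exponential_window(records)
        selected = records[start:stop]
    else:
        t0, t1 = window
        selected = [r for r in records if t0 <= r.time <= t1]
    selected = [r for r in selected if r.od600 > 0]
    if len(selected) < 3:
        raise ValueError(
            f"need >= 3 positive-OD points in the exponential window, got {len(selected)}"
        )
    t = np.array([r.time for r in selected])
    y = np.log([r.od600 for r in selected])
    if np.ptp(y) == 0.0:
        return 0.0
    return float(linregress(t, y).slope)


def lag_time(
    times: Sequence[float],
    conc: Sequence[float],
    threshold_fraction: float = 0.05,
) -> float | None:
    """Onset time of decline: when the species first drops by more than
    `threshold_fraction` of its initial value, the segment that crosses the
    threshold is extrapolated linearly back to the initial concentration.

    An immediate decline gives 0; a series flat to time T then declining
    gives T (within one sampling interval); None if the species never
    declines past the threshold.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if conc.size == 0 or conc[0] <= 0:
        raise ValueError("series must start with a positive concentration")
    c_init = conc[0]
    threshold = c_init * (1.0 - threshold_fraction)
    below = np.flatnonzero(conc < threshold)
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    c0, c1 = conc[i - 1], conc[i]
    if c0 == c1:
        return float(t1)
    onset = t0 + (c_init - c0) * (t1 - t0) / (c1 - c0)
    return float(min(max(onset, times[0]), t1))


YIELD_DEFINITIONS = ("n2_per_no3", "od_per_no3", "od_per_acetate")


def yield_coefficient(
    product_change: float, substrate_change: float, definition: str = "n2_per_no3"
) -> float:
    """Product formed per substrate consumed under the named definition.

    The default mol-N2-per-mol-NO3 definition has a theoretical maximum of 0.5.
    The definition tag travels with the value because published yield columns
    are not always recoverable from any single ratio.
    """
    if definition not in YIELD_DEFINITIONS:
        raise ValueError(f"unknown yield definition {definition!r}; use {YIELD_DEFINITIONS}")
    if substrate_change <= 0:
        raise ValueError("substrate change must be positive")
    if product_change < 0:
        raise ValueError("product change must be >= 0")
    return product_change / substrate_change


def summarize_bottle(
    times: Sequence[float],
    no3: Sequence[float],
    no2: Sequence[float],
    n2o: Sequence[float],
    n2: Sequence[float],
    od: Sequence[float] | None = None,
    detection_limit: float = 0.001,
    growth_window: tuple[float, float] | None = None,
) -> KineticSummary:
    """One-stop kinetic summary of a single bottle time series."""
    t_done = completion_time(times, no3, no2, n2o, detection_limit)
    no3_0 = float(no3[0])
    rate = denitrification_rate(no3_0, t_done) if t_done and t_done > 0 else None
    lag = lag_time(times, no3) if no3_0 > 0 else None
    mu = max_od = None
    if od is not None:
        max_od = float(np.max(od))
        try:
            mu = exponential_growth_rate(
                [GrowthRecord(t, x) for t, x in zip(times, od)], window=growth_window
            )
        except ValueError:
            mu = None
    n2_produced = float(n2[-1]) - float(n2[0])
    no3_consumed = no3_0 - float(no3[-1])
    yld = (
        yield_coefficient(max(n2_produced, 0.0), no3_consumed)
        if no3_consumed > 0
        else None
    )
    return KineticSummary(rate, t_done, lag, mu, max_od, yld)
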