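"""FUCCI cell-cycle classification, phase-duration tracing and statistics.

State gating follows the red/green logic: red-high & green-low -> G1,
green-high & red-low -> G2/M, double-high -> S, double-low -> early G1
(values exactly at a gate count as "low").

Tracing scores one cell from a post-mitosis start to the next metaphase.
Non-cycling rules, applied in order:

1. residence in a single phase beyond ``noncycling_hours`` (default 24 h)
   -> non-cycling (stall);
2. a green-to-red transition without an intervening mitosis event
   -> non-cycling (slip).

Cells whose trace ends before mitosis without triggering either rule are
censored, unless ``strict_movie_end`` is set, in which case any trace
reaching the movie end mid-phase is scored as a stall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters

__all__ = [
    "Phase",
    "CyclingStatus",
    "FucciTrace",
    "CellCycleGates",
    "PhaseDurations",
    "classify_state",
    "calibrate_gates",
    "trace_durations",
    "compare_durations",
    "cycling_association",
]

PHASE_ORDER = ("earlyG1", "G1", "S", "G2")


class Phase(str, Enum):
    EARLY_G1 = "earlyG1"
    G1 = "G1"
    S = "S"
    G2 = "G2"


class CyclingStatus(str, Enum):
    CYCLING = "cycling"
    NONCYCLING_STALL = "noncycling_stall"
    NONCYCLING_SLIP = "noncycling_slip"
    CENSORED = "censored"


@dataclass
class FucciTrace:
    """Per-frame red/green intensities for one tracked cell."""

    cell_id: int | str
    time_h: np.ndarray
    red: np.ndarray
    green: np.ndarray
    mitosis: np.ndarray  # bool per frame
    frame_interval_h: float

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.mitosis = np.asarray(self.mitosis, dtype=bool)
        n = len(self.time_h)
        if not (len(self.red) == len(self.green) == len(self.mitosis) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.red < 0) or np.any(self.green < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class CellCycleGates:
    red_high: float
    green_high: float

    def __post_init__(self) -> None:
        if self.red_high <= 0 or self.green_high <= 0:
            raise ValueError("gate thresholds must be > 0")


@dataclass
class PhaseDurations:
    cell_id: int | str
    durations_h: dict[str, float]
    total_h: float
    status: CyclingStatus


def classify_state(red: float, green: float, gates: CellCycleGates) -> Phase:
    """Gate a single (red, green) measurement into a cell-cycle state."""
    red_high = red > gates.red_high
    green_high = green > gates.green_high
    if red_high and green_high:
        return Phase.S
    if red_high:
        return Phase.G1
    if green_high:
        return Phase.G2
    return Phase.EARLY_G1


def _otsu_log(values: np.ndarray) -> float | None:
    positive = values[values > 0]
    if len(positive) < 2 or np.ptp(positive) == 0:
        return None
    logv = np.log(positive)
    try:
        thr = filters.threshold_otsu(logv)
    except ValueError:
        return None
    return float(np.exp(thr))


def calibrate_gates(
    red: np.ndarray, green: np.ndarray, fallback_factor: float = 2.0
) -> CellCycleGates:
    """Per-channel intensity gates from two-class Otsu on log intensities.

    A channel without a usable bimodal log-histogram falls back to
    ``median * fallback_factor`` (warned). Deterministic; requires >= 100
    measurements per channel.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if len(red) < 100 or len(green) < 100:
        raise ValueError("need >= 100 measurements to calibrate gates")
    gates = []
    for name, values in (("red", red), ("green", green)):
        thr = _otsu_log(values)
        if thr is None:
            med = float(np.median(values))
            thr = med * fallback_factor if med > 0 else 1.0
            warnings.warn(
                f"{name} channel not bimodal: falling back to median-based gate"
            )
        gates.append(thr)
    return CellCycleGates(red_high=gates[0], green_high=gates[1])


def _majority_smooth(states: list[Phase], window: int = 3) -> list[Phase]:
    if len(states) < window:
        return list(states)
    half = window // 2
    out = list(states)
    for i in range(half, len(states) - half):
        neighborhood = states[i - half : i + half + 1]
        counts: dict[Phase, int] = {}
        for s in neighborhood:
            counts[s] = counts.get(s, 0) + 1
        best = max(counts.values())
        if counts.get(states[i], 0) < best:
            # tie broken toward the earliest majority holder in the window
            for s in neighborhood:
                if counts[s] == best:
                    out[i] = s
                    break
    return out


def _runs(states: list[Phase]) -> list[tuple[Phase, int, int]]:
    """Contiguous (state, start_idx, end_idx_exclusive) runs."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start, i))
            start = i
    return runs


def trace_durations(
    trace: FucciTrace,
    gates: CellCycleGates,
    noncycling_hours: float = 24.0,
    smooth_window: int = 3,
    strict_movie_end: bool = False,
) -> PhaseDurations:
    """Score per-phase residence times and cycling status for one trace."""
    states = [
        classify_state(r, g, gates) for r, g in zip(trace.red, trace.green)
    ]
    states = _majority_smooth(states, window=smooth_window)
    dt = trace.frame_interval_h

    mitosis_idx = np.flatnonzero(trace.mitosis)
    # the mitosis (metaphase) frame is the cycle boundary, not residence time
    end = int(mitosis_idx[0]) if len(mitosis_idx) else len(states)
    observed = states[:end]
    runs = _runs(observed)
    complete_trace = len(mitosis_idx) > 0

    durations = {name: 0.0 for name in PHASE_ORDER}
    for state, start, stop in runs:
        durations[state.value] += (stop - start) * dt

    # rule 1: stall — excessive single-phase residence (the final, still-open
    # run counts once its residence already exceeds the limit)
    for state, start, stop in runs:
        if (stop - start) * dt > noncycling_hours:
            return PhaseDurations(
                trace.cell_id, durations, sum(durations.values()),
                CyclingStatus.NONCYCLING_STALL,
            )
    if strict_movie_end and not complete_trace:
        return PhaseDurations(
            trace.cell_id, durations, sum(durations.values()),
            CyclingStatus.NONCYCLING_STALL,
        )

    # rule 2: slip — green-to-red reversal without an intervening mitosis
    for (prev, _, _), (cur, cur_start, _) in zip(runs, runs[1:]):
        if (
            prev is Phase.G2
            and cur is Phase.G1
            and not trace.mitosis[: cur_start + 1].any()
        ):
            return PhaseDurations(
                trace.cell_id, durations, sum(durations.values()),
                CyclingStatus.NONCYCLING_SLIP,
            )

    if not complete_trace:
        return PhaseDurations(
            trace.cell_id, durations, sum(durations.values()),
            CyclingStatus.CENSORED,
        )
    total = sum(durations.values())
    return PhaseDurations(trace.cell_id, durations, total, CyclingStatus.CYCLING)


def traces_from_frame(df: pd.DataFrame, frame_interval_h: float) -> list[FucciTrace]:
    """Build FucciTrace objects from a long-format table.

    Expects columns ``cell_id``, ``t_h``, ``red``, ``green``, ``mitosis``.
    """
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("t_h")
        traces.append(
            FucciTrace(
                cell_id=cell_id,
                time_h=group["t_h"].to_numpy(),
                red=group["red"].to_numpy(),
                green=group["green"].to_numpy(),
                mitosis=group["mitosis"].to_numpy().astype(bool),
                frame_interval_h=frame_interval_h,
            )
        )
    return traces


def compare_durations(groups: dict[str, list | np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across duration groups."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def cycling_association(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 cycling/non-cycling contingency table.

    The two-sided p sums, over the hypergeometric support at fixed margins,
    every table whose probability does not exceed the observed one. Counts
    are integers, so the summation runs in exact integer arithmetic and the
    single float division at the end is the only rounding step. Returns
    (odds_ratio, p); the odds ratio uses the Haldane +0.5 correction when
    any cell is zero.
    """
    a, b = (int(x) for x in group_a)
    c, d = (int(x) for x in group_b)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        raise ValueError("contingency table has an empty margin")

    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalized hypergeometric weights: comb(r1,k) * comb(r2, c1-k)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    p = sum(w for w in weights if w <= observed) / sum(weights)

    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
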