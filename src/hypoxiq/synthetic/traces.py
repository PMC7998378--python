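"""Synthetic FUCCI red/green time-lapse traces with known phase structure.

Cycling cells run colorless early G1 -> red G1 -> double-positive S ->
green G2/M and end at a mitosis-flagged metaphase frame. Non-cycling
cells follow one of two modes: "stall" cells remain in a uniformly chosen
phase until the trace end; "slip" cells turn from green back to red at a
random frame without a mitosis event.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ..config import SimulationConfig

PHASES = ("earlyG1", "G1", "S", "G2")

# (red, green) intensity levels per phase: low/high per channel
_LEVELS = {
    "earlyG1": (10.0, 10.0),
    "G1": (100.0, 10.0),
    "S": (100.0, 100.0),
    "G2": (10.0, 100.0),
}


def generate_fucci_traces(
    n_cells: int,
    phase_means_h: tuple[float, float, float, float] = (2.0, 8.0, 7.0, 3.0),
    noncycling_fraction: float = 0.0,
    cfg: SimulationConfig | None = None,
    noise_cv: float = 0.1,
    phase_cv: float = 0.15,
    movie_h: float = 60.0,
    noncycling_mode: str = "mixed",  # stall | slip | mixed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format trace table plus per-cell ground truth.

    Returns (traces, truth): traces with columns ``cell_id, t_h, red,
    green, mitosis``; truth with the planted per-phase durations, status
    (cycling / noncycling_stall / noncycling_slip) and, for stall cells,
    the stalled phase. Intensity noise is multiplicative log-normal with
    coefficient of variation ``noise_cv``.
    """
    cfg = cfg or SimulationConfig()
    if any(m <= 0 for m in phase_means_h):
        raise ValueError("phase means must be > 0")
    if not (0 <= noncycling_fraction <= 1):
        raise ValueError("noncycling_fraction must be in [0, 1]")
    if noncycling_mode not in ("stall", "slip", "mixed"):
        raise ValueError("noncycling_mode must be stall, slip or mixed")
    dt = cfg.frame_interval_h
    if dt > min(phase_means_h):
        warnings.warn(
            "frame interval exceeds the shortest phase mean: durations quantized"
        )
    rng = cfg.rng(salt=404)
    sigma = np.sqrt(np.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0

    trace_rows, truth_rows = [], []
    for cell in range(n_cells):
        noncycling = rng.uniform() < noncycling_fraction
        mode = None
        if noncycling:
            if noncycling_mode == "mixed":
                mode = "stall" if rng.uniform() < 0.5 else "slip"
            else:
                mode = noncycling_mode

        if phase_cv > 0:
            s = np.sqrt(np.log(1 + phase_cv**2))
            durations = np.array(phase_means_h) * rng.lognormal(
                -(s**2) / 2, s, size=4
            )
        else:
            durations = np.array(phase_means_h, dtype=float)
        # keep sampled cycling phases safely under the 24 h stall rule
        durations = np.minimum(durations, 20.0)

        if not noncycling:
            total = float(durations.sum())
            bounds = np.cumsum(durations)
            n_frames = int(np.ceil(total / dt)) + 1
            times = np.arange(n_frames) * dt
            states = [PHASES[int(np.searchsorted(bounds, t, side="right"))]
                      if t < total else "G2" for t in times]
            mitosis = np.zeros(n_frames, dtype=bool)
            mitosis[-1] = True
            truth_rows.append(
                {
                    "cell_id": cell,
                    "status": "cycling",
                    "stall_phase": "",
                    "earlyG1_h": durations[0],
                    "G1_h": durations[1],
                    "S_h": durations[2],
                    "G2_h": durations[3],
                    "total_h": total,
                }
            )
        elif mode == "stall":
            stall_phase = PHASES[int(rng.integers(0, 4))]
            pre = []
            for name, dur in zip(PHASES, durations):
                if name == stall_phase:
                    break
                pre.append((name, dur))
            n_frames = int(np.ceil(movie_h / dt)) + 1
            times = np.arange(n_frames) * dt
            states = []
            for t in times:
                acc = 0.0
                state = stall_phase
                for name, dur in pre:
                    if t < acc + dur:
                        state = name
                        break
                    acc += dur
                states.append(state)
            mitosis = np.zeros(n_frames, dtype=bool)
            truth_rows.append(
                {
                    "cell_id": cell,
                    "status": "noncycling_stall",
                    "stall_phase": stall_phase,
                    "earlyG1_h": np.nan,
                    "G1_h": np.nan,
                    "S_h": np.nan,
                    "G2_h": np.nan,
                    "total_h": np.nan,
                }
            )
        else:  # slip: green, then back to red without mitosis
            g2_h = float(rng.uniform(2.0, 6.0))
            post_red_h = float(rng.uniform(4.0, 18.0))
            segments = [
                ("earlyG1", durations[0]),
                ("G1", durations[1]),
                ("S", durations[2]),
                ("G2", g2_h),
                ("G1", post_red_h),
            ]
            total = sum(d for _, d in segments)
            n_frames = int(np.ceil(total / dt))
            times = np.arange(n_frames) * dt
            states = []
            for t in times:
                acc = 0.0
                state = segments[-1][0]
                for name, dur in segments:
                    if t < acc + dur:
                        state = name
                        break
                    acc += dur
                states.append(state)
            mitosis = np.zeros(n_frames, dtype=bool)
            truth_rows.append(
                {
                    "cell_id": cell,
                    "status": "noncycling_slip",
                    "stall_phase": "",
                    "earlyG1_h": np.nan,
                    "G1_h": np.nan,
                    "S_h": np.nan,
                    "G2_h": np.nan,
                    "total_h": np.nan,
                }
            )

        for t, state, mito in zip(times, states, mitosis):
            red_level, green_level = _LEVELS[state]
            if sigma > 0:
                red = red_level * rng.lognormal(-(sigma**2) / 2, sigma)
                green = green_level * rng.lognormal(-(sigma**2) / 2, sigma)
            else:
                red, green = red_level, green_level
            trace_rows.append(
                {
                    "cell_id": cell,
                    "t_h": float(t),
                    "red": float(red),
                    "green": float(green),
                    "mitosis": bool(mito),
                }
            )

    traces = pd.DataFrame.from_records(trace_rows)
    truth = pd.DataFrame.from_records(truth_rows)
    return traces, truth
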