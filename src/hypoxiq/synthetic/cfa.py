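"""Poisson colony counts under a linear-quadratic dose response."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig


def simulate_cfa_counts(
    alpha: float,
    beta: float,
    doses: list[float],
    seeded_per_well: int = 250,
    plating_efficiency: float = 1.0,
    replicates: int = 6,
    cfg: SimulationConfig | None = None,
    condition: str = "sim",
) -> pd.DataFrame:
    """Colony-count plate table with Poisson well counts.

    Each well count is Poisson with mean
    ``seeded * PE * exp(-alpha*D - beta*D^2)``. Returns a long table with
    columns ``condition``, ``dose_gy``, ``replicate``, ``seeded``,
    ``colonies``.
    """
    cfg = cfg or SimulationConfig()
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    if not (0 <= plating_efficiency <= 1):
        raise ValueError("plating efficiency must be in [0, 1]")
    doses = [float(d) for d in doses]
    if 0.0 not in doses:
        raise ValueError("doses must include 0 Gy (plating-efficiency reference)")
    if seeded_per_well <= 0 or replicates <= 0:
        raise ValueError("seeded_per_well and replicates must be > 0")

    rng = cfg.rng(salt=101)
    records = []
    for dose in doses:
        sf = np.exp(-alpha * dose - beta * dose**2)
        mean = seeded_per_well * plating_efficiency * sf
        counts = rng.poisson(mean, size=replicates)
        for rep, count in enumerate(counts):
            records.append(
                {
                    "condition": condition,
                    "dose_gy": dose,
                    "replicate": rep,
                    "seeded": seeded_per_well,
                    "colonies": int(count),
                }
            )
    return pd.DataFrame.from_records(records)
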