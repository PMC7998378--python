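"""Clonogenic-assay statistics.

Plating efficiency and surviving fractions from per-well colony counts,
linear-quadratic (LQ) dose-response fitting ``SF = exp(-alpha*D - beta*D^2)``
with non-negative parameters, nested-model comparison of two survival
curves by the extra-sum-of-squares F-test, and iso-effect dose inversion.

Fitting is ordinary least squares in log-SF space: ``ln SF = -aD - bD^2``
is linear in (a, b), so the constrained optimum is found exactly by
non-negative least squares. Wells with zero colonies at positive dose are
excluded from the log-space fit (log undefined) and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalDataset",
    "SurvivalPoint",
    "LQFit",
    "FTestResult",
    "surviving_fractions",
    "per_well_points",
    "lq_sf",
    "fit_lq",
    "compare_curves_ftest",
    "dose_for_sf",
]


@dataclass
class SurvivalDataset:
    """Per-well colony counts for one experimental condition.

    ``wells`` must hold columns ``dose_gy``, ``seeded``, ``colonies`` and
    include 0 Gy wells (the plating-efficiency reference).
    """

    condition: str
    wells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dose_gy", "seeded", "colonies"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"wells table missing columns: {sorted(missing)}")
        if (self.wells["colonies"] < 0).any():
            raise ValueError("colony counts must be >= 0")
        if (self.wells["seeded"] <= 0).any():
            raise ValueError("seeded counts must be > 0")
        if not (self.wells["dose_gy"] == 0).any():
            raise ValueError("dataset must contain 0 Gy wells")

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "SurvivalDataset":
        df = pd.read_csv(path)
        if condition is not None:
            name = condition
            if "condition" in df.columns:
                df = df[df["condition"] == condition]
        else:
            name = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
        return cls(condition=name, wells=df.reset_index(drop=True))

    def plating_efficiency(self) -> float:
        zero = self.wells[self.wells["dose_gy"] == 0]
        pe = float((zero["colonies"] / zero["seeded"]).mean())
        if pe == 0:
            raise ValueError("plating efficiency undefined: zero colonies at 0 Gy")
        return pe


@dataclass(frozen=True)
class SurvivalPoint:
    dose_gy: float
    sf: float
    sem: float = 0.0  # dispersion over replicate wells
    zero_flagged: bool = False
    # inverse-variance weight for log-space fitting; for a well with N
    # colonies var(ln N) ~ 1/N, so per-well points carry their colony count
    weight: float = 1.0


@dataclass
class LQFit:
    alpha: float
    beta: float
    rss: float  # residual sum of squares in log-SF space
    df: int
    cov: np.ndarray | None = None
    constrained: bool = False  # non-negativity constraint active
    n_points: int = 0
    dropped_zero_sf: int = 0


@dataclass
class FTestResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    rss_simple: float
    rss_complex: float
    perfect_fit: bool = False  # RSS_complex == 0 branch


def surviving_fractions(data: SurvivalDataset) -> list[SurvivalPoint]:
    """Per-dose surviving fractions normalized by plating efficiency.

    PE is the mean colonies/seeded over the 0 Gy wells; SF(D) is the
    mean colonies/seeded at D divided by PE, so SF(0) == 1 by construction.
    Doses where no well grew colonies are reported as SF 0 with a flag.
    """
    pe = data.plating_efficiency()
    points = []
    for dose, group in data.wells.groupby("dose_gy", sort=True):
        frac = group["colonies"] / group["seeded"] / pe
        sf = float(frac.mean())
        sem = float(frac.sem()) if len(frac) > 1 else 0.0
        points.append(
            SurvivalPoint(
                dose_gy=float(dose), sf=sf, sem=sem, zero_flagged=(sf == 0)
            )
        )
    return points


def per_well_points(data: SurvivalDataset) -> list[SurvivalPoint]:
    """One SurvivalPoint per well (replication preserved for fitting df)."""
    pe = data.plating_efficiency()
    return [
        SurvivalPoint(
            dose_gy=float(row.dose_gy),
            sf=float(row.colonies / row.seeded / pe),
            zero_flagged=(row.colonies == 0),
            weight=float(row.colonies),
        )
        for row in data.wells.itertuples()
    ]


def lq_sf(alpha: float, beta: float, dose) -> float | np.ndarray:
    """Linear-quadratic surviving fraction ``exp(-alpha*D - beta*D^2)``."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    out = np.exp(-alpha * dose - beta * dose**2)
    return float(out) if out.ndim == 0 else out


def _usable(
    points: list[SurvivalPoint],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    doses = np.array([p.dose_gy for p in points], dtype=float)
    sfs = np.array([p.sf for p in points], dtype=float)
    weights = np.array([p.weight for p in points], dtype=float)
    keep = sfs > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"excluding {dropped} zero-SF point(s) from log-space LQ fit",
            stacklevel=3,
        )
    return doses[keep], sfs[keep], weights[keep], dropped


def _solve_lq(
    doses: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    group_ids: np.ndarray | None = None,
    intercept: bool = False,
) -> tuple[float, float, float]:
    """Weighted least squares for ``y = c_g + alpha*D + beta*D^2``.

    alpha, beta >= 0 are enforced through NNLS; optional per-group
    intercepts c_g are free in sign (entered as +/- column pairs).
    Returns (alpha, beta, weighted RSS).
    """
    cols = [doses, doses**2]
    ids = np.zeros(len(doses), dtype=int) if group_ids is None else group_ids
    if intercept:
        for g in range(int(ids.max()) + 1):
            ind = (ids == g).astype(float)
            cols.extend([ind, -ind])
    X = np.column_stack(cols)
    sw = np.sqrt(weights)
    params, _ = optimize.nnls(X * sw[:, None], y * sw)
    resid = (y - X @ params) * sw
    return float(params[0]), float(params[1]), float(resid @ resid)


def fit_lq(points: list[SurvivalPoint], intercept: bool = False) -> LQFit:
    """Constrained least-squares LQ fit in log-SF space.

    Solves ``min sum w_i (ln SF_i + alpha*D_i + beta*D_i^2)^2`` for
    ``(alpha, beta) >= 0`` — an exact (weighted) non-negative
    least-squares problem. ``intercept=True`` adds a free normalization
    term absorbing plating-efficiency misestimation (one extra parameter).
    """
    doses, sfs, weights, dropped = _usable(points)
    if len(np.unique(doses)) < 3:
        raise ValueError("need >= 3 distinct doses with SF > 0 to fit LQ model")
    y = -np.log(sfs)
    alpha, beta, rss = _solve_lq(doses, y, weights, intercept=intercept)
    n = len(doses)
    df = n - 2 - int(intercept)
    X = np.column_stack([doses, doses**2])
    # unconstrained solution tells us whether the bound is active
    unconstrained, *_ = np.linalg.lstsq(X * np.sqrt(weights)[:, None],
                                        y * np.sqrt(weights), rcond=None)
    constrained = bool(np.any(unconstrained < 0) and (alpha == 0 or beta == 0))
    cov = None
    if df > 0:
        sigma2 = rss / df
        try:
            cov = sigma2 * np.linalg.inv((X * weights[:, None]).T @ X)
        except np.linalg.LinAlgError:
            cov = None
    return LQFit(
        alpha=alpha,
        beta=beta,
        rss=rss,
        df=df,
        cov=cov,
        constrained=constrained,
        n_points=n,
        dropped_zero_sf=dropped,
    )


def compare_curves_ftest(
    group_a: list[SurvivalPoint],
    group_b: list[SurvivalPoint],
    intercept: bool = True,
) -> FTestResult:
    """Extra-sum-of-squares F-test: one pooled LQ curve vs one per group.

    The null model fits both groups with a single (alpha, beta); the
    alternative fits each group separately. ``F = ((RSS_s - RSS_c)/2) /
    (RSS_c / df_c)``.

    By default each group keeps a free normalization intercept in both
    models (the plating efficiency is itself estimated from the 0 Gy
    wells, which otherwise shifts a whole group off any shared curve and
    inflates the type-I error well beyond nominal); weights attached to
    the points make the log-space residuals comparable across doses.
    ``intercept=False`` reproduces the plain two-parameter comparison.
    """
    fit_a = fit_lq(group_a, intercept=intercept)
    fit_b = fit_lq(group_b, intercept=intercept)
    if len(group_a) == len(group_b) and all(
        a.dose_gy == b.dose_gy and a.sf == b.sf
        for a, b in zip(group_a, group_b)
    ):
        # identical groups: pooled fit equals the individual fits exactly
        df_den = fit_a.df + fit_b.df
        return FTestResult(0.0, 2, df_den, 1.0, 2 * fit_a.rss, 2 * fit_a.rss)

    doses_a, sfs_a, w_a, _ = _usable(group_a)
    doses_b, sfs_b, w_b, _ = _usable(group_b)
    doses = np.concatenate([doses_a, doses_b])
    y = -np.log(np.concatenate([sfs_a, sfs_b]))
    w = np.concatenate([w_a, w_b])
    ids = np.concatenate(
        [np.zeros(len(doses_a), int), np.ones(len(doses_b), int)]
    )
    *_, rss_simple = _solve_lq(doses, y, w, group_ids=ids, intercept=intercept)

    rss_complex = fit_a.rss + fit_b.rss
    df_num = 2
    df_den = fit_a.df + fit_b.df  # n_total minus all per-group parameters
    if df_den <= 0:
        raise ValueError("not enough points for the F-test denominator df")
    if rss_complex <= 1e-12 * max(rss_simple, 1.0):
        perfect = True
        if rss_simple <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
        return FTestResult(f_stat, df_num, df_den, p, rss_simple, rss_complex, perfect)
    extra = max(rss_simple - rss_complex, 0.0)
    f_stat = (extra / df_num) / (rss_complex / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return FTestResult(f_stat, df_num, df_den, p, rss_simple, rss_complex)


def dose_for_sf(fit: LQFit, target_sf: float) -> float:
    """Dose producing ``target_sf`` under the fitted LQ curve.

    Positive root of ``beta*D^2 + alpha*D + ln(target_sf) = 0``; the pure
    linear model falls back to ``D = -ln(target_sf)/alpha``.
    """
    if not (0 < target_sf <= 1):
        raise ValueError("target_sf must be in (0, 1]")
    if target_sf == 1:
        return 0.0
    alpha, beta = fit.alpha, fit.beta
    c = math.log(target_sf)  # negative
    if alpha == 0 and beta == 0:
        raise ValueError("alpha = beta = 0: no dose achieves the target SF")
    if beta == 0:
        return -c / alpha
    # rationalized root avoids cancellation when beta*|c| << alpha^2
    disc = alpha**2 - 4 * beta * c
    return 2 * (-c) / (alpha + math.sqrt(disc))
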