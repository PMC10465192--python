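"""Shared statistics: weighted trait summaries, exact binomial test,
rate ratios and gradient-importance summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TraitSummary",
    "weighted_trait_stats",
    "weighted_pearson",
    "exact_binomial",
    "rate_ratio",
    "gradient_importance",
    "smooth_trait_landscape",
]


@dataclass(frozen=True)
class TraitSummary:
    """Weighted trait means, step changes and the T-S correlation.

    ``delta_*`` are step-to-step changes (nan when no previous state is
    given); ``ts_corr`` is the weighted Pearson correlation of tolerance
    and suppression across genotypes, nan when either trait is constant
    under the weights.  ``rate_ratio`` is |delta_S| / |delta_T|, nan when
    |delta_T| is below 1e-10.
    """

    mean_tolerance: float
    mean_suppression: float
    delta_tolerance: float
    delta_suppression: float
    ts_corr: float

    @property
    def rate_ratio(self) -> float:
        if not math.isfinite(self.delta_tolerance) or abs(self.delta_tolerance) <= 1e-10:
            return math.nan
        return abs(self.delta_suppression) / abs(self.delta_tolerance)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation; nan when either variable is constant."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return math.nan
    return float(cov / math.sqrt(vx * vy))


def weighted_trait_stats(
    tolerance: np.ndarray,
    suppression: np.ndarray,
    weights: np.ndarray,
    prev: "TraitSummary | None" = None,
) -> TraitSummary:
    """Density/abundance-weighted trait summary for one time step."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights")
    w = w / total
    mt = float(w @ np.asarray(tolerance, dtype=float))
    ms = float(w @ np.asarray(suppression, dtype=float))
    corr = weighted_pearson(tolerance, suppression, w)
    if prev is None:
        dt = ds = math.nan
    else:
        dt = mt - prev.mean_tolerance
        ds = ms - prev.mean_suppression
    return TraitSummary(mt, ms, dt, ds, corr)


def exact_binomial(successes: int, trials: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value.

    Standard exact convention: the sum of the probabilities of all
    outcomes whose point probability does not exceed that of the
    observed count.
    """
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    return float(sps.binomtest(successes, trials, p0, alternative="two-sided").pvalue)


def rate_ratio(
    mean_tolerance: np.ndarray,
    mean_suppression: np.ndarray,
    floor: float = 1e-10,
) -> float:
    """Maximum per-step |dS_bar| / |dT_bar| over a trajectory.

    Measures how fast suppression evolves relative to tolerance; computed
    only over steps where |dT_bar| exceeds ``floor``.  Invariant to
    relabelling of time steps.  Returns nan when no step qualifies.
    """
    dT = np.diff(np.asarray(mean_tolerance, dtype=float))
    dS = np.diff(np.asarray(mean_suppression, dtype=float))
    ok = np.abs(dT) > floor
    if not ok.any():
        return math.nan
    return float(np.max(np.abs(dS[ok]) / np.abs(dT[ok])))


def gradient_importance(
    alphas=(0.6, 0.8, 1.0),
    rhos=(0.6, 0.8, 1.0),
    betas=(0.25, 0.5, 0.75),
    n: int = 1,
    phi: float = 1.0,
    levels: int = 13,
    trait_min: float = 0.2,
    trait_max: float = 0.8,
    max_survival: float = 0.8,
) -> pd.DataFrame:
    """Deficit of the suppression gradient relative to the tolerance
    gradient over a parameter grid.

    For every (alpha, rho, beta) cell and every genotype of a uniform
    T x S grid population, evaluates the analytic selection gradients and
    reports ``100 * (1 - |dP_hat/dS| / |dP_hat/dT|)`` — the percentage by
    which the fitness effect of suppression falls short of that of
    tolerance.  Cells with a vanishing tolerance gradient are flagged
    undefined (nan deficit).
    """
    from .core import Population, SFMParams
    from .dynamics import selection_gradient

    pop = Population.trait_grid(levels, trait_min, trait_max, max_survival)
    rows = []
    for a in alphas:
        for r in rhos:
            for b in betas:
                params = SFMParams(alpha=a, rho=r, beta=b, n=n, phi=phi)
                gT, gS = selection_gradient(pop, params)
                with np.errstate(divide="ignore", invalid="ignore"):
                    deficit = np.where(
                        np.abs(gT) > 0, 100.0 * (1.0 - np.abs(gS) / np.abs(gT)), np.nan
                    )
                rows.append(
                    pd.DataFrame(
                        {
                            "alpha": a,
                            "rho": r,
                            "beta": b,
                            "n": n,
                            "phi": phi,
                            "tolerance": pop.tolerance,
                            "suppression": pop.suppression,
                            "grad_T": gT,
                            "grad_S": gS,
                            "deficit_pct": deficit,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def smooth_trait_landscape(values: np.ndarray) -> np.ndarray:
    """3x3 moving-average smoothing of a trait-grid landscape (display
    convenience for per-genotype fitness maps; raw values are kept)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a 2-D trait-grid array")
    padded = np.pad(v, 1, mode="edge")
    out = np.zeros_like(v)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            out += padded[1 + dx : 1 + dx + v.shape[0], 1 + dy : 1 + dy + v.shape[1]]
    return out / 9.0
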