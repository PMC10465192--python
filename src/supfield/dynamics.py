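"""Density dynamics of suppression-field populations.

The population is a fixed set of clonal genotypes whose relative
densities follow a discrete replicator update with fitness equal to
effective survival:

    D_i  <-  D_i * P_hat_i / sum_j D_j * P_hat_j

Selection therefore acts only through differences in survival; traits
never change within a genotype.  On top of the iteration this module
provides the analytic selection gradients on tolerance and suppression,
the threshold density at which the fitness effect of suppression changes
sign under kin assortativity, invasion trials against (near-)equilibrium
residents, and strategy-outcome sweeps over competition intensity and
replacement rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Population, SFMParams, assorted_suppression, effective_survival, initiator_term
from .errors import PopulationCollapseError, ThresholdUndefinedError
from .stats import weighted_pearson

__all__ = [
    "Trajectory",
    "ThresholdResult",
    "InvasionResult",
    "TUNED_PRESETS",
    "step_sfm",
    "run_sfm",
    "equilibrate",
    "selection_gradient",
    "threshold_density",
    "invasion_test",
    "ess_sweep",
]

#: genotypes whose density drops below this are removed before renormalizing
EXTINCTION_FLOOR = 1e-12

#: named "tuned" (alpha*rho, beta) presets estimated from the lattice ABMs.
#: ``tuned_age`` is the with-age-effects estimate quoted in the iteration
#: protocol (alpha*rho = 0.6); ``tuned_age_fig`` is the with-age-effects
#: value quoted alongside the trajectory figures (alpha*rho = 0.96).  The
#: two printed values disagree; both are exposed rather than resolved.
#: ``tuned_noage`` is the no-age-effects estimate.
TUNED_PRESETS: dict[str, dict[str, float]] = {
    "tuned_age": {"alpharho": 0.6, "beta": 0.85},
    "tuned_age_fig": {"alpharho": 0.96, "beta": 0.85},
    "tuned_noage": {"alpharho": 0.975, "beta": 0.755},
}


def tuned_params(preset: str, **kw) -> SFMParams:
    """Build :class:`SFMParams` from a named tuned preset.

    The alpha*rho product is applied through ``rho`` with ``alpha = 1``
    (only the product enters the model).
    """
    p = TUNED_PRESETS[preset]
    return SFMParams(alpha=1.0, rho=p["alpharho"], beta=p["beta"], **kw)


@dataclass
class Trajectory:
    """Per-step record of a density-iteration run.

    ``frame`` holds one row per step: step index, density-weighted mean
    tolerance and suppression, their step-to-step changes, and the
    density-weighted T-S Pearson correlation.  ``densities`` is the full
    (steps+1, k) density history.
    """

    frame: pd.DataFrame
    densities: np.ndarray
    population: Population
    params: SFMParams
    preset: str | None = None
    extras: dict = field(default_factory=dict)

    @property
    def initial(self) -> pd.Series:
        return self.frame.iloc[0]

    @property
    def final(self) -> pd.Series:
        return self.frame.iloc[-1]

    def final_population(self) -> Population:
        return self.population.with_density(self.densities[-1])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def step_sfm(
    pop: Population, params: SFMParams, extinction_floor: float = EXTINCTION_FLOOR
) -> Population:
    """One replicator update of the densities.

    Genotypes falling below ``extinction_floor`` are zeroed before the
    final renormalization (prevents denormal drift on large grids).
    """
    p_hat, _ = effective_survival(pop, params)
    mass = pop.density * p_hat
    total = float(mass.sum())
    if total <= 0.0:
        raise PopulationCollapseError("all genotypes reached zero effective survival")
    D = mass / total
    D[D < extinction_floor] = 0.0
    D /= D.sum()
    return pop.with_density(D)


def _record(step: int, pop: Population, prev_row: dict | None) -> dict:
    mt = pop.mean_tolerance
    ms = pop.mean_suppression
    row = {
        "step": step,
        "mean_T": mt,
        "mean_S": ms,
        "delta_T": math.nan if prev_row is None else mt - prev_row["mean_T"],
        "delta_S": math.nan if prev_row is None else ms - prev_row["mean_S"],
        "ts_corr": weighted_pearson(pop.tolerance, pop.suppression, pop.density),
    }
    return row


def run_sfm(
    pop: Population,
    params: SFMParams,
    steps: int = 200,
    extinction_floor: float = EXTINCTION_FLOOR,
    preset: str | None = None,
) -> Trajectory:
    """Iterate a population for ``steps`` updates, recording each state.

    The returned trajectory has ``steps + 1`` rows including the initial
    state (``steps = 0`` records the initial state only).
    """
    rows = [_record(0, pop, None)]
    dens = np.empty((steps + 1, pop.k))
    dens[0] = pop.density
    cur = pop
    for t in range(1, steps + 1):
        cur = step_sfm(cur, params, extinction_floor)
        rows.append(_record(t, cur, rows[-1]))
        dens[t] = cur.density
    return Trajectory(pd.DataFrame(rows), dens, pop, params, preset=preset)


def equilibrate(
    pop: Population,
    params: SFMParams,
    tol: float = 1e-9,
    max_steps: int = 200,
) -> tuple[Population, int]:
    """Iterate until max per-genotype |dD| < ``tol`` or the step cap."""
    cur = pop
    for t in range(1, max_steps + 1):
        nxt = step_sfm(cur, params)
        if float(np.max(np.abs(nxt.density - cur.density))) < tol:
            return nxt, t
        cur = nxt
    return cur, max_steps


# ---------------------------------------------------------------------------
# selection gradients
# ---------------------------------------------------------------------------


def selection_gradient(
    pop: Population, params: SFMParams, genotype_index: int | None = None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Analytic partials of effective survival w.r.t. own traits.

    Returns ``(dP_hat/dT_i, dP_hat/dS_i)`` holding densities fixed.  The
    population means T_bar and S_bar are functions of the focal trait
    (with weight D_i), so a genotype's traits act both directly and
    through the field:

      dP/dT_i = P_i s_i B_i - P_i s_i (1 - T_i) dB/dT_i,
                dB/dT_i = P_bar (1-beta) (Q_i / n) D_i
      dP/dS_i = -P_i (1 - T_i) [ (ds_i/dS_i) B_i + s_i dB/dS_i ]

    with Q_i = (n-1) s_i + alpha rho S_i,
    ds_i/dS_i = alpha rho phi D_i / (D_i (phi - 1) + 1) and
    dB/dS_i = -P_bar (1-beta) (1 - T_bar)/n * ((n-1) ds_i/dS_i + alpha rho).
    Only a scalar ``phi`` is supported.
    """
    if params.phi_matrix is not None:
        raise NotImplementedError("analytic gradients require a scalar phi")
    D = pop.density
    S = pop.suppression
    T = pop.tolerance
    P = pop.max_survival
    ar = params.alpharho
    n = params.n
    phi = params.phi
    beta = params.beta
    p_bar = pop.mean_survival
    t_bar = pop.mean_tolerance

    s_hat = assorted_suppression(pop, params)
    B = initiator_term(pop, params, felt_suppression=s_hat)
    denom = D * (phi - 1.0) + 1.0
    ds_dS = ar * phi * D / denom
    q = (n - 1.0) * s_hat + ar * S
    dB_dT = p_bar * (1.0 - beta) * (q / n) * D
    dB_dS = -p_bar * (1.0 - beta) * (1.0 - t_bar) / n * ((n - 1.0) * ds_dS + ar)

    grad_T = P * s_hat * B - P * s_hat * (1.0 - T) * dB_dT
    grad_S = -P * (1.0 - T) * (ds_dS * B + s_hat * dB_dS)
    if genotype_index is not None:
        return float(grad_T[genotype_index]), float(grad_S[genotype_index])
    return grad_T, grad_S


# ---------------------------------------------------------------------------
# threshold densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold density of a genotype's suppression fitness effect.

    ``formula`` is the closed form evaluated with the initiator terms
    frozen at the supplied population state,

        D_th = (alpha rho B_i S_bar - E(sB)) / ((phi - 1)(E(sB) - alpha rho S_i B_i))

    where ``E(sB) = sum_j D_j s_hat_j B_j``; ``scan`` is an independent
    numerically located sign change of the self-consistent differential
    ``s_hat_i(D) B_i(D) - E(sB)(D)`` as the focal density is varied (nan
    when no sign change exists in (0, 1)).
    """

    formula: float
    scan: float
    expectation_sB: float


def _suppression_differential(
    genotype_index: int, pop: Population, params: SFMParams, d: float
) -> float:
    """s_hat_i B_i - E(s_hat B) with the focal genotype at density d."""
    D = pop.density.copy()
    others = 1.0 - D[genotype_index]
    if others <= 0:
        raise ValueError("focal genotype is the whole population; no density to vary")
    scale = (1.0 - d) / others
    D *= scale
    D[genotype_index] = d
    p = pop.with_density(D / D.sum())
    s_hat = assorted_suppression(p, params)
    B = initiator_term(p, params, felt_suppression=s_hat)
    E = float(p.density @ (s_hat * B))
    return float(s_hat[genotype_index] * B[genotype_index]) - E


def threshold_density(
    genotype_index: int,
    pop: Population,
    params: SFMParams,
    scan_points: int = 10_000,
    refine_tol: float = 1e-6,
) -> ThresholdResult:
    """Threshold density for the focal genotype (requires phi != 1).

    Below the threshold a stronger-than-average suppressor gains from its
    suppression and a weaker-than-average one loses; above it the signs
    flip, driving the bistable positive-feedback dynamics of assorted
    populations.  Returns both the frozen-coefficient closed form and a
    brute-force scan oracle (sign change located on ``scan_points``
    evenly spaced densities, bisected to ``refine_tol``).
    """
    if params.phi_matrix is not None:
        raise NotImplementedError("threshold density requires a scalar phi")
    if params.phi == 1.0:
        raise ThresholdUndefinedError(
            "phi_ii = 1: no kin assortativity, the suppression fitness "
            "effect has no sign change"
        )
    phi = params.phi
    ar = params.alpharho
    s_hat = assorted_suppression(pop, params)
    B = initiator_term(pop, params, felt_suppression=s_hat)
    E = float(pop.density @ (s_hat * B))
    b_i = float(B[genotype_index])
    s_i = float(pop.suppression[genotype_index])
    s_bar = pop.mean_suppression
    denom = (phi - 1.0) * (E - ar * s_i * b_i)
    formula = math.nan if denom == 0 else (ar * b_i * s_bar - E) / denom

    # brute-force oracle on the self-consistent differential; thresholds
    # are characteristically tiny, so the even grid is augmented with
    # log-spaced points below its first node
    lin = np.linspace(0.0, 1.0, scan_points + 2)[1:-1]
    grid = np.unique(np.concatenate([np.geomspace(1e-9, lin[0], 200), lin]))
    vals = np.array(
        [_suppression_differential(genotype_index, pop, params, d) for d in grid]
    )
    scan = math.nan
    vals[np.abs(vals) < 1e-13] = 0.0  # degenerate differentials are noise, not crossings
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size:
        lo, hi = float(grid[flips[0]]), float(grid[flips[0] + 1])
        flo = vals[flips[0]]
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            fmid = _suppression_differential(genotype_index, pop, params, mid)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        scan = 0.5 * (lo + hi)
    return ThresholdResult(formula=formula, scan=scan, expectation_sB=E)


# ---------------------------------------------------------------------------
# invasion analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InvasionResult:
    outcome: str  # "invades" | "repelled" | "neutral"
    invader_density: np.ndarray  # per-step density of the invader
    steps_run: int


def invasion_test(
    resident: Population,
    params: SFMParams,
    invader_tolerance: float,
    invader_suppression: float,
    intro_density: float,
    steps: int = 200,
    growth_factor: float = 2.0,
    invader_max_survival: float | None = None,
    extinction_floor: float = EXTINCTION_FLOOR,
) -> InvasionResult:
    """Introduce a rare strategy into a resident population and classify.

    The invader is appended at ``intro_density`` (residents rescaled by
    ``1 - intro_density``) and the system run forward.  The invasion
    succeeds if the invader's density grows past ``growth_factor`` times
    its introduction density within ``steps``; it is repelled if the
    density shrinks symmetrically (below ``intro_density /
    growth_factor``) or falls below the extinction floor; otherwise the
    outcome is neutral.
    """
    if not 0.0 < intro_density < 1.0:
        raise ValueError("intro_density must lie in (0, 1)")
    pmax = (
        float(np.mean(resident.max_survival))
        if invader_max_survival is None
        else invader_max_survival
    )
    T = np.append(resident.tolerance, invader_tolerance)
    S = np.append(resident.suppression, invader_suppression)
    P = np.append(resident.max_survival, pmax)
    D = np.append(resident.density * (1.0 - intro_density), intro_density)
    pop = Population(T, S, P, D / D.sum())
    inv = pop.k - 1
    history = [intro_density]
    outcome = "neutral"
    t = 0
    for t in range(1, steps + 1):
        pop = step_sfm(pop, params, extinction_floor)
        d = float(pop.density[inv])
        history.append(d)
        if d >= growth_factor * intro_density:
            outcome = "invades"
            break
        if d <= extinction_floor or d <= intro_density / growth_factor:
            outcome = "repelled"
            break
    return InvasionResult(outcome, np.asarray(history), t)


# ---------------------------------------------------------------------------
# strategy sweeps
# ---------------------------------------------------------------------------


def ess_sweep(
    max_tolerances: np.ndarray,
    betas: np.ndarray,
    phi: float = 10.0,
    max_survival: float = 0.8,
    alpharho: float = 1.0,
    n: int = 8,
    levels: int = 13,
    steps: int = 200,
    neutral_tol: float = 1e-9,
) -> pd.DataFrame:
    """Dominant-strategy map over competition intensity and replacement.

    For each (max tolerance, beta) cell a ``levels x levels`` grid
    population is run to (near-)equilibrium; the cell is labelled
    ``"defection"`` when mean suppression rises from its starting value
    (escalation favoured), ``"cooperation"`` when it falls, ``"neutral"``
    otherwise.  The tolerance axis of the trait grid is scaled
    proportionally with the maximum (the grid spans ``[max_T/4, max_T]``,
    mirroring the canonical 0.2-0.8 span at ``max_T = 0.8``); the
    suppression axis keeps the canonical span.
    """
    rows = []
    for t_max in np.atleast_1d(max_tolerances):
        pop = Population.trait_grid(
            levels,
            max_survival=max_survival,
            tol_min=t_max / 4.0,
            tol_max=t_max,
        )
        for b in np.atleast_1d(betas):
            params = SFMParams(alpha=1.0, rho=alpharho, beta=float(b), n=n, phi=phi)
            traj = run_sfm(pop, params, steps=steps)
            change = float(traj.final["mean_S"] - traj.initial["mean_S"])
            if change > neutral_tol:
                label = "defection"
            elif change < -neutral_tol:
                label = "cooperation"
            else:
                label = "neutral"
            rows.append(
                {
                    "max_T": float(t_max),
                    "beta": float(b),
                    "phi": phi,
                    "mean_S_change": change,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)
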