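"""Lattice agent-based model of suppression among sessile competitors.

A 100 x 100 wrapping lattice holds at most one agent per cell.  Each
agent belongs to one of the genotypes of a T x S trait grid and carries
an age; traits ramp linearly with age up to a maturity age.  Survival
mirrors the field model locally: an agent survives with probability
``P - P * s_local * (1 - T_eff)`` where ``s_local`` is the mean
age-effective suppression over its 8 Moore neighbours (empty cells
counting zero).  Kin assortativity, replacement and maturity are *not*
parameters here — they emerge from dispersal mode, fecundity and the
age structure, and are measured (``rho_hat``, ``alpha_hat``,
``beta_hat``, ``phi_hat``) for comparison with the mean-field model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .stats import exact_binomial, weighted_pearson

__all__ = [
    "SpeciesParams",
    "Lattice",
    "EmergentParams",
    "ABMResult",
    "PosthocResult",
    "DISPERSAL_MODES",
    "init_lattice",
    "step_lattice",
    "run_abm",
    "posthoc_suppression_runs",
    "measure_emergent",
]

DISPERSAL_MODES = {
    "random": _kernels.MODE_RANDOM,
    "limited": _kernels.MODE_LIMITED,
    "overdispersed": _kernels.MODE_OVERDISPERSED,
}


@dataclass(frozen=True)
class SpeciesParams:
    """Species-wide constants of the lattice model.

    Defaults: maximum survival 0.8 (matching the field-model default),
    fecundity 4 offspring per fully mature agent per step, maturity at 25
    steps with linear trait ramps — calibrated so the emergent
    replacement rate and kin-assortativity odds ratio of the lattice runs
    land in the ranges the field model is compared against.  The three ``age_on_*`` flags switch
    the age ramp per trait; :meth:`with_age_effects` toggles all three.
    """

    max_survival: float = 0.8
    fecundity: int = 4
    maturity_age: int = 25
    age_on_T: bool = True
    age_on_S: bool = True
    age_on_F: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_survival <= 1.0:
            raise ValueError("max_survival must lie in [0, 1]")
        if self.fecundity < 0:
            raise ValueError("fecundity must be >= 0")
        if self.maturity_age < 1:
            raise ValueError("maturity_age must be >= 1")

    def with_age_effects(self, on: bool) -> "SpeciesParams":
        return replace(self, age_on_T=on, age_on_S=on, age_on_F=on)


@dataclass
class Lattice:
    """Lattice state: genotype grid (-1 empty), age grid, and the trait
    vectors indexed by genotype id."""

    genotype: np.ndarray
    age: np.ndarray
    tolerance: np.ndarray
    suppression: np.ndarray

    @property
    def side(self) -> int:
        return self.genotype.shape[0]

    @property
    def n_agents(self) -> int:
        return int((self.genotype >= 0).sum())

    @property
    def occupancy(self) -> float:
        return self.n_agents / self.genotype.size

    @property
    def k(self) -> int:
        return self.tolerance.size

    def counts(self) -> np.ndarray:
        occ = self.genotype[self.genotype >= 0]
        return np.bincount(occ, minlength=self.k).astype(np.int64)

    def copy(self) -> "Lattice":
        return Lattice(
            self.genotype.copy(), self.age.copy(), self.tolerance, self.suppression
        )

    def to_csv(self, path) -> None:
        """Write the grid as CSV rows (x, y, genotype, age) for occupied cells."""
        xs, ys = np.nonzero(self.genotype >= 0)
        pd.DataFrame(
            {"x": xs, "y": ys, "genotype": self.genotype[xs, ys], "age": self.age[xs, ys]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class EmergentParams:
    """Emergent counterparts of the field-model parameters.

    ``rho_hat``: occupancy fraction; ``alpha_hat``: mean age-ramp
    multiplier over agents; ``beta_hat``: fraction of death-vacated cells
    re-occupied by the next state (nan when no deaths occurred);
    ``phi_hat``: odds ratio of same-genotype Moore-neighbour pairs versus
    random mixing (nan when degenerate, e.g. a single genotype).
    """

    rho_hat: float
    alpha_hat: float
    beta_hat: float
    phi_hat: float


def default_trait_grid(levels: int = 13, lo: float = 0.2, hi: float = 0.8):
    """The canonical levels x levels T x S genotype grid."""
    t = np.linspace(lo, hi, levels)
    TT, SS = np.meshgrid(t, t, indexing="ij")
    return TT.ravel().copy(), SS.ravel().copy()


def phi_odds_ratio(counts: np.ndarray, same: int, total: int) -> float:
    """Kin-assortativity odds ratio from neighbour-pair counts.

    Compares the odds of a both-occupied Moore pair sharing a genotype
    against the random-mixing expectation ``p_rand = sum (D_i)^2``.
    """
    n = counts.sum()
    if total == 0 or n == 0:
        return math.nan
    d = counts / n
    p_rand = float(d @ d)
    p_obs = same / total
    if p_rand >= 1.0 or p_obs >= 1.0 or p_rand <= 0.0:
        return math.nan
    return (p_obs / (1.0 - p_obs)) / (p_rand / (1.0 - p_rand))


def measure_emergent(
    lattice: Lattice,
    species: SpeciesParams,
    deaths_mask: np.ndarray | None = None,
) -> EmergentParams:
    """Emergent parameters of one lattice state.

    ``beta_hat`` needs the death locations of the update that produced
    this state (``deaths_mask``); without it, or when no deaths occurred,
    it is reported missing (nan), never zero.
    """
    g = lattice.genotype
    occ = g >= 0
    n = int(occ.sum())
    rho = n / g.size
    if n:
        mult = np.minimum(lattice.age[occ] / species.maturity_age, 1.0)
        alpha = float(mult.mean())
    else:
        alpha = 0.0
    same, total = _kernels.neighbour_pair_counts(np.ascontiguousarray(g))
    phi = phi_odds_ratio(lattice.counts(), same, total)
    if deaths_mask is None or not deaths_mask.any():
        beta = math.nan
    else:
        beta = float(occ[deaths_mask].mean())
    return EmergentParams(rho, alpha, beta, phi)


def init_lattice(
    tolerance: np.ndarray,
    suppression: np.ndarray,
    occupancy: float = 0.2,
    side: int = 100,
    seed: int = 0,
) -> Lattice:
    """Seed a lattice uniformly at random.

    Each cell is occupied independently with probability ``occupancy``;
    occupants draw a genotype uniformly over the grid and start at age 1.
    Warns (does not fail) if the expected agent count cannot cover every
    genotype.
    """
    if not 0.0 < occupancy <= 1.0:
        raise ValueError("occupancy must lie in (0, 1]")
    T = np.asarray(tolerance, dtype=float)
    S = np.asarray(suppression, dtype=float)
    if T.shape != S.shape or T.ndim != 1:
        raise ValueError("trait vectors must be equal-length 1-D arrays")
    k = T.size
    if occupancy * side * side < k:
        import warnings

        warnings.warn(
            f"expected agent count {occupancy * side * side:.0f} below genotype "
            f"richness {k}; some genotypes will start absent",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    occupied = rng.random((side, side)) < occupancy
    gen = np.full((side, side), _kernels.EMPTY, dtype=np.int64)
    gen[occupied] = rng.integers(0, k, size=int(occupied.sum()))
    age = np.zeros((side, side), dtype=np.int64)
    age[occupied] = 1
    return Lattice(gen, age, T, S)


def step_lattice(
    lattice: Lattice,
    species: SpeciesParams,
    dispersal: str = "random",
    seed: int = 0,
) -> tuple["Lattice", dict]:
    """One synchronous update (survival -> reproduction -> aging).

    Returns the new lattice and a dict with the update's death and refill
    counts.  Convenience wrapper over the compiled multi-step kernel.
    """
    new = lattice.copy()
    out = _kernels.simulate(
        new.genotype,
        new.age,
        new.tolerance,
        new.suppression,
        species.max_survival,
        species.fecundity,
        species.maturity_age,
        species.age_on_T,
        species.age_on_S,
        species.age_on_F,
        DISPERSAL_MODES[dispersal],
        1,
        int(seed),
    )
    _, _, _, _, _, deaths, refilled, _ = out
    return new, {"deaths": int(deaths[0]), "refilled": int(refilled[0])}


@dataclass
class ABMResult:
    """One replicate: per-step trajectory plus run metadata.

    ``trajectory`` columns: step, n (agents), abundance-weighted mean_T /
    mean_S, their step changes, T-S correlation, and the emergent
    parameter series rho_hat / alpha_hat / beta_hat / phi_hat.
    """

    trajectory: pd.DataFrame
    seed: int
    dispersal: str
    extinct: bool
    final: Lattice

    def to_csv(self, path) -> None:
        self.trajectory.to_csv(path, index=False, float_format="%.10g")


def _replicate_seeds(seed: int, replicates: int) -> list[tuple[int, int]]:
    """Independent (init, simulate) seeds per replicate.

    Streams derive from (master seed, replicate index) so changing the
    replicate count never perturbs earlier replicates.
    """
    out = []
    for rep in range(replicates):
        a, b = np.random.SeedSequence((seed, rep)).generate_state(2)
        out.append((int(a % 2**31), int(b % 2**31)))
    return out


def _trajectory_frame(
    T, S, maturity, counts, occupied, alpha_mean, pairs_same, pairs_total, deaths, refilled, steps_done
) -> pd.DataFrame:
    rows = []
    k = T.size
    nrec = steps_done + 1
    prev_t = prev_s = math.nan
    for t in range(nrec):
        c = counts[t]
        n = occupied[t]
        if n > 0:
            w = c / n
            mt = float(w @ T)
            ms = float(w @ S)
            corr = weighted_pearson(T, S, c) if n else math.nan
        else:
            mt = ms = corr = math.nan
        phi = phi_odds_ratio(c, int(pairs_same[t]), int(pairs_total[t]))
        if t == 0:
            beta = math.nan
        else:
            beta = refilled[t - 1] / deaths[t - 1] if deaths[t - 1] > 0 else math.nan
        rows.append(
            {
                "step": t,
                "n": int(n),
                "mean_T": mt,
                "mean_S": ms,
                "delta_T": mt - prev_t if t else math.nan,
                "delta_S": ms - prev_s if t else math.nan,
                "ts_corr": corr,
                "rho_hat": math.nan,  # filled by the caller (depends on lattice size)
                "alpha_hat": float(alpha_mean[t]),
                "beta_hat": beta,
                "phi_hat": phi,
            }
        )
        prev_t, prev_s = mt, ms
    return pd.DataFrame(rows)


def run_abm(
    tolerance: np.ndarray | None = None,
    suppression: np.ndarray | None = None,
    species: SpeciesParams | None = None,
    dispersal: str = "random",
    age_effects: bool = True,
    steps: int = 200,
    replicates: int = 1,
    seed: int = 0,
    occupancy: float = 0.2,
    side: int = 100,
) -> list[ABMResult]:
    """Run replicate lattice simulations.

    Defaults to the canonical 13 x 13 trait grid (169 genotypes) on a
    100 x 100 lattice at 20% initial occupancy.  Each replicate gets its
    own derived RNG streams; identical seeds give bit-identical
    trajectories.
    """
    if dispersal not in DISPERSAL_MODES:
        raise ValueError(f"unknown dispersal mode {dispersal!r}")
    if tolerance is None or suppression is None:
        tolerance, suppression = default_trait_grid()
    species = (species or SpeciesParams()).with_age_effects(age_effects)
    results = []
    for init_seed, sim_seed in _replicate_seeds(seed, replicates):
        lat = init_lattice(tolerance, suppression, occupancy, side, init_seed)
        out = _kernels.simulate(
            lat.genotype,
            lat.age,
            lat.tolerance,
            lat.suppression,
            species.max_survival,
            species.fecundity,
            species.maturity_age,
            species.age_on_T,
            species.age_on_S,
            species.age_on_F,
            DISPERSAL_MODES[dispersal],
            steps,
            sim_seed,
        )
        counts, occupied, alpha_mean, pairs_same, pairs_total, deaths, refilled, steps_done = out
        frame = _trajectory_frame(
            lat.tolerance,
            lat.suppression,
            species.maturity_age,
            counts,
            occupied,
            alpha_mean,
            pairs_same,
            pairs_total,
            deaths,
            refilled,
            steps_done,
        )
        frame["rho_hat"] = frame["n"] / (side * side)
        results.append(
            ABMResult(
                trajectory=frame,
                seed=sim_seed,
                dispersal=dispersal,
                extinct=steps_done < steps,
                final=lat,
            )
        )
    return results


@dataclass
class PosthocResult:
    """Aggregate of suppression-only replicate runs at a fixed tolerance.

    ``fraction_increased``: share of replicates whose abundance-weighted
    mean suppression ended above its starting value;
    ``mean_pct_change``: mean per-replicate percent change of mean S;
    ``p_value``: two-sided exact binomial test of the increase fraction
    against 0.5 (nan when mean S never moved in any replicate).
    """

    fraction_increased: float
    mean_pct_change: float
    p_value: float
    increased: np.ndarray
    pct_change: np.ndarray
    n_extinct: int

    @property
    def replicates(self) -> int:
        return self.increased.size


def posthoc_suppression_runs(
    fixed_tolerance: float = 0.8,
    steps: int = 500,
    replicates: int = 200,
    seed: int = 0,
    levels: int = 13,
    s_min: float = 0.2,
    s_max: float = 0.8,
    species: SpeciesParams | None = None,
    dispersal: str = "random",
    occupancy: float = 0.2,
    side: int = 100,
) -> PosthocResult:
    """Replicated runs in which S varies but T does not.

    Every genotype shares ``fixed_tolerance``; suppression spans
    ``levels`` values in [s_min, s_max]; age effects on, random dispersal
    by default.  Used to resolve whether the fitness effect of
    suppression is exactly zero or merely close to zero under
    neutral-assortativity conditions.
    """
    S = np.linspace(s_min, s_max, levels)
    T = np.full(levels, fixed_tolerance)
    results = run_abm(
        T,
        S,
        species=species,
        dispersal=dispersal,
        age_effects=True,
        steps=steps,
        replicates=replicates,
        seed=seed,
        occupancy=occupancy,
        side=side,
    )
    increased = np.zeros(replicates, dtype=bool)
    pct = np.full(replicates, np.nan)
    n_extinct = 0
    for i, res in enumerate(results):
        tr = res.trajectory
        if res.extinct:
            n_extinct += 1
        first = tr["mean_S"].iloc[0]
        last = tr["mean_S"].dropna().iloc[-1]
        increased[i] = bool(last > first + 1e-9)
        pct[i] = 100.0 * (last - first) / first
    if np.all(np.abs(pct) < 1e-7):
        p = math.nan
    else:
        p = exact_binomial(int(increased.sum()), replicates, 0.5)
    return PosthocResult(
        fraction_increased=float(increased.mean()),
        mean_pct_change=float(np.nanmean(pct)),
        p_value=p,
        increased=increased,
        pct_change=pct,
        n_extinct=n_extinct,
    )
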