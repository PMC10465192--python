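"""Closed-form suppression-field terms.

The model pictures interference competition in a large community as a
*field*: every individual contributes suppression in proportion to its
suppression trait ``S``, and every individual's survival is reduced in
proportion to the field strength it experiences and its own tolerance
trait ``T``.  Survival of genotype *i* is

    P_hat_i = P_i - P_i * s_hat_i * B_i * (1 - T_i)

where ``s_hat_i`` is the suppression felt by genotype *i* (a density- and
kin-weighted mean of the population's suppression abilities), and ``B_i``
is the *initiator effect*: the proportionate relief from future
competition enjoyed by a genotype that suppresses its neighbours
(``B -> 0`` strong relief, ``B -> 1`` none).

Two departures from the uniform mean field are modelled:

* kin assortativity ``phi_ii`` — an odds ratio biasing how often a
  genotype encounters itself (dispersal limitation gives ``phi_ii > 1``,
  over-dispersal / kin avoidance gives ``phi_ii < 1``);
* the initiator effect, controlled by the replacement rate ``beta`` of
  killed competitors (``beta = 1``: instant replacement, no initiator
  benefit) and the neighbourhood size ``n``.

All traits and densities are dimensionless fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DensityError, FieldRangeError

__all__ = [
    "Genotype",
    "Population",
    "SFMParams",
    "PopulationSummary",
    "FieldTerms",
    "mean_field_suppression",
    "assorted_suppression",
    "initiator_term",
    "effective_survival",
]

#: absolute tolerance used for simplex and range checks
_ATOL = 1e-12


@dataclass(frozen=True)
class Genotype:
    """One clonal genotype: intrinsic traits plus its current density.

    Parameters
    ----------
    tolerance
        Ability to withstand suppression, ``T_i`` in [0, 1]; survival loss
        scales with ``1 - T_i``.
    suppression
        Ability to harm competitors, ``S_i`` in [0, 1].
    max_survival
        Competition-free survival probability ``P_i`` in [0, 1].
    density
        Relative density ``D_i``; across a population densities sum to 1.
    """

    tolerance: float
    suppression: float
    max_survival: float = 0.8
    density: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tolerance", "suppression", "max_survival", "density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"Genotype.{name}={v!r} outside [0, 1]")


class Population:
    """A fixed set of genotypes with evolving relative densities.

    Stores the trait vectors as numpy arrays; only densities change over
    time (reproduction is clonal, traits are constants of a genotype).
    """

    __slots__ = ("tolerance", "suppression", "max_survival", "density")

    def __init__(
        self,
        tolerance: np.ndarray | Sequence[float],
        suppression: np.ndarray | Sequence[float],
        max_survival: np.ndarray | Sequence[float] | float = 0.8,
        density: np.ndarray | Sequence[float] | None = None,
    ):
        T = np.asarray(tolerance, dtype=float)
        S = np.asarray(suppression, dtype=float)
        if T.shape != S.shape or T.ndim != 1 or T.size == 0:
            raise ValueError("tolerance and suppression must be equal-length 1-D vectors")
        P = np.broadcast_to(np.asarray(max_survival, dtype=float), T.shape).copy()
        if density is None:
            D = np.full(T.shape, 1.0 / T.size)
        else:
            D = np.asarray(density, dtype=float).copy()
        if D.shape != T.shape:
            raise ValueError("density vector length does not match traits")
        for name, v in (("tolerance", T), ("suppression", S), ("max_survival", P)):
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} values outside [0, 1]")
        if np.any(D < 0):
            raise DensityError("negative densities")
        dev = abs(float(D.sum()) - 1.0)
        if dev > 1e-9:
            raise DensityError(
                f"densities must sum to 1; got sum={float(D.sum())!r} (deviation {dev:.3e})"
            )
        self.tolerance = T
        self.suppression = S
        self.max_survival = P
        self.density = D

    # -- constructors -------------------------------------------------

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[Genotype]) -> "Population":
        return cls(
            [g.tolerance for g in genotypes],
            [g.suppression for g in genotypes],
            [g.max_survival for g in genotypes],
            [g.density for g in genotypes],
        )

    @classmethod
    def trait_grid(
        cls,
        levels: int = 13,
        trait_min: float = 0.2,
        trait_max: float = 0.8,
        max_survival: float | Sequence[float] = 0.8,
        tol_min: float | None = None,
        tol_max: float | None = None,
    ) -> "Population":
        """Full factorial T x S grid at equal starting densities.

        ``levels`` values of each trait spanning ``[trait_min, trait_max]``
        (richness 16, 169 or 10201 for levels 4, 13 or 101).  The tolerance
        axis range may be overridden independently (``tol_min``/``tol_max``)
        for sweeps over the maximum allowed tolerance.  ``max_survival``
        may be a sequence of P levels, crossed with the trait grid.
        """
        s_levels = np.linspace(trait_min, trait_max, levels)
        t_levels = np.linspace(
            trait_min if tol_min is None else tol_min,
            trait_max if tol_max is None else tol_max,
            levels,
        )
        TT, SS = np.meshgrid(t_levels, s_levels, indexing="ij")
        T, S = TT.ravel(), SS.ravel()
        p_levels = np.atleast_1d(np.asarray(max_survival, dtype=float))
        T = np.repeat(T, p_levels.size)
        S = np.repeat(S, p_levels.size)
        P = np.tile(p_levels, levels * levels)
        return cls(T, S, P)

    # -- summaries ----------------------------------------------------

    @property
    def k(self) -> int:
        return self.tolerance.size

    @property
    def mean_tolerance(self) -> float:
        return float(self.density @ self.tolerance)

    @property
    def mean_suppression(self) -> float:
        return float(self.density @ self.suppression)

    @property
    def mean_survival(self) -> float:
        return float(self.density @ self.max_survival)

    def summary(self) -> "PopulationSummary":
        return PopulationSummary(
            mean_suppression=self.mean_suppression,
            mean_tolerance=self.mean_tolerance,
            mean_survival=self.mean_survival,
        )

    def with_density(self, density: np.ndarray) -> "Population":
        new = Population.__new__(Population)
        new.tolerance = self.tolerance
        new.suppression = self.suppression
        new.max_survival = self.max_survival
        D = np.asarray(density, dtype=float)
        if D.shape != self.tolerance.shape or np.any(D < 0):
            raise DensityError("invalid replacement density vector")
        dev = abs(float(D.sum()) - 1.0)
        if dev > 1e-9:
            raise DensityError(f"densities must sum to 1 (deviation {dev:.3e})")
        new.density = D
        return new

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Population(k={self.k}, mean_T={self.mean_tolerance:.3f}, "
            f"mean_S={self.mean_suppression:.3f})"
        )


@dataclass(frozen=True)
class PopulationSummary:
    """Density-weighted trait means S-bar, T-bar, P-bar."""

    mean_suppression: float
    mean_tolerance: float
    mean_survival: float


@dataclass(frozen=True)
class SFMParams:
    """Community/system parameters of the suppression-field model.

    Parameters
    ----------
    alpha
        Effective maturity of the population (age effects), in [0, 1];
        1 means most individuals express their full traits.
    rho
        Total relative population density in [0, 1].
    beta
        Replacement rate of killed competitors in [0, 1]; 1 means a killed
        competitor is instantly replaced by an equivalent one, which
        removes any initiator benefit.
    n
        Neighbourhood size (number of interacting competitors), >= 1.
    phi
        Self-encounter odds ratio ``phi_ii`` >= 0 (kin assortativity);
        1 is neutral random mixing.
    phi_matrix
        Optional full k x k odds-ratio matrix ``phi_ij``; when given it
        overrides ``phi`` and the general association form is used.
    """

    alpha: float = 1.0
    rho: float = 1.0
    beta: float = 1.0
    n: int = 8
    phi: float = 1.0
    phi_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("alpha", "rho", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SFMParams.{name}={v!r} outside [0, 1]")
        if self.n < 1:
            raise ValueError(f"SFMParams.n={self.n!r} must be >= 1")
        if self.phi < 0:
            raise ValueError(f"SFMParams.phi={self.phi!r} must be >= 0")
        if self.phi_matrix is not None:
            m = np.asarray(self.phi_matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1] or np.any(m < 0):
                raise ValueError("phi_matrix must be a square non-negative matrix")
            object.__setattr__(self, "phi_matrix", m)

    @property
    def alpharho(self) -> float:
        """The product alpha*rho, the overall intensity scaling of the field."""
        return self.alpha * self.rho

    def replace(self, **kw) -> "SFMParams":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class FieldTerms:
    """All intermediate terms of the assembled model, per genotype."""

    felt_suppression: np.ndarray  # s_hat_i
    initiator: np.ndarray  # B_i
    kin_ratio: np.ndarray  # A_i = s_hat_i / (alpha rho S-bar); nan if undefined
    competition_cost: np.ndarray  # C_i = P_i s_hat_i B_i (1 - T_i)
    effective_survival: np.ndarray  # P_hat_i
    effective_tolerance: np.ndarray  # T_hat_i (= T_i; age adjustment lives in the ABM)


def _check_simplex(pop: Population) -> None:
    dev = abs(float(pop.density.sum()) - 1.0)
    if dev > 1e-9:
        raise DensityError(f"densities not normalized (deviation {dev:.3e})")


def mean_field_suppression(pop: Population, params: SFMParams) -> float:
    """Uniform suppression field: s_hat = alpha * rho * sum_j D_j S_j.

    The field felt by a typical individual when genotype encounters are
    proportional to density alone — identical for every genotype.
    """
    _check_simplex(pop)
    return params.alpharho * float(pop.density @ pop.suppression)


def assorted_suppression(
    pop: Population, params: SFMParams, genotype_index: int | None = None
) -> np.ndarray | float:
    """Kin-weighted suppression field ``s_hat_i`` per genotype.

    With a scalar self-encounter odds ratio ``phi_ii`` (off-diagonal odds
    unbiased), the field felt by genotype *i* is

        s_hat_i = alpha rho * (D_i S_i (phi - 1) + S_bar) / (D_i (phi - 1) + 1)

    which reduces to :func:`mean_field_suppression` at ``phi = 1`` and to
    ``alpha rho S_i`` as ``phi -> inf``.  If ``params.phi_matrix`` is
    supplied, the general association form is used instead:

        s_hat_i = alpha rho * sum_j [phi_ij / (D_j (phi_ij - 1) + 1)] D_j S_j

    Note the two forms differ for off-diagonal-one matrices except at
    ``phi = 1``: the scalar form renormalizes the encounter odds, the
    matrix form does not.  The scalar form is the normative one for a
    scalar ``phi_ii``.
    """
    _check_simplex(pop)
    D, S = pop.density, pop.suppression
    ar = params.alpharho
    if params.phi_matrix is not None:
        m = params.phi_matrix
        if m.shape[0] != pop.k:
            raise ValueError("phi_matrix size does not match population richness")
        denom = D[None, :] * (m - 1.0) + 1.0
        if np.any(denom <= 0):
            raise ValueError("phi matrix / density combination gives non-positive odds denominator")
        s_hat = ar * (m / denom * (D * S)[None, :]).sum(axis=1)
    else:
        phi = params.phi
        denom = D * (phi - 1.0) + 1.0
        if np.any(denom <= 0):
            bad = int(np.argmin(denom))
            raise ValueError(
                f"odds denominator D_i(phi-1)+1 <= 0 for genotype {bad} "
                f"(D={D[bad]!r}, phi={phi!r})"
            )
        s_bar = float(D @ S)
        s_hat = ar * (D * S * (phi - 1.0) + s_bar) / denom
    if genotype_index is not None:
        return float(s_hat[genotype_index])
    return s_hat


def initiator_term(
    pop: Population,
    params: SFMParams,
    felt_suppression: np.ndarray | None = None,
    genotype_index: int | None = None,
) -> np.ndarray | float:
    """Initiator-effect term ``B_i`` in [beta, 1].

        B_i = P_bar (1 - beta) (1 - (1/n) ((n-1) s_hat_i + alpha rho S_i)(1 - T_bar)) + beta

    ``B_i -> beta`` marks the strongest possible relief from future
    competition for a suppressor; ``beta = 1`` collapses the term to 1
    (killed competitors instantly replaced, no initiator benefit).  For
    in-range inputs ``B_i`` stays in [beta, 1]; if a parameter combination
    pushes it outside [0, 1] a :class:`FieldRangeError` is raised with
    diagnostics rather than clamping silently.
    """
    _check_simplex(pop)
    if felt_suppression is None:
        felt_suppression = assorted_suppression(pop, params)
    s_hat = np.asarray(felt_suppression, dtype=float)
    p_bar = pop.mean_survival
    t_bar = pop.mean_tolerance
    n = params.n
    q = (n - 1.0) * s_hat + params.alpharho * pop.suppression
    B = p_bar * (1.0 - params.beta) * (1.0 - q / n * (1.0 - t_bar)) + params.beta
    if np.any(B < -_ATOL) or np.any(B > 1.0 + _ATOL):
        bad = int(np.argmax(np.abs(B - 0.5)))
        raise FieldRangeError(
            f"initiator term outside [0, 1]: B[{bad}]={B[bad]!r} "
            f"(P_bar={p_bar}, T_bar={t_bar}, beta={params.beta}, n={n}, "
            f"s_hat={s_hat[bad]!r}, S_i={pop.suppression[bad]!r})"
        )
    if genotype_index is not None:
        return float(B[genotype_index])
    return B


def effective_survival(
    pop: Population, params: SFMParams, genotype_index: int | None = None
) -> tuple[np.ndarray | float, FieldTerms]:
    """Assembled model: effective survival P_hat_i and all field terms.

        P_hat_i = P_i - P_i * s_hat_i * B_i * (1 - T_i)

    Returns the per-genotype survival vector (or a scalar when
    ``genotype_index`` is given) together with a :class:`FieldTerms`
    record of every intermediate quantity.
    """
    s_hat = assorted_suppression(pop, params)
    B = initiator_term(pop, params, felt_suppression=s_hat)
    T = pop.tolerance
    P = pop.max_survival
    cost = P * s_hat * B * (1.0 - T)
    p_hat = P - cost
    if np.any(p_hat < -_ATOL) or np.any(p_hat > P + _ATOL):
        bad = int(np.argmin(p_hat))
        raise FieldRangeError(
            f"effective survival outside [0, P_i]: P_hat[{bad}]={p_hat[bad]!r}"
        )
    mean_field = params.alpharho * pop.mean_suppression
    with np.errstate(divide="ignore", invalid="ignore"):
        kin_ratio = np.where(mean_field > 0, s_hat / mean_field, np.nan)
    terms = FieldTerms(
        felt_suppression=s_hat,
        initiator=np.asarray(B, dtype=float),
        kin_ratio=kin_ratio,
        competition_cost=cost,
        effective_survival=p_hat,
        effective_tolerance=T.copy(),
    )
    if genotype_index is not None:
        return float(p_hat[genotype_index]), terms
    return p_hat, terms
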