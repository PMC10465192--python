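"""Run configuration, presets, orchestration and serialization.

A :class:`RunConfig` fully determines one experiment (field-model run,
lattice run, post-hoc design or game table).  Configurations round-trip
through YAML, unknown keys are a hard error, and every run writes a
manifest recording the exact configuration, its hash and the package
version, so outputs are reproducible byte for byte under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "PRESETS", "load_config", "write_config", "write_manifest", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """One experiment: model tier, parameters, grid, schedule and seed.

    Defaults follow the canonical study conditions: a 13 x 13 trait grid
    on [0.2, 0.8], maximum survival 0.8, 200 steps, neighbourhood 8,
    alpha = rho = 1.
    """

    tier: str = "sfm"  # sfm | abm | game
    experiment: str = "run"
    # field-model parameters
    alpha: float = 1.0
    rho: float = 1.0
    beta: float = 1.0
    n: int = 8
    phi: float | list = 1.0
    preset: str | None = None  # tuned (alpharho, beta) preset name
    # trait grid
    levels: int = 13
    trait_min: float = 0.2
    trait_max: float = 0.8
    max_survival: float | list = 0.8
    fix_T: float | None = None  # suppression-only design: all genotypes share T
    # lattice / species
    dispersal: str = "random"
    age_effects: bool = True
    fecundity: int = 4
    maturity_age: int = 25
    occupancy: float = 0.2
    side: int = 100
    # schedule
    steps: int = 200
    replicates: int = 1
    seed: int = 0
    outdir: str = "runs"

    def __post_init__(self) -> None:
        if self.tier not in ("sfm", "abm", "game"):
            raise ConfigError(f"tier={self.tier!r} not one of sfm/abm/game")
        if self.dispersal not in ("random", "limited", "overdispersed"):
            raise ConfigError(f"dispersal={self.dispersal!r} unknown")
        problems = []
        for name, lo, hi in (
            ("alpha", 0, 1),
            ("rho", 0, 1),
            ("beta", 0, 1),
            ("trait_min", 0, 1),
            ("trait_max", 0, 1),
            ("occupancy", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                problems.append(f"{name}={v!r} outside [{lo}, {hi}]")
        if self.n < 1:
            problems.append(f"n={self.n!r} must be >= 1")
        for p in np.atleast_1d(np.asarray(self.phi, dtype=float)):
            if p < 0:
                problems.append(f"phi={p!r} must be >= 0")
        if self.levels < 1:
            problems.append(f"levels={self.levels!r} must be >= 1")
        if self.steps < 0:
            problems.append(f"steps={self.steps!r} must be >= 0")
        if self.replicates < 1:
            problems.append(f"replicates={self.replicates!r} must be >= 1")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    # -- helpers ------------------------------------------------------

    def phi_values(self) -> list[float]:
        return [float(p) for p in np.atleast_1d(np.asarray(self.phi, dtype=float))]

    def sfm_params(self, phi: float):
        from .core import SFMParams
        from .dynamics import TUNED_PRESETS

        if self.preset is not None:
            p = TUNED_PRESETS[self.preset]
            return SFMParams(alpha=1.0, rho=p["alpharho"], beta=p["beta"], n=self.n, phi=phi)
        return SFMParams(alpha=self.alpha, rho=self.rho, beta=self.beta, n=self.n, phi=phi)

    def population(self):
        from .core import Population

        if self.fix_T is not None:
            S = np.linspace(self.trait_min, self.trait_max, self.levels)
            T = np.full(self.levels, self.fix_T)
            p = self.max_survival
            return Population(T, S, p if np.isscalar(p) else np.asarray(p))
        return Population.trait_grid(
            self.levels, self.trait_min, self.trait_max, self.max_survival
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=float)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML configuration; unknown keys are a hard error."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        warnings.warn(f"empty configuration {path}; using defaults", stacklevel=2)
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys {unknown}")
    return RunConfig(**data)


def write_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def write_manifest(config: RunConfig, outdir) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "preset": config.preset,
        "package": "supfield",
        "version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n")
    return path


# ---------------------------------------------------------------------------
# presets: every figure-level experiment runnable from one name
# ---------------------------------------------------------------------------

PRESETS: dict[str, RunConfig] = {
    # field-model trajectory panels: 169 genotypes, tuned with-age values,
    # one run per kin-assortativity level
    "fig3": RunConfig(
        tier="sfm", experiment="fig3", phi=[1.0, 10.0, 100.0, 1000.0],
        preset="tuned_age_fig", levels=13, steps=200,
    ),
    # kin-assortativity series at alpha = rho = 1
    "sfm-phi-series": RunConfig(
        tier="sfm", experiment="sfm-phi-series",
        phi=[0.0, 1.0, 10.0, 100.0, 1000.0, 10000.0], levels=13, steps=200,
    ),
    # heterogeneous maximum survival (10 P levels crossed with the grid)
    "sfm-hetP": RunConfig(
        tier="sfm", experiment="sfm-hetP", phi=[1.0, 100.0],
        max_survival=[0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95],
        levels=13, steps=200,
    ),
    # lattice runs per dispersal mode, age effects on
    "abm-random": RunConfig(tier="abm", experiment="abm-random", dispersal="random",
                            steps=200, replicates=5),
    "abm-limited": RunConfig(tier="abm", experiment="abm-limited", dispersal="limited",
                             steps=200, replicates=5),
    "abm-overdispersed": RunConfig(tier="abm", experiment="abm-overdispersed",
                                   dispersal="overdispersed", steps=200, replicates=5),
    # suppression-only designs (S varies, T fixed), age effects on
    "posthoc-T08": RunConfig(tier="abm", experiment="posthoc", fix_T=0.8,
                             steps=500, replicates=200),
    "posthoc-T02": RunConfig(tier="abm", experiment="posthoc", fix_T=0.2,
                             steps=500, replicates=200),
}


def run_experiment(config: RunConfig, outdir=None) -> dict:
    """Execute a configuration and write its output bundle.

    Writes one trajectory CSV per run/replicate, a summary JSON and a
    manifest JSON into ``outdir`` (defaults to
    ``<config.outdir>/<experiment>``).  Deterministic given the seed.
    Returns the summary dictionary.
    """
    outdir = Path(outdir if outdir is not None else Path(config.outdir) / config.experiment)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"experiment": config.experiment, "tier": config.tier, "runs": []}
    if config.tier == "sfm":
        from .dynamics import run_sfm

        pop = config.population()
        for phi in config.phi_values():
            params = config.sfm_params(phi)
            traj = run_sfm(pop, params, steps=config.steps, preset=config.preset)
            name = f"sfm_phi{phi:g}"
            traj.to_csv(outdir / f"{name}.csv")
            summary["runs"].append(
                {
                    "name": name,
                    "phi": phi,
                    "final_mean_T": float(traj.final["mean_T"]),
                    "final_mean_S": float(traj.final["mean_S"]),
                }
            )
    elif config.tier == "abm":
        from .abm import SpeciesParams, posthoc_suppression_runs, run_abm

        species = SpeciesParams(
            max_survival=float(np.atleast_1d(config.max_survival)[0]),
            fecundity=config.fecundity,
            maturity_age=config.maturity_age,
        )
        if config.fix_T is not None:
            res = posthoc_suppression_runs(
                fixed_tolerance=config.fix_T,
                steps=config.steps,
                replicates=config.replicates,
                seed=config.seed,
                levels=config.levels,
                s_min=config.trait_min,
                s_max=config.trait_max,
                species=species,
                dispersal=config.dispersal,
                occupancy=config.occupancy,
                side=config.side,
            )
            summary["posthoc"] = {
                "fixed_T": config.fix_T,
                "fraction_increased": res.fraction_increased,
                "mean_pct_change": res.mean_pct_change,
                "p_value": res.p_value,
                "replicates": res.replicates,
                "n_extinct": res.n_extinct,
            }
        else:
            results = run_abm(
                species=species,
                dispersal=config.dispersal,
                age_effects=config.age_effects,
                steps=config.steps,
                replicates=config.replicates,
                seed=config.seed,
                occupancy=config.occupancy,
                side=config.side,
            )
            for i, r in enumerate(results):
                name = f"abm_{config.dispersal}_rep{i}"
                r.to_csv(outdir / f"{name}.csv")
                tr = r.trajectory
                summary["runs"].append(
                    {
                        "name": name,
                        "extinct": r.extinct,
                        "final_mean_T": float(tr["mean_T"].dropna().iloc[-1]),
                        "final_mean_S": float(tr["mean_S"].dropna().iloc[-1]),
                        "final_phi_hat": float(tr["phi_hat"].dropna().iloc[-1])
                        if tr["phi_hat"].notna().any()
                        else None,
                    }
                )
    else:  # game
        from .game import simple_kill_game

        m = simple_kill_game(1.0, 0.4)
        summary["payoffs"] = asdict(m)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
    )
    write_manifest(config, outdir)
    return summary
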