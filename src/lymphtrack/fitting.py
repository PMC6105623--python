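"""Multi-objective calibration of motility models to observed track data.

A candidate parameter set is simulated, and its pooled speed distribution,
pooled turn-speed distribution and MSD slope are compared with the
observed population:

* ``ks_speed`` — KS D between simulated and observed instantaneous speeds;
* ``ks_turn`` — KS D between simulated and observed turn speeds;
* ``msd_slope_diff`` — |α_sim − α_obs|.

NSGA-II minimises the three objectives jointly and returns the Pareto
front of non-dominated trade-offs. Each solution carries a scalar quality
score Λ = max(ks_speed, ks_turn, msd_slope_diff / 2): the worst of the
three alignments with the slope difference mapped onto [0, 1] via α's
plausible two-unit range, so Λ is small only when *all* metrics align
("equally good alignments"). Λ and the overfitting rule below are this
package's definitions.

Overfitting control: a fraction of the observed tracks is held out before
fitting; after each generation the median Λ of the current front against
the holdout tracks is logged, and fitting stops early when that median has
not improved for ``patience`` consecutive generations.

Objective noise is tamed with common random numbers: every candidate in a
generation is simulated with the same seed, so ranking within a
generation compares like with like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .metrics import MetricError, MetricsConfig, instantaneous_speeds, ks_two_sample, msd_curve, turn_speeds
from .models import MotilityModel, model_from_vector, model_to_vector, param_space
from .nsga2 import fast_non_dominated_sort, nsga2
from .simulate import SimulationConfig, simulate
from .tracks import TrackSet

__all__ = [
    "ObjectiveScores",
    "ParetoSolution",
    "FitConfig",
    "FitLog",
    "TargetSummary",
    "evaluate_objectives",
    "lambda_score",
    "nsga2_fit",
    "detect_overfitting",
]

#: Objectives assigned to a candidate whose simulation yields no usable tracks.
INFEASIBLE = (1.0, 1.0, 4.0)


@dataclass(frozen=True)
class ObjectiveScores:
    ks_speed: float
    ks_turn: float
    msd_slope_diff: float

    def __post_init__(self):
        for name in ("ks_speed", "ks_turn", "msd_slope_diff"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and ≥ 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ks_speed, self.ks_turn, self.msd_slope_diff])


def lambda_score(scores: ObjectiveScores) -> float:
    """Λ = max(ks_speed, ks_turn, msd_slope_diff / 2); lower is better.

    The slope difference is halved so all three terms live on [0, 1]
    (two units spans the sub- to ballistic α range); Λ = 0 iff every
    objective is 0.
    """
    return float(max(scores.ks_speed, scores.ks_turn, scores.msd_slope_diff / 2.0))


@dataclass(frozen=True)
class ParetoSolution:
    """One member of the fitted Pareto front."""

    model: MotilityModel
    scores: ObjectiveScores
    lambda_score: float


@dataclass(frozen=True)
class FitConfig:
    """NSGA-II fitting configuration (defaults: population 50, ≤ 40 generations)."""

    population_size: int = 50
    max_generations: int = 40
    replicates_per_eval: int = 1
    holdout_fraction: float = 0.25
    patience: int = 5
    param_bounds: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and ≥ 4")
        if self.max_generations < 1:
            raise ValueError("max_generations must be ≥ 1")
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.replicates_per_eval < 1:
            raise ValueError("replicates_per_eval must be ≥ 1")


@dataclass
class FitLog:
    """Per-generation record of an NSGA-II fit."""

    generations: list = field(default_factory=list)
    n_evaluations: int = 0
    stopped_early: bool = False
    stop_generation: int | None = None
    holdout_enabled: bool = True

    def holdout_trajectory(self) -> list[float]:
        return [g["holdout_lambda_median"] for g in self.generations]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)


@dataclass(frozen=True)
class TargetSummary:
    """Cached metrics of an observed population (speeds, turns, α)."""

    speeds: np.ndarray
    turns: np.ndarray
    alpha: float

    @classmethod
    def from_trackset(cls, ts: TrackSet, cfg: MetricsConfig | None = None) -> "TargetSummary":
        cfg = cfg or MetricsConfig()
        return cls(instantaneous_speeds(ts), turn_speeds(ts), msd_curve(ts, cfg).alpha)


def _pool_simulation(model, sim_cfg: SimulationConfig, seed: int, replicates: int,
                     metrics_cfg: MetricsConfig):
    """Simulate ``replicates`` runs, pool, and summarise; None if unusable."""
    speeds, turns, sets = [], [], []
    for r in range(replicates):
        # replicate 0 reuses the seed verbatim so a single-replicate
        # evaluation reproduces simulate(model, seed) exactly
        child = int(seed) if r == 0 else (int(seed) * 1000003 + r) % (2 ** 31)
        cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": child})
        sets.append(simulate(model, cfg))
    try:
        for ts in sets:
            speeds.append(instantaneous_speeds(ts))
            turns.append(turn_speeds(ts))
        all_tracks = [tr for ts in sets for tr in ts]
        # replicate runs may reuse fragment ids; qualify them before pooling
        pooled = TrackSet(
            tuple(
                type(tr)(f"r{j}:{tr.track_id}", tr.t, tr.xyz, tr.nominal_dt)
                for j, tr in enumerate(all_tracks)
            ),
            label=sets[0].label,
        )
        alpha = msd_curve(pooled, metrics_cfg).alpha
    except MetricError:
        return None
    return np.concatenate(speeds), np.concatenate(turns), alpha


def evaluate_objectives(
    model: MotilityModel,
    target: TrackSet | TargetSummary,
    sim_cfg: SimulationConfig,
    seed: int = 0,
    replicates: int = 1,
    metrics_cfg: MetricsConfig | None = None,
) -> ObjectiveScores:
    """Simulate a candidate model and score it against the target population.

    A simulation that yields no usable tracks (nothing recorded inside the
    volume, or too few points for the metrics) is infeasible and scores
    worst on every objective.
    """
    metrics_cfg = metrics_cfg or MetricsConfig()
    if isinstance(target, TrackSet):
        target = TargetSummary.from_trackset(target, metrics_cfg)
    pooled = _pool_simulation(model, sim_cfg, seed, replicates, metrics_cfg)
    if pooled is None:
        return ObjectiveScores(*INFEASIBLE)
    speeds, turns, alpha = pooled
    return ObjectiveScores(
        ks_speed=ks_two_sample(speeds, target.speeds).d,
        ks_turn=ks_two_sample(turns, target.turns).d,
        msd_slope_diff=abs(alpha - target.alpha),
    )


def detect_overfitting(holdout_medians, patience: int) -> tuple[bool, int | None]:
    """Early-stop rule on the holdout Λ trajectory.

    Stop once the trajectory's running minimum has not improved for
    ``patience`` consecutive generations; returns ``(stop, generation)``
    with the generation at which the rule first fires.
    """
    best = np.inf
    since_improved = 0
    for g, v in enumerate(holdout_medians):
        if v < best:
            best = v
            since_improved = 0
        else:
            since_improved += 1
            if since_improved >= patience:
                return True, g
    return False, None


def _front_indices(F: np.ndarray) -> np.ndarray:
    return fast_non_dominated_sort(F)[0]


def nsga2_fit(
    family: str,
    target: TrackSet,
    fit_cfg: FitConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    metrics_cfg: MetricsConfig | None = None,
) -> tuple[list[ParetoSolution], FitLog]:
    """Calibrate a model family to an observed TrackSet with NSGA-II.

    The target is split into training and holdout tracks up front; training
    tracks drive the three objectives, holdout tracks only the early-stop
    diagnostic. Returns the final non-dominated front sorted by Λ
    (training), plus the fit log. Deterministic given ``fit_cfg.seed``.
    """
    fit_cfg = fit_cfg or FitConfig()
    sim_cfg = sim_cfg or SimulationConfig()
    metrics_cfg = metrics_cfg or MetricsConfig()
    rng = np.random.default_rng(fit_cfg.seed)

    ids = [tr.track_id for tr in target]
    n_hold = int(round(fit_cfg.holdout_fraction * len(ids)))
    perm = rng.permutation(len(ids))
    hold_ids = {ids[i] for i in perm[:n_hold]}
    train = target.subset([i for i in ids if i not in hold_ids])
    log = FitLog()
    if n_hold < 5:
        log.holdout_enabled = False
        train = target
        holdout_summary = None
    else:
        holdout_summary = TargetSummary.from_trackset(target.subset(hold_ids), metrics_cfg)
    train_summary = TargetSummary.from_trackset(train, metrics_cfg)

    space = param_space(family, fit_cfg.param_bounds)
    bounds = [(lo, hi) for _, lo, hi in space]

    def eval_batch(X, gen):
        # common random numbers: one simulation seed per generation
        gen_seed = (int(fit_cfg.seed) * 9176 + 77 * gen + 1) % (2 ** 31)
        F = np.empty((len(X), 4))
        for i, x in enumerate(X):
            model = model_from_vector(family, x, fit_cfg.param_bounds)
            pooled = _pool_simulation(model, sim_cfg, gen_seed,
                                      fit_cfg.replicates_per_eval, metrics_cfg)
            if pooled is None:
                F[i, :3] = INFEASIBLE
                F[i, 3] = lambda_score(ObjectiveScores(*INFEASIBLE))
                continue
            speeds, turns, alpha = pooled
            scores = ObjectiveScores(
                ks_two_sample(speeds, train_summary.speeds).d,
                ks_two_sample(turns, train_summary.turns).d,
                abs(alpha - train_summary.alpha),
            )
            F[i, :3] = scores.as_array()
            if holdout_summary is None:
                F[i, 3] = lambda_score(scores)
            else:
                hold = ObjectiveScores(
                    ks_two_sample(speeds, holdout_summary.speeds).d,
                    ks_two_sample(turns, holdout_summary.turns).d,
                    abs(alpha - holdout_summary.alpha),
                )
                F[i, 3] = lambda_score(hold)
        return F

    def on_generation(gen, X, F):
        front = _front_indices(F[:, :3])
        med = float(np.median(F[front, 3]))
        log.generations.append(
            {
                "generation": gen,
                "front_size": int(len(front)),
                "train_lambda_min": float(
                    min(lambda_score(ObjectiveScores(*F[i, :3])) for i in front)
                ),
                "holdout_lambda_median": med,
            }
        )
        if not log.holdout_enabled:
            return False
        stop, at = detect_overfitting(log.holdout_trajectory(), fit_cfg.patience)
        if stop:
            log.stopped_early = True
            log.stop_generation = at
        return stop

    X, F, n_eval = nsga2(
        eval_batch,
        bounds,
        fit_cfg.population_size,
        fit_cfg.max_generations,
        seed=fit_cfg.seed,
        n_obj=3,
        callback=on_generation,
    )
    log.n_evaluations = n_eval

    front = _front_indices(F[:, :3])
    solutions = []
    seen = set()
    for i in front:
        key = tuple(np.round(X[i], 12))
        if key in seen:
            continue
        seen.add(key)
        scores = ObjectiveScores(*F[i, :3])
        solutions.append(
            ParetoSolution(
                model=model_from_vector(family, X[i], fit_cfg.param_bounds),
                scores=scores,
                lambda_score=lambda_score(scores),
            )
        )
    solutions.sort(key=lambda s: s.lambda_score)
    return solutions, log
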