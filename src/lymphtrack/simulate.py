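"""3D agent-based realisation of the candidate motility models.

Cells are non-overlapping spheres walking in boundless space; positions
are recorded only while an agent is inside an artificial imaging volume,
at a fixed recording interval, so simulated output carries the same
boundary-truncation artefacts as intravital two-photon data. All models
step at 30 s except the Lévy walk, which steps at 3 s to resolve its
variable run durations; recording is every 30 s for all models.

Collisions are handled by propose–reject: a move bringing two sphere
centres closer than one cell diameter is re-sampled (up to 10 times) and
the agent holds its position if no collision-free move is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImagingVolume
from .models import BrownianModel, CRWModel, LevyModel, MotilityModel
from .tracks import Track, TrackSet, split_at_volume

__all__ = [
    "SimulationConfig",
    "AgentState",
    "simulate",
    "draw_agent_params",
    "step_brownian",
    "rotate_headings",
    "sample_truncated_power_law",
    "DEFAULT_VOLUME",
]

#: Default imaging volume: a 300 × 300 μm field, 150 μm deep.
DEFAULT_VOLUME = ImagingVolume((0.0, 0.0, 0.0), (300.0, 300.0, 150.0))

_MAX_RESAMPLE = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation contract shared by all model families.

    ``dt`` defaults to 30 s (3 s for the Lévy walk); ``record_interval``
    must be an integer multiple of ``dt``. ``placement_margin`` inflates
    the initial-placement box beyond the imaging volume so agents can flux
    in and out of view; it defaults to a quarter of the volume's longest
    axis.
    """

    n_agents: int = 200
    duration: float = 1770.0          # seconds; 59 intervals → 60 records
    volume: ImagingVolume = DEFAULT_VOLUME
    agent_radius: float = 5.0
    dt: float | None = None
    record_interval: float = 30.0
    placement_margin: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("n_agents must be ≥ 1")
        if self.duration < self.record_interval:
            raise ValueError("duration must be ≥ record_interval")
        if self.agent_radius < 0:
            raise ValueError("agent_radius must be ≥ 0")

    def resolved_dt(self, model: MotilityModel) -> float:
        dt = self.dt if self.dt is not None else (3.0 if model.family == "levy" else 30.0)
        ratio = self.record_interval / dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"record_interval={self.record_interval} must be a multiple of dt={dt}"
            )
        return dt

    def resolved_margin(self) -> float:
        if self.placement_margin is not None:
            return self.placement_margin
        return 0.25 * float(np.max(self.volume.extent))


@dataclass
class AgentState:
    """Mutable per-agent state (positions in μm, heading a unit vector)."""

    position: np.ndarray
    heading: np.ndarray
    own_speed_scale: float = 0.0
    own_turn_scale: float = 0.0
    current_run: tuple = (0.0, 0.0)   # (speed μm/min, remaining duration s) — Lévy


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_truncated_power_law(
    rng: np.random.Generator, mu: float, lo: float, hi: float, size=None
) -> np.ndarray:
    """Sample x ∝ x^(−mu) on [lo, hi] by inverse-CDF."""
    u = rng.uniform(size=size)
    if lo == hi:
        return np.full_like(np.asarray(u, dtype=float), lo)
    a = 1.0 - mu
    return (lo ** a + u * (hi ** a - lo ** a)) ** (1.0 / a)


def draw_agent_params(model: CRWModel, rng: np.random.Generator, n: int):
    """Per-agent speed and turn scales for a CRW population.

    Heterogeneous variants draw the scales log-normally around the
    population medians; homogeneous variants give every agent the medians.
    Inverse variants couple the two draws rank-inversely (an agent's turn
    quantile is one minus its speed quantile), so fast agents are the
    straight ones.
    """
    if not isinstance(model, CRWModel):
        raise ValueError(f"draw_agent_params applies to CRW families, got {model.family}")
    if not model.heterogeneous:
        return (np.full(n, model.speed_median), np.full(n, model.turn_median))
    z_speed = rng.normal(size=n)
    z_turn = -z_speed if model.inverse else rng.normal(size=n)
    speed = model.speed_median * np.exp(model.speed_sigma * z_speed)
    turn = model.turn_median * np.exp(model.turn_sigma * z_turn)
    return speed, turn


def step_brownian(model: BrownianModel, dt: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Isotropic Gaussian displacements, per-axis sd √(2 D dt)."""
    sd = np.sqrt(2.0 * model.d * dt / 60.0)  # D is per minute, dt in seconds
    return rng.normal(scale=sd, size=(n, 3)) if sd > 0 else np.zeros((n, 3))


def rotate_headings(headings: np.ndarray, angles_rad: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit heading by its angle about a random perpendicular axis.

    The rotation axis is uniform among directions perpendicular to the
    heading, i.e. turning is isotropic about the direction of motion.
    """
    n = len(headings)
    raw = rng.normal(size=(n, 3))
    perp = raw - np.sum(raw * headings, axis=1, keepdims=True) * headings
    norm = np.linalg.norm(perp, axis=1, keepdims=True)
    # degenerate draws (parallel to heading) are vanishingly rare; regularise
    perp = np.where(norm > 1e-12, perp / np.maximum(norm, 1e-12), np.array([1.0, 0.0, 0.0]))
    c = np.cos(angles_rad)[:, None]
    s = np.sin(angles_rad)[:, None]
    out = headings * c + perp * s
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _lognormal_about(median: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal draw with the given median and coefficient of variation."""
    if cv == 0.0:
        return np.array(median, dtype=float, copy=True)
    sigma = np.sqrt(np.log1p(cv * cv))
    return median * np.exp(sigma * rng.normal(size=np.shape(median)))


def _overlap_mask(pos: np.ndarray, min_dist: float) -> np.ndarray:
    """Boolean mask of agents involved in any pairwise overlap."""
    n = len(pos)
    if n < 2 or min_dist <= 0:
        return np.zeros(n, dtype=bool)
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    return (d2 < min_dist * min_dist).any(axis=1)


def _place_agents(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    box = cfg.volume.inflate(cfg.resolved_margin())
    pos = np.empty((cfg.n_agents, 3))
    min_dist = 2.0 * cfg.agent_radius
    for i in range(cfg.n_agents):
        for _ in range(1000):
            cand = box.origin + rng.uniform(size=3) * box.extent
            if i == 0 or np.min(np.linalg.norm(pos[:i] - cand, axis=1)) >= min_dist:
                pos[i] = cand
                break
        else:
            raise RuntimeError("could not place non-overlapping agents; volume too crowded")
    return pos


class _Stepper:
    """Draws proposed displacements (and heading updates) per family."""

    def __init__(self, model: MotilityModel, cfg: SimulationConfig, dt: float,
                 rng: np.random.Generator):
        self.model = model
        self.dt = dt
        self.rng = rng
        n = cfg.n_agents
        self.heading = _random_unit_vectors(rng, n)
        if isinstance(model, CRWModel):
            self.own_speed, self.own_turn = draw_agent_params(model, rng, n)
        elif isinstance(model, LevyModel):
            self.run_speed = np.zeros(n)
            self.run_left = np.zeros(n)
            self._renew_runs(np.ones(n, dtype=bool))

    def _renew_runs(self, mask: np.ndarray) -> None:
        m = self.model
        k = int(mask.sum())
        if k == 0:
            return
        self.run_speed[mask] = sample_truncated_power_law(
            self.rng, m.mu_speed, *m.speed_bounds, size=k)
        self.run_left[mask] = sample_truncated_power_law(
            self.rng, m.mu_duration, *m.duration_bounds, size=k)
        self.heading[mask] = _random_unit_vectors(self.rng, k)

    def propose(self, mask: np.ndarray):
        """Proposed displacement and new heading for agents in ``mask``."""
        m, dt, rng = self.model, self.dt, self.rng
        k = int(mask.sum())
        if isinstance(m, BrownianModel):
            return step_brownian(m, dt, rng, k), self.heading[mask]
        if isinstance(m, CRWModel):
            speeds = _lognormal_about(self.own_speed[mask], m.step_cv, rng)
            turns = _lognormal_about(self.own_turn[mask], m.step_cv, rng)
            angles = np.radians(turns) * dt / 60.0
            new_head = rotate_headings(self.heading[mask], angles, rng)
            disp = new_head * (speeds * dt / 60.0)[:, None]
            return disp, new_head
        # Lévy: on re-proposal the agent abandons its run and draws a new one
        disp = self.heading[mask] * (self.run_speed[mask] * dt / 60.0)[:, None]
        return disp, self.heading[mask]

    def commit(self, accepted: np.ndarray, new_heading: np.ndarray) -> None:
        self.heading[accepted] = new_heading
        if isinstance(self.model, LevyModel):
            self.run_left -= self.dt
            self._renew_runs(self.run_left <= 0)

    def resample(self, mask: np.ndarray):
        if isinstance(self.model, LevyModel):
            self._renew_runs(mask)
        return self.propose(mask)


def simulate(model: MotilityModel, cfg: SimulationConfig) -> TrackSet:
    """Run one agent-based simulation and return the recorded TrackSet.

    Agents start uniformly placed (non-overlapping) in the imaging volume
    inflated by the placement margin and walk in boundless space; the
    recorded output keeps only in-volume positions, split into fragments
    exactly as real tracks fragment at the volume boundary. The output is
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.resolved_dt(model)
    rec_every = int(round(cfg.record_interval / dt))
    n_steps = int(round(cfg.duration / dt))
    min_dist = 2.0 * cfg.agent_radius

    pos = _place_agents(rng, cfg)
    stepper = _Stepper(model, cfg, dt, rng)

    n = cfg.n_agents
    n_records = n_steps // rec_every + 1
    recorded = np.empty((n_records, n, 3))
    recorded[0] = pos
    rec_i = 1

    all_agents = np.ones(n, dtype=bool)
    for step in range(1, n_steps + 1):
        disp, new_head = stepper.propose(all_agents)
        prop = pos + disp
        heading_next = new_head.copy()
        for _ in range(_MAX_RESAMPLE):
            bad = _overlap_mask(prop, min_dist)
            if not bad.any():
                break
            d2, h2 = stepper.resample(bad)
            prop[bad] = pos[bad] + d2
            heading_next[bad] = h2
        # any agents still colliding hold their previous position/heading
        while True:
            bad = _overlap_mask(prop, min_dist)
            if not bad.any():
                break
            prop[bad] = pos[bad]
            heading_next[bad] = stepper.heading[bad]
        pos = prop
        stepper.commit(all_agents, heading_next)
        if step % rec_every == 0:
            recorded[rec_i] = pos
            rec_i += 1

    times = cfg.record_interval * np.arange(n_records)
    tracks = [
        Track(f"a{i}", times, recorded[:, i, :], cfg.record_interval)
        for i in range(n)
    ]
    raw = TrackSet(tuple(tracks), label=model.family, volume=cfg.volume)
    return split_at_volume(raw, cfg.volume)
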