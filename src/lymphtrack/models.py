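"""Candidate motility models and their fit parameterisations.

Six model families describe lymphocyte motility:

* ``brownian`` — isotropic Brownian motion with diffusion coefficient D
  (μm²/min);
* ``levy`` — a Lévy walk whose run speeds and run durations are drawn from
  truncated power laws (heavy tails produce rare long relocations);
* four correlated random walks (CRW) combining two axes:
  agents statistically identical (``homog``) vs individually parameterised
  (``hetero``), and speed and turn scales drawn independently vs with an
  imposed inverse rank correlation (``inv``): ``crw_homog``,
  ``crw_hetero``, ``crw_inv_homog``, ``crw_inv_hetero``.

CRW population parameters are log-normal: the median and log-sd of the
per-agent speed scale (μm/min) and turn-speed scale (deg/min), plus a
per-step coefficient of variation describing frame-to-frame variability
around an agent's own scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BrownianModel",
    "LevyModel",
    "CRWModel",
    "MotilityModel",
    "FAMILIES",
    "model_from_family",
    "param_space",
    "model_from_vector",
    "model_to_vector",
]


@dataclass(frozen=True)
class BrownianModel:
    """Isotropic Brownian motion; ``d`` is the diffusion coefficient (μm²/min)."""

    d: float = 10.0

    def __post_init__(self):
        if not (np.isfinite(self.d) and self.d >= 0):
            raise ValueError(f"diffusion coefficient must be ≥ 0, got {self.d}")

    @property
    def family(self) -> str:
        return "brownian"


@dataclass(frozen=True)
class LevyModel:
    """Lévy walk with truncated power-law run speeds and durations.

    ``mu_speed`` / ``mu_duration`` are the power-law exponents (> 1);
    speeds are bounded in μm/min and durations in seconds.
    """

    mu_speed: float = 2.0
    mu_duration: float = 2.0
    speed_bounds: tuple = (1.0, 50.0)
    duration_bounds: tuple = (6.0, 300.0)

    def __post_init__(self):
        for name in ("mu_speed", "mu_duration"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be > 1")
        for name in ("speed_bounds", "duration_bounds"):
            lo, hi = getattr(self, name)
            # lower == upper degenerates to a point mass, useful for testing
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lower ≤ upper")

    @property
    def family(self) -> str:
        return "levy"


@dataclass(frozen=True)
class CRWModel:
    """Correlated random walk with optional agent heterogeneity.

    speed_median : μm/min, median of the per-agent speed scale (> 0).
    speed_sigma : log-sd of per-agent speed scales (≥ 0; ignored when
        homogeneous).
    turn_median : deg/min, median per-agent turn-speed scale (≥ 0; 0 means
        no turning, the ballistic limit).
    turn_sigma : log-sd of per-agent turn scales (≥ 0).
    step_cv : per-step coefficient of variation around an agent's own
        scales (≥ 0; 0 removes frame-to-frame variability).
    heterogeneous : draw per-agent scales (True) or give every agent the
        population medians (False).
    inverse : impose turn quantile = 1 − speed quantile per agent
        (fast agents turn little), a rank correlation of −1.
    """

    speed_median: float = 6.0
    speed_sigma: float = 0.35
    turn_median: float = 60.0
    turn_sigma: float = 0.35
    step_cv: float = 0.3
    heterogeneous: bool = True
    inverse: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.speed_median) and self.speed_median > 0):
            raise ValueError(f"speed_median must be > 0, got {self.speed_median}")
        for name in ("speed_sigma", "turn_median", "turn_sigma", "step_cv"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be ≥ 0, got {v}")

    @property
    def family(self) -> str:
        inv = "inv_" if self.inverse else ""
        kind = "hetero" if self.heterogeneous else "homog"
        return f"crw_{inv}{kind}"


MotilityModel = BrownianModel | LevyModel | CRWModel

FAMILIES = ("brownian", "levy", "crw_homog", "crw_hetero", "crw_inv_homog", "crw_inv_hetero")

_CRW_FLAGS = {
    "crw_homog": (False, False),
    "crw_hetero": (True, False),
    "crw_inv_homog": (False, True),
    "crw_inv_hetero": (True, True),
}


def model_from_family(family: str, **params) -> MotilityModel:
    """Build a model of the named family with keyword parameter overrides."""
    if family == "brownian":
        return BrownianModel(**params)
    if family == "levy":
        return LevyModel(**params)
    if family in _CRW_FLAGS:
        hetero, inverse = _CRW_FLAGS[family]
        return CRWModel(heterogeneous=hetero, inverse=inverse, **params)
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


# --- fit parameterisation ---------------------------------------------------
# Each family exposes the free parameters NSGA-II searches over, with
# default bounds spanning plausible lymphocyte motility.

_PARAM_SPACES = {
    "brownian": [("d", 0.5, 40.0)],
    "levy": [("mu_speed", 1.1, 3.5), ("mu_duration", 1.1, 3.5)],
    "crw_homog": [("speed_median", 0.1, 20.0), ("turn_median", 1.0, 360.0),
                  ("step_cv", 0.0, 1.0)],
    "crw_hetero": [("speed_median", 0.1, 20.0), ("speed_sigma", 0.0, 1.0),
                   ("turn_median", 1.0, 360.0), ("turn_sigma", 0.0, 1.0),
                   ("step_cv", 0.0, 1.0)],
}
_PARAM_SPACES["crw_inv_homog"] = _PARAM_SPACES["crw_homog"]
_PARAM_SPACES["crw_inv_hetero"] = _PARAM_SPACES["crw_hetero"]


def param_space(family: str, overrides: dict | None = None) -> list[tuple[str, float, float]]:
    """``(name, lower, upper)`` bounds of the family's free fit parameters."""
    if family not in _PARAM_SPACES:
        raise ValueError(f"unknown model family {family!r}")
    space = [list(p) for p in _PARAM_SPACES[family]]
    if overrides:
        for name, (lo, hi) in overrides.items():
            for p in space:
                if p[0] == name:
                    p[1], p[2] = lo, hi
                    break
            else:
                raise ValueError(f"{name!r} is not a free parameter of {family}")
    return [tuple(p) for p in space]


def model_from_vector(family: str, x, overrides: dict | None = None) -> MotilityModel:
    names = [n for n, _, _ in param_space(family, overrides)]
    return model_from_family(family, **dict(zip(names, map(float, x))))


def model_to_vector(model: MotilityModel) -> np.ndarray:
    names = [n for n, _, _ in param_space(model.family)]
    return np.array([getattr(model, n) for n in names], dtype=float)
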