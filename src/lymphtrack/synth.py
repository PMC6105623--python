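"""Synthetic-data generators with known ground truth.

These emulate the inputs of an intravital two-photon imaging study so the
whole analysis chain is testable without microscope data: track tables
acquired at 30 s intervals for 60 cycles inside a ~150 μm-deep volume
(with boundary fragmentation, localisation noise and frame dropout),
photoconversion count series with exponential lymph-node dwell, macrophage
surface models lining the subcapsular band, and scripted cell-contact
scenarios. Every generator is deterministic under a fixed seed and
returns its ground truth in machine-readable form.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import ImagingVolume, Sphere, SurfaceModel
from .metrics import ContactEvent
from .models import MotilityModel
from .simulate import DEFAULT_VOLUME, SimulationConfig, simulate
from .tracks import PhotoconversionSeries, Track, TrackSet

__all__ = [
    "TPMScenario",
    "make_tracks",
    "make_photoconversion_series",
    "make_surface",
    "make_contact_scenario",
]


@dataclass(frozen=True)
class TPMScenario:
    """A two-photon acquisition scenario layered on a motility model.

    Defaults mirror the acquisition protocol: 60 frames at 30 s intervals
    (30 min) over a 300 × 300 × 150 μm volume. ``localisation_sd`` is the
    isotropic centroid-localisation noise in μm (0.5 μm default, typical
    of two-photon spot detection); ``dropout_rate`` is the per-frame
    probability that a cell's detection is missed, leaving a gap.
    """

    model: MotilityModel
    n_cells: int = 200
    frames: int = 60
    frame_interval: float = 30.0
    volume: ImagingVolume = DEFAULT_VOLUME
    localisation_sd: float = 0.5
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.frames < 2:
            raise ValueError("frames must be ≥ 2")
        if self.localisation_sd < 0:
            raise ValueError("localisation_sd must be ≥ 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


def make_tracks(sc: TPMScenario) -> tuple[TrackSet, dict]:
    """Simulate a scenario and degrade it like real imaging data.

    Runs the agent-based simulation, adds isotropic Gaussian localisation
    noise and drops frames at the dropout rate (gaps stay gaps — no
    interpolation). With zero noise and zero dropout the output is the
    simulation output, bit for bit. Returns the TrackSet and a ground-truth
    record of the generating model and scenario.
    """
    sim_cfg = SimulationConfig(
        n_agents=sc.n_cells,
        duration=(sc.frames - 1) * sc.frame_interval,
        volume=sc.volume,
        record_interval=sc.frame_interval,
        seed=sc.seed,
    )
    ts = simulate(sc.model, sim_cfg)
    truth = {
        "family": sc.model.family,
        "model": asdict(sc.model),
        "n_cells": sc.n_cells,
        "frames": sc.frames,
        "frame_interval": sc.frame_interval,
        "localisation_sd": sc.localisation_sd,
        "dropout_rate": sc.dropout_rate,
        "seed": sc.seed,
    }
    if sc.localisation_sd == 0 and sc.dropout_rate == 0:
        return ts, truth

    rng = np.random.default_rng((sc.seed * 2654435761 + 1) % (2 ** 31))
    degraded = []
    for tr in ts:
        xyz = tr.xyz
        if sc.localisation_sd > 0:
            xyz = xyz + rng.normal(scale=sc.localisation_sd, size=xyz.shape)
        keep = np.ones(len(tr), dtype=bool)
        if sc.dropout_rate > 0:
            keep = rng.uniform(size=len(tr)) >= sc.dropout_rate
        if not keep.any():
            continue
        degraded.append(Track(tr.track_id, tr.t[keep], xyz[keep], tr.nominal_dt))
    return TrackSet(tuple(degraded), label=ts.label, volume=ts.volume), truth


def make_photoconversion_series(
    lambda_rate: float,
    times,
    n0: float = 1000.0,
    noise: str = "none",
    seed: int | None = None,
    influx_level: float | None = None,
) -> PhotoconversionSeries:
    """Photoconversion counts under exponential dwell at rate ``lambda_rate``.

    The resident photoconverted pool decays as n0·exp(−λt) (λ per hour,
    t in hours); the non-photoconverted arm is the steady-state level of
    new arrivals, a constant (default n0/2, a nuisance scale that cancels
    in the ratio), so converted/unconverted decays exponentially at rate λ.
    ``noise="poisson"`` perturbs both arms with Poisson counting noise.
    """
    if not (np.isfinite(lambda_rate) and lambda_rate > 0):
        raise ValueError(f"lambda_rate must be > 0, got {lambda_rate}")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    conv = n0 * np.exp(-lambda_rate * t)
    unconv = np.full_like(t, n0 / 2.0 if influx_level is None else influx_level)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        conv = rng.poisson(conv).astype(float)
        unconv = rng.poisson(unconv).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    return PhotoconversionSeries(t, conv, unconv)


def make_surface(
    style: str = "subcapsular_band",
    volume: ImagingVolume = DEFAULT_VOLUME,
    params: dict | None = None,
    seed: int = 0,
) -> SurfaceModel:
    """Synthetic macrophage surface models.

    ``subcapsular_band`` scatters spheres through the shallow z-band of
    the volume (z increases with depth, so the band starts at the capsule);
    defaults: 40 spheres of radius 8 μm within the top 20 μm. Params:
    ``n_spheres``, ``radius``, ``band_depth``. ``single_sphere`` places one
    sphere; params ``center`` (default volume centre) and ``radius``
    (default 10 μm).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if style == "single_sphere":
        center = p.get("center", volume.center)
        return SurfaceModel("surface", (Sphere(center, p.get("radius", 10.0)),))
    if style != "subcapsular_band":
        raise ValueError(f"unknown surface style {style!r}")
    band = float(p.get("band_depth", 20.0))
    if band > volume.extent[2]:
        raise ValueError("band_depth exceeds the volume's z extent")
    n = int(p.get("n_spheres", 40))
    radius = float(p.get("radius", 8.0))
    centers = np.column_stack(
        [
            volume.origin[0] + rng.uniform(size=n) * volume.extent[0],
            volume.origin[1] + rng.uniform(size=n) * volume.extent[1],
            volume.origin[2] + rng.uniform(size=n) * band,
        ]
    )
    return SurfaceModel("scs_macrophages", tuple(Sphere(c, radius) for c in centers))


def make_contact_scenario(
    n_events: int,
    duration_frames: int = 4,
    seed: int = 0,
    dt: float = 30.0,
    gap_frames: int = 4,
    excursion_in_event: int | None = None,
) -> tuple[TrackSet, TrackSet, list[ContactEvent]]:
    """Scripted approach–dwell–depart trajectories with planted contacts.

    One subject cell walks along x; for each planted event a distinct
    partner approaches to within the default 10 μm contact threshold,
    dwells ``duration_frames`` frames, then departs. Events are separated
    by ``gap_frames`` non-contact frames (≥ 2 so the single-frame
    gap-bridging rule cannot merge them). ``excursion_in_event`` makes the
    chosen event include a one-frame excursion out of contact, which the
    bridging rule should merge back into a single event.

    Returns ``(subjects, partners, truth)`` where ``truth`` lists the
    planted events.
    """
    if n_events < 0:
        raise ValueError("n_events must be ≥ 0")
    if duration_frames < 1:
        raise ValueError("duration_frames must be ≥ 1")
    if gap_frames < 2:
        raise ValueError("gap_frames must be ≥ 2 to keep planted events separate")
    rng = np.random.default_rng(seed)
    n_frames = max(2, n_events * (duration_frames + gap_frames) + gap_frames)
    t = dt * np.arange(n_frames)
    step = 8.0  # μm advanced by the subject per frame
    subj_xyz = np.column_stack([step * np.arange(n_frames), np.zeros(n_frames), np.zeros(n_frames)])
    subjects = TrackSet((Track("subject", t, subj_xyz, dt),), label="subjects")

    far = 80.0  # approach/depart stand-off, well beyond the threshold
    near = 2.0  # dwell distance, well inside it
    partners = []
    truth = []
    for e in range(n_events):
        s = gap_frames + e * (duration_frames + gap_frames)
        y = np.full(n_frames, far)
        y[s : s + duration_frames] = near
        if excursion_in_event == e and duration_frames >= 3:
            y[s + duration_frames // 2] = far  # one-frame excursion, bridged
        # partner shadows the subject in x so contact is governed by y alone
        xyz = np.column_stack([subj_xyz[:, 0], y, np.zeros(n_frames)])
        xyz[:, 0] += rng.normal(scale=0.1, size=n_frames)  # sub-μm jitter
        partners.append(Track(f"partner{e}", t, xyz, dt))
        t_start = float(t[s])
        t_end = float(t[s + duration_frames - 1])
        truth.append(
            ContactEvent("subject", f"partner{e}", t_start, t_end, t_end - t_start + dt)
        )
    if not partners:
        # a partner that never comes close, so contact detection sees
        # overlapping timepoints but zero events
        xyz = np.column_stack([subj_xyz[:, 0], np.full(n_frames, far), np.zeros(n_frames)])
        partners.append(Track("partner_far", t, xyz, dt))
    return subjects, TrackSet(tuple(partners), label="partners"), truth
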