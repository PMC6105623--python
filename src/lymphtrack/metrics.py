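"""Track-derived motility statistics.

All speed-like quantities are reported in μm/min (the field's customary
unit) although track timestamps are stored in seconds. Metrics that
consume steps use only single-frame steps: a step spanning a dropped frame
is excluded rather than interpolated.

The central quantities:

* instantaneous speed — per-step displacement over the frame interval,
  pooled across a population and summarised as an ECDF;
* meandering index — net displacement over total path length, a
  straightness measure in [0, 1];
* mean squared displacement (MSD) and its log–log slope α, the anomalous
  exponent (α = 1 diffusive, α > 1 superdiffusive, α = 2 ballistic);
* arrest coefficient — fraction of time below a slow-speed threshold
  (default 3 μm/min);
* two-sample Kolmogorov–Smirnov D between pooled distributions;
* surface proximity, distance-segmented speeds, T–B contact events and
  compartment assignment;
* exponential residence-time estimation from photoconversion ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import RegionModel, SurfaceModel
from .tracks import PhotoconversionSeries, Track, TrackPoint, TrackSet

__all__ = [
    "MetricsConfig",
    "MSDCurve",
    "KSResult",
    "ResidenceEstimate",
    "ContactEvent",
    "ECDF",
    "MetricError",
    "instantaneous_speeds",
    "ecdf",
    "net_displacement",
    "meandering_index",
    "msd_curve",
    "arrest_coefficient",
    "turn_speeds",
    "ks_two_sample",
    "distance_to_surface",
    "proximity_fraction",
    "segment_speeds_by_distance",
    "contact_events",
    "contact_rate",
    "assign_tracks_to_regions",
    "estimate_residence_time",
]

LN2 = float(np.log(2.0))


class MetricError(ValueError):
    """A metric is undefined for the given input (signalled, not silent)."""


@dataclass(frozen=True)
class MetricsConfig:
    """Thresholds shared across metrics.

    proximity_threshold : μm; a cell closer than this to a surface counts
        as "in proximity" (default 20).
    arrest_speed : μm/min; steps slower than this count as arrested
        (default 3).
    msd_max_fraction : MSD lags run up to this fraction of the longest
        track duration (default 0.25).
    contact_threshold : μm centroid distance defining a contact
        (default 10, about one cell diameter).
    contact_window : minutes; reporting window for contact rates
        (default 5).
    """

    proximity_threshold: float = 20.0
    arrest_speed: float = 3.0
    msd_max_fraction: float = 0.25
    contact_threshold: float = 10.0
    contact_window: float = 5.0

    def __post_init__(self):
        for name in ("proximity_threshold", "arrest_speed", "contact_threshold", "contact_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.msd_max_fraction <= 1):
            raise ValueError("msd_max_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MSDCurve:
    """MSD(τ) with pair counts and the fitted log–log slope α."""

    taus: np.ndarray      # seconds, increasing
    msd: np.ndarray       # μm²
    n_pairs: np.ndarray
    alpha: float


@dataclass(frozen=True)
class KSResult:
    d: float
    p: float
    n1: int
    n2: int

    def __post_init__(self):
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"KS D outside [0,1]: {self.d}")


@dataclass(frozen=True)
class ResidenceEstimate:
    """Exponential dwell fit: rate λ (per hour), half-life and mean residence.

    half_life = ln2/λ and residence_time = 1/λ hold identically.
    """

    lambda_rate: float
    half_life: float
    residence_time: float
    r_squared: float


@dataclass(frozen=True)
class ContactEvent:
    subject_id: str
    partner_id: str
    t_start: float
    t_end: float
    duration: float


class ECDF:
    """Right-continuous empirical CDF of a pooled sample.

    ``ecdf(v)`` is the proportion of the sample ≤ v; at the sample points it
    takes values 1/n, 2/n, …, 1, and a value of 0.5 marks the (upper)
    median.
    """

    def __init__(self, sample):
        x = np.asarray(sample, dtype=float).ravel()
        if x.size == 0:
            raise MetricError("ECDF of an empty sample is undefined")
        self.x = np.sort(x)
        self.n = x.size
        self.y = np.arange(1, self.n + 1) / self.n

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        out = np.searchsorted(self.x, v, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def ecdf(sample) -> ECDF:
    """Empirical cumulative distribution function of a pooled sample."""
    return ECDF(sample)


def _track_speeds(tr: Track) -> np.ndarray:
    disp, _ = tr.step_vectors()
    if len(disp) == 0:
        return np.empty(0)
    return np.linalg.norm(disp, axis=1) / tr.nominal_dt * 60.0


def instantaneous_speeds(ts: TrackSet) -> np.ndarray:
    """Pooled per-step speeds (μm/min) across a population.

    One speed per single-frame step; gap-spanning steps are excluded;
    raises if no track contributes a step.
    """
    pools = [_track_speeds(tr) for tr in ts]
    pooled = np.concatenate(pools) if pools else np.empty(0)
    if pooled.size == 0:
        raise MetricError("no track with ≥ 2 consecutive points")
    return pooled


def net_displacement(tr: Track) -> float:
    """Euclidean distance between first and last observations (μm)."""
    if len(tr) < 2:
        raise MetricError("net displacement needs ≥ 2 points")
    return float(np.linalg.norm(tr.xyz[-1] - tr.xyz[0]))


def meandering_index(tr: Track) -> float:
    """Net displacement over total path length; 1 = straight, 0 = closed."""
    if len(tr) < 2:
        raise MetricError("meandering index needs ≥ 2 points")
    path = float(np.sum(np.linalg.norm(np.diff(tr.xyz, axis=0), axis=1)))
    if path == 0.0:
        raise MetricError("meandering index undefined: zero path length")
    return net_displacement(tr) / path


def msd_curve(ts: TrackSet, cfg: MetricsConfig | None = None) -> MSDCurve:
    """Population mean squared displacement and anomalous exponent α.

    MSD(τ) averages the squared displacement over *all* ordered observation
    pairs separated by exactly τ within each track (time intervals taken
    from anywhere in the series, not anchored at t = 0), pooled across
    tracks with pair-count weights. The lag grid is every multiple of the
    frame interval up to ``msd_max_fraction`` of the longest track
    duration, which avoids biasing long lags towards slow cells that
    persist in the imaging volume. α is the ordinary least-squares slope of
    log10 MSD on log10 τ over lags with at least one pair and positive MSD.
    """
    cfg = cfg or MetricsConfig()
    if len(ts) == 0:
        raise MetricError("empty track set")
    dt = ts.nominal_dt
    longest = max(tr.duration for tr in ts)
    kmax = int(np.floor(cfg.msd_max_fraction * longest / dt + 1e-9))
    if kmax < 1:
        raise MetricError("no usable lags: tracks too short for msd_max_fraction")
    sums = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=np.int64)
    for tr in ts:
        idx = tr.frame_index()
        span = idx[-1] + 1
        # slot[i] = row of the point at frame i, -1 if missing
        slot = np.full(span, -1, dtype=np.int64)
        slot[idx] = np.arange(len(idx))
        for k in range(1, min(kmax, span - 1) + 1):
            a, b = slot[:-k], slot[k:]
            ok = (a >= 0) & (b >= 0)
            if not ok.any():
                continue
            d = tr.xyz[b[ok]] - tr.xyz[a[ok]]
            sums[k - 1] += float(np.sum(d * d))
            counts[k - 1] += int(ok.sum())
    taus = dt * np.arange(1, kmax + 1)
    msd = np.divide(sums, counts, out=np.zeros(kmax), where=counts > 0)
    usable = (counts > 0) & (msd > 0)
    if usable.sum() < 2:
        raise MetricError("fewer than 2 usable lags: alpha undefined")
    alpha = float(np.polyfit(np.log10(taus[usable]), np.log10(msd[usable]), 1)[0])
    return MSDCurve(taus, msd, counts, alpha)


def arrest_coefficient(tr: Track, cfg: MetricsConfig | None = None) -> float:
    """Fraction of a cell's steps slower than the arrest threshold."""
    cfg = cfg or MetricsConfig()
    speeds = _track_speeds(tr)
    if speeds.size == 0:
        raise MetricError("arrest coefficient needs ≥ 1 usable step")
    return float(np.mean(speeds < cfg.arrest_speed))


def turn_speeds(ts: TrackSet) -> np.ndarray:
    """Pooled turn speeds (degrees/min) across a population.

    For each pair of successive single-frame steps the angle between the
    two displacement vectors is divided by the frame interval. Steps with a
    zero-length displacement carry no direction and are skipped.
    """
    pooled = []
    for tr in ts:
        if len(tr) < 3:
            continue
        dt_min = tr.nominal_dt / 60.0
        disp, start = tr.step_vectors()
        # successive steps: step starting at i followed by step starting at i+1
        for j in range(len(start) - 1):
            if start[j + 1] != start[j] + 1:
                continue
            v1, v2 = disp[j], disp[j + 1]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0.0 or n2 == 0.0:
                continue
            ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)), np.dot(v1, v2)))
            pooled.append(ang / dt_min)
    if not pooled:
        raise MetricError("no track with ≥ 3 consecutive points")
    return np.asarray(pooled)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison.

    D is the maximum vertical distance between the two ECDFs: 0 for
    identical distributions, 1 for non-overlapping ones. The p-value uses
    the asymptotic two-sample Kolmogorov distribution.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise MetricError("KS test needs two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def distance_to_surface(point, surface: SurfaceModel) -> float:
    """Distance (μm) from a point to the nearest surface primitive, 0 inside."""
    if isinstance(point, TrackPoint):
        p = np.array([point.x, point.y, point.z])
    else:
        p = np.asarray(point, dtype=float)
    return float(surface.distance(p.reshape(1, 3))[0])


def _time_key(t: float) -> float:
    return round(float(t), 6)


def proximity_fraction(ts: TrackSet, surface: SurfaceModel, cfg: MetricsConfig | None = None):
    """Per-timepoint fraction of observed cells within the proximity threshold.

    Returns ``(times, fractions)`` sorted by time.
    """
    cfg = cfg or MetricsConfig()
    buckets: dict[float, list[float]] = {}
    for tr in ts:
        d = surface.distance(tr.xyz)
        for t, di in zip(tr.t, d):
            buckets.setdefault(_time_key(t), []).append(float(di))
    if not buckets:
        raise MetricError("no observed timepoints")
    times = np.array(sorted(buckets))
    fracs = np.array(
        [np.mean(np.asarray(buckets[t]) < cfg.proximity_threshold) for t in times]
    )
    return times, fracs


def segment_speeds_by_distance(
    ts: TrackSet, surface: SurfaceModel, cfg: MetricsConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split pooled speeds by the step start point's distance to a surface.

    Returns ``(close, far)`` speed samples (μm/min): a step is "close" when
    its start point lies within the proximity threshold of the surface. The
    two samples partition :func:`instantaneous_speeds` exactly.
    """
    cfg = cfg or MetricsConfig()
    close, far = [], []
    for tr in ts:
        disp, start = tr.step_vectors()
        if len(disp) == 0:
            continue
        speeds = np.linalg.norm(disp, axis=1) / tr.nominal_dt * 60.0
        d = surface.distance(tr.xyz[start])
        is_close = d < cfg.proximity_threshold
        close.append(speeds[is_close])
        far.append(speeds[~is_close])
    close_all = np.concatenate(close) if close else np.empty(0)
    far_all = np.concatenate(far) if far else np.empty(0)
    if close_all.size + far_all.size == 0:
        raise MetricError("no track with ≥ 2 consecutive points")
    return close_all, far_all


def contact_events(
    subjects: TrackSet, partners: TrackSet, cfg: MetricsConfig | None = None
) -> list[ContactEvent]:
    """Detect cell–cell contacts between two populations.

    A subject is in contact at a frame when its nearest partner centroid is
    within ``contact_threshold``. Maximal runs of contacting frames with
    the same nearest partner form one event; a single-frame interruption
    inside a run is bridged. Event duration counts the closing frame
    interval: duration = t_end − t_start + Δt.
    """
    cfg = cfg or MetricsConfig()
    # partner positions per timepoint
    part: dict[float, tuple[list[str], list[np.ndarray]]] = {}
    for tr in partners:
        for t, p in zip(tr.t, tr.xyz):
            ids, pos = part.setdefault(_time_key(t), ([], []))
            ids.append(tr.track_id)
            pos.append(p)
    overlap = False
    events: list[ContactEvent] = []
    for tr in subjects:
        dt = tr.nominal_dt
        frames = tr.frame_index()
        # (frame, partner_id) for frames in contact
        contacts: list[tuple[int, str, float]] = []
        for f, t, p in zip(frames, tr.t, tr.xyz):
            entry = part.get(_time_key(t))
            if entry is None:
                continue
            overlap = True
            ids, pos = entry
            dists = np.linalg.norm(np.asarray(pos) - p, axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= cfg.contact_threshold:
                contacts.append((int(f), ids[j], float(t)))
        # group into events: same partner, frame gap ≤ 2 (one-frame gaps bridged)
        for k, (f, pid, t) in enumerate(contacts):
            if k > 0 and pid == contacts[k - 1][1] and f - contacts[k - 1][0] <= 2:
                ev = events[-1]
                events[-1] = ContactEvent(ev.subject_id, ev.partner_id, ev.t_start, t,
                                          t - ev.t_start + dt)
            else:
                events.append(ContactEvent(tr.track_id, pid, t, t, dt))
    if not overlap:
        raise MetricError("no overlapping timepoints between subjects and partners")
    return events


def contact_rate(events, subject_duration: float, cfg: MetricsConfig | None = None) -> float:
    """Contacts per reporting window, normalised by subject track duration.

    ``subject_duration`` is in seconds; the window (default 5 min) is
    converted to seconds internally.
    """
    cfg = cfg or MetricsConfig()
    if subject_duration <= 0:
        raise MetricError("subject duration must be > 0")
    window_s = cfg.contact_window * 60.0
    return len(list(events)) * window_s / subject_duration


def assign_tracks_to_regions(ts: TrackSet, rm: RegionModel) -> dict[str, str]:
    """Label each track by the region holding the majority of its points.

    Ties are broken by the region containing the first point; tracks with
    most points outside all regions are labelled ``"other"``.
    """
    out: dict[str, str] = {}
    for tr in ts:
        labels = rm.label_points(tr.xyz)
        uniq, counts = np.unique(labels, return_counts=True)
        best = counts.max()
        winners = set(uniq[counts == best])
        if len(winners) == 1:
            out[tr.track_id] = winners.pop()
        else:
            first = labels[0]
            out[tr.track_id] = first if first in winners else sorted(winners)[0]
    return out


def estimate_residence_time(ps: PhotoconversionSeries) -> ResidenceEstimate:
    """Fit an exponential dwell time to a photoconversion ratio series.

    The ratio of resident (photoconverted) to newly arrived (unconverted)
    cells decays as exp(−λt) when residents leave at rate λ and arrivals
    hold steady; a least-squares fit of ln(ratio) against time (hours)
    gives λ = −slope, half-life ln2/λ and mean residence time 1/λ.
    """
    ratio = ps.ratio
    if np.any(ratio <= 0):
        raise MetricError("ratio must be strictly positive at every timepoint")
    res = stats.linregress(ps.times, np.log(ratio))
    lam = -float(res.slope)
    if lam <= 0:
        raise MetricError("no decay detected (non-negative slope): cannot estimate residence time")
    return ResidenceEstimate(
        lambda_rate=lam,
        half_life=LN2 / lam,
        residence_time=1.0 / lam,
        r_squared=float(res.rvalue) ** 2,
    )
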