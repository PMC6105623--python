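"""Cell-track data model, CSV readers/writers and basic track transforms.

A :class:`Track` is the ordered, timestamped sequence of 3D centroid
positions of one cell, in micrometres and seconds, acquired at a nominal
frame interval (30 s for the two-photon protocol this package targets).
Missing frames are retained as gaps — consecutive timestamps must be
integer multiples of ``nominal_dt`` apart and downstream metrics use only
single-frame steps, so positions are never interpolated.

Two CSV dialects are supported:

* ``plain`` — columns ``track_id,t_s,x_um,y_um,z_um`` (the package's
  canonical format; seconds and micrometres).
* ``imaris_position`` — the "Position" export of commercial tracking
  software, by default columns ``Position X/Y/Z``, ``Time``, ``TrackID``.
  Column names and the seconds-per-time-unit factor are configurable since
  export headers vary by software version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ImagingVolume

__all__ = [
    "TrackPoint",
    "Track",
    "TrackSet",
    "PhotoconversionSeries",
    "read_tracks",
    "write_tracks",
    "read_photoconversion",
    "write_photoconversion",
    "recenter_tracks",
    "split_at_volume",
    "IMARIS_DEFAULT_MAP",
]

#: Default column mapping for the ``imaris_position`` dialect.
#: ``time_scale`` converts the file's time unit into seconds.
IMARIS_DEFAULT_MAP = {
    "track_id": "TrackID",
    "t": "Time",
    "x": "Position X",
    "y": "Position Y",
    "z": "Position Z",
    "time_scale": 1.0,
}

_REL_TOL = 1e-6


@dataclass(frozen=True)
class TrackPoint:
    """One spatiotemporal observation: time in seconds, position in μm."""

    t: float
    x: float
    y: float
    z: float

    def __post_init__(self):
        vals = (self.t, self.x, self.y, self.z)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite track point {vals}")
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")


@dataclass(frozen=True)
class Track:
    """An ordered cell track.

    Parameters
    ----------
    track_id : str
        Opaque identifier, unique within a :class:`TrackSet`.
    t : ndarray, shape (n,)
        Strictly increasing timestamps in seconds, gaps allowed as integer
        multiples of ``nominal_dt``.
    xyz : ndarray, shape (n, 3)
        Positions in μm.
    nominal_dt : float
        Sampling interval in seconds.
    """

    track_id: str
    t: np.ndarray
    xyz: np.ndarray
    nominal_dt: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if t.ndim != 1 or len(t) != len(xyz):
            raise ValueError("t and xyz must have matching first dimension")
        if len(t) < 1:
            raise ValueError("a track needs at least one point")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xyz))):
            raise ValueError(f"track {self.track_id!r}: non-finite values")
        if np.any(t < 0):
            raise ValueError(f"track {self.track_id!r}: negative timestamps")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {self.track_id!r}: timestamps not strictly increasing")
        if not (np.isfinite(self.nominal_dt) and self.nominal_dt > 0):
            raise ValueError(f"track {self.track_id!r}: nominal_dt must be > 0")
        steps = np.diff(t) / self.nominal_dt
        if len(steps) and np.any(np.abs(steps - np.rint(steps)) > _REL_TOL * np.maximum(1.0, steps)):
            raise ValueError(
                f"track {self.track_id!r}: frame gaps are not integer multiples "
                f"of nominal_dt={self.nominal_dt}"
            )
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xyz", xyz)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> list[TrackPoint]:
        return [TrackPoint(float(t), *map(float, p)) for t, p in zip(self.t, self.xyz)]

    @property
    def duration(self) -> float:
        """Track duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.t) > self.nominal_dt * (1 + _REL_TOL)))

    def frame_index(self) -> np.ndarray:
        """Integer frame index of each point relative to the first."""
        return np.rint((self.t - self.t[0]) / self.nominal_dt).astype(int)

    def step_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Displacement vectors of single-frame steps.

        Returns ``(disp, start_idx)`` where ``disp[k]`` is the displacement
        over the step starting at point ``start_idx[k]``; steps spanning a
        gap (more than one nominal_dt) are excluded.
        """
        dt = np.diff(self.t)
        ok = np.isclose(dt, self.nominal_dt, rtol=_REL_TOL)
        disp = np.diff(self.xyz, axis=0)[ok]
        return disp, np.nonzero(ok)[0]

    @classmethod
    def from_points(cls, track_id: str, points, nominal_dt: float) -> "Track":
        pts = list(points)
        t = np.array([p.t for p in pts], dtype=float)
        xyz = np.array([[p.x, p.y, p.z] for p in pts], dtype=float)
        return cls(track_id, t, xyz, nominal_dt)


@dataclass(frozen=True)
class TrackSet:
    """A population of tracks plus optional imaging-volume metadata."""

    tracks: tuple
    label: str = ""
    volume: ImagingVolume | None = None

    def __post_init__(self):
        tracks = tuple(self.tracks)
        ids = [tr.track_id for tr in tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate track ids in set: {dupes}")
        object.__setattr__(self, "tracks", tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]

    @property
    def nominal_dt(self) -> float:
        if not self.tracks:
            raise ValueError("empty track set has no nominal_dt")
        dts = {tr.nominal_dt for tr in self.tracks}
        if len(dts) > 1:
            raise ValueError(f"mixed nominal_dt within set: {sorted(dts)}")
        return dts.pop()

    def subset(self, track_ids) -> "TrackSet":
        wanted = set(track_ids)
        return replace(self, tracks=tuple(tr for tr in self.tracks if tr.track_id in wanted))


@dataclass(frozen=True)
class PhotoconversionSeries:
    """Counts of photoconverted vs non-photoconverted cells over time (hours).

    Produced by photoconverting the resident population (Kaede red) and
    following the ratio of resident converted to newly arrived unconverted
    cells over days.
    """

    times: np.ndarray
    converted: np.ndarray
    unconverted: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.converted, dtype=float)
        u = np.asarray(self.unconverted, dtype=float)
        if not (len(t) == len(c) == len(u)):
            raise ValueError("times/converted/unconverted lengths differ")
        if len(t) < 2:
            raise ValueError("photoconversion series needs ≥ 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0) or np.any(u < 0):
            raise ValueError("counts must be ≥ 0")
        if np.any(c + u <= 0):
            raise ValueError("converted + unconverted must be > 0 at each timepoint")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "converted", c)
        object.__setattr__(self, "unconverted", u)

    @property
    def ratio(self) -> np.ndarray:
        return self.converted / self.unconverted


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_PLAIN_COLUMNS = ["track_id", "t_s", "x_um", "y_um", "z_um"]


def read_tracks(
    path,
    dialect: str = "plain",
    column_map: dict | None = None,
    nominal_dt: float | None = None,
    label: str = "",
    volume: ImagingVolume | None = None,
) -> TrackSet:
    """Read a track table into a validated :class:`TrackSet`.

    Rows are grouped by track id and sorted by time; units are converted to
    μm / seconds according to the dialect. ``nominal_dt`` defaults to the
    smallest frame interval observed in the file.
    """
    if dialect == "plain":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _PLAIN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track CSV {path} missing columns {missing}")
        df = df[_PLAIN_COLUMNS].copy()
    elif dialect == "imaris_position":
        cmap = dict(IMARIS_DEFAULT_MAP)
        if column_map:
            cmap.update(column_map)
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [cmap[k] for k in ("track_id", "t", "x", "y", "z") if cmap[k] not in df.columns]
        if missing:
            raise ValueError(f"track CSV {path} missing columns {missing}")
        df = pd.DataFrame(
            {
                "track_id": df[cmap["track_id"]],
                "t_s": df[cmap["t"]] * float(cmap["time_scale"]),
                "x_um": df[cmap["x"]],
                "y_um": df[cmap["y"]],
                "z_um": df[cmap["z"]],
            }
        )
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")

    for col in ("t_s", "x_um", "y_um", "z_um"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["track_id"] = df["track_id"].astype(str)

    dup = df.duplicated(subset=["track_id", "t_s"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (track_id, t) row in {path}: "
            f"track_id={row['track_id']!r} t={row['t_s']}"
        )

    df = df.sort_values(["track_id", "t_s"], kind="stable")
    if nominal_dt is None and len(df):
        gaps = df.groupby("track_id", sort=False)["t_s"].diff().dropna()
        nominal_dt = float(gaps.min()) if len(gaps) else 30.0
    tracks = [
        Track(tid, g["t_s"].to_numpy(), g[["x_um", "y_um", "z_um"]].to_numpy(), nominal_dt)
        for tid, g in df.groupby("track_id", sort=False)
    ]
    return TrackSet(tuple(tracks), label=label, volume=volume)


def write_tracks(ts: TrackSet, path, dialect: str = "plain", column_map: dict | None = None) -> None:
    """Write a TrackSet to CSV; ``read_tracks`` round-trips it exactly."""
    rows = {
        "track_id": [],
        "t_s": [],
        "x_um": [],
        "y_um": [],
        "z_um": [],
    }
    for tr in ts:
        rows["track_id"].extend([tr.track_id] * len(tr))
        rows["t_s"].extend(tr.t)
        rows["x_um"].extend(tr.xyz[:, 0])
        rows["y_um"].extend(tr.xyz[:, 1])
        rows["z_um"].extend(tr.xyz[:, 2])
    df = pd.DataFrame(rows, columns=_PLAIN_COLUMNS)
    if dialect == "plain":
        pass
    elif dialect == "imaris_position":
        cmap = dict(IMARIS_DEFAULT_MAP)
        if column_map:
            cmap.update(column_map)
        df = pd.DataFrame(
            {
                cmap["track_id"]: df["track_id"],
                cmap["t"]: df["t_s"] / float(cmap["time_scale"]),
                cmap["x"]: df["x_um"],
                cmap["y"]: df["y_um"],
                cmap["z"]: df["z_um"],
            }
        )
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    df.to_csv(path, index=False)


def read_photoconversion(path) -> PhotoconversionSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t_h", "converted", "unconverted") if c not in df.columns]
    if missing:
        raise ValueError(f"photoconversion CSV {path} missing columns {missing}")
    df = df.sort_values("t_h")
    return PhotoconversionSeries(
        df["t_h"].to_numpy(float), df["converted"].to_numpy(float), df["unconverted"].to_numpy(float)
    )


def write_photoconversion(ps: PhotoconversionSeries, path) -> None:
    pd.DataFrame(
        {"t_h": ps.times, "converted": ps.converted, "unconverted": ps.unconverted}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Track transforms
# ---------------------------------------------------------------------------


def recenter_tracks(ts: TrackSet, max_tracks: int = 40) -> list[np.ndarray]:
    """Origin-centred xy displacement series for a representative subsample.

    Tracks are ranked by net displacement and at most ``max_tracks`` are
    taken uniformly across that ranking, so the subsample spans the least to
    the most displaced cells. Each returned ``(n, 2)`` array starts at
    ``(0, 0)``.
    """
    if max_tracks < 1:
        raise ValueError("max_tracks must be ≥ 1")
    if len(ts) == 0:
        raise ValueError("empty track set")
    net = np.array([np.linalg.norm(tr.xyz[-1] - tr.xyz[0]) for tr in ts])
    order = np.argsort(net, kind="stable")
    if len(ts) <= max_tracks:
        chosen = order
    else:
        chosen = order[np.rint(np.linspace(0, len(ts) - 1, max_tracks)).astype(int)]
    return [ts[i].xyz[:, :2] - ts[i].xyz[0, :2] for i in chosen]


def split_at_volume(ts: TrackSet, vol: ImagingVolume) -> TrackSet:
    """Crop tracks to an imaging volume, splitting at exits.

    Points outside ``vol`` are removed and each maximal run of consecutive
    in-volume points becomes its own track. A track whose points all lie
    inside keeps its id; fragments get ids ``"<parent>#k"``.
    """
    out = []
    for tr in ts:
        inside = vol.contains(tr.xyz)
        if inside.all():
            out.append(tr)
            continue
        # maximal runs of consecutive in-volume points
        idx = np.nonzero(inside)[0]
        if len(idx) == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, breaks + 1)
        for k, run in enumerate(runs):
            out.append(Track(f"{tr.track_id}#{k}", tr.t[run], tr.xyz[run], tr.nominal_dt))
    return TrackSet(tuple(out), label=ts.label, volume=vol)
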