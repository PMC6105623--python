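"""Labelled 3D geometry: imaging volumes, surface models and tissue regions.

Coordinates are right-handed micrometre axes with z increasing with imaging
depth (z = 0 at the capsule for a lymph-node stack). Surfaces are unions of
spheres (points are radius-0 spheres); regions are unions of spheres and
axis-aligned boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sphere",
    "Box",
    "ImagingVolume",
    "SurfaceModel",
    "RegionModel",
    "read_surface",
    "read_regions",
    "write_geometry",
]


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite 3-vector: {v!r}")
    return a


@dataclass(frozen=True)
class Sphere:
    """Sphere primitive (centre in μm, radius ≥ 0; radius 0 is a point)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        if not (np.isfinite(self.radius) and self.radius >= 0):
            raise ValueError(f"sphere radius must be ≥ 0, got {self.radius}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return np.linalg.norm(pts - self.center, axis=1) <= self.radius

    def distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance from points to the sphere surface, 0 inside."""
        pts = np.atleast_2d(pts)
        d = np.linalg.norm(pts - self.center, axis=1) - self.radius
        return np.maximum(d, 0.0)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by centre and full edge lengths (μm)."""

    center: np.ndarray
    extent: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        object.__setattr__(self, "extent", _as_vec3(self.extent))
        if not np.all(self.extent > 0):
            raise ValueError(f"box extents must be > 0, got {self.extent}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        half = self.extent / 2.0
        return np.all(np.abs(pts - self.center) <= half, axis=1)

    def distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        half = self.extent / 2.0
        d = np.maximum(np.abs(pts - self.center) - half, 0.0)
        return np.linalg.norm(d, axis=1)


@dataclass(frozen=True)
class ImagingVolume:
    """Axis-aligned recording volume: origin corner plus positive extents."""

    origin: np.ndarray
    extent: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_vec3(self.origin))
        object.__setattr__(self, "extent", _as_vec3(self.extent))
        if not np.all(self.extent > 0):
            raise ValueError(f"imaging-volume extents must be > 0, got {self.extent}")

    @property
    def center(self) -> np.ndarray:
        return self.origin + self.extent / 2.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rel = pts - self.origin
        return np.all((rel >= 0.0) & (rel <= self.extent), axis=1)

    def inflate(self, margin: float) -> "ImagingVolume":
        return ImagingVolume(self.origin - margin, self.extent + 2.0 * margin)


@dataclass(frozen=True)
class SurfaceModel:
    """A labelled surface as a non-empty union of spheres/points.

    Used for the CD169+ subcapsular-sinus macrophage layer: each stained
    macrophage body is one sphere; distance queries return the distance to
    the nearest primitive surface, floored at zero for interior points.
    """

    label: str
    primitives: tuple = ()

    def __post_init__(self):
        prims = tuple(self.primitives)
        if not prims:
            raise ValueError("SurfaceModel needs at least one primitive")
        if not all(isinstance(p, Sphere) for p in prims):
            raise ValueError("SurfaceModel primitives must be spheres (radius ≥ 0)")
        object.__setattr__(self, "primitives", prims)

    def distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = np.min([p.distance(pts) for p in self.primitives], axis=0)
        return d


@dataclass(frozen=True)
class RegionModel:
    """Named tissue compartments (e.g. SPF / FM / GC), each a union of primitives.

    Membership is tested per region in insertion order; a point inside no
    region belongs to the implicit label ``"other"``.
    """

    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.regions:
            raise ValueError("RegionModel needs at least one region")
        for label, prims in self.regions.items():
            if not prims:
                raise ValueError(f"region {label!r} is empty")

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """Label each point by the first region containing it, else 'other'."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        labels = np.full(len(pts), "other", dtype=object)
        unassigned = np.ones(len(pts), dtype=bool)
        for label, prims in self.regions.items():
            inside = np.zeros(len(pts), dtype=bool)
            for p in prims:
                inside |= p.contains(pts)
            take = inside & unassigned
            labels[take] = label
            unassigned &= ~inside
        return labels


_GEOM_COLUMNS = ["label", "shape", "cx", "cy", "cz", "r_or_ex", "ey", "ez"]


def _read_geometry_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _GEOM_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"geometry CSV {path} missing columns {missing}")
    return df


def _row_primitive(row):
    center = (row["cx"], row["cy"], row["cz"])
    if row["shape"] == "sphere":
        return Sphere(center, float(row["r_or_ex"]))
    if row["shape"] == "box":
        return Box(center, (row["r_or_ex"], row["ey"], row["ez"]))
    raise ValueError(f"unknown primitive shape {row['shape']!r}")


def read_surface(path, label: str | None = None) -> SurfaceModel:
    """Read a sphere-set surface model from geometry CSV."""
    df = _read_geometry_table(path)
    if label is not None:
        df = df[df["label"] == label]
    prims = [_row_primitive(r) for _, r in df.iterrows()]
    lab = label if label is not None else (df["label"].iloc[0] if len(df) else "surface")
    return SurfaceModel(lab, prims)


def read_regions(path) -> RegionModel:
    """Read a labelled region model (boxes and spheres) from geometry CSV."""
    df = _read_geometry_table(path)
    regions: dict[str, list] = {}
    for _, row in df.iterrows():
        regions.setdefault(str(row["label"]), []).append(_row_primitive(row))
    return RegionModel(regions)


def write_geometry(primitives_by_label: dict, path) -> None:
    rows = []
    for label, prims in primitives_by_label.items():
        for p in prims:
            if isinstance(p, Sphere):
                rows.append([label, "sphere", *p.center, p.radius, "", ""])
            else:
                rows.append([label, "box", *p.center, *p.extent])
    pd.DataFrame(rows, columns=_GEOM_COLUMNS).to_csv(path, index=False)
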