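"""Per-taxon range metrics: Extent of Occurrence and Area of Occupancy.

EOO is the area of the minimum convex polygon (MCP) around the occurrence
points, the standard construction in IUCN Red List criterion B. AOO counts
occupied cells on a fixed square grid (IUCN default 2 km cell width) and
multiplies by cell area. Both are computed on an equal-area projection so
that the MCP area and range-size thresholds are meaningful in km².

A Lambert cylindrical equal-area projection on the authalic sphere is used:

    x = R (λ − λ0) cos φs,   y = R sin φ / cos φs

with R the authalic Earth radius and φs the standard parallel. The forward
and inverse maps are exact closed forms, so round-trip error is limited by
floating point only, and the projection is exactly area-preserving on the
sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint

from .errors import IntegrityError, ParameterError
from .occurrences import OccurrenceRecord

#: Authalic Earth radius, km (sphere with the same surface area as WGS84).
EARTH_RADIUS_KM = 6371.0072

#: A hull thinner than this (km²) is treated as collinear/degenerate.
COLLINEAR_AREA_TOL_KM2 = 1e-9


@dataclass(frozen=True)
class EqualAreaProjection:
    """Lambert cylindrical equal-area projection centred on (lon0, lat_ts)."""

    lon0: float = 0.0
    lat_ts: float = 0.0

    def forward(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lon-lat degrees → planar (x, y) in km."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        c = math.cos(math.radians(self.lat_ts))
        dlon = (lons - self.lon0 + 180.0) % 360.0 - 180.0
        x = EARTH_RADIUS_KM * np.radians(dlon) * c
        y = EARTH_RADIUS_KM * np.sin(np.radians(lats)) / c
        return x, y

    def inverse(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Planar km → lon-lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = math.cos(math.radians(self.lat_ts))
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_KM * c))
        lat = np.degrees(np.arcsin(np.clip(y * c / EARTH_RADIUS_KM, -1.0, 1.0)))
        return lon, lat

    @classmethod
    def for_points(cls, points: Sequence[tuple[float, float]]) -> "EqualAreaProjection":
        """Projection centred on the lon-lat centroid of a point set."""
        arr = np.asarray(points, dtype=float)
        return cls(lon0=float(arr[:, 0].mean()), lat_ts=float(arr[:, 1].mean()))


@dataclass(frozen=True)
class GridParams:
    """Parameters of the AOO occupancy grid and the working projection.

    ``projection`` of ``None`` means: centre an equal-area projection on the
    centroid of the points of each call. Fixing a projection instead makes
    grids comparable across calls (and AOO monotone under point addition).
    """

    aoo_cell_width_km: float = 2.0
    aoo_grid_origin: tuple[float, float] = (0.0, 0.0)
    projection: EqualAreaProjection | None = None

    def __post_init__(self) -> None:
        if self.aoo_cell_width_km <= 0:
            raise ParameterError(
                f"aoo_cell_width_km must be > 0, got {self.aoo_cell_width_km}"
            )

    def resolve_projection(self, points: Sequence[tuple[float, float]]) -> EqualAreaProjection:
        if self.projection is not None:
            return self.projection
        return EqualAreaProjection.for_points(points)


@dataclass
class RangeMetrics:
    """EOO/AOO and point counts for one taxon, globally and inside/outside
    the focal country."""

    taxon_id: str
    eoo_km2: float
    aoo_km2: float
    n_points: int
    n_unique_points: int
    n_aoo_cells: int
    inside_fraction: float
    eoo_outside_km2: float
    n_outside_points: int
    eoo_is_fallback: bool

    @property
    def eoo_effective_km2(self) -> float:
        """Fallback-aware EOO: never below AOO (degenerate hulls use AOO)."""
        return max(self.eoo_km2, self.aoo_km2)


def project_points(
    points: Sequence[tuple[float, float]],
    projection: EqualAreaProjection,
) -> list[tuple[float, float]]:
    """Project lon-lat pairs to planar km coordinates. Empty in → empty out."""
    if len(points) == 0:
        return []
    arr = np.asarray(points, dtype=float)
    x, y = projection.forward(arr[:, 0], arr[:, 1])
    return list(zip(x.tolist(), y.tolist()))


def _hull_area_km2(xy: np.ndarray) -> float:
    """Convex hull area of projected points; 0 for degenerate hulls."""
    return float(MultiPoint(xy).convex_hull.area)


def compute_aoo(
    points: Sequence[tuple[float, float]], grid: GridParams
) -> tuple[float, int]:
    """Area of Occupancy: occupied grid cells × cell area.

    Cells are axis-aligned squares of ``aoo_cell_width_km`` anchored at
    ``aoo_grid_origin`` in projected space.
    """
    if len(points) == 0:
        raise ParameterError("compute_aoo requires at least one point")
    proj = grid.resolve_projection(points)
    arr = np.asarray(points, dtype=float)
    x, y = proj.forward(arr[:, 0], arr[:, 1])
    w = grid.aoo_cell_width_km
    ox, oy = grid.aoo_grid_origin
    ix = np.floor((x - ox) / w).astype(np.int64)
    iy = np.floor((y - oy) / w).astype(np.int64)
    n_cells = len(set(zip(ix.tolist(), iy.tolist())))
    return n_cells * w * w, n_cells


def compute_eoo(
    points: Sequence[tuple[float, float]], grid: GridParams
) -> tuple[float, bool]:
    """Extent of Occurrence: MCP area in km², with the AOO fallback.

    With fewer than 3 non-collinear unique points the hull is degenerate;
    standard batch Red List practice then substitutes AOO for EOO, flagged
    via the returned boolean.
    """
    if len(points) == 0:
        raise ParameterError("compute_eoo requires at least one point")
    proj = grid.resolve_projection(points)
    arr = np.asarray(points, dtype=float)
    x, y = proj.forward(arr[:, 0], arr[:, 1])
    xy = np.unique(np.column_stack([x, y]), axis=0)
    if len(xy) >= 3:
        area = _hull_area_km2(xy)
        if area >= COLLINEAR_AREA_TOL_KM2:
            return area, False
    aoo_km2, _ = compute_aoo(points, grid)
    return aoo_km2, True


def compute_range_metrics(
    taxon_id: str,
    records: Sequence[OccurrenceRecord],
    grid: GridParams | None = None,
) -> RangeMetrics:
    """Fill every range-metric field for one taxon.

    Requires that :func:`~endemapper.occurrences.assign_country` has run
    (``inside_focal`` set on every record). Duplicate coordinates collapse
    for the hull and cell counts but are retained in ``n_points`` and
    ``inside_fraction``.
    """
    if grid is None:
        grid = GridParams()
    if len(records) == 0:
        raise ParameterError(f"no records for taxon {taxon_id!r}")
    for r in records:
        if r.taxon_id != taxon_id:
            raise IntegrityError(
                f"record {r.record_id} belongs to {r.taxon_id!r}, not {taxon_id!r}"
            )
        if r.inside_focal is None:
            raise IntegrityError(
                f"record {r.record_id} has unassigned inside_focal; "
                "run assign_country first"
            )
    pts = [(r.longitude, r.latitude) for r in records]
    # One projection for all partitions of this taxon's points.
    proj = grid.resolve_projection(pts)
    g = GridParams(grid.aoo_cell_width_km, grid.aoo_grid_origin, proj)

    eoo_km2, fallback = compute_eoo(pts, g)
    aoo_km2, n_cells = compute_aoo(pts, g)
    n_unique = len({p for p in pts})
    inside = [r for r in records if r.inside_focal]
    outside = [r for r in records if not r.inside_focal]
    out_pts = [(r.longitude, r.latitude) for r in outside]
    if len({p for p in out_pts}) < 3:
        eoo_outside = 0.0
    else:
        eoo_outside, _ = compute_eoo(out_pts, g)
    return RangeMetrics(
        taxon_id=taxon_id,
        eoo_km2=eoo_km2,
        aoo_km2=aoo_km2,
        n_points=len(records),
        n_unique_points=n_unique,
        n_aoo_cells=n_cells,
        inside_fraction=len(inside) / len(records),
        eoo_outside_km2=eoo_outside,
        n_outside_points=len(outside),
        eoo_is_fallback=fallback,
    )
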