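"""Hexagonal-grid richness and weighted endemism.

The analysis grid is a tiling of pointy-top hexagons of fixed angular
height (default a quarter degree, point to point) built directly in lon-lat
space. Cells are indexed by (row, col) in odd-row-offset coordinates; the
tiling is analytic, so any point on Earth maps to a cell without
pre-building a bounded grid (the bounded grid is only materialised for
output and mapping).

Per-taxon weights combine the inverse of the two range metrics, each
normalised by the smallest value in the analysis set so the
narrowest-ranged taxon scores 1:

    w = ( min(AOO)/AOO + min(EOO*)/EOO* ) / 2,   EOO* = max(EOO, AOO)

Weighted endemism of a cell is the sum of the weights of the taxa recorded
in it; richness is the count of distinct taxa (species, subspecies and
varieties each counted as units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon

from .errors import IntegrityError, ParameterError
from .occurrences import OccurrenceRecord
from .ranges import RangeMetrics

SQRT3 = math.sqrt(3.0)

#: Distances within this (degrees) of the minimum count as ties for the
#: boundary tie-break.
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class HexGridSpec:
    """Pointy-top hexagon tiling of fixed angular height.

    ``origin`` is the lon-lat centre of cell (0, 0). ``hex_height_deg`` is
    the vertical point-to-point extent, i.e. twice the circumradius.
    """

    hex_height_deg: float = 0.25
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.hex_height_deg <= 0:
            raise ParameterError("hex_height_deg must be > 0")

    @property
    def circumradius(self) -> float:
        return self.hex_height_deg / 2.0

    @property
    def width(self) -> float:
        """Horizontal extent of a cell (flat-to-flat), = column spacing."""
        return SQRT3 * self.circumradius

    # -- coordinate conversions ------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        r = self.circumradius
        x = self.origin[0] + self.width * (col + 0.5 * (row & 1))
        y = self.origin[1] + 1.5 * r * row
        return x, y

    def cell_polygon(self, row: int, col: int) -> Polygon:
        cx, cy = self.cell_center(row, col)
        r = self.circumradius
        verts = [
            (cx + r * math.cos(a), cy + r * math.sin(a))
            for a in (math.radians(30 + 60 * k) for k in range(6))
        ]
        return Polygon(verts)

    def _axial_to_offset(self, q: int, r: int) -> tuple[int, int]:
        return r, q + (r - (r & 1)) // 2

    def cell_of_point(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a lon-lat point.

        Cells are the Voronoi regions of the hexagon centres, so the
        containing cell is the nearest centre; points equidistant from
        several centres (shared edges/vertices) go to the lexicographically
        smallest (row, col).
        """
        px = lon - self.origin[0]
        py = lat - self.origin[1]
        rad = self.circumradius
        qf = (SQRT3 / 3.0 * px - py / 3.0) / rad
        rf = (2.0 / 3.0 * py) / rad
        q0, r0 = _cube_round(qf, rf)
        # Check the rounded cell and its six axial neighbours; ties resolve
        # to the smallest (row, col).
        best: tuple[int, int] | None = None
        best_d = math.inf
        for dq, dr in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)):
            q, r = q0 + dq, r0 + dr
            row, col = self._axial_to_offset(q, r)
            cx, cy = self.cell_center(row, col)
            d = (lon - cx) ** 2 + (lat - cy) ** 2
            if d < best_d - _TIE_TOL:
                best, best_d = (row, col), d
            elif d <= best_d + _TIE_TOL and best is not None and (row, col) < best:
                best = (row, col)
        assert best is not None
        return best


def _cube_round(qf: float, rf: float) -> tuple[int, int]:
    sf = -qf - rf
    q, r, s = round(qf), round(rf), round(sf)
    dq, dr, ds = abs(q - qf), abs(r - rf), abs(s - sf)
    if dq > dr and dq > ds:
        q = -r - s
    elif dr > ds:
        r = -q - s
    return int(q), int(r)


@dataclass(frozen=True)
class TaxonWeight:
    """Per-taxon endemism weight and its two components, each in (0, 1]."""

    taxon_id: str
    weight: float
    aoo_component: float
    eoo_component: float


@dataclass
class CellStats:
    """One hexagonal cell of the output grid."""

    cell_id: tuple[int, int]
    polygon: Polygon
    richness: int
    weighted_endemism: float


def build_hexgrid(
    bbox: tuple[float, float, float, float], spec: HexGridSpec | None = None
) -> list[tuple[tuple[int, int], Polygon]]:
    """Materialise all cells intersecting a (minx, miny, maxx, maxy) bbox.

    The returned cells tile the bbox: every point of it is covered, shared
    edges belonging to the lexicographically smaller cell under the
    assignment tie-break.
    """
    if spec is None:
        spec = HexGridSpec()
    minx, miny, maxx, maxy = bbox
    if not (maxx > minx and maxy > miny):
        raise ParameterError(f"degenerate bbox {bbox}")
    r = spec.circumradius
    w = spec.width
    row_lo = math.floor((miny - spec.origin[1] - r) / (1.5 * r)) - 1
    row_hi = math.ceil((maxy - spec.origin[1] + r) / (1.5 * r)) + 1
    col_lo = math.floor((minx - spec.origin[0] - w) / w) - 1
    col_hi = math.ceil((maxx - spec.origin[0] + w) / w) + 1
    from shapely.geometry import box

    bb = box(minx, miny, maxx, maxy)
    cells = []
    for row in range(row_lo, row_hi + 1):
        for col in range(col_lo, col_hi + 1):
            poly = spec.cell_polygon(row, col)
            if poly.intersects(bb):
                cells.append(((row, col), poly))
    return cells


def assign_to_cells(
    records: Sequence[OccurrenceRecord], spec: HexGridSpec | None = None
) -> dict[tuple[int, int], set[str]]:
    """Map each record to exactly one cell; returns cell → set of taxon ids.

    The tiling is analytic, so points outside any previously built bbox are
    still assigned (the grid auto-expands).
    """
    if spec is None:
        spec = HexGridSpec()
    members: dict[tuple[int, int], set[str]] = {}
    for rec in records:
        cell = spec.cell_of_point(rec.longitude, rec.latitude)
        members.setdefault(cell, set()).add(rec.taxon_id)
    return members


def taxon_weight(
    metrics: RangeMetrics, ref_aoo_km2: float, ref_eoo_km2: float
) -> TaxonWeight:
    """Endemism weight from min-normalised inverse AOO and inverse EOO.

    ``ref_aoo_km2``/``ref_eoo_km2`` are the minima of AOO and fallback-aware
    EOO over the analysis taxon set, so every component lies in (0, 1] and
    the narrowest-ranged taxon weighs exactly 1.
    """
    if metrics.aoo_km2 <= 0 or metrics.eoo_effective_km2 <= 0:
        raise IntegrityError(f"taxon {metrics.taxon_id}: zero-area range metrics")
    if ref_aoo_km2 <= 0 or ref_eoo_km2 <= 0:
        raise ParameterError("reference areas must be > 0")
    aoo_c = ref_aoo_km2 / metrics.aoo_km2
    eoo_c = ref_eoo_km2 / metrics.eoo_effective_km2
    return TaxonWeight(metrics.taxon_id, 0.5 * (aoo_c + eoo_c), aoo_c, eoo_c)


def compute_weights(metrics: Iterable[RangeMetrics]) -> dict[str, TaxonWeight]:
    """Weights for an analysis set, references taken as the set's minima."""
    ms = list(metrics)
    if not ms:
        return {}
    ref_aoo = min(m.aoo_km2 for m in ms)
    ref_eoo = min(m.eoo_effective_km2 for m in ms)
    return {m.taxon_id: taxon_weight(m, ref_aoo, ref_eoo) for m in ms}


def cell_weighted_endemism(
    cell_members: Mapping[tuple[int, int], set[str]],
    weights: Mapping[str, TaxonWeight],
    spec: HexGridSpec | None = None,
) -> list[CellStats]:
    """Per-cell richness and summed weighted endemism.

    Only occupied cells are returned. A widespread taxon contributes its
    single weight to every cell it occurs in.
    """
    if spec is None:
        spec = HexGridSpec()
    out = []
    for cell_id in sorted(cell_members):
        taxa = cell_members[cell_id]
        missing = [t for t in taxa if t not in weights]
        if missing:
            raise IntegrityError(f"cell {cell_id}: taxa without weights: {missing}")
        out.append(
            CellStats(
                cell_id=cell_id,
                polygon=spec.cell_polygon(*cell_id),
                richness=len(taxa),
                weighted_endemism=sum(weights[t].weight for t in taxa),
            )
        )
    return out


def rank_cells(
    cells: Sequence[CellStats], by: str = "richness", top_n: int = 10
) -> list[CellStats]:
    """Top cells in descending order of one metric.

    Ties are broken by the other metric (descending), then by cell id.
    """
    if by not in ("richness", "weighted_endemism"):
        raise ParameterError(f"rank_cells: unknown metric {by!r}")
    if top_n < 1:
        raise ParameterError("top_n must be >= 1")
    other = "weighted_endemism" if by == "richness" else "richness"
    ordered = sorted(
        cells,
        key=lambda c: (-getattr(c, by), -getattr(c, other), c.cell_id),
    )
    return ordered[:top_n]
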