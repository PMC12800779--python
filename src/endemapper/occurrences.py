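"""Occurrence-record and checklist I/O, precision filtering and country assignment.

Occurrence files are delimited text (comma or tab) with Darwin Core-style
headers; polygons are GeoJSON in WGS84 lon-lat order. Records with
out-of-bounds or unparseable coordinates are rejected (never clamped) and
each rejection is logged with its reason.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .errors import ConfigurationError, GeometryError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Default Darwin Core-style header mapping for occurrence files.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "record_id": "occurrenceID",
    "taxon_id": "taxonID",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "uncertainty_m": "coordinateUncertaintyInMeters",
    "country_code": "countryCode",
    "collector": "recordedBy",
    "year": "year",
}

#: Columns that must be present; the rest are optional and default to missing.
REQUIRED_FIELDS = ("taxon_id", "latitude", "longitude")

GROWTH_FORMS = ("tree", "shrub", "liana", "herb", "pteridophyte", "cycad")
GROWTH_SUBCATEGORIES = ("a", "p", "s", "e", "c", "geo", "gram-a", "gram-p")
REDLIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD", "NE")
RANKS = ("species", "subspecies", "variety")


@dataclass
class OccurrenceRecord:
    """One georeferenced record of a taxon.

    ``inside_focal`` is tri-state: ``None`` until :func:`assign_country`
    has run, then strictly ``True``/``False`` (boundary points count as
    inside).
    """

    record_id: str
    taxon_id: str
    latitude: float
    longitude: float
    uncertainty_m: float | None = None
    country_code: str | None = None
    collector: str | None = None
    year: int | None = None
    inside_focal: bool | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValidationError(f"longitude {self.longitude} outside [-180, 180]")
        if self.uncertainty_m is not None and self.uncertainty_m < 0:
            raise ValidationError(f"uncertainty_m {self.uncertainty_m} is negative")


@dataclass
class TaxonRecord:
    """Checklist entry: identity, rank, growth forms, Red List category, flags.

    ``growth_forms`` holds tokens like ``"tree"`` or ``"herb:p"`` (main
    category with optional sub-category after a colon); a taxon with
    variation in growth form or life cycle carries several tokens.
    """

    taxon_id: str
    accepted_name: str
    rank: str
    family: str
    genus: str = ""
    growth_forms: frozenset[str] = frozenset()
    basionym_year: int | None = None
    redlist_category: str = "NE"
    is_hybrid: bool = False
    is_undescribed: bool = False
    floristic_regions: frozenset[str] = frozenset()
    region_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.growth_forms = frozenset(self.growth_forms)
        self.floristic_regions = frozenset(self.floristic_regions)
        self.region_ids = frozenset(self.region_ids)
        if self.rank not in RANKS:
            raise ValidationError(f"rank {self.rank!r} not one of {RANKS}")
        if self.redlist_category not in REDLIST_CATEGORIES:
            raise ValidationError(
                f"unknown Red List category {self.redlist_category!r}"
            )
        for token in self.growth_forms:
            main = token.split(":", 1)[0]
            if main not in GROWTH_FORMS:
                raise ValidationError(f"unknown growth form {token!r}")
        if not self.genus:
            self.genus = self.accepted_name.split()[0] if self.accepted_name else ""

    @property
    def species_key(self) -> tuple[str, str]:
        """Species-level aggregation key (genus, epithet)."""
        parts = self.accepted_name.split()
        epithet = parts[1] if len(parts) > 1 else ""
        return (self.genus, epithet)


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    header = path.open(encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[OccurrenceRecord]:
    """Read occurrence records from a delimited text file.

    Parameters
    ----------
    path
        Delimited text file (UTF-8) with a header row.
    column_map
        Mapping from :class:`OccurrenceRecord` field names to file column
        names; defaults to Darwin Core-style names. Fields absent from the
        mapping (or whose column is absent for optional fields) are read as
        missing.
    delimiter
        Field delimiter; auto-detected among comma/tab when ``None``.

    Returns
    -------
    list of OccurrenceRecord
        One record per well-formed row, input order preserved. Malformed
        rows (unparseable or out-of-bounds coordinates) are rejected and
        logged; the total rejected count is logged at the end.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"occurrence file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map is not None:
        cmap.update(column_map)
    delim = _sniff_delimiter(path, delimiter)

    records: list[OccurrenceRecord] = []
    n_rejected = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for fld in REQUIRED_FIELDS:
            col = cmap.get(fld)
            if col is None or col not in header:
                raise ConfigurationError(
                    f"required column {col!r} (field {fld!r}) missing from header"
                )
        for i, row in enumerate(reader):
            try:
                records.append(_parse_row(row, cmap, header, i))
            except (ValidationError, ValueError) as exc:
                n_rejected += 1
                logger.warning("rejected row %d: %s", i + 2, exc)
    if n_rejected:
        logger.warning("rejected %d of %d data rows", n_rejected, n_rejected + len(records))
    return records


def _get(row: Mapping[str, str], cmap: Mapping[str, str], header: Sequence[str], fld: str) -> str | None:
    col = cmap.get(fld)
    if col is None or col not in header:
        return None
    val = row.get(col)
    if val is None or val.strip() == "":
        return None
    return val.strip()


def _parse_row(
    row: Mapping[str, str], cmap: Mapping[str, str], header: Sequence[str], idx: int
) -> OccurrenceRecord:
    lat_s = _get(row, cmap, header, "latitude")
    lon_s = _get(row, cmap, header, "longitude")
    if lat_s is None or lon_s is None:
        raise ValidationError("missing coordinate")
    unc = _get(row, cmap, header, "uncertainty_m")
    year = _get(row, cmap, header, "year")
    return OccurrenceRecord(
        record_id=_get(row, cmap, header, "record_id") or f"row{idx}",
        taxon_id=_get(row, cmap, header, "taxon_id") or "",
        latitude=float(lat_s),
        longitude=float(lon_s),
        uncertainty_m=float(unc) if unc is not None else None,
        country_code=_get(row, cmap, header, "country_code"),
        collector=_get(row, cmap, header, "collector"),
        year=int(year) if year is not None else None,
    )


def write_occurrences(
    records: Iterable[OccurrenceRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write records as delimited text with Darwin Core-style headers."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map is not None:
        cmap.update(column_map)
    fields = list(cmap)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([cmap[f] for f in fields])
        for rec in records:
            row = []
            for f in fields:
                v = getattr(rec, f)
                row.append("" if v is None else (repr(v) if isinstance(v, float) else str(v)))
            writer.writerow(row)


def filter_by_precision(
    records: Sequence[OccurrenceRecord],
    max_uncertainty_m: float = 10_000.0,
    keep_missing: bool = True,
) -> list[OccurrenceRecord]:
    """Drop records with coordinate uncertainty above a threshold.

    Records with no stated uncertainty are kept by default: localities
    georeferenced from gazetteers often lack an explicit precision but are
    still usable at the grid scales analysed here.

    Never mutates its input; output order follows input order.
    """
    if max_uncertainty_m <= 0:
        raise ParameterError(f"max_uncertainty_m must be > 0, got {max_uncertainty_m}")
    out = []
    for rec in records:
        if rec.uncertainty_m is None:
            if keep_missing:
                out.append(rec)
        elif rec.uncertainty_m <= max_uncertainty_m:
            out.append(rec)
    return out


def assign_country(
    records: Sequence[OccurrenceRecord],
    focal_polygon: Polygon | MultiPolygon,
) -> list[OccurrenceRecord]:
    """Mark each record as inside or outside the focal country.

    Points exactly on the boundary count as inside (ties favour endemism,
    the conservative call for conservation). Returns new records; inputs
    are not mutated.
    """
    if focal_polygon.is_empty or not focal_polygon.is_valid:
        raise GeometryError("focal polygon is empty or invalid")
    pts = shapely.points(
        [r.longitude for r in records], [r.latitude for r in records]
    )
    shapely.prepare(focal_polygon)
    inside = shapely.covers(focal_polygon, pts)
    return [replace(r, inside_focal=bool(b)) for r, b in zip(records, inside)]


# ---------------------------------------------------------------------------
# Checklist and polygon I/O


def read_checklist(path: str | Path, delimiter: str | None = None) -> list[TaxonRecord]:
    """Read a taxon checklist from delimited text.

    Expected columns: taxon_id, accepted_name, rank, family, growth_forms
    (semicolon-separated tokens), basionym_year, redlist_category,
    is_hybrid, is_undescribed, floristic_regions, region_ids
    (semicolon-separated). Missing optional columns default to empty.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"checklist file not found: {path}")
    delim = _sniff_delimiter(path, delimiter)
    taxa = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for row in reader:
            get = lambda k: (row.get(k) or "").strip()  # noqa: E731
            taxa.append(
                TaxonRecord(
                    taxon_id=get("taxon_id"),
                    accepted_name=get("accepted_name"),
                    rank=get("rank") or "species",
                    family=get("family"),
                    genus=get("genus"),
                    growth_forms=frozenset(t for t in get("growth_forms").split(";") if t),
                    basionym_year=int(get("basionym_year")) if get("basionym_year") else None,
                    redlist_category=get("redlist_category") or "NE",
                    is_hybrid=get("is_hybrid").lower() in ("true", "1", "yes"),
                    is_undescribed=get("is_undescribed").lower() in ("true", "1", "yes"),
                    floristic_regions=frozenset(t for t in get("floristic_regions").split(";") if t),
                    region_ids=frozenset(t for t in get("region_ids").split(";") if t),
                )
            )
    return taxa


def write_checklist(taxa: Iterable[TaxonRecord], path: str | Path) -> None:
    cols = [
        "taxon_id", "accepted_name", "rank", "family", "genus", "growth_forms",
        "basionym_year", "redlist_category", "is_hybrid", "is_undescribed",
        "floristic_regions", "region_ids",
    ]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for t in taxa:
            writer.writerow([
                t.taxon_id, t.accepted_name, t.rank, t.family, t.genus,
                ";".join(sorted(t.growth_forms)),
                "" if t.basionym_year is None else t.basionym_year,
                t.redlist_category, t.is_hybrid, t.is_undescribed,
                ";".join(sorted(t.floristic_regions)),
                ";".join(sorted(t.region_ids)),
            ])


def read_polygon(path: str | Path) -> Polygon | MultiPolygon:
    """Read the first Polygon/MultiPolygon from a GeoJSON file (WGS84 lon-lat)."""
    with Path(path).open(encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = shape(gj["features"][0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise GeometryError(f"expected Polygon/MultiPolygon, got {geom.geom_type}")
    if not geom.is_valid:
        raise GeometryError("polygon in file is invalid")
    return geom


def write_geojson(
    geoms: Sequence, path: str | Path, properties: Sequence[Mapping] | None = None
) -> None:
    """Write geometries (with optional per-feature properties) as GeoJSON."""
    props = properties if properties is not None else [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
            for g, p in zip(geoms, props)
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(fc, fh, indent=None, separators=(",", ":"), sort_keys=True)
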