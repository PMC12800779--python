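"""Seeded synthetic inputs: country and region polygons, a taxon checklist
and clustered occurrence records.

The generator stands in for a national occurrence database. It emulates the
statistical structure the downstream analysis assumes:

* a convex, irregular focal-country polygon a few hundred km across,
  partitioned into ecoregion-like polygons;
* "montane hotspot" centres inside the country around which strict endemics
  cluster;
* four taxon classes with controlled range sizes and inside-country
  fractions — strict endemics (every record inside), two flavours of
  cross-border near-endemics (NE1: majority inside with a tight cluster
  beyond the border; NE2: small global range straddling the border) and
  widespread taxa (large ranges, minority of records inside);
* variable georeference precision (precise / coarse / missing uncertainty)
  and Red List category labels.

Point clouds are isotropic bivariate normals whose spread is calibrated so
the expected minimum-convex-polygon area matches the class's target extent
of occurrence: E[hull area] of n Gaussian points scales exactly as
sigma^2 x f(n), so f(n) is estimated once per n by pilot simulation and
sigma solved in closed form. A truth table records every taxon's
generating class and targets for recovery tests.

All randomness flows from one root seed through named substreams, so
adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .errors import ValidationError
from .occurrences import (
    OccurrenceRecord,
    TaxonRecord,
    write_checklist,
    write_geojson,
    write_occurrences,
)
from .ranges import EqualAreaProjection

CLASSES = ("strict_endemic", "near_endemic_ne1", "near_endemic_ne2", "widespread")
EXPECTED_STATUS = {
    "strict_endemic": "E",
    "near_endemic_ne1": "NE",
    "near_endemic_ne2": "NE",
    "widespread": "NOT",
}

_FAMILIES = [
    "Asteraceae", "Asphodelaceae", "Asparagaceae", "Orchidaceae", "Cyperaceae",
    "Rubiaceae", "Fabaceae", "Rosaceae", "Acanthaceae", "Euphorbiaceae",
    "Lamiaceae", "Poaceae", "Apocynaceae", "Malvaceae", "Melastomataceae",
    "Balsaminaceae", "Crassulaceae", "Ericaceae", "Gesneriaceae", "Zamiaceae",
]

_GROWTH_TOKENS = [
    "herb:p", "herb:a", "herb:s", "herb:e", "herb:c", "herb:geo",
    "herb:gram-a", "herb:gram-p", "shrub", "shrub:s", "tree", "tree:s",
    "liana", "pteridophyte", "cycad",
]
_GROWTH_PROBS = [
    0.30, 0.08, 0.05, 0.04, 0.04, 0.05, 0.02, 0.04, 0.14, 0.02, 0.11, 0.02,
    0.05, 0.02, 0.02,
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study system. The defaults describe a
    mid-sized tropical country near the equator, a checklist of 200
    candidate taxa most of which are endemic or near-endemic, and about
    25 records per taxon (≈5,000 records in total)."""

    seed: int = 0
    n_taxa: int = 200
    mix: tuple[float, float, float, float] = (0.35, 0.15, 0.25, 0.25)
    n_hotspots: int = 5
    n_regions: int = 8
    points_mean: float = 25.0
    points_dispersion: float = 5.0  # negative-binomial shape k
    points_min: int = 5
    # per-class log-uniform bounds for the target EOO, km²
    range_scale_km2: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "strict_endemic": (50.0, 5_000.0),
            "near_endemic_ne1": (2_000.0, 30_000.0),
            "near_endemic_ne2": (1_000.0, 8_000.0),
            "widespread": (50_000.0, 500_000.0),
        }
    )
    # per-class uniform bounds for the inside-country record fraction
    inside_fraction_target: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "strict_endemic": (1.0, 1.0),
            "near_endemic_ne1": (0.70, 0.90),
            "near_endemic_ne2": (0.50, 0.70),
            "widespread": (0.15, 0.45),
        }
    )
    uncertainty_mix: tuple[float, float, float] = (0.60, 0.25, 0.15)  # precise/coarse/missing
    precise_range_m: tuple[float, float] = (10.0, 1_000.0)
    coarse_range_m: tuple[float, float] = (15_000.0, 50_000.0)
    redlist_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "LC": 0.34, "NT": 0.02, "VU": 0.22, "EN": 0.19, "CR": 0.12,
            "DD": 0.05, "NE": 0.06,
        }
    )
    year_range: tuple[int, int] = (1893, 2020)
    undescribed_fraction: float = 0.05
    hybrid_fraction: float = 0.015
    country_center: tuple[float, float] = (32.5, 1.5)
    country_radius_km: float = 250.0

    def validate(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValidationError("class mix must sum to 1")
        if abs(sum(self.uncertainty_mix) - 1.0) > 1e-9:
            raise ValidationError("uncertainty mix must sum to 1")
        if abs(sum(self.redlist_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("Red List mix must sum to 1")
        country_area = 2.6 * self.country_radius_km**2  # hexagon lower bound
        hi = self.range_scale_km2["strict_endemic"][1]
        if hi > country_area:
            raise ValidationError(
                f"strict-endemic target EOO up to {hi} km² cannot fit inside a "
                f"country of ~{country_area:.0f} km²"
            )
        for cls in CLASSES:
            lo, hi = self.range_scale_km2[cls]
            if not (0 < lo <= hi):
                raise ValidationError(f"bad range bounds for {cls}")

    @property
    def projection(self) -> EqualAreaProjection:
        return EqualAreaProjection(*self.country_center)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Hull-area calibration

_HULL_FACTOR_CACHE: dict[int, float] = {}
_CALIBRATION_REPS = 200


def hull_area_factor(n: int) -> float:
    """E[convex-hull area] of n iid standard bivariate normal points.

    Estimated once per n by pilot simulation with a fixed calibration seed
    (independent of any study seed) and cached; the hull area of a Gaussian
    with spread sigma is then sigma² times this factor, by homogeneity.
    """
    if n < 3:
        return 1.0  # degenerate; spread is irrelevant downstream
    if n not in _HULL_FACTOR_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([987654321, n]))
        total = 0.0
        for _ in range(_CALIBRATION_REPS):
            pts = rng.standard_normal((n, 2))
            total += MultiPoint(pts).convex_hull.area
        _HULL_FACTOR_CACHE[n] = total / _CALIBRATION_REPS
    return _HULL_FACTOR_CACHE[n]


# ---------------------------------------------------------------------------
# Country and regions


def generate_country(config: SimulationConfig) -> tuple[Polygon, list[Polygon]]:
    """A convex irregular hexagonal country with Voronoi ecoregions.

    Vertices are drawn in an equal-area km plane and mapped to lon-lat;
    regions are the Voronoi cells of random interior points, clipped to the
    country, so they tile it exactly.
    """
    config.validate()
    rng = _rng(config.seed, "country")
    proj = config.projection
    angles = np.sort(np.radians(np.arange(6) * 60.0 + rng.uniform(-18.0, 18.0, 6)))
    radii = config.country_radius_km * rng.uniform(0.75, 1.10, 6)
    vx = radii * np.cos(angles)
    vy = radii * np.sin(angles)
    hull = MultiPoint(np.column_stack([vx, vy])).convex_hull
    lon, lat = proj.inverse(*np.asarray(hull.exterior.coords).T)
    country = Polygon(np.column_stack([lon, lat]))

    k = config.n_regions
    if k == 1:
        return country, [country]
    seeds = _uniform_in_polygon(rng, country, k)
    cells = voronoi_diagram(MultiPoint(seeds), envelope=country.buffer(2.0))
    regions: list[Polygon] = []
    for pt in seeds:
        for cell in cells.geoms:
            if cell.covers(Point(pt)):
                regions.append(cell.intersection(country))
                break
    return country, regions


def _uniform_in_polygon(
    rng: np.random.Generator, poly: Polygon, n: int
) -> list[tuple[float, float]]:
    minx, miny, maxx, maxy = poly.bounds
    out: list[tuple[float, float]] = []
    while len(out) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            out.append((x, y))
    return out


# ---------------------------------------------------------------------------
# Taxa and records


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    country: Polygon
    regions: list[Polygon]
    hotspots: list[tuple[float, float]]
    taxa: list[TaxonRecord]
    records: list[OccurrenceRecord]
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write all inputs as delimited text / GeoJSON; returns the paths."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "occurrences": d / "occurrences.csv",
            "checklist": d / "checklist.csv",
            "country": d / "country.geojson",
            "regions": d / "regions.geojson",
            "truth": d / "truth.csv",
        }
        write_occurrences(self.records, paths["occurrences"])
        write_checklist(self.taxa, paths["checklist"])
        write_geojson([self.country], paths["country"], [{"role": "focal_country"}])
        write_geojson(
            self.regions,
            paths["regions"],
            [{"region_id": f"R{i}"} for i in range(len(self.regions))],
        )
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _sample_conditioned(
    rng: np.random.Generator,
    center_km: tuple[float, float],
    sigma_km: float,
    n: int,
    country: Polygon,
    proj: EqualAreaProjection,
    inside: bool,
    max_tries: int = 400,
) -> np.ndarray:
    """n lon-lat points from an isotropic normal, conditioned in/outside the
    country. Falls back to uniform draws over the relevant side if the
    normal mass there is tiny."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries * n:
        m = max(n - len(pts), 8) * 4
        xy = np.asarray(center_km) + sigma_km * rng.standard_normal((m, 2))
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        ok = shapely.covers(country, shapely.points(lon, lat))
        if not inside:
            ok = ~ok
        for lo, la in zip(lon[ok], lat[ok]):
            if len(pts) < n:
                pts.append((float(lo), float(la)))
        tries += m
    while len(pts) < n:  # fallback: uniform over the relevant side
        minx, miny, maxx, maxy = country.bounds
        pad = 2.0
        x = rng.uniform(minx - pad, maxx + pad)
        y = rng.uniform(miny - pad, maxy + pad)
        if country.covers(Point(x, y)) == inside:
            pts.append((x, y))
    return np.asarray(pts)


def _boundary_point(rng: np.random.Generator, country: Polygon) -> tuple[float, float]:
    u = rng.uniform(0.0, country.exterior.length)
    p = country.exterior.interpolate(u)
    return p.x, p.y


def generate_taxa_and_records(
    config: SimulationConfig,
    country: Polygon | None = None,
    regions: Sequence[Polygon] | None = None,
) -> SyntheticDataset:
    """Generate the checklist, occurrence records and truth table."""
    config.validate()
    if country is None:
        country, regions = generate_country(config)
    assert regions is not None
    proj = config.projection
    shapely.prepare(country)

    rng_taxa = _rng(config.seed, "taxa")
    rng_pts = _rng(config.seed, "points")
    rng_unc = _rng(config.seed, "uncertainty")
    rng_cat = _rng(config.seed, "categories")

    interior = country.buffer(-0.5)
    if interior.is_empty:
        interior = country.buffer(-0.1)
    hotspots = _uniform_in_polygon(rng_taxa, interior, config.n_hotspots)

    classes = rng_taxa.choice(CLASSES, size=config.n_taxa, p=list(config.mix))
    k_nb = config.points_dispersion
    n_points_all = rng_taxa.negative_binomial(
        k_nb, k_nb / (k_nb + config.points_mean), size=config.n_taxa
    )
    n_points_all = np.maximum(n_points_all, config.points_min)

    taxa: list[TaxonRecord] = []
    records: list[OccurrenceRecord] = []
    truth_rows = []
    rl_cats = list(config.redlist_mix)
    rl_probs = list(config.redlist_mix.values())

    for i in range(config.n_taxa):
        cls = str(classes[i])
        n = int(n_points_all[i])
        lo, hi = config.range_scale_km2[cls]
        target_eoo = float(np.exp(rng_pts.uniform(np.log(lo), np.log(hi))))
        sigma = float(np.sqrt(target_eoo / hull_area_factor(n)))
        f_lo, f_hi = config.inside_fraction_target[cls]
        f_in = float(rng_pts.uniform(f_lo, f_hi))

        hotspot_idx = -1
        if cls == "strict_endemic":
            hotspot_idx = int(rng_pts.integers(config.n_hotspots))
            hx, hy = hotspots[hotspot_idx]
            cx, cy = proj.forward(np.array([hx]), np.array([hy]))
            center_km = (float(cx[0]), float(cy[0]))
            center_lonlat = (hx, hy)
        elif cls == "widespread":
            (cpt,) = _uniform_in_polygon(rng_pts, country, 1)
            center_lonlat = cpt
            cx, cy = proj.forward(np.array([cpt[0]]), np.array([cpt[1]]))
            center_km = (float(cx[0]), float(cy[0]))
        else:  # cross-border classes centre on the border itself
            center_lonlat = _boundary_point(rng_pts, country)
            cx, cy = proj.forward(
                np.array([center_lonlat[0]]), np.array([center_lonlat[1]])
            )
            center_km = (float(cx[0]), float(cy[0]))

        if cls == "strict_endemic":
            n_in, n_out = n, 0
        else:
            n_in = int(round(n * f_in))
            n_in = min(max(n_in, 1), n - 1)  # cross-border: both sides occupied
            n_out = n - n_in

        pts_in = _sample_conditioned(rng_pts, center_km, sigma, n_in, country, proj, True)
        if n_out:
            if cls == "near_endemic_ne1":
                # scarce AND tightly clustered beyond the border
                anchor = _sample_conditioned(
                    rng_pts, center_km, sigma, 1, country, proj, False
                )[0]
                ax, ay = proj.forward(np.array([anchor[0]]), np.array([anchor[1]]))
                pts_out = _sample_conditioned(
                    rng_pts, (float(ax[0]), float(ay[0])), 3.0, n_out, country, proj, False
                )
            else:
                pts_out = _sample_conditioned(
                    rng_pts, center_km, sigma, n_out, country, proj, False
                )
            pts = np.vstack([pts_in, pts_out])
        else:
            pts = pts_in

        taxon_id = f"T{i:04d}"
        taxon = _make_taxon(taxon_id, i, rng_cat, rl_cats, rl_probs, config)
        # region membership from the geometry of the generated points
        member_regions = {
            f"R{j}"
            for j, reg in enumerate(regions)
            if any(reg.covers(Point(x, y)) for x, y in pts[:n_in])
        }
        taxon = replace(taxon, region_ids=frozenset(member_regions))
        taxa.append(taxon)

        kinds = rng_unc.choice(3, size=n, p=list(config.uncertainty_mix))
        for j, ((x, y), kind) in enumerate(zip(pts, kinds)):
            if kind == 0:
                unc = float(rng_unc.uniform(*config.precise_range_m))
            elif kind == 1:
                unc = float(rng_unc.uniform(*config.coarse_range_m))
            else:
                unc = None
            records.append(
                OccurrenceRecord(
                    record_id=f"{taxon_id}-{j:03d}",
                    taxon_id=taxon_id,
                    latitude=float(y),
                    longitude=float(x),
                    uncertainty_m=unc,
                    collector=f"Collector {int(rng_unc.integers(40)):02d}",
                    year=int(rng_unc.integers(1950, 2021)),
                )
            )
        truth_rows.append(
            {
                "taxon_id": taxon_id,
                "class": cls,
                "expected_status": EXPECTED_STATUS[cls],
                "target_eoo_km2": target_eoo,
                "inside_fraction_target": f_in,
                "n_points": n,
                "sigma_km": sigma,
                "center_lon": center_lonlat[0],
                "center_lat": center_lonlat[1],
                "hotspot": hotspot_idx,
            }
        )

    return SyntheticDataset(
        config=config,
        country=country,
        regions=list(regions),
        hotspots=hotspots,
        taxa=taxa,
        records=records,
        truth=pd.DataFrame(truth_rows),
    )


def _make_taxon(
    taxon_id: str,
    i: int,
    rng: np.random.Generator,
    rl_cats: list[str],
    rl_probs: list[float],
    config: SimulationConfig,
) -> TaxonRecord:
    genus = f"Genus{int(rng.integers(60)):02d}"
    rank = str(rng.choice(["species", "subspecies", "variety"], p=[0.73, 0.12, 0.15]))
    name = f"{genus} species{i}"
    if rank == "subspecies":
        name += f" subsp. infra{i}"
    elif rank == "variety":
        name += f" var. infra{i}"
    # Zipf-ish family distribution so rankings have structure
    fam_w = 1.0 / np.arange(1, len(_FAMILIES) + 1)
    family = str(rng.choice(_FAMILIES, p=fam_w / fam_w.sum()))
    n_forms = 1 + int(rng.random() < 0.12)
    forms = rng.choice(_GROWTH_TOKENS, size=n_forms, replace=False, p=_GROWTH_PROBS)
    n_flor = 1 + int(rng.random() < 0.3)
    flor = rng.choice(["U1", "U2", "U3", "U4"], size=n_flor, replace=False)
    u = rng.random()
    return TaxonRecord(
        taxon_id=taxon_id,
        accepted_name=name,
        rank=rank,
        family=family,
        genus=genus,
        growth_forms=frozenset(str(f) for f in forms),
        basionym_year=int(rng.integers(config.year_range[0], config.year_range[1] + 1)),
        redlist_category=str(rng.choice(rl_cats, p=rl_probs)),
        is_hybrid=u < config.hybrid_fraction,
        is_undescribed=config.hybrid_fraction <= u
        < config.hybrid_fraction + config.undescribed_fraction,
        floristic_regions=frozenset(str(f) for f in flor),
    )
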