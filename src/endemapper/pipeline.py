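"""End-to-end analysis: records + checklist + country polygon → classified
checklist, per-taxon weights, hex-cell statistics and summary tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from shapely.geometry import MultiPolygon, Polygon

from . import summaries
from .classify import (
    ClassificationParams,
    EndemismStatus,
    classify_checklist,
)
from .hexgrid import (
    CellStats,
    HexGridSpec,
    assign_to_cells,
    cell_weighted_endemism,
    compute_weights,
    TaxonWeight,
)
from .occurrences import (
    OccurrenceRecord,
    TaxonRecord,
    assign_country,
    filter_by_precision,
    write_geojson,
)
from .ranges import GridParams, RangeMetrics, compute_range_metrics

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything one full run produces."""

    records_used: list[OccurrenceRecord]
    metrics: dict[str, RangeMetrics]
    statuses: list[EndemismStatus]
    weights: dict[str, TaxonWeight]
    cells: list[CellStats]

    @property
    def status_by_taxon(self) -> dict[str, str]:
        return {s.taxon_id: s.status for s in self.statuses}

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics.values():
            rows.append(vars(m) | {"eoo_effective_km2": m.eoo_effective_km2})
        return pd.DataFrame(rows)

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.statuses:
            row = {
                "taxon_id": s.taxon_id,
                "status": s.status,
                "criteria_met": "+".join(sorted(s.criteria_met)),
            }
            if s.evidence is not None:
                row |= {
                    "eoo_km2": s.evidence.eoo_km2,
                    "aoo_km2": s.evidence.aoo_km2,
                    "inside_fraction": s.evidence.inside_fraction,
                    "n_outside_points": s.evidence.n_outside_points,
                    "eoo_outside_km2": s.evidence.eoo_outside_km2,
                    "eoo_is_fallback": s.evidence.eoo_is_fallback,
                }
            rows.append(row)
        return pd.DataFrame(rows)

    def cells_frame(self, spec: HexGridSpec | None = None) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            cx, cy = c.polygon.centroid.x, c.polygon.centroid.y
            rows.append(
                {
                    "row": c.cell_id[0],
                    "col": c.cell_id[1],
                    "centroid_lon": cx,
                    "centroid_lat": cy,
                    "richness": c.richness,
                    "weighted_endemism": c.weighted_endemism,
                }
            )
        return pd.DataFrame(rows)

    def write_cells_geojson(self, path: str | Path) -> None:
        write_geojson(
            [c.polygon for c in self.cells],
            path,
            [
                {
                    "row": c.cell_id[0],
                    "col": c.cell_id[1],
                    "richness": c.richness,
                    "weighted_endemism": c.weighted_endemism,
                }
                for c in self.cells
            ],
        )


def run_analysis(
    records: Sequence[OccurrenceRecord],
    taxa: Sequence[TaxonRecord],
    country: Polygon | MultiPolygon,
    max_uncertainty_m: float = 10_000.0,
    keep_missing_uncertainty: bool = True,
    grid: GridParams | None = None,
    params: ClassificationParams | None = None,
    hex_spec: HexGridSpec | None = None,
    grid_statuses: tuple[str, ...] = ("E", "NE"),
) -> AnalysisResult:
    """Run the full pipeline on one coherent record set.

    Records are precision-filtered once; the same filtered set feeds the
    range metrics, the classification, the weights and the cell
    memberships. The hexagonal maps cover the endemic flora only
    (``grid_statuses``) by default.
    """
    filtered = filter_by_precision(records, max_uncertainty_m, keep_missing_uncertainty)
    logger.info("precision filter kept %d of %d records", len(filtered), len(records))
    assigned = assign_country(filtered, country)

    by_taxon: dict[str, list[OccurrenceRecord]] = {}
    for r in assigned:
        by_taxon.setdefault(r.taxon_id, []).append(r)
    metrics = {
        tid: compute_range_metrics(tid, recs, grid) for tid, recs in by_taxon.items()
    }
    statuses = classify_checklist(taxa, metrics, params)
    status_of = {s.taxon_id: s.status for s in statuses}

    keep = {tid for tid, st in status_of.items() if st in grid_statuses}
    grid_records = [r for r in assigned if r.taxon_id in keep]
    weights = compute_weights([m for tid, m in metrics.items() if tid in keep])
    members = assign_to_cells(grid_records, hex_spec)
    cells = cell_weighted_endemism(members, weights, hex_spec)
    return AnalysisResult(
        records_used=assigned,
        metrics=metrics,
        statuses=statuses,
        weights=weights,
        cells=cells,
    )


def summary_report(
    result: AnalysisResult, taxa: Sequence[TaxonRecord]
) -> dict:
    """Machine-readable bundle of all checklist summaries for the endemic
    subset of a classified checklist."""
    status = result.status_by_taxon
    endemic = [t for t in taxa if status.get(t.taxon_id) in ("E", "NE")]
    totals = summaries.checklist_totals(endemic, status)
    per_form, per_sub = summaries.growth_form_breakdown(endemic)
    rl = summaries.redlist_summary(endemic)
    curve = summaries.discovery_curve(endemic, status)
    return {
        "totals": {
            "described_E": totals.col_total("E"),
            "described_NE": totals.col_total("NE"),
            "described_total": totals.described_total,
            "grand_total": totals.grand_total,
        },
        "family_ranking_all": summaries.family_ranking(endemic, status, "all"),
        "family_ranking_strict": summaries.family_ranking(endemic, status, "strict"),
        "growth_forms": {f: {"count": c, "percent": p} for f, (c, p) in per_form.items()},
        "growth_form_subcategories": {f"{m}:{s}": c for (m, s), c in per_sub.items()},
        "regions": summaries.region_tally(endemic, status).to_dict("records"),
        "redlist": {
            "counts": rl.counts,
            "n_assessed": rl.n_assessed,
            "n_total": rl.n_total,
            "percent_assessed": rl.percent_assessed,
            "percent_threatened": rl.percent_threatened,
            "percent_by_category": rl.percentages,
        },
        "discovery_curve": curve.to_dict("records"),
    }
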