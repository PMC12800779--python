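"""Endemic / near-endemic classification rules.

A taxon is strictly endemic (E) when every occurrence lies inside the focal
country. Cross-border taxa can still be near-endemic (NE) under either of
two criteria:

* NE1 — the majority of the taxon's range lies inside the country and it is
  scarce and/or highly range-restricted beyond the border. "Majority" is
  measured as the fraction of occurrence records inside (strictly > 0.5 by
  default); "scarce/range-restricted beyond" is the disjunction of few
  outside records (≤ 5) or a small outside-range MCP (≤ 1,000 km²).
* NE2 — the global range (fallback-aware EOO) is less than 10,000 km², a
  threshold aligned with Important Plant Area criterion B(ii). The
  inequality is strict: exactly 10,000 km² does not qualify.

Everything else is NOT. All thresholds are configurable and every decision
carries the range-metrics evidence it used, so borderline calls can be
audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import IntegrityError, ParameterError
from .occurrences import TaxonRecord
from .ranges import RangeMetrics

logger = logging.getLogger(__name__)

STATUS_ENDEMIC = "E"
STATUS_NEAR_ENDEMIC = "NE"
STATUS_NOT_ENDEMIC = "NOT"
STATUS_UNCLASSIFIABLE = "UNCLASSIFIABLE"


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the endemism rules (areas in km²)."""

    ne2_eoo_max_km2: float = 10_000.0
    ne1_inside_fraction_min: float = 0.5
    ne1_outside_max_records: int = 5
    ne1_outside_max_eoo_km2: float = 1_000.0

    def __post_init__(self) -> None:
        if self.ne2_eoo_max_km2 <= 0 or self.ne1_outside_max_eoo_km2 <= 0:
            raise ParameterError("area thresholds must be > 0")
        if not (0.0 < self.ne1_inside_fraction_min < 1.0):
            raise ParameterError("ne1_inside_fraction_min must be in (0, 1)")
        if self.ne1_outside_max_records < 0:
            raise ParameterError("ne1_outside_max_records must be >= 0")


@dataclass(frozen=True)
class EndemismStatus:
    """Classification outcome with the evidence used."""

    taxon_id: str
    status: str
    criteria_met: frozenset[str]
    evidence: RangeMetrics | None

    @property
    def is_endemic_or_near(self) -> bool:
        return self.status in (STATUS_ENDEMIC, STATUS_NEAR_ENDEMIC)


def classify_taxon(
    metrics: RangeMetrics, params: ClassificationParams | None = None
) -> EndemismStatus:
    """Apply the E / NE1 / NE2 rules to one taxon's range metrics."""
    if params is None:
        params = ClassificationParams()
    if metrics.inside_fraction == 1.0:
        return EndemismStatus(metrics.taxon_id, STATUS_ENDEMIC, frozenset(), metrics)
    criteria: set[str] = set()
    if metrics.eoo_effective_km2 < params.ne2_eoo_max_km2:
        criteria.add("NE2")
    if metrics.inside_fraction > params.ne1_inside_fraction_min and (
        metrics.n_outside_points <= params.ne1_outside_max_records
        or metrics.eoo_outside_km2 <= params.ne1_outside_max_eoo_km2
    ):
        criteria.add("NE1")
    status = STATUS_NEAR_ENDEMIC if criteria else STATUS_NOT_ENDEMIC
    return EndemismStatus(metrics.taxon_id, status, frozenset(criteria), metrics)


def classify_checklist(
    taxa: Sequence[TaxonRecord],
    metrics_by_taxon: Mapping[str, RangeMetrics],
    params: ClassificationParams | None = None,
) -> list[EndemismStatus]:
    """Classify every checklist taxon; deterministic given the inputs.

    Taxa with no occurrence records (absent from ``metrics_by_taxon``) are
    reported as unclassifiable with a logged reason, never silently
    dropped.
    """
    if params is None:
        params = ClassificationParams()
    out = []
    for taxon in taxa:
        metrics = metrics_by_taxon.get(taxon.taxon_id)
        if metrics is None:
            logger.warning(
                "taxon %s has no occurrence records; reported unclassifiable",
                taxon.taxon_id,
            )
            out.append(
                EndemismStatus(taxon.taxon_id, STATUS_UNCLASSIFIABLE, frozenset(), None)
            )
            continue
        if metrics.taxon_id != taxon.taxon_id:
            raise IntegrityError(
                f"metrics for {metrics.taxon_id!r} supplied under key {taxon.taxon_id!r}"
            )
        out.append(classify_taxon(metrics, params))
    return out
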