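"""Checklist summary statistics: totals, family rankings, growth forms,
region tallies, Red List breakdown and the discovery curve.

Conventions used throughout (all configurable where it matters):

* percentages are rounded half-up, to 1 decimal place by default;
* "threatened" is exactly VU ∪ EN ∪ CR;
* undescribed taxa and hybrids appear in the checklist totals but are
  excluded from family, growth-form, region and Red List summaries;
* Red List category percentages are over assessed taxa (category != NE);
  the assessed share itself is over all described taxa.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, ParameterError, ValidationError
from .occurrences import GROWTH_FORMS, REDLIST_CATEGORIES, TaxonRecord

logger = logging.getLogger(__name__)

THREATENED = ("VU", "EN", "CR")
RANK_CLASSES = ("species", "subspecies", "variety", "undescribed", "hybrid")


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 × n/d, rounded half-up to ``decimals`` places.

    House rounding rule for every printed percentage, so that e.g.
    (170, 184) → 92.4 and (134, 4816, 2 decimals) → 2.78.
    """
    if denominator <= 0:
        raise ParameterError("percentage: denominator must be > 0")
    if numerator < 0:
        raise ParameterError("percentage: numerator must be >= 0")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _rank_class(t: TaxonRecord) -> str:
    if t.is_hybrid:
        return "hybrid"
    if t.is_undescribed:
        return "undescribed"
    return t.rank


def _described(taxa: Iterable[TaxonRecord]) -> list[TaxonRecord]:
    return [t for t in taxa if not (t.is_hybrid or t.is_undescribed)]


@dataclass
class ChecklistTotals:
    """Counts by rank class × endemism status with all margins."""

    counts: dict[tuple[str, str], int]

    def cell(self, rank_class: str, status: str) -> int:
        return self.counts.get((rank_class, status), 0)

    def row_total(self, rank_class: str) -> int:
        return self.cell(rank_class, "E") + self.cell(rank_class, "NE")

    def col_total(self, status: str, described_only: bool = True) -> int:
        classes = ("species", "subspecies", "variety") if described_only else RANK_CLASSES
        return sum(self.cell(rc, status) for rc in classes)

    @property
    def described_total(self) -> int:
        return self.col_total("E") + self.col_total("NE")

    @property
    def grand_total(self) -> int:
        return self.col_total("E", False) + self.col_total("NE", False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rc in RANK_CLASSES:
            rows.append((rc, self.cell(rc, "E"), self.cell(rc, "NE"), self.row_total(rc)))
        rows.insert(3, ("total described", self.col_total("E"), self.col_total("NE"),
                        self.described_total))
        rows.append(("total", self.col_total("E", False), self.col_total("NE", False),
                     self.grand_total))
        return pd.DataFrame(rows, columns=["rank", "E", "NE", "E+NE"])


def checklist_totals(
    taxa: Sequence[TaxonRecord], status_by_taxon: Mapping[str, str]
) -> ChecklistTotals:
    """Tabulate the endemic checklist by rank class and status.

    The checklist passed in must contain endemic/near-endemic taxa only;
    a NOT status is an integrity error, since the totals describe the
    endemic flora.
    """
    counts: dict[tuple[str, str], int] = {}
    for t in taxa:
        status = status_by_taxon[t.taxon_id]
        if status not in ("E", "NE"):
            raise IntegrityError(
                f"taxon {t.taxon_id} has status {status}; totals cover the "
                "endemic checklist only"
            )
        key = (_rank_class(t), status)
        counts[key] = counts.get(key, 0) + 1
    return ChecklistTotals(counts)


def family_ranking(
    taxa: Sequence[TaxonRecord],
    status_by_taxon: Mapping[str, str],
    scope: str = "all",
    exclude_flags: bool = True,
) -> list[tuple[int, str, int]]:
    """Families ordered by endemic-taxon count, competition-ranked.

    ``scope`` is ``"strict"`` (E only) or ``"all"`` (E + NE). Tied families
    share a rank and consume successive positions (1, 2, 2, 2, 5, ...).
    Hybrids and undescribed taxa are excluded by default.
    """
    if scope not in ("strict", "all"):
        raise ParameterError(f"unknown scope {scope!r}")
    pool = _described(taxa) if exclude_flags else list(taxa)
    wanted = ("E",) if scope == "strict" else ("E", "NE")
    counts: dict[str, int] = {}
    for t in pool:
        if status_by_taxon.get(t.taxon_id) in wanted:
            counts[t.family] = counts.get(t.family, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = []
    for pos, (fam, n) in enumerate(ordered, start=1):
        if ranked and ranked[-1][2] == n:
            rank = ranked[-1][0]
        else:
            rank = pos
        ranked.append((rank, fam, n))
    return ranked


def growth_form_breakdown(
    taxa: Sequence[TaxonRecord],
) -> tuple[dict[str, tuple[int, float]], dict[tuple[str, str], int]]:
    """Taxon counts and percentages per growth form, plus sub-category counts.

    A taxon recorded in several forms counts once in each; percentages use
    the described-taxon total as denominator (so they can sum to > 100).
    Returns ``(per-form {form: (count, pct)}, per-(form, sub) counts)``.
    """
    pool = _described(taxa)
    total = len(pool)
    form_counts: dict[str, set[str]] = {f: set() for f in GROWTH_FORMS}
    sub_counts: dict[tuple[str, str], set[str]] = {}
    for t in pool:
        if not t.growth_forms:
            raise IntegrityError(f"described taxon {t.taxon_id} has no growth form")
        for token in t.growth_forms:
            main, _, sub = token.partition(":")
            form_counts[main].add(t.taxon_id)
            if sub:
                sub_counts.setdefault((main, sub), set()).add(t.taxon_id)
    per_form = {
        f: (len(ids), percentage(len(ids), total) if total else 0.0)
        for f, ids in form_counts.items()
    }
    per_sub = {k: len(v) for k, v in sorted(sub_counts.items())}
    return per_form, per_sub


def region_tally(
    taxa: Sequence[TaxonRecord],
    status_by_taxon: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-region taxon counts, unique-to-region counts and percentages.

    ``count`` is the number of described endemic taxa recorded in the
    region; ``unique_count`` those whose region set is exactly that region.
    A taxon spanning two regions appears in both counts and neither
    unique count.
    """
    pool = _described(taxa)
    if status_by_taxon is not None:
        pool = [t for t in pool if status_by_taxon.get(t.taxon_id) in ("E", "NE")]
    total = len(pool)
    regions = sorted({r for t in pool for r in t.region_ids})
    rows = []
    for region in regions:
        members = [t for t in pool if region in t.region_ids]
        unique = [t for t in members if t.region_ids == frozenset({region})]
        rows.append(
            (region, len(members),
             percentage(len(members), total) if total else 0.0, len(unique))
        )
    return pd.DataFrame(rows, columns=["region", "count", "percent", "unique_count"])


def region_union_count(
    taxa: Sequence[TaxonRecord],
    region_group: Iterable[str],
    status_by_taxon: Mapping[str, str] | None = None,
) -> int:
    """Distinct described taxa recorded in any region of a stated group."""
    group = set(region_group)
    pool = _described(taxa)
    if status_by_taxon is not None:
        pool = [t for t in pool if status_by_taxon.get(t.taxon_id) in ("E", "NE")]
    return sum(1 for t in pool if t.region_ids & group)


@dataclass
class RedListSummary:
    """Counts and percentages of Red List categories over the endemic flora."""

    counts: dict[str, int]
    n_assessed: int
    n_total: int
    percent_assessed: float
    percent_threatened: float
    percentages: dict[str, float]  # per category, over n_assessed

    def to_frame(self) -> pd.DataFrame:
        cats = [c for c in REDLIST_CATEGORIES if c != "NE"]
        return pd.DataFrame(
            {"category": cats,
             "count": [self.counts.get(c, 0) for c in cats],
             "percent_of_assessed": [self.percentages.get(c, 0.0) for c in cats]}
        )


def redlist_summary(taxa: Sequence[TaxonRecord]) -> RedListSummary:
    """Extinction-risk breakdown of the described endemic flora.

    Not Evaluated (NE) taxa are excluded from the assessed denominator;
    threatened = VU + EN + CR over assessed taxa.
    """
    pool = _described(taxa)
    counts: dict[str, int] = {}
    for t in pool:
        if t.redlist_category not in REDLIST_CATEGORIES:
            raise ValidationError(f"unknown Red List category {t.redlist_category!r}")
        counts[t.redlist_category] = counts.get(t.redlist_category, 0) + 1
    n_total = len(pool)
    n_assessed = n_total - counts.get("NE", 0)
    n_threat = sum(counts.get(c, 0) for c in THREATENED)
    percentages = {
        c: (percentage(counts.get(c, 0), n_assessed) if n_assessed else 0.0)
        for c in REDLIST_CATEGORIES if c != "NE"
    }
    return RedListSummary(
        counts=counts,
        n_assessed=n_assessed,
        n_total=n_total,
        percent_assessed=percentage(n_assessed, n_total) if n_total else 0.0,
        percent_threatened=percentage(n_threat, n_assessed) if n_assessed else 0.0,
        percentages=percentages,
    )


def discovery_curve(
    taxa: Sequence[TaxonRecord],
    status_by_taxon: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cumulative described taxa by basionym publication year.

    Returns a step series (one row per year with ≥ 1 description) with
    columns ``year``, ``cumulative_all`` and ``cumulative_strict``; the
    year of first valid publication is what counts, not the date of any
    later recombination. Taxa with unknown years are excluded with a
    logged count; a future year is a validation error.
    """
    this_year = datetime.date.today().year
    pool = _described(taxa)
    dated = []
    for t in pool:
        if t.basionym_year is None:
            continue
        if t.basionym_year > this_year:
            raise ValidationError(
                f"taxon {t.taxon_id}: basionym year {t.basionym_year} is in the future"
            )
        strict = (status_by_taxon or {}).get(t.taxon_id) == "E"
        dated.append((t.basionym_year, strict))
    n_missing = len(pool) - len(dated)
    if n_missing:
        logger.warning("discovery_curve: %d taxa lack basionym years", n_missing)
    if not dated:
        return pd.DataFrame(columns=["year", "cumulative_all", "cumulative_strict"])
    df = pd.DataFrame(dated, columns=["year", "strict"])
    per_year = df.groupby("year").agg(n=("strict", "size"), n_strict=("strict", "sum"))
    per_year["cumulative_all"] = per_year["n"].cumsum()
    per_year["cumulative_strict"] = per_year["n_strict"].cumsum()
    return per_year.reset_index()[["year", "cumulative_all", "cumulative_strict"]]
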