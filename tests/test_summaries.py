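import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from endemapper import (
    IntegrityError,
    ParameterError,
    TaxonRecord,
    ValidationError,
    checklist_totals,
    discovery_curve,
    family_ranking,
    growth_form_breakdown,
    percentage,
    redlist_summary,
    region_tally,
    region_union_count,
)


def make_taxon(tid, rank="species", family="Asteraceae", forms=("herb:p",),
               year=1950, rl="LC", hybrid=False, undescribed=False, regions=()):
    return TaxonRecord(
        taxon_id=tid,
        accepted_name=f"Genus sp{tid}",
        rank=rank,
        family=family,
        growth_forms=frozenset(forms),
        basionym_year=year,
        redlist_category=rl,
        is_hybrid=hybrid,
        is_undescribed=undescribed,
        region_ids=frozenset(regions),
    )


class TestPercentage:
    @pytest.mark.parametrize(
        "num, den, dec, expected",
        [
            (134, 4816, 2, 2.78),
            (170, 184, 1, 92.4),
            (0, 10, 1, 0.0),
            (9, 170, 1, 5.3),
            (5, 8, 0, 63.0),  # 62.5 rounds up (half-up, not banker's)
            (1, 8, 1, 12.5),
        ],
    )
    def test_examples(self, num, den, dec, expected):
        assert percentage(num, den, dec) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            percentage(1, 0)

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_always_in_unit_range_when_part_of_whole(self, n, d):
        assert 0.0 <= percentage(min(n, d), d) <= 100.0


def _table1_fixture():
    """Checklist with the published national-study margins:
    species 52 E / 82 NE; subspecies 5/18; varieties 10/17;
    undescribed 18/1; hybrids 2/1."""
    taxa, status = [], {}
    spec = [
        ("species", False, False, 52, 82),
        ("subspecies", False, False, 5, 18),
        ("variety", False, False, 10, 17),
        ("species", False, True, 18, 1),
        ("species", True, False, 2, 1),
    ]
    i = 0
    for rank, hybrid, undesc, n_e, n_ne in spec:
        for st_, n in (("E", n_e), ("NE", n_ne)):
            for _ in range(n):
                t = make_taxon(f"x{i}", rank=rank, hybrid=hybrid, undescribed=undesc)
                taxa.append(t)
                status[t.taxon_id] = st_
                i += 1
    return taxa, status


class TestChecklistTotals:
    def test_published_margins_recovered(self):
        taxa, status = _table1_fixture()
        tot = checklist_totals(taxa, status)
        assert tot.col_total("E") == 67
        assert tot.col_total("NE") == 117
        assert tot.described_total == 184
        assert tot.col_total("E", described_only=False) == 87
        assert tot.col_total("NE", described_only=False) == 119
        assert tot.grand_total == 206
        assert tot.cell("undescribed", "E") == 18
        assert tot.cell("hybrid", "NE") == 1

    def test_empty_list_all_zero(self):
        tot = checklist_totals([], {})
        assert tot.described_total == 0 and tot.grand_total == 0

    def test_single_strict_species(self):
        t = make_taxon("a")
        tot = checklist_totals([t], {"a": "E"})
        assert tot.described_total == 1

    def test_not_endemic_status_is_integrity_error(self):
        t = make_taxon("a")
        with pytest.raises(IntegrityError):
            checklist_totals([t], {"a": "NOT"})

    @given(st.lists(st.tuples(st.sampled_from(["species", "subspecies", "variety"]),
                              st.sampled_from(["E", "NE"])), max_size=60))
    def test_margins_equal_sum_of_cells(self, spec):
        taxa = [make_taxon(f"t{i}", rank=r) for i, (r, _) in enumerate(spec)]
        status = {f"t{i}": s for i, (_, s) in enumerate(spec)}
        tot = checklist_totals(taxa, status)
        for st_ in ("E", "NE"):
            assert tot.col_total(st_) == sum(
                tot.cell(rc, st_) for rc in ("species", "subspecies", "variety")
            )
        assert tot.described_total == len(spec)


class TestFamilyRanking:
    def test_leading_family(self):
        taxa = [make_taxon(f"a{i}", family="Asparagaceae") for i in range(10)]
        taxa += [make_taxon(f"b{i}", family="Asteraceae") for i in range(6)]
        status = {t.taxon_id: "E" for t in taxa}
        ranked = family_ranking(taxa, status, scope="strict")
        assert ranked[0] == (1, "Asparagaceae", 10)

    def test_competition_ranking_with_ties(self):
        taxa = [make_taxon(f"l{i}", family="Lead") for i in range(5)]
        for fam in ("A", "B", "C"):
            taxa += [make_taxon(f"{fam}{i}", family=fam) for i in range(3)]
        taxa += [make_taxon("z0", family="Tail")]
        status = {t.taxon_id: "E" for t in taxa}
        ranked = family_ranking(taxa, status, scope="all")
        assert [(r, n) for r, _, n in ranked] == [(1, 5), (2, 3), (2, 3), (2, 3), (5, 1)]

    def test_empty_input(self):
        assert family_ranking([], {}) == []

    def test_hybrids_and_undescribed_excluded(self):
        taxa = [make_taxon("a"), make_taxon("h", hybrid=True), make_taxon("u", undescribed=True)]
        status = {t.taxon_id: "E" for t in taxa}
        assert family_ranking(taxa, status) == [(1, "Asteraceae", 1)]

    @given(st.permutations(list(range(8))))
    def test_permutation_invariant(self, order):
        fams = ["A", "A", "A", "B", "B", "C", "D", "D"]
        taxa = [make_taxon(f"t{i}", family=fams[i]) for i in range(8)]
        status = {t.taxon_id: "NE" for t in taxa}
        shuffled = [taxa[i] for i in order]
        assert family_ranking(shuffled, status) == family_ranking(taxa, status)


class TestGrowthForms:
    def test_published_tree_and_herb_shares(self):
        taxa = [make_taxon(f"t{i}", forms=("tree",)) for i in range(25)]
        taxa += [make_taxon(f"h{i}", forms=("herb:p",)) for i in range(111)]
        taxa += [make_taxon(f"s{i}", forms=("shrub",)) for i in range(48)]
        per_form, _ = growth_form_breakdown(taxa)
        assert per_form["tree"] == (25, 13.6)
        assert per_form["herb"] == (111, 60.3)

    def test_multi_form_taxon_counts_in_each(self):
        taxa = [make_taxon("m", forms=("herb:p", "shrub"))]
        per_form, per_sub = growth_form_breakdown(taxa)
        assert per_form["herb"][0] == 1 and per_form["shrub"][0] == 1
        assert per_sub[("herb", "p")] == 1

    def test_described_taxon_without_form_is_integrity_error(self):
        t = make_taxon("a")
        t.growth_forms = frozenset()
        with pytest.raises(IntegrityError):
            growth_form_breakdown([t])


class TestRegions:
    def test_montane_union_share(self):
        montane = ("R1", "R8", "R78", "R86")
        taxa = [make_taxon(f"m{i}", regions=(montane[i % 4],)) for i in range(122)]
        taxa += [make_taxon(f"o{i}", regions=("R61",)) for i in range(62)]
        assert region_union_count(taxa, montane) == 122
        assert percentage(region_union_count(taxa, montane), len(taxa)) == 66.3

    def test_two_region_taxon_in_both_counts_neither_unique(self):
        taxa = [
            make_taxon("a", regions=("R1", "R2")),
            make_taxon("b", regions=("R1",)),
        ]
        df = region_tally(taxa).set_index("region")
        assert df.loc["R1", "count"] == 2 and df.loc["R1", "unique_count"] == 1
        assert df.loc["R2", "count"] == 1 and df.loc["R2", "unique_count"] == 0

    def test_single_region_everything_unique(self):
        taxa = [make_taxon(f"t{i}", regions=("R5",)) for i in range(7)]
        df = region_tally(taxa).set_index("region")
        assert df.loc["R5", "count"] == df.loc["R5", "unique_count"] == 7


class TestRedList:
    def _fixture(self):
        # 170 assessed of 184; 99 threatened; 9 DD
        cats = ["VU"] * 40 + ["EN"] * 39 + ["CR"] * 20 + ["LC"] * 58 + ["NT"] * 4
        cats += ["DD"] * 9 + ["NE"] * 14
        return [make_taxon(f"t{i}", rl=c) for i, c in enumerate(cats)]

    def test_assessed_share_and_dd_share(self):
        rl = redlist_summary(self._fixture())
        assert rl.n_total == 184 and rl.n_assessed == 170
        assert rl.percent_assessed == 92.4
        assert rl.percentages["DD"] == 5.3

    def test_threatened_is_vu_en_cr(self):
        rl = redlist_summary(self._fixture())
        assert rl.percent_threatened == percentage(99, 170)

    def test_one_of_each_category(self):
        taxa = [make_taxon(f"t{i}", rl=c) for i, c in enumerate(
            ["LC", "VU", "EN", "CR", "DD", "NE"])]
        rl = redlist_summary(taxa)
        assert rl.n_assessed == 5
        assert rl.percent_threatened == 60.0

    def test_unknown_category_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="XX"):
            make_taxon("bad", rl="XX")

    def test_category_percentages_reconcile(self):
        rl = redlist_summary(self._fixture())
        assert sum(rl.counts[c] for c in rl.percentages if c in rl.counts) == rl.n_assessed
        assert abs(sum(rl.percentages.values()) - 100.0) <= 0.2


class TestDiscoveryCurve:
    def test_step_series(self):
        taxa = [make_taxon("a", year=1893), make_taxon("b", year=1893),
                make_taxon("c", year=1950)]
        df = discovery_curve(taxa)
        assert df[df.year == 1893].cumulative_all.item() == 2
        assert df[df.year == 1950].cumulative_all.item() == 3
        assert df.year.iloc[0] == 1893

    def test_strict_series_counts_only_strict(self):
        taxa = [make_taxon("a", year=1900), make_taxon("b", year=1910)]
        df = discovery_curve(taxa, {"a": "E", "b": "NE"})
        assert df.cumulative_strict.iloc[-1] == 1
        assert df.cumulative_all.iloc[-1] == 2

    def test_empty_input(self):
        assert discovery_curve([]).empty

    def test_future_year_rejected(self):
        with pytest.raises(ValidationError):
            discovery_curve([make_taxon("a", year=2999)])

    def test_missing_years_excluded_with_log(self, caplog):
        taxa = [make_taxon("a", year=1950), make_taxon("b", year=None)]
        with caplog.at_level("WARNING"):
            df = discovery_curve(taxa)
        assert df.cumulative_all.iloc[-1] == 1
        assert any("lack basionym years" in m for m in caplog.messages)

    def test_non_decreasing_and_ends_at_dated_count(self, dataset60):
        df = discovery_curve(dataset60.taxa)
        dated = [t for t in dataset60.taxa
                 if not (t.is_hybrid or t.is_undescribed) and t.basionym_year]
        assert (df.cumulative_all.diff().dropna() >= 0).all()
        assert df.cumulative_all.iloc[-1] == len(dated)
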