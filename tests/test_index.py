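"""Lethality ratio, SDLI and SALI construction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdli import (
    ConfigurationError,
    LethalityEntry,
    LethalityTable,
    UndefinedRatioError,
    build_lethality_table,
    compute_sali_series,
    count_all_seizures,
    count_single_drug_deaths,
    count_single_drug_seizures,
    filter_unintentional,
    lethality_ratio,
    round_half_up,
)

from conftest import make_death, make_seizure

# reference-year single-drug counts as published for the six indexed drugs
PUBLISHED_2017 = {
    "fentanyl": (1497, 3812, 0.393),
    "cocaine": (254, 5781, 0.044),
    "prescription_opioids": (217, 3650, 0.059),
    "heroin": (110, 2486, 0.044),
    "amphetamines": (85, 9012, 0.009),
    "benzodiazepines": (28, 5437, 0.005),
}


class TestCounts:
    def test_single_drug_deaths_fixture(self):
        deaths = [
            make_death("D1", 2017, {"fentanyl"}),
            make_death("D2", 2017, {"fentanyl", "cocaine"}),
            make_death("D3", 2016, {"fentanyl"}),
        ]
        assert count_single_drug_deaths(deaths, "fentanyl", 2017) == 1
        assert count_single_drug_deaths([], "fentanyl", 2017) == 0

    def test_single_drug_seizures_fixture(self):
        seizures = [
            make_seizure("S1", 2017, {"fentanyl"}),
            make_seizure("S2", 2017, {"fentanyl", "heroin"}),
        ]
        assert count_single_drug_seizures(seizures, "fentanyl", 2017) == 1
        assert count_single_drug_seizures([], "fentanyl", 2017) == 0

    def test_all_seizures_counts_mixed_once_per_drug(self):
        seizures = [
            make_seizure("S1", 2017, {"fentanyl"}),
            make_seizure("S2", 2017, {"fentanyl", "cocaine"}),
        ]
        assert count_all_seizures(seizures, "fentanyl", 2017) == 2
        assert count_all_seizures(seizures, "cocaine", 2017) == 1

    def test_ignore_other_substances_flag(self):
        deaths = [make_death("D1", 2017, {"fentanyl", "other:alcohol"})]
        assert count_single_drug_deaths(deaths, "fentanyl", 2017) == 0
        assert count_single_drug_deaths(deaths, "fentanyl", 2017, ignore_other=True) == 1

    def test_counts_match_exhaustive_scan_on_synthetic(self, small_market):
        params, seizures, deaths, _ = small_market
        udeaths = filter_unintentional(deaths)
        for drug in params.drugs:
            for year in (2009, 2013, 2017):
                assert count_single_drug_deaths(udeaths, drug, year) == sum(
                    1 for d in udeaths
                    if d.year == year and d.tox_substances == frozenset({drug}))
                assert count_single_drug_seizures(seizures, drug, year) == sum(
                    1 for s in seizures
                    if s.year == year and s.substances == frozenset({drug}))
                n_all = count_all_seizures(seizures, drug, year)
                assert n_all == sum(
                    1 for s in seizures if s.year == year and drug in s.substances)
                assert n_all >= count_single_drug_seizures(seizures, drug, year)

    def test_year_partition(self, small_market):
        params, seizures, _, _ = small_market
        total = sum(count_all_seizures(seizures, "fentanyl", y) for y in params.years)
        assert total == sum(1 for s in seizures if "fentanyl" in s.substances)


class TestLethalityRatio:
    @pytest.mark.parametrize("drug", sorted(PUBLISHED_2017))
    def test_published_reference_year_ratios(self, drug):
        deaths, seizures, expected = PUBLISHED_2017[drug]
        assert round_half_up(lethality_ratio(deaths, seizures), 3) == expected

    def test_zero_deaths(self):
        assert lethality_ratio(0, 100) == 0.0

    def test_zero_seizures_raises(self):
        with pytest.raises(UndefinedRatioError, match="fentanyl"):
            lethality_ratio(5, 0, drug="fentanyl")

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 10_000), st.integers(1, 50))
    def test_scale_consistency(self, deaths, seizures, k):
        assert lethality_ratio(k * deaths, k * seizures) == pytest.approx(
            lethality_ratio(deaths, seizures), abs=1e-12)

    def test_round_half_up_is_half_away_from_zero(self):
        # 254/5781 = 0.04393...; bankers' rounding would give the same here,
        # but 0.0445 must go up
        assert round_half_up(0.0445, 3) == 0.045
        assert round_half_up(0.0435, 3) == 0.044


class TestLethalityTable:
    @staticmethod
    def _records_from_published():
        deaths, seizures = [], []
        for drug, (nd, ns, _) in PUBLISHED_2017.items():
            deaths += [make_death(f"D-{drug}-{i}", 2017, {drug}) for i in range(nd)]
            seizures += [make_seizure(f"S-{drug}-{i}", 2017, {drug}) for i in range(ns)]
        return deaths, seizures

    def test_reproduces_published_ratios_from_records(self):
        deaths, seizures = self._records_from_published()
        table = build_lethality_table(deaths, seizures, 2017, sorted(PUBLISHED_2017))
        assert len(table.entries) == 6
        for e in table.entries:
            nd, ns, lr3 = PUBLISHED_2017[e.drug]
            assert (e.single_deaths, e.single_seizures) == (nd, ns)
            assert e.lr_3dp == lr3

    def test_zero_seizure_drug_excluded_with_warning(self, caplog):
        deaths = [make_death("D1", 2017, {"fentanyl"})]
        seizures = [make_seizure("S1", 2017, {"fentanyl"})]
        table = build_lethality_table(
            deaths, seizures, 2017, ["fentanyl", "cocaine"])
        assert table.drugs == ("fentanyl",)
        assert any("cocaine" in r.message for r in caplog.records)

    def test_empty_drug_list_raises(self):
        with pytest.raises(ConfigurationError):
            build_lethality_table([], [], 2017, [])

    def test_recovers_generator_lethality(self, small_market):
        """Estimated LR within 3 binomial SEs of the generating θ."""
        params, seizures, deaths, _ = small_market
        udeaths = filter_unintentional(deaths)
        table = build_lethality_table(
            udeaths, seizures, 2017, list(params.drugs))
        for e in table.entries:
            theta = params.true_lethality[e.drug]
            se = (theta * (1 - theta) / e.single_seizures) ** 0.5
            assert abs(e.lr - theta) <= 3 * se + 1e-12, e.drug


class TestSALI:
    def test_one_term_sum(self):
        table = LethalityTable(2017, (LethalityEntry("fentanyl", 5, 10, 0.5),))
        seizures = [make_seizure(f"S{i}", 2018, {"fentanyl"}) for i in range(10)]
        series = compute_sali_series(table, seizures, [2018])
        assert series.values[2018] == pytest.approx(5.0)

    def test_two_term_sum(self):
        table = LethalityTable(2017, (
            LethalityEntry("fentanyl", 1, 10, 0.1),
            LethalityEntry("cocaine", 2, 10, 0.2),
        ))
        seizures = [make_seizure(f"F{i}", 2018, {"fentanyl"}) for i in range(10)]
        seizures += [make_seizure(f"C{i}", 2018, {"cocaine"}) for i in range(5)]
        series = compute_sali_series(table, seizures, [2018])
        assert series.values[2018] == pytest.approx(2.0)

    def test_empty_years_or_table_raise(self):
        table = LethalityTable(2017, (LethalityEntry("fentanyl", 1, 10, 0.1),))
        with pytest.raises(ConfigurationError):
            compute_sali_series(table, [], [])
        with pytest.raises(ConfigurationError):
            compute_sali_series(LethalityTable(2017, ()), [], [2018])

    def test_matches_spreadsheet_recomputation(self, small_market):
        """Each SALI equals Σ_drug lr × all-seizure count recomputed directly."""
        params, seizures, deaths, _ = small_market
        table = build_lethality_table(
            filter_unintentional(deaths), seizures, 2017, list(params.drugs))
        series = compute_sali_series(table, seizures, list(params.years))
        for year in params.years:
            expected = sum(
                e.lr * sum(1 for s in seizures if s.year == year and e.drug in s.substances)
                for e in table.entries)
            assert series.values[year] == pytest.approx(expected, rel=1e-12)
        # per-drug SDLI entries are retained and consistent with the sum
        for year in params.years:
            assert sum(e.sdli for e in series.entries if e.year == year) == pytest.approx(
                series.values[year])

    def test_linearity_in_seizure_counts(self):
        table = LethalityTable(2017, (
            LethalityEntry("fentanyl", 1, 10, 0.1),
            LethalityEntry("heroin", 3, 10, 0.3),
        ))
        base = [make_seizure(f"S{i}", 2018, {"fentanyl"}) for i in range(4)]
        base += [make_seizure(f"H{i}", 2018, {"heroin"}) for i in range(3)]
        doubled = base + [make_seizure(s.seizure_id + "b", 2018, s.substances)
                          for s in base]
        one = compute_sali_series(table, base, [2018]).values[2018]
        two = compute_sali_series(table, doubled, [2018]).values[2018]
        assert two == pytest.approx(2 * one)

    def test_additivity_over_disjoint_drug_sets(self, small_market):
        params, seizures, deaths, _ = small_market
        table = build_lethality_table(
            filter_unintentional(deaths), seizures, 2017, list(params.drugs))
        entries_a = tuple(e for e in table.entries if e.drug in ("fentanyl", "heroin"))
        entries_b = tuple(e for e in table.entries if e.drug not in ("fentanyl", "heroin"))
        years = [2015, 2017]
        full = compute_sali_series(table, seizures, years)
        part_a = compute_sali_series(LethalityTable(2017, entries_a), seizures, years)
        part_b = compute_sali_series(LethalityTable(2017, entries_b), seizures, years)
        for y in years:
            assert part_a.values[y] + part_b.values[y] == pytest.approx(full.values[y])
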