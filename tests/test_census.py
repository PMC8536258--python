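"""Yield disaggregation, census normalization, and production estimates."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from ovoclone import (
    CategoryStats,
    CloneCategory,
    CloneCategoryTable,
    DegenerateInputError,
    InconsistentInputsError,
    LineageTypeFrequencies,
    NoFSCProductionError,
    PerLineageYields,
    UndefinedCompositionError,
    category_pair_composition,
    datasets,
    ecfsc_yields_by_subtraction,
    germarium_production,
    nondividing_ec_estimate,
    per_lineage_yield,
    precursor_census,
    total_lineage_count,
)

FREQS_0HR = LineageTypeFrequencies(p_ec=0.63, p_ecfsc=0.13, p_fsc=0.05, p_fc=0.19)


class TestComposition:
    def test_ec_only_composition_published(self):
        comp = category_pair_composition(FREQS_0HR, 0.3, CloneCategory.EC_ONLY)
        assert comp.w_same == pytest.approx(0.624, abs=0.001)
        assert comp.w_cross == pytest.approx(0.376, abs=0.001)
        assert comp.lineages_per_ovariole == pytest.approx(1.44, abs=0.005)

    def test_fsc_only_composition_published(self):
        comp = category_pair_composition(FREQS_0HR, 0.3, CloneCategory.FSC_ONLY)
        assert comp.w_same == pytest.approx(0.116, abs=0.001)
        assert comp.w_cross == pytest.approx(0.884, abs=0.001)
        assert comp.lineages_per_ovariole == pytest.approx(1.08, abs=0.005)

    def test_all_single_means_one_lineage_per_ovariole(self):
        for cat in (CloneCategory.EC_ONLY, CloneCategory.FSC_ONLY):
            assert category_pair_composition(FREQS_0HR, 1.0, cat).lineages_per_ovariole == 1.0

    def test_undefined_when_no_mass(self):
        freqs = LineageTypeFrequencies(p_ec=0.0, p_ecfsc=1.0, p_fsc=0.0, p_fc=0.0)
        with pytest.raises(UndefinedCompositionError):
            category_pair_composition(freqs, 0.3, CloneCategory.EC_ONLY)

    def test_only_focal_categories_supported(self):
        with pytest.raises(UndefinedCompositionError):
            category_pair_composition(FREQS_0HR, 0.3, CloneCategory.EC_FSC)


class TestPerLineageYield:
    def test_published_chains(self):
        assert per_lineage_yield(2.53, 1.44) == pytest.approx(1.76, abs=0.005)
        assert per_lineage_yield(14 / 3, 1.08) == pytest.approx(4.32, abs=0.005)

    def test_identity_with_one_lineage(self):
        assert per_lineage_yield(3.7, 1.0) == 3.7

    def test_rejects_zero_lineages(self):
        with pytest.raises(DegenerateInputError):
            per_lineage_yield(2.0, 0.0)


class TestSubtraction:
    def test_published_pupariation_chain(self, marcm_0hr):
        yields = PerLineageYields(1.76, 4.32)
        out = ecfsc_yields_by_subtraction(marcm_0hr.table, FREQS_0HR, 0.3, yields)
        assert out.ec_per_ecfsc_lineage == pytest.approx(3.15, abs=0.01)
        assert out.fsc_per_ecfsc_lineage == pytest.approx(3.47, abs=0.01)

    def test_accounting_identity(self, marcm_0hr):
        """The subtraction construction makes the EC and FSC books balance
        exactly against the experiment totals."""
        table = marcm_0hr.table
        yields = PerLineageYields(1.76, 4.32)
        out = ecfsc_yields_by_subtraction(table, FREQS_0HR, 0.3, yields)
        lineages = total_lineage_count(table.marked, 0.3)
        ec_total = lineages * (
            FREQS_0HR.p_ec * out.ec_per_ec_lineage
            + FREQS_0HR.p_ecfsc * out.ec_per_ecfsc_lineage
        )
        fsc_total = lineages * (
            FREQS_0HR.p_fsc * out.fsc_per_fsc_lineage
            + FREQS_0HR.p_ecfsc * out.fsc_per_ecfsc_lineage
        )
        assert ec_total == pytest.approx(table.total_ec_marked, abs=1e-9)
        assert fsc_total == pytest.approx(table.total_fsc_marked, abs=1e-9)

    def test_no_subtraction_when_only_ecfsc_lineages(self):
        table = CloneCategoryTable(
            categories={CloneCategory.EC_FSC: CategoryStats(n=10, mean_ec=3.0, mean_fsc=2.0)},
            total_ec_marked=30.0,
            total_fsc_marked=20.0,
        )
        freqs = LineageTypeFrequencies(p_ec=0.0, p_ecfsc=1.0, p_fsc=0.0, p_fc=0.0)
        out = ecfsc_yields_by_subtraction(table, freqs, 1.0, PerLineageYields(1.0, 1.0))
        assert out.ec_per_ecfsc_lineage == pytest.approx(3.0)
        assert out.fsc_per_ecfsc_lineage == pytest.approx(2.0)

    def test_negative_residual_raises_with_diagnostics(self, marcm_0hr):
        huge = PerLineageYields(50.0, 4.32)
        with pytest.raises(InconsistentInputsError, match="residual negative"):
            ecfsc_yields_by_subtraction(marcm_0hr.table, FREQS_0HR, 0.3, huge)


class TestCensus:
    @pytest.mark.parametrize(
        "name, expected_total",
        [("marcm_0hr", 24.0), ("marcm_36hr", 34.9), ("multicolor_0hr", 17.3)],
    )
    def test_published_census_from_published_parameters(self, name, expected_total):
        """16/(qx + ry) applied to each experiment's published per-lineage
        frequencies and FSC yields reproduces the published totals."""
        ds = datasets.ALL_DATASETS[name]()
        p, q, r, s = ds.reference.lineage_freqs
        total = 1.0 if abs(p + q + r + s - 1.0) < 1e-9 else p + q + r + s
        freqs = LineageTypeFrequencies(p / total, q / total, r / total, s / total)
        census = precursor_census(freqs, ds.reference.yields)
        assert census.n_total == pytest.approx(expected_total, abs=0.5)
        for got, want in zip(census.as_tuple(), ds.reference.per_type):
            assert got == pytest.approx(want, abs=0.5)

    def test_single_ecfsc_type_normalization(self):
        freqs = LineageTypeFrequencies(p_ec=0.0, p_ecfsc=1.0, p_fsc=0.0, p_fc=0.0)
        census = precursor_census(freqs, PerLineageYields(1.0, 1.0, 1.0, 16.0))
        assert census.n_total == pytest.approx(1.0)

    def test_no_fsc_production_raises(self):
        freqs = LineageTypeFrequencies(p_ec=1.0, p_ecfsc=0.0, p_fsc=0.0, p_fc=0.0)
        with pytest.raises(NoFSCProductionError):
            precursor_census(freqs, PerLineageYields(2.0, 3.0, 2.0, 3.0))

    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        x=st.floats(0.5, 10.0),
        y=st.floats(0.5, 10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_conservation(self, raw, x, y):
        """Per-type counts sum to the total and implied FSC output is 16."""
        total = sum(raw)
        freqs = LineageTypeFrequencies(*(v / total for v in raw))
        census = precursor_census(freqs, PerLineageYields(1.0, y, 1.0, x))
        assert sum(census.as_tuple()) == pytest.approx(census.n_total, abs=1e-9)
        implied_fsc = census.n_total * (freqs.p_ecfsc * x + freqs.p_fsc * y)
        assert implied_fsc == pytest.approx(16.0, abs=1e-9)


class TestGermariumProduction:
    @pytest.mark.parametrize("day", sorted(datasets.PUBLISHED_PRODUCTION))
    def test_published_time_course(self, day):
        totals = datasets.ec_fsc_production_totals()
        row = totals[totals.days_before_eclosion == day].iloc[0]
        prod = germarium_production(row.x_r1, row.y_r2a, row.z_fsc)
        r1, r2a, ec = datasets.PUBLISHED_PRODUCTION[day]
        assert prod.r1_made == pytest.approx(r1, abs=0.05)
        assert prod.r2a_made == pytest.approx(r2a, abs=0.05)
        assert prod.ec_made == pytest.approx(ec, abs=0.05)
        assert prod.ec_made == prod.r1_made + prod.r2a_made

    def test_zero_totals(self):
        prod = germarium_production(0, 0, 50)
        assert (prod.r1_made, prod.r2a_made, prod.ec_made) == (0.0, 0.0, 0.0)

    def test_zero_fsc_denominator_rejected(self):
        with pytest.raises(DegenerateInputError):
            germarium_production(10, 10, 0)


class TestNonDividingEstimate:
    def test_published_decline_values(self):
        early = germarium_production(356, 253, 295)  # -6d induction
        late3 = germarium_production(41, 46, 93)  # -3d induction
        late4 = germarium_production(156, 80, 134)  # -4d induction
        assert round(nondividing_ec_estimate(early, late3)) == 18
        assert round(nondividing_ec_estimate(early, late4)) == 5

    def test_identical_inputs_give_zero(self):
        prod = germarium_production(10, 10, 20)
        assert nondividing_ec_estimate(prod, prod) == 0.0

    def test_negative_delta_warns(self, caplog):
        early = germarium_production(10, 10, 40)
        late = germarium_production(30, 30, 40)
        with caplog.at_level(logging.WARNING, logger="ovoclone.census"):
            delta = nondividing_ec_estimate(early, late)
        assert delta < 0 and "negative" in caplog.text
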