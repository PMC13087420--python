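import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from smnvar.epi import (
    CohortSpec,
    EU27_PRESET,
    GNOMAD_V41_EUROPEAN_N as N_EUR,
    VariantFrequencyRecord,
    carrier_frequency,
    compound_het_frequency,
    expected_annual_births,
    expected_individuals,
    risk_estimate,
    risk_report,
)


def _records(counts, population="EUR", n=N_EUR):
    return [
        VariantFrequencyRecord(f"v{i}", population, c, c, n)
        for i, c in enumerate(counts)
    ]


class TestCarrierFrequency:
    def test_combined_sixty_carriers(self):
        r = carrier_frequency(13 + 47, N_EUR)
        assert r.reciprocal_display == 9828
        assert r.fraction == Fraction(60, N_EUR)

    def test_expanded_111_carriers(self):
        r = carrier_frequency(111, N_EUR)
        assert r.fraction == Fraction(111, N_EUR)
        assert r.reciprocal_display == 5312

    def test_all_carriers(self):
        assert carrier_frequency(10, 10).fraction == 1

    def test_zero_carriers_flagged_infinite(self):
        r = carrier_frequency(0, 100)
        assert r.fraction == 0 and math.isinf(r.reciprocal_display)

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            carrier_frequency(11, 10)


class TestCompoundHetFrequency:
    def test_display_reciprocal_chain(self):
        r = compound_het_frequency(Fraction(1, 35), Fraction(1, 9828))
        assert r.reciprocal_exact == pytest.approx(1_375_920)
        assert r.reciprocal_display == pytest.approx(1.37e6)

    def test_exact_fraction_chain(self):
        r = compound_het_frequency(Fraction(1, 35), Fraction(60, N_EUR))
        assert r.reciprocal_exact == pytest.approx(35 * (N_EUR / 60) * 4)
        assert r.reciprocal_exact == pytest.approx(1_376_022.67, abs=0.01)
        assert r.reciprocal_display == pytest.approx(1.37e6)

    def test_expanded_set_reciprocal(self):
        r = compound_het_frequency(Fraction(1, 35), Fraction(111, N_EUR))
        assert round(r.reciprocal_exact) == 743_796
        assert r.reciprocal_display == 743_796

    def test_mendelian_factor_alone(self):
        assert compound_het_frequency(Fraction(1), Fraction(1)).fraction == Fraction(1, 4)

    def test_parental_order_flag_doubles(self):
        base = compound_het_frequency(Fraction(1, 35), Fraction(1, 9828))
        strict = compound_het_frequency(Fraction(1, 35), Fraction(1, 9828),
                                        include_parental_order_factor=True)
        assert strict.fraction == 2 * base.fraction


class TestExpectedCounts:
    def test_individuals_existing(self):
        assert expected_individuals(1.13e9, 1 / 1.37e6) == 824
        assert expected_individuals(1.13e9, 1 / 743_796) == 1519
        assert expected_individuals(1e9, 0) == 0

    def test_annual_births_display(self):
        raw, display = expected_annual_births(3.67e6, 1 / 1.37e6)
        assert raw == pytest.approx(2.6788, abs=1e-3)
        assert display == 2.6  # truncated, not rounded
        raw, display = expected_annual_births(3.67e6, 1 / 743_796)
        assert raw == pytest.approx(4.934, abs=1e-3)
        assert display == 5  # rounded at >= 3
        assert expected_annual_births(1e6, 0.5, coverage=0)[0] == 0


class TestRiskReport:
    def test_two_variant_headline_chain(self):
        estimates = risk_report(_records([13, 47]), EU27_PRESET)
        combined = estimates["combined"]
        assert combined.vus_carrier.reciprocal_display == 9828
        assert combined.compound_het.reciprocal_display == pytest.approx(1.37e6)
        assert combined.expected_individuals == 824
        assert combined.expected_births_display == 2.6

    def test_expanded_set_chain(self):
        est = risk_estimate(111, N_EUR, EU27_PRESET, scenario="expanded")
        assert est.compound_het.reciprocal_display == 743_796
        assert est.expected_individuals == 1519
        assert est.expected_births_display == 5

    def test_single_carrier(self):
        est = risk_report(_records([1]), EU27_PRESET)["combined"]
        assert est.vus_carrier.fraction == Fraction(1, N_EUR)
        assert est.expected_individuals > 0
        assert est.expected_births_raw > 0

    def test_per_variant_estimates_present(self):
        estimates = risk_report(_records([13, 47]), EU27_PRESET)
        assert set(estimates) == {"v0", "v1", "combined"}

    def test_mixed_populations_rejected(self):
        records = _records([5]) + _records([5], population="AFR")
        with pytest.raises(ValueError, match="stratify"):
            risk_report(records, EU27_PRESET)

    def test_screening_coverage_applied_on_request(self):
        full = risk_estimate(60, N_EUR, EU27_PRESET)
        scaled = risk_estimate(60, N_EUR, EU27_PRESET, apply_screening_coverage=True)
        assert scaled.expected_births_raw == pytest.approx(0.64 * full.expected_births_raw)

    def test_provenance_records_rounding(self):
        est = risk_estimate(60, N_EUR, EU27_PRESET)
        assert est.provenance["carrier_reciprocal_exact"] == pytest.approx(9828.73, abs=0.01)
        assert "truncated" in est.provenance["carrier_display_rule"]

    @given(st.integers(1, 500), st.integers(1, 500))
    def test_monotone_in_carrier_count(self, c1, c2):
        lo, hi = sorted((c1, c2))
        est_lo = risk_estimate(lo, 10_000, EU27_PRESET)
        est_hi = risk_estimate(hi, 10_000, EU27_PRESET)
        assert est_hi.expected_individuals >= est_lo.expected_individuals
        assert est_hi.expected_births_raw >= est_lo.expected_births_raw

    @given(st.integers(1, 1000), st.integers(1, 20))
    def test_scale_invariance(self, carriers, factor):
        n = 50_000
        a = carrier_frequency(carriers, n)
        b = carrier_frequency(carriers * factor, n * factor)
        assert a.fraction == b.fraction


class TestValidation:
    def test_record_invariants(self):
        with pytest.raises(ValueError, match="carrier_count"):
            VariantFrequencyRecord("v", "EUR", allele_count=1, carrier_count=2,
                                   n_individuals=10)
        with pytest.raises(ValueError, match="carrier_count"):
            VariantFrequencyRecord("v", "EUR", allele_count=30, carrier_count=2,
                                   n_individuals=10)

    def test_cohort_invariants(self):
        with pytest.raises(ValueError):
            CohortSpec(population_size=0, births_per_year=1e6)
        with pytest.raises(ValueError):
            CohortSpec(population_size=1e9, births_per_year=1e6, screening_coverage=1.5)
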