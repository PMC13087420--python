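import numpy as np
import pytest

from smnvar.assay import AssayComponent, AssayDefinition, ComponentRole, screen_table
from smnvar.cohort import (
    DEMO_ASSAY,
    make_paralog_pair,
    make_scenario,
    make_smn_like_pair,
    make_variant_table,
    simulate_newborn_cohort,
    write_scenario,
)
from smnvar.digest import DDEI, find_sites
from smnvar.hgvs import parse_hgvs_c, protein_consequence


def _window_sites(model, window):
    lo, hi = window
    return [c for c in find_sites(model.sequence, DDEI) if lo <= c + 1 <= hi]


class TestParalogPair:
    def test_hamming_distance_equals_discriminating_count(self):
        a, b = make_paralog_pair(3)
        assert sum(x != y for x, y in zip(a.sequence, b.sequence)) == 2

    def test_enzyme_site_only_in_second_paralog_window(self):
        a, b = make_paralog_pair(3)
        window = (a.cds_end + 1, len(a.sequence))
        assert _window_sites(a, window) == []
        assert len(_window_sites(b, window)) >= 1

    def test_same_seed_reproduces_bitwise(self):
        a1, b1 = make_paralog_pair(12)
        a2, b2 = make_paralog_pair(12)
        assert a1 == a2 and b1 == b2

    def test_different_seeds_differ(self):
        a1, _ = make_paralog_pair(1)
        a2, _ = make_paralog_pair(2)
        assert a1.sequence != a2.sequence

    def test_equal_discriminating_bases_rejected(self):
        with pytest.raises(ValueError, match="equal in both"):
            make_paralog_pair(1, discriminating=[(7, 30, "C", "C"), (8, 80, "A", "T")])

    def test_models_satisfy_all_invariants(self):
        # construction runs the TranscriptModel validator; spot-check CDS
        for seed in range(3):
            a, b = make_paralog_pair(seed)
            assert a.cds.startswith("ATG") and a.cds_length % 3 == 0
            assert a.exons == b.exons and a.cds_start == b.cds_start


class TestSmnLikePair:
    def test_reconstructed_region_consequences(self):
        smn1, _ = make_smn_like_pair(99)  # any seed: the region is fixed
        calls = {text: protein_consequence(smn1, parse_hgvs_c(text)).hgvs_p
                 for text in ("c.855_858delAGAA", "c.861_864delAAGG",
                              "c.861_862insT", "c.863G>T")}
        assert calls["c.855_858delAGAA"] == calls["c.861_864delAAGG"] == "p.Arg288AlafsTer5"
        assert calls["c.861_862insT"] == "p.Arg288Ter"
        assert calls["c.863G>T"] == "p.Arg288Met"

    def test_discriminating_positions_declared(self, scenario):
        assert dict(scenario.smn1.discriminating_positions) == {"840": "C", "*11": "A"}
        assert dict(scenario.smn2.discriminating_positions) == {"840": "T", "*11": "T"}


class TestVariantTable:
    def test_designated_deletions_share_consequence(self, scenario):
        by_id = dict(scenario.variants)
        c1 = protein_consequence(scenario.smn1, by_id["hotspot_del_855"])
        c2 = protein_consequence(scenario.smn1, by_id["hotspot_del_861"])
        assert c1.hgvs_p == c2.hgvs_p
        assert c1.kind.value == "frameshift"

    def test_all_variants_heterozygous(self, scenario):
        t = scenario.variant_table
        assert (t.allele_count == t.carrier_count).all()

    def test_carrier_count_range_bounds(self, smn1):
        _, table = make_variant_table(5, smn1, (801, 876), n_variants=2,
                                      carrier_count_range=(13, 47))
        assert 26 <= table.carrier_count.sum() <= 94

    def test_region_too_small_raises(self, smn1):
        with pytest.raises(ValueError, match="too small|contain"):
            make_variant_table(5, smn1, (855, 866), n_variants=40)

    def test_variants_confined_to_component_intervals(self, scenario):
        report = screen_table(scenario.variants, [scenario.assay])
        assert report.summary["no_overlap"] == 0

    def test_determinism(self, smn1):
        _, t1 = make_variant_table(8, smn1, (801, 876))
        _, t2 = make_variant_table(8, smn1, (801, 876))
        assert t1.equals(t2)


class TestSimulator:
    def test_zero_frequencies_zero_positives(self, scenario):
        out = simulate_newborn_cohort(1, 10_000, 0.0, 0.0, scenario.assay,
                                      (scenario.smn1, scenario.smn2))
        assert out["n_screen_positive"] == 0

    def test_amplifying_vus_makes_compound_hets_screen_negative(self, scenario):
        """If the variant allele still amplifies (no assay overlap), del/vus
        newborns give an SMN1 signal and screen negative."""
        off_target_assay = AssayDefinition(
            "elsewhere", (AssayComponent(ComponentRole.REVERSE_PRIMER, 100, 130),))
        out = simulate_newborn_cohort(1, 200_000, 1 / 70, 1 / 500, off_target_assay,
                                      (scenario.smn1, scenario.smn2),
                                      vus_variant=parse_hgvs_c("c.855_858del"))
        assert out["vus_dropout_classification"] == "no_overlap"
        assert out["n_false_positive_like"] == 0
        assert out["n_screen_positive"] == out["n_true_positive"]

    def test_compound_het_count_matches_binomial_expectation(self, scenario):
        """Mean del/vus count over replicates sits within 3 SE of
        n x 2 x p_del x p_vus (allele-level Hardy-Weinberg)."""
        n, p_del, p_vus = 500_000, 1 / 70, 1 / 2_000
        counts = [
            simulate_newborn_cohort(seed, n, p_del, p_vus, scenario.assay,
                                    (scenario.smn1, scenario.smn2))["n_compound_het_del_vus"]
            for seed in range(10)
        ]
        expectation = n * 2 * p_del * p_vus
        se_mean = np.sqrt(expectation / len(counts))  # Poisson-scale spread
        assert abs(np.mean(counts) - expectation) <= 3 * se_mean

    def test_frequencies_out_of_range(self, scenario):
        with pytest.raises(ValueError):
            simulate_newborn_cohort(1, 100, 0.2, 0.2, scenario.assay,
                                    (scenario.smn1, scenario.smn2))

    def test_determinism(self, scenario):
        args = (9, 50_000, 1 / 70, 1 / 1000, scenario.assay,
                (scenario.smn1, scenario.smn2))
        assert simulate_newborn_cohort(*args) == simulate_newborn_cohort(*args)


class TestScenario:
    def test_scenario_regenerable(self):
        s1, s2 = make_scenario(4), make_scenario(4)
        assert s1.smn1 == s2.smn1 and s1.variant_table.equals(s2.variant_table)

    def test_written_files_roundtrip(self, tmp_path, scenario):
        from smnvar.assay import load_assays_json
        from smnvar.epi import load_cohort_json
        from smnvar.refmodel import load_annotation, load_fasta

        paths = write_scenario(scenario, tmp_path)
        sequences = load_fasta(paths["fasta"])
        smn1 = load_annotation(paths["smn1_json"], sequences)
        assert smn1 == scenario.smn1
        assert load_assays_json(paths["assay_json"])[0] == scenario.assay
        assert load_cohort_json(paths["cohort_json"]) == scenario.cohort
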