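import numpy as np
import pytest

from _oracles import implementation_summary, oracle_consequence, random_coding_variant
from smnvar.cohort import make_paralog_pair
from smnvar.hgvs import (
    ConsequenceKind,
    HgvsParseError,
    HgvsVariant,
    ProteinConsequence,
    ReferenceMismatchError,
    VariantKind,
    apply_variant,
    format_p,
    parse_hgvs_c,
    protein_consequence,
    translate,
)


class TestParse:
    @pytest.mark.parametrize(
        "text, kind, start, end, ref, alt",
        [
            ("c.855_858delAGAA", VariantKind.DELETION, 855, 858, "AGAA", ""),
            ("c.861_864delAAGG", VariantKind.DELETION, 861, 864, "AAGG", ""),
            ("c.855_858del", VariantKind.DELETION, 855, 858, "", ""),
            ("c.12del", VariantKind.DELETION, 12, 12, "", ""),
            ("c.861_862insT", VariantKind.INSERTION, 861, 862, "", "T"),
            ("c.863G>T", VariantKind.SUBSTITUTION, 863, 863, "G", "T"),
            ("c.10_13dup", VariantKind.DUPLICATION, 10, 13, "", ""),
            ("c.10dup", VariantKind.DUPLICATION, 10, 10, "", ""),
            ("c.5_7delinsAC", VariantKind.DELINS, 5, 7, "", "AC"),
        ],
    )
    def test_supported_grammar(self, text, kind, start, end, ref, alt):
        v = parse_hgvs_c(text)
        assert (v.kind, v.start_c, v.end_c, v.ref_allele, v.alt_allele) == (
            kind, start, end, ref, alt)
        assert v.raw == text

    @pytest.mark.parametrize("text", ["c.100+3A>G", "c.100-2del", "c.*12A>G",
                                      "c.10_12inv", "c.10A>", "nonsense"])
    def test_unsupported_syntax_rejected(self, text):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(text)

    def test_invariant_violations(self):
        with pytest.raises(HgvsParseError, match="flanking"):
            HgvsVariant("x", VariantKind.INSERTION, 10, 12, "", "T")
        with pytest.raises(HgvsParseError, match="span length"):
            HgvsVariant("x", VariantKind.DELETION, 10, 12, "AG", "")
        with pytest.raises(HgvsParseError, match="differing"):
            HgvsVariant("x", VariantKind.SUBSTITUTION, 10, 10, "A", "A")


class TestApply:
    def test_substitution_involution(self, toy_model):
        mutated = apply_variant(toy_model, parse_hgvs_c("c.8G>A"))
        assert mutated[7] == "A"
        # applying the reverse substitution restores the reference
        from smnvar.refmodel import TranscriptModel
        mut_model = TranscriptModel("toy_mut", mutated, 1, 18, ((1, 24),))
        assert apply_variant(mut_model, parse_hgvs_c("c.8A>G")) == toy_model.sequence

    def test_deletion_length_bookkeeping(self, toy_model):
        mutated = apply_variant(toy_model, parse_hgvs_c("c.7_10delAGAA"))
        assert len(mutated) == len(toy_model.sequence) - 4

    def test_reference_mismatch_reported(self, toy_model):
        with pytest.raises(ReferenceMismatchError, match="expected 'AGAG'.*found 'AGAA'"):
            apply_variant(toy_model, parse_hgvs_c("c.7_10delAGAG"))

    def test_insertion_and_duplication_lengths(self, toy_model):
        assert len(apply_variant(toy_model, parse_hgvs_c("c.7_8insTT"))) == 26
        assert len(apply_variant(toy_model, parse_hgvs_c("c.7_10dup"))) == 28


class TestTranslate:
    @pytest.mark.parametrize("cds, protein, stop", [
        ("ATGTAA", "M", True),
        ("ATGGCTAGAAGGCATTGA", "MARRH", True),
        ("ATGGCA", "MA", False),
    ])
    def test_examples(self, cds, protein, stop):
        assert translate(cds) == (protein, stop)

    def test_bad_codon(self):
        with pytest.raises(ValueError, match="codon"):
            translate("ATGNNN")


class TestConsequence:
    def test_toy_frameshift(self, toy_model):
        c = protein_consequence(toy_model, parse_hgvs_c("c.7_10delAGAA"))
        assert c.kind is ConsequenceKind.FRAMESHIFT
        assert (c.first_residue, c.ref_aa, c.alt_aa, c.ter_offset) == (3, "Arg", "Gly", 4)
        assert c.hgvs_p == "p.Arg3GlyfsTer4"

    def test_toy_missense(self, toy_model):
        c = protein_consequence(toy_model, parse_hgvs_c("c.8G>A"))
        assert c.kind is ConsequenceKind.MISSENSE
        assert c.hgvs_p == "p.Arg3Lys"

    def test_toy_synonymous(self, toy_model):
        # codon 2 GCT -> GCC, both Ala
        c = protein_consequence(toy_model, parse_hgvs_c("c.6T>C"))
        assert c.kind is ConsequenceKind.SYNONYMOUS
        assert c.hgvs_p == "p.Ala2="

    def test_smn_like_shared_frameshift(self, smn1):
        c1 = protein_consequence(smn1, parse_hgvs_c("c.855_858delAGAA"))
        c2 = protein_consequence(smn1, parse_hgvs_c("c.861_864delAAGG"))
        assert c1.hgvs_p == c2.hgvs_p == "p.Arg288AlafsTer5"

    def test_smn_like_nonsense_when_shifted_codon_is_stop(self, smn1):
        c = protein_consequence(smn1, parse_hgvs_c("c.861_862insT"))
        assert c.kind is ConsequenceKind.NONSENSE
        assert c.hgvs_p == "p.Arg288Ter"

    def test_smn_like_missense(self, smn1):
        assert protein_consequence(smn1, parse_hgvs_c("c.863G>T")).hgvs_p == "p.Arg288Met"

    def test_determinism(self, smn1):
        results = {protein_consequence(smn1, parse_hgvs_c("c.855_858delAGAA")).hgvs_p
                   for _ in range(5)}
        assert len(results) == 1


class TestFormatP:
    @pytest.mark.parametrize("consequence, expected", [
        (ProteinConsequence(ConsequenceKind.FRAMESHIFT, 288, "Arg", "Ala", 5),
         "p.Arg288AlafsTer5"),
        (ProteinConsequence(ConsequenceKind.NONSENSE, 288, "Arg", "Ter"), "p.Arg288Ter"),
        (ProteinConsequence(ConsequenceKind.MISSENSE, 288, "Arg", "Met"), "p.Arg288Met"),
        (ProteinConsequence(ConsequenceKind.SYNONYMOUS, 2, "Ala", "Ala"), "p.Ala2="),
    ])
    def test_examples(self, consequence, expected):
        assert format_p(consequence) == expected


class TestOracleEquivalence:
    def test_random_variants_agree_with_translation_oracle(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for model_seed in range(6):
            model, _ = make_paralog_pair(model_seed)
            for _ in range(50):
                var = random_coding_variant(rng, model)
                expected = oracle_consequence(model, var)
                observed = implementation_summary(model, var)
                assert observed == expected, f"{var.raw} on seed {model_seed}"
                n_checked += 1
        assert n_checked == 300

    def test_frame_preserving_variants_never_frameshift(self):
        rng = np.random.default_rng(99)
        model, _ = make_paralog_pair(5)
        for _ in range(100):
            pos = int(rng.integers(4, model.cds_length - 12))
            var = parse_hgvs_c(rng.choice([
                f"c.{pos}_{pos + 2}del", f"c.{pos}_{pos + 5}del",
                f"c.{pos}_{pos + 1}insTAG", f"c.{pos}_{pos + 2}dup",
            ]))
            assert var.length_change() % 3 == 0
            summary = implementation_summary(model, var)
            assert summary["kind"] != "frameshift"
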