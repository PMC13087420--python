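"""Synthetic scenario generator: paralog pair, assay, variant table, cohort.

The pipeline's real-world inputs — the SMN1 reference transcript, gnomAD
carrier counts, and the proprietary screening-kit primer coordinates —
cannot be redistributed, so this module fabricates structurally
equivalent stand-ins: a paralogous transcript pair differing at declared
discriminating positions (one of which creates the DdeI site in the
second paralog's last exon, mirroring SMN2 exon 8), a demo assay whose
reverse-primer interval contains the variant hotspot, a table of rare
heterozygous variants, and an allele-level newborn cohort simulator.

The SMN-like pair embeds a *reconstructed* C-terminal coding region
(c.853-c.885): the four published exon-7 variants and their protein
consequences mutually constrain those codons (codon 288 must be AGG for
c.863G>T to give Met; both 4-bp deletions reaching p.Arg288AlafsTer5
force Gly at 287, Ala in the shifted frame at 288, and a TGA five
shifted codons later), so the engine's headline consequence strings are
reproduced on a transcript that is synthetic everywhere else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import (AssayComponent, AssayDefinition, ComponentRole, DropoutClass,
                    classify_variant_vs_assay, save_assays_json)
from .digest import DDEI, Enzyme, find_sites
from .epi import CohortSpec, EU27_PRESET, GNOMAD_V41_EUROPEAN_N, VariantFrequencyRecord, save_cohort_json
from .hgvs import HgvsVariant, VariantKind, parse_hgvs_c
from .refmodel import STOP_CODONS, TranscriptModel, c_to_index, save_annotation, write_fasta

BASES = "ACGT"

# Codons 285-stop of the SMN-like CDS (c.853-c.885), reconstructed from the
# published variant/consequence constraints; see module docstring.
RECONSTRUCTED_CTERM = "AAAGAAGGAAGGAGCTCCCATGAAATGACATAA"
_CTERM_C_START = 853

SMN_LIKE_EXONS = ((1, 145), (146, 280), (281, 400), (401, 550),
                  (551, 700), (701, 830), (831, 918), (919, 960))
SMN_LIKE_CDS = (31, 915)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no stops)."""
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if a + b + c not in STOP_CODONS]
    return "".join(rng.choice(sense, size=n))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _scrub_motif(seq: list[str], lo: int, hi: int, motif_len: int,
                 protected: set[int], enzyme: Enzyme) -> None:
    """Destroy accidental enzyme sites cutting within seq[lo:hi] (0-based).

    Only motifs whose *cut position* falls in the window matter (that is
    what transcript classification tests), which also guarantees every
    edited base lies at or beyond ``lo - cut_offset`` — in the 3'UTR, so
    the CDS is never touched.
    """
    for _ in range(10 * (hi - lo)):
        start = max(0, lo - motif_len + 1)
        window = "".join(seq[start : hi + motif_len - 1])
        hits = [start + c - enzyme.cut_offset for c in find_sites(window, enzyme)
                if lo <= start + c < hi]
        hits = [m for m in hits if not any(p in protected for p in range(m, m + motif_len))]
        if not hits:
            return
        m = hits[0]
        seq[m + 1] = "G"  # break the motif's invariant T
    raise RuntimeError("could not scrub enzyme sites")  # pragma: no cover


def _build_pair(
    rng: np.random.Generator,
    exons: tuple[tuple[int, int], ...],
    cds_start: int,
    cds_end: int,
    discriminating: list[tuple[str, str, str]],
    ddei_entry: int,
    pair_ids: tuple[str, str] = ("PARA1", "PARA2"),
    cterm_override: str | None = None,
    enzyme: Enzyme = DDEI,
) -> tuple[TranscriptModel, TranscriptModel]:
    """Core builder shared by the generic and SMN-like generators.

    ``discriminating``: list of (c_position, base_a, base_b); the
    ``ddei_entry``-th one gets a C.AAG context so that base_b = 'T'
    completes the enzyme's CTNAG site in paralog B only.  Requires that
    entry to sit in the 3'UTR.
    """
    length = exons[-1][1]
    cds_len = cds_end - cds_start + 1
    seq = list(
        _random_bases(rng, cds_start - 1)
        + "ATG" + _random_codons(rng, cds_len // 3 - 2) + "TAA"
        + _random_bases(rng, length - cds_end)
    )
    if cterm_override:
        start = (cds_start - 1) + (_CTERM_C_START - 1)
        seq[start : start + len(cterm_override)] = list(cterm_override)

    protected: set[int] = set()
    indices: list[int] = []
    for n, (c_pos, a, b) in enumerate(discriminating):
        if a == b:
            raise ValueError(f"discriminating base at c.{c_pos} equal in both paralogs")
        text = str(c_pos)
        idx = (cds_end + int(text[1:]) - 1) if text.startswith("*") else (cds_start - 1 + int(text) - 1)
        if idx >= length:
            raise ValueError(f"discriminating position c.{c_pos} beyond transcript")
        in_cds = cds_start - 1 <= idx <= cds_end - 1
        if in_cds:
            codon_ord = (idx - (cds_start - 1)) // 3
            if codon_ord == 0 or codon_ord == cds_len // 3 - 1:
                raise ValueError(f"discriminating position c.{c_pos} hits start/stop codon")
            if cterm_override is None:
                # keep the codon a sense codon for either base: C?? is never a stop
                codon_idx = cds_start - 1 + 3 * codon_ord
                fix = codon_idx if codon_idx != idx else codon_idx + 1
                seq[fix] = "C"
                protected.add(fix)
        if n == ddei_entry:
            if idx <= cds_end - 1:
                raise ValueError("enzyme-site discriminating position must lie in the 3'UTR")
            if b != "T":
                raise ValueError("enzyme-site discriminating base_b must be T (completes CTNAG)")
            ctx = {idx - 1: "C", idx + 1: "A", idx + 2: "A", idx + 3: "G"}
            if max(ctx) >= length:
                raise ValueError("enzyme-site context runs past transcript end")
            for k, v in ctx.items():
                seq[k] = v
            protected.update(ctx)
        seq[idx] = a
        protected.add(idx)
        indices.append(idx)

    # last exon's 3'UTR segment is the classification window: no stray sites
    window_lo = max(cds_end, exons[-1][0] - 1)
    _scrub_motif(seq, window_lo, length, len(enzyme.recognition), protected, enzyme)

    seq_a = "".join(seq)
    seq_b_list = list(seq)
    for (c_pos, _a, b), idx in zip(discriminating, indices):
        seq_b_list[idx] = b
    seq_b = "".join(seq_b_list)

    disc_a = tuple((str(p), a) for p, a, _b in discriminating)
    disc_b = tuple((str(p), b) for p, _a, b in discriminating)
    model_a = TranscriptModel(pair_ids[0], seq_a, cds_start, cds_end, exons, disc_a)
    model_b = TranscriptModel(pair_ids[1], seq_b, cds_start, cds_end, exons, disc_b)
    return model_a, model_b


def make_paralog_pair(
    seed: int,
    n_exons: int = 8,
    exon_len: int = 120,
    discriminating: list[tuple[int, int, str, str]] | None = None,
) -> tuple[TranscriptModel, TranscriptModel]:
    """Generate a paralogous transcript pair on an equal-exon layout.

    ``discriminating``: (exon ordinal, 1-based within-exon offset,
    base_a, base_b).  The last entry must fall in the final exon's 3'UTR
    and have base_b 'T'; it is given a CTNAG-completing context so the
    second paralog carries the enzyme site (the SMN2-exon-8 analogue)
    and the first does not.  The pair differs at exactly the declared
    positions (Hamming distance = number of entries).
    """
    if n_exons < 2 or exon_len < 30:
        raise ValueError("need at least 2 exons of >= 30 bases")
    length = n_exons * exon_len
    exons = tuple((k * exon_len + 1, (k + 1) * exon_len) for k in range(n_exons))
    cds_start = 31
    cds_len = 3 * ((length - 30 - 45) // 3)
    cds_end = cds_start + cds_len - 1
    if discriminating is None:
        discriminating = [(max(1, n_exons - 1), 30, "C", "T"), (n_exons, exon_len - 40, "A", "T")]
    disc_c: list[tuple[str, str, str]] = []
    for exon_ord, offset, a, b in discriminating:
        pos1 = exons[exon_ord - 1][0] + offset - 1
        if pos1 < cds_start:
            raise ValueError("discriminating positions in the 5'UTR are unsupported")
        c_pos = str(pos1 - cds_start + 1) if pos1 <= cds_end else f"*{pos1 - cds_end}"
        disc_c.append((c_pos, a, b))
    rng = np.random.default_rng(seed)
    return _build_pair(rng, exons, cds_start, cds_end, disc_c, ddei_entry=len(disc_c) - 1)


def make_smn_like_pair(seed: int) -> tuple[TranscriptModel, TranscriptModel]:
    """The SMN1/SMN2-like fixture pair used by the demo scenario.

    960-nt transcripts, 885-nt CDS (294 codons, real SMN scale), exon 7
    spanning c.801-c.888 so the published exon-7 coordinates fall where
    they should, the reconstructed C-terminal coding region at
    c.853-c.885, a C/T discriminating base at c.840 (the classic
    SMN1/SMN2 splice-determining analogue), and the paralogous DdeI site
    in the SMN2-like exon 8 (3'UTR position *11).
    """
    rng = np.random.default_rng(seed)
    return _build_pair(
        rng,
        SMN_LIKE_EXONS,
        SMN_LIKE_CDS[0],
        SMN_LIKE_CDS[1],
        [("840", "C", "T"), ("*11", "A", "T")],
        ddei_entry=1,
        pair_ids=("SMN1-like", "SMN2-like"),
        cterm_override=RECONSTRUCTED_CTERM,
    )


DEMO_ASSAY = AssayDefinition(
    "demo-smn-nbs",
    (
        AssayComponent(ComponentRole.FORWARD_PRIMER, 801, 825),
        AssayComponent(ComponentRole.PROBE, 830, 845),
        AssayComponent(ComponentRole.REVERSE_PRIMER, 850, 876),
    ),
)
# Illustrative coordinates only: the commercial kits' primer sequences are
# proprietary; what matters is that the reverse-primer interval contains the
# c.855-c.864 variant hotspot, as the real assays' failure demonstrates.


def make_variant_table(
    seed: int,
    model: TranscriptModel,
    region: tuple[int, int],
    n_variants: int = 15,
    n_individuals: int = GNOMAD_V41_EUROPEAN_N,
    carrier_count_range: tuple[int, int] = (1, 8),
    within: list[tuple[int, int]] | None = None,
    population: str = "EUR",
    designated_deletions: bool = True,
) -> tuple[list[tuple[str, HgvsVariant]], pd.DataFrame]:
    """Random rare heterozygous small variants in a coding region.

    A mix of substitutions, 4-bp deletions and 1-bp insertions at
    distinct positions inside ``region`` (optionally restricted to the
    ``within`` intervals, e.g. an assay's component intervals).  When
    ``designated_deletions`` is set, the table opens with the two
    hotspot 4-bp deletions c.855_858del and c.861_864del (reference
    alleles read from the model), carrier counts 13 and 47 — the
    published observation this fixture emulates.  All variants are
    heterozygous: allele_count = carrier_count.
    """
    lo, hi = region
    if not (1 <= lo < hi <= model.cds_length):
        raise ValueError("region must lie within the CDS")
    rng = np.random.default_rng(seed)
    intervals = [(max(lo, a), min(hi, b)) for a, b in (within or [region])]
    intervals = [(a, b) for a, b in intervals if a <= b]
    if not intervals:
        raise ValueError("no usable positions: region and 'within' do not intersect")
    candidate_positions = sorted({p for a, b in intervals for p in range(a, b + 1)})

    def model_bases(c_start: int, length: int) -> str:
        i = c_to_index(model, c_start)
        return model.sequence[i : i + length]

    variants: list[tuple[str, HgvsVariant]] = []
    rows: list[dict] = []
    used: set[int] = set()

    def add(vid: str, var: HgvsVariant, carriers: int) -> None:
        variants.append((vid, var))
        rows.append({
            "variant_id": vid, "hgvs_c": var.raw, "population": population,
            "allele_count": carriers, "carrier_count": carriers,
            "n_individuals": n_individuals, "annotation_flags": "",
        })
        used.update(range(var.start_c - 1, var.end_c + 2))

    if designated_deletions:
        if n_variants < 2:
            raise ValueError("designated deletions need n_variants >= 2")
        for vid, (s, e), carriers in (("hotspot_del_855", (855, 858), 13),
                                      ("hotspot_del_861", (861, 864), 47)):
            if not (lo <= s and e <= hi):
                raise ValueError("region must contain the designated deletions (c.855-c.864)")
            ref = model_bases(s, 4)
            add(vid, parse_hgvs_c(f"c.{s}_{e}del{ref}"), carriers)

    guard = 0
    stop_codon_start = model.cds_length - 2
    while len(variants) < n_variants:
        guard += 1
        if guard > 200 * n_variants:
            raise ValueError("region too small to place distinct variants")
        pos = int(rng.choice(candidate_positions))
        kind = rng.choice(["sub", "sub", "del4", "ins1"])
        if kind == "del4":
            end = pos + 3
            if end >= stop_codon_start or end > hi:
                continue
            span = range(pos, end + 1)
            text = f"c.{pos}_{end}del{model_bases(pos, 4)}"
        elif kind == "ins1":
            if pos + 1 >= stop_codon_start:
                continue
            span = range(pos, pos + 2)
            text = f"c.{pos}_{pos + 1}ins{rng.choice(list(BASES))}"
        else:
            if pos >= stop_codon_start:
                continue
            span = range(pos, pos + 1)
            ref = model_bases(pos, 1)
            alt = rng.choice([b for b in BASES if b != ref])
            text = f"c.{pos}{ref}>{alt}"
        if any(p in used for p in span):
            continue
        carriers = int(rng.integers(carrier_count_range[0], carrier_count_range[1] + 1))
        add(f"var_{len(variants) + 1:02d}_c{pos}", parse_hgvs_c(text), carriers)

    table = pd.DataFrame(rows, columns=["variant_id", "hgvs_c", "population", "allele_count",
                                        "carrier_count", "n_individuals", "annotation_flags"])
    return variants, table


def simulate_newborn_cohort(
    seed: int,
    n_newborns: int,
    del_allele_freq: float,
    vus_allele_freq: float,
    assay: AssayDefinition,
    models: tuple[TranscriptModel, TranscriptModel],
    vus_variant: HgvsVariant | None = None,
) -> dict:
    """Allele-level newborn cohort with a mechanistic screening readout.

    Each newborn draws two alleles independently from {wild-type,
    deletion, vus} at the stated frequencies (counts realised in one
    multinomial draw over the nine ordered genotype combinations, which
    is distributionally identical to per-individual sampling).  An
    allele yields assay signal iff it amplifies: wild-type always,
    deletion never (no template), vus iff its dropout classification is
    ``no_overlap``.  A newborn screens positive when neither allele
    yields signal.
    """
    if not (0 <= del_allele_freq and 0 <= vus_allele_freq
            and del_allele_freq + vus_allele_freq < 0.1):
        raise ValueError("allele frequencies must be small (sum < 0.1) and non-negative")
    if n_newborns < 1:
        raise ValueError("need at least one newborn")
    if vus_variant is None:
        vus_variant = parse_hgvs_c("c.855_858del")
    call = classify_variant_vs_assay(vus_variant, assay)
    vus_amplifies = call.classification is DropoutClass.NO_OVERLAP

    alleles = ("wt", "del", "vus")
    signal = {"wt": True, "del": False, "vus": vus_amplifies}
    p = np.array([1.0 - del_allele_freq - vus_allele_freq, del_allele_freq, vus_allele_freq])
    combos = [(a, b) for a in alleles for b in alleles]
    probs = np.array([p[alleles.index(a)] * p[alleles.index(b)] for a, b in combos])
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_newborns, probs)

    genotype_counts = {f"{a}/{b}": int(c) for (a, b), c in zip(combos, counts)}
    n_screen_positive = sum(
        int(c) for (a, b), c in zip(combos, counts) if not signal[a] and not signal[b]
    )
    n_true_positive = genotype_counts["del/del"]
    n_compound_het = genotype_counts["del/vus"] + genotype_counts["vus/del"]
    n_false_positive_like = n_compound_het if not vus_amplifies else 0
    return {
        "seed": seed,
        "n_newborns": n_newborns,
        "vus_dropout_classification": call.classification.value,
        "genotype_counts": genotype_counts,
        "n_true_positive": n_true_positive,
        "n_compound_het_del_vus": n_compound_het,
        "n_false_positive_like": n_false_positive_like,
        "n_screen_positive": n_screen_positive,
        "n_screen_negative": n_newborns - n_screen_positive,
    }


@dataclass
class SyntheticScenario:
    """A complete, seed-reproducible input set for the whole pipeline."""

    seed: int
    smn1: TranscriptModel
    smn2: TranscriptModel
    assay: AssayDefinition
    variants: list[tuple[str, HgvsVariant]]
    variant_table: pd.DataFrame
    cohort: CohortSpec
    exon7_tag: str
    exon8_window: tuple[int, int]
    enzyme: Enzyme = DDEI

    @property
    def frequency_records(self) -> list[VariantFrequencyRecord]:
        return [
            VariantFrequencyRecord(
                variant_id=str(r.variant_id), population=str(r.population),
                allele_count=int(r.allele_count), carrier_count=int(r.carrier_count),
                n_individuals=int(r.n_individuals),
            )
            for r in self.variant_table.itertuples()
        ]

    def amplicons(self, first_exon: int = 5, last_exon: int = 8,
                  skipped_exon: int = 7) -> dict[str, str]:
        """The 2x2 cDNA species (gene x isoform) spanning exons 5-8."""
        out = {}
        for model, gene in ((self.smn1, "SMN1"), (self.smn2, "SMN2")):
            fl, d7 = [], []
            for ordinal in range(first_exon, last_exon + 1):
                s, e = model.exon_interval(ordinal)
                fl.append(model.sequence[s - 1 : e])
                if ordinal != skipped_exon:
                    d7.append(model.sequence[s - 1 : e])
            out[f"{gene}_FL"] = "".join(fl)
            out[f"{gene}_Delta7"] = "".join(d7)
        return out


def make_scenario(seed: int, n_variants: int = 15,
                  cohort: CohortSpec = EU27_PRESET) -> SyntheticScenario:
    """Build the bundled demo scenario: SMN-like pair + assay + variants."""
    smn1, smn2 = make_smn_like_pair(seed)
    component_intervals = [c.interval for c in DEMO_ASSAY.components]
    variants, table = make_variant_table(
        seed + 1, smn1, DEMO_ASSAY.annealing_region, n_variants=n_variants,
        within=component_intervals,
    )
    # exon-7 tag: 20 bases of the reconstructed region (c.853-c.872)
    tag_start = c_to_index(smn1, 853)
    exon7_tag = smn1.sequence[tag_start : tag_start + 20]
    exon8 = smn1.exon_interval(8)
    exon8_window = (max(exon8[0], smn1.cds_end + 1), exon8[1])
    return SyntheticScenario(seed, smn1, smn2, DEMO_ASSAY, variants, table,
                             cohort, exon7_tag, exon8_window)


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, str]:
    """Emit the scenario as the FASTA/TSV/JSON files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "smn1_json": outdir / "smn1_annotation.json",
        "smn2_json": outdir / "smn2_annotation.json",
        "assay_json": outdir / "assay.json",
        "variants_tsv": outdir / "variants.tsv",
        "cohort_json": outdir / "cohort.json",
        "amplicons_fasta": outdir / "amplicons.fasta",
        "enzymes_tsv": outdir / "enzymes.tsv",
        "meta_json": outdir / "scenario.json",
    }
    write_fasta({scenario.smn1.id: scenario.smn1.sequence,
                 scenario.smn2.id: scenario.smn2.sequence}, paths["fasta"])
    save_annotation(scenario.smn1, paths["smn1_json"])
    save_annotation(scenario.smn2, paths["smn2_json"])
    save_assays_json([scenario.assay], paths["assay_json"])
    scenario.variant_table.to_csv(paths["variants_tsv"], sep="\t", index=False)
    save_cohort_json(scenario.cohort, paths["cohort_json"])
    write_fasta(scenario.amplicons(), paths["amplicons_fasta"])
    pd.DataFrame(
        [{"name": scenario.enzyme.name, "motif": scenario.enzyme.recognition,
          "cut_offset": scenario.enzyme.cut_offset}]
    ).to_csv(paths["enzymes_tsv"], sep="\t", index=False)
    meta = {
        "seed": scenario.seed,
        "smn1_id": scenario.smn1.id,
        "smn2_id": scenario.smn2.id,
        "exon7_tag": scenario.exon7_tag,
        "exon8_window": list(scenario.exon8_window),
        "enzyme": scenario.enzyme.name,
    }
    paths["meta_json"].write_text(json.dumps(meta, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
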