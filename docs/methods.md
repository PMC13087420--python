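# Methods

## Coordinate model

All reasoning happens in spliced-transcript space. A `TranscriptModel` holds
the transcript sequence, 1-based CDS bounds, an exon tiling of the transcript,
and the positions that distinguish it from its paralog. HGVS `c.` positions
(positive coding positions and `*n` 3'UTR positions) convert to 0-based
indices at exactly one boundary (`c_to_index` / `index_to_c`); intronic
offsets (`c.100+3`) are rejected rather than silently mis-mapped, because a
spliced model cannot represent them. Genomic (`g.`) coordinates are out of
scope: every step of the analysis — consequence calling, primer overlap,
digestion — is transcript-relative, and the screening kits' genomic primer
sequences are proprietary and unpublished, so assays are declared directly in
`c.` space as user configuration.

## Protein consequence calling

Variants are applied exactly as written, with a stated reference allele
checked against the transcript (a mismatch aborts with expected-vs-observed
bases; this is the main defence against coordinate bugs). No 3'-most
normalisation is performed before consequence calling: the two hotspot 4-bp
deletions are distinct molecular events that happen to share a consequence,
and collapsing them would erase exactly the observation of interest.

The consequence algorithm translates the reference CDS and the mutated
sequence from the start codon through the transcript end — deliberately
reading past the reference stop into the 3'UTR so frameshifted frames can find
their new stop — and compares residue by residue:

* no difference, frame preserved → synonymous;
* in-frame, one residue substituted → missense, or nonsense if the new codon
  is a stop;
* in-frame with residues gained or lost → in-frame indel (a category added to
  the outcome enum so that frame-preserving events are never reported as
  frameshifts);
* frame-shifting → frameshift `p.XxxNYyyfsTerM`, where `M` counts the new stop
  with the first changed residue as 1. If the first shifted codon is itself a
  stop, the call is nonsense `p.XxxNTer` (this is why the 1-bp insertion
  c.861_862insT reports p.Arg288Ter, not fsTer1). If the transcript ends
  before a stop appears, the kind is `no_stop_found` rather than a guess.

Stop-loss / extension variants raise: HGVS `ext` nomenclature is out of scope.
The genetic code table is hard-coded (standard code only, no selenocysteine);
Biopython's translator is used only as the independent oracle in tests, never
in the calling path, so the dual-route check stays meaningful.

## The reconstructed C-terminal region

The engine's headline check — both deletions giving p.Arg288AlafsTer5 — needs
the SMN1 coding sequence around codon 288, and the full reference transcript
is an external accession not bundled here. The published variants and their
consequences, however, mutually determine most of the local sequence: codon
288 must be AGG (c.863G>T → Met requires A_G→ATG, and the stated deleted bases
fix c.861–864 = AAGG); both frameshift calls starting at residue 288 force
Gly at codon 287 (GGA), GC at c.866–867 (the shifted-frame Ala), and a TGA at
c.878–880 (the shifted-frame stop five codons on); the insertion's immediate
TAG stop then follows automatically. `smnvar.cohort.RECONSTRUCTED_CTERM`
encodes c.853–c.885 under these constraints; positions the publications do not
constrain (and the entire rest of the transcript) are synthetic. Tests of
these consequence strings therefore demonstrate the engine's arithmetic on the
true local variant context, not recovery of the full reference sequence.

## Assay-dropout model

Assay components are 1-based closed intervals with a role (forward primer,
reverse primer, probe). A forward primer's 3' terminus is its right boundary;
a reverse primer anneals to the opposite strand, so in transcript orientation
its 3' terminus is its left boundary. The rule cascade is deliberately
qualitative — no melting-temperature or ΔG thermodynamics:

1. no component overlapped → `no_overlap`;
2. any indel/dup/delins overlapping any component → `likely_dropout_indel`
   (a length change under an oligo distorts annealing far beyond a point
   mismatch);
3. a substitution within `three_prime_window` bases of a primer 3' terminus
   (default 5, the usual PCR rule of thumb; the terminal base counts as the
   first) → `likely_dropout_3prime_substitution`, since extension requires a
   matched 3' end;
4. any other overlapping substitution, probes included →
   `at_risk_substitution` — single-mismatch probes often still report, so
   probe hits are flagged rather than called dropouts.

When several components overlap, the one with maximal overlap is reported
(ties broken forward primer < reverse primer < probe, fixed and documented).
The bundled demo assay's coordinates are illustrative: what matters, and what
the screen preserves, is that its reverse-primer interval contains the
c.855–c.864 hotspot.

## In-silico digestion and transcript classification

Enzymes are an IUPAC recognition motif plus a cut offset; DdeI is CTNAG with
offset 1 (C^TNAG). CTNAG is its own reverse complement as an IUPAC pattern, so
a single-strand scan suffices; asymmetric motifs are additionally scanned on
the bottom strand with cuts mapped back to top-strand coordinates. Fragment
lengths always sum to the input length (property-tested).

Amplicon classification mirrors reading a digest gel, but by presence/absence
rather than band size, because absolute fragment sizes depend on primer
placement that is not modelled: isoform is FL iff the exon-7 tag subsequence
is present; gene is SMN2 iff a cut falls inside the exon-8 window (the
paralogous site carried only by the SMN2-like transcript). Amplicons must
match an expected exon-5–8 splice form exactly (mismatch tolerance 0 by
default, configurable); anything else is refused as unclassifiable.

## Epidemiology and the rounding ledger

Carrier frequencies are fractions of heterozygous *individuals*, not alleles —
60 carriers (13 + 47) and 111 carriers are the counts that reproduce the
downstream numbers, not the 112 alleles. The compound-het frequency is
`f_del × f_vus × 1/4`. A strict random-mating derivation would multiply by a
further 2 for the two parental assignments; that factor is available
(`include_parental_order_factor=True`) but off by default, keeping the chain
as conventionally computed; the allele-level simulator makes the relationship
explicit (below).

All arithmetic is exact (`fractions.Fraction`). Display rounding is a separate
recorded step, with one policy that reproduces every headline figure:

* carrier reciprocals truncate to integers (589,724/60 = 9,828.73 → 9,828);
* compound-het reciprocals display in millions truncated to two decimals when
  ≥ 10⁶ (1,376,022.67 → 1.37 M), else rounded to the nearest integer
  (743,796.04 → 743,796);
* expected existing individuals floor (1.13 × 10⁹ / 1.37 × 10⁶ → 824);
* expected annual births truncate to one decimal below 3 (2.678 → 2.6), else
  round to the nearest integer (4.934 → 5).

The headline chain feeds each step the previous step's *display* value
(`use_display_chain=True`); an exact end-to-end chain is equally available,
and every estimate's provenance records which was used, the raw values, and
each rounding rule applied. Screening coverage (64% of EU27 newborns) is
carried in the cohort spec but applied to expected births only on request,
since the headline per-year figures are computed over all births.
Assumptions: Hardy–Weinberg, random mating, no consanguinity, no fitness
effects, and point estimates only — no confidence intervals on the carrier
counts.

## Synthetic data: what it emulates and what it does not

`make_paralog_pair` generates two transcripts identical except at declared
discriminating positions, one of which (required to lie in the final exon's
3'UTR) is given a C·AAG context so that the second paralog's T completes a
CTNAG site — the SMN2-exon-8 analogue — while accidental CTNAG sites whose
cuts fall in that window are scrubbed. The SMN-like pair uses 960-nt
transcripts with an 885-nt CDS (294 codons — real SMN scale, chosen so the
c.850s exist and land in the exon labelled 7) and embeds the reconstructed
C-terminal region; exon boundaries are otherwise cosmetic. Variant tables
place a mix of substitutions, 4-bp deletions and 1-bp insertions at distinct
positions inside assay component intervals, all heterozygous
(allele_count = carrier_count), led by the two designated hotspot deletions at
carrier counts 13 and 47.

The cohort simulator draws each newborn's two alleles independently from
{wild-type, deletion, vus} (realised as one multinomial over the nine ordered
genotype pairs — distributionally identical to per-individual draws and fast
enough for 4 × 10⁶ × 20 cohorts in well under a second) and computes the screen
result mechanistically: an allele signals iff it amplifies — wild-type always,
deletion never, vus iff its dropout classification is `no_overlap`. The
simulation is allele-level (del/vus genotype frequency 2·p_del·p_vus) while
the headline formula is carrier-level; the two agree because
(2p_del)(2p_vus)·¼·2 = 2·p_del·p_vus, and the test suite checks the simulator
against the allele-level expectation within 3 standard errors at n = 4 million
× 20 replicates (analysis driver 05 prints the same comparison).

What the generator does **not** emulate: real mutation-rate spectra, linkage
and population structure, gene conversion between the paralogs, splice-impact
of variants (the exon-7-skipping effect of c.863G>T is a wet-lab observation
carried only as an annotation flag, never computed), probe/primer
thermodynamics, and sequencing/assay noise. Passing tests therefore show the
pipeline's logic is correct on structurally faithful inputs, not that it has
been validated against clinical samples.

## Numerical and design choices

* Default seeds: the demo scenario uses seed 7; every generator is
  reproducible bit-for-bit from (seed, parameters), and outputs record the
  seed.
* Problem sizes: oracle-equivalence checks run 1,000 random variants /
  1,000 random sequences; the simulator check runs 20 replicates of 4 million
  newborns — sizes at which the stochastic tolerances above are comfortably
  discriminating while the whole suite runs in seconds.
* Degenerate inputs: zero carriers yield frequency 0 with an infinite
  reciprocal flag; empty variant tables produce a report with zero rows and no
  epidemiology section; mixed-population frequency records are refused rather
  than silently pooled.
* The `pipeline` CLI preset `eu27-gnomad` bundles the cohort constants
  (deletion carriers 1/35, N = 589,724 European individuals, 1.13 × 10⁹
  individuals of European descent, 3.67 × 10⁶ EU27 births, coverage 0.64).

## Known limitations

Single-transcript models only (no multi-isoform gene models, liftover or GFF
ingestion); small variants only (no structural variants or gene-conversion
events); consequence nomenclature omits `ext` (stop-loss raises) and uses a
simplified delins naming for in-frame multi-residue changes; the dropout model
is interval logic, not chemistry, so its classes are screening priorities
rather than calibrated probabilities.
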