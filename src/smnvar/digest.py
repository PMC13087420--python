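"""In-silico restriction digestion and SMN transcript classification.

SMN1 and SMN2 cDNA amplicons spanning exons 5-8 can be told apart by a
DdeI digest: the paralogous site in SMN2's exon 8 is cut, SMN1's is not.
Presence of the exon-7 sequence separates full-length (FL) from
exon-7-skipped (Delta7) transcripts.  Classification is by presence or
absence of the exon-8 cut and the exon-7 tag, not by absolute band
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .refmodel import TranscriptModel

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease as a recognition motif plus cut offset.

    ``cut_offset`` counts bases after the motif start on the scanned
    strand; DdeI (C^TNAG) has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition motif")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset outside the recognition motif")
        bad = set(self.recognition.upper()) - set(IUPAC_EXPAND)
        if bad:
            raise ValueError(f"non-IUPAC characters in motif: {sorted(bad)}")
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def is_self_complementary(self) -> bool:
        """True when the motif equals its own reverse complement (as IUPAC)."""
        return self.recognition == reverse_complement(self.recognition)


DDEI = Enzyme("DdeI", "CTNAG", 1)


@dataclass(frozen=True)
class DigestResult:
    input_length: int
    cut_positions: tuple[int, ...]  # 0-based; cut falls between index-1 and index
    fragments: tuple[int, ...]


def _iupac_match(seq: str, pos: int, motif: str) -> bool:
    for k, m in enumerate(motif):
        if seq[pos + k] not in IUPAC_EXPAND[m]:
            return False
    return True


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All cut positions of an enzyme on a sequence (overlaps allowed).

    The top strand is scanned with a sliding IUPAC window.  For
    self-complementary motifs (DdeI's CTNAG reads CTNAG on both strands)
    one scan suffices; asymmetric motifs are additionally scanned on the
    bottom strand, mapping each cut back to top-strand coordinates.
    """
    seq = seq.upper()
    motif = enzyme.recognition
    k = len(motif)
    cuts = set()
    for pos in range(len(seq) - k + 1):
        if _iupac_match(seq, pos, motif):
            cuts.add(pos + enzyme.cut_offset)
    if not enzyme.is_self_complementary:
        rc = reverse_complement(seq)
        for pos in range(len(rc) - k + 1):
            if _iupac_match(rc, pos, motif):
                # bottom-strand cut after offset o maps to top-strand
                # position L - (pos + o)
                cuts.add(len(seq) - (pos + enzyme.cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: str, enzyme: Enzyme) -> DigestResult:
    """Fragment lengths from cutting at every recognition site."""
    cuts = find_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(len(seq), tuple(cuts), fragments)


class UnclassifiableAmplicon(ValueError):
    """Amplicon does not match any expected spliced form of either paralog."""


def _spliced_amplicon(model: TranscriptModel, first_exon: int, last_exon: int,
                      skip_exon: int | None = None) -> str:
    parts = []
    for ordinal in range(first_exon, last_exon + 1):
        if ordinal == skip_exon:
            continue
        start, end = model.exon_interval(ordinal)
        parts.append(model.sequence[start - 1 : end])
    return "".join(parts)


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def classify_transcript(
    amplicon: str,
    smn1_model: TranscriptModel,
    smn2_model: TranscriptModel,
    exon7_tag: str,
    exon8_window: tuple[int, int],
    enzyme: Enzyme = DDEI,
    first_exon: int = 5,
    skipped_exon: int = 7,
    last_exon: int = 8,
    mismatch_tolerance: int = 0,
) -> dict:
    """Assign gene (SMN1/SMN2) and isoform (FL/Delta7) to a cDNA amplicon.

    The amplicon is expected to span exons ``first_exon``..``last_exon``
    of one paralog, either full-length or with ``skipped_exon`` spliced
    out.  Isoform is called by presence of ``exon7_tag``; gene is SMN2
    iff an enzyme cut falls inside ``exon8_window`` (a 1-based closed
    interval in transcript coordinates, shared by the paralog pair).
    """
    amplicon = amplicon.upper().replace("\n", "")
    references = {}
    for model, gene in ((smn1_model, "SMN1"), (smn2_model, "SMN2")):
        references[(gene, "FL")] = _spliced_amplicon(model, first_exon, last_exon)
        references[(gene, "Delta7")] = _spliced_amplicon(model, first_exon, last_exon, skipped_exon)
    matches = {
        key: d for key, ref in references.items()
        if (d := _hamming(amplicon, ref)) is not None and d <= mismatch_tolerance
    }
    if not matches:
        raise UnclassifiableAmplicon(
            "amplicon matches no expected exon "
            f"{first_exon}-{last_exon} splice form within {mismatch_tolerance} mismatch(es)"
        )

    isoform = "FL" if exon7_tag.upper() in amplicon else "Delta7"

    # map amplicon cut positions back to transcript coordinates
    exon_start_1, _ = smn1_model.exon_interval(first_exon)
    skip_start, skip_end = smn1_model.exon_interval(skipped_exon)
    skip_len = skip_end - skip_start + 1
    cut_in_window = False
    for cut in find_sites(amplicon, enzyme):
        pos1 = exon_start_1 + cut  # transcript 1-based position right of the cut
        if isoform == "Delta7" and pos1 >= skip_start:
            pos1 += skip_len
        if exon8_window[0] <= pos1 <= exon8_window[1]:
            cut_in_window = True
            break
    gene = "SMN2" if cut_in_window else "SMN1"
    return {"gene": gene, "isoform": isoform}


def digest_report(records: dict[str, str], enzyme: Enzyme) -> pd.DataFrame:
    """Digest every record of a multi-FASTA dict into a tidy table."""
    rows = []
    for name, seq in records.items():
        result = digest(seq, enzyme)
        rows.append(
            {
                "record": name,
                "enzyme": enzyme.name,
                "input_length": result.input_length,
                "n_cuts": len(result.cut_positions),
                "cut_positions": ",".join(map(str, result.cut_positions)),
                "fragments": ",".join(map(str, result.fragments)),
            }
        )
    return pd.DataFrame(rows, columns=["record", "enzyme", "input_length", "n_cuts",
                                       "cut_positions", "fragments"])


def load_enzymes_tsv(path: str | Path) -> dict[str, Enzyme]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(row.name_): Enzyme(str(row.name_), str(row.motif), int(row.cut_offset))
        for row in df.rename(columns={"name": "name_"}).itertuples()
    }
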