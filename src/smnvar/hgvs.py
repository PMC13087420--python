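"""HGVS small-variant parsing, application, and protein consequence calling.

The consequence engine answers the question at the heart of
primer-dropout false positives: what does a small coding variant do to
the protein?  Two distinct 4-bp deletions in the SMN1 C-terminal coding
region can shift translation into the same reading frame and therefore
share a single consequence string (p.Arg288AlafsTer5); the engine
derives this by applying the edit to the transcript, re-translating
from the start codon through the 3'UTR, and scanning for the first
differing residue.

Supported grammar (coding positions only, no intronic offsets):

    c.N REF>ALT          substitution
    c.N del[SEQ]         single-base deletion
    c.N_M del[SEQ]       multi-base deletion
    c.N_M ins SEQ        insertion between flanking bases N and M=N+1
    c.N dup / c.N_M dup  duplication
    c.N_M delins SEQ     deletion-insertion
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .refmodel import TranscriptModel, c_to_index


class HgvsParseError(ValueError):
    """Unsupported or malformed HGVS c. description."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the transcript sequence."""


class ConsequenceError(ValueError):
    """Variant whose protein consequence is outside the supported nomenclature."""


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"


@dataclass(frozen=True)
class HgvsVariant:
    """A parsed small coding variant in HGVS c. coordinates."""

    raw: str
    kind: VariantKind
    start_c: int
    end_c: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.start_c > self.end_c:
            raise HgvsParseError(f"{self.raw}: start {self.start_c} > end {self.end_c}")
        k = self.kind
        if k is VariantKind.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1 or self.ref_allele == self.alt_allele:
                raise HgvsParseError(f"{self.raw}: substitution needs single, differing ref/alt")
        elif k is VariantKind.DELETION:
            if self.alt_allele:
                raise HgvsParseError(f"{self.raw}: deletion must have empty alt")
            if self.ref_allele and len(self.ref_allele) != self.end_c - self.start_c + 1:
                raise HgvsParseError(f"{self.raw}: stated deleted bases do not match span length")
        elif k is VariantKind.INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise HgvsParseError(f"{self.raw}: insertion must have empty ref, non-empty alt")
            if self.end_c != self.start_c + 1:
                raise HgvsParseError(f"{self.raw}: insertion positions must be flanking (N_N+1)")
        elif k is VariantKind.DELINS:
            if not self.alt_allele:
                raise HgvsParseError(f"{self.raw}: delins needs inserted sequence")

    @property
    def span(self) -> tuple[int, int]:
        """Affected closed c. interval (insertions: the flanking pair)."""
        return (self.start_c, self.end_c)

    def length_change(self, model: TranscriptModel | None = None) -> int:
        """len(alt) - len(ref); duplications count their span as gain."""
        if self.kind is VariantKind.SUBSTITUTION:
            return 0
        if self.kind is VariantKind.DELETION:
            return -(self.end_c - self.start_c + 1)
        if self.kind is VariantKind.INSERTION:
            return len(self.alt_allele)
        if self.kind is VariantKind.DUPLICATION:
            return self.end_c - self.start_c + 1
        return len(self.alt_allele) - (self.end_c - self.start_c + 1)


_SEQ = r"[ACGTacgt]+"
_PATTERNS = [
    (re.compile(rf"^c\.(\d+)_(\d+)delins({_SEQ})$"), VariantKind.DELINS),
    (re.compile(rf"^c\.(\d+)delins({_SEQ})$"), VariantKind.DELINS),
    (re.compile(rf"^c\.(\d+)_(\d+)del({_SEQ})?$"), VariantKind.DELETION),
    (re.compile(rf"^c\.(\d+)del({_SEQ})?$"), VariantKind.DELETION),
    (re.compile(rf"^c\.(\d+)_(\d+)ins({_SEQ})$"), VariantKind.INSERTION),
    (re.compile(rf"^c\.(\d+)_(\d+)dup$"), VariantKind.DUPLICATION),
    (re.compile(rf"^c\.(\d+)dup$"), VariantKind.DUPLICATION),
    (re.compile(rf"^c\.(\d+)([ACGTacgt])>([ACGTacgt])$"), VariantKind.SUBSTITUTION),
]
_UNSUPPORTED_HINTS = re.compile(r"[+\-*]|inv|\[")


def parse_hgvs_c(text: str) -> HgvsVariant:
    """Parse an HGVS c. description of a small variant.

    Variants are kept exactly as written (no 3' normalisation): distinct
    events that happen to share a protein consequence stay distinct.
    """
    text = text.strip()
    for pattern, kind in _PATTERNS:
        m = pattern.match(text)
        if not m:
            continue
        groups = m.groups()
        if kind is VariantKind.SUBSTITUTION:
            start = end = int(groups[0])
            ref, alt = groups[1].upper(), groups[2].upper()
        elif kind is VariantKind.DELINS:
            if len(groups) == 3:
                start, end, alt = int(groups[0]), int(groups[1]), groups[2].upper()
            else:
                start = end = int(groups[0])
                alt = groups[1].upper()
            ref = ""
        elif kind is VariantKind.DELETION:
            if len(groups) == 3:
                start, end = int(groups[0]), int(groups[1])
                ref = (groups[2] or "").upper()
            else:
                start = end = int(groups[0])
                ref = (groups[1] or "").upper()
            alt = ""
        elif kind is VariantKind.INSERTION:
            start, end, alt = int(groups[0]), int(groups[1]), groups[2].upper()
            ref = ""
        else:  # duplication
            start = int(groups[0])
            end = int(groups[1]) if len(groups) > 1 and groups[1] else start
            ref = alt = ""
        return HgvsVariant(raw=text, kind=kind, start_c=start, end_c=end,
                           ref_allele=ref, alt_allele=alt)
    hint = _UNSUPPORTED_HINTS.search(text.removeprefix("c."))
    if hint:
        raise HgvsParseError(
            f"unsupported HGVS syntax near {hint.group(0)!r} in {text!r} "
            "(intronic offsets, UTR positions, inversions and repeats are not supported)"
        )
    raise HgvsParseError(f"cannot parse HGVS description {text!r}")


def apply_variant(model: TranscriptModel, var: HgvsVariant) -> str:
    """Apply a variant to the transcript, returning the mutated sequence.

    A stated reference allele is checked against the transcript; a
    mismatch raises with expected vs observed bases — the primary
    defence against coordinate bugs.
    """
    seq = model.sequence
    i = c_to_index(model, var.start_c)
    j = c_to_index(model, var.end_c)
    if var.kind is VariantKind.SUBSTITUTION:
        observed = seq[i]
        if observed != var.ref_allele:
            raise ReferenceMismatchError(
                f"{var.raw}: expected {var.ref_allele!r} at c.{var.start_c}, found {observed!r}"
            )
        return seq[:i] + var.alt_allele + seq[i + 1 :]
    if var.kind in (VariantKind.DELETION, VariantKind.DELINS):
        observed = seq[i : j + 1]
        if var.ref_allele and observed != var.ref_allele:
            raise ReferenceMismatchError(
                f"{var.raw}: expected {var.ref_allele!r} at c.{var.start_c}_{var.end_c}, "
                f"found {observed!r}"
            )
        return seq[:i] + var.alt_allele + seq[j + 1 :]
    if var.kind is VariantKind.INSERTION:
        # flanking convention: insert between start_c and end_c = start_c + 1
        return seq[: i + 1] + var.alt_allele + seq[i + 1 :]
    if var.kind is VariantKind.DUPLICATION:
        return seq[: j + 1] + seq[i : j + 1] + seq[j + 1 :]
    raise AssertionError(f"unhandled kind {var.kind}")  # pragma: no cover


# Standard genetic code, hard-coded: standard table only, no
# selenocysteine.  Stop codons map to '*'.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def translate(cds: str) -> tuple[str, bool]:
    """Translate from position 1, stopping at (and excluding) the first stop.

    Returns ``(protein, stop_found)``.  A trailing partial codon is
    ignored; a codon containing a non-ACGT base raises.
    """
    if len(cds) < 3:
        raise ValueError("sequence shorter than one codon")
    residues = []
    for k in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[k : k + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at position {k + 1}")
        if aa == "*":
            return "".join(residues), True
        residues.append(aa)
    return "".join(residues), False


class ConsequenceKind(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    NO_STOP_FOUND = "no_stop_found"


@dataclass(frozen=True)
class ProteinConsequence:
    """Typed protein-level outcome of a small coding variant."""

    kind: ConsequenceKind
    first_residue: int | None = None
    ref_aa: str | None = None  # 3-letter code
    alt_aa: str | None = None  # 3-letter code or "Ter"
    ter_offset: int | None = None  # frameshift: new stop ordinal, first changed residue = 1
    last_residue: int | None = None  # in-frame indels: end of replaced ref run
    last_ref_aa: str | None = None

    @property
    def hgvs_p(self) -> str:
        return format_p(self)


def format_p(c: ProteinConsequence) -> str:
    """Render a ProteinConsequence as an HGVS p. string (pure function)."""
    k = c.kind
    if k is ConsequenceKind.SYNONYMOUS:
        if c.first_residue is None:
            return "p.="
        return f"p.{c.ref_aa}{c.first_residue}="
    if k is ConsequenceKind.MISSENSE:
        return f"p.{c.ref_aa}{c.first_residue}{c.alt_aa}"
    if k is ConsequenceKind.NONSENSE:
        return f"p.{c.ref_aa}{c.first_residue}Ter"
    if k is ConsequenceKind.FRAMESHIFT:
        return f"p.{c.ref_aa}{c.first_residue}{c.alt_aa}fsTer{c.ter_offset}"
    if k is ConsequenceKind.NO_STOP_FOUND:
        return f"p.{c.ref_aa}{c.first_residue}{c.alt_aa}fsTer?"
    # in-frame indel: replaced ref run -> alt run (may be empty = pure deletion)
    left = f"{c.ref_aa}{c.first_residue}"
    if c.last_residue is not None and c.last_residue != c.first_residue:
        left += f"_{c.last_ref_aa}{c.last_residue}"
    if c.alt_aa:
        return f"p.{left}delins{c.alt_aa}"
    return f"p.{left}del"


def protein_consequence(model: TranscriptModel, var: HgvsVariant) -> ProteinConsequence:
    """Derive the protein consequence of a small coding variant.

    The reference CDS and the mutated transcript (read from the start
    codon through the transcript end, i.e. into the 3'UTR when a
    frameshift runs past the old stop) are translated and compared
    residue by residue.  The first difference, together with the frame
    change, classifies the event:

    * no difference, frame preserved -> synonymous
    * in-frame, single residue changed -> missense, or nonsense if the
      new residue is a stop
    * in-frame, residues gained/lost -> in-frame indel
    * frame-shifting -> frameshift ``p.XxxNYyyfsTerM`` where M counts
      the new stop with the first changed residue as 1; if the first
      shifted codon is itself a stop the event is reported as nonsense
      (``p.XxxNTer``), and if no stop occurs before the transcript ends
      the kind is ``no_stop_found``.
    """
    if var.end_c > model.cds_length:
        raise ConsequenceError(
            f"{var.raw}: variant extends beyond the CDS (consequences outside "
            "the coding region are not called)"
        )
    mutated = apply_variant(model, var)
    p_ref, _ = translate(model.cds)
    tail = mutated[model.cds_start - 1 :]
    p_mut, mut_stop_found = translate(tail)

    frame_change = var.length_change() % 3

    # first differing residue (0-based)
    i = 0
    limit = min(len(p_ref), len(p_mut))
    while i < limit and p_ref[i] == p_mut[i]:
        i += 1

    if frame_change == 0 and p_ref == p_mut and len(p_ref) == len(p_mut):
        first = ref3 = None
        if var.kind is VariantKind.SUBSTITUTION:
            first = (var.start_c - 1) // 3 + 1
            ref3 = AA3[p_ref[first - 1]]
        return ProteinConsequence(ConsequenceKind.SYNONYMOUS, first, ref3, ref3)

    if i == len(p_ref):
        # reference protein is a strict prefix: stop codon disturbed
        raise ConsequenceError(
            f"{var.raw}: stop-loss / extension variants are not supported"
        )

    ref_aa1 = p_ref[i]
    alt_aa1 = p_mut[i] if i < len(p_mut) else "*"  # '*' when mutant stops early at i

    if frame_change == 0:
        if alt_aa1 == "*" and i < len(p_mut):
            # in-frame change whose first altered codon is a stop
            return ProteinConsequence(
                ConsequenceKind.NONSENSE, i + 1, AA3[ref_aa1], "Ter"
            )
        if len(p_ref) == len(p_mut):
            if i < len(p_mut) and p_ref[i + 1 :] == p_mut[i + 1 :]:
                return ProteinConsequence(
                    ConsequenceKind.MISSENSE, i + 1, AA3[ref_aa1], AA3[alt_aa1]
                )
            # same length but several residues substituted: delins naming
        if i == len(p_mut) and not mut_stop_found:
            return ProteinConsequence(
                ConsequenceKind.NO_STOP_FOUND, i + 1, AA3[ref_aa1], None
            )
        if i == len(p_mut):
            # truncation by early stop at residue i+1
            return ProteinConsequence(
                ConsequenceKind.NONSENSE, i + 1, AA3[ref_aa1], "Ter"
            )
        # in-frame indel: align from the right to find the replaced run
        j_ref, j_mut = len(p_ref), len(p_mut)
        while j_ref > i and j_mut > i and p_ref[j_ref - 1] == p_mut[j_mut - 1]:
            j_ref -= 1
            j_mut -= 1
        alt_run = "".join(AA3[a] for a in p_mut[i:j_mut])
        if i == j_ref:  # pure insertion of residues; name as delins over flanking residue
            j_ref = i + 1
            alt_run = AA3[p_ref[i]] + alt_run
        return ProteinConsequence(
            ConsequenceKind.INFRAME_INDEL,
            i + 1,
            AA3[p_ref[i]],
            alt_run,
            last_residue=j_ref if j_ref > i + 1 else None,
            last_ref_aa=AA3[p_ref[j_ref - 1]] if j_ref > i + 1 else None,
        )

    # frameshift
    if i >= len(p_mut):
        if mut_stop_found:
            # shifted frame's first changed codon is a stop -> nonsense
            return ProteinConsequence(ConsequenceKind.NONSENSE, i + 1, AA3[ref_aa1], "Ter")
        return ProteinConsequence(ConsequenceKind.NO_STOP_FOUND, i + 1, AA3[ref_aa1], None)
    if not mut_stop_found:
        return ProteinConsequence(
            ConsequenceKind.NO_STOP_FOUND, i + 1, AA3[ref_aa1], AA3[alt_aa1]
        )
    ter_offset = len(p_mut) - i + 1  # stop sits right after p_mut; first changed = 1
    return ProteinConsequence(
        ConsequenceKind.FRAMESHIFT, i + 1, AA3[ref_aa1], AA3[alt_aa1], ter_offset
    )
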