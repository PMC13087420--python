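"""Transcript data model and coordinate arithmetic.

Everything downstream (variant application, assay overlap, digestion,
simulation) works in the coordinate frame defined here: a spliced
transcript sequence with 1-based HGVS ``c.`` positions on the coding
sequence and ``*n`` positions in the 3'UTR.  Internal indices are
0-based half-open; the conversion happens only in :func:`c_to_index`
and :func:`index_to_c`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_IUPAC = set("ACGTRYSWKMBDHVN")
_AMBIGUOUS = _IUPAC - set("ACGT")


class RefModelError(ValueError):
    """Invalid transcript model or unresolvable position."""


class UnsupportedPositionError(RefModelError):
    """HGVS position syntax outside the supported (c.N / c.*N) grammar."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with CDS bounds and exon structure.

    Parameters
    ----------
    id : str
        Transcript identifier.
    sequence : str
        Transcript-space nucleotide sequence, 5'->3', uppercase ACGT.
    cds_start, cds_end : int
        1-based transcript positions of the first base of the start
        codon and the last base of the stop codon.
    exons : tuple of (int, int)
        Ordered 1-based closed intervals in transcript space that tile
        the sequence exactly.
    discriminating_positions : tuple of (str, str)
        ``(c_position, base)`` pairs marking bases that distinguish the
        transcript from its paralog.  Positions use HGVS coding syntax:
        ``"840"`` or ``"*11"``.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]
    discriminating_positions: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(
            self,
            "discriminating_positions",
            tuple((str(p), b.upper()) for p, b in self.discriminating_positions),
        )
        seq = self.sequence
        if not seq:
            raise RefModelError(f"{self.id}: empty sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise RefModelError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        if not (1 <= self.cds_start < self.cds_end <= len(seq)):
            raise RefModelError(f"{self.id}: CDS bounds outside transcript")
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3 != 0 or cds_len < 6:
            raise RefModelError(f"{self.id}: CDS length {cds_len} not a positive multiple of 3")
        cds = self.cds
        if not cds.startswith("ATG"):
            raise RefModelError(f"{self.id}: CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise RefModelError(f"{self.id}: CDS does not end with a stop codon")
        # exons must tile [1, len] with no gaps or overlaps
        cursor = 1
        for start, end in self.exons:
            if start != cursor or end < start:
                raise RefModelError(f"{self.id}: exons do not tile the transcript at {start}")
            cursor = end + 1
        if cursor != len(seq) + 1:
            raise RefModelError(f"{self.id}: exons end at {cursor - 1}, transcript length {len(seq)}")
        for c_pos, base in self.discriminating_positions:
            idx = c_to_index(self, c_pos)
            if self.sequence[idx] != base:
                raise RefModelError(
                    f"{self.id}: discriminating position c.{c_pos} is "
                    f"{self.sequence[idx]}, declared {base}"
                )

    @property
    def cds(self) -> str:
        """Coding sequence, start codon through stop codon."""
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def exon_interval(self, ordinal: int) -> tuple[int, int]:
        """1-based closed transcript interval of the given exon ordinal."""
        return self.exons[ordinal - 1]

    def to_annotation_dict(self) -> dict:
        return {
            "id": self.id,
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "exons": [list(e) for e in self.exons],
            "discriminating_positions": [list(d) for d in self.discriminating_positions],
        }


_C_POS_RE = re.compile(r"^(\*)?(\d+)$")
_INTRONIC_RE = re.compile(r"^\*?\d+[+-]\d+$")


def c_to_index(model: TranscriptModel, c_pos: int | str) -> int:
    """Convert an HGVS coding position to a 0-based transcript index.

    Supports positive coding positions (``855`` or ``"855"``) and 3'UTR
    positions (``"*11"``).  Intronic offsets (``"100+3"``) are rejected:
    the model is spliced-transcript space and cannot represent them.
    """
    text = str(c_pos)
    if _INTRONIC_RE.match(text):
        raise UnsupportedPositionError(f"intronic offset position 'c.{text}' is not supported")
    m = _C_POS_RE.match(text)
    if not m:
        raise UnsupportedPositionError(f"cannot parse position 'c.{text}'")
    utr3, n = m.group(1), int(m.group(2))
    if n < 1:
        raise UnsupportedPositionError(f"position 'c.{text}' must be >= 1 (5'UTR positions unsupported)")
    if utr3:
        idx = model.cds_end + (n - 1)
    else:
        idx = model.cds_start - 1 + (n - 1)
    if idx >= len(model.sequence):
        raise RefModelError(
            f"position c.{text} maps beyond transcript end ({len(model.sequence)} nt)"
        )
    return idx


def index_to_c(model: TranscriptModel, idx: int) -> str:
    """Inverse of :func:`c_to_index` for indices at or past the CDS start."""
    if not 0 <= idx < len(model.sequence):
        raise RefModelError(f"index {idx} outside transcript")
    if idx >= model.cds_end:
        return f"*{idx - model.cds_end + 1}"
    if idx >= model.cds_start - 1:
        return str(idx - (model.cds_start - 1) + 1)
    raise UnsupportedPositionError("5'UTR indices have no supported c. representation")


def exon_of(model: TranscriptModel, c_pos: int | str) -> int:
    """1-based ordinal of the exon containing an HGVS coding position."""
    pos1 = c_to_index(model, c_pos) + 1
    for ordinal, (start, end) in enumerate(model.exons, start=1):
        if start <= pos1 <= end:
            return ordinal
    raise RefModelError(f"position c.{c_pos} not covered by any exon")  # pragma: no cover


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA into a dict.

    Sequences are uppercased and whitespace-stripped.  IUPAC ambiguity
    codes are preserved but logged; characters outside the IUPAC
    nucleotide set raise, naming the record and offset.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        for offset, ch in enumerate(seq):
            if ch not in _IUPAC:
                raise RefModelError(
                    f"record '{rec.id}': non-nucleotide character {ch!r} at offset {offset}"
                )
        ambiguous = set(seq) & _AMBIGUOUS
        if ambiguous:
            logger.warning("record %s contains IUPAC ambiguity codes %s", rec.id, sorted(ambiguous))
        records[rec.id] = seq
    if not records:
        raise RefModelError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def save_annotation(model: TranscriptModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_annotation_dict(), indent=2) + "\n")


def load_annotation(path: str | Path, sequences: dict[str, str]) -> TranscriptModel:
    """Build a TranscriptModel from an annotation JSON plus its FASTA sequence."""
    meta = json.loads(Path(path).read_text())
    if meta["id"] not in sequences:
        raise RefModelError(f"sequence for transcript {meta['id']!r} not found in FASTA")
    return TranscriptModel(
        id=meta["id"],
        sequence=sequences[meta["id"]],
        cds_start=meta["cds_start"],
        cds_end=meta["cds_end"],
        exons=tuple(tuple(e) for e in meta["exons"]),
        discriminating_positions=tuple(tuple(d) for d in meta.get("discriminating_positions", [])),
    )
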