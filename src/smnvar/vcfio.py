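"""Transcript-space VCF ingestion.

A deliberately narrow VCF dialect: POS is the 1-based HGVS c. position
on the spliced transcript (NOT a genomic coordinate), and REF/ALT follow
ordinary VCF left-anchored conventions.  This maps the common SNV /
simple indel shapes onto :class:`~smnvar.hgvs.HgvsVariant`; anything
else (multi-allelic rows, symbolic alleles) is rejected.
"""

from __future__ import annotations

from pathlib import Path

from cyvcf2 import VCF

from .hgvs import HgvsVariant, parse_hgvs_c


def read_transcript_vcf(path: str | Path) -> list[tuple[str, HgvsVariant]]:
    """Read a transcript-space VCF into (variant_id, HgvsVariant) pairs."""
    out: list[tuple[str, HgvsVariant]] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at POS {rec.POS}: split first")
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if not (set(ref) <= set("ACGT") and set(alt) <= set("ACGT")):
            raise ValueError(f"symbolic or non-ACGT allele at POS {rec.POS}")
        pos = rec.POS
        if len(ref) == 1 and len(alt) == 1:
            text = f"c.{pos}{ref}>{alt}"
        elif len(alt) == 1 and ref[0] == alt:  # left-anchored deletion
            start, end = pos + 1, pos + len(ref) - 1
            deleted = ref[1:]
            text = f"c.{start}del{deleted}" if start == end else f"c.{start}_{end}del{deleted}"
        elif len(ref) == 1 and alt[0] == ref:  # left-anchored insertion
            text = f"c.{pos}_{pos + 1}ins{alt[1:]}"
        else:
            end = pos + len(ref) - 1
            text = f"c.{pos}_{end}delins{alt}" if end > pos else f"c.{pos}delins{alt}"
        vid = rec.ID or f"c{pos}"
        out.append((vid, parse_hgvs_c(text)))
    return out
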