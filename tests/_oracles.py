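"""Independent brute-force oracles used to cross-check the implementation.

Deliberately built on different machinery: Biopython's translation table
(vs the package's hard-coded codon dict), direct string surgery from the
parsed variant fields (vs apply_variant), and a regex expansion of IUPAC
motifs (vs the sliding-window scanner).
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Seq import Seq

from smnvar.hgvs import HgvsVariant, VariantKind, parse_hgvs_c
from smnvar.refmodel import TranscriptModel


def oracle_mutate(model: TranscriptModel, var: HgvsVariant) -> str:
    seq = model.sequence
    i = model.cds_start - 1 + var.start_c - 1
    j = model.cds_start - 1 + var.end_c - 1
    if var.kind is VariantKind.SUBSTITUTION:
        return seq[:i] + var.alt_allele + seq[i + 1 :]
    if var.kind is VariantKind.DELETION:
        return seq[:i] + seq[j + 1 :]
    if var.kind is VariantKind.INSERTION:
        return seq[: i + 1] + var.alt_allele + seq[i + 1 :]
    if var.kind is VariantKind.DUPLICATION:
        return seq[: j + 1] + seq[i : j + 1] + seq[j + 1 :]
    return seq[:i] + var.alt_allele + seq[j + 1 :]


def _bio_translate(seq: str) -> tuple[str, bool]:
    trimmed = seq[: len(seq) - len(seq) % 3]
    protein = str(Seq(trimmed).translate())
    stop = protein.find("*")
    if stop >= 0:
        return protein[:stop], True
    return protein, False


def oracle_consequence(model: TranscriptModel, var: HgvsVariant) -> dict:
    """Kind / first residue / ter offset by direct translation comparison."""
    mutated = oracle_mutate(model, var)
    p_ref, _ = _bio_translate(model.cds)
    p_mut, stop_found = _bio_translate(mutated[model.cds_start - 1 :])
    shift = (len(mutated) - len(model.sequence)) % 3

    i = next((k for k in range(min(len(p_ref), len(p_mut)))
              if p_ref[k] != p_mut[k]), min(len(p_ref), len(p_mut)))

    if shift == 0 and p_ref == p_mut:
        return {"kind": "synonymous", "first_residue": None, "ter_offset": None}
    if i == len(p_ref):
        # reference protein is a strict prefix of the mutant: stop disturbed
        return {"kind": "stop_loss", "first_residue": None, "ter_offset": None}
    if shift == 0:
        if i == len(p_mut):
            return {"kind": "nonsense", "first_residue": i + 1, "ter_offset": None}
        if len(p_ref) == len(p_mut) and p_ref[i + 1 :] == p_mut[i + 1 :]:
            return {"kind": "missense", "first_residue": i + 1, "ter_offset": None}
        return {"kind": "inframe_indel", "first_residue": i + 1, "ter_offset": None}
    if i >= len(p_mut):
        if stop_found:
            return {"kind": "nonsense", "first_residue": i + 1, "ter_offset": None}
        return {"kind": "no_stop_found", "first_residue": i + 1, "ter_offset": None}
    if not stop_found:
        return {"kind": "no_stop_found", "first_residue": i + 1, "ter_offset": None}
    return {"kind": "frameshift", "first_residue": i + 1,
            "ter_offset": len(p_mut) - i + 1}


def random_coding_variant(rng: np.random.Generator, model: TranscriptModel) -> HgvsVariant:
    """A random small variant safely inside the CDS (clear of the stop codon)."""
    last_safe = model.cds_length - 3  # keep the stop codon untouched
    kind = rng.choice(["sub", "del1", "del3", "del4", "ins1", "ins2", "dup", "delins"])
    pos = int(rng.integers(1, last_safe - 8))
    seq_at = lambda n, ln: model.sequence[model.cds_start - 1 + n - 1 :
                                          model.cds_start - 1 + n - 1 + ln]
    bases = "ACGT"
    if kind == "sub":
        ref = seq_at(pos, 1)
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        return parse_hgvs_c(f"c.{pos}{ref}>{alt}")
    if kind == "del1":
        return parse_hgvs_c(f"c.{pos}del")
    if kind in ("del3", "del4"):
        ln = 3 if kind == "del3" else 4
        return parse_hgvs_c(f"c.{pos}_{pos + ln - 1}del{seq_at(pos, ln)}")
    if kind == "ins1":
        return parse_hgvs_c(f"c.{pos}_{pos + 1}ins{bases[int(rng.integers(0, 4))]}")
    if kind == "ins2":
        ins = "".join(bases[int(rng.integers(0, 4))] for _ in range(2))
        return parse_hgvs_c(f"c.{pos}_{pos + 1}ins{ins}")
    if kind == "dup":
        ln = int(rng.integers(1, 5))
        if ln == 1:
            return parse_hgvs_c(f"c.{pos}dup")
        return parse_hgvs_c(f"c.{pos}_{pos + ln - 1}dup")
    ln = int(rng.integers(1, 4))
    ins = "".join(bases[int(rng.integers(0, 4))] for _ in range(int(rng.integers(1, 5))))
    return parse_hgvs_c(f"c.{pos}_{pos + ln - 1}delins{ins}")


def implementation_summary(model: TranscriptModel, var: HgvsVariant) -> dict:
    """The engine's call, projected onto the fields the oracle reports."""
    from smnvar.hgvs import ConsequenceError, protein_consequence

    try:
        c = protein_consequence(model, var)
    except ConsequenceError:
        return {"kind": "stop_loss", "first_residue": None, "ter_offset": None}
    kind = c.kind.value
    return {
        "kind": kind,
        "first_residue": None if kind == "synonymous" else c.first_residue,
        "ter_offset": c.ter_offset if kind == "frameshift" else None,
    }


def regex_find_sites(seq: str, motif: str, cut_offset: int) -> list[int]:
    """IUPAC motif scan via regex lookahead (overlapping matches)."""
    expand = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
              "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
              "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]"}
    pattern = re.compile("(?=" + "".join(expand[m] for m in motif) + ")")
    cuts = [m.start() + cut_offset for m in pattern.finditer(seq)]
    return [c for c in cuts if 0 < c < len(seq)]
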