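"""Predicted effect of small variants on PCR/qPCR amplification.

Newborn-screening assays for SMA call SMN1 absent when its exon-7
amplicon yields no signal.  A variant under a primer or probe can
abolish that signal from an allele that is otherwise present — the
false-positive mechanism this module screens for.  Assay intervals are
declared in 1-based closed HGVS c. coordinates; the real kits' primer
sequences are proprietary, so assays are user-supplied configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .hgvs import HgvsVariant, VariantKind


class ComponentRole(str, Enum):
    FORWARD_PRIMER = "forward_primer"
    REVERSE_PRIMER = "reverse_primer"
    PROBE = "probe"


# tie-break precedence when several components share the maximal overlap
_ROLE_PRECEDENCE = {
    ComponentRole.FORWARD_PRIMER: 0,
    ComponentRole.REVERSE_PRIMER: 1,
    ComponentRole.PROBE: 2,
}


class DropoutClass(str, Enum):
    NO_OVERLAP = "no_overlap"
    AT_RISK_SUBSTITUTION = "at_risk_substitution"
    LIKELY_DROPOUT_3PRIME_SUBSTITUTION = "likely_dropout_3prime_substitution"
    LIKELY_DROPOUT_INDEL = "likely_dropout_indel"


@dataclass(frozen=True)
class AssayComponent:
    role: ComponentRole
    start_c: int
    end_c: int

    def __post_init__(self) -> None:
        if self.start_c > self.end_c:
            raise ValueError(f"empty component interval ({self.start_c}, {self.end_c})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_c, self.end_c)

    @property
    def three_prime_c(self) -> int | None:
        """Transcript-orientation position of the primer's 3' terminus.

        Forward primers extend rightward (3' end = right boundary);
        reverse primers anneal to the opposite strand and extend leftward
        in transcript orientation (3' end = left boundary).  Probes have
        no polarity here.
        """
        if self.role is ComponentRole.FORWARD_PRIMER:
            return self.end_c
        if self.role is ComponentRole.REVERSE_PRIMER:
            return self.start_c
        return None


@dataclass(frozen=True)
class AssayDefinition:
    name: str
    components: tuple[AssayComponent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def annealing_region(self) -> tuple[int, int]:
        """Smallest interval covering every primer/probe component."""
        return (
            min(c.start_c for c in self.components),
            max(c.end_c for c in self.components),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "components": [
                {"role": c.role.value, "start_c": c.start_c, "end_c": c.end_c}
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayDefinition":
        return cls(
            name=d["name"],
            components=tuple(
                AssayComponent(ComponentRole(c["role"]), int(c["start_c"]), int(c["end_c"]))
                for c in d["components"]
            ),
        )


@dataclass(frozen=True)
class DropoutCall:
    variant_id: str
    assay_name: str
    component_hit: ComponentRole | None
    overlap_bases: int
    classification: DropoutClass
    rationale: str


def overlap_bases(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Bases shared by two 1-based closed intervals (0 if disjoint)."""
    (a1, a2), (b1, b2) = span_a, span_b
    if a1 > a2 or b1 > b2:
        raise ValueError("interval start must not exceed end")
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def classify_variant_vs_assay(
    var: HgvsVariant,
    assay: AssayDefinition,
    three_prime_window: int = 5,
    variant_id: str | None = None,
) -> DropoutCall:
    """Classify a variant's predicted effect on one assay.

    Rule cascade: (1) no component overlapped -> ``no_overlap``;
    (2) any indel/dup/delins overlapping any component -> ``likely_dropout_indel``
    (a length change under a primer or probe distorts annealing far more
    than a single mismatch); (3) a substitution within
    ``three_prime_window`` bases of a primer's 3' terminus (terminal base
    counts as the first) -> ``likely_dropout_3prime_substitution``
    (polymerase extension requires a matched 3' end); (4) any other
    overlapping substitution, including probe hits ->
    ``at_risk_substitution``.
    """
    vid = variant_id or var.raw
    span = var.span
    hits = [(c, overlap_bases(span, c.interval)) for c in assay.components]
    hits = [(c, ob) for c, ob in hits if ob > 0]
    if not hits:
        return DropoutCall(vid, assay.name, None, 0, DropoutClass.NO_OVERLAP,
                           "variant span overlaps no primer or probe interval")
    # component with maximal overlap; ties by fixed role precedence
    component, ob = max(hits, key=lambda h: (h[1], -_ROLE_PRECEDENCE[h[0].role]))
    if var.kind is not VariantKind.SUBSTITUTION:
        return DropoutCall(
            vid, assay.name, component.role, ob, DropoutClass.LIKELY_DROPOUT_INDEL,
            f"{var.kind.value} overlapping {component.role.value} "
            f"({component.start_c}-{component.end_c}) by {ob} base(s)",
        )
    for c, c_ob in hits:
        tp = c.three_prime_c
        if tp is not None and abs(var.start_c - tp) <= three_prime_window - 1:
            return DropoutCall(
                vid, assay.name, c.role, c_ob,
                DropoutClass.LIKELY_DROPOUT_3PRIME_SUBSTITUTION,
                f"substitution within {three_prime_window} bases of the "
                f"{c.role.value} 3' terminus (c.{tp})",
            )
    return DropoutCall(
        vid, assay.name, component.role, ob, DropoutClass.AT_RISK_SUBSTITUTION,
        f"substitution overlapping {component.role.value} away from any 3' terminus",
    )


@dataclass
class ScreenReport:
    calls: list[DropoutCall]
    summary: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.summary = {cls.value: 0 for cls in DropoutClass}
        for call in self.calls:
            self.summary[call.classification.value] += 1

    @property
    def flagged(self) -> list[DropoutCall]:
        """Calls with any predicted assay impact (the annealing-region set)."""
        return [c for c in self.calls if c.classification is not DropoutClass.NO_OVERLAP]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant_id": c.variant_id,
                    "assay_name": c.assay_name,
                    "component_hit": c.component_hit.value if c.component_hit else "",
                    "overlap_bases": c.overlap_bases,
                    "classification": c.classification.value,
                    "rationale": c.rationale,
                }
                for c in self.calls
            ],
            columns=["variant_id", "assay_name", "component_hit", "overlap_bases",
                     "classification", "rationale"],
        )


def screen_table(
    variants: list[tuple[str, HgvsVariant]],
    assays: list[AssayDefinition],
    three_prime_window: int = 5,
) -> ScreenReport:
    """One DropoutCall per variant x assay, with per-class summary counts."""
    calls = [
        classify_variant_vs_assay(var, assay, three_prime_window, variant_id=vid)
        for vid, var in variants
        for assay in assays
    ]
    return ScreenReport(calls)


def load_assays_json(path: str | Path) -> list[AssayDefinition]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [AssayDefinition.from_dict(d) for d in data]


def save_assays_json(assays: list[AssayDefinition], path: str | Path) -> None:
    Path(path).write_text(json.dumps([a.to_dict() for a in assays], indent=2) + "\n")


def load_assays_tsv(path: str | Path) -> list[AssayDefinition]:
    """BED-like TSV, but 1-based closed intervals in c. space.

    Columns: assay_name, role, start_c, end_c.
    """
    df = pd.read_csv(path, sep="\t")
    assays = []
    for name, group in df.groupby("assay_name", sort=False):
        components = tuple(
            AssayComponent(ComponentRole(row.role), int(row.start_c), int(row.end_c))
            for row in group.itertuples()
        )
        assays.append(AssayDefinition(str(name), components))
    return assays
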