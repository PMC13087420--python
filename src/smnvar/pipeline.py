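"""One call from input files to a combined decision-support report.

The report joins, per variant: the HGVS protein consequence, the
predicted assay-dropout classification, and the carrier frequency —
then, over all variants of the stratum, the compound-heterozygote
frequency chain with its expected individual and annual-birth counts.
Reports are reproducible: no timestamps in the JSON, input hashes and
the seed in provenance, byte-identical on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assay import AssayDefinition, load_assays_json, screen_table
from .epi import CohortSpec, load_cohort_json, load_frequency_records, risk_report
from .hgvs import parse_hgvs_c, protein_consequence
from .refmodel import TranscriptModel, load_annotation, load_fasta

logger = logging.getLogger(__name__)


@dataclass
class ReportConfig:
    fasta: str
    transcript_json: str
    variants_tsv: str
    assay_json: str
    cohort_json: str | None = None
    cohort: CohortSpec | None = None
    three_prime_window: int = 5
    apply_screening_coverage: bool = False
    seed: int | None = None
    extra_provenance: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "ReportConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_report(config: ReportConfig) -> dict:
    """Execute consequence calling -> dropout screen -> risk arithmetic.

    Raises on any schema or reference-mismatch error before anything is
    written; an empty variant table yields a report with zero rows and
    no epidemiology section.
    """
    sequences = load_fasta(config.fasta)
    model: TranscriptModel = load_annotation(config.transcript_json, sequences)
    assays: list[AssayDefinition] = load_assays_json(config.assay_json)
    table = pd.read_csv(config.variants_tsv, sep="\t")
    cohort = config.cohort
    if cohort is None and config.cohort_json:
        cohort = load_cohort_json(config.cohort_json)

    logger.info("model %s: CDS %d-%d, %d exons; %d variants; %d assay(s); "
                "3' window %d",
                model.id, model.cds_start, model.cds_end, len(model.exons),
                len(table), len(assays), config.three_prime_window)

    variants = [(str(row.variant_id), parse_hgvs_c(str(row.hgvs_c)))
                for row in table.itertuples()]
    consequences = {vid: protein_consequence(model, var) for vid, var in variants}
    screen = screen_table(variants, assays, config.three_prime_window)
    dropout_by_vid = {(c.variant_id, c.assay_name): c for c in screen.calls}

    rows = []
    for row in table.itertuples():
        vid = str(row.variant_id)
        cons = consequences[vid]
        for assay in assays:
            call = dropout_by_vid[(vid, assay.name)]
            rows.append({
                "variant_id": vid,
                "hgvs_c": str(row.hgvs_c),
                "hgvs_p": cons.hgvs_p,
                "consequence_kind": cons.kind.value,
                "assay_name": assay.name,
                "dropout_classification": call.classification.value,
                "component_hit": call.component_hit.value if call.component_hit else "",
                "population": str(row.population),
                "carrier_count": int(row.carrier_count),
                "n_individuals": int(row.n_individuals),
                "carrier_frequency": int(row.carrier_count) / int(row.n_individuals),
                "annotation_flags": "" if pd.isna(row.annotation_flags) else str(row.annotation_flags),
            })

    report: dict = {
        "tool_version": __version__,
        "per_variant": rows,
        "screen_summary": screen.summary,
        "provenance": {
            "inputs": {
                "fasta": _sha256(config.fasta),
                "transcript_json": _sha256(config.transcript_json),
                "variants_tsv": _sha256(config.variants_tsv),
                "assay_json": _sha256(config.assay_json),
            },
            "seed": config.seed,
            "three_prime_window": config.three_prime_window,
            **config.extra_provenance,
        },
    }

    if len(table) and cohort is not None:
        # epidemiology runs on the assay-impacted subset, the set an
        # undetectable-in-trans compound heterozygote can be drawn from
        flagged_ids = {c.variant_id for c in screen.flagged}
        records = [
            r for r in load_frequency_records(config.variants_tsv)
            if r.variant_id in flagged_ids
        ]
        if records:
            estimates = risk_report(records, cohort,
                                    apply_screening_coverage=config.apply_screening_coverage)
            report["epidemiology"] = {k: v.to_dict() for k, v in estimates.items()}
            report["provenance"]["cohort"] = cohort.to_dict()
    return report


def write_report(report: dict, out_dir: str | Path) -> dict[str, str]:
    """Write the JSON report and its per-variant TSV companion."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    tsv_path = out_dir / "report_per_variant.tsv"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(report["per_variant"]).to_csv(tsv_path, sep="\t", index=False)
    return {"json": str(json_path), "tsv": str(tsv_path)}
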