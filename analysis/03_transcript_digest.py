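#!/usr/bin/env python
"""Paralog and isoform discrimination by in-silico DdeI digestion.

Generates the four cDNA amplicon species (SMN1/SMN2 x FL/Delta7 over
exons 5-8), digests each with DdeI (C^TNAG), and classifies them: the
paralogous site in the SMN2-like exon 8 is cut, the SMN1-like one is
not; the exon-7 tag separates full-length from exon-7-skipped
transcripts.  All four labels are recovered exactly — the in-silico
counterpart of reading the gel banding pattern.
"""

import argparse
from pathlib import Path

import pandas as pd

from smnvar.cohort import make_scenario
from smnvar.digest import DDEI, classify_transcript, digest


def main(seed: int, out_dir: Path) -> None:
    scenario = make_scenario(seed)
    rows = []
    for name, seq in scenario.amplicons().items():
        result = digest(seq, DDEI)
        label = classify_transcript(seq, scenario.smn1, scenario.smn2,
                                    scenario.exon7_tag, scenario.exon8_window)
        truth_gene, truth_iso = name.split("_")
        rows.append({
            "amplicon": name, "length": result.input_length,
            "fragments": ",".join(map(str, result.fragments)),
            "called_gene": label["gene"], "called_isoform": label["isoform"],
            "correct": label == {"gene": truth_gene, "isoform": truth_iso},
        })
    df = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "transcript_digest.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")
    print(df.to_string(index=False))
    assert df.correct.all()
    print("2x2 classification (gene x isoform) exactly recovered.")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=7)
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    a = p.parse_args()
    main(a.seed, a.out_dir)
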