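#!/usr/bin/env python
"""Protein consequences of the exon-7 hotspot variants.

Derives, on the SMN1-like transcript (C-terminal coding region
reconstructed from the published variant constraints), the protein-level
outcome of the two screening-failure 4-bp deletions and the two
comparison variants, plus every variant in the synthetic annealing-region
table.  Key finding: c.855_858delAGAA and c.861_864delAAGG shift into the
same reading frame and therefore share one consequence, p.Arg288AlafsTer5.
"""

import argparse
from pathlib import Path

import pandas as pd

from smnvar.cohort import make_scenario
from smnvar.hgvs import parse_hgvs_c, protein_consequence

HOTSPOT = ["c.855_858delAGAA", "c.861_864delAAGG", "c.861_862insT", "c.863G>T"]


def main(seed: int, out_dir: Path) -> None:
    scenario = make_scenario(seed)
    model = scenario.smn1

    rows = []
    for text in HOTSPOT:
        cons = protein_consequence(model, parse_hgvs_c(text))
        rows.append({"hgvs_c": text, "hgvs_p": cons.hgvs_p, "kind": cons.kind.value,
                     "first_residue": cons.first_residue, "set": "hotspot"})
    for vid, var in scenario.variants:
        cons = protein_consequence(model, var)
        rows.append({"hgvs_c": var.raw, "hgvs_p": cons.hgvs_p, "kind": cons.kind.value,
                     "first_residue": cons.first_residue, "set": "synthetic_table"})

    df = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = out_dir / "protein_consequences.tsv"
    df.to_csv(out, sep="\t", index=False)

    fs = df[(df["set"] == "hotspot") & df.hgvs_c.str.contains("855_858|861_864")]
    print(f"wrote {out} ({len(df)} rows)")
    print("hotspot deletions:", " and ".join(fs.hgvs_c), "->", set(fs.hgvs_p))
    assert set(fs.hgvs_p) == {"p.Arg288AlafsTer5"}
    print("distinct 4-bp deletions, one shared frameshift consequence.")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=7)
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    a = p.parse_args()
    main(a.seed, a.out_dir)
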