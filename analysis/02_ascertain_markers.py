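#!/usr/bin/env python
"""Select candidate CpGs from the literature-style EWAS-evidence table.

Applies the three inclusion criteria (>= 2 studies, >= 10% beta difference
in at least one study, sign-consistent across studies) and reports the
resulting candidate panel — 20 CpGs under the bundled evidence table, with
the deliberately failing probes excluded.
"""

import argparse
from pathlib import Path

from smokesig.ascertainment import filter_candidates
from smokesig.datasets import default_ewas_evidence
from smokesig.io import write_evidence, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

evidence = default_ewas_evidence(seed=args.seed)
candidates = filter_candidates(evidence)

write_evidence(evidence, args.outdir / "ewas_evidence.tsv")
write_table(candidates.to_frame(), args.outdir / "candidates.tsv")

print(f"evidence rows: {len(evidence)} over {evidence['cpg_id'].nunique()} CpGs")
print(f"candidates passing all three criteria: {len(candidates)}")
print(candidates.to_frame().to_string())
excluded = sorted(set(evidence["cpg_id"]) - set(candidates.cpg_ids))
print(f"excluded: {excluded}")
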