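#!/usr/bin/env python
"""QC the cohort, run backward elimination, and apply the chi-squared stop.

Reads the cohort written by 01_simulate_cohort.py (or regenerates it),
applies the three exclusion rules, then removes markers one at a time by
minimal |z| while recording the cumulative-AUC profile and the nested
likelihood-ratio test of each removal.  The selection keeps the marker set
in place before the first significant removal.
"""

import argparse
from pathlib import Path

from smokesig.elimination import backward_eliminate, chisq_stop
from smokesig.io import write_table
from smokesig.qc import apply_exclusions
from smokesig.synthetic import SyntheticParams, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

cohort = generate_cohort(SyntheticParams(seed=args.seed))
betas, phenos, log = apply_exclusions(cohort.betas, cohort.phenotypes)
print("exclusions:")
print(log.to_frame().to_string(index=False))

data = betas.join(phenos)
data["y"] = (data["status"] == "current").astype(int)
trace = backward_eliminate(data, list(betas.columns), label_col="y")
selected = chisq_stop(trace, alpha=args.alpha)

write_table(trace.to_frame(), args.outdir / "elimination_trace.tsv", index=False)
(args.outdir / "selected_markers.txt").write_text("\n".join(selected) + "\n")

print(f"\nfull {len(trace.initial_markers)}-CpG model AUC: {trace.initial_auc:.4f}")
print(trace.to_frame().to_string(index=False))
informative = set(cohort.informative_cpgs())
print(f"\nselected {len(selected)} markers at alpha={args.alpha}: {sorted(selected)}")
print(f"planted informative markers recovered: {len(set(selected) & informative)}/13")
print(
    "note: under the correlated default generator some planted markers are\n"
    "conditionally redundant (their signal is carried by the shared dose\n"
    "latent), so the stop can discard them; the dedicated recovery study\n"
    "(synthetic.recovery_study_params) uses the noise-limited configuration\n"
    "in which every planted marker is conditionally informative."
)
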