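"""Reference fixtures: published call counts and a literature-style
EWAS-evidence table.

The cohort methylation data behind the published smoking classifiers are
access-restricted, but several of their summary tables are fully determined
by printed counts.  This module encodes those counts so the package's
confusion/partition arithmetic can be checked against them, and provides a
synthetic EWAS-evidence table whose signs and magnitudes are consistent
with the 20 top smoking-associated CpGs that the three ascertainment
criteria select.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import NEAR_NULL_IDS, default_cpg_panel

__all__ = [
    "COTININE_SUBSET_CELLS",
    "cotinine_concordance_calls",
    "children_reference_calls",
    "REPORTED_BINARY_APPARENT_AUC",
    "REPORTED_BINARY_OPTIMISM",
    "default_ewas_evidence",
    "EPIC_MISSING_CPGS",
]

#: Three-way agreement cells for the 488-participant validation subset in
#: which questionnaire self-report, plasma cotinine and the 13-CpG model
#: were all available.  Keys are (questionnaire, cotinine, cpg_model) with
#: 1 = called smoker.
COTININE_SUBSET_CELLS: dict[tuple[int, int, int], int] = {
    (1, 1, 1): 75,   # smokers by all three methods
    (0, 0, 0): 340,  # non-smokers by all three methods
    (1, 0, 1): 12,   # questionnaire + CpG model only
    (1, 1, 0): 30,   # questionnaire + cotinine only
    (0, 1, 1): 2,    # cotinine + CpG model only
    (1, 0, 0): 23,   # questionnaire only
    (0, 0, 1): 2,    # CpG model only
    (0, 1, 0): 4,    # cotinine only
}

#: Reported apparent AUC of the binary 13-CpG model and its bootstrap
#: optimism (1000 replicates).
REPORTED_BINARY_APPARENT_AUC = 0.901
REPORTED_BINARY_OPTIMISM = 0.0032

#: CpGs absent from the EPIC array; dropping them gives the 10-CpG sub-model.
EPIC_MISSING_CPGS = ("cg06126421", "cg22132788", "cg05951221")

#: Reference child-application call counts: cohort size and number of
#: children correctly called non-smokers under the all-non-smoker coding.
_CHILD_CALLS = {
    "birth": (1111, 127),
    "six_years": (355, 353),
    "ten_years": (309, 307),
}


def cotinine_concordance_calls() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand the 8 agreement cells into three 488-long binary call vectors."""
    q, c, m = [], [], []
    for (a, b, d), count in sorted(COTININE_SUBSET_CELLS.items(), reverse=True):
        q += [a] * count
        c += [b] * count
        m += [d] * count
    return np.array(q), np.array(c), np.array(m)


def children_reference_calls(timepoint: str) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, labels) encoding the reference child call counts.

    All children are truly non-smokers (label 0); correct calls get a
    probability below the 0.5 threshold and incorrect calls one above it.
    ``timepoint`` is ``"birth"``, ``"six_years"`` or ``"ten_years"``.
    """
    if timepoint not in _CHILD_CALLS:
        raise ValueError(f"timepoint must be one of {sorted(_CHILD_CALLS)}")
    n, correct = _CHILD_CALLS[timepoint]
    probs = np.concatenate([np.full(correct, 0.1), np.full(n - correct, 0.9)])
    labels = np.zeros(n, dtype=int)
    return probs, labels


def default_ewas_evidence(seed: int = 0) -> pd.DataFrame:
    """A literature-style evidence table selecting exactly the 20-CpG panel.

    Each of the 20 panel CpGs (13 informative + 7 near-null decoys) appears
    in 2-4 studies with sign-consistent deltas and at least one |delta| >=
    0.10.  Extra CpGs violating one criterion each (single study, sign
    conflict, sub-threshold magnitude) are included so the three predicates
    all bind.
    """
    rng = np.random.default_rng(seed)
    rows = []
    panel = [(s.cpg_id, s.smoker_delta) for s in default_cpg_panel()]
    panel += [(c, -0.12) for c in NEAR_NULL_IDS]
    for cpg_id, lead_delta in panel:
        n_studies = int(rng.integers(2, 5))
        sign = np.sign(lead_delta)
        deltas = [abs(lead_delta)] + list(
            rng.uniform(0.03, abs(lead_delta), n_studies - 1)
        )
        start = int(rng.integers(1, 15))
        for k, d in enumerate(deltas):
            rows.append(
                {
                    "cpg_id": cpg_id,
                    "study_id": f"EWAS{(start + k - 1) % 14 + 1:02d}",
                    "delta_beta": float(sign * d),
                }
            )
    # deliberate failures, one per criterion
    rows.append({"cpg_id": "cg00000001", "study_id": "EWAS01", "delta_beta": -0.30})
    rows += [
        {"cpg_id": "cg00000002", "study_id": "EWAS01", "delta_beta": 0.12},
        {"cpg_id": "cg00000002", "study_id": "EWAS02", "delta_beta": -0.11},
    ]
    rows += [
        {"cpg_id": "cg00000003", "study_id": "EWAS03", "delta_beta": -0.05},
        {"cpg_id": "cg00000003", "study_id": "EWAS04", "delta_beta": -0.08},
    ]
    return pd.DataFrame(rows)
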