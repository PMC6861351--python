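"""Candidate-marker ascertainment from an EWAS-evidence table.

A CpG enters the candidate set only if it is (1) highlighted in at least
``min_studies`` distinct EWASs, (2) shows an absolute beta-value difference
between current smokers and never/non-smokers of at least ``min_abs_delta``
in at least one study, and (3) shows the same direction of effect in every
study that reports it.  A delta of exactly zero has no direction and fails
criterion 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = ["EwasEvidence", "CandidateSummary", "CandidateSet", "filter_candidates"]


@dataclass(frozen=True)
class EwasEvidence:
    """One study's reported beta difference for one CpG (smoker minus non-smoker)."""

    cpg_id: str
    study_id: str
    delta_beta: float


@dataclass(frozen=True)
class CandidateSummary:
    cpg_id: str
    n_studies: int
    max_abs_delta: float
    consensus_sign: int  # +1 or -1


@dataclass(frozen=True)
class CandidateSet:
    """Candidates passing all three criteria, sorted by CpG id."""

    candidates: tuple[CandidateSummary, ...]

    @property
    def cpg_ids(self) -> list[str]:
        return [c.cpg_id for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    def __contains__(self, cpg_id: str) -> bool:
        return cpg_id in set(self.cpg_ids)

    def __iter__(self):
        return iter(self.candidates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cpg_id": c.cpg_id,
                    "n_studies": c.n_studies,
                    "max_abs_delta": c.max_abs_delta,
                    "consensus_sign": c.consensus_sign,
                }
                for c in self.candidates
            ]
        ).set_index("cpg_id") if self.candidates else pd.DataFrame(
            columns=["n_studies", "max_abs_delta", "consensus_sign"],
            index=pd.Index([], name="cpg_id"),
        )


EvidenceLike = Union[pd.DataFrame, Iterable[EwasEvidence]]


def _as_frame(evidence: EvidenceLike) -> pd.DataFrame:
    if isinstance(evidence, pd.DataFrame):
        df = evidence.copy()
    else:
        df = pd.DataFrame(
            [(e.cpg_id, e.study_id, e.delta_beta) for e in evidence],
            columns=["cpg_id", "study_id", "delta_beta"],
        )
    required = {"cpg_id", "study_id", "delta_beta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("evidence table is empty")
    dupes = df.duplicated(subset=["cpg_id", "study_id"])
    if dupes.any():
        rows = df.loc[dupes, ["cpg_id", "study_id"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (cpg, study) rows: {rows}")
    bad = df[(df["delta_beta"] < -1) | (df["delta_beta"] > 1) | df["delta_beta"].isna()]
    if len(bad):
        raise ValueError(
            f"delta_beta outside [-1, 1] for rows: "
            f"{bad[['cpg_id', 'study_id', 'delta_beta']].to_records(index=False).tolist()}"
        )
    return df


def filter_candidates(
    evidence: EvidenceLike,
    min_studies: int = 2,
    min_abs_delta: float = 0.10,
) -> CandidateSet:
    """Apply the three inclusion criteria; output is order-invariant.

    Criterion 2 is inclusive (``>=``) at the threshold; criterion 3 counts a
    zero delta as a direction violation.
    """
    df = _as_frame(evidence)
    out: list[CandidateSummary] = []
    for cpg_id, grp in df.groupby("cpg_id", sort=True):
        deltas = grp["delta_beta"].to_numpy(float)
        n_studies = grp["study_id"].nunique()
        if n_studies < min_studies:
            continue
        max_abs = float(np.max(np.abs(deltas)))
        if max_abs < min_abs_delta:
            continue
        signs = np.sign(deltas)
        if np.any(signs == 0) or len(np.unique(signs)) != 1:
            continue
        out.append(
            CandidateSummary(
                cpg_id=str(cpg_id),
                n_studies=int(n_studies),
                max_abs_delta=max_abs,
                consensus_sign=int(signs[0]),
            )
        )
    return CandidateSet(tuple(out))
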