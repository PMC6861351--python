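"""Participant exclusions and smoking-history derivations.

Exclusions are applied in a fixed order: (1) missing smoking status,
(2) missing beta values for the predictive CpGs, (3) extreme per-CpG
outliers (outside mean +/- 4 SD, with the moments computed once on the
samples surviving rules 1-2).

History quantities: pack-years = cigarettes/day / 20 x years smoked;
cessation time = age - age stopped.  Two boundary conventions coexist in
the model suite and are implemented exactly as specified:

* the standalone dichotomous history models code ``value >= cutoff`` as 1
  (so cessation exactly 10 years is the "long-quit" class at horizon 10);
* the five-category lifetime coding places former smokers with cessation
  ``<= 10`` years in category 3 and ``> 10`` in category 2 (so cessation
  exactly 10 years is the "recent-quit" category there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VALID_STATUSES",
    "ExclusionLog",
    "compute_pack_years",
    "compute_cessation",
    "derive_history",
    "apply_exclusions",
    "dichotomize_history",
    "code_five_category",
]

VALID_STATUSES = ("current", "former", "never")

FIVE_CATEGORY_LABELS = {
    1: "never",
    2: "former, cessation > 10 y",
    3: "former, cessation <= 10 y",
    4: "current, below pack-year cutoff",
    5: "current, at/above pack-year cutoff",
}


def compute_pack_years(cigs_per_day, years_smoked):
    """Lifetime dose: cigarettes/day divided by 20, times years of smoking."""
    cpd = np.asarray(cigs_per_day, dtype=float)
    yrs = np.asarray(years_smoked, dtype=float)
    if np.any(cpd[~np.isnan(cpd)] < 0) or np.any(yrs[~np.isnan(yrs)] < 0):
        raise ValueError("cigs_per_day and years_smoked must be non-negative")
    out = cpd / 20.0 * yrs
    return float(out) if out.ndim == 0 else out


def compute_cessation(age, age_stopped):
    """Years since quitting: current age minus the age smoking stopped."""
    a = np.asarray(age, dtype=float)
    s = np.asarray(age_stopped, dtype=float)
    valid = ~(np.isnan(a) | np.isnan(s))
    if np.any(a[valid] < s[valid]):
        raise ValueError("age_stopped exceeds age")
    out = a - s
    return float(out) if out.ndim == 0 else out


def derive_history(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample pack-years and cessation time from the phenotype table.

    Years smoked is age - age_started for current smokers and
    age_stopped - age_started for former smokers (real-valued).
    """
    status = phenotypes["status"]
    years = pd.Series(np.nan, index=phenotypes.index)
    cur = status == "current"
    fmr = status == "former"
    years[cur] = phenotypes.loc[cur, "age"] - phenotypes.loc[cur, "age_started"]
    years[fmr] = phenotypes.loc[fmr, "age_stopped"] - phenotypes.loc[fmr, "age_started"]
    pack_years = phenotypes["cigs_per_day"] / 20.0 * years
    cessation = pd.Series(np.nan, index=phenotypes.index)
    cessation[fmr] = compute_cessation(
        phenotypes.loc[fmr, "age"], phenotypes.loc[fmr, "age_stopped"]
    )
    return pd.DataFrame({"pack_years": pack_years, "cessation_years": cessation})


@dataclass(frozen=True)
class ExclusionLog:
    n_input: int
    n_missing_status: int
    n_missing_beta: int
    n_outlier: int
    n_final: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input",
                    "missing smoking status",
                    "missing beta values",
                    "outlier beyond mean +/- k SD",
                    "final",
                ],
                "n": [
                    self.n_input,
                    self.n_missing_status,
                    self.n_missing_beta,
                    self.n_outlier,
                    self.n_final,
                ],
            }
        )


def apply_exclusions(
    betas: pd.DataFrame,
    phenotypes: pd.DataFrame,
    markers: list[str] | None = None,
    sd_mult: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Drop samples with missing status, missing betas, or outlier betas.

    Outlier moments are computed per CpG on the samples surviving rules 1-2,
    in a single pass (no re-computation after removals), so the operation is
    idempotent.  Returns the filtered betas and phenotypes (restricted to
    ``markers`` when given) and a log of counts per rule.
    """
    if markers is not None:
        missing_cols = [m for m in markers if m not in betas.columns]
        if missing_cols:
            raise KeyError(f"markers not in beta matrix: {missing_cols}")
        betas = betas[list(markers)]
    if not betas.index.equals(phenotypes.index):
        phenotypes = phenotypes.loc[betas.index]

    n_input = len(betas)
    status = phenotypes["status"]
    ok_status = status.isin(VALID_STATUSES)
    n_missing_status = int((~ok_status).sum())
    betas1 = betas.loc[ok_status]
    phen1 = phenotypes.loc[ok_status]

    complete = ~betas1.isna().any(axis=1)
    n_missing_beta = int((~complete).sum())
    betas2 = betas1.loc[complete]
    phen2 = phen1.loc[complete]

    mean = betas2.mean(axis=0)
    sd = betas2.std(axis=0, ddof=1).fillna(0.0)
    lo, hi = mean - sd_mult * sd, mean + sd_mult * sd
    inlier = ((betas2 >= lo) & (betas2 <= hi)).all(axis=1)
    n_outlier = int((~inlier).sum())
    betas3 = betas2.loc[inlier]
    phen3 = phen2.loc[inlier]

    if len(betas3) == 0:
        raise ValueError("cohort is empty after exclusions")
    log = ExclusionLog(n_input, n_missing_status, n_missing_beta, n_outlier, len(betas3))
    return betas3, phen3, log


def dichotomize_history(value, cutoff: float):
    """Code 1 iff the history value is at or above the cutoff (inclusive)."""
    v = np.asarray(value, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("history value missing for this participant class")
    out = (v >= cutoff).astype(int)
    return int(out) if out.ndim == 0 else out


def code_five_category(status, pack_years, cessation_years, py_cutoff: float = 15.0):
    """Lifetime smoking label in 1..5.

    1 = never; 2 = former with cessation > 10 y; 3 = former with cessation
    <= 10 y; 4 = current below the pack-year cutoff; 5 = current at/above it.
    ``py_cutoff`` is 15 (model 1) or 10 (model 2).
    """
    if py_cutoff not in (10.0, 15.0, 10, 15):
        raise ValueError("py_cutoff must be 10 or 15")
    status = np.asarray(status, dtype=object)
    py = np.asarray(pack_years, dtype=float)
    ces = np.asarray(cessation_years, dtype=float)
    scalar = status.ndim == 0
    status, py, ces = np.atleast_1d(status), np.atleast_1d(py), np.atleast_1d(ces)

    labels = np.zeros(len(status), dtype=int)
    never = status == "never"
    fmr = status == "former"
    cur = status == "current"
    unknown = ~(never | fmr | cur)
    if unknown.any():
        raise ValueError(f"unknown status values: {np.unique(status[unknown])}")
    if np.any(np.isnan(ces[fmr])):
        raise ValueError("cessation time missing for former smokers")
    if np.any(np.isnan(py[cur])):
        raise ValueError("pack-years missing for current smokers")
    labels[never] = 1
    labels[fmr & (ces > 10.0)] = 2
    labels[fmr & (ces <= 10.0)] = 3
    labels[cur & (py < py_cutoff)] = 4
    labels[cur & (py >= py_cutoff)] = 5
    return int(labels[0]) if scalar else labels
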