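"""Backward marker elimination with a chi-squared stopping rule.

Starting from the full candidate model, the marker with the smallest
absolute z-statistic (|coefficient / SE|) is removed, the reduced model is
refitted, its AUC recorded, and the two consecutive models compared with a
likelihood-ratio chi-squared test.  This repeats down to a single marker,
yielding the cumulative-AUC profile.  The stopping rule walks the removals
in order and keeps the marker set in place immediately before the first
removal whose nested test is significant at ``alpha``.

Covariates, when supplied, are part of every fit but never candidates for
removal.  Ties in |z| break lexicographically by CpG id, so the elimination
order is a pure function of the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ascertainment import CandidateSet
from .evaluation import roc_auc
from .glm import FittedGLM, NestedTest, fit_binary, lr_test, predict_prob

__all__ = ["EliminationStep", "EliminationTrace", "backward_eliminate", "chisq_stop"]


@dataclass(frozen=True)
class EliminationStep:
    """One removal: the victim, the surviving set, the reduced model's AUC,
    and the nested test of the model before vs after the removal."""

    removed: str
    remaining: tuple[str, ...]
    auc: float
    test: NestedTest | None
    error: str | None = None


@dataclass
class EliminationTrace:
    """The full removal history, including the starting full model."""

    initial_markers: tuple[str, ...]
    initial_auc: float
    steps: list[EliminationStep]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": 0,
                "removed": "",
                "n_remaining": len(self.initial_markers),
                "auc": self.initial_auc,
                "chi_sq": np.nan,
                "p_value": np.nan,
            }
        ]
        for i, s in enumerate(self.steps, start=1):
            rows.append(
                {
                    "step": i,
                    "removed": s.removed,
                    "n_remaining": len(s.remaining),
                    "auc": s.auc,
                    "chi_sq": s.test.chi_sq if s.test else np.nan,
                    "p_value": s.test.p_value if s.test else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def auc_by_size(self) -> pd.Series:
        """Cumulative-AUC profile indexed by model size (number of markers)."""
        frame = self.to_frame()
        return frame.set_index("n_remaining")["auc"].sort_index()


def _resolve_candidates(candidates) -> list[str]:
    if isinstance(candidates, CandidateSet):
        return list(candidates.cpg_ids)
    return list(candidates)


def backward_eliminate(
    data: pd.DataFrame,
    candidates,
    label_col: str = "y",
    covariates: pd.DataFrame | None = None,
) -> EliminationTrace:
    """Run |z|-ranked backward elimination down to a single marker.

    ``data`` holds one column per candidate CpG plus the binary label column.
    A fit failure at the initial full model is raised; a failure at a later
    step is recorded as a flagged terminal step and the trace halts there.
    """
    markers = sorted(_resolve_candidates(candidates))
    if len(markers) < 2:
        raise ValueError("need at least two candidate markers")
    missing = [m for m in markers if m not in data.columns]
    if missing:
        raise KeyError(f"candidate markers absent from data: {missing}")
    y = data[label_col].to_numpy()

    current = markers
    fit_cur = fit_binary(data[current], y, covariates=covariates)
    initial_auc = roc_auc(predict_prob(fit_cur, data[current], covariates), y)

    steps: list[EliminationStep] = []
    while len(current) > 1:
        z = fit_cur.marker_z(current)
        victim = min(current, key=lambda m: (z[m], m))
        reduced = [m for m in current if m != victim]
        try:
            fit_red = fit_binary(data[reduced], y, covariates=covariates)
        except Exception as exc:  # recorded, step flagged, trace halts
            steps.append(
                EliminationStep(
                    removed=victim,
                    remaining=tuple(reduced),
                    auc=float("nan"),
                    test=None,
                    error=f"fit failed: {exc}",
                )
            )
            break
        auc = roc_auc(predict_prob(fit_red, data[reduced], covariates), y)
        test = lr_test(fit_cur, fit_red)
        steps.append(
            EliminationStep(removed=victim, remaining=tuple(reduced), auc=auc, test=test)
        )
        current, fit_cur = reduced, fit_red
    return EliminationTrace(
        initial_markers=tuple(markers), initial_auc=initial_auc, steps=steps
    )


def chisq_stop(trace: EliminationTrace, alpha: float = 0.05) -> tuple[str, ...]:
    """Select the marker set in place before the first significant removal.

    Walking the removals in order, the first nested test with p < ``alpha``
    stops the elimination; the returned set still contains that step's
    removed marker.  If no removal is significant, the final single-marker
    set is returned with a warning.  With ``alpha = 1`` any p < 1 stops at
    the first step, i.e. nothing is removed.
    """
    if not trace.steps:
        raise ValueError("empty elimination trace")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    previous: tuple[str, ...] = trace.initial_markers
    for step in trace.steps:
        if step.error is not None:
            warnings.warn(
                f"elimination halted by fit failure at {step.removed}: {step.error}; "
                "selecting the last successfully fitted set",
                UserWarning,
                stacklevel=2,
            )
            return previous
        if step.test.p_value < alpha:
            return previous
        previous = step.remaining
    warnings.warn(
        "no removal was significant; selection ran to a single marker",
        UserWarning,
        stacklevel=2,
    )
    return previous
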