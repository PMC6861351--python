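"""The concrete smoking-inference model suite.

All classifiers share the selected CpG marker panel and the logit machinery
of :mod:`smokesig.glm`:

* a binary current-vs-non-smoker model (threshold 0.5);
* a three-category current/former/never multinomial (argmax rule);
* dichotomous cessation-time models in former smokers at horizons 5/10/15
  years, each with its own fixed decision threshold (0.8733, 0.7650,
  0.6397 — treated as given constants, overridable);
* dichotomous pack-year models in current smokers at cutoffs 10/15
  (threshold 0.5);
* two five-category lifetime models combining never / long-quit /
  recent-quit former / light / heavy current smokers (argmax rule);
* the cotinine rule: smoker iff plasma cotinine > 50 ng/mL;
* application of a frozen adult binary model to child cohorts under five
  prenatal-exposure recodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import qc
from .evaluation import ClassificationReport, confusion_at, multiclass_report, roc_auc
from .glm import FittedGLM, fit_binary, fit_multinomial, predict_prob
from .synthetic import SyntheticCohort

__all__ = [
    "CESSATION_THRESHOLDS",
    "COTININE_CUTOFF_NG_ML",
    "ModelSpec",
    "FitResult",
    "build_binary_smoker_model",
    "build_three_category_model",
    "build_cessation_model",
    "build_packyear_model",
    "build_five_category_model",
    "cotinine_classify",
    "children_application",
    "binary_smoker_spec",
]

#: Fixed decision thresholds of the cessation-horizon models, by horizon in
#: years.  Constants of the published procedure; their derivation is not
#: stated, so they are treated as given (and overridable per call).
CESSATION_THRESHOLDS = {5: 0.8733, 10: 0.7650, 15: 0.6397}

#: Plasma cotinine cut-off: > 50 ng/mL is called a smoker, <= 50 a non-smoker.
COTININE_CUTOFF_NG_ML = 50.0


@dataclass(frozen=True)
class ModelSpec:
    """A refittable model definition: markers, outcome, family, decision rule.

    ``label_fn`` maps a modeling frame to the outcome vector, so validation
    routines can refit on arbitrary training slices without touching
    held-out labels.
    """

    name: str
    markers: tuple[str, ...]
    outcome: str
    family: str  # "binary" | "multinomial"
    threshold: float | None
    label_fn: Callable[[pd.DataFrame], np.ndarray]
    covariates: tuple[str, ...] = ()
    categories: tuple | None = None

    def __post_init__(self):
        if self.family == "binary" and self.threshold is None:
            raise ValueError("binary models need a probability threshold")
        if self.family == "multinomial" and self.threshold is not None:
            raise ValueError("multinomial models use the argmax rule, not a threshold")

    def _design(self, data: pd.DataFrame):
        X = data[list(self.markers)]
        cov = data[list(self.covariates)] if self.covariates else None
        return X, cov

    def labels(self, data: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.label_fn(data))

    def fit(self, data: pd.DataFrame) -> FittedGLM:
        X, cov = self._design(data)
        y = self.labels(data)
        if self.family == "binary":
            return fit_binary(X, y, covariates=cov)
        return fit_multinomial(X, y, categories=list(self.categories), covariates=cov)

    def scores(self, fitted: FittedGLM, data: pd.DataFrame):
        X, cov = self._design(data)
        return predict_prob(fitted, X, covariates=cov)


@dataclass
class FitResult:
    """A fitted model plus its apparent performance on the fitting data."""

    spec: ModelSpec
    fitted: FittedGLM
    report: ClassificationReport | dict[str, ClassificationReport]

    def predict(self, data: pd.DataFrame):
        return self.spec.scores(self.fitted, data)


def _frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, SyntheticCohort):
        return cohort.modeling_frame()
    return cohort


def binary_smoker_spec(
    markers,
    covariates: tuple[str, ...] = (),
    threshold: float = 0.5,
    name: str = "current vs non-smoker",
) -> ModelSpec:
    return ModelSpec(
        name=name,
        markers=tuple(markers),
        outcome="current smoker (former and never combined as non-smoker)",
        family="binary",
        threshold=threshold,
        label_fn=lambda df: (df["status"] == "current").astype(int).to_numpy(),
        covariates=tuple(covariates),
    )


def build_binary_smoker_model(
    cohort, markers, covariates: tuple[str, ...] = ()
) -> FitResult:
    """Current smokers vs former+never combined, called at prob > 0.5."""
    data = _frame(cohort)
    spec = binary_smoker_spec(markers, covariates)
    fitted = spec.fit(data)
    probs = np.asarray(spec.scores(fitted, data), dtype=float)
    report = confusion_at(probs, spec.labels(data), threshold=spec.threshold)
    return FitResult(spec, fitted, report)


def build_three_category_model(cohort, markers) -> FitResult:
    """Current vs former vs never multinomial; per-category one-vs-rest reports."""
    data = _frame(cohort)
    if not data["status"].isin(("current", "former", "never")).all():
        raise ValueError("three-category model requires complete smoking status")
    spec = ModelSpec(
        name="current vs former vs never",
        markers=tuple(markers),
        outcome="three-category smoking status",
        family="multinomial",
        threshold=None,
        label_fn=lambda df: df["status"].to_numpy(object),
        categories=("never", "former", "current"),
    )
    fitted = spec.fit(data)
    probs = spec.scores(fitted, data)
    report = multiclass_report(probs, spec.labels(data))
    return FitResult(spec, fitted, report)


def build_cessation_model(
    former_cohort, markers, horizon: int, threshold: float | None = None
) -> FitResult:
    """Cessation >= horizon years (1) vs shorter (0), in former smokers only.

    The decision threshold is the fixed constant for the horizon unless
    overridden.
    """
    if horizon not in CESSATION_THRESHOLDS:
        raise ValueError(f"horizon must be one of {sorted(CESSATION_THRESHOLDS)}")
    data = _frame(former_cohort)
    if not (data["status"] == "former").all():
        raise ValueError("cessation models are fitted on former smokers only")
    thr = CESSATION_THRESHOLDS[horizon] if threshold is None else threshold

    def label_fn(df: pd.DataFrame) -> np.ndarray:
        ces = qc.derive_history(df)["cessation_years"]
        return qc.dichotomize_history(ces, horizon)

    spec = ModelSpec(
        name=f"cessation >= {horizon} y",
        markers=tuple(markers),
        outcome=f"smoking cessation time >= {horizon} years",
        family="binary",
        threshold=thr,
        label_fn=label_fn,
    )
    fitted = spec.fit(data)
    probs = np.asarray(spec.scores(fitted, data), dtype=float)
    report = confusion_at(probs, spec.labels(data), threshold=thr)
    return FitResult(spec, fitted, report)


def build_packyear_model(current_cohort, markers, cutoff: int) -> FitResult:
    """Pack-years >= cutoff (1) vs fewer (0), in current smokers, prob > 0.5."""
    if cutoff not in (10, 15):
        raise ValueError("cutoff must be 10 or 15")
    data = _frame(current_cohort)
    if not (data["status"] == "current").all():
        raise ValueError("pack-year models are fitted on current smokers only")

    def label_fn(df: pd.DataFrame) -> np.ndarray:
        py = qc.derive_history(df)["pack_years"]
        return qc.dichotomize_history(py, cutoff)

    spec = ModelSpec(
        name=f"pack-years >= {cutoff}",
        markers=tuple(markers),
        outcome=f"pack-years >= {cutoff}",
        family="binary",
        threshold=0.5,
        label_fn=label_fn,
    )
    fitted = spec.fit(data)
    probs = np.asarray(spec.scores(fitted, data), dtype=float)
    report = confusion_at(probs, spec.labels(data), threshold=0.5)
    return FitResult(spec, fitted, report)


def build_five_category_model(cohort, markers, py_cutoff: int = 15) -> FitResult:
    """Five-category lifetime model (argmax rule); per-category reports."""
    data = _frame(cohort)

    def label_fn(df: pd.DataFrame) -> np.ndarray:
        hist = qc.derive_history(df)
        return qc.code_five_category(
            df["status"].to_numpy(object),
            hist["pack_years"].to_numpy(float),
            hist["cessation_years"].to_numpy(float),
            py_cutoff=py_cutoff,
        )

    spec = ModelSpec(
        name=f"five-category lifetime (pack-year cutoff {py_cutoff})",
        markers=tuple(markers),
        outcome="lifetime smoking category 1..5",
        family="multinomial",
        threshold=None,
        label_fn=label_fn,
        categories=(1, 2, 3, 4, 5),
    )
    fitted = spec.fit(data)
    probs = spec.scores(fitted, data)
    report = multiclass_report(probs, spec.labels(data))
    return FitResult(spec, fitted, report)


def cotinine_classify(cotinine_ng_ml):
    """Smoker (1) iff plasma cotinine strictly exceeds 50 ng/mL."""
    v = np.asarray(cotinine_ng_ml, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("cotinine value missing")
    out = (v > COTININE_CUTOFF_NG_ML).astype(int)
    return int(out) if out.ndim == 0 else out


def _child_labels(data: pd.DataFrame, analysis: int) -> tuple[pd.DataFrame, np.ndarray]:
    required = ("mother_sustained", "mother_stopped_when_aware", "passive_exposure")
    if analysis != 1:
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(
                f"analysis {analysis} needs exposure columns, missing: {missing}"
            )
    if analysis == 1:
        return data, np.zeros(len(data), dtype=int)
    sus = data["mother_sustained"].to_numpy(bool)
    stop = data["mother_stopped_when_aware"].to_numpy(bool)
    pas = data["passive_exposure"].to_numpy(bool)
    if analysis == 2:
        return data, sus.astype(int)
    if analysis == 3:
        return data, (sus | stop).astype(int)
    if analysis == 4:
        return data, (sus | stop | pas).astype(int)
    if analysis == 5:
        keep = ~(sus | stop)  # mothers who did not actively smoke
        return data.loc[keep], pas[keep].astype(int)
    raise ValueError("analysis must be in 1..5")


def children_application(
    adult_model: FitResult, child_cohort, analysis: int
) -> ClassificationReport:
    """Apply a frozen adult binary model to a child cohort.

    Analysis recodings: (1) all children non-smokers (accuracy of the
    non-smoker call); (2) sustained maternal smoking coded 1; (3) adding
    mothers who stopped when aware of the pregnancy; (4) adding passive
    smoking in the household/at work; (5) passive smoking alone, restricted
    to children of non-smoking mothers.  The adult model is never refitted.
    """
    if adult_model.spec.family != "binary":
        raise ValueError("children application requires the binary adult model")
    data = _frame(child_cohort)
    data, labels = _child_labels(data, analysis)
    probs = np.asarray(adult_model.predict(data), dtype=float)
    with_auc = analysis != 1
    return confusion_at(
        probs, labels, threshold=adult_model.spec.threshold, with_auc=with_auc
    )
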