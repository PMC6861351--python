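"""Internal validation: fivefold cross-validation and bootstrap optimism.

Cross-validation partitions the cohort at random into k near-equal folds
(unstratified by default, as the original scheme randomises without
stratification); each fold is scored by a model fitted on the remaining
folds.  Bootstrap optimism refits the model on B resamples drawn with
replacement, scores each refit on its own resample (apparent) and on the
original cohort (test), and estimates optimism as the mean apparent - test
difference; the adjusted AUC is the apparent AUC minus this optimism.

A model specification passed here must expose ``fit(df)``, ``scores(fitted,
df)``, ``labels(df)``, a ``threshold`` and a ``family`` attribute (see
:mod:`smokesig.models`).  Fitting only ever receives training slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import ClassificationReport, confusion_at, roc_auc

__all__ = ["CrossValReport", "OptimismReport", "kfold_cv", "bootstrap_optimism"]


@dataclass
class CrossValReport:
    """Per-fold held-out reports plus mean and SD per metric."""

    fold_reports: list[ClassificationReport]
    k: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.fold_reports]
        df = pd.DataFrame(rows)[["accuracy", "sensitivity", "specificity", "auc"]]
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.fold_reports]))


@dataclass
class OptimismReport:
    """Bootstrap optimism correction for an AUC.

    ``optimism`` is the mean over replicates of (apparent-in-replicate minus
    test-on-original); ``adjusted`` subtracts it from the apparent AUC of the
    original fit.
    """

    apparent_auc: float
    optimism: float
    boot_apparent_mean: float = float("nan")
    boot_test_mean: float = float("nan")
    B: int = 0
    seed: int | None = None
    n_retries: int = 0
    replicates: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    @property
    def adjusted_auc(self) -> float:
        return self.apparent_auc - self.optimism

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": [
                    "apparent AUC",
                    "bootstrap apparent AUC (mean)",
                    "bootstrap test AUC (mean)",
                    "optimism",
                    "optimism-adjusted AUC",
                ],
                "value": [
                    self.apparent_auc,
                    self.boot_apparent_mean,
                    self.boot_test_mean,
                    self.optimism,
                    self.adjusted_auc,
                ],
            }
        )


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _has_all_classes(labels: np.ndarray, classes: np.ndarray) -> bool:
    return all(np.any(labels == c) for c in classes)


def kfold_cv(data: pd.DataFrame, model_spec, k: int = 5, seed: int = 0) -> CrossValReport:
    """k-fold cross-validation of a binary model specification.

    Fold sizes differ by at most one.  If any training fold lacks a class the
    partition is re-randomised, up to 100 times, before erroring.
    """
    if k < 2 or k > len(data):
        raise ValueError(f"k must be in [2, n]; got k={k}, n={len(data)}")
    labels_all = np.asarray(model_spec.labels(data))
    classes = np.unique(labels_all)
    rng = np.random.default_rng(seed)
    folds = None
    for _ in range(100):
        trial = _fold_indices(len(data), k, rng)
        ok = all(
            _has_all_classes(np.delete(labels_all, test), classes) for test in trial
        )
        if ok:
            folds = trial
            break
    if folds is None:
        raise ValueError(
            "could not build folds with every class in every training set "
            "after 100 randomisations"
        )
    reports = []
    for test_idx in folds:
        mask = np.zeros(len(data), dtype=bool)
        mask[test_idx] = True
        train, test = data.loc[~mask], data.loc[mask]
        fitted = model_spec.fit(train)
        probs = np.asarray(model_spec.scores(fitted, test), dtype=float)
        y = np.asarray(model_spec.labels(test), dtype=int)
        reports.append(confusion_at(probs, y, threshold=model_spec.threshold))
    return CrossValReport(fold_reports=reports, k=k, seed=seed)


def bootstrap_optimism(
    data: pd.DataFrame,
    model_spec,
    B: int = 1000,
    seed: int = 0,
) -> OptimismReport:
    """Bootstrap optimism estimate of the AUC of a binary model.

    Per-replicate random streams are spawned deterministically from the
    master seed, so reducing B keeps earlier replicates identical.
    Replicates missing a class are redrawn (retries are counted).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y_all = np.asarray(model_spec.labels(data), dtype=int)
    fitted0 = model_spec.fit(data)
    apparent = roc_auc(model_spec.scores(fitted0, data), y_all)

    streams = np.random.SeedSequence(seed).spawn(B)
    n = len(data)
    app_b = np.empty(B)
    test_b = np.empty(B)
    retries = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        for _ in range(100):
            idx = rng.integers(0, n, n)
            if len(np.unique(y_all[idx])) == 2:
                break
            retries += 1
        else:
            raise ValueError("bootstrap replicate missing a class after 100 retries")
        boot = data.iloc[idx]
        fitted_b = model_spec.fit(boot)
        app_b[b] = roc_auc(model_spec.scores(fitted_b, boot), y_all[idx])
        test_b[b] = roc_auc(model_spec.scores(fitted_b, data), y_all)
    optimism = float(np.mean(app_b - test_b))
    return OptimismReport(
        apparent_auc=float(apparent),
        optimism=optimism,
        boot_apparent_mean=float(np.mean(app_b)),
        boot_test_mean=float(np.mean(test_b)),
        B=B,
        seed=seed,
        n_retries=retries,
        replicates=pd.DataFrame({"apparent": app_b, "test": test_b}),
    )
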