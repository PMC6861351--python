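"""Binary and baseline-category multinomial logit fits with nested-model tests.

Fitting is delegated to statsmodels (``sm.GLM`` with a binomial family and
logit link; ``sm.MNLogit`` for K >= 3 categories); this module adds the
contracts the marker-selection algorithm relies on: z-statistics defined as
coefficient / standard error, rank-deficiency and separation surfacing, and
the likelihood-ratio chi-squared test between nested fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RankDeficientError",
    "SeparationWarning",
    "FittedGLM",
    "NestedTest",
    "fit_binary",
    "fit_multinomial",
    "predict_prob",
    "lr_test",
]

#: |coefficient| beyond which a logit fit is flagged as (quasi-)separated.
SEPARATION_COEF = 15.0


class RankDeficientError(ValueError):
    """The design matrix does not have full column rank."""


class SeparationWarning(UserWarning):
    """The classes are (quasi-)perfectly separated; estimates are unstable."""


@dataclass
class FittedGLM:
    """A fitted logit model.

    ``params``/``bse``/``z_stats`` are DataFrames with one row per predictor
    (including ``const``) and one column per non-reference category (a single
    column named ``"1"`` for binary fits).  ``categories`` lists all outcome
    categories with the reference first.
    """

    kind: str  # "binary" | "multinomial"
    predictor_names: tuple[str, ...]
    params: pd.DataFrame
    bse: pd.DataFrame
    z_stats: pd.DataFrame
    llf: float
    deviance: float
    nobs: int
    categories: tuple
    converged: bool
    separation: bool

    @property
    def n_params(self) -> int:
        return int(self.params.size)

    def marker_z(self, markers) -> pd.Series:
        """Max |z| per marker across non-reference categories (binary: the z)."""
        z = self.z_stats.loc[list(markers)]
        return z.abs().max(axis=1)

    def coefficients_frame(self) -> pd.DataFrame:
        """Long-format dump: predictor, category, coefficient, SE, z."""
        rows = []
        for cat in self.params.columns:
            for pred in self.params.index:
                rows.append(
                    {
                        "category": cat,
                        "predictor": pred,
                        "coefficient": self.params.loc[pred, cat],
                        "se": self.bse.loc[pred, cat],
                        "z": self.z_stats.loc[pred, cat],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NestedTest:
    """Likelihood-ratio chi-squared test between nested fits."""

    chi_sq: float
    df: int
    p_value: float


def _design(X: pd.DataFrame, covariates: pd.DataFrame | None) -> pd.DataFrame:
    if covariates is not None:
        X = pd.concat([X, covariates], axis=1)
    X = X.astype(float)
    design = sm.add_constant(X, has_constant="add")
    arr = design.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise RankDeficientError(
            f"design matrix is rank deficient (columns: {list(design.columns)})"
        )
    return design


def _check_separation(params: np.ndarray) -> bool:
    if np.max(np.abs(params)) > SEPARATION_COEF:
        warnings.warn(
            "coefficients diverged beyond "
            f"|{SEPARATION_COEF}|: classes may be perfectly separated; "
            "estimates and z-statistics are unstable",
            SeparationWarning,
            stacklevel=3,
        )
        return True
    return False


def fit_binary(
    X: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
) -> FittedGLM:
    """Maximum-likelihood binomial GLM with logit link.

    ``y`` must contain both classes (0/1).  Optional covariates (age, sex,
    cell proportions) are appended to the design; they share the fit but are
    never elimination candidates.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(f"y must contain both classes 0 and 1, got {classes}")
    design = _design(X, covariates)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        res = model.fit(maxiter=100, tol=1e-8)
    params = res.params.to_numpy()
    separation = _check_separation(params)
    names = tuple(design.columns)
    pframe = pd.DataFrame({"1": res.params}, index=design.columns)
    bframe = pd.DataFrame({"1": res.bse}, index=design.columns)
    return FittedGLM(
        kind="binary",
        predictor_names=names,
        params=pframe,
        bse=bframe,
        z_stats=pframe / bframe,
        llf=float(res.llf),
        deviance=float(res.deviance),
        nobs=int(res.nobs),
        categories=(0, 1),
        converged=bool(res.converged),
        separation=separation,
    )


def fit_multinomial(
    X: pd.DataFrame,
    y,
    categories: list | None = None,
    covariates: pd.DataFrame | None = None,
) -> FittedGLM:
    """Baseline-category multinomial logit.

    The reference is the first entry of ``categories``; by default the sorted
    category list with ``"never"`` moved first when present.  With K = 2 the
    coefficients reproduce :func:`fit_binary`.
    """
    y = pd.Series(np.asarray(y, dtype=object))
    present = sorted(y.unique(), key=str)
    if categories is None:
        categories = list(present)
        if "never" in categories:
            categories.remove("never")
            categories = ["never"] + categories
    empty = [c for c in categories if (y == c).sum() == 0]
    if empty or set(present) - set(categories):
        raise ValueError(
            f"every category must be non-empty and declared; empty={empty}, "
            f"undeclared={sorted(set(present) - set(categories), key=str)}"
        )
    codes = y.map({c: i for i, c in enumerate(categories)}).to_numpy(int)
    design = _design(X, covariates)
    model = sm.MNLogit(codes, design.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=100, disp=0)
    cols = [str(c) for c in categories[1:]]
    pframe = pd.DataFrame(res.params, index=design.columns, columns=cols)
    bframe = pd.DataFrame(res.bse, index=design.columns, columns=cols)
    separation = _check_separation(res.params)
    llf = float(res.llf)
    return FittedGLM(
        kind="multinomial",
        predictor_names=tuple(design.columns),
        params=pframe,
        bse=bframe,
        z_stats=pframe / bframe,
        llf=llf,
        deviance=float(-2.0 * llf),
        nobs=int(res.nobs),
        categories=tuple(categories),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
    )


def predict_prob(model: FittedGLM, X: pd.DataFrame, covariates: pd.DataFrame | None = None):
    """Response-scale probabilities.

    Binary: a vector of P(y=1).  Multinomial: a DataFrame over all K
    categories (reference included) whose rows sum to 1.
    """
    if covariates is not None:
        X = pd.concat([X, covariates], axis=1)
    X = X.astype(float)
    design = sm.add_constant(X, has_constant="add")
    expected = list(model.predictor_names)
    if list(design.columns) != expected:
        if set(design.columns) == set(expected):
            design = design[expected]
        else:
            raise ValueError(
                f"predictor mismatch: model expects {expected}, got {list(design.columns)}"
            )
    eta = design.to_numpy() @ model.params.to_numpy()  # n x (K-1)
    if model.kind == "binary":
        return 1.0 / (1.0 + np.exp(-eta[:, 0]))
    full = np.concatenate([np.zeros((len(eta), 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, index=X.index, columns=[str(c) for c in model.categories])


def lr_test(full: FittedGLM, reduced: FittedGLM) -> NestedTest:
    """Chi-squared test of a reduced model nested in a full one.

    ``chi_sq = 2 (ll_full - ll_reduced)``, floored at 0 against round-off;
    df is the parameter-count difference.
    """
    if not set(reduced.predictor_names) <= set(full.predictor_names):
        raise ValueError("models are not nested: reduced predictors not in full model")
    if full.nobs != reduced.nobs:
        raise ValueError("models were fitted on different numbers of samples")
    df = full.n_params - reduced.n_params
    if df <= 0:
        df = max(df, 0)
    chi = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi, df))
    return NestedTest(chi_sq=chi, df=df, p_value=p)
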