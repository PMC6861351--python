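"""The assembled model suite: thresholds, codings, freezing, applications."""

import warnings

import numpy as np
import pandas as pd
import pytest

from smokesig.models import (
    CESSATION_THRESHOLDS,
    build_binary_smoker_model,
    build_cessation_model,
    build_five_category_model,
    build_packyear_model,
    build_three_category_model,
    children_application,
    cotinine_classify,
)
from smokesig.synthetic import (
    SyntheticParams,
    generate_child_cohort,
    generate_cohort,
    simulate_maternal_exposure,
)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SyntheticParams(n_participants=1500, seed=33))


@pytest.fixture(scope="module")
def markers(cohort):
    return cohort.informative_cpgs()


@pytest.fixture(scope="module")
def binary_fit(cohort, markers):
    return build_binary_smoker_model(cohort, markers)


class TestCotinineRule:
    @pytest.mark.parametrize("value, expected", [(60, 1), (50, 0), (50.01, 1), (0, 0)])
    def test_cutoff_boundary(self, value, expected):
        assert cotinine_classify(value) == expected

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError):
            cotinine_classify(np.nan)


class TestBinaryModel:
    def test_reports_auc_above_chance(self, binary_fit):
        assert binary_fit.report.auc > 0.75

    def test_covariates_change_auc_only_marginally(self, cohort, markers):
        """Age and sex are simulated independent of methylation, so adding
        them moves the apparent AUC by construction by < 0.02."""
        base = build_binary_smoker_model(cohort, markers)
        data = cohort.modeling_frame().copy()
        data["sex_male"] = (data["sex"] == "M").astype(float)
        aug = build_binary_smoker_model(data, markers, covariates=("age", "sex_male"))
        assert abs(aug.report.auc - base.report.auc) < 0.02


class TestThreeCategory:
    def test_former_harder_than_current(self, cohort, markers):
        """Cessation decay erodes the former-smoker signal, so the former
        category separates worse than current."""
        res = build_three_category_model(cohort, markers)
        assert res.report["former"].auc < res.report["current"].auc

    def test_label_permutation_gives_chance_aucs(self):
        """Permuting status destroys the signal; the small residual excess
        over 0.5 is apparent-fit optimism at n=3764 with 13 predictors."""
        c = generate_cohort(SyntheticParams(seed=33))
        data = c.modeling_frame().copy()
        rng = np.random.default_rng(0)
        data["status"] = rng.permutation(data["status"].to_numpy())
        res = build_three_category_model(data, c.informative_cpgs())
        for rep in res.report.values():
            assert abs(rep.auc - 0.5) < 0.06


class TestHistoryModels:
    def test_cessation_threshold_constants(self, cohort, markers):
        former = cohort.modeling_frame()
        former = former[former["status"] == "former"]
        for horizon, thr in CESSATION_THRESHOLDS.items():
            res = build_cessation_model(former, markers, horizon=horizon)
            assert res.spec.threshold == thr
            assert res.report.threshold == thr

    def test_invalid_horizon_rejected(self, cohort, markers):
        former = cohort.modeling_frame()
        former = former[former["status"] == "former"]
        with pytest.raises(ValueError, match="horizon"):
            build_cessation_model(former, markers, horizon=7)

    def test_single_class_cessation_cohort_errors(self, cohort, markers):
        former = cohort.modeling_frame()
        former = former[former["status"] == "former"].copy()
        former["age_stopped"] = former["age"] - 40.0  # everyone quit 40 y ago
        former["age_started"] = former[["age_started", "age_stopped"]].min(axis=1)
        with pytest.raises(ValueError, match="both classes"):
            build_cessation_model(former, markers, horizon=5)

    def test_packyear_model_beats_chance_with_dose_scaling(self, cohort, markers):
        current = cohort.modeling_frame()
        current = current[current["status"] == "current"]
        res = build_packyear_model(current, markers, cutoff=10)
        assert res.spec.threshold == 0.5
        assert res.report.auc > 0.5

    def test_packyear_model_chance_without_dose_effect(self):
        """With a flat dose response the pack-year label carries no
        methylation signal: cross-validated AUC is at chance (CV avoids the
        apparent-fit optimism of refitting 13 markers on a few hundred
        smokers)."""
        from smokesig.validation import kfold_cv

        p = SyntheticParams(
            n_participants=3000,
            seed=6,
            packyear_scaling=lambda py: np.full_like(np.asarray(py, float), 0.7),
        )
        c = generate_cohort(p)
        current = c.modeling_frame()
        current = current[current["status"] == "current"]
        res = build_packyear_model(current, c.informative_cpgs(), cutoff=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = kfold_cv(current, res.spec, k=5, seed=1)
        n1 = res.report.tp + res.report.fn
        n0 = res.report.tn + res.report.fp
        fold_se = np.sqrt((n1 / 5 + n0 / 5 + 1) / (12 * (n1 / 5) * (n0 / 5)))
        assert abs(cv.mean_auc() - 0.5) < 3 * fold_se / np.sqrt(5)


class TestFiveCategory:
    def test_reports_cover_all_five_categories(self, cohort, markers):
        res = build_five_category_model(cohort, markers, py_cutoff=15)
        assert set(res.report) == {"1", "2", "3", "4", "5"}

    def test_dose_ordering_of_current_categories(self, cohort, markers):
        """Dose scaling separates heavy current smokers better than light
        ones and than long-quit former smokers."""
        res = build_five_category_model(cohort, markers, py_cutoff=15)
        heavy = res.report["5"].auc
        assert heavy > res.report["4"].auc  # light current
        assert heavy > res.report["2"].auc  # long-quit former

    def test_sensitivities_consistent_with_argmax_margins(self, cohort, markers):
        res = build_five_category_model(cohort, markers, py_cutoff=15)
        for rep in res.report.values():
            assert rep.tp + rep.fn + rep.fp + rep.tn == rep.n


class TestChildren:
    @pytest.fixture(scope="class")
    def child_setup(self, cohort, markers, binary_fit):
        params = SyntheticParams(seed=40, cordblood_offset=0.0)
        expo = simulate_maternal_exposure(400, seed=41)
        kids = generate_child_cohort(params, expo, tissue="whole", seed=42)
        return binary_fit, kids

    def test_model_is_never_refit(self, child_setup):
        fit, kids = child_setup
        before = fit.fitted.params.copy()
        children_application(fit, kids, analysis=2)
        pd.testing.assert_frame_equal(fit.fitted.params, before)

    def test_unexposed_children_called_non_smokers(self, child_setup):
        fit, kids = child_setup
        rep = children_application(fit, kids, analysis=1)
        assert rep.accuracy > 0.9
        assert rep.auc is None  # single-class coding: accuracy only

    def test_cordblood_offset_flips_calls(self, cohort, markers, binary_fit):
        """A strong smoker-direction cord-blood shift makes the frozen adult
        model call most newborns smokers."""
        deltas = cohort.cpg_truth["smoker_delta"]
        offset = {c: float(np.sign(deltas[c]) * 2.0) for c in deltas.index}
        params = SyntheticParams(seed=50, cordblood_offset=offset)
        expo = simulate_maternal_exposure(200, seed=51, p_sustained=0.0, p_stopped=0.0)
        kids = generate_child_cohort(params, expo, tissue="cord", seed=52)
        rep = children_application(binary_fit, kids, analysis=1)
        assert rep.accuracy < 0.5

    def test_sustained_smoking_coding_detectable(self, cohort, binary_fit):
        params = SyntheticParams(seed=60, cordblood_offset=None)
        expo = simulate_maternal_exposure(600, seed=61)
        kids = generate_child_cohort(
            params, expo, tissue="whole", sustained_attenuation=0.8, seed=62
        )
        rep = children_application(binary_fit, kids, analysis=2)
        assert rep.auc > 0.55

    def test_analysis_five_restricted_to_nonsmoking_mothers(self, child_setup):
        fit, kids = child_setup
        rep = children_application(fit, kids, analysis=5)
        active = (
            kids.phenotypes["mother_sustained"]
            | kids.phenotypes["mother_stopped_when_aware"]
        )
        assert rep.n == int((~active).sum())

    def test_missing_exposure_fields_rejected(self, binary_fit, cohort):
        frame = cohort.modeling_frame().head(10)
        with pytest.raises(ValueError, match="exposure"):
            children_application(binary_fit, frame, analysis=3)


def test_ten_marker_model_is_refit_not_subset(cohort, markers):
    """Dropping the EPIC-missing CpGs refits the model: shared coefficients
    differ from the 13-marker fit."""
    from smokesig.datasets import EPIC_MISSING_CPGS

    full = build_binary_smoker_model(cohort, markers)
    reduced_markers = [m for m in markers if m not in EPIC_MISSING_CPGS]
    assert len(reduced_markers) == len(markers) - 3
    sub = build_binary_smoker_model(cohort, reduced_markers)
    shared = [m for m in reduced_markers]
    assert not np.allclose(
        sub.fitted.params.loc[shared, "1"].to_numpy(),
        full.fitted.params.loc[shared, "1"].to_numpy(),
    )
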