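"""Generator fidelity: determinism, planted effect sizes, decoy neutrality,
and the child-cohort construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from smokesig.synthetic import (
    CpGSpec,
    SyntheticParams,
    generate_child_cohort,
    generate_cohort,
    saturating_packyear_scaling,
    simulate_maternal_exposure,
)


def logit_normal_mean(mu: float, sigma: float) -> float:
    """Deterministic oracle: E[expit(mu + sigma Z)], Z standard normal."""
    val, _ = integrate.quad(
        lambda z: expit(mu + sigma * z) * stats.norm.pdf(z), -10, 10
    )
    return val


def plain(**kw) -> SyntheticParams:
    base = dict(
        susceptibility_shape=None,
        shared_noise_sd_logit=0.0,
        misreport_rate=0.0,
    )
    base.update(kw)
    return SyntheticParams(**base)


class TestValidation:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(
                SyntheticParams(class_mix={"current": 0.5, "former": 0.4, "never": 0.2})
            )

    def test_bad_reversion_timescale_rejected(self):
        with pytest.raises(ValueError, match="reversion_timescale"):
            CpGSpec("cgX", 0.5, -0.1, reversion_timescale=0.0)

    def test_baseline_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="baseline_beta"):
            CpGSpec("cgX", 1.2, -0.1)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_participants"):
            generate_cohort(SyntheticParams(n_participants=5))


def test_seed_determinism():
    p = SyntheticParams(n_participants=200, seed=42)
    a, b = generate_cohort(p), generate_cohort(p)
    pd.testing.assert_frame_equal(a.betas, b.betas)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_betas_bounded_and_aligned(small_cohort):
    assert ((small_cohort.betas > 0) & (small_cohort.betas < 1)).all().all()
    assert small_cohort.betas.index.equals(small_cohort.phenotypes.index)


def test_zero_delta_gives_no_signal():
    """With delta = 0 everywhere the class means coincide up to sampling noise."""
    specs = [CpGSpec("cgA", 0.6, 0.0), CpGSpec("cgB", 0.4, 0.0)]
    p = plain(n_participants=2000, cpg_specs=specs, n_decoy_cpgs=0, seed=3)
    c = generate_cohort(p)
    status = c.truth["true_status"]
    for cpg in c.betas.columns:
        cur = c.betas.loc[status == "current", cpg]
        nev = c.betas.loc[status == "never", cpg]
        se = np.sqrt(cur.var() / len(cur) + nev.var() / len(nev))
        assert abs(cur.mean() - nev.mean()) < 3 * se


def test_long_cessation_decays_to_baseline():
    """Former smokers who quit ~40 years ago are indistinguishable from never
    smokers when the reversion timescale is short (shift ~ delta * e^-10)."""
    specs = [CpGSpec("cgA", 0.6, -0.15, reversion_timescale=4.0)]
    p = plain(n_participants=4000, cpg_specs=specs, n_decoy_cpgs=0, seed=5)
    c = generate_cohort(p)
    status = c.truth["true_status"]
    old_quit = (status == "former") & (c.truth["cessation_years"] > 25)
    assert old_quit.sum() > 30
    fmr = c.betas.loc[old_quit, "cgA"]
    nev = c.betas.loc[status == "never", "cgA"]
    se = np.sqrt(fmr.var() / len(fmr) + nev.var() / len(nev))
    assert abs(fmr.mean() - nev.mean()) < 3 * se + 0.15 * np.exp(-25 / 4.0)


def test_current_shift_matches_logit_normal_oracle():
    """Empirical current-vs-never beta difference agrees within 0.02 with the
    logit-normal mean integrated per sample at its own pack-year dose."""
    m0, delta, sd = 0.6, -0.15, 0.3
    specs = [CpGSpec("cgA", m0, delta)]
    p = plain(
        n_participants=5000,
        class_mix={"current": 0.5, "former": 0.0, "never": 0.5},
        cpg_specs=specs,
        n_decoy_cpgs=0,
        noise_sd_logit=sd,
        seed=17,
    )
    c = generate_cohort(p)
    status = c.truth["true_status"]
    cur = status == "current"
    deriv = m0 * (1 - m0)
    g = saturating_packyear_scaling(c.truth.loc[cur, "pack_years"].to_numpy())
    mus = logit(m0) + delta * g / deriv
    oracle_cur = np.mean([logit_normal_mean(mu, sd) for mu in mus])
    oracle_nev = logit_normal_mean(logit(m0), sd)
    empirical = c.betas.loc[cur, "cgA"].mean() - c.betas.loc[~cur, "cgA"].mean()
    assert empirical == pytest.approx(oracle_cur - oracle_nev, abs=0.02)


def test_effect_estimate_sharpens_with_cohort_size():
    """Mean absolute deviation from the oracle shrinks from n=500 to n=5000."""
    m0, delta, sd = 0.6, -0.15, 0.3
    specs = [CpGSpec("cgA", m0, delta)]
    devs = {}
    for n in (500, 5000):
        errs = []
        for seed in range(5):
            p = plain(
                n_participants=n,
                class_mix={"current": 0.5, "former": 0.0, "never": 0.5},
                cpg_specs=specs,
                n_decoy_cpgs=0,
                noise_sd_logit=sd,
                seed=seed,
            )
            c = generate_cohort(p)
            cur = c.truth["true_status"] == "current"
            deriv = m0 * (1 - m0)
            g = saturating_packyear_scaling(c.truth.loc[cur, "pack_years"].to_numpy())
            mus = logit(m0) + delta * g / deriv
            oracle = np.mean([logit_normal_mean(mu, sd) for mu in mus])
            oracle -= logit_normal_mean(logit(m0), sd)
            emp = c.betas.loc[cur, "cgA"].mean() - c.betas.loc[~cur, "cgA"].mean()
            errs.append(abs(emp - oracle))
        devs[n] = np.mean(errs)
    assert devs[5000] < devs[500]


def test_decoy_pvalues_uniform_across_seeds():
    """Decoy CpGs show no association with status: rank-test p-values over
    seeds are compatible with uniformity."""
    pvals = []
    for seed in range(12):
        p = plain(n_participants=400, seed=seed)
        c = generate_cohort(p)
        decoy = c.cpg_truth.index[~c.cpg_truth["informative"]][0]
        cur = c.truth["true_status"] == "current"
        res = stats.mannwhitneyu(c.betas.loc[cur, decoy], c.betas.loc[~cur, decoy])
        pvals.append(res.pvalue)
    assert stats.kstest(pvals, "uniform").pvalue > 0.05


def test_planted_defects_recorded_in_truth():
    p = SyntheticParams(
        n_participants=500,
        seed=2,
        missing_status_rate=0.03,
        missing_beta_rate=0.02,
        n_planted_outliers=1,
    )
    c = generate_cohort(p)
    assert c.truth["planted_missing_status"].sum() == 15
    assert c.truth["planted_missing_beta"].sum() == 10
    assert c.truth["planted_outlier"].sum() == 1
    assert c.phenotypes["status"].isna().sum() == 15
    assert c.betas.isna().any(axis=1).sum() == 10


class TestChildCohort:
    def test_cord_blood_requires_offset(self):
        expo = simulate_maternal_exposure(50, seed=0)
        with pytest.raises(ValueError, match="cordblood_offset"):
            generate_child_cohort(SyntheticParams(), expo, tissue="cord")

    def test_missing_exposure_columns_rejected(self):
        expo = pd.DataFrame({"mother_sustained": [True, False]})
        with pytest.raises(ValueError, match="missing columns"):
            generate_child_cohort(SyntheticParams(), expo, tissue="whole")

    def test_unexposed_children_match_adult_never_smokers(self):
        """Offset-free children of never-smoking mothers are distributionally
        indistinguishable from adult never smokers, CpG by CpG."""
        p = plain(n_participants=2000, seed=21)
        adults = generate_cohort(p)
        nev = adults.truth["true_status"] == "never"
        expo = pd.DataFrame(
            {
                "mother_sustained": [False] * 400,
                "mother_stopped_when_aware": [False] * 400,
                "passive_exposure": [False] * 400,
            }
        )
        kids = generate_child_cohort(p, expo, tissue="whole", seed=22)
        n_cpgs = len(kids.betas.columns)
        for cpg in kids.betas.columns:
            res = stats.mannwhitneyu(kids.betas[cpg], adults.betas.loc[nev, cpg])
            assert res.pvalue > 0.05 / n_cpgs

    def test_sustained_exposure_shift_is_attenuated_delta(self):
        """With attenuation 0.5 the expected child shift is 0.5 * delta."""
        m0, delta, sd = 0.6, -0.16, 0.3
        specs = [CpGSpec("cgA", m0, delta)]
        p = plain(cpg_specs=specs, n_decoy_cpgs=0, noise_sd_logit=sd, seed=9)
        n = 4000
        expo_on = pd.DataFrame(
            {
                "mother_sustained": [True] * n,
                "mother_stopped_when_aware": [False] * n,
                "passive_exposure": [False] * n,
            }
        )
        expo_off = expo_on.copy()
        for col in expo_off.columns:
            expo_off[col] = False
        kids_on = generate_child_cohort(
            p, expo_on, tissue="whole", sustained_attenuation=0.5, seed=31
        )
        kids_off = generate_child_cohort(p, expo_off, tissue="whole", seed=32)
        deriv = m0 * (1 - m0)
        oracle = logit_normal_mean(logit(m0) + 0.5 * delta / deriv, sd)
        oracle -= logit_normal_mean(logit(m0), sd)
        emp = kids_on.betas["cgA"].mean() - kids_off.betas["cgA"].mean()
        assert emp == pytest.approx(oracle, abs=0.015)
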