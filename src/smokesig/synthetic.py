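"""Synthetic blood-methylation cohorts for smoking-classifier development.

Real training data for smoking classifiers (beta-value matrices plus
questionnaire phenotypes) sit behind cohort access agreements, so every
downstream stage of this package is exercised on simulated cohorts that
reproduce the statistical structure the analysis assumes:

* per-CpG never-smoker baseline beta values in (0, 1);
* current-smoker shifts of fixed sign per CpG, |delta| >= 0.10 on the beta
  scale for informative markers, scaled by a saturating function of
  pack-years;
* former-smoker shifts decaying exponentially with cessation time;
* decoy CpGs with no smoking association;
* plasma cotinine concentrated above/below 50 ng/mL by true smoking status,
  with a small fraction of true smokers self-reporting as never smokers.

Beta values are sampled as the inverse logit of Gaussian noise around a
logit-scale mean (a logit-normal), which keeps them bounded in [0, 1].
Shifts are specified on the beta scale and converted to the logit scale via
the local derivative at the baseline, so the ">= 10% beta difference"
ascertainment criterion stays directly expressible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CLIP_EPS",
    "CpGSpec",
    "CotinineParams",
    "SyntheticParams",
    "SyntheticCohort",
    "default_cpg_panel",
    "near_null_cpg_ids",
    "saturating_packyear_scaling",
    "generate_cohort",
    "simulate_maternal_exposure",
    "generate_child_cohort",
]

#: Beta values are clipped to [CLIP_EPS, 1 - CLIP_EPS] after sampling.
CLIP_EPS = 1e-6

STATUSES = ("current", "former", "never")


@dataclass(frozen=True)
class CpGSpec:
    """Generative spec for one CpG.

    Parameters
    ----------
    cpg_id : probe identifier (e.g. ``cg05575921``).
    baseline_beta : never-smoker mean beta, in (0, 1).
    smoker_delta : signed beta-scale shift in current smokers at full dose.
        Sign is fixed per CpG; informative markers use ``|delta| >= 0.10``.
    reversion_timescale : e-folding time (years) of the former-smoker shift.
    informative : False marks a decoy with no smoking effect.
    """

    cpg_id: str
    baseline_beta: float
    smoker_delta: float
    reversion_timescale: float = 10.0
    informative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_beta < 1.0:
            raise ValueError(
                f"{self.cpg_id}: baseline_beta must lie in (0, 1), "
                f"got {self.baseline_beta}"
            )
        if self.reversion_timescale <= 0:
            raise ValueError(
                f"{self.cpg_id}: reversion_timescale must be positive"
            )


def saturating_packyear_scaling(pack_years, half_saturation: float = 10.0):
    """Default dose-response multiplier g(PY) = PY / (PY + 10), in [0, 1)."""
    py = np.asarray(pack_years, dtype=float)
    return py / (py + half_saturation)


@dataclass(frozen=True)
class CotinineParams:
    """Log-normal plasma cotinine (ng/mL) by true current-smoking status.

    Defaults put true smokers at a median of 200 ng/mL and non-smokers at
    2 ng/mL, so the conventional 50 ng/mL cut-off separates the groups well
    but not perfectly.
    """

    smoker_median: float = 200.0
    smoker_sigma: float = 0.8
    nonsmoker_median: float = 2.0
    nonsmoker_sigma: float = 1.0


# The 13-marker panel mirrors the smoking-associated CpGs best replicated
# across blood EWASs (AHRR, F2RL3, GFI1, MYO1G, PDZD2 and intergenic sites
# on 2q37/6p21/3p25).  Baselines and shifts are plausible whole-blood values
# chosen once; EWASs report the shifts only graphically, so the exact deltas
# are free parameters constrained by the |delta| >= 0.10 selection rule.
_PANEL = [
    # (cpg_id, baseline, delta, tau_years)
    ("cg05575921", 0.85, -0.18, 19.0),   # AHRR, slow reverter
    ("cg23576855", 0.60, -0.16, 18.0),   # AHRR
    ("cg03636183", 0.70, -0.12, 12.0),   # F2RL3
    ("cg21566642", 0.50, -0.15, 10.0),   # 2q37.1
    ("cg01940273", 0.55, -0.12, 9.0),    # 2q37.1
    ("cg05951221", 0.55, -0.13, 10.0),   # 2q37.1
    ("cg06126421", 0.75, -0.14, 15.0),   # 6p21.33
    ("cg09935388", 0.65, -0.10, 6.0),    # GFI1
    ("cg12876356", 0.60, -0.11, 6.0),    # GFI1
    ("cg12803068", 0.75, +0.12, 10.0),   # MYO1G, hypermethylated
    ("cg22132788", 0.80, +0.10, 10.0),   # MYO1G
    ("cg13039251", 0.65, -0.10, 8.0),    # PDZD2
    ("cg15693572", 0.45, +0.11, 7.0),    # 3p25.3
]

#: Probe ids used for the default near-null (decoy) CpGs; these sites were
#: nominated by individual EWASs but carry no effect in the generator.
NEAR_NULL_IDS = (
    "cg19572487",  # RARA
    "cg19859270",  # GPR15
    "cg18146737",  # GFI1 region
    "cg21161138",  # AHRR region
    "cg23480021",  # 3p25.3
    "cg21188533",  # CACNA1D
    "cg03274391",  # 3p25.3
)


def default_cpg_panel() -> list[CpGSpec]:
    """The default 13 informative marker specs."""
    return [CpGSpec(c, b, d, t) for c, b, d, t in _PANEL]


def near_null_cpg_ids() -> tuple[str, ...]:
    return NEAR_NULL_IDS


@dataclass
class SyntheticParams:
    """Full parameterisation of a simulated adult cohort.

    The defaults are the study conditions of the model-building analysis:
    3764 participants with the current/former/never mix of the
    history-complete subset (364 / 1332 / 1243 out of 2939), the 13-marker
    informative panel plus 7 decoys, and a 5% misreporting fraction among
    true smokers.

    noise_sd_logit is idiosyncratic per-CpG noise; shared_noise_sd_logit is
    a per-sample component added to every CpG (correlated biological and
    cell-composition variation); susceptibility_shape parameterises a
    gamma-distributed per-smoker response multiplier with mean 1 (None
    disables it).  With the latter two switched off the model is exactly an
    independent logit-normal per CpG.
    """

    n_participants: int = 3764
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"current": 0.124, "former": 0.453, "never": 0.423}
    )
    cpg_specs: Sequence[CpGSpec] = field(default_factory=default_cpg_panel)
    n_decoy_cpgs: int = 7
    noise_sd_logit: float = 0.35
    shared_noise_sd_logit: float = 0.25
    susceptibility_shape: float | None = 4.0
    packyear_scaling: Callable[[np.ndarray], np.ndarray] = saturating_packyear_scaling
    cotinine_params: CotinineParams = field(default_factory=CotinineParams)
    misreport_rate: float = 0.05
    cordblood_offset: Mapping[str, float] | float | None = None
    missing_status_rate: float = 0.0
    missing_beta_rate: float = 0.0
    n_planted_outliers: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 20:
            raise ValueError("n_participants must be >= 20")
        if set(self.class_mix) != set(STATUSES):
            raise ValueError(f"class_mix must have keys {STATUSES}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_mix must sum to 1, got {total!r}")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        if not self.cpg_specs and self.n_decoy_cpgs == 0:
            raise ValueError("at least one CpG spec is required")
        if not any(s.informative for s in self.cpg_specs):
            raise ValueError("at least one informative CpG is required")
        if self.noise_sd_logit <= 0:
            raise ValueError("noise_sd_logit must be positive")
        if self.shared_noise_sd_logit < 0:
            raise ValueError("shared_noise_sd_logit must be non-negative")
        if not 0.0 <= self.misreport_rate < 1.0:
            raise ValueError("misreport_rate must be in [0, 1)")

    def replace(self, **kw) -> "SyntheticParams":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    """A simulated cohort: beta matrix, phenotypes, and ground truth.

    ``betas`` and ``phenotypes`` share the sample index and are the only
    model-fitting inputs; ``truth`` (per sample) and ``cpg_truth`` (per CpG)
    record the generative ground truth and never feed into fitting.
    """

    betas: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    cpg_truth: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.betas)

    def modeling_frame(self) -> pd.DataFrame:
        """Betas joined with phenotypes — everything a model may see."""
        return self.betas.join(self.phenotypes)

    def informative_cpgs(self) -> list[str]:
        return list(self.cpg_truth.index[self.cpg_truth["informative"]])


def _expected_shift(spec: CpGSpec, status, pack_years, cessation, g) -> np.ndarray:
    """Noise-free beta-scale shift per sample for one CpG.

    Current smokers: delta * g(PY).  Former smokers: delta * exp(-t/tau)
    where t is cessation time.  Never smokers and decoys: 0.
    """
    shift = np.zeros(len(status))
    if not spec.informative or spec.smoker_delta == 0.0:
        return shift
    cur = status == "current"
    fmr = status == "former"
    shift[cur] = spec.smoker_delta * g(pack_years[cur])
    shift[fmr] = spec.smoker_delta * np.exp(
        -cessation[fmr] / spec.reversion_timescale
    )
    return shift


def _logit_mu(baseline: float, beta_shift: np.ndarray) -> np.ndarray:
    # beta-scale shift -> logit scale via the local derivative at baseline
    deriv = baseline * (1.0 - baseline)
    return logit(baseline) + beta_shift / deriv


def _all_specs(params: SyntheticParams) -> list[CpGSpec]:
    # decoy baselines come from a dedicated params-derived stream so that
    # adult and child cohorts built from the same params share CpG specs
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    specs = list(params.cpg_specs)
    taken = {s.cpg_id for s in specs}
    pool = [c for c in NEAR_NULL_IDS if c not in taken]
    for i in range(params.n_decoy_cpgs):
        cpg_id = pool[i] if i < len(pool) else f"cgDECOY{i:04d}"
        specs.append(
            CpGSpec(
                cpg_id=cpg_id,
                baseline_beta=float(rng.uniform(0.25, 0.75)),
                smoker_delta=0.0,
                informative=False,
            )
        )
    ids = [s.cpg_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate CpG ids in cpg_specs")
    return specs


def generate_cohort(params: SyntheticParams) -> SyntheticCohort:
    """Generate an adult cohort; identical params give a bit-identical cohort."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants

    probs = np.array([params.class_mix[s] for s in STATUSES])
    true_status = rng.choice(np.array(STATUSES), size=n, p=probs)
    for s in STATUSES:
        if params.class_mix[s] > 0 and not np.any(true_status == s):
            raise ValueError(
                f"n={n} too small: no participants drawn for class {s!r}"
            )

    age = np.clip(rng.normal(50.0, 12.0, n), 20.0, 80.0)
    sex = rng.choice(np.array(["F", "M"]), size=n)

    ever = np.isin(true_status, ("current", "former"))
    cigs = np.full(n, np.nan)
    cigs[ever] = rng.integers(1, 41, ever.sum()).astype(float)
    age_started = np.full(n, np.nan)
    age_started[ever] = np.minimum(rng.uniform(14.0, 25.0, ever.sum()), age[ever] - 1.0)

    fmr = true_status == "former"
    age_stopped = np.full(n, np.nan)
    age_stopped[fmr] = rng.uniform(age_started[fmr] + 0.5, age[fmr])

    pack_years = np.zeros(n)
    cur = true_status == "current"
    pack_years[cur] = (age[cur] - age_started[cur]) * cigs[cur] / 20.0
    pack_years[fmr] = (age_stopped[fmr] - age_started[fmr]) * cigs[fmr] / 20.0
    cessation = np.zeros(n)
    cessation[fmr] = age[fmr] - age_stopped[fmr]

    if params.susceptibility_shape is None:
        suscept = np.ones(n)
    else:
        k = params.susceptibility_shape
        suscept = np.ones(n)
        suscept[ever] = rng.gamma(k, 1.0 / k, ever.sum())

    specs = _all_specs(params)
    g = params.packyear_scaling
    mu = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        shift = _expected_shift(spec, true_status, pack_years, cessation, g)
        mu[:, j] = _logit_mu(spec.baseline_beta, shift * suscept)

    shared = rng.normal(0.0, params.shared_noise_sd_logit, n)
    noise = rng.normal(0.0, params.noise_sd_logit, mu.shape)
    betas = expit(mu + shared[:, None] + noise)
    betas = np.clip(betas, CLIP_EPS, 1.0 - CLIP_EPS)

    cot = params.cotinine_params
    cotinine = np.where(
        cur,
        np.exp(rng.normal(np.log(cot.smoker_median), cot.smoker_sigma, n)),
        np.exp(rng.normal(np.log(cot.nonsmoker_median), cot.nonsmoker_sigma, n)),
    )

    # granulocyte / lymphocyte / monocyte fractions, independent of smoking
    cells = rng.dirichlet((30.0, 15.0, 5.0), n)

    # self-report: a misreport_rate fraction of true current smokers claim never
    misreport = cur & (rng.random(n) < params.misreport_rate)
    reported = true_status.astype(object).copy()
    reported[misreport] = "never"

    sample_ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")
    cpg_ids = [s.cpg_id for s in specs]

    pheno = pd.DataFrame(
        {
            "status": reported,
            "age": age,
            "sex": sex,
            "age_started": np.where(misreport, np.nan, age_started),
            "age_stopped": age_stopped,
            "cigs_per_day": np.where(misreport, np.nan, cigs),
            "cotinine": cotinine,
            "cell_gran": cells[:, 0],
            "cell_lymph": cells[:, 1],
            "cell_mono": cells[:, 2],
        },
        index=sample_ids,
    )
    beta_df = pd.DataFrame(betas, index=sample_ids, columns=cpg_ids)

    # planted data-quality defects for exercising the exclusion rules; chosen
    # on disjoint sample sets so the exclusion log matches the plant exactly
    order = rng.permutation(n)
    k_status = int(round(params.missing_status_rate * n))
    k_beta = int(round(params.missing_beta_rate * n))
    k_out = params.n_planted_outliers
    idx_status = order[:k_status]
    idx_beta = order[k_status : k_status + k_beta]
    idx_out = order[k_status + k_beta : k_status + k_beta + k_out]
    pheno.iloc[idx_status, pheno.columns.get_loc("status")] = np.nan
    for i in idx_beta:
        j = int(rng.integers(0, len(cpg_ids)))
        beta_df.iloc[i, j] = np.nan
    for i in idx_out:
        j = int(rng.integers(0, len(cpg_ids)))
        extreme = 1.0 - CLIP_EPS if specs[j].baseline_beta < 0.5 else CLIP_EPS
        beta_df.iloc[i, j] = extreme

    planted_status = np.zeros(n, bool)
    planted_status[idx_status] = True
    planted_beta = np.zeros(n, bool)
    planted_beta[idx_beta] = True
    planted_out = np.zeros(n, bool)
    planted_out[idx_out] = True

    truth = pd.DataFrame(
        {
            "true_status": true_status,
            "pack_years": pack_years,
            "cessation_years": cessation,
            "susceptibility": suscept,
            "misreported": misreport,
            "planted_missing_status": planted_status,
            "planted_missing_beta": planted_beta,
            "planted_outlier": planted_out,
        },
        index=sample_ids,
    )
    cpg_truth = pd.DataFrame(
        {
            "informative": [s.informative for s in specs],
            "baseline_beta": [s.baseline_beta for s in specs],
            "smoker_delta": [s.smoker_delta for s in specs],
            "reversion_timescale": [s.reversion_timescale for s in specs],
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return SyntheticCohort(beta_df, pheno, truth, cpg_truth)


def recovery_study_params(seed: int = 0) -> SyntheticParams:
    """Study conditions for the marker-recovery simulation.

    The recovery study asks whether backward elimination with the
    chi-squared stop retrieves the planted informative panel from among
    decoys.  That question is only well-posed when every planted marker
    carries *conditionally* independent information, so this configuration
    uses the plain independent logit-normal model (no shared noise, no
    response heterogeneity), current vs never smokers only, no
    misreporting, and a large per-CpG measurement noise (sd 1.0 on the
    logit scale) so that classification is measurement-noise limited rather
    than saturated.  Cohort size and current-smoker prevalence match the
    model-building defaults.
    """
    return SyntheticParams(
        class_mix={"current": 0.124, "former": 0.0, "never": 0.876},
        noise_sd_logit=1.0,
        shared_noise_sd_logit=0.0,
        susceptibility_shape=None,
        misreport_rate=0.0,
        seed=seed,
    )


EXPOSURE_COLUMNS = ("mother_sustained", "mother_stopped_when_aware", "passive_exposure")


def simulate_maternal_exposure(
    n: int,
    seed: int = 0,
    p_sustained: float = 0.145,
    p_stopped: float = 0.09,
    p_passive: float = 0.25,
) -> pd.DataFrame:
    """Draw mutually exclusive maternal active-smoking codes plus passive exposure.

    Default prevalences follow a birth cohort in which ~14.5% of mothers
    smoked throughout pregnancy.  ``passive_exposure`` (smoking by the father
    or others in the household/at work > 1 h/day) is drawn independently.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    sustained = u < p_sustained
    stopped = (u >= p_sustained) & (u < p_sustained + p_stopped)
    passive = rng.random(n) < p_passive
    return pd.DataFrame(
        {
            "mother_sustained": sustained,
            "mother_stopped_when_aware": stopped,
            "passive_exposure": passive,
        }
    )


def generate_child_cohort(
    params: SyntheticParams,
    maternal_exposure: pd.DataFrame,
    tissue: str = "cord",
    sustained_attenuation: float = 0.5,
    stopped_attenuation: float = 0.15,
    passive_attenuation: float = 0.0,
    child_age: float = 0.0,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a child cohort exposed (or not) to maternal smoking.

    Children are non-smokers; their methylation carries an attenuated version
    of the adult current-smoker shift according to prenatal exposure
    (sustained maternal smoking > stopped-when-aware > passive), plus, for
    cord blood, a per-CpG additive logit offset modelling the tissue
    difference between cord and peripheral blood.

    ``maternal_exposure`` must have boolean columns ``mother_sustained``,
    ``mother_stopped_when_aware`` and ``passive_exposure`` (one row per
    child); precedence is in that order when coding the effect.
    """
    missing = [c for c in EXPOSURE_COLUMNS if c not in maternal_exposure.columns]
    if missing:
        raise ValueError(f"maternal_exposure missing columns: {missing}")
    if tissue not in ("cord", "whole"):
        raise ValueError("tissue must be 'cord' or 'whole'")
    if tissue == "cord" and params.cordblood_offset is None:
        raise ValueError("cordblood_offset is required for cord-blood cohorts")

    n = len(maternal_exposure)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    specs = _all_specs(params)
    cpg_ids = [s.cpg_id for s in specs]

    expo = maternal_exposure.reset_index(drop=True)
    factor = np.zeros(n)
    factor[expo["passive_exposure"].to_numpy(bool)] = passive_attenuation
    factor[expo["mother_stopped_when_aware"].to_numpy(bool)] = stopped_attenuation
    factor[expo["mother_sustained"].to_numpy(bool)] = sustained_attenuation

    if tissue == "cord":
        off = params.cordblood_offset
        offsets = np.array(
            [off[c] for c in cpg_ids] if isinstance(off, Mapping) else [off] * len(cpg_ids),
            dtype=float,
        )
    else:
        offsets = np.zeros(len(cpg_ids))

    mu = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        shift = spec.smoker_delta * factor if spec.informative else np.zeros(n)
        mu[:, j] = _logit_mu(spec.baseline_beta, shift) + offsets[j]

    shared = rng.normal(0.0, params.shared_noise_sd_logit, n)
    noise = rng.normal(0.0, params.noise_sd_logit, mu.shape)
    betas = np.clip(expit(mu + shared[:, None] + noise), CLIP_EPS, 1.0 - CLIP_EPS)

    sample_ids = pd.Index([f"C{i + 1:05d}" for i in range(n)], name="sample_id")
    beta_df = pd.DataFrame(betas, index=sample_ids, columns=cpg_ids)
    pheno = pd.DataFrame(
        {
            "status": "never",
            "age": float(child_age),
            "sex": rng.choice(np.array(["F", "M"]), size=n),
            "mother_sustained": expo["mother_sustained"].to_numpy(bool),
            "mother_stopped_when_aware": expo["mother_stopped_when_aware"].to_numpy(bool),
            "passive_exposure": expo["passive_exposure"].to_numpy(bool),
        },
        index=sample_ids,
    )
    truth = pd.DataFrame(
        {
            "true_status": "never",
            "exposure_factor": factor,
            "tissue": tissue,
        },
        index=sample_ids,
    )
    cpg_truth = pd.DataFrame(
        {
            "informative": [s.informative for s in specs],
            "baseline_beta": [s.baseline_beta for s in specs],
            "smoker_delta": [s.smoker_delta for s in specs],
            "reversion_timescale": [s.reversion_timescale for s in specs],
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    return SyntheticCohort(beta_df, pheno, truth, cpg_truth)
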