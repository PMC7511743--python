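"""Synthetic cohort, lesion-stack and reaction-time generation.

The generators emulate the statistical structure the analysis assumes so
the whole pipeline is testable without restricted cohort data:

* covariate tables with the published marginal distributions and
  prevalences (age 62.9 +/- 7.4 truncated to [45.1, 80.7], 7,236/13,680
  female, hypertension 6,408/13,680, etc.), generated as *raw* assessment
  fields (blood-pressure reading pairs, smoking history, circumferences,
  genotypes, qualifications) so the risk-factor derivation can be exercised
  end to end;
* right-skewed WMH loads driven by the published log-load model
  coefficients (intercept 2.19, age 0.06, sex -0.48, age x sex 0.01,
  head size -0.29, CVR score 0.14) with log-normal noise and a floor of
  3 voxels (the smallest observed load);
* spatially smooth voxel-wise lesion probabilities Phi(beta0(s) + effects),
  with a raised "periventricular" core in the baseline field and
  covariate-dependent spherical effect regions of known probit amplitude;
* a reaction-time outcome with a built-in mediation path (treatment ->
  mediator a=0.11, mediator -> outcome b=0.05, direct effect 2.55).

Every generator is a pure function of (config, seed). Risk factors are
independent by default; a Gaussian copula option introduces pairwise
latent correlation for stress-testing confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import risk_factors
from .voxelwise import LesionStack

__all__ = [
    "GeneratorConfig",
    "EffectBlob",
    "BaselineFieldSpec",
    "generate_covariates",
    "generate_wmh_loads",
    "generate_lesion_stack",
    "generate_reaction_times",
    "generate_cohort",
    "DEFAULT_LOAD_COEFS",
    "DEFAULT_RT_COEFS",
]

N_REFERENCE = 13_680  # cohort size all published prevalences refer to

#: Log-load linear model coefficients (published univariate model).
DEFAULT_LOAD_COEFS = {
    "intercept": 2.19,
    "age": 0.06,
    "female": -0.48,
    "age:female": 0.01,
    "head_size": -0.29,
    "cvr_score": 0.14,
}

#: Reaction-time / mediation generator coefficients. The treatment (log
#: load) direct effect and the mediation paths a (treatment -> mediator) and
#: b (mediator -> outcome) follow the published point estimates.
DEFAULT_RT_COEFS = {
    "intercept": 500.0,
    "treatment": 2.55,
    "path_a": 0.11,
    "path_b": 0.05,
    "outcome_covariates": {"age": 0.3, "female": 5.0, "head_size": -5.0,
                           "education_years": -0.5},
    "mediator_covariates": {"age": 0.002, "female": -0.05, "head_size": 0.0,
                            "education_years": 0.0},
}

_FACTOR_ORDER = ["hypertension", "hypercholesterolemia", "diabetes",
                 "smoking", "whr", "apoe"]

_EDUCATION_FREQS = {  # years -> cohort count
    7: 780, 10: 1679, 13: 757, 15: 1481, 19: 2027, 20: 6006,
}
_YEARS_TO_QUALIFICATION = {
    7: "none", 10: "o_levels_gcses", 13: "a_levels",
    15: "other_professional", 19: "nvq_hnd_hnc", 20: "degree",
}


@dataclass
class BaselineFieldSpec:
    """Smooth baseline probit field with a raised core.

    The field is ``floor + peak * exp(-d^2 / (2 sigma^2))`` where d is the
    distance to the core centre, giving a periventricular-like gradient in
    the empirical probability map.
    """

    core_center: tuple | None = None     # default: grid centre
    core_sigma: float | None = None      # default: 0.25 * min(grid)
    floor: float = -1.6                  # Phi(-1.6) ~ 5.5% background
    peak: float = 1.5                    # core at Phi(-0.1) ~ 46%


@dataclass(frozen=True)
class EffectBlob:
    """Spherical covariate effect region with constant probit amplitude."""

    covariate: str
    center: tuple
    radius: float
    amplitude: float


@dataclass
class GeneratorConfig:
    n_subjects: int = N_REFERENCE
    seed: int = 0
    age_mean: float = 62.9
    age_sd: float = 7.4
    age_range: tuple = (45.1, 80.7)
    sex_prob_female: float = 7236 / N_REFERENCE
    head_size_mean: float = 1.3
    head_size_sd: float = 0.1
    prevalences: dict = field(default_factory=lambda: {
        "hypertension": 6408 / N_REFERENCE,
        "hypercholesterolemia": 2781 / N_REFERENCE,
        "diabetes": 663 / N_REFERENCE,
        "smoking": (11291 / N_REFERENCE, 2238 / N_REFERENCE, 151 / N_REFERENCE),
        "apoe": (10226 / N_REFERENCE, 3150 / N_REFERENCE, 304 / N_REFERENCE),
    })
    whr_mean: float = 0.9
    whr_sd: float = 0.1
    copula_corr: dict = field(default_factory=dict)  # (factor_a, factor_b) -> r
    load_coefs: dict = field(default_factory=lambda: dict(DEFAULT_LOAD_COEFS))
    load_sigma: float = 0.86
    grid_dims: tuple = (20, 20, 10)
    baseline_map_spec: BaselineFieldSpec = field(default_factory=BaselineFieldSpec)
    effect_blobs: list = field(default_factory=list)
    rt_coefs: dict = field(default_factory=lambda: dict(DEFAULT_RT_COEFS))
    rt_sigma: float = 1.0
    mediator_sigma: float = 1.0

    def __post_init__(self):
        for key, val in self.prevalences.items():
            arr = np.atleast_1d(np.asarray(val, dtype=float))
            if np.any(arr < 0) or np.any(arr > 1) or arr.sum() > 1 + 1e-9:
                raise ValueError(f"invalid prevalence for {key!r}: {val}")
        if self.load_sigma < 0 or self.rt_sigma < 0 or self.mediator_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if any(g <= 0 for g in self.grid_dims):
            raise ValueError("grid dimensions must be positive")


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _latent_correlation(config) -> np.ndarray:
    R = np.eye(len(_FACTOR_ORDER))
    for (a, b), r in config.copula_corr.items():
        ia, ib = _FACTOR_ORDER.index(a), _FACTOR_ORDER.index(b)
        R[ia, ib] = R[ib, ia] = float(r)
    # validity check: must be positive semi-definite
    if np.min(np.linalg.eigvalsh(R)) < -1e-10:
        raise ValueError("copula correlation matrix is not positive semi-definite")
    return R


def _ordinal_from_latent(z, probs):
    """Map standard-normal latents to ordinal levels at given prevalences."""
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if probs.size == 1:  # binary: prevalence of level 1
        return (z > stats.norm.ppf(1.0 - probs[0])).astype(int)
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, z, side="left").astype(int)


def generate_covariates(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a full synthetic assessment table (raw + derived columns).

    Raw fields (blood-pressure reading pairs, medication flags, smoking
    history, circumferences, genotype, qualification) are constructed to be
    consistent with the intended categorical risk levels, and the derived
    columns are then produced by :mod:`wmhmap.risk_factors`, so the
    generated indicators and the derivation code agree by construction.
    """
    rng = _rng(config.seed if rng is None else rng)
    n = config.n_subjects

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    female = rng.random(n) < config.sex_prob_female
    sex = np.where(female, "female", "male")
    head = np.clip(rng.normal(config.head_size_mean, config.head_size_sd, n),
                   0.9, 1.8)

    R = _latent_correlation(config)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    z = rng.standard_normal((n, R.shape[0])) @ L.T
    lat = dict(zip(_FACTOR_ORDER, z.T))

    prev = config.prevalences
    htn = _ordinal_from_latent(lat["hypertension"], prev["hypertension"])
    chol = _ordinal_from_latent(lat["hypercholesterolemia"],
                                prev["hypercholesterolemia"])
    diab = _ordinal_from_latent(lat["diabetes"], prev["diabetes"])
    smoke_probs = np.asarray(prev["smoking"], dtype=float)
    smoke = _ordinal_from_latent(lat["smoking"], smoke_probs / smoke_probs.sum())
    apoe_probs = np.asarray(prev["apoe"], dtype=float)
    apoe = _ordinal_from_latent(lat["apoe"], apoe_probs / apoe_probs.sum())

    raw = pd.DataFrame({
        "subject_id": [f"sub-{i:06d}" for i in range(n)],
        "age": age, "sex": sex, "head_size": head,
    })
    _raw_blood_pressure(raw, htn, rng)
    raw["chol_medication"] = chol.astype(float)
    raw["diabetes_diagnosed"] = diab.astype(float)
    _raw_smoking(raw, smoke, age, rng)
    _raw_whr(raw, lat["whr"], config, rng)
    raw["apoe_genotype"] = _raw_genotype(apoe, rng)
    years = np.array(sorted(_EDUCATION_FREQS))
    freqs = np.array([_EDUCATION_FREQS[y] for y in years], dtype=float)
    edu_years = rng.choice(years, size=n, p=freqs / freqs.sum())
    raw["qualification"] = [_YEARS_TO_QUALIFICATION[y] for y in edu_years]

    derived = risk_factors.derive_risk_table(raw)
    derived = derived.drop(columns=["subject_id"])
    return pd.concat([raw, derived.drop(columns=["age", "head_size"],
                                        errors="ignore")], axis=1)


def _raw_blood_pressure(raw, htn, rng):
    n = len(raw)
    med = np.zeros(n)
    med[htn == 1] = rng.random((htn == 1).sum()) < 0.5
    sbp_mean = np.empty(n)
    dbp_mean = np.empty(n)
    hi_nomed = (htn == 1) & (med == 0)
    hi_med = (htn == 1) & (med == 1)
    lo = htn == 0
    # untreated hypertensives: mean systolic strictly over 140
    sbp_mean[hi_nomed] = 141.0 + rng.gamma(2.0, 6.0, hi_nomed.sum())
    dbp_mean[hi_nomed] = rng.normal(88.0, 6.0, hi_nomed.sum())
    # treated: pressure may be controlled; the medication flag codes the risk
    sbp_mean[hi_med] = rng.normal(135.0, 10.0, hi_med.sum())
    dbp_mean[hi_med] = rng.normal(82.0, 7.0, hi_med.sum())
    # non-hypertensives: both channel means at or below threshold
    sbp_mean[lo] = 140.0 - rng.gamma(2.0, 8.0, lo.sum())
    dbp_mean[lo] = np.minimum(90.0 - rng.gamma(1.5, 5.0, lo.sum()),
                              sbp_mean[lo] - 20.0)
    dbp_mean = np.minimum(dbp_mean, sbp_mean - 10.0)
    # reading pairs symmetric about the mean so the per-channel average is exact
    d_s = rng.normal(0.0, 3.0, n)
    d_d = rng.normal(0.0, 2.0, n)
    raw["sbp_1"], raw["sbp_2"] = sbp_mean + d_s, sbp_mean - d_s
    raw["dbp_1"], raw["dbp_2"] = dbp_mean + d_d, dbp_mean - d_d
    raw["bp_medication"] = med


def _raw_smoking(raw, smoke, age, rng):
    """Draw smoking histories whose derived pack-years land in the target band."""
    n = len(raw)
    cigs = np.zeros(n)
    started = np.full(n, np.nan)
    stopped = np.full(n, np.nan)
    abst = np.zeros(n)
    smoker = smoke > 0
    ever0 = (smoke == 0) & (rng.random(n) < 0.2)  # light ever-smokers score 0 too
    smoker = smoker | ever0
    idx = np.flatnonzero(smoker)
    m = idx.size
    if m:
        band_lo = np.array([0.5, 10.5, 51.0])[smoke[idx]]
        band_hi = np.array([9.5, 49.5, 90.0])[smoke[idx]]
        py = rng.uniform(band_lo, band_hi)
        start = rng.uniform(16.0, 24.0, m)
        years = np.minimum(rng.uniform(8.0, 45.0, m), age[idx] - start - 1.0)
        years = np.where(years <= 0, np.maximum(age[idx] - start - 1.0, 1.0), years)
        current = rng.random(m) < 0.3
        gave_up = (~current) & (rng.random(m) < 0.5)
        abst_i = np.where(gave_up, rng.uniform(1.0, 8.0, m), 0.0)
        years = np.where(current, age[idx] - start, years)
        stop = start + years + np.where(abst_i > 0.5, abst_i, 0.0)
        # ex-smokers must have stopped by the assessment age
        over = np.clip(stop - age[idx], 0.0, None)
        years = np.where(~current, np.maximum(years - over, 1.0), years)
        stop = start + years + np.where(abst_i > 0.5, abst_i, 0.0)
        cigs[idx] = 20.0 * py / years
        started[idx] = start
        stopped[idx] = np.where(current, np.nan, stop)
        abst[idx] = abst_i
    raw["cigs_per_day"] = cigs
    raw["age_started_smoking"] = started
    raw["age_stopped_smoking"] = stopped
    raw["abstinence_years"] = abst


def _raw_whr(raw, z_whr, config, rng):
    n = len(raw)
    hip = np.clip(rng.normal(100.0, 8.0, n), 70.0, None)
    whr = np.clip(config.whr_mean + config.whr_sd * z_whr, 0.6, 1.2)
    raw["hip_cm"] = hip
    raw["waist_cm"] = whr * hip


def _raw_genotype(apoe, rng):
    u = rng.random(apoe.shape[0])
    out = np.empty(apoe.shape, dtype=object)
    out[apoe == 0] = "e3/e3"
    out[(apoe == 0) & (u >= 0.85)] = "e2/e3"
    out[(apoe == 0) & (u >= 0.98)] = "e2/e2"
    out[apoe == 1] = "e3/e4"
    out[(apoe == 1) & (u >= 0.94)] = "e2/e4"
    out[apoe == 2] = "e4/e4"
    return out


def generate_wmh_loads(table: pd.DataFrame, load_coefs: dict | None = None,
                       load_sigma: float = 0.86,
                       seed=0) -> pd.DataFrame:
    """Add log-normal WMH loads driven by the log-load model coefficients.

    log load = linear predictor + N(0, sigma^2); the voxel count is
    ``round(exp(log load))`` floored at 3 voxels (the smallest load the
    published cohort contains), which keeps the log transform defined and
    the marginal right-skewed.
    """
    rng = _rng(seed)
    coefs = dict(DEFAULT_LOAD_COEFS if load_coefs is None else load_coefs)
    lp = np.full(len(table), coefs.pop("intercept", 0.0))
    for name, beta in coefs.items():
        if ":" in name:
            a, b = name.split(":")
            vals = table[a].to_numpy(float) * table[b].to_numpy(float)
        else:
            vals = table[name].to_numpy(float)
        lp = lp + beta * vals
    log_load = lp + rng.normal(0.0, load_sigma, len(table))
    load = np.maximum(np.rint(np.exp(log_load)), 3.0)
    out = table.copy()
    out["wmh_load"] = load
    out["log_wmh_load"] = np.log(load)
    return out


def _baseline_field(grid_dims, spec: BaselineFieldSpec) -> np.ndarray:
    center = spec.core_center
    if center is None:
        center = tuple((g - 1) / 2.0 for g in grid_dims)
    sigma = spec.core_sigma
    if sigma is None:
        sigma = 0.25 * min(grid_dims)
    coords = np.indices(grid_dims, dtype=float)
    d2 = sum((coords[k] - center[k]) ** 2 for k in range(3))
    return spec.floor + spec.peak * np.exp(-d2 / (2.0 * sigma ** 2))


def _blob_mask(grid_dims, center, radius) -> np.ndarray:
    coords = np.indices(grid_dims, dtype=float)
    d2 = sum((coords[k] - center[k]) ** 2 for k in range(3))
    return d2 <= radius ** 2


def generate_lesion_stack(table: pd.DataFrame, grid_dims=(20, 20, 10),
                          baseline_map_spec: BaselineFieldSpec | None = None,
                          effect_blobs=(), seed=0):
    """Simulate binary lesion masks from a voxel-wise probit model.

    Per voxel s and subject i, Y_i(s) ~ Bernoulli(Phi(beta0(s) + sum_b
    amplitude_b(s) * x_i,b)) with a smooth baseline field raised near a
    designated core and constant-amplitude spherical effect regions.
    Returns ``(stack, truth)`` where truth holds the baseline and effect
    fields used, for recovery checks.
    """
    rng = _rng(seed)
    spec = baseline_map_spec or BaselineFieldSpec()
    for blob in effect_blobs:
        if not all(0 <= c < g for c, g in zip(blob.center, grid_dims)):
            raise ValueError(f"blob centre {blob.center} outside grid {grid_dims}")
    beta0 = _baseline_field(grid_dims, spec)
    nvox = int(np.prod(grid_dims))
    eta = np.broadcast_to(beta0.ravel(), (len(table), nvox)).copy()
    effect_fields = {}
    for blob in effect_blobs:
        fieldvol = np.where(_blob_mask(grid_dims, blob.center, blob.radius),
                            blob.amplitude, 0.0)
        effect_fields[blob.covariate] = (
            effect_fields.get(blob.covariate, 0.0) + fieldvol)
        x = table[blob.covariate].to_numpy(float)
        eta += x[:, None] * fieldvol.ravel()[None, :]
    if np.max(np.abs(eta)) > 8.0:
        warnings.warn("linear predictor clamped to +/-8 (probabilities "
                      "saturate numerically beyond that)", stacklevel=2)
        eta = np.clip(eta, -8.0, 8.0)
    prob = stats.norm.cdf(eta)
    data = (rng.random(prob.shape) < prob).astype(np.uint8)
    data = data.reshape((len(table),) + tuple(grid_dims))
    stack = LesionStack(
        data=data,
        brain_mask=np.ones(grid_dims, dtype=bool),
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        subject_ids=list(table["subject_id"]) if "subject_id" in table else None,
    )
    truth = {"baseline_field": beta0, "effect_fields": effect_fields,
             "probability": prob.reshape(data.shape) if nvox * len(table) < 5e7 else None}
    return stack, truth


def generate_reaction_times(table: pd.DataFrame, rt_coefs: dict | None = None,
                            rt_sigma: float = 1.0, mediator_sigma: float = 1.0,
                            seed=0) -> pd.DataFrame:
    """Add a mediator and a reaction-time outcome with a mediation path.

    mediator = a * log load + covariate terms + noise;
    rt = intercept + c' * log load + b * mediator + covariate terms + noise.
    The implied total treatment effect is c' + a*b.
    """
    rng = _rng(seed)
    coefs = dict(DEFAULT_RT_COEFS if rt_coefs is None else rt_coefs)
    loglood = table["log_wmh_load"].to_numpy(float)

    def lin(term_coefs):
        out = np.zeros(len(table))
        for name, beta in term_coefs.items():
            out += beta * table[name].to_numpy(float)
        return out

    med = (coefs["path_a"] * loglood + lin(coefs["mediator_covariates"])
           + rng.normal(0.0, mediator_sigma, len(table)))
    rt = (coefs["intercept"] + coefs["treatment"] * loglood
          + coefs["path_b"] * med + lin(coefs["outcome_covariates"])
          + rng.normal(0.0, rt_sigma, len(table)))
    out = table.copy()
    out["mediator"] = med
    out["reaction_time"] = rt
    return out


def generate_cohort(config: GeneratorConfig, with_stack: bool = False):
    """Full synthetic dataset: covariates, loads, reaction times (+stack).

    All randomness flows from ``config.seed`` through a single generator.
    Returns ``table`` or ``(table, stack, truth)`` when ``with_stack``.
    """
    rng = _rng(config.seed)
    table = generate_covariates(config, rng=rng)
    table = generate_wmh_loads(table, config.load_coefs, config.load_sigma,
                               seed=rng)
    table = generate_reaction_times(table, config.rt_coefs, config.rt_sigma,
                                    config.mediator_sigma, seed=rng)
    if not with_stack:
        return table
    stack, truth = generate_lesion_stack(
        table, config.grid_dims, config.baseline_map_spec,
        config.effect_blobs, seed=rng)
    return table, stack, truth
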