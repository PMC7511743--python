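"""Causal mediation analysis with nonparametric-bootstrap uncertainty.

The question: how much of the effect of log lesion load (treatment X) on
reaction time (outcome Y) operates through a cerebrovascular risk variable
(mediator M)? Two models are fitted with shared covariates (age, sex,
age x sex, head size, years of education):

    M = a X + covariates + error          (mediator model)
    Y = c' X + b M + covariates + error   (outcome model)

For continuous mediators the average causal mediation effect (ACME) is the
product a x b, the average direct effect (ADE) is c', and in the all-linear
case the total effect (from Y ~ X + covariates) decomposes exactly as
ACME + ADE. For binary mediators the mediator model is a binary GLM and the
ACME is computed by potential-outcome composition, averaging
b x [P(M=1 | X=x+1) - P(M=1 | X=x)] over the sample. Uncertainty comes from
resampling whole subject rows (nonparametric bootstrap, 10,000 resamples by
default) with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import br_glm
from ._design import build_design

__all__ = [
    "MediationSpec",
    "MediationEstimate",
    "fit_mediation",
    "acme_closed_form",
    "proportion_mediated",
]


@dataclass
class MediationSpec:
    treatment: str
    mediator: str
    outcome: str
    covariates: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    mediator_family: str = "linear"     # "linear" | "probit" | "logit"
    n_boot: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if len({self.treatment, self.mediator, self.outcome}) != 3:
            raise ValueError("treatment, mediator and outcome must be distinct")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.mediator_family not in ("linear", "probit", "logit"):
            raise ValueError(f"unknown mediator family {self.mediator_family!r}")


@dataclass
class MediationEstimate:
    acme: float
    ade: float
    total: float
    proportion_mediated: float          # full-sample acme/total
    proportion_mediated_boot: float     # median of resample-wise ratios
    path_a: float
    path_b: float
    ci95: dict                          # quantity -> (low, high)
    p_values: dict
    n_boot: int
    undefined_proportion: bool = False


def acme_closed_form(path_a: float, path_b: float) -> float:
    """Product-of-coefficients mediation effect for all-linear models."""
    return float(path_a * path_b)


def proportion_mediated(acme: float, total: float):
    """ACME as a fraction of the total effect; undefined when total is 0."""
    if total == 0:
        return np.nan
    return float(acme / total)


def _ols_coef(X, y):
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _point_estimates(Z, x, m, y, spec):
    """Fit mediator/outcome/total models on (covariate block Z, x, m, y)."""
    Xm = np.column_stack([Z, x])                # mediator ~ covs + t
    Xy = np.column_stack([Z, x, m])             # outcome ~ covs + t + m
    Xt = Xm                                     # total    ~ covs + t
    if spec.mediator_family == "linear":
        a = _ols_coef(Xm, m)[-1]
        coef_y = _ols_coef(Xy, y)
        cprime, b = coef_y[-2], coef_y[-1]
        acme = a * b
    else:
        d = br_glm.BinaryDesign(X=Xm, y=m, link=spec.mediator_family)
        fit = br_glm.fit_binary_glm(d, estimator="BR")
        coef_y = _ols_coef(Xy, y)
        cprime, b = coef_y[-2], coef_y[-1]
        # potential-outcome composition: average shift in P(M=1) for a unit
        # increment of the treatment, times the outcome's mediator slope
        eta0 = Xm @ fit.estimates
        eta1 = eta0 + fit.estimates[-1]
        if spec.mediator_family == "probit":
            from scipy.stats import norm
            pshift = norm.cdf(eta1) - norm.cdf(eta0)
        else:
            from scipy.special import expit
            pshift = expit(eta1) - expit(eta0)
        a = float(np.mean(pshift))
        acme = b * a
    total = _ols_coef(Xt, y)[-1]
    return float(acme), float(cprime), float(total), float(a), float(b)


def _boot_pvalue(draws: np.ndarray) -> float:
    """Two-sided bootstrap p: 2 min(#<=0, #>=0)/B with +1 continuity."""
    B = draws.size
    lo = np.sum(draws <= 0.0)
    hi = np.sum(draws >= 0.0)
    return float(min(1.0, 2.0 * (min(lo, hi) + 1) / (B + 1)))


def fit_mediation(table: pd.DataFrame, spec: MediationSpec) -> MediationEstimate:
    """Point estimates plus percentile bootstrap CIs and p-values.

    Rows with missing values in any used column must be filtered first.
    The bootstrap resamples whole subject rows and is reproducible for a
    fixed ``spec.seed``.
    """
    used = [spec.treatment, spec.mediator, spec.outcome]
    if table[used].isna().any().any():
        raise ValueError("missing values in mediation variables; filter first")
    design = build_design(table, spec.covariates, spec.interactions)
    Z = design.X
    x = table[spec.treatment].to_numpy(dtype=float)
    m = table[spec.mediator].to_numpy(dtype=float)
    y = table[spec.outcome].to_numpy(dtype=float)
    if spec.mediator_family != "linear" and not np.all(np.isin(m, (0.0, 1.0))):
        raise ValueError("binary mediator family requires 0/1 mediator values")
    # collinearity of mediator with treatment makes paths unidentifiable
    full = np.column_stack([Z, x, m])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise np.linalg.LinAlgError(
            "mediator is collinear with treatment/covariates")

    acme, ade, total, a, b = _point_estimates(Z, x, m, y, spec)

    rng = np.random.default_rng(spec.seed)
    n = len(table)
    B = spec.n_boot
    if spec.mediator_family == "linear":
        draws = _linear_bootstrap(Z, x, m, y, B, rng)
    else:
        draws = np.empty((B, 3))
        for bi in range(B):
            idx = rng.integers(0, n, size=n)
            acme_b, ade_b, total_b, _, _ = _point_estimates(
                Z[idx], x[idx], m[idx], y[idx], spec)
            draws[bi] = (acme_b, ade_b, total_b)

    alpha = 1.0 - spec.ci_level
    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    labels = ("acme", "ade", "total")
    ci95 = {lab: tuple(np.percentile(draws[:, k], [qlo, qhi]))
            for k, lab in enumerate(labels)}
    p_values = {lab: _boot_pvalue(draws[:, k]) for k, lab in enumerate(labels)}
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_draws = draws[:, 0] / draws[:, 2]
    prop_draws = prop_draws[np.isfinite(prop_draws)]
    if prop_draws.size:
        ci95["proportion_mediated"] = tuple(np.percentile(prop_draws, [qlo, qhi]))
        p_values["proportion_mediated"] = _boot_pvalue(prop_draws)

    undefined = np.isclose(total, 0.0)
    return MediationEstimate(
        acme=acme, ade=ade, total=total,
        proportion_mediated=np.nan if undefined else acme / total,
        proportion_mediated_boot=float(np.median(prop_draws)) if prop_draws.size else np.nan,
        path_a=a, path_b=b, ci95=ci95, p_values=p_values,
        n_boot=B, undefined_proportion=bool(undefined))


def _linear_bootstrap(Z, x, m, y, B, rng, chunk: int | None = None):
    """Vectorised row-resampling bootstrap for the all-linear case."""
    n = Z.shape[0]
    if chunk is None:  # cap the (chunk, n, p) work array around ~200 MB
        chunk = int(np.clip(2.5e6 // max(n, 1), 1, 200))
    draws = np.empty((B, 3))
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        idx = rng.integers(0, n, size=(nb, n))
        Xm = np.concatenate([Z[idx], x[idx][..., None]], axis=2)
        Xy = np.concatenate([Xm, m[idx][..., None]], axis=2)
        a_co = _batched_ols(Xm, m[idx])
        y_co = _batched_ols(Xy, y[idx])
        t_co = _batched_ols(Xm, y[idx])
        a_b = a_co[:, -1]
        b_b = y_co[:, -1]
        c_b = y_co[:, -2]
        draws[done:done + nb, 0] = a_b * b_b
        draws[done:done + nb, 1] = c_b
        draws[done:done + nb, 2] = t_co[:, -1]
        done += nb
    return draws


def _batched_ols(X, y):
    """Normal-equation OLS over a batch of (n x p) designs."""
    G = np.einsum("bni,bnj->bij", X, X)
    r = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(G, r[..., None])[..., 0]


def mediation_summary_table(est: MediationEstimate) -> pd.DataFrame:
    """Export rows mirroring the standard mediation report layout."""
    rows = [
        ("X on M", est.path_a, None, None),
        ("M on Y", est.path_b, None, None),
        ("Mediation effect", est.acme, est.ci95.get("acme"), est.p_values.get("acme")),
        ("Direct effect", est.ade, est.ci95.get("ade"), est.p_values.get("ade")),
        ("Total effect", est.total, est.ci95.get("total"), est.p_values.get("total")),
        ("Proportion mediated", est.proportion_mediated,
         est.ci95.get("proportion_mediated"), est.p_values.get("proportion_mediated")),
    ]
    recs = []
    for name, estv, ci, p in rows:
        recs.append({
            "quantity": name, "estimate": estv,
            "ci_low": ci[0] if ci else np.nan,
            "ci_high": ci[1] if ci else np.nan,
            "p_value": p if p is not None else np.nan,
        })
    return pd.DataFrame(recs)
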