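"""Subject-level linear models of log lesion load.

Total WMH load (a voxel count) is strongly right-skewed, so it is modelled
on the natural-log scale with normal linear models: confounders age, sex,
their interaction and head size, plus risk terms. Goodness of fit is
summarised by adjusted R² and by a partial adjusted R² per term (an
adjusted version of the classical partial R², computed against an explicit
reduced-model refit). A tricube-weighted local polynomial smoother (loess,
20% span by default) supports exploratory age trends, and coefficients on
the log scale are interpreted as multiplicative fold changes in load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._design import ModelSpec, Term, build_design

__all__ = [
    "ModelSpec",
    "Term",
    "LinearFit",
    "LoessCurve",
    "prepare_log_load",
    "fit_linear_load_model",
    "partial_adjusted_r2",
    "fold_change",
    "loess_smooth",
]


@dataclass
class LinearFit:
    """OLS/ML fit of a normal linear model with per-term diagnostics."""

    params: pd.Series
    se: pd.Series
    ci95: pd.DataFrame          # columns: low, high
    p_values: pd.Series
    sigma2_hat: float           # ML residual variance (SSE / N)
    r2_adj: float
    partial_r2_adj: pd.Series   # indexed by term label
    n: int
    residuals: np.ndarray
    design_names: list[str]
    term_columns: dict[str, list[int]]
    spec: ModelSpec = field(repr=False, default=None)

    def summary_table(self) -> pd.DataFrame:
        """Term-level export: estimate, CI, p-value, partial adjusted R²."""
        rows = []
        for name in self.params.index:
            rows.append({
                "term": name,
                "estimate": self.params[name],
                "ci_low": self.ci95.loc[name, "low"],
                "ci_high": self.ci95.loc[name, "high"],
                "p_value": self.p_values[name],
            })
        tab = pd.DataFrame(rows)
        pr2 = self.partial_r2_adj.rename("partial_r2_adj")
        return tab, pr2


@dataclass
class LoessCurve:
    eval_x: np.ndarray
    fitted_y: np.ndarray
    span: float
    degree: int


def prepare_log_load(table: pd.DataFrame, load_col: str = "wmh_load",
                     out_col: str = "log_wmh_load") -> pd.DataFrame:
    """Add the natural-log load column, refusing non-positive loads."""
    load = table[load_col].to_numpy(dtype=float)
    if np.any(load <= 0):
        raise ValueError("non-positive WMH load: log is undefined "
                         "(the smallest observable load here is 1 voxel)")
    out = table.copy()
    out[out_col] = np.log(load)
    return out


def fit_linear_load_model(table: pd.DataFrame, spec: ModelSpec) -> LinearFit:
    """Least-squares fit with t-based 95% CIs and two-sided p-values.

    Factors expand to treatment contrasts against level 0; the design must
    be full rank (collinear columns are named in the error). Partial
    adjusted R² is computed for every non-intercept term by refitting
    without that term's contrast block.
    """
    if table[spec.response].isna().any():
        raise ValueError(f"missing values in response {spec.response!r}; filter first")
    y = table[spec.response].to_numpy(dtype=float)
    design = build_design(table, spec.coerced_terms(), spec.interactions)
    model = sm.OLS(y, design.X)
    res = model.fit()
    names = design.names
    ci = res.conf_int(alpha=0.05)  # t-distribution quantiles, df = N - P
    n, p = design.X.shape
    partial = {}
    for term, cols in design.term_columns.items():
        if term == "Intercept":
            continue
        partial[term] = _partial_r2_adj_from_design(y, design.X, cols)
    return LinearFit(
        params=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        ci95=pd.DataFrame(ci, index=names, columns=["low", "high"]),
        p_values=pd.Series(res.pvalues, index=names),
        sigma2_hat=float(res.ssr / n),
        r2_adj=float(res.rsquared_adj),
        partial_r2_adj=pd.Series(partial, dtype=float),
        n=n,
        residuals=np.asarray(res.resid),
        design_names=names,
        term_columns=design.term_columns,
        spec=spec,
    )


def _sse(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _partial_r2_adj_from_design(y, X, cols) -> float:
    """1 - [SSE_full/(N-P_full)] / [SSE_reduced/(N-P_reduced)].

    The reduced model drops the term's full contrast block (both dummies of
    a 3-level factor jointly).
    """
    n, p_full = X.shape
    keep = [j for j in range(p_full) if j not in set(cols)]
    sse_full = _sse(y, X)
    sse_red = _sse(y, X[:, keep])
    p_red = len(keep)
    return 1.0 - (sse_full / (n - p_full)) / (sse_red / (n - p_red))


def partial_adjusted_r2(table: pd.DataFrame, spec: ModelSpec, term: str) -> float:
    """Partial adjusted R² of one term (or interaction label ``"a:b"``)."""
    y = table[spec.response].to_numpy(dtype=float)
    design = build_design(table, spec.coerced_terms(), spec.interactions)
    if term not in design.term_columns or term == "Intercept":
        raise KeyError(f"term {term!r} not in model "
                       f"(available: {[t for t in design.term_columns if t != 'Intercept']})")
    return _partial_r2_adj_from_design(y, design.X, design.term_columns[term])


def fold_change(coefficient: float, multiplier: float = 1.0) -> float:
    """Multiplicative change in load per ``multiplier`` units of a covariate.

    Valid when the model response is log load: exp(coefficient x multiplier).
    """
    return float(np.exp(coefficient * multiplier))


def loess_smooth(x, y, span: float = 0.2, degree: int = 1,
                 n_eval: int = 50, eval_x=None) -> LoessCurve:
    """Locally weighted polynomial smoothing with tricube weights.

    At each evaluation point the nearest ``ceil(span * n)`` observations are
    fitted by weighted polynomial regression of the given degree (0, 1 or 2)
    and the fitted value at the point is returned. The default 20% span
    means each local window holds 20% of the data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    n = x.size
    k = max(degree + 2, int(np.ceil(span * n)))
    if n < k:
        raise ValueError(f"need at least {k} points for span={span}, degree={degree}")
    if eval_x is None:
        eval_x = np.linspace(x.min(), x.max(), n_eval)
    eval_x = np.asarray(eval_x, dtype=float)

    fitted = np.empty_like(eval_x)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, x0 in enumerate(eval_x):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, None) ** 3
        w = np.where(w <= 0, 1e-12, w)  # keep boundary points in the fit
        xc = xs[idx] - x0
        B = np.vander(xc, degree + 1, increasing=True)
        WB = B * w[:, None]
        coef, *_ = np.linalg.lstsq(WB.T @ B, WB.T @ ys[idx], rcond=None)
        fitted[i] = coef[0]
    return LoessCurve(eval_x=eval_x, fitted_y=fitted, span=span, degree=degree)
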