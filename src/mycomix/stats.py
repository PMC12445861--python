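"""Group-comparison statistics: linear mixed models with a plot random
effect, single-step Tukey-Kramer all-pairwise contrasts, and two-sample
t-tests.

The model is a one-way cell-means linear mixed model

    y_ij = mu_g(ij) + b_plot(ij) + e_ij,
    b_plot ~ N(0, sigma2_plot), e ~ N(0, sigma2_resid),

fitted by REML through :mod:`statsmodels` ``MixedLM``. Fixed effects use the
cell-means parameterisation (one coefficient per group, no intercept), so a
coefficient IS that group's adjusted mean. Pairwise contrasts are adjusted
with the studentized-range (Tukey-Kramer) distribution; the denominator
degrees of freedom use the containment rule df = n - k - (p - 1), i.e. the
residual df after removing group and plot-block df (df = n - k when there is
a single plot). With exactly two groups the adjusted p equals the ordinary
two-sided t p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "LmmFit",
    "ContrastTable",
    "TTestResult",
    "fit_group_lmm",
    "tukey_kramer",
    "two_sample_t",
    "two_sample_t_from_stats",
]


@dataclass(frozen=True)
class LmmFit:
    """A fitted one-way linear mixed model with a plot random intercept."""

    response: str
    fixed_levels: tuple[str, ...]
    coefficients: dict[str, float]      # group -> estimated group mean
    cov_fe: np.ndarray                  # covariance of fixed effects
    plot_variance: float
    residual_variance: float
    n_obs: int
    n_plots: int
    group_ns: dict[str, int]
    converged: bool = True

    @property
    def contrast_df(self) -> int:
        """Containment denominator df for pairwise group contrasts."""
        k, p = len(self.fixed_levels), self.n_plots
        df = self.n_obs - k - (p - 1 if p > 1 else 0)
        return max(df, 1)


@dataclass(frozen=True)
class ContrastTable:
    """All pairwise group contrasts with single-step adjusted p-values."""

    pairs: pd.DataFrame  # group_a, group_b, estimate, se, statistic, p_adj
    method: str
    df: int

    def __iter__(self):
        return iter(self.pairs.itertuples(index=False))


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def _coerce_frame(
    data, response: str, group_col: str, plot_col: str
) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data
    else:
        seq = list(data)
        if not seq:
            raise InvalidInputError("no observations")
        rows = []
        for obj in seq:
            rows.append(
                {
                    group_col: getattr(obj, group_col),
                    plot_col: getattr(obj, plot_col),
                    response: getattr(obj, response),
                }
            )
        df = pd.DataFrame(rows)
    missing = {response, group_col, plot_col} - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    return df[[group_col, plot_col, response]].dropna()


def fit_group_lmm(
    data,
    response: str = "delta13C",
    group_col: str = "group",
    plot_col: str = "plot_id",
) -> LmmFit:
    """REML fit of ``response ~ 0 + group + (1 | plot)``.

    Parameters
    ----------
    data
        Tidy DataFrame, or a sequence of objects exposing the three columns
        as attributes (``IsotopeSample`` or ``EnrichmentRecord`` work).
    response
        Which measurement to model (raw delta values by default; enrichment
        factors may be modelled instead by passing ``eps13C``/``eps15N``).

    Notes
    -----
    Variance components are bounded at zero; a boundary (zero) plot variance
    is legitimate and reduces the fixed effects to ordinary least-squares
    group means. Singular fits warn instead of raising. When the data contain
    a single plot the random effect is unidentifiable and an OLS fit with
    zero plot variance is returned.
    """
    df = _coerce_frame(data, response, group_col, plot_col)
    if df[group_col].nunique() < 2:
        raise InvalidInputError("fit_group_lmm needs at least 2 groups")
    if len(df) < 2:
        raise InvalidInputError("fit_group_lmm needs at least 2 observations")

    levels = tuple(sorted(df[group_col].unique()))
    group_ns = df[group_col].value_counts().to_dict()
    n_plots = df[plot_col].nunique()
    y = df[response].to_numpy(dtype=float)
    X = pd.get_dummies(df[group_col]).reindex(columns=levels).to_numpy(dtype=float)

    if np.ptp(y) == 0.0:
        # constant response: everything is exactly zero
        return LmmFit(
            response=response,
            fixed_levels=levels,
            coefficients={g: float(y[0]) for g in levels},
            cov_fe=np.zeros((len(levels), len(levels))),
            plot_variance=0.0,
            residual_variance=0.0,
            n_obs=len(df),
            n_plots=n_plots,
            group_ns=group_ns,
        )
    if n_plots < 2:
        # random intercept unidentifiable with a single plot
        return _ols_fit(y, X, levels, group_ns, response, n_plots)

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = sm.MixedLM(y, X, groups=df[plot_col].to_numpy())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True, method="lbfgs")
            if not res.converged:
                res = model.fit(reml=True, method="powell")
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(
                "mixed-model fit is singular; falling back to OLS group means",
                UserWarning,
                stacklevel=2,
            )
            return _ols_fit(y, X, levels, group_ns, response, n_plots)

    if not converged:
        warnings.warn("mixed-model REML did not fully converge", UserWarning,
                      stacklevel=2)
    plot_var = float(np.asarray(res.cov_re)[0, 0])
    return LmmFit(
        response=response,
        fixed_levels=levels,
        coefficients={g: float(b) for g, b in zip(levels, res.fe_params)},
        cov_fe=np.asarray(res.cov_params())[: len(levels), : len(levels)],
        plot_variance=max(plot_var, 0.0),
        residual_variance=max(float(res.scale), 0.0),
        n_obs=len(df),
        n_plots=n_plots,
        group_ns=group_ns,
        converged=converged,
    )


def _ols_fit(y, X, levels, group_ns, response, n_plots) -> LmmFit:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - len(levels), 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    return LmmFit(
        response=response,
        fixed_levels=levels,
        coefficients={g: float(b) for g, b in zip(levels, beta)},
        cov_fe=s2 * XtX_inv,
        plot_variance=0.0,
        residual_variance=s2,
        n_obs=len(y),
        n_plots=n_plots,
        group_ns=group_ns,
    )


def tukey_kramer(fit: LmmFit, alpha: float = 0.05) -> ContrastTable:
    """Single-step all-pairwise comparisons from a fitted group LMM.

    For each unordered pair (a, b) the contrast estimate is
    ``mu_a - mu_b`` with standard error from the fitted fixed-effect
    covariance; the family-wise adjusted p-value is
    ``P(Q_{k,df} >= sqrt(2) |t|)`` where Q is the studentized range with
    k = number of groups and the containment df of the fit. This is the
    Tukey-Kramer procedure, valid under unequal group sizes.
    """
    levels = fit.fixed_levels
    if len(levels) < 2:
        raise InvalidInputError("tukey_kramer needs a fit with >= 2 groups")
    k, df = len(levels), fit.contrast_df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            est = fit.coefficients[a] - fit.coefficients[b]
            var = (
                fit.cov_fe[i, i] + fit.cov_fe[j, j] - 2.0 * fit.cov_fe[i, j]
            )
            se = math.sqrt(max(var, 0.0))
            if se == 0.0:
                t = 0.0 if est == 0.0 else math.inf
            else:
                t = est / se
            if math.isinf(t):
                p = 0.0
            else:
                p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(t), k, df))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "estimate": est,
                    "se": se,
                    "statistic": t,
                    "p_adj": min(max(p, 0.0), 1.0),
                    "significant": p < alpha,
                }
            )
    return ContrastTable(
        pairs=pd.DataFrame(rows),
        method="tukey-kramer (studentized range, single-step)",
        df=df,
    )


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test; pooled-variance (Student's) by default.

    Welch's unequal-variance form is available behind ``welch=True``.
    Degenerate zero-variance inputs are resolved by convention: equal means
    give (t=0, p=1); unequal means with zero pooled variance give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs n >= 2")
    return two_sample_t_from_stats(
        a.mean(), a.std(ddof=1), a.size,
        b.mean(), b.std(ddof=1), b.size,
        welch=welch,
    )


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    welch: bool = False,
) -> TTestResult:
    """t-test from summary statistics (mean, sample SD, n per group).

    Useful for re-analysing published "mean +/- SD (n)" summaries.
    """
    if n_a < 2 or n_b < 2:
        raise InvalidInputError("each sample needs n >= 2")
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            df = n_a + n_b - 2
            return TTestResult(0.0, float(df), 1.0)
        return TTestResult(math.inf if mean_a > mean_b else -math.inf,
                           float(n_a + n_b - 2), 0.0)
    equal_var = not welch
    t, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    if equal_var:
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(float(t), df, float(p))
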