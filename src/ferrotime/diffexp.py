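"""Per-transcript differential expression against the 0 h reference.

Each transcript is fit with a one-way design over time points: the 0 h
group is the intercept and the coefficient for post-treatment time point t
is the log2 fold change beta_t = mean(log2 at t) - mean(log2 at 0 h), with
a pooled within-time-point residual variance s^2 on d = n_arrays -
n_timepoints degrees of freedom.

With only two replicate arrays per time point the per-transcript variance
estimate is extremely noisy, so it is stabilized by empirical-Bayes
shrinkage toward a common prior: the marginal distribution of s^2 under a
scaled inverse-chi-square prior (s0^2, d0) makes log s^2 follow a shifted
log-F, whose mean and variance involve digamma/trigamma of the half
degrees of freedom.  Matching the observed moments of log s^2 yields (d0,
s0^2); the posterior (moderated) variance is the precision-weighted blend

    s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d)

and moderated t statistics gain d0 extra degrees of freedom.  p-values are
corrected by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionSet


@dataclass
class DEThresholds:
    """Differential-expression call thresholds.

    The primary analysis uses q < 0.05 and |log2FC| >= 1 (2-fold); the
    looser cross-study harmonization criteria (|log2FC| >= 0.5, p < 0.01)
    live in :mod:`ferrotime.meta`.
    """

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")


@dataclass
class LinearFitResult:
    """Group-mean fit per transcript plus moderation state."""

    coefficients: pd.DataFrame  # transcript x post-treatment timepoint (log2FC)
    s2: pd.Series  # pooled residual variance
    df_residual: int
    group_sizes: dict[float, int]
    d0: float | None = None
    s0_2: float | None = None
    s2_moderated: pd.Series | None = None

    @property
    def reference(self) -> float:
        return 0.0


def fit_linear_model(expr: ExpressionSet, expressed_only: bool = True) -> LinearFitResult:
    """One-way group-means fit: log2FC per post-treatment time point and a
    pooled within-group variance."""
    values = expr.expressed_values() if expressed_only else expr.values
    design = expr.design
    tps = np.sort(design["timepoint"].unique())
    if 0 not in tps:
        raise ValueError("design must contain the 0 h reference time point")
    group_cols = {t: design.loc[design["timepoint"] == t, "array_id"].tolist() for t in tps}
    sizes = {t: len(cols) for t, cols in group_cols.items()}
    if any(n < 1 for n in sizes.values()):
        raise ValueError("every time point needs at least one array")
    n_arrays = sum(sizes.values())
    d = n_arrays - len(tps)
    if d < 1:
        raise ValueError("no residual degrees of freedom (need replicates)")

    means = {t: values[cols].mean(axis=1) for t, cols in group_cols.items()}
    coeffs = pd.DataFrame(
        {t: means[t] - means[0] for t in tps if t != 0}, index=values.index
    )
    rss = pd.Series(0.0, index=values.index)
    for t, cols in group_cols.items():
        centered = values[cols].sub(means[t], axis=0)
        rss += (centered**2).sum(axis=1)
    s2 = rss / d
    return LinearFitResult(coefficients=coeffs, s2=s2, df_residual=d, group_sizes=sizes)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by a bracketed monotone root search."""
    lo, hi = 1e-2, 1e6
    f = lambda x: special.polygamma(1, x) - y
    if f(lo) < 0:  # y above trigamma(1e-2): solution below bracket
        return lo
    if f(hi) > 0:  # y below trigamma(1e6): effectively infinite x
        return np.inf
    return optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)


def moderate_variances(fit: LinearFitResult, min_transcripts: int = 10) -> LinearFitResult:
    """Estimate the variance prior (d0, s0^2) by moment matching on log s^2
    and fill in the moderated variances.

    If the observed spread of log s^2 is no larger than expected from a
    chi-square with d degrees of freedom alone, the prior is degenerate
    (d0 = +inf) and all moderated variances equal s0^2.
    """
    s2 = fit.s2
    d = fit.df_residual
    finite = s2[np.isfinite(s2) & (s2 > 0)]
    if (s2 <= 0).all():
        warnings.warn("all residual variances are zero; moderation skipped")
        fit.d0, fit.s0_2, fit.s2_moderated = 0.0, 0.0, s2.copy()
        return fit
    if len(finite) < min_transcripts:
        warnings.warn("too few transcripts for moderation; using raw variances")
        fit.d0, fit.s0_2, fit.s2_moderated = 0.0, float("nan"), s2.copy()
        return fit

    z = np.log(finite.to_numpy())
    e_z = z.mean()
    var_z = z.var(ddof=1)
    if var_z < 1e-12:
        # all variances (numerically) identical: the chi-square sampling model
        # cannot hold, so skip its bias correction and take the common value
        fit.d0, fit.s0_2 = np.inf, float(np.exp(e_z))
        fit.s2_moderated = pd.Series(fit.s0_2, index=s2.index)
        return fit
    excess = var_z - special.polygamma(1, d / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_z - special.digamma(d / 2.0) + np.log(d / 2.0)
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0 if np.isfinite(half_d0) else np.inf
        if np.isfinite(d0):
            log_s0 = (
                e_z
                + special.digamma(half_d0)
                - np.log(half_d0)
                - special.digamma(d / 2.0)
                + np.log(d / 2.0)
            )
        else:
            log_s0 = e_z - special.digamma(d / 2.0) + np.log(d / 2.0)
    s0_2 = float(np.exp(log_s0))

    if np.isinf(d0):
        s2_mod = pd.Series(s0_2, index=s2.index)
    else:
        s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)
    fit.d0, fit.s0_2, fit.s2_moderated = float(d0), s0_2, s2_mod
    return fit


def moderated_test(fit: LinearFitResult) -> pd.DataFrame:
    """Two-sided p-values per transcript per post-treatment time point.

    t = beta_t / sqrt(s_tilde^2 * (1/n_t + 1/n_0)) on d0 + d degrees of
    freedom (standard normal when d0 = +inf).
    """
    s2 = fit.s2_moderated if fit.s2_moderated is not None else fit.s2
    d_total = fit.df_residual + (fit.d0 or 0.0)
    n0 = fit.group_sizes[0.0]
    pvals = {}
    for t in fit.coefficients.columns:
        c_t = 1.0 / fit.group_sizes[t] + 1.0 / n0
        se = np.sqrt(s2 * c_t)
        beta = fit.coefficients[t]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        if np.isinf(d_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df=d_total)
        # degenerate variance: certain calls
        zero_se = se == 0
        if zero_se.any():
            warnings.warn("zero moderated variance for some transcripts")
            p = np.where(zero_se & (beta != 0), 0.0, p)
            p = np.where(zero_se & (beta == 0), 1.0, p)
        pvals[t] = p
    return pd.DataFrame(pvals, index=fit.coefficients.index)


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_(i) = min_{j>=i} n*p_(j)/j, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def call_de(fc_table: pd.DataFrame, thresholds: DEThresholds | None = None) -> pd.DataFrame:
    """Per-time-point and overall DE flags from a fold-change table.

    Expects columns ``log2fc_<t>``/``q_<t>``; a transcript is DE at t iff
    q_t < q_max and |log2FC_t| >= min_abs_log2fc, and DE overall if DE at
    any time point.
    """
    th = thresholds or DEThresholds()
    tps = [c.removeprefix("log2fc_") for c in fc_table.columns if c.startswith("log2fc_")]
    flags = pd.DataFrame(index=fc_table.index)
    for t in tps:
        flags[f"de_{t}"] = (fc_table[f"q_{t}"] < th.q_max) & (
            fc_table[f"log2fc_{t}"].abs() >= th.min_abs_log2fc
        )
    flags["de_any"] = flags.any(axis=1)
    return flags


def differential_expression(
    expr: ExpressionSet,
    thresholds: DEThresholds | None = None,
    moderation: bool = True,
    fdr_scope: str = "per-timepoint",
) -> pd.DataFrame:
    """Full DE analysis of an expression set; returns the fold-change table.

    Columns: ``log2fc_<t>``, ``p_<t>``, ``q_<t>``, ``de_<t>`` for each
    post-treatment time point plus ``de_any``.  FDR is computed across
    transcripts within each time point by default (``fdr_scope="global"``
    pools all time points).
    """
    if fdr_scope not in ("per-timepoint", "global"):
        raise ValueError("fdr_scope must be 'per-timepoint' or 'global'")
    fit = fit_linear_model(expr)
    if moderation:
        fit = moderate_variances(fit)
    pvals = moderated_test(fit)

    if fdr_scope == "global":
        q_flat = bh_fdr(pvals.to_numpy().ravel())
        qvals = pd.DataFrame(
            q_flat.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
        )
    else:
        qvals = pvals.apply(lambda col: bh_fdr(col.to_numpy()), axis=0)

    table = pd.DataFrame(index=fit.coefficients.index)
    for t in fit.coefficients.columns:
        label = f"{t:g}h"
        table[f"log2fc_{label}"] = fit.coefficients[t]
        table[f"p_{label}"] = pvals[t]
        table[f"q_{label}"] = qvals[t]
    flags = call_de(table, thresholds)
    return pd.concat([table, flags], axis=1)
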