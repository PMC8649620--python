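"""Paired differential expression with empirical-Bayes variance moderation.

Every contrast is recurrent-minus-initial within one patient, so
between-patient and between-histology variation cancels by construction.
The moderated test shrinks each gene's variance of paired differences toward
a cohort-wide prior estimated by moment matching on the log variances
(the standard empirical-Bayes hierarchical model: s2_g | sigma2_g is scaled
chi-square on df, and 1/sigma2_g is scaled chi-square on d0 with scale
s0_sq), which adds d0 prior degrees of freedom to every gene's test.

A patient contributing several recurrent/progressive tumors contributes one
pair per tumor, each against the same initial sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "quantile_normalize",
    "median_positive_filter",
    "paired_differences",
    "fit_fdist_moments",
    "trigamma_inverse",
    "moderated_paired_t",
    "paired_t_plain",
    "expected_by_chance",
    "purity_adjusted_association",
    "bh_adjust",
]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean-of-order-statistics distribution.

    After normalization each column holds the same sorted value vector: the
    across-sample mean of the k-th smallest values. Ties within a column
    receive the mean of the quantile values they span (midrank interpolation).
    """
    if m.shape[1] < 1:
        raise ValueError("quantile normalization requires at least one sample")
    values = m.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy() - 1.0
    out = np.interp(ranks, np.arange(len(reference)), reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def median_positive_filter(linear: pd.DataFrame) -> pd.DataFrame:
    """Keep genes whose median across samples is positive (linear scale).

    Applied to linear-scale abundance before the log2(x+1) transform, this
    drops genes undetected in at least half the cohort.
    """
    return linear.loc[linear.median(axis=1) > 0]


def paired_differences(m: pd.DataFrame, pairing: pd.DataFrame) -> pd.DataFrame:
    """Center each recurrent/progressive tumor on its patient's initial tumor.

    Returns a genes x recurrent-samples matrix; column r is
    ``m[:, r] - m[:, initial(r)]``, one column per pairing row.
    """
    for col in ("initial_sample_id", "recurrent_sample_id"):
        missing = set(pairing[col]) - set(m.columns)
        if missing:
            raise KeyError(
                f"pairing column {col} references samples absent from the "
                f"expression matrix: {sorted(missing)}"
            )
    rec = m[list(pairing["recurrent_sample_id"])].to_numpy()
    init = m[list(pairing["initial_sample_id"])].to_numpy()
    return pd.DataFrame(
        rec - init, index=m.index, columns=list(pairing["recurrent_sample_id"])
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0.

    trigamma is strictly decreasing from +inf at 0+ to 0 at +inf, so the
    root is unique; bracketed bisection via brentq is robust for the range
    met in variance-moderation fits.
    """
    if x <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    if special.polygamma(1, hi) > x:
        return hi
    from scipy.optimize import brentq

    return float(brentq(lambda y: special.polygamma(1, y) - x, lo, hi, xtol=1e-12))


def fit_fdist_moments(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching fit of the variance prior (d0, s0_sq) on log variances.

    With e_g = log(s2_g) - digamma(df/2) + log(df/2), the model implies
    E[e] = log(s0_sq) + digamma(d0/2) - log(d0/2) and
    Var[e] = trigamma(d0/2) + trigamma(df/2). The excess of the observed
    variance of e over trigamma(df/2) identifies d0; non-positive excess
    means no detectable between-gene variance spread, giving d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero; cannot fit a variance prior")
    if positive.size < 10:
        raise ValueError(f"need >=10 genes with positive variance, got {positive.size}")
    e = np.log(positive) - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_bar = float(e.mean())
    v = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if v <= 0:
        # no detectable between-gene spread: the prior variance is the
        # pooled common variance
        return math.inf, float(positive.mean())
    half_d0 = trigamma_inverse(v)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(e_bar + special.digamma(half_d0) - math.log(half_d0))
    return d0, s0_sq


def _stats_frame(
    index: pd.Index,
    mean_diff: np.ndarray,
    s2: np.ndarray,
    df_residual,
    t: np.ndarray,
    p: np.ndarray,
) -> pd.DataFrame:
    direction = np.where(mean_diff > 0, "up", np.where(mean_diff < 0, "down", "none"))
    out = pd.DataFrame(
        {
            "mean_paired_diff": mean_diff,
            "s2": s2,
            "df_residual": df_residual,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "direction": direction,
        },
        index=index,
    )
    return out


def moderated_paired_t(
    m: pd.DataFrame,
    pairing: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test per gene.

    Posterior variance s~2 = (d0*s0_sq + df*s2_g) / (d0 + df); the statistic
    mean/(s~/sqrt(n)) is referred to a t distribution on d0 + df degrees of
    freedom (standard normal when d0 is infinite). Forcing ``d0=0`` recovers
    the ordinary paired t; forcing ``d0=inf`` applies full shrinkage to
    ``s0_sq``.

    Result carries the fitted hyperparameters in ``DataFrame.attrs``
    (``d0``, ``s0_sq``, ``n_pairs``).
    """
    diffs = paired_differences(m, pairing)
    n = diffs.shape[1]
    if n < 3:
        raise ValueError(f"moderated paired t requires >=3 pairs, got {n}")
    d = diffs.to_numpy()
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    df = n - 1
    if d0 is None:
        d0, fitted_s0 = fit_fdist_moments(s2, df)
        if s0_sq is None:
            s0_sq = fitted_s0
    elif s0_sq is None and d0 != 0:
        _, s0_sq = fit_fdist_moments(s2, df)
    if d0 == 0:
        post_var = s2.copy()
        df_total = float(df)
    elif math.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        post_var = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(post_var / n)
    t = np.where(np.isnan(t), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = _stats_frame(m.index, mean, s2, df, t, p)
    out.attrs.update(d0=d0, s0_sq=s0_sq, n_pairs=n)
    return out


def paired_t_plain(m: pd.DataFrame, pairing: pd.DataFrame) -> pd.DataFrame:
    """Classical paired t per gene, no shrinkage.

    Genes with missing values use complete pairs only, with per-gene degrees
    of freedom; genes with fewer than 2 complete pairs get NaN statistics and
    are flagged in the ``insufficient_pairs`` column.
    """
    diffs = paired_differences(m, pairing)
    if diffs.shape[1] < 2:
        raise ValueError(f"paired t requires >=2 pairs, got {diffs.shape[1]}")
    d = diffs.to_numpy()
    valid = ~np.isnan(d)
    n_g = valid.sum(axis=1)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # genes with <2 complete pairs produce all-NaN slices by design
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(valid, d, np.nan), axis=1)
        s2 = np.nanvar(np.where(valid, d, np.nan), axis=1, ddof=1)
    t = np.full(d.shape[0], np.nan)
    p = np.full(d.shape[0], np.nan)
    ok = n_g >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ok = mean[ok] / np.sqrt(s2[ok] / n_g[ok])
    t_ok = np.where(np.isnan(t_ok), 0.0, t_ok)
    p_ok = 2.0 * stats.t.sf(np.abs(t_ok), n_g[ok] - 1)
    # all-zero differences: s2=0 and mean=0 -> t=0, p=1; nonzero mean with
    # s2=0 -> infinite t, p collapses to the smallest positive float
    p_ok = np.where(np.isinf(t_ok), np.finfo(float).tiny, p_ok)
    t[ok], p[ok] = t_ok, np.clip(p_ok, np.finfo(float).tiny, 1.0)
    out = _stats_frame(m.index, mean, s2, np.where(ok, n_g - 1, 0), t, p)
    out["insufficient_pairs"] = ~ok
    out.attrs.update(d0=0.0, s0_sq=None, n_pairs=diffs.shape[1])
    return out


@dataclass(frozen=True)
class ChanceExpectation:
    n_tests: int
    alpha: float
    expected: int
    expected_raw: float


def expected_by_chance(n_tests: int, alpha: float) -> ChanceExpectation:
    """Number of tests expected significant at alpha under the global null."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    raw = n_tests * alpha
    return ChanceExpectation(n_tests, alpha, int(raw), raw)


def purity_adjusted_association(
    diffs: pd.DataFrame,
    purity: pd.Series,
    pairing: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene tumor-status association with sample purity as covariate.

    For each gene, ordinary least squares over stacked rows: each initial
    tumor contributes (expression 0, purity 0, status 0) and each
    recurrent/progressive tumor contributes (pair-centered expression,
    purity centered on its initial pair, status 1). The reported p is the
    two-sided t-test on the status coefficient; a purity column collinear
    with status (e.g. all-zero deviations) is dropped and flagged.
    """
    rec = list(pairing["recurrent_sample_id"])
    init = list(pairing["initial_sample_id"])
    missing = (set(rec) | set(init)) - set(purity.index)
    if missing:
        raise KeyError(f"purity scores missing for samples: {sorted(missing)}")
    n = len(rec)
    d = diffs[rec].to_numpy()
    purity_dev = purity[rec].to_numpy(dtype=float) - purity[init].to_numpy(dtype=float)
    status = np.concatenate([np.zeros(n), np.ones(n)])
    pur = np.concatenate([np.zeros(n), purity_dev])
    design = np.column_stack([np.ones(2 * n), status, pur])
    dropped_purity = np.linalg.matrix_rank(design) < 3
    if dropped_purity:
        design = design[:, :2]
    rank = design.shape[1]
    dof = 2 * n - rank
    xtx_inv = np.linalg.pinv(design.T @ design)
    hat = xtx_inv @ design.T
    rows = []
    for g in range(d.shape[0]):
        y = np.concatenate([np.zeros(n), d[g]])
        beta = hat @ y
        resid = y - design @ beta
        sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
        se = math.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
        tval = beta[1] / se if se > 0 else 0.0
        pval = 2.0 * stats.t.sf(abs(tval), dof) if dof > 0 else np.nan
        rows.append((beta[1], tval, pval))
    out = pd.DataFrame(rows, index=diffs.index, columns=["status_coef", "t", "p"])
    out["purity_dropped"] = dropped_purity
    out.attrs.update(df_residual=dof)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q
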