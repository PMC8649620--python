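"""Signature derivation, t-score cohort scoring, and survival association.

The recurrence/progression signature is the set of genes passing a paired
differential-expression threshold, split by direction of change. An
external, median-centered expression profile is scored by the t-score: the
pooled-variance two-sample t statistic contrasting the profile's values
over the signature-up genes against the signature-down genes — high when
the profile mirrors the signature in both directions.

Survival machinery: Kaplan-Meier product-limit curves, the (optionally
stratified) log-rank test, and a single-covariate Cox proportional-hazards
fit by Newton-Raphson on the partial likelihood with Breslow tie handling
(Efron available behind a flag). With strata, risk sets form within stratum
and contributions are summed, so the stratifying factor alone cannot drive
the association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "derive_signature",
    "median_center",
    "t_score",
    "score_cohort",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "per_gene_outcome_scan",
    "LogrankResult",
    "CoxResult",
]

VARIANCE_FLOOR = 1e-8  # degenerate zero-variance profiles get this pooled s2


@dataclass(frozen=True)
class Signature:
    up_genes: frozenset
    down_genes: frozenset
    alpha_used: float
    source: str = ""

    @property
    def genes(self) -> frozenset:
        return self.up_genes | self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def derive_signature(stats_table: pd.DataFrame, alpha: float, source: str = "") -> Signature:
    """Select signature genes at a significance threshold, split by direction.

    up = {p < alpha, effect > 0}; down = {p < alpha, effect < 0}. Genes with
    exactly zero effect are excluded from both sets.
    """
    sig = stats_table[stats_table["p"] < alpha]
    up = frozenset(sig.index[sig["mean_paired_diff"] > 0])
    down = frozenset(sig.index[sig["mean_paired_diff"] < 0])
    if not up and not down:
        raise ValueError(
            f"no genes pass p < {alpha}; increase alpha to obtain a signature"
        )
    return Signature(up, down, alpha, source)


def median_center(m: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's across-sample median (per-gene median becomes 0)."""
    if m.shape[1] < 1:
        raise ValueError("median centering requires at least one sample")
    return m.sub(m.median(axis=1), axis=0)


def t_score(profile: pd.Series, sig: Signature) -> float:
    """Pooled-variance two-sample t: up-gene values versus down-gene values.

    Requires at least two genes from each side present in the profile;
    returns NaN (with a log message) otherwise. Zero pooled variance gets a
    floor so perfectly signature-like profiles give a large finite score.
    """
    up = profile.reindex(sorted(sig.up_genes)).dropna()
    down = profile.reindex(sorted(sig.down_genes)).dropna()
    if len(up) < 2 or len(down) < 2:
        logger.warning(
            "t_score: insufficient signature coverage (%d up, %d down)", len(up), len(down)
        )
        return float("nan")
    n1, n2 = len(up), len(down)
    s2 = ((n1 - 1) * up.var(ddof=1) + (n2 - 1) * down.var(ddof=1)) / (n1 + n2 - 2)
    s2 = max(float(s2), VARIANCE_FLOOR)
    return float((up.mean() - down.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2)))


def score_cohort(m: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """t-score every sample of a median-centered matrix and bin into tertiles.

    Tertiles partition the scored samples into thirds by score rank (sizes
    differ by at most one; remainders go to the lower bins; ties broken by
    stable sample order). Samples without a score keep an empty tertile.
    """
    covered = len(sig.up_genes & set(m.index)), len(sig.down_genes & set(m.index))
    logger.info("signature coverage in matrix: %d up, %d down", *covered)
    scores = pd.Series(
        [t_score(m[s], sig) for s in m.columns], index=m.columns, name="t_score"
    )
    tertile = pd.Series("", index=m.columns, name="tertile", dtype=object)
    scored = scores.dropna()
    order = scored.sort_values(kind="stable").index
    n = len(order)
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    labels = ["low"] * sizes[0] + ["mid"] * sizes[1] + ["high"] * sizes[2]
    tertile[order] = labels
    return pd.DataFrame({"t_score": scores, "tertile": tertile})


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a table (time, at_risk, events, survival) with one row per
    distinct event time; censoring at an event time is handled after the
    events (standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    return out[out["events"] > 0].reset_index(drop=True) if (events == 1).any() else out


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)


def _logrank_moments(times, events, groups, labels):
    """Per-stratum observed, expected, and covariance of the log-rank vector."""
    g = len(labels)
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    member = np.stack([groups == lab for lab in labels])  # g x n
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        died = (times == t) & (events == 1)
        d_t = int(died.sum())
        if n_t == 0 or d_t == 0:
            continue
        n_j = member[:, at_risk].sum(axis=1).astype(float)
        d_j = member[:, died].sum(axis=1).astype(float)
        observed += d_j
        expected += d_t * n_j / n_t
        if n_t > 1:
            frac = n_j / n_t
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))
    return observed, expected, cov


def logrank_test(times, events, group, strata=None) -> LogrankResult:
    """Multi-group log-rank test, optionally stratified.

    Observed-minus-expected event counts and their covariance are summed
    over event times (within each stratum when stratified), and the
    chi-square statistic is formed on the first g-1 groups. No events at
    all yields p = 1 with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = list(pd.unique(group))
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two groups")
    strata_arr = (
        np.zeros(times.size) if strata is None else np.asarray(strata)
    )
    g = len(labels)
    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    any_contrast = False
    for s in pd.unique(strata_arr):
        mask = strata_arr == s
        if len(pd.unique(group[mask])) > 1:
            any_contrast = True
        o, e, c = _logrank_moments(times[mask], events[mask], group[mask], labels)
        observed += o
        expected += e
        cov += c
    if not any_contrast:
        raise ValueError("every stratum contains a single group; no contrast remains")
    if events.sum() == 0:
        logger.warning("log-rank: no events observed; p = 1")
        return LogrankResult(0.0, g - 1, 1.0)
    z = (observed - expected)[: g - 1]
    v = cov[: g - 1, : g - 1]
    chi2 = float(z @ np.linalg.pinv(v) @ z)
    p = float(stats.chi2.sf(chi2, g - 1))
    return LogrankResult(
        chi2,
        g - 1,
        p,
        dict(zip(map(str, labels), observed)),
        dict(zip(map(str, labels), expected)),
    )


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    se: float
    p_wald: float
    score_chi2: float
    score_p: float
    n_events: int
    converged: bool
    separation_flag: bool


def _cox_derivatives(beta, x, times, events, strata, ties):
    """Log partial likelihood, gradient and information for one covariate."""
    loglik = 0.0
    grad = 0.0
    info = 0.0
    for s in pd.unique(strata):
        m = strata == s
        xs, ts, es = x[m], times[m], events[m]
        order = np.argsort(-ts, kind="stable")
        xs, ts, es = xs[order], ts[order], es[order]
        eta = beta * xs
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        for t in np.unique(ts[es == 1]):
            died = (ts == t) & (es == 1)
            d = int(died.sum())
            idx = np.searchsorted(-ts, -t, side="right") - 1  # last index with ts >= t
            S0, S1, S2 = s0[idx], s1[idx], s2[idx]
            xsum = xs[died].sum()
            esum = eta[died].sum()
            if ties == "breslow" or d == 1:
                loglik += esum - d * math.log(S0)
                grad += xsum - d * (S1 / S0)
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            else:  # efron
                wd = w[died]
                D0, D1, D2 = wd.sum(), (wd * xs[died]).sum(), (wd * xs[died] ** 2).sum()
                loglik += esum
                for r in range(d):
                    f = r / d
                    a0 = S0 - f * D0
                    a1 = S1 - f * D1
                    a2 = S2 - f * D2
                    loglik -= math.log(a0)
                    grad += xsum / d - a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
    return loglik, grad, info


def cox_fit(
    covariate,
    times,
    events,
    strata=None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    Newton-Raphson on the partial likelihood; Breslow tie handling by
    default, Efron behind ``ties='efron'``. With strata, risk sets form
    within stratum and log-likelihood contributions are summed. Also
    reports the score test at beta = 0, which for a binary covariate
    without ties equals the log-rank chi-square.
    """
    x = np.asarray(covariate, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    if events.sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; no association estimable")
    strata_arr = np.zeros(x.size) if strata is None else np.asarray(strata)

    _, u0, i0 = _cox_derivatives(0.0, x, times, events, strata_arr, ties)
    score_chi2 = u0 * u0 / i0 if i0 > 0 else 0.0
    score_p = float(stats.chi2.sf(score_chi2, 1))

    beta = 0.0
    converged = False
    separation = False
    for _ in range(max_iter):
        _, grad, info = _cox_derivatives(beta, x, times, events, strata_arr, ties)
        if info <= 0:
            separation = True
            break
        step = grad / info
        beta += step
        if abs(beta) > 50:
            separation = True
            break
        if abs(step) < tol:
            converged = True
            break
    if separation:
        raise FloatingPointError(
            "monotone partial likelihood (perfect separation or degenerate risk "
            f"sets); |beta| diverged at {beta:.3g}"
        )
    if not converged:
        raise RuntimeError(f"Cox Newton-Raphson did not converge in {max_iter} iterations")
    _, _, info = _cox_derivatives(beta, x, times, events, strata_arr, ties)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    return CoxResult(
        beta=float(beta),
        hr=float(math.exp(beta)),
        se=float(se),
        p_wald=float(2 * stats.norm.sf(abs(z))),
        score_chi2=float(score_chi2),
        score_p=score_p,
        n_events=int(events.sum()),
        converged=True,
        separation_flag=False,
    )


def per_gene_outcome_scan(
    m: pd.DataFrame,
    clinical: pd.DataFrame,
    genes,
    strata_col: str | None = "histology",
    sig: Signature | None = None,
) -> pd.DataFrame:
    """Stratified Cox scan of individual genes as continuous covariates.

    ``clinical`` must be indexed by sample id with ``os_time``/``os_event``
    columns. Per-gene fit failures are recorded, not raised. When a
    signature is supplied, a consistency flag marks genes whose Cox beta
    sign matches their signature direction (up genes hazardous, down genes
    protective).
    """
    genes = list(genes)
    if not genes:
        return pd.DataFrame(columns=["beta", "p", "error"], index=pd.Index([], name="gene"))
    samples = [s for s in m.columns if s in clinical.index]
    cl = clinical.loc[samples]
    times = cl["os_time"].to_numpy(dtype=float)
    events = cl["os_event"].to_numpy(dtype=int)
    strata = cl[strata_col].to_numpy() if strata_col else None
    rows = []
    for gene in genes:
        if gene not in m.index:
            rows.append({"gene": gene, "beta": np.nan, "p": np.nan, "error": "absent"})
            continue
        try:
            fit = cox_fit(m.loc[gene, samples].to_numpy(), times, events, strata)
            rows.append({"gene": gene, "beta": fit.beta, "p": fit.p_wald, "error": ""})
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            rows.append({"gene": gene, "beta": np.nan, "p": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows).set_index("gene")
    if sig is not None:
        direction = pd.Series(
            {g: 1.0 for g in sig.up_genes} | {g: -1.0 for g in sig.down_genes}
        )
        out["consistent"] = np.sign(out["beta"]) == direction.reindex(out.index)
    return out
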