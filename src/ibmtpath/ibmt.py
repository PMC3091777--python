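"""Intensity-based empirical-Bayes moderated t-statistics for two-group contrasts.

Per-gene variance estimates from 3-4 subject pairs are too noisy to support a
classical t-test.  The empirical-Bayes remedy places a scaled-inverse-chi-square
prior on the gene-wise variance, sigma_g^2 ~ d0 * s0_g^2 / chi^2(d0), and
replaces the observed residual variance s_g^2 by the posterior mean

    s~_g^2 = (d0 * s0_g^2 + d_g * s_g^2) / (d0 + d_g),

giving a t-statistic with d0 + d_g degrees of freedom.  The intensity-based
variant lets the prior scale s0^2 depend on the gene's mean log2 intensity
a_g: low-intensity probes are systematically noisier, so the prior follows a
smooth (lowess) trend of the bias-corrected log residual variance on a_g.
Hyperparameters are estimated by method of moments on

    e_g = ln s_g^2 - psi(d_g/2) + ln(d_g/2),

whose residual spread around the fitted trend determines d0 through the
trigamma identity  psi'(d0/2) = E[r^2] - mean psi'(d_g/2).

d0 = 0 recovers the ordinary t exactly; d0 = +inf pools fully to the trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .study_model import Comparison, ConsistencyError, ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "EBHyper",
    "InsufficientReplicationError",
    "fit_gene_stats",
    "estimate_eb_hyperparameters",
    "moderated_test",
    "bh_fdr",
]

#: columns of the per-gene statistics frame produced by :func:`fit_gene_stats`
GENE_STAT_COLUMNS = ("b", "u", "s2", "d", "a", "sign")


class InsufficientReplicationError(ConsistencyError):
    """Residual degrees of freedom < 1 after sample selection."""


def fit_gene_stats(study: ExpressionStudy, comparison: Comparison) -> pd.DataFrame:
    """Per-gene contrast estimates for one comparison.

    Returns a frame indexed by probe id with columns

    * ``b`` — contrast estimate (log2 fold change, case minus reference);
    * ``u`` — unscaled standard error (design multiplier: 1/sqrt(n) paired,
      sqrt(1/n1 + 1/n2) unpaired);
    * ``s2`` — residual variance (of paired differences, or pooled);
    * ``d`` — residual degrees of freedom;
    * ``a`` — mean log2 intensity over all samples in the comparison;
    * ``sign`` — sign of ``b`` (+1, 0, -1).
    """
    values = study.values
    if comparison.mode == "paired":
        pairs = comparison.paired_samples(study)
        n = len(pairs)
        if n - 1 < 1:
            raise InsufficientReplicationError(
                f"comparison {comparison.name!r}: insufficient replication "
                f"({n} pair(s), need >=2)"
            )
        comparison.select(study)  # validates selector disjointness
        case_cols = [c for c, _ in pairs]
        ref_cols = [r for _, r in pairs]
        diffs = values[case_cols].to_numpy() - values[ref_cols].to_numpy()
        b = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        d = float(n - 1)
        u = 1.0 / np.sqrt(n)
        used = case_cols + ref_cols
    else:
        case, ref = comparison.select(study)
        n1, n2 = len(case), len(ref)
        if n1 + n2 - 2 < 1:
            raise InsufficientReplicationError(
                f"comparison {comparison.name!r}: insufficient replication"
            )
        x1 = values[case].to_numpy()
        x2 = values[ref].to_numpy()
        b = x1.mean(axis=1) - x2.mean(axis=1)
        ss1 = x1.var(axis=1, ddof=1) * (n1 - 1) if n1 > 1 else np.zeros(len(values))
        ss2 = x2.var(axis=1, ddof=1) * (n2 - 1) if n2 > 1 else np.zeros(len(values))
        d = float(n1 + n2 - 2)
        s2 = (ss1 + ss2) / d
        u = np.sqrt(1.0 / n1 + 1.0 / n2)
        used = list(case) + list(ref)
    a = values[used].to_numpy().mean(axis=1)
    return pd.DataFrame(
        {
            "b": b,
            "u": np.full(len(values), u),
            "s2": s2,
            "d": np.full(len(values), d),
            "a": a,
            "sign": np.sign(b),
        },
        index=values.index,
    )


@dataclass
class EBHyper:
    """Empirical-Bayes hyperparameters: prior df and intensity-dependent prior scale.

    ``d0`` may be ``0.0`` (no shrinkage, forced externally), finite, or
    ``np.inf`` (full shrinkage to the trend).  ``s0_sq`` holds the per-probe
    prior variance s0^2(a_g); ``trend`` the fitted log-scale trend e^(a_g).
    """

    d0: float
    s0_sq: pd.Series
    span: float
    trend: pd.Series | None = None

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (possibly +inf)")
        if (np.asarray(self.s0_sq, dtype=float) <= 0).any():
            raise ValueError("prior variances must be positive")


def estimate_eb_hyperparameters(
    stats_df: pd.DataFrame,
    span: float = 0.75,
    min_probes: int = 100,
) -> EBHyper:
    """Method-of-moments fit of (d0, s0^2(a)) from per-gene residual variances.

    The trend is a lowess fit (fraction ``span``) of the bias-corrected log
    variance e_g on mean intensity a_g.  Probes with s2 == 0 are excluded
    from the fit but still receive a prior variance by interpolating the
    trend at their intensity.  d0 solves psi'(d0/2) = E[r^2]*m/(m-1) -
    mean psi'(d_g/2) by monotone root finding on [0.01, 1e6]; a non-positive
    right-hand side (residual spread no larger than sampling noise) yields
    d0 = +inf.
    """
    s2 = stats_df["s2"].to_numpy(dtype=float)
    d = stats_df["d"].to_numpy(dtype=float)
    a = stats_df["a"].to_numpy(dtype=float)
    ok = s2 > 0
    m = int(ok.sum())
    if m < min_probes:
        raise ValueError(
            f"need >= {min_probes} probes with positive residual variance, have {m}"
        )
    e = np.log(s2[ok]) - special.digamma(d[ok] / 2.0) + np.log(d[ok] / 2.0)
    a_ok = a[ok]
    delta = 0.01 * (a_ok.max() - a_ok.min())
    e_hat_ok = lowess(e, a_ok, frac=span, delta=delta, return_sorted=False)
    r = e - e_hat_ok

    e_hat = np.empty_like(a)
    e_hat[ok] = e_hat_ok
    if (~ok).any():
        order = np.argsort(a_ok, kind="stable")
        e_hat[~ok] = np.interp(a[~ok], a_ok[order], e_hat_ok[order])

    rhs = np.mean(r ** 2) * m / (m - 1) - np.mean(special.polygamma(1, d[ok] / 2.0))
    if rhs <= 0:
        d0 = np.inf
    else:
        lo, hi = 1e-2, 1e6
        f = lambda d0_: special.polygamma(1, d0_ / 2.0) - rhs
        if f(hi) > 0:          # rhs below trigamma(5e5): effectively infinite
            d0 = np.inf
        elif f(lo) < 0:        # rhs above trigamma(0.005): clamp at the floor
            d0 = lo
        else:
            d0 = optimize.brentq(f, lo, hi, xtol=1e-8)
    if np.isinf(d0):
        s0_sq = np.exp(e_hat)
    else:
        s0_sq = np.exp(e_hat + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    logger.info("estimated d0=%s over %d probes (span=%.3g)", d0, m, span)
    return EBHyper(
        d0=float(d0),
        s0_sq=pd.Series(s0_sq, index=stats_df.index, name="s0_sq"),
        span=span,
        trend=pd.Series(e_hat, index=stats_df.index, name="trend"),
    )


def moderated_test(stats_df: pd.DataFrame, hyper: EBHyper) -> pd.DataFrame:
    """Moderated t-test of b = 0 per gene under the fitted variance prior.

    Returns a frame with ``s2_post`` (posterior variance), ``t`` (moderated
    t-statistic), ``df``, ``p`` (two-sided), ``q`` (Benjamini-Hochberg over
    all probes with a defined p), and ``ok`` (False where the posterior
    variance degenerates to 0 and no p-value is defined).
    """
    b = stats_df["b"].to_numpy(dtype=float)
    u = stats_df["u"].to_numpy(dtype=float)
    s2 = stats_df["s2"].to_numpy(dtype=float)
    d = stats_df["d"].to_numpy(dtype=float)
    s0 = hyper.s0_sq.loc[stats_df.index].to_numpy(dtype=float)
    d0 = hyper.d0

    if np.isinf(d0):
        s2_post = s0.copy()
        df = np.full(len(b), np.inf)
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df = d0 + d

    ok = s2_post > 0
    t = np.full(len(b), np.nan)
    p = np.full(len(b), np.nan)
    t[ok] = b[ok] / (u[ok] * np.sqrt(s2_post[ok]))
    if np.isinf(d0):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), np.broadcast_to(df, t.shape)[ok])
    np.clip(p, np.nextafter(0, 1), 1.0, out=p)

    q = np.full(len(b), np.nan)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    out = pd.DataFrame(
        {
            "s2_post": s2_post,
            "t": t,
            "df": np.broadcast_to(df, t.shape),
            "p": p,
            "q": q,
            "ok": ok,
        },
        index=stats_df.index,
    )
    if (~ok).any():
        logger.warning("%d probe(s) with zero posterior variance flagged (no p-value)",
                       int((~ok).sum()))
    return out


def bh_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, with stable tie order.
    ``m`` defaults to len(p) (the number of tests in the family); passing a
    larger m supports testing a subset of a declared family.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    if m is None:
        m = n
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(q_sorted, 1.0)
    return out
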