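"""Per-gene two-group linear models with empirical-Bayes moderated t-statistics.

The study design compares, within each tissue, three condition pairs:

* ``cx_vs_sham`` — castrated versus sham-operated,
* ``T_vs_cx``   — testosterone-treated castrated versus castrated,
* ``F_vs_cx``   — follistatin-treated castrated versus castrated.

Each gene's contrast is an ordinary two-group fit (mean difference,
pooled within-group variance). Residual variances are shrunk toward a
scaled inverse-chi-square prior whose hyperparameters (d0, s0^2) are
estimated by moment matching on log s^2 (digamma/trigamma matching),
giving the moderated t

    t~ = beta / (u * sqrt(s~^2)),   s~^2 = (d0 s0^2 + d s^2) / (d0 + d)

on d0 + d degrees of freedom. Multiplicity is handled by the
Benjamini-Hochberg step-up adjustment; the adjusted p is reported as the
q-value. Tissues are never pooled: every fit is computed per tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import ExpressionMatrix

__all__ = [
    "COMPARISONS",
    "LinearFit",
    "ModerationParams",
    "fit_per_gene",
    "estimate_moderation",
    "moderated_t",
    "bh_adjust",
    "run_comparison",
    "run_all_comparisons",
]

# comparison label -> (test condition, reference condition);
# log2FC is mean(test) - mean(reference)
COMPARISONS = {
    "cx_vs_sham": ("cx", "sham"),
    "T_vs_cx": ("cx_T", "cx"),
    "F_vs_cx": ("cx_F", "cx"),
}


@dataclass
class LinearFit:
    """Two-group fit per gene: estimate, pooled variance, scale, residual df."""

    comparison: str
    tissue: str
    table: pd.DataFrame  # index gene; columns beta, s2, u, df


@dataclass(frozen=True)
class ModerationParams:
    s2_0: float          # prior variance
    d0: float            # prior degrees of freedom; may be math.inf

    def __post_init__(self) -> None:
        if not self.s2_0 > 0:
            raise ValueError("prior variance must be positive")
        if self.d0 < 0:
            raise ValueError("prior df must be non-negative")


def fit_per_gene(expr: ExpressionMatrix, comparison: str, tissue: str) -> LinearFit:
    """Two-group linear fit for one comparison within one tissue.

    beta is the mean log2 difference (test minus reference), s2 the pooled
    within-group variance, u = sqrt(1/n1 + 1/n2) the unscaled standard
    deviation of beta, and df = n1 + n2 - 2.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    test_cond, ref_cond = COMPARISONS[comparison]
    sub = expr.subset_tissue(tissue)
    meta = sub.samples
    cols_test = meta.index[meta["condition"] == test_cond]
    cols_ref = meta.index[meta["condition"] == ref_cond]
    n1, n2 = len(cols_test), len(cols_ref)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"comparison {comparison!r} in tissue {tissue!r} needs >=2 replicates "
            f"per condition (got {n1} and {n2})"
        )
    a = sub.values[cols_test].to_numpy(dtype=float)
    b = sub.values[cols_ref].to_numpy(dtype=float)
    beta = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    u = math.sqrt(1.0 / n1 + 1.0 / n2)
    table = pd.DataFrame(
        {"beta": beta, "s2": s2, "u": u, "df": float(df)}, index=sub.values.index
    )
    return LinearFit(comparison, tissue, table)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return x


def estimate_moderation(fits: LinearFit) -> ModerationParams:
    """Fit the scaled inverse-chi-square prior to the observed variances.

    Moment matching on z = log s^2: with e = z - digamma(d/2) + log(d/2),
    E[e] = log s0^2 - digamma(d0/2) + log(d0/2) and
    Var[e] = trigamma(d/2) + trigamma(d0/2), so d0 solves
    trigamma(d0/2) = Var[e] - trigamma(d/2). When the sample spread of e
    implies a non-positive prior trigamma the prior df is infinite.

    Genes with no residual df or zero variance carry no information and
    are excluded from the estimation.
    """
    tab = fits.table
    use = (tab["df"] >= 1) & (tab["s2"] > 0)
    s2 = tab.loc[use, "s2"].to_numpy(dtype=float)
    d = tab.loc[use, "df"].to_numpy(dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 genes with positive variance")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    if np.ptp(z) == 0.0:
        # all sample variances identical: no evidence of gene-to-gene spread
        return ModerationParams(s2_0=float(s2[0]), d0=math.inf)
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar <= 0:
        return ModerationParams(s2_0=float(math.exp(emean)), d0=math.inf)
    d0 = 2.0 * _trigamma_inverse(evar)
    s2_0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return ModerationParams(s2_0=s2_0, d0=d0)


def moderated_t(fits: LinearFit, params: ModerationParams) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values for one comparison.

    Posterior variance s~^2 = (d0 s0^2 + d s^2)/(d0 + d); the statistic is
    referred to a t-distribution on d0 + d df, or the standard normal when
    d0 is infinite (full shrinkage). d0 = 0 recovers the ordinary t-test.
    """
    tab = fits.table
    beta = tab["beta"].to_numpy(dtype=float)
    s2 = tab["s2"].to_numpy(dtype=float)
    u = tab["u"].to_numpy(dtype=float)
    d = tab["df"].to_numpy(dtype=float)
    if np.any(u <= 0):
        raise ValueError("unscaled standard deviation u must be positive")
    if math.isinf(params.d0):
        s2_post = np.full_like(s2, params.s2_0)
        t = beta / (u * np.sqrt(s2_post))
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_post = (params.d0 * params.s2_0 + d * s2) / (params.d0 + d)
        t = beta / (u * np.sqrt(s2_post))
        p = 2.0 * stats.t.sf(np.abs(t), params.d0 + d)
    out = pd.DataFrame(
        {"log2fc": beta, "t_mod": t, "p": p}, index=tab.index
    )
    out.attrs["comparison"] = fits.comparison
    out.attrs["tissue"] = fits.tissue
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} p_(j) * n / j, capped at 1, evaluating each term as
    (p * n) / j so results agree bit-for-bit with the textbook step-up.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def run_comparison(
    expr: ExpressionMatrix, comparison: str, tissue: str,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Fit -> moderate -> adjust for one tissue x comparison.

    Hyperparameters are estimated from this comparison's own variances
    unless supplied. Returns gene-indexed columns log2fc, t_mod, p, q.
    """
    fits = fit_per_gene(expr, comparison, tissue)
    if params is None:
        params = estimate_moderation(fits)
    res = moderated_t(fits, params)
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def run_all_comparisons(expr: ExpressionMatrix, tissue: str) -> dict:
    """All three condition contrasts for one tissue."""
    return {c: run_comparison(expr, c, tissue) for c in COMPARISONS}
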