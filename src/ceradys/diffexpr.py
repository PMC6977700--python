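"""Two-group differential expression on log2 data.

The default test is a moderated t-statistic: per-gene pooled variances are
shrunk toward an empirical-Bayes prior fitted across all genes (scaled
inverse-chi-square, moment-matched on the log variances), which stabilizes
small-sample inference. A plain Welch unequal-variance t-test is available
as a fallback. log2 fold change is mean(group2) - mean(group1) on the
already-log2 data. Raw p < alpha calls a gene significantly differentially
expressed (SDE); no multiple-testing correction gates the call, though a
Benjamini-Hochberg FDR column is reported for information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_model import ExpressionMatrix

P_FLOOR = 1e-300  # p-value floor applied before any -log10

DE_METHODS = ("moderated", "welch")


@dataclass
class DifferentialResult:
    gene_id: str
    log2fc: float
    p_value: float
    fdr: float
    is_sde: bool
    direction: str  # up | down | flat


def _check_groups(expr: ExpressionMatrix, group1: Sequence[str], group2: Sequence[str]) -> None:
    s1, s2 = set(group1), set(group2)
    if s1 & s2:
        raise ValueError(f"groups overlap: {sorted(s1 & s2)[:5]}")
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples")
    known = set(expr.sample_ids)
    missing = (s1 | s2) - known
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)[:5]}")


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-gene variances toward a fitted scaled-inv-chi2 prior.

    Moment-matches the distribution of log(s2): with true residual df d,
    e_g = log(s2_g) - digamma(d/2) + log(d/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2), from
    which prior df d0 and prior variance s0^2 are solved. Returns the
    posterior variances (d0*s0^2 + d*s2)/(d0 + d) and d0.
    """
    s2 = np.maximum(s2, 1e-30)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 1e-10 or len(s2) < 2:
        # no between-gene dispersion beyond sampling noise: infinite prior df
        s0_2 = math.exp(e_mean)
        return np.full_like(s2, s0_2), math.inf

    def trigamma_gap(x: float) -> float:
        return float(special.polygamma(1, x / 2.0)) - e_var

    # trigamma is decreasing; bracket the root of trigamma(d0/2) = e_var
    lo, hi = 1e-6, 1e8
    if trigamma_gap(hi) > 0:
        d0 = math.inf
    elif trigamma_gap(lo) < 0:
        d0 = lo
    else:
        d0 = optimize.brentq(trigamma_gap, lo, hi, xtol=1e-10)
    if not math.isfinite(d0):
        s0_2 = math.exp(e_mean)
        return np.full_like(s2, s0_2), math.inf
    s0_2 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def differential_expression(
    expr: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    method: str = "moderated",
    sde_alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-gene two-group differential expression.

    ``group1`` is the reference state (e.g. control), ``group2`` the
    comparison state; log2fc = mean(group2) - mean(group1).
    """
    if method not in DE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {DE_METHODS}")
    _check_groups(expr, group1, group2)
    x1 = expr.subset_samples(list(group1)).values
    x2 = expr.subset_samples(list(group2)).values
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m2 - m1
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    if method == "welch":
        se2 = v1 / n1 + v2 / n2
        se2 = np.maximum(se2, 1e-30)
        t = log2fc / np.sqrt(se2)
        # Welch-Satterthwaite degrees of freedom
        num = se2**2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        dfree = np.where(den > 0, num / np.maximum(den, 1e-300), n1 + n2 - 2)
        p = 2.0 * stats.t.sf(np.abs(t), dfree)
    else:
        dfree0 = n1 + n2 - 2
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / dfree0
        post, d0 = _squeeze_var(pooled, float(dfree0))
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
        t = log2fc / np.maximum(se, 1e-30)
        total_df = dfree0 if math.isinf(d0) else dfree0 + d0
        if math.isinf(total_df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), total_df)

    p = np.clip(p, P_FLOOR, 1.0)
    fdr = _bh_fdr(p)
    results = []
    for gid, fc, pv, q in zip(expr.gene_ids, log2fc, p, fdr):
        direction = "up" if fc > 0 else ("down" if fc < 0 else "flat")
        results.append(
            DifferentialResult(
                gene_id=gid,
                log2fc=float(fc),
                p_value=float(pv),
                fdr=float(q),
                is_sde=bool(pv < sde_alpha),
                direction=direction,
            )
        )
    return results


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def sde_direction_summary(results: Sequence[DifferentialResult]) -> dict[str, float]:
    """Percentages (0-100 scale) of SDE genes and of up/down among SDE."""
    if not results:
        raise ValueError("empty result list")
    n = len(results)
    sde = [r for r in results if r.is_sde]
    pct_sde = 100.0 * len(sde) / n
    if sde:
        pct_up = 100.0 * sum(r.direction == "up" for r in sde) / len(sde)
        pct_down = 100.0 * sum(r.direction == "down" for r in sde) / len(sde)
    else:
        pct_up = pct_down = 0.0
    return {"pct_sde": pct_sde, "pct_up_among_sde": pct_up, "pct_down_among_sde": pct_down}


def always_sde_genes(
    expr: ExpressionMatrix,
    ordered_groups: Sequence[Sequence[str]],
    method: str = "moderated",
    sde_alpha: float = 0.05,
) -> set[str]:
    """Genes SDE in every adjacent-group comparison along a stage ordering."""
    if len(ordered_groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    survivors: Optional[set[str]] = None
    for g1, g2 in zip(ordered_groups[:-1], ordered_groups[1:]):
        res = differential_expression(expr, g1, g2, method=method, sde_alpha=sde_alpha)
        sde = {r.gene_id for r in res if r.is_sde}
        survivors = sde if survivors is None else survivors & sde
        if not survivors:
            return set()
    assert survivors is not None
    return survivors


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "is_sde": r.is_sde,
                "direction": r.direction,
            }
            for r in results
        ]
    )
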