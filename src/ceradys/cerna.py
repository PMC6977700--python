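"""Candidate ceRNA triplet discovery in the reference (control) state.

A candidate lncRNA-miRNA-mRNA competing triplet requires:

1. the mRNA and lncRNA share a significant number of targeting miRNAs
   (one-sided hypergeometric test, p < ``hyper_alpha``);
2. for a shared miRNA, the miRNA is negatively correlated with both the
   mRNA and the lncRNA, and the lncRNA-mRNA pair is positively correlated,
   all at p < ``corr_alpha`` in reference samples (Pearson, exact
   t-transform p-values);
3. within each link class (miRNA-mRNA, miRNA-lncRNA, lncRNA-mRNA), only
   pairs whose |r| reaches the ``percentile_cut`` percentile of |r| among
   all sign- and significance-valid pairs of that class are retained; a
   triplet survives only if all three of its links survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, InteractionSet

logger = logging.getLogger("ceradys")


@dataclass
class CandidateConfig:
    hyper_alpha: float = 0.05
    corr_alpha: float = 0.05
    percentile_cut: float = 90.0
    #: restrict the hypergeometric universe to miRNAs present in the
    #: miRNA expression matrix (in addition to having >= 1 interaction)
    restrict_to_expressed: bool = True

    def __post_init__(self) -> None:
        for name in ("hyper_alpha", "corr_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0,1), got {a}")
        if not 0 <= self.percentile_cut < 100:
            raise ValueError(f"percentile_cut must lie in [0,100), got {self.percentile_cut}")


@dataclass
class CandidateTriplet:
    lncrna: str
    mirna: str
    mrna: str
    shared_mirna_count: int
    hypergeom_p: float
    r_mi_m: float
    r_mi_l: float
    r_l_m: float
    p_mi_m: float
    p_mi_l: float
    p_l_m: float

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def shared_mirna_test(
    mrna: str,
    lncrna: str,
    interactions: InteractionSet,
    universe: Optional[set[str]] = None,
) -> tuple[int, float]:
    """Hypergeometric test for shared miRNA regulators of an mRNA/lncRNA pair.

    Universe N defaults to all distinct miRNAs with at least one
    interaction of either kind; K = miRNAs targeting the mRNA, n = miRNAs
    targeting the lncRNA, k = shared. Returns (k, P(X >= k)).
    """
    if universe is None:
        universe = interactions.mirnas()
    mir_m = interactions.mirnas_targeting_mrna(mrna) & universe
    mir_l = interactions.mirnas_targeting_lncrna(lncrna) & universe
    if not mir_m:
        raise ValueError(f"mRNA {mrna!r} is not a target of any miRNA in the universe")
    if not mir_l:
        raise ValueError(f"lncRNA {lncrna!r} is not a target of any miRNA in the universe")
    k = len(mir_m & mir_l)
    N, K, n = len(universe), len(mir_m), len(mir_l)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


class _CorrCache:
    """Memoized Pearson (r, p) between rows of two expression matrices."""

    def __init__(self, a: ExpressionMatrix, b: ExpressionMatrix):
        self.a, self.b = a, b
        self._cache: dict[tuple[str, str], tuple[float, float]] = {}

    def get(self, gene_a: str, gene_b: str) -> tuple[float, float]:
        key = (gene_a, gene_b)
        if key not in self._cache:
            self._cache[key] = correlation_with_p(self.a.row(gene_a), self.b.row(gene_b))
        return self._cache[key]


def find_candidates(
    mrna_expr: ExpressionMatrix,
    lncrna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    interactions: InteractionSet,
    config: Optional[CandidateConfig] = None,
) -> list[CandidateTriplet]:
    """Enumerate candidate triplets from reference-state matrices.

    All three matrices must carry identical sample ids (reference samples).
    Output order is (lncRNA, miRNA, mRNA) lexicographic, independent of
    enumeration order.
    """
    config = config or CandidateConfig()
    if not (mrna_expr.sample_ids == lncrna_expr.sample_ids == mirna_expr.sample_ids):
        raise ValueError("reference sample ids must be identical across the three matrices")
    if not interactions.mirna_to_mrna or not interactions.mirna_to_lncrna:
        raise ValueError("interaction maps must be non-empty")

    inter = interactions.restrict_to(
        mirnas=set(mirna_expr.gene_ids) if config.restrict_to_expressed else None,
        mrnas=set(mrna_expr.gene_ids),
        lncrnas=set(lncrna_expr.gene_ids),
    )
    universe = inter.mirnas()
    if not universe:
        raise ValueError("no miRNA is both expressed and present in the interaction maps")

    # pairs of (mRNA, lncRNA) sharing >= 1 miRNA, with their shared miRNAs
    shared: dict[tuple[str, str], set[str]] = {}
    for mirna in sorted(universe):
        for mrna in inter.mirna_to_mrna.get(mirna, ()):
            for lnc in inter.mirna_to_lncrna.get(mirna, ()):
                shared.setdefault((mrna, lnc), set()).add(mirna)

    cc_mi_m = _CorrCache(mirna_expr, mrna_expr)
    cc_mi_l = _CorrCache(mirna_expr, lncrna_expr)
    cc_l_m = _CorrCache(lncrna_expr, mrna_expr)

    raw: list[CandidateTriplet] = []
    for (mrna, lnc), mirnas in shared.items():
        k, p_hyper = shared_mirna_test(mrna, lnc, inter, universe)
        if p_hyper >= config.hyper_alpha:
            continue
        for mirna in mirnas:
            r_mm, p_mm = cc_mi_m.get(mirna, mrna)
            if not (r_mm < 0 and p_mm < config.corr_alpha):
                continue
            r_ml, p_ml = cc_mi_l.get(mirna, lnc)
            if not (r_ml < 0 and p_ml < config.corr_alpha):
                continue
            r_lm, p_lm = cc_l_m.get(lnc, mrna)
            if not (r_lm > 0 and p_lm < config.corr_alpha):
                continue
            raw.append(
                CandidateTriplet(
                    lncrna=lnc, mirna=mirna, mrna=mrna,
                    shared_mirna_count=k, hypergeom_p=p_hyper,
                    r_mi_m=r_mm, r_mi_l=r_ml, r_l_m=r_lm,
                    p_mi_m=p_mm, p_mi_l=p_ml, p_l_m=p_lm,
                )
            )

    if not raw:
        return []

    # percentile retention per link class on |r| over distinct valid pairs
    def _threshold(values: dict[tuple[str, str], float]) -> float:
        return float(np.percentile(list(values.values()), config.percentile_cut))

    pairs_mi_m = {(t.mirna, t.mrna): abs(t.r_mi_m) for t in raw}
    pairs_mi_l = {(t.mirna, t.lncrna): abs(t.r_mi_l) for t in raw}
    pairs_l_m = {(t.lncrna, t.mrna): abs(t.r_l_m) for t in raw}
    thr_mm = _threshold(pairs_mi_m)
    thr_ml = _threshold(pairs_mi_l)
    thr_lm = _threshold(pairs_l_m)

    kept = [
        t for t in raw
        if abs(t.r_mi_m) >= thr_mm
        and abs(t.r_mi_l) >= thr_ml
        and abs(t.r_l_m) >= thr_lm
    ]
    kept.sort(key=lambda t: (t.lncrna, t.mirna, t.mrna))
    logger.info(
        "candidates: %d pairs sharing miRNAs -> %d sign/significance-valid "
        "triplets -> %d after %gth-percentile retention",
        len(shared), len(raw), len(kept), config.percentile_cut,
    )
    return kept


def candidates_to_frame(triplets: Sequence[CandidateTriplet]) -> pd.DataFrame:
    cols = [
        "lncrna", "mirna", "mrna", "shared_mirna_count", "hypergeom_p",
        "r_mi_m", "r_mi_l", "r_l_m", "p_mi_m", "p_mi_l", "p_l_m",
    ]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in triplets], columns=cols)
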