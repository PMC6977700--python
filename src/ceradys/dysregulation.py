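"""Dysregulation scoring of candidate triplets between two biological states.

Each triplet gets three node scores (one per transcript, from its
differential-expression p-value and log2 fold change) and three edge
scores (one per link, from the change in Pearson co-expression between
the states, Fisher z-transformed and normalized to a z-like statistic).
Both kinds of component are mapped onto the standard-normal quantile
scale with the same tail transform

    score = Phi^-1(2 * Phi(d) - 1),    d >= 0,

so that larger differential signals give larger scores. The triplet
score is a weighted mean, omega * mean(node scores) + (1 - omega) *
mean(edge scores); with omega = 0.5 and three nodes / three edges it is
the plain mean of the six components. Significance comes from an
empirical null of randomly assembled triplets scored identically; the
empirical p-value is the fraction of null scores strictly larger than
the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cerna import CandidateConfig, CandidateTriplet, find_candidates
from .data_model import ExpressionMatrix, InteractionSet
from .diffexpr import P_FLOOR, differential_expression

logger = logging.getLogger("ceradys")

#: fixed link order used everywhere: miRNA-mRNA, miRNA-lncRNA, lncRNA-mRNA
EDGE_ORDER = ("mi_m", "mi_l", "l_m")
#: fixed node order: lncRNA, miRNA, mRNA
NODE_ORDER = ("lncrna", "mirna", "mrna")


@dataclass
class ScoringConfig:
    omega: float = 0.5
    n_permutations: int = 10_000
    perm_alpha: float = 0.05
    seed: int = 0
    clamp_eps: float = 1e-15
    #: draw a fresh null per observed triplet instead of one shared null
    per_triplet_null: bool = False
    de_method: str = "moderated"

    def __post_init__(self) -> None:
        if not 0 <= self.omega <= 1:
            raise ValueError(f"omega must lie in [0,1], got {self.omega}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class TripletScore:
    lncrna: str
    mirna: str
    mrna: str
    node_scores: tuple[float, float, float]  # lncRNA, miRNA, mRNA
    edge_scores: tuple[float, float, float]  # mi-m, mi-l, l-m
    xi: tuple[float, float, float]           # signed edge statistics, same order
    score: float
    empirical_p: Optional[float] = None
    dysregulated: Optional[bool] = None

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


# ---------------------------------------------------------------------------
# elementary transforms (scalar or ndarray)

ArrayLike = Union[float, np.ndarray]


def tail_transform(d: ArrayLike, clamp_eps: float = 1e-15) -> ArrayLike:
    """Map a non-negative statistic onto the standard-normal quantile scale.

    Returns Phi^-1(q) with q = 1 - 2*(1 - Phi(d)) = 2*Phi(d) - 1, q clamped
    into [clamp_eps, 1 - clamp_eps] so the result is always finite (q is
    exactly 0 at d = 0).
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("tail_transform requires d >= 0")
    q = 2.0 * stats.norm.cdf(d_arr) - 1.0
    q = np.clip(q, clamp_eps, 1.0 - clamp_eps)
    out = stats.norm.ppf(q)
    return float(out) if np.isscalar(d) or d_arr.ndim == 0 else out


def node_score(p: ArrayLike, log2fc: ArrayLike, clamp_eps: float = 1e-15) -> ArrayLike:
    """Node score from differential expression: D = (-log10 p) * |log2FC|."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    d = -np.log10(np.maximum(p_arr, P_FLOOR)) * np.abs(np.asarray(log2fc, dtype=float))
    return tail_transform(d, clamp_eps)


def fisher_z(r: ArrayLike) -> ArrayLike:
    """Fisher z-transform, 0.5*ln((1+r)/(1-r)); |r| clamped to 1 - 1e-7."""
    r_arr = np.clip(np.asarray(r, dtype=float), -1 + 1e-7, 1 - 1e-7)
    out = 0.5 * np.log((1.0 + r_arr) / (1.0 - r_arr))
    return float(out) if np.isscalar(r) or np.asarray(r).ndim == 0 else out


def edge_score(
    r1: ArrayLike, p1: ArrayLike, n1: int,
    r2: ArrayLike, p2: ArrayLike, n2: int,
    clamp_eps: float = 1e-15,
) -> tuple[ArrayLike, ArrayLike]:
    """Differential co-expression statistic xi and its tail-transformed score.

    xi = [F(r2)(-log10 p2) - F(r1)(-log10 p1)] / sqrt(1/(n2-3) + 1/(n1-3));
    state 1 is the reference, state 2 the comparison. Only |xi| enters the
    score, so the orientation affects the sign of xi but not the score.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("edge score needs more than 3 samples per state")
    w1 = -np.log10(np.maximum(np.asarray(p1, dtype=float), P_FLOOR))
    w2 = -np.log10(np.maximum(np.asarray(p2, dtype=float), P_FLOOR))
    denom = np.sqrt(1.0 / (n2 - 3) + 1.0 / (n1 - 3))
    xi = (fisher_z(r2) * w2 - fisher_z(r1) * w1) / denom
    score = tail_transform(np.abs(xi), clamp_eps)
    if np.isscalar(r1) and np.isscalar(r2):
        return float(xi), float(score)
    return xi, score


def triplet_score(
    node_scores: Sequence[float], edge_scores: Sequence[float], omega: float = 0.5
) -> float:
    """Weighted combination omega*mean(nodes) + (1-omega)*mean(edges)."""
    if len(node_scores) != 3 or len(edge_scores) != 3:
        raise ValueError("exactly 3 node scores and 3 edge scores are required")
    if not 0 <= omega <= 1:
        raise ValueError(f"omega must lie in [0,1], got {omega}")
    return float(omega * np.mean(node_scores) + (1 - omega) * np.mean(edge_scores))


# ---------------------------------------------------------------------------
# vectorized correlation over paired rows


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-test p for each paired row of a and b."""
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    r = np.clip(r, -1.0, 1.0)
    r_safe = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_safe * np.sqrt((n - 2) / (1.0 - r_safe**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.clip(p, P_FLOOR, 1.0)
    return r, p


# ---------------------------------------------------------------------------
# scoring context


@dataclass
class ScoringContext:
    """Everything needed to score any triplet between two states.

    Holds the three class matrices restricted to each state's samples and
    the per-class differential-expression lookups (state1 -> state2).
    """

    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    state1_samples: list[str]
    state2_samples: list[str]
    de_method: str = "moderated"

    _state1: dict = field(init=False, repr=False, default_factory=dict)
    _state2: dict = field(init=False, repr=False, default_factory=dict)
    _de_p: dict = field(init=False, repr=False, default_factory=dict)
    _de_fc: dict = field(init=False, repr=False, default_factory=dict)
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.state1_samples) < 4 or len(self.state2_samples) < 4:
            raise ValueError(
                "each state needs at least 4 samples (correlation p-values "
                "and the 1/(n-3) variance terms require n > 3)"
            )
        if set(self.state1_samples) & set(self.state2_samples):
            raise ValueError("states share samples")
        for cls, expr in (("mrna", self.mrna), ("lncrna", self.lncrna), ("mirna", self.mirna)):
            self._state1[cls] = expr.subset_samples(self.state1_samples).values
            self._state2[cls] = expr.subset_samples(self.state2_samples).values
            self._index[cls] = {g: i for i, g in enumerate(expr.gene_ids)}
            res = differential_expression(
                expr, self.state1_samples, self.state2_samples, method=self.de_method
            )
            self._de_p[cls] = np.array([r.p_value for r in res])
            self._de_fc[cls] = np.array([r.log2fc for r in res])

    @property
    def n1(self) -> int:
        return len(self.state1_samples)

    @property
    def n2(self) -> int:
        return len(self.state2_samples)

    def gene_index(self, cls: str, genes: Sequence[str]) -> np.ndarray:
        idx = self._index[cls]
        try:
            return np.array([idx[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise ValueError(f"gene {exc.args[0]!r} absent from the {cls} matrix") from None

    def score_triplet_arrays(
        self,
        lnc_idx: np.ndarray,
        mi_idx: np.ndarray,
        m_idx: np.ndarray,
        config: ScoringConfig,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Score triplets given per-class row indices (all same length k).

        Returns (node_scores (k,3), edge_scores (k,3), xi (k,3), score (k,)).
        """
        eps = config.clamp_eps
        nodes = np.column_stack([
            node_score(self._de_p["lncrna"][lnc_idx], self._de_fc["lncrna"][lnc_idx], eps),
            node_score(self._de_p["mirna"][mi_idx], self._de_fc["mirna"][mi_idx], eps),
            node_score(self._de_p["mrna"][m_idx], self._de_fc["mrna"][m_idx], eps),
        ])
        edges = np.empty((len(lnc_idx), 3))
        xis = np.empty((len(lnc_idx), 3))
        links = (
            (self._state1["mirna"][mi_idx], self._state1["mrna"][m_idx],
             self._state2["mirna"][mi_idx], self._state2["mrna"][m_idx]),
            (self._state1["mirna"][mi_idx], self._state1["lncrna"][lnc_idx],
             self._state2["mirna"][mi_idx], self._state2["lncrna"][lnc_idx]),
            (self._state1["lncrna"][lnc_idx], self._state1["mrna"][m_idx],
             self._state2["lncrna"][lnc_idx], self._state2["mrna"][m_idx]),
        )
        for j, (a1, b1, a2, b2) in enumerate(links):
            r1, p1 = _rowwise_corr(a1, b1)
            r2, p2 = _rowwise_corr(a2, b2)
            xi, sc = edge_score(r1, p1, self.n1, r2, p2, self.n2, eps)
            xis[:, j] = xi
            edges[:, j] = sc
        scores = config.omega * nodes.mean(axis=1) + (1 - config.omega) * edges.mean(axis=1)
        return nodes, edges, xis, scores


def score_candidates(
    candidates: Sequence[CandidateTriplet],
    context: ScoringContext,
    config: Optional[ScoringConfig] = None,
) -> list[TripletScore]:
    """Score each candidate triplet between the context's two states."""
    if not candidates:
        raise ValueError("no candidate triplets to score")
    config = config or ScoringConfig()
    lnc_idx = context.gene_index("lncrna", [t.lncrna for t in candidates])
    mi_idx = context.gene_index("mirna", [t.mirna for t in candidates])
    m_idx = context.gene_index("mrna", [t.mrna for t in candidates])
    nodes, edges, xis, scores = context.score_triplet_arrays(lnc_idx, mi_idx, m_idx, config)
    return [
        TripletScore(
            lncrna=t.lncrna, mirna=t.mirna, mrna=t.mrna,
            node_scores=tuple(map(float, nodes[i])),
            edge_scores=tuple(map(float, edges[i])),
            xi=tuple(map(float, xis[i])),
            score=float(scores[i]),
        )
        for i, t in enumerate(candidates)
    ]


def permutation_pvalues(
    scored: Sequence[TripletScore],
    pools: tuple[Sequence[str], Sequence[str], Sequence[str]],
    context: ScoringContext,
    config: Optional[ScoringConfig] = None,
) -> list[TripletScore]:
    """Assign empirical p-values from a null of randomly assembled triplets.

    ``pools`` is (lncRNA ids, miRNA ids, mRNA ids); each null triplet draws
    one id from each pool independently and is scored with the same
    machinery as the observed triplets (no interaction support is
    required of null triplets). empirical_p = #(null score > observed) /
    n_permutations, and triplets with empirical_p < perm_alpha are flagged
    dysregulated.
    """
    config = config or ScoringConfig()
    lnc_pool, mi_pool, m_pool = (list(p) for p in pools)
    if not (lnc_pool and mi_pool and m_pool):
        raise ValueError("null pools must be non-empty")
    rng = np.random.default_rng(config.seed)
    obs = np.array([t.score for t in scored])

    def _null_scores(n: int) -> np.ndarray:
        lnc_idx = context.gene_index("lncrna", rng.choice(lnc_pool, size=n))
        mi_idx = context.gene_index("mirna", rng.choice(mi_pool, size=n))
        m_idx = context.gene_index("mrna", rng.choice(m_pool, size=n))
        return context.score_triplet_arrays(lnc_idx, mi_idx, m_idx, config)[3]

    if config.per_triplet_null:
        p_emp = np.array([
            np.sum(_null_scores(config.n_permutations) > s) / config.n_permutations
            for s in obs
        ])
    else:
        null = np.sort(_null_scores(config.n_permutations))
        # count of null scores strictly greater than each observed score
        greater = len(null) - np.searchsorted(null, obs, side="right")
        p_emp = greater / config.n_permutations

    out = [
        replace(t, empirical_p=float(p), dysregulated=bool(p < config.perm_alpha))
        for t, p in zip(scored, p_emp)
    ]
    n_dys = sum(t.dysregulated for t in out)
    logger.info(
        "permutation test: %d/%d triplets dysregulated at alpha=%g "
        "(%d permutations)",
        n_dys, len(out), config.perm_alpha, config.n_permutations,
    )
    return out


def traditional_method(
    mrna_expr: ExpressionMatrix,
    lncrna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    control_samples: Sequence[str],
    case_samples: Sequence[str],
    interactions: InteractionSet,
    sde_alpha: float = 0.05,
    hyper_alpha: float = 0.05,
    corr_alpha: float = 0.05,
    de_method: str = "moderated",
) -> list[CandidateTriplet]:
    """Comparator: threshold-based dysregulated-triplet calling (no scores).

    A triplet is called when (1) its mRNA, lncRNA and miRNA are each SDE
    between cases and controls; (2) the mRNA and lncRNA share a
    significant number of miRNAs (hypergeometric p < hyper_alpha); (3) in
    control samples the miRNA-mRNA and miRNA-lncRNA pairs are negatively
    and the lncRNA-mRNA pair positively correlated (p < corr_alpha), while
    in case samples the lncRNA-mRNA correlation is lost (r <= 0 or p >=
    corr_alpha). Returns an unscored triplet list.
    """
    control = list(control_samples)
    case = list(case_samples)
    ctrl_cfg = CandidateConfig(
        hyper_alpha=hyper_alpha, corr_alpha=corr_alpha, percentile_cut=0.0
    )
    base = find_candidates(
        mrna_expr.subset_samples(control),
        lncrna_expr.subset_samples(control),
        mirna_expr.subset_samples(control),
        interactions,
        ctrl_cfg,
    )
    if not base:
        return []

    sde: dict[str, set[str]] = {}
    for cls, expr in (("mrna", mrna_expr), ("lncrna", lncrna_expr), ("mirna", mirna_expr)):
        res = differential_expression(expr, control, case, method=de_method, sde_alpha=sde_alpha)
        sde[cls] = {r.gene_id for r in res if r.is_sde}

    lnc_case = lncrna_expr.subset_samples(case)
    m_case = mrna_expr.subset_samples(case)
    lnc_idx = {g: i for i, g in enumerate(lnc_case.gene_ids)}
    m_idx = {g: i for i, g in enumerate(m_case.gene_ids)}
    lv, mv = lnc_case.values, m_case.values

    out = []
    for t in base:
        if t.mrna not in sde["mrna"] or t.lncrna not in sde["lncrna"] or t.mirna not in sde["mirna"]:
            continue
        r_case, p_case = _rowwise_corr(
            lv[lnc_idx[t.lncrna]][None, :], mv[m_idx[t.mrna]][None, :]
        )
        if r_case[0] > 0 and p_case[0] < corr_alpha:
            continue  # competing link intact in cases: not dysregulated
        out.append(t)
    return out


def scores_to_frame(scored: Sequence[TripletScore]) -> pd.DataFrame:
    rows = []
    for t in scored:
        row = {"lncrna": t.lncrna, "mirna": t.mirna, "mrna": t.mrna}
        for name, v in zip(NODE_ORDER, t.node_scores):
            row[f"node_{name}"] = v
        for name, v in zip(EDGE_ORDER, t.edge_scores):
            row[f"edge_{name}"] = v
        for name, v in zip(EDGE_ORDER, t.xi):
            row[f"xi_{name}"] = v
        row["score"] = t.score
        row["empirical_p"] = t.empirical_p
        row["dysregulated"] = t.dysregulated
        rows.append(row)
    return pd.DataFrame(rows)
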