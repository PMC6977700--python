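"""Time-course utilities: trend clustering, co-expression partners, enrichment.

Stage profiles are per-gene means over each stage's samples, standardized
per gene (mean 0, sd 1) so clustering sees trends rather than expression
levels. Soft clustering uses fuzzy c-means; cluster counts are user
inputs. Cluster function is probed by extracting strongly co-expressed
mRNA partners (|Pearson r| above a cutoff) and testing them against
user-supplied gene-set collections (GMT) with a hypergeometric
upper-tail test; when several sets share a parent pathway label only the
lowest-p one is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cerna import correlation_with_p
from .data_model import ExpressionMatrix, SampleMetadata
from .dysregulation import _rowwise_corr


@dataclass
class ClusterResult:
    gene_ids: list[str]
    membership: np.ndarray  # genes x clusters, rows sum to 1
    hard_labels: np.ndarray  # argmax cluster per gene
    centroids: np.ndarray   # clusters x stages
    objective_trace: list[float]


def stage_means(
    expr: ExpressionMatrix, metadata: SampleMetadata, ordered_stages: Sequence[str]
) -> pd.DataFrame:
    """Per-gene mean expression within each stage, columns in stage order."""
    cols = {}
    for stage in ordered_stages:
        samples = metadata.samples_in_group(stage)
        if not samples:
            raise ValueError(f"no samples in stage {stage!r}")
        cols[stage] = expr.subset_samples(samples).values.mean(axis=1)
    return pd.DataFrame(cols, index=expr.gene_ids)


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rescale each row to mean 0, sd 1 (population sd)."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 stages to standardize a profile")
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        genes = [profiles.index[i] for i in constant[:5]]
        raise ValueError(f"constant stage profile for gene(s) {genes}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ClusterResult:
    """Fuzzy c-means on standardized stage profiles.

    Standard alternating iteration: centroids are membership^m weighted
    means; memberships follow the inverse-distance rule with exponent
    2/(m-1). Stops when the largest membership change drops below ``tol``
    or after ``max_iter`` rounds. Initialization is a seeded random
    membership matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)

    trace: list[float] = []
    for _ in range(max_iter):
        w = u**m
        centroids = (w.T @ x) / np.maximum(w.sum(axis=0)[:, None], 1e-300)
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((w * d2).sum()))
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        shift = float(np.abs(u_new - u).max())
        u = u_new
        if shift < tol:
            break
    w = u**m
    centroids = (w.T @ x) / np.maximum(w.sum(axis=0)[:, None], 1e-300)
    return ClusterResult(
        gene_ids=list(profiles.index),
        membership=u,
        hard_labels=u.argmax(axis=1),
        centroids=centroids,
        objective_trace=trace,
    )


def coexpressed_partners(
    ncrna_profile: np.ndarray,
    mrna_expr: ExpressionMatrix,
    r_cut: float = 0.7,
    p_cut: float = 0.01,
) -> set[str]:
    """mRNAs with |Pearson r| > r_cut and p < p_cut versus an ncRNA profile."""
    ncrna_profile = np.asarray(ncrna_profile, dtype=float)
    values = mrna_expr.values
    if values.shape[1] != len(ncrna_profile):
        raise ValueError(
            f"profile length {len(ncrna_profile)} does not match "
            f"{values.shape[1]} mRNA samples"
        )
    r, p = _rowwise_corr(values, np.broadcast_to(ncrna_profile, values.shape))
    keep = (np.abs(r) > r_cut) & (p < p_cut)
    return {g for g, k in zip(mrna_expr.gene_ids, keep) if k}


# ---------------------------------------------------------------------------
# gene-set enrichment


@dataclass
class GeneSet:
    name: str
    description: str
    members: set[str]

    @property
    def parent(self) -> str:
        """Parent pathway label: the GMT description if given, else the name."""
        return self.description if self.description else self.name


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT collection (name, description, tab-separated members)."""
    path = Path(path)
    if not path.exists():
        raise ValueError(f"GMT file not found: {path}")
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                raise ValueError(f"malformed GMT line {lineno} in {path}")
            members = {g for g in parts[2:] if g}
            sets.append(GeneSet(name=parts[0], description=parts[1], members=members))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def geneset_enrichment(
    query: set[str],
    collections: Sequence[GeneSet],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Per set: k = |query & set|, K = |set & universe|; p = P(X >= k) with X
    hypergeometric(N=|universe|, K, n=|query|). Sets sharing a parent
    pathway label keep only their lowest-p member (sub-pathway retention).
    Returns rows sorted by p with a ``significant`` flag at ``alpha``.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for gs in collections:
        K = len(gs.members & universe)
        if K == 0:
            continue
        k = len(query & gs.members & universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set_name": gs.name, "parent": gs.parent,
            "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["set_name", "parent", "k", "K", "n", "N", "p_value"])
    if df.empty:
        return df.assign(significant=pd.Series(dtype=bool))
    df = df.sort_values(["p_value", "set_name"], kind="stable")
    df = df.drop_duplicates(subset="parent", keep="first")
    df["significant"] = df["p_value"] < alpha
    return df.reset_index(drop=True)


def cluster_to_frame(result: ClusterResult) -> pd.DataFrame:
    out = pd.DataFrame(
        result.membership,
        index=result.gene_ids,
        columns=[f"membership_c{i}" for i in range(result.membership.shape[1])],
    )
    out.insert(0, "hard_label", result.hard_labels)
    out.index.name = "gene_id"
    return out
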