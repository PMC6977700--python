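"""Synthetic sample-matched three-class expression cohorts with ground truth.

The generator emulates the structure of a case/control transcriptomic
study with matched mRNA / lncRNA / miRNA profiles: planted competing
triplets are driven by a per-sample latent factor L so that, in control
samples, the mRNA and lncRNA load positively and the miRNA negatively on
L — guaranteeing the ceRNA sign pattern (negative miRNA links, positive
lncRNA-mRNA link) by construction. In case samples, dysregulated
triplets lose the latent coupling (links collapse to independence) and
their members receive +-delta log2 mean shifts; non-dysregulated planted
triplets keep the control structure. Background genes are independent
noise throughout. Interaction tables contain both links of every planted
triplet plus random decoys.

Default sizes scale down a two-arm cohort of 46 controls / 73 cases with
200 mRNAs, 60 lncRNAs, 40 miRNAs and 20 planted triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    InteractionSet,
    SampleMetadata,
    write_interactions,
)


@dataclass
class CohortParams:
    n_control: int = 46
    n_case: int = 73
    n_mrna: int = 200
    n_lncrna: int = 60
    n_mirna: int = 40
    n_planted: int = 20
    n_dysregulated: int = 10
    rho: float = 0.9     # latent-factor loading of planted genes
    delta: float = 1.0   # log2 mean shift of dysregulated members in cases
    sigma: float = 0.3   # per-gene noise sd (log2 units)
    n_decoy_interactions: int = 30
    n_followup: int = 13  # cases with an HF / non-HF outcome label
    n_hf: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError(f"rho must lie in (0,1), got {self.rho}")
        if self.n_dysregulated > self.n_planted:
            raise ValueError("n_dysregulated cannot exceed n_planted")
        if self.n_planted > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError("n_planted exceeds a per-class gene count")
        if self.n_decoy_interactions > 0 and (
            self.n_mrna <= self.n_planted or self.n_lncrna <= self.n_planted
        ):
            raise ValueError("decoy interactions need background mRNAs and lncRNAs")
        if self.n_followup > self.n_case or self.n_hf > self.n_followup:
            raise ValueError("inconsistent follow-up counts")
        for name in ("n_control", "n_case", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticTruth:
    #: (lncrna, mirna, mrna, is_dysregulated) per planted triplet
    planted_triplets: list[tuple[str, str, str, bool]]
    params: CohortParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_triplets,
            columns=["lncrna", "mirna", "mrna", "is_dysregulated"],
        )


@dataclass
class Cohort:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    metadata: SampleMetadata
    interactions: InteractionSet
    truth: SyntheticTruth

    @property
    def control_samples(self) -> list[str]:
        return self.metadata.samples_in_group("control")

    @property
    def case_samples(self) -> list[str]:
        return self.metadata.samples_in_group("case")


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_cohort(params: Optional[CohortParams] = None) -> Cohort:
    """Generate a two-state cohort with planted triplets and ground truth."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n_samples = params.n_control + params.n_case
    samples = [f"CTL{i:03d}" for i in range(1, params.n_control + 1)] + [
        f"CASE{i:03d}" for i in range(1, params.n_case + 1)
    ]
    is_case = np.array([False] * params.n_control + [True] * params.n_case)

    mrna_ids = _gene_ids("mRNA", params.n_mrna)
    lncrna_ids = _gene_ids("lncRNA", params.n_lncrna)
    mirna_ids = _gene_ids("miRNA", params.n_mirna)

    # baseline log2 means, drawn once per gene
    base = {
        "mrna": rng.uniform(6.0, 10.0, params.n_mrna),
        "lncrna": rng.uniform(4.0, 8.0, params.n_lncrna),
        "mirna": rng.uniform(2.0, 6.0, params.n_mirna),
    }
    # background: independent noise around the baseline
    mats = {
        cls: base[cls][:, None] + rng.normal(0.0, params.sigma, (len(base[cls]), n_samples))
        for cls in ("mrna", "lncrna", "mirna")
    }

    planted: list[tuple[str, str, str, bool]] = []
    # marginal sd of a latent-coupled gene, used for decoupled case samples
    coupled_sd = float(np.hypot(params.rho, params.sigma))
    for t in range(params.n_planted):
        dys = t < params.n_dysregulated
        lnc, mi, mr = lncrna_ids[t], mirna_ids[t], mrna_ids[t]
        planted.append((lnc, mi, mr, dys))
        latent = rng.normal(0.0, 1.0, n_samples)
        noise = rng.normal(0.0, params.sigma, (3, n_samples))
        coupled = np.vstack([
            params.rho * latent,    # mRNA
            params.rho * latent,    # lncRNA
            -params.rho * latent,   # miRNA
        ]) + noise
        if dys:
            decoupled = rng.normal(0.0, coupled_sd, (3, n_samples))
            shift = np.array([params.delta, -params.delta, params.delta])
            signal = np.where(is_case[None, :], decoupled + shift[:, None], coupled)
        else:
            signal = coupled
        mats["mrna"][t] = base["mrna"][t] + signal[0]
        mats["lncrna"][t] = base["lncrna"][t] + signal[1]
        mats["mirna"][t] = base["mirna"][t] + signal[2]

    inter = InteractionSet()
    for lnc, mi, mr, _ in planted:
        inter.mirna_to_mrna.setdefault(mi, set()).add(mr)
        inter.mirna_to_lncrna.setdefault(mi, set()).add(lnc)
    # decoy targets come from background genes only: a decoy hitting a
    # planted mRNA/lncRNA would perturb that pair's shared-miRNA test
    for _ in range(params.n_decoy_interactions):
        mi = mirna_ids[rng.integers(0, params.n_mirna)]
        inter.mirna_to_mrna.setdefault(mi, set()).add(
            mrna_ids[rng.integers(params.n_planted, params.n_mrna)]
        )
        mi = mirna_ids[rng.integers(0, params.n_mirna)]
        inter.mirna_to_lncrna.setdefault(mi, set()).add(
            lncrna_ids[rng.integers(params.n_planted, params.n_lncrna)]
        )

    outcome = [pd.NA] * n_samples
    case_positions = np.flatnonzero(is_case)
    followup = rng.choice(case_positions, size=params.n_followup, replace=False)
    hf = set(followup[: params.n_hf])
    for pos in followup:
        outcome[pos] = "HF" if pos in hf else "non-HF"
    metadata = SampleMetadata(
        pd.DataFrame({
            "sample_id": samples,
            "group": np.where(is_case, "case", "control"),
            "outcome": outcome,
        })
    )

    def _mat(cls: str, ids: list[str], label: str) -> ExpressionMatrix:
        return ExpressionMatrix(pd.DataFrame(mats[cls], index=ids, columns=samples), label)

    return Cohort(
        mrna=_mat("mrna", mrna_ids, "mRNA"),
        lncrna=_mat("lncrna", lncrna_ids, "lncRNA"),
        mirna=_mat("mirna", mirna_ids, "miRNA"),
        metadata=metadata,
        interactions=inter,
        truth=SyntheticTruth(planted_triplets=planted, params=params),
    )


# ---------------------------------------------------------------------------
# staged (time-course) cohorts


@dataclass
class StagedCohort:
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    metadata: SampleMetadata
    stage_labels: list[str]  # S0 (control) .. Sk
    #: gene -> trend family ("spike" peaks at S1 then decays toward
    #: baseline; "dip" is its mirror image); absent genes are flat
    trend_families: dict[str, str]


def generate_stages(
    params: Optional[CohortParams] = None,
    n_stages: int = 4,
    n_per_stage: int = 20,
    trend_amplitude: float = 2.0,
    n_trend_genes: int = 10,
) -> StagedCohort:
    """Generate a staged cohort with planted stage-trend genes.

    Stage S0 is the control group; stages S1..Sk carry per-gene mean
    trajectories for planted trend genes: a "spike" family jumping by
    ``trend_amplitude`` at S1 then halving toward baseline each later
    stage, and a mirrored "dip" family. Every inter-stage transition
    moves the mean, so trend genes are differentially expressed in each
    adjacent comparison, while flat background genes are not. The first
    ``n_trend_genes`` genes of each ncRNA class form the spike family,
    the next ``n_trend_genes`` the dip family.
    """
    params = params or CohortParams()
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if 2 * n_trend_genes > min(params.n_lncrna, params.n_mirna):
        raise ValueError("2*n_trend_genes exceeds an ncRNA class size")
    rng = np.random.default_rng(params.seed)
    stage_labels = [f"S{i}" for i in range(n_stages + 1)]
    samples, groups = [], []
    for s, label in enumerate(stage_labels):
        for i in range(1, n_per_stage + 1):
            samples.append(f"{label}_{i:03d}")
            groups.append(label)
    n_samples = len(samples)

    # spike trajectory over S0..Sk: 0, A, A/2, A/4, ...
    spike = np.zeros(n_stages + 1)
    for s in range(1, n_stages + 1):
        spike[s] = trend_amplitude / (2 ** (s - 1))
    stage_of_sample = np.repeat(np.arange(n_stages + 1), n_per_stage)

    ids = {
        "mrna": _gene_ids("mRNA", params.n_mrna),
        "lncrna": _gene_ids("lncRNA", params.n_lncrna),
        "mirna": _gene_ids("miRNA", params.n_mirna),
    }
    base = {
        "mrna": rng.uniform(6.0, 10.0, params.n_mrna),
        "lncrna": rng.uniform(4.0, 8.0, params.n_lncrna),
        "mirna": rng.uniform(2.0, 6.0, params.n_mirna),
    }
    trend_families: dict[str, str] = {}
    mats = {}
    for cls in ("mrna", "lncrna", "mirna"):
        m = base[cls][:, None] + rng.normal(0.0, params.sigma, (len(ids[cls]), n_samples))
        if cls in ("lncrna", "mirna"):
            for g in range(n_trend_genes):
                m[g] += spike[stage_of_sample]
                trend_families[ids[cls][g]] = "spike"
            for g in range(n_trend_genes, 2 * n_trend_genes):
                m[g] -= spike[stage_of_sample]
                trend_families[ids[cls][g]] = "dip"
        mats[cls] = m

    metadata = SampleMetadata(pd.DataFrame({"sample_id": samples, "group": groups}))
    return StagedCohort(
        mrna=ExpressionMatrix(pd.DataFrame(mats["mrna"], index=ids["mrna"], columns=samples), "mRNA"),
        lncrna=ExpressionMatrix(pd.DataFrame(mats["lncrna"], index=ids["lncrna"], columns=samples), "lncRNA"),
        mirna=ExpressionMatrix(pd.DataFrame(mats["mirna"], index=ids["mirna"], columns=samples), "miRNA"),
        metadata=metadata,
        stage_labels=stage_labels,
        trend_families=trend_families,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort files in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna_expression.tsv",
        "lncrna": outdir / "lncrna_expression.tsv",
        "mirna": outdir / "mirna_expression.tsv",
        "metadata": outdir / "sample_metadata.tsv",
        "interactions_mrna": outdir / "mirna_mrna_interactions.tsv",
        "interactions_lncrna": outdir / "mirna_lncrna_interactions.tsv",
        "truth": outdir / "planted_triplets.tsv",
    }
    cohort.mrna.write(paths["mrna"])
    cohort.lncrna.write(paths["lncrna"])
    cohort.mirna.write(paths["mirna"])
    cohort.metadata.write(paths["metadata"])
    write_interactions(
        cohort.interactions, paths["interactions_mrna"], paths["interactions_lncrna"]
    )
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
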