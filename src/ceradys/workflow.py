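"""End-to-end orchestration: discovery and progression runs with manifests.

A discovery run chains candidate-triplet detection in the reference
state, two-state dysregulation scoring, and permutation significance,
optionally alongside the threshold-based comparator. A progression run
repeats discovery per stage transition (control-vs-stage or
adjacent-stage) and derives stage-specific triplet members. Every run
can write its tables as TSV plus a JSON manifest holding all parameters
and seeds, from which a rerun reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cerna import CandidateConfig, CandidateTriplet, candidates_to_frame, find_candidates
from .data_model import (
    FLOAT_FORMAT,
    ExpressionMatrix,
    InteractionSet,
    SampleMetadata,
    align_samples,
)
from .dysregulation import (
    ScoringConfig,
    ScoringContext,
    TripletScore,
    permutation_pvalues,
    score_candidates,
    scores_to_frame,
    traditional_method,
)

logger = logging.getLogger("ceradys")

POOL_SCOPES = ("candidates", "all")


@dataclass
class DiscoveryReport:
    candidates: list[CandidateTriplet]
    scored: list[TripletScore]
    traditional: Optional[list[CandidateTriplet]]
    summary: dict

    @property
    def dysregulated(self) -> list[TripletScore]:
        return [t for t in self.scored if t.dysregulated]


def _member_counts(triplets: Sequence) -> dict:
    return {
        "n_triplets": len(triplets),
        "n_mrna": len({t.mrna for t in triplets}),
        "n_lncrna": len({t.lncrna for t in triplets}),
        "n_mirna": len({t.mirna for t in triplets}),
    }


def _pools(
    candidates: Sequence[CandidateTriplet],
    matrices: dict[str, ExpressionMatrix],
    scope: str,
) -> tuple[list[str], list[str], list[str]]:
    if scope == "all":
        return (
            matrices["lncrna"].gene_ids,
            matrices["mirna"].gene_ids,
            matrices["mrna"].gene_ids,
        )
    return (
        sorted({t.lncrna for t in candidates}),
        sorted({t.mirna for t in candidates}),
        sorted({t.mrna for t in candidates}),
    )


def run_discovery(
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    metadata: SampleMetadata,
    interactions: InteractionSet,
    control_group: str = "control",
    case_group: str = "case",
    candidate_config: Optional[CandidateConfig] = None,
    scoring_config: Optional[ScoringConfig] = None,
    pool_scope: str = "candidates",
    include_traditional: bool = False,
    outdir: Optional[str | Path] = None,
    reference_samples: Optional[Sequence[str]] = None,
) -> DiscoveryReport:
    """Candidate detection + scoring + permutation between two groups.

    Candidates are detected in ``reference_samples`` (default: the
    control group); scoring compares ``control_group`` (state 1) against
    ``case_group`` (state 2). Null-pool scope is ``"candidates"`` (genes
    appearing in candidate triplets) or ``"all"`` (all profiled genes).
    """
    if pool_scope not in POOL_SCOPES:
        raise ValueError(f"pool_scope must be one of {POOL_SCOPES}")
    candidate_config = candidate_config or CandidateConfig()
    scoring_config = scoring_config or ScoringConfig()
    mrna, lncrna, mirna = align_samples([mrna, lncrna, mirna], metadata)
    control = [s for s in mrna.sample_ids if s in set(metadata.samples_in_group(control_group))]
    case = [s for s in mrna.sample_ids if s in set(metadata.samples_in_group(case_group))]
    if not control or not case:
        raise RuntimeError(
            f"discovery aborted at sample selection: empty group "
            f"({control_group}: {len(control)}, {case_group}: {len(case)})"
        )
    reference = list(reference_samples) if reference_samples is not None else control

    try:
        candidates = find_candidates(
            mrna.subset_samples(reference),
            lncrna.subset_samples(reference),
            mirna.subset_samples(reference),
            interactions,
            candidate_config,
        )
    except Exception as exc:
        raise RuntimeError(f"discovery aborted at candidate detection: {exc}") from exc

    matrices = {"mrna": mrna, "lncrna": lncrna, "mirna": mirna}
    if candidates:
        try:
            context = ScoringContext(
                mrna=mrna, lncrna=lncrna, mirna=mirna,
                state1_samples=control, state2_samples=case,
                de_method=scoring_config.de_method,
            )
            scored = score_candidates(candidates, context, scoring_config)
            scored = permutation_pvalues(
                scored, _pools(candidates, matrices, pool_scope), context, scoring_config
            )
        except Exception as exc:
            raise RuntimeError(f"discovery aborted at scoring: {exc}") from exc
    else:
        scored = []

    traditional = None
    if include_traditional:
        try:
            traditional = traditional_method(
                mrna, lncrna, mirna, control, case, interactions,
                hyper_alpha=candidate_config.hyper_alpha,
                corr_alpha=candidate_config.corr_alpha,
                de_method=scoring_config.de_method,
            )
        except Exception as exc:
            raise RuntimeError(f"discovery aborted at comparator: {exc}") from exc

    dys = [t for t in scored if t.dysregulated]
    summary = {
        "n_candidates": len(candidates),
        "dysregulated": _member_counts(dys),
        "groups": {control_group: len(control), case_group: len(case)},
    }
    if traditional is not None:
        summary["traditional"] = _member_counts(traditional)
    logger.info(
        "discovery %s vs %s: %d candidates, %d dysregulated triplets "
        "(%d mRNAs, %d lncRNAs, %d miRNAs)",
        control_group, case_group, len(candidates),
        summary["dysregulated"]["n_triplets"], summary["dysregulated"]["n_mrna"],
        summary["dysregulated"]["n_lncrna"], summary["dysregulated"]["n_mirna"],
    )
    report = DiscoveryReport(candidates, scored, traditional, summary)
    if outdir is not None:
        _write_discovery(
            report, Path(outdir),
            manifest={
                "task": "discovery",
                "version": __version__,
                "control_group": control_group,
                "case_group": case_group,
                "pool_scope": pool_scope,
                "include_traditional": include_traditional,
                "candidate_config": dataclasses.asdict(candidate_config),
                "scoring_config": dataclasses.asdict(scoring_config),
            },
        )
    return report


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _write_discovery(report: DiscoveryReport, outdir: Path, manifest: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(candidates_to_frame(report.candidates), outdir / "candidates.tsv")
    _write_tsv(scores_to_frame(report.scored), outdir / "scored_triplets.tsv")
    if report.traditional is not None:
        _write_tsv(candidates_to_frame(report.traditional), outdir / "traditional_triplets.tsv")
    manifest = dict(manifest)
    manifest["summary"] = report.summary
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass
class ProgressionReport:
    transitions: dict[str, DiscoveryReport]
    #: stage label -> ncRNA ids appearing in that stage's dysregulated
    #: triplets and in no other stage's (biomarker candidates)
    stage_specific_lncrnas: dict[str, set[str]] = field(default_factory=dict)
    stage_specific_mirnas: dict[str, set[str]] = field(default_factory=dict)


def run_progression(
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    metadata: SampleMetadata,
    interactions: InteractionSet,
    ordered_stages: Sequence[str],
    mode: str = "control_vs_stage",
    candidate_config: Optional[CandidateConfig] = None,
    scoring_config: Optional[ScoringConfig] = None,
    pool_scope: str = "candidates",
    outdir: Optional[str | Path] = None,
) -> ProgressionReport:
    """Per-transition discovery along an ordered stage sequence.

    ``ordered_stages`` starts with the reference stage (e.g. S0 =
    control). ``mode`` is ``"control_vs_stage"`` (reference vs each later
    stage) or ``"adjacent"`` (each consecutive pair). Candidates are
    always detected in the reference stage's samples. Stage-specific
    ncRNAs are members of exactly one transition's dysregulated set.
    """
    if len(ordered_stages) < 2:
        raise ValueError("need at least 2 ordered stages")
    known = set(metadata.groups())
    unknown = [s for s in ordered_stages if s not in known]
    if unknown:
        raise ValueError(f"unknown stage labels: {unknown}")
    if mode not in ("control_vs_stage", "adjacent"):
        raise ValueError(f"unknown mode {mode!r}")

    reference = ordered_stages[0]
    ref_samples = metadata.samples_in_group(reference)
    if mode == "adjacent":
        pairs = list(zip(ordered_stages[:-1], ordered_stages[1:]))
    else:
        pairs = [(reference, s) for s in ordered_stages[1:]]

    transitions: dict[str, DiscoveryReport] = {}
    for g1, g2 in pairs:
        label = f"{g1}_vs_{g2}"
        transitions[label] = run_discovery(
            mrna, lncrna, mirna, metadata, interactions,
            control_group=g1, case_group=g2,
            candidate_config=candidate_config, scoring_config=scoring_config,
            pool_scope=pool_scope,
            outdir=None if outdir is None else Path(outdir) / label,
            reference_samples=ref_samples,
        )

    report = ProgressionReport(transitions=transitions)
    lnc_sets = {lab: {t.lncrna for t in r.dysregulated} for lab, r in transitions.items()}
    mi_sets = {lab: {t.mirna for t in r.dysregulated} for lab, r in transitions.items()}
    for lab in transitions:
        other_l = set().union(*(s for k, s in lnc_sets.items() if k != lab)) if len(lnc_sets) > 1 else set()
        other_m = set().union(*(s for k, s in mi_sets.items() if k != lab)) if len(mi_sets) > 1 else set()
        report.stage_specific_lncrnas[lab] = lnc_sets[lab] - other_l
        report.stage_specific_mirnas[lab] = mi_sets[lab] - other_m

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {"transition": lab, "class": cls, "gene_id": g}
            for cls, bystage in (("lncRNA", report.stage_specific_lncrnas),
                                 ("miRNA", report.stage_specific_mirnas))
            for lab, genes in bystage.items()
            for g in sorted(genes)
        ]
        _write_tsv(
            pd.DataFrame(rows, columns=["transition", "class", "gene_id"]),
            outdir / "stage_specific_ncrnas.tsv",
        )
        manifest = {
            "task": "progression",
            "version": __version__,
            "mode": mode,
            "ordered_stages": list(ordered_stages),
            "pool_scope": pool_scope,
            "candidate_config": dataclasses.asdict(candidate_config or CandidateConfig()),
            "scoring_config": dataclasses.asdict(scoring_config or ScoringConfig()),
            "summary": {lab: r.summary for lab, r in transitions.items()},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
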