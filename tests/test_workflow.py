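"""End-to-end discovery/progression orchestration and the CLI surface."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from ceradys import (
    CandidateConfig,
    CohortParams,
    ScoringConfig,
    generate_cohort,
    run_discovery,
    run_progression,
    write_cohort,
)
from ceradys.cli import main as cli_main


@pytest.fixture(scope="module")
def planted_cohort():
    return generate_cohort(CohortParams(seed=1))


CFG = dict(
    candidate_config=CandidateConfig(percentile_cut=0),
    scoring_config=ScoringConfig(n_permutations=500, seed=9),
)


class TestRunDiscovery:
    def test_planted_triplets_flagged(self, planted_cohort):
        co = planted_cohort
        report = run_discovery(co.mrna, co.lncrna, co.mirna, co.metadata,
                               co.interactions, **CFG)
        flagged = {t.ids for t in report.dysregulated}
        truth = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if d}
        assert truth <= flagged
        assert report.summary["dysregulated"]["n_triplets"] == len(flagged)

    def test_summary_member_counts(self, planted_cohort):
        co = planted_cohort
        report = run_discovery(co.mrna, co.lncrna, co.mirna, co.metadata,
                               co.interactions, **CFG)
        dys = report.dysregulated
        assert report.summary["dysregulated"]["n_lncrna"] == len({t.lncrna for t in dys})
        assert report.summary["dysregulated"]["n_mrna"] == len({t.mrna for t in dys})

    def test_traditional_side_by_side(self, planted_cohort):
        co = planted_cohort
        report = run_discovery(co.mrna, co.lncrna, co.mirna, co.metadata,
                               co.interactions, include_traditional=True, **CFG)
        assert report.traditional is not None
        assert "traditional" in report.summary

    def test_rerun_outputs_byte_identical(self, planted_cohort, tmp_path):
        co = planted_cohort
        for d in ("run1", "run2"):
            run_discovery(co.mrna, co.lncrna, co.mirna, co.metadata,
                          co.interactions, outdir=tmp_path / d, **CFG)
        for name in ("candidates.tsv", "scored_triplets.tsv", "manifest.json"):
            assert filecmp.cmp(tmp_path / "run1" / name, tmp_path / "run2" / name,
                               shallow=False), name

    def test_stage_named_error_on_bad_group(self, planted_cohort):
        co = planted_cohort
        with pytest.raises(RuntimeError, match="sample selection"):
            run_discovery(co.mrna, co.lncrna, co.mirna, co.metadata,
                          co.interactions, case_group="no-such-group", **CFG)


@pytest.fixture(scope="module")
def staged_two_state():
    """A cohort whose metadata carries three stage labels, with signal
    planted only between S0 and S1 (S2 duplicates the S1 distribution
    minus the shift: effectively a no-change transition)."""
    import pandas as pd

    from ceradys import SampleMetadata

    co = generate_cohort(CohortParams(n_control=60, n_case=60, seed=14))
    # split cases into two equal pseudo-stages S1, S2
    case = co.case_samples
    groups = {}
    for s in co.control_samples:
        groups[s] = "S0"
    for i, s in enumerate(case):
        groups[s] = "S1" if i < 30 else "S2"
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": list(groups), "group": list(groups.values())
    }))
    return co, meta


class TestRunProgression:
    def test_control_vs_stage_mode(self, staged_two_state):
        co, meta = staged_two_state
        report = run_progression(
            co.mrna, co.lncrna, co.mirna, meta, co.interactions,
            ordered_stages=["S0", "S1", "S2"], mode="control_vs_stage", **CFG,
        )
        assert set(report.transitions) == {"S0_vs_S1", "S0_vs_S2"}
        # dysregulation was planted into every case sample, so both
        # case stages show flagged triplets against control
        assert report.transitions["S0_vs_S1"].summary["dysregulated"]["n_triplets"] > 0

    def test_identical_stages_null_xi(self, staged_two_state):
        """Between two identically distributed stages, the signed edge
        statistics of intact planted triplets are centred on zero (no
        systematic co-expression change), unlike the control-to-case
        transition where dysregulated links collapse."""
        co, meta = staged_two_state
        report = run_progression(
            co.mrna, co.lncrna, co.mirna, meta, co.interactions,
            ordered_stages=["S0", "S1", "S2"], mode="adjacent", **CFG,
        )
        xi_same = [x for t in report.transitions["S1_vs_S2"].scored for x in t.xi]
        # median signed xi near 0: no directional rewiring between S1 and S2
        assert abs(float(np.median(xi_same))) < 2.0
        truth_dys = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if d}
        xi_change = [
            t.xi[2] for t in report.transitions["S0_vs_S1"].scored if t.ids in truth_dys
        ]
        # the competing link of every dysregulated triplet weakens (xi < 0)
        assert all(x < 0 for x in xi_change)

    def test_stage_order_reversal_flips_xi_keeps_flags(self, staged_two_state):
        co, meta = staged_two_state
        ref = meta.samples_in_group("S0")
        fwd = run_discovery(co.mrna, co.lncrna, co.mirna, meta, co.interactions,
                            control_group="S1", case_group="S2",
                            reference_samples=ref, **CFG)
        rev = run_discovery(co.mrna, co.lncrna, co.mirna, meta, co.interactions,
                            control_group="S2", case_group="S1",
                            reference_samples=ref, **CFG)
        for a, b in zip(fwd.scored, rev.scored):
            assert a.ids == b.ids
            np.testing.assert_allclose(a.xi, [-x for x in b.xi], rtol=1e-9)
            assert a.score == pytest.approx(b.score, rel=1e-9)
        assert [t.dysregulated for t in fwd.scored] == [t.dysregulated for t in rev.scored]

    def test_stage_specific_sets_are_disjoint_from_others(self, staged_two_state):
        co, meta = staged_two_state
        report = run_progression(
            co.mrna, co.lncrna, co.mirna, meta, co.interactions,
            ordered_stages=["S0", "S1", "S2"], mode="control_vs_stage", **CFG,
        )
        labels = list(report.transitions)
        for lab in labels:
            others = set()
            for other in labels:
                if other != lab:
                    others |= {t.lncrna for t in report.transitions[other].dysregulated}
            assert not (report.stage_specific_lncrnas[lab] & others)

    def test_unknown_stage_rejected(self, staged_two_state):
        co, meta = staged_two_state
        with pytest.raises(ValueError, match="unknown stage"):
            run_progression(co.mrna, co.lncrna, co.mirna, meta, co.interactions,
                            ordered_stages=["S0", "S9"], **CFG)


class TestCli:
    def test_simulate_then_score_roundtrip(self, tmp_path):
        runner = CliRunner()
        sim = tmp_path / "sim"
        res = runner.invoke(cli_main, [
            "simulate", "--outdir", str(sim), "--seed", "3",
        ])
        assert res.exit_code == 0, res.output
        out = tmp_path / "run"
        res = runner.invoke(cli_main, [
            "score",
            "--mrna", str(sim / "mrna_expression.tsv"),
            "--lncrna", str(sim / "lncrna_expression.tsv"),
            "--mirna", str(sim / "mirna_expression.tsv"),
            "--metadata", str(sim / "sample_metadata.tsv"),
            "--interactions-mrna", str(sim / "mirna_mrna_interactions.tsv"),
            "--interactions-lncrna", str(sim / "mirna_lncrna_interactions.tsv"),
            "--permutations", "200", "--seed", "5", "--percentile-cut", "0",
            "--outdir", str(out),
        ])
        assert res.exit_code == 0, res.output
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["summary"]["n_candidates"] > 0
        assert (out / "scored_triplets.tsv").exists()

    def test_de_command(self, tmp_path, planted_cohort):
        paths = write_cohort(planted_cohort, tmp_path)
        runner = CliRunner()
        out = tmp_path / "de.tsv"
        res = runner.invoke(cli_main, [
            "de", "--expression", str(paths["mirna"]), "--transcript-class", "miRNA",
            "--metadata", str(paths["metadata"]),
            "--group1", "control", "--group2", "case", "--out", str(out),
        ])
        assert res.exit_code == 0, res.output
        assert out.exists()
        assert "pct_sde" in res.output
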