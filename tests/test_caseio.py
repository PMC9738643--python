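"""Case files, elicitation tables, fixture integrity, and report rendering."""

import numpy as np
import pandas as pd
import pytest
import yaml

import bayesdca as b
from bayesdca.caseio import case_from_dict, case_to_dict


@pytest.fixture()
def minimal_doc():
    return {
        "name": "toy",
        "diagnoses": ["A", "B"],
        "priors": {"values": {"A": 60, "B": 40}},
        "stages": [
            {
                "name": "workup",
                "findings": ["exam"],
                "conditionals": {"A": {"exam": 80}, "B": {"exam": 20}},
            }
        ],
        "decision": {
            "disease": "A",
            "utilities": {
                "composite": {
                    "treated_disease": 80,
                    "treated_no_disease": 60,
                    "untreated_disease": 20,
                }
            },
        },
    }


class TestLoadCase:
    def test_bundled_ferret_case_loads_with_printed_composites(self, ferret):
        assert ferret.belief(0).prior("GI Foreign Body") == 46.7
        assert len(ferret.differential) == 7
        assert [s.name for s in ferret.stages] == ["pre-surgical", "post-surgical"]
        assert ferret.disease == "GI Foreign Body"
        assert ferret.utilities.treated_disease == 83.3
        assert len(ferret.utilities_experts) == 3

    def test_missing_conditional_cell_names_the_pair(self, minimal_doc):
        del minimal_doc["stages"][0]["conditionals"]["B"]["exam"]
        with pytest.raises(b.CaseSchemaError, match="'B', 'exam'"):
            case_from_dict(minimal_doc)

    def test_missing_diagnosis_row_named(self, minimal_doc):
        del minimal_doc["stages"][0]["conditionals"]["B"]
        with pytest.raises(b.CaseSchemaError, match="no conditional row for diagnosis 'B'"):
            case_from_dict(minimal_doc)

    def test_unparseable_yaml_is_a_file_error(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("diagnoses: [unclosed\n  - nope")
        with pytest.raises(b.CaseFileError, match="parse"):
            b.load_case(p)
        with pytest.raises(b.CaseFileError, match="read"):
            b.load_case(tmp_path / "absent.yaml")

    def test_zero_prior_is_a_validation_error(self, minimal_doc):
        minimal_doc["priors"]["values"]["B"] = 0
        with pytest.raises(b.CaseValidationError, match="strictly positive"):
            case_from_dict(minimal_doc)

    def test_panel_below_floor_fails_validation_unless_clamped(self, minimal_doc):
        minimal_doc.pop("priors")
        minimal_doc["experts"] = [
            {
                "id": "e1",
                "priors": {"A": 60, "B": 0.2},
                "conditionals": {"A": {"exam": 80}, "B": {"exam": 20}},
            }
        ]
        with pytest.raises(b.CaseValidationError, match="floor"):
            case_from_dict(minimal_doc)
        bundle = case_from_dict(minimal_doc, clamp=True)
        assert bundle.priors[1] == b.PROBABILITY_FLOOR

    def test_decision_disease_must_be_in_differential(self, minimal_doc):
        minimal_doc["decision"]["disease"] = "C"
        with pytest.raises(b.UnknownLabelError):
            case_from_dict(minimal_doc)

    def test_round_trip_preserves_structure(self, ferret, tmp_path):
        p = tmp_path / "ferret.yaml"
        b.save_case(ferret, p)
        reloaded = b.load_case(p)
        assert list(reloaded.differential) == list(ferret.differential)
        np.testing.assert_allclose(reloaded.priors, ferret.priors)
        for s1, s2 in zip(reloaded.stages, ferret.stages):
            assert s1.name == s2.name and list(s1.findings) == list(s2.findings)
            np.testing.assert_allclose(s1.conditionals, s2.conditionals)
        assert reloaded.utilities == ferret.utilities
        assert reloaded.utilities_experts == ferret.utilities_experts

    def test_serialized_percents_have_one_decimal_by_default(self, minimal_doc):
        minimal_doc["priors"]["values"]["A"] = 60.04
        doc = case_to_dict(case_from_dict(minimal_doc))
        assert doc["priors"]["values"]["A"] == 60.0


class TestElicitationCsv:
    def test_expert_csv_round_trip(self, tmp_path):
        dx = b.DifferentialSet(["A", "B"])
        fs = b.FindingSet(["exam", "imaging"])
        e = b.ExpertElicitation(
            "alice",
            priors={"A": 70.0, "B": 30.0},
            conditionals={"A": {"exam": 55.5, "imaging": 10.0},
                          "B": {"exam": 44.4, "imaging": 90.0}},
        )
        path = tmp_path / "alice.csv"
        b.write_expert_csv(e, dx, fs, path)
        back = b.read_expert_csv(path)
        assert back.expert_id == "alice"
        assert back.priors == e.priors
        assert back.conditionals == e.conditionals

    def test_long_format_panel(self, tmp_path):
        frame = pd.DataFrame(
            [
                ("e1", "A", "prior", 70), ("e1", "B", "prior", 30),
                ("e1", "A", "exam", 80), ("e1", "B", "exam", 20),
                ("e2", "A", "prior", 50), ("e2", "B", "prior", 50),
                ("e2", "A", "exam", 60), ("e2", "B", "exam", 40),
            ],
            columns=["expert", "diagnosis", "field", "value"],
        )
        path = tmp_path / "panel.csv"
        frame.to_csv(path, index=False)
        panel = b.read_panel(path)
        assert [e.expert_id for e in panel] == ["e1", "e2"]
        comp = b.aggregate_experts(
            panel, b.DifferentialSet(["A", "B"]), b.FindingSet(["exam"])
        )
        assert comp.prior("A") == pytest.approx(60.0)
        assert comp.conditional("B", "exam") == pytest.approx(30.0)

    def test_malformed_tables_raise_schema_errors(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("diagnosis,conditional\nA,5\n")
        with pytest.raises(b.CaseSchemaError, match="prior"):
            b.read_expert_csv(p)
        q = tmp_path / "bad_long.csv"
        q.write_text("expert,diagnosis,value\ne1,A,5\n")
        with pytest.raises(b.CaseSchemaError, match="field"):
            b.read_panel(q)
        empty = tmp_path / "empty_dir"
        empty.mkdir()
        with pytest.raises(b.CaseFileError, match="no .csv"):
            b.read_panel(empty)


def exact_belief(bundle: b.CaseBundle) -> b.BeliefState:
    """Stage-1 belief with composites restored to exact three-expert means.

    The published posterior and product columns were computed from
    unrounded composite means; the printed one-decimal inputs recover
    them by snapping to the nearest third.
    """
    belief = bundle.belief(0)
    return b.BeliefState(
        belief.differential,
        belief.findings,
        b.reconstruct_unrounded(belief.priors),
        b.reconstruct_unrounded(belief.conditionals),
        provenance=belief.provenance,
    )


class TestFixtureIntegrity:
    """Recompute every derived column of the bundled case from its inputs."""

    def test_pre_surgical_posteriors_match_at_printed_precision(self, ferret):
        result = b.posterior(exact_belief(ferret))
        for dx, printed in ferret.reference["pre_surgical"]["posteriors"].items():
            decimals = len(str(printed).split(".")[-1]) if "." in str(printed) else 0
            assert round(result[dx], decimals) == pytest.approx(printed), dx

    def test_euthanasia_posteriors_match_at_printed_precision(self, ferret):
        first = b.posterior(exact_belief(ferret))
        s2 = ferret.stage(1)
        chained = b.chain(
            first, b.reconstruct_unrounded(s2.conditionals), s2.findings
        )
        for dx, printed in ferret.reference["at_euthanasia"]["posteriors"].items():
            decimals = len(str(printed).split(".")[-1]) if "." in str(printed) else 0
            assert round(chained[dx], decimals) == pytest.approx(printed), dx

    def test_stage1_product_column_from_unrounded_composites(self, ferret):
        products = b.posterior(exact_belief(ferret)).score
        printed = ferret.reference["pre_surgical"]["products"]
        for dx, value in zip(ferret.differential, products):
            assert value == pytest.approx(printed[dx], rel=5e-3), dx
        assert products.sum() == pytest.approx(
            ferret.reference["pre_surgical"]["products_sum"], rel=5e-3
        )

    def test_stage2_product_column_from_chained_unrounded_posteriors(self, ferret):
        s2 = ferret.stage(1)
        chained = b.chain(
            b.posterior(exact_belief(ferret)),
            b.reconstruct_unrounded(s2.conditionals),
            s2.findings,
        )
        # stage-2 score = (unrounded stage-1 posterior %) × conditionals,
        # which is exactly the printed product column
        products = chained.score
        printed = ferret.reference["at_euthanasia"]["products"]
        # one cytology conditional (6.1) is not recoverable at full
        # precision from the printed digits; 0.6% covers the residual
        for dx, value in zip(ferret.differential, products):
            assert value == pytest.approx(printed[dx], rel=6e-3), dx

    def test_decision_reference_values(self, ferret):
        ref = ferret.reference["decision"]
        d = b.expected_values(31.0, ferret.utilities)
        assert round(d.ev_treat) == ref["expected_value_treat"]
        assert round(d.ev_no_treat) == ref["expected_value_no_treat"]
        assert round(b.treatment_threshold(ferret.utilities)) == ref["threshold_composite_pct"]
        assert [
            round(b.treatment_threshold(u)) for u in ferret.utilities_experts
        ] == ref["thresholds_experts_pct"]

    def test_counterfactual_reference_value(self, ferret, ferret_belief):
        printed = ferret.reference["counterfactual_ultrasound_only"]["GI Foreign Body"]
        assert round(b.posterior(ferret_belief, ["Ultrasonography"])["GI Foreign Body"]) == printed


class TestReport:
    def test_full_ferret_report_states_the_headline_numbers(self, ferret):
        rep = b.render_report(ferret)
        assert "31" in rep.text and "40%" in rep.text
        assert "no surgery" in rep.text
        assert rep.summary["decision"]["optimal"] == "no-treat"
        assert rep.summary["decision"]["verdict"] == "no surgery"
        assert round(rep.summary["decision"]["threshold_pct"]) == 40
        assert round(rep.summary["stages"][0]["posterior_pct"]["GI Foreign Body"]) == 31
        assert round(rep.summary["stages"][1]["posterior_pct"]["Bacterial Gastroenteritis"]) == 76
        assert set(rep.tables) >= {"stage1_pre-surgical", "stage2_post-surgical"}

    def test_counterfactual_report_flips_the_verdict(self, ferret):
        rep = b.render_report(ferret, findings_used=["Ultrasonography"])
        assert rep.summary["decision"]["verdict"] == "surgery"
        assert round(rep.summary["stages"][0]["posterior_pct"]["GI Foreign Body"]) == 64
        assert len(rep.summary["stages"]) == 1  # later stages dropped

    def test_empty_findings_report_uses_priors(self, ferret):
        rep = b.render_report(ferret, findings_used=[])
        assert "priors only" in rep.text
        p = rep.summary["stages"][0]["posterior_pct"]["GI Foreign Body"]
        assert p == pytest.approx(100 * 46.7 / 100.7)

    def test_report_files_round_trip(self, ferret, tmp_path):
        rep = b.render_report(ferret)
        written = rep.save(tmp_path)
        assert (tmp_path / "report.txt").exists()
        assert (tmp_path / "report.json").exists()
        assert any(p.suffix == ".csv" for p in written)

    def test_posterior_table_layout(self, ferret_belief):
        result = b.posterior(ferret_belief)
        table = b.posterior_table(ferret_belief, result)
        assert list(table.columns)[0] == "prior_pct"
        assert list(table.columns)[-2:] == ["product", "posterior_pct"]
        assert table["posterior_pct"].sum() == pytest.approx(100.0)

    def test_decision_tree_text_marks_the_optimal_branch(self, ferret):
        d = b.expected_values(31.0, ferret.utilities)
        text = b.decision_tree_text(d, "GI Foreign Body", "surgery", "no surgery")
        assert "[no surgery] EV = 76.2   <-- optimal" in text
        assert "[surgery] EV = 67.2" in text

    def test_plots_write_png(self, ferret_belief, ferret, tmp_path):
        traj = b.trajectory(ferret_belief)
        b.plot_trajectory(traj, tmp_path / "traj.png")
        sweep = b.sensitivity_sweep(ferret.utilities)
        b.plot_sweep(sweep, tmp_path / "sweep.png")
        assert (tmp_path / "traj.png").stat().st_size > 0
        assert (tmp_path / "sweep.png").stat().st_size > 0
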