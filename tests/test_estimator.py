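"""Estimator API conventions and the command-line interface."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner
from sklearn.base import clone

from lipidpath.cli import main
from lipidpath.estimator import LipidPathwayAnalysis, analyze
from lipidpath.synthetic import PlantedEffect, SimulationSpec, simulate_dataset


@pytest.fixture(scope="module")
def planted_xy():
    spec = SimulationSpec(effects=(PlantedEffect("PC->DG", 2.0),), seed=42)
    table, _ = simulate_dataset(spec)
    X = table.set_index("Species").T
    y = [spec.design().sample_assignment[s] for s in X.index]
    return X, y


class TestSklearnConventions:
    def test_get_set_params_and_clone(self):
        est = LipidPathwayAnalysis(alpha=0.01, level="species")
        params = est.get_params()
        assert params["alpha"] == 0.01 and params["level"] == "species"
        est2 = clone(est)
        assert est2.get_params() == params
        est2.set_params(alpha=0.1)
        assert est2.alpha == 0.1 and est.alpha == 0.01

    def test_fitted_attributes(self, planted_xy):
        X, y = planted_xy
        est = LipidPathwayAnalysis(condition_of_interest="treated",
                                   control="control").fit(X, y)
        assert est.n_features_in_ == X.shape[1]
        assert est.network_.number_of_edges() > 0
        assert set(est.reaction_scores_.columns) >= {"reaction", "z", "p", "status"}
        rep = est.classification_report_
        assert rep.total == X.shape[1]

    def test_rejects_non_dataframe(self):
        with pytest.raises(TypeError):
            LipidPathwayAnalysis().fit([[1, 2]], ["a", "b"])

    def test_needs_two_conditions(self, planted_xy):
        X, _ = planted_xy
        from lipidpath.datasets import ConfigurationError

        with pytest.raises(ConfigurationError):
            LipidPathwayAnalysis().fit(X, ["only"] * len(X))


class TestAnalysis:
    def test_planted_reaction_called_active(self, planted_xy):
        X, y = planted_xy
        est = analyze(X, y, condition_of_interest="treated", control="control")
        row = est.reaction_scores_.query("reaction == 'PC->DG'").iloc[0]
        assert row["status"] == "active" and row["z"] > 1.645
        assert any("PC→DG" in s.label for s in est.pathway_scores_["active"])

    def test_condition_swap_mirrors(self, planted_xy):
        X, y = planted_xy
        a = analyze(X, y, condition_of_interest="treated", control="control")
        b = analyze(X, y, condition_of_interest="control", control="treated")
        za = a.reaction_scores_.set_index("reaction")["z"]
        zb = b.reaction_scores_.set_index("reaction")["z"]
        assert ((za + zb).abs() < 1e-9).all()
        row = b.reaction_scores_.query("reaction == 'PC->DG'").iloc[0]
        assert row["status"] == "suppressed"

    def test_fit_predict_series(self, planted_xy):
        X, y = planted_xy
        out = LipidPathwayAnalysis(
            condition_of_interest="treated", control="control"
        ).fit_predict(X, y)
        assert isinstance(out, pd.Series)
        assert out.loc["PC→DG"] == "active"

    def test_species_level_agrees_with_single_species_subclasses(self):
        spec = SimulationSpec(
            species={"PA": ("34:2",), "DG": ("34:2",), "FA": ("16:0",)},
            seed=9, effects=(PlantedEffect("PA->DG", 1.5),),
        )
        table, _ = simulate_dataset(spec)
        X = table.set_index("Species").T
        y = [spec.design().sample_assignment[s] for s in X.index]
        sub = analyze(X, y, condition_of_interest="treated", control="control",
                      level="subclass")
        spe = analyze(X, y, condition_of_interest="treated", control="control",
                      level="species")
        z_sub = sub.reaction_scores_.set_index("reaction")["z"]
        z_spe = spe.reaction_scores_.set_index("reaction")["z"]
        assert z_sub["PA->DG"] == pytest.approx(z_spe["PA->DG"])


class TestCli:
    def run_cli(self, *args):
        return CliRunner().invoke(main, list(args), catch_exceptions=False)

    def test_simulate_validate_run_round_trip(self, tmp_path):
        csv = tmp_path / "sim.csv"
        res = self.run_cli(
            "simulate", "--out", str(csv), "--seed", "7",
            "--effect", "PC->DG=2.0",
            "--manifest", str(tmp_path / "truth.json"),
        )
        assert res.exit_code == 0, res.output
        assert json.loads((tmp_path / "truth.json").read_text())["seed"] == 7

        res = self.run_cli("validate", "--input", str(csv))
        assert res.exit_code == 0
        assert "unrecognised=0" in res.output

        assigns = []
        for i in range(1, 6):
            assigns += ["--assign", f"treated{i}=treated",
                        "--assign", f"control{i}=control"]
        out = tmp_path / "results"
        res = self.run_cli(
            "run", "--input", str(csv), "--interest", "treated",
            "--control", "control", *assigns, "--out", str(out),
        )
        assert res.exit_code == 0, res.output
        assert (out / "network.json").exists()
        assert (out / "active_pathways.tsv").exists()
        active = (out / "active_reactions.tsv").read_text()
        assert "PC→DG" in active

    def test_configuration_error_exit_code_2(self, tmp_path):
        csv = tmp_path / "sim.csv"
        self.run_cli("simulate", "--out", str(csv), "--seed", "1")
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["run", "--input", str(csv), "--interest", "treated",
             "--control", "control", "--assign", "treated1=treated"],
        )
        assert res.exit_code == 2

    def test_export_db(self):
        res = self.run_cli("export-db")
        assert res.exit_code == 0
        assert "PE->PC" in res.output
        res = self.run_cli("export-db", "--format", "json")
        doc = json.loads(res.output)
        assert len(doc["reactions"]) == 94
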