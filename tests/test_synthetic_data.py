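import dataclasses

import numpy as np
import pandas as pd
import pytest

import rootmix as rm


class TestDesign:
    def test_planned_observation_count(self):
        design = rm.build_design()
        assert len(design) == 144
        assert (design["method"] == "humax").sum() == 72
        assert (design["method"] == "puerckhauer").sum() == 72

    def test_design_keys_unique(self):
        design = rm.build_design()
        keys = design[["plot_id", "depth", "method", "position",
                       "size_class"]]
        assert not keys.duplicated().any()

    def test_treatment_block_structure(self):
        design = rm.build_design()
        plots = design.groupby("plot_id")[["treatment", "block"]].nunique()
        assert (plots == 1).all().all()
        assert design["plot_id"].nunique() == 12
        per_block = design.drop_duplicates("plot_id").groupby("block")[
            "treatment"].nunique()
        assert (per_block == 3).all()


class TestTrueFractions:
    def test_degenerate_scenario_is_constant(self):
        scenario = rm.Scenario.null(dispersion_logit=0.0,
                                    baseline_fraction=0.6)
        truth = rm.draw_true_fractions(rm.build_design(), scenario, seed=0)
        assert truth["true_fraction"].to_numpy() == pytest.approx(0.6)

    def test_deterministic_given_seed(self, baseline_scenario):
        design = rm.build_design()
        a = rm.draw_true_fractions(design, baseline_scenario, seed=5)
        b = rm.draw_true_fractions(design, baseline_scenario, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_strictly_inside_unit_interval(self, baseline_scenario):
        truth = rm.draw_true_fractions(rm.build_design(), baseline_scenario,
                                       seed=2)
        f = truth["true_fraction"]
        assert ((f > 0) & (f < 1)).all()

    def test_depth_cell_means_increase(self, baseline_scenario):
        # without sampling noise the configured depth offsets order the
        # cell means exactly
        scenario = dataclasses.replace(baseline_scenario,
                                       dispersion_logit=0.0,
                                       coarse_pure_prob=0.0)
        truth = rm.draw_true_fractions(rm.build_design(), scenario, seed=0)
        means = truth.groupby("depth")["true_fraction"].mean()
        assert means["D1"] < means["D2"] < means["D3"]


class TestSynthesize:
    def test_noise_free_midpoint(self):
        scenario = rm.Scenario.null(
            root_endmember=(-13.3, 0.0), eom_endmember=(-29.3, 0.0),
            sigma_instrument=0.0, dispersion_logit=0.0,
            baseline_fraction=0.5, n_missing=0)
        truth = rm.draw_true_fractions(rm.build_design(), scenario, seed=0)
        table = rm.synthesize_delta13c(truth, scenario, seed=0)
        deltas = np.array([r.delta13c for r in table])
        assert deltas == pytest.approx(-21.3)

    def test_noise_free_pipeline_recovers_truth_exactly(self, exact_pair):
        scenario = rm.Scenario(
            root_endmember=(-13.3, 0.0), eom_endmember=(-29.3, 0.0),
            sigma_instrument=0.0, n_missing=0)
        truth = rm.draw_true_fractions(rm.build_design(), scenario, seed=4)
        table = rm.synthesize_delta13c(truth, scenario, seed=4)
        results = rm.run_mixing(table, exact_pair, draws=0)
        frame = rm.results_frame(table, results)
        merged = frame.merge(truth[["sample_id", "true_fraction"]],
                             on="sample_id")
        assert merged["fraction"].to_numpy() == pytest.approx(
            merged["true_fraction"].to_numpy(), abs=1e-9)

    def test_mass_ratio_applied(self, baseline_scenario):
        table, _, _ = rm.generate_study(baseline_scenario, seed=6)
        coarse = {r.dry_mass for r in table if r.size_class == "coarse"}
        fine = {r.dry_mass for r in table if r.size_class == "fine"}
        assert coarse == {1.0}
        assert fine == {baseline_scenario.mass_ratio_fine_to_coarse}


class TestMissingness:
    def test_realized_count(self, baseline_scenario):
        table, _, _ = rm.generate_study(baseline_scenario, seed=1)
        assert len(table) == 139

    def test_zero_missing_keeps_all(self):
        scenario = dataclasses.replace(rm.Scenario(), n_missing=0)
        table, _, _ = rm.generate_study(scenario, seed=1)
        assert len(table) == 144

    def test_deterministic_and_schema_valid(self, baseline_scenario):
        table, _, _ = rm.generate_study(baseline_scenario, seed=1)
        a = rm.apply_missingness(table, 10, seed=3)
        b = rm.apply_missingness(table, 10, seed=3)
        assert [r.sample_id for r in a] == [r.sample_id for r in b]
        assert len(a) == len(table) - 10
        assert rm.validate_table(a) == []


class TestReferenceLey:
    def test_constant_when_sd_zero(self):
        scenario = dataclasses.replace(rm.Scenario(),
                                       eom_endmember=(-29.3, 0.0))
        ref = rm.generate_reference_ley(scenario, seed=0)
        assert len(ref) == 12
        assert ref["delta13c"].to_numpy() == pytest.approx(-29.3)

    def test_estimator_recovers_mean(self, baseline_scenario):
        ref = rm.generate_reference_ley(baseline_scenario, n=12, seed=8)
        est = rm.estimate_eom_endmember(ref["delta13c"].to_numpy())
        mu, sd = baseline_scenario.eom_endmember
        assert abs(est.mean - mu) < 3 * sd / np.sqrt(12)

    def test_minimum_size(self, baseline_scenario):
        with pytest.raises(rm.ScenarioError):
            rm.generate_reference_ley(baseline_scenario, n=1)


class TestScenario:
    def test_rejects_invalid_parameters(self):
        with pytest.raises(rm.ScenarioError):
            rm.Scenario(baseline_fraction=1.2)
        with pytest.raises(rm.ScenarioError):
            rm.Scenario(sigma_instrument=-0.1)
        with pytest.raises(rm.ScenarioError):
            rm.Scenario(n_missing=144)
        with pytest.raises(rm.ScenarioError):
            rm.Scenario(root_endmember=(-29.3, 0.5),
                        eom_endmember=(-13.3, 0.3))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "baseline_fraction: 0.5\n"
            "dispersion_logit: 0.4\n"
            "root_endmember: [-12.0, 0.2]\n")
        sc = rm.Scenario.from_yaml(path)
        assert sc.baseline_fraction == 0.5
        assert sc.root_endmember == (-12.0, 0.2)
        with pytest.raises(rm.ScenarioError):
            path.write_text("turnover: 3\n")
            rm.Scenario.from_yaml(path)


def test_same_seed_same_study(baseline_scenario):
    a_table, a_ref, a_truth = rm.generate_study(baseline_scenario, seed=17)
    b_table, b_ref, b_truth = rm.generate_study(baseline_scenario, seed=17)
    assert [r.delta13c for r in a_table] == [r.delta13c for r in b_table]
    pd.testing.assert_frame_equal(a_ref, b_ref)
    pd.testing.assert_frame_equal(a_truth, b_truth)
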