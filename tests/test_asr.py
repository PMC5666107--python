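"""Constrained-model presets, ML fitting, and marginal reconstruction."""

import numpy as np
import pytest

from conftest import enumeration_posterior, random_rate_model

from odontree.asr import (
    MkAncestralReconstruction,
    asr_report,
    fit_mk,
    marginal_reconstruction,
    preset_model,
    replicate_representatives,
)
from odontree.charmatrix import CharacterMatrix
from odontree.ctmc import prune_loglik
from odontree.synth import simulate_chronogram, simulate_discrete_character
from odontree.treeio import read_newick


class TestPresets:
    def test_model1_gain_class_shared(self):
        m = preset_model("odontode_model1")
        cmap = m.class_map
        assert cmap[(0, 1)] == cmap[(0, 2)] == cmap[(0, 3)]
        assert cmap[(1, 0)] == cmap[(2, 0)] == cmap[(3, 0)]
        assert cmap[(2, 3)] == cmap[(3, 1)] == cmap[(3, 2)] == cmap[(1, 3)]
        # default completion: p12/p21 share the shift class -> 3 classes
        assert m.n_classes == 3
        assert cmap[(1, 2)] == cmap[(2, 3)]

    def test_model1_configurable_shift12(self):
        m = preset_model("odontode_model1", separate_shift_12=True)
        assert m.n_classes == 4
        assert m.class_map[(1, 2)] == m.class_map[(2, 1)] != m.class_map[(2, 3)]

    def test_model2_trunk_classes(self):
        m = preset_model("odontode_model2")
        cmap = m.class_map
        assert cmap[(0, 2)] == cmap[(0, 3)] == cmap[(1, 2)] == cmap[(1, 3)]
        assert cmap[(2, 0)] == cmap[(3, 0)] == cmap[(2, 1)] == cmap[(3, 1)]
        assert m.n_classes == 4
        assert preset_model("odontode_model2", six_classes=True).n_classes == 6

    def test_plates_model_two_free_classes(self):
        m = preset_model("plates_independent")
        assert m.n_states == 2 and m.n_classes == 2

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="plates_independent"):
            preset_model("nope")


class TestFitMk:
    def test_same_seed_identical_fit(self):
        tree = simulate_chronogram(30, 100.0, seed=4)
        model = preset_model("plates_independent").with_values([0.01, 0.005])
        sim = simulate_discrete_character(tree, model, seed=11)
        fit_a = fit_mk(tree, sim.tips, "plates_independent", restarts=8, seed=3)
        fit_b = fit_mk(tree, sim.tips, "plates_independent", restarts=8, seed=3)
        assert np.array_equal(fit_a.model.values, fit_b.model.values)
        assert fit_a.log_likelihood == fit_b.log_likelihood

    def test_fitted_loglik_beats_random_probes(self):
        tree = simulate_chronogram(40, 120.0, seed=8)
        model = preset_model("plates_independent").with_values([0.02, 0.01])
        sim = simulate_discrete_character(tree, model, seed=5)
        fit = fit_mk(tree, sim.tips, "plates_independent", restarts=10, seed=0)
        states = sim.tips.as_indices()
        rng = np.random.default_rng(42)
        probes = np.exp(rng.uniform(np.log(1e-8), np.log(10.0), size=(50, 2)))
        for probe in probes:
            ll = prune_loglik(tree, states, fit.model.with_values(probe))
            assert fit.log_likelihood >= ll - 1e-9

    def test_restart_bookkeeping(self):
        tree = simulate_chronogram(12, 60.0, seed=1)
        model = preset_model("plates_independent").with_values([0.02, 0.02])
        sim = simulate_discrete_character(tree, model, seed=2)
        fit = fit_mk(tree, sim.tips, "plates_independent", restarts=5, seed=9)
        assert fit.restarts == 5
        assert len(fit.restart_log_likelihoods) == 5
        assert fit.log_likelihood >= np.nanmax(fit.restart_log_likelihoods) - 1e-9

    def test_state_relabelling_leaves_loglik_unchanged(self):
        tree = simulate_chronogram(20, 90.0, seed=13)
        model = preset_model("plates_independent").with_values([0.02, 0.01])
        sim = simulate_discrete_character(tree, model, seed=21)
        fit = fit_mk(tree, sim.tips, "plates_independent", restarts=12, seed=0)
        # swap state symbols in both data and model: swap classes = swap rates
        from odontree.ctmc import RateModel

        swapped_char = sim.tips.relabelled({"0": "1", "1": "0"})
        swapped_model = RateModel(
            labels=["0", "1"],
            class_map={(0, 1): 0, (1, 0): 1},
            values=np.array([1.0, 1.0]),
            class_names=["gain", "loss"],
        )
        fit_sw = fit_mk(tree, swapped_char, swapped_model, restarts=12, seed=0)
        assert fit_sw.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-6)


class TestMarginalReconstruction:
    @pytest.mark.parametrize("newick,states,k", [
        ("((A:3,B:3):5,C:8):0;", {"A": 0, "B": 1, "C": 0}, 2),
        ("((A:3,B:3):5,(C:4,D:4):4):0;", {"A": 0, "B": 3, "C": 1, "D": 2}, 4),
        ("(((A:2,B:2):2,C:4):4,(D:5,E:5):3):0;",
         {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1}, 2),
    ])
    def test_matches_enumeration_posterior(self, newick, states, k):
        tree = read_newick(newick)
        rng = np.random.default_rng(k)
        model = random_rate_model(k, rng)
        char = CharacterMatrix(
            "x", [str(i) for i in range(k)],
            {t: str(s) for t, s in states.items()},
        )
        est = MkAncestralReconstruction(model=model, restarts=1, seed=0, polish=False)
        est.model_ = model
        est.tree_index_ = __import__("odontree.ctmc", fromlist=["TreeIndex"]).TreeIndex(tree)
        est.states_ = char.as_indices()
        recon = est.predict_proba()
        clades = tree.clade_tip_sets()
        for node in tree.internal_nodes():
            expected = enumeration_posterior(tree, char.as_indices(), model, node)
            assert recon.by_clade[clades[node]] == pytest.approx(expected, abs=1e-8)

    def test_posteriors_sum_to_one(self, fixture_bundle):
        fit = fit_mk(fixture_bundle.tree, fixture_bundle.plates,
                     "plates_independent", restarts=6, seed=0)
        recon = marginal_reconstruction(fixture_bundle.tree, fixture_bundle.plates, fit)
        for vec in recon.by_clade.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(vec >= 0) and np.all(vec <= 1)

    def test_presets_match_enumeration_on_small_tree(self):
        tree = read_newick("((A:30,B:30):50,(C:40,D:40):40):0;")
        char = CharacterMatrix("od", ["0", "1", "2", "3"],
                               {"A": "0", "B": "1", "C": "3", "D": "2"})
        for name in ("odontode_model1", "odontode_model2"):
            model = preset_model(name).with_values(
                np.linspace(0.004, 0.01, preset_model(name).n_classes)
            )
            est = MkAncestralReconstruction(model=model)
            from odontree.ctmc import TreeIndex

            est.model_ = model
            est.tree_index_ = TreeIndex(tree)
            est.states_ = char.as_indices()
            recon = est.predict_proba()
            clades = tree.clade_tip_sets()
            for node in tree.internal_nodes():
                expected = enumeration_posterior(tree, char.as_indices(), model, node)
                assert recon.by_clade[clades[node]] == pytest.approx(expected, abs=1e-8)


class TestRecoveryCalibration:
    def test_root_state_recovery_matches_posterior_calibration(self, fixture_bundle):
        """Argmax recovery rate should track the mean reported root posterior."""
        model = preset_model("odontode_model2").with_values(
            [0.004, 0.002, 0.004, 0.002]
        )
        tree = fixture_bundle.tree
        n_rep = 120
        hits, confidences = [], []
        for rep in range(n_rep):
            sim = simulate_discrete_character(tree, model, seed=1000 + rep)
            est = MkAncestralReconstruction(model=model)
            from odontree.ctmc import TreeIndex

            est.model_ = model
            est.tree_index_ = TreeIndex(tree)
            est.states_ = sim.tips.as_indices()
            recon = est.predict_proba()
            clades = tree.clade_tip_sets()
            root_vec = recon.by_clade[clades[tree.root]]
            hits.append(int(np.argmax(root_vec)) == sim.root_state)
            confidences.append(root_vec.max())
        observed = np.mean(hits)
        expected = np.mean(confidences)
        assert observed == pytest.approx(expected, abs=0.08)


class TestReport:
    def test_report_rows_and_trunk_totals(self, fixture_bundle):
        tree = fixture_bundle.tree
        fit = fit_mk(tree, fixture_bundle.odontodes, "odontode_model1",
                     restarts=8, seed=0)
        recon = marginal_reconstruction(tree, fixture_bundle.odontodes, fit)
        named = {"Loricarioidei": ["Nematogenyidae", "Loricariidae"]}
        table = asr_report({"odontode_model1": recon}, tree, named,
                           fits={"odontode_model1": fit})
        row = table.iloc[0]
        assert row["P_trunk"] == pytest.approx(row["P_2"] + row["P_3"], abs=1e-12)
        assert round(row["P_trunk"], 2) == round(float(f"{row['P_trunk']:.10f}"), 2)

    def test_report_regeneration_identical(self, fixture_bundle):
        tree = fixture_bundle.tree
        fit = fit_mk(tree, fixture_bundle.plates, "plates_independent",
                     restarts=6, seed=0)
        recon = marginal_reconstruction(tree, fixture_bundle.plates, fit)
        named = {"CSAL": ["Callichthyidae", "Loricariidae"]}
        a = asr_report({"m": recon}, tree, named).to_csv(index=False)
        b = asr_report({"m": recon}, tree, named).to_csv(index=False)
        assert a == b


def test_replicate_representatives_shape(fixture_bundle):
    tree2, char2 = replicate_representatives(
        fixture_bundle.tree, fixture_bundle.plates, n=2
    )
    assert len(tree2.tips()) == 46
    assert char2["Loricariidae_1"] == char2["Loricariidae_2"] == "1"
    # family crowns sit strictly below their stems
    assert tree2.mrca(["Loricariidae_1", "Loricariidae_2"]).age > 0
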