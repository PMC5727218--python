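import numpy as np
import pytest

from nichepop.enm import (
    MaxentModel,
    auc_scores,
    clean_occurrences,
    fit_maxent,
    fit_maxent_weights,
    permutation_importance,
    project_model,
)
from nichepop.geo_core import OccurrenceSet
from nichepop.synthetic_data import SimConfig, gen_env_layers, gen_occurrences


class TestCleanOccurrences:
    def test_exact_duplicates_collapsed(self):
        occ = OccurrenceSet("t", [(1.0, 1.0), (2.0, 2.0), (1.0, 1.0), (3.0, 3.0),
                                  (4.0, 4.0)])
        clean, report = clean_occurrences(occ)
        assert len(clean) == 4
        assert [r["reason"] for r in report] == ["duplicate"]

    def test_invalid_latitude_rejected_with_reason(self):
        clean, report = clean_occurrences(OccurrenceSet("t", [(0.0, 95.0), (0.0, 0.0)]))
        assert len(clean) == 1
        assert report[0]["reason"] == "invalid coordinate"

    def test_distance_to_reference_threshold(self):
        # ~1 degree of latitude = 111.2 km; 0.54 deg ~ 60 km, 0.36 deg ~ 40 km
        occ = OccurrenceSet("t", [(0.0, 0.54), (10.0, 0.36)])
        refs = [(0.0, 0.0), (10.0, 0.0)]
        clean, report = clean_occurrences(occ, reference_points=refs, max_km=50.0)
        assert len(clean) == 1
        assert clean.points[0] == (10.0, 0.36)
        assert "km" in report[0]["reason"]


class TestCoreFit:
    def test_single_binary_feature_analytic_weight(self):
        """Moment condition e^w n1/(e^w n1 + n0) = 0.8 with n1 = n0 gives w = ln 4."""
        F_bg = np.array([[1.0]] * 50 + [[0.0]] * 50)
        F_pres = np.array([[1.0]] * 8 + [[0.0]] * 2)
        w = fit_maxent_weights(F_pres, F_bg, 0.0)
        assert w[0] == pytest.approx(np.log(4.0), abs=1e-5)

    def test_kkt_condition_with_regularization(self):
        rng = np.random.default_rng(0)
        F_bg = rng.standard_normal((400, 4))
        F_pres = F_bg[:80] + 0.5
        betas = np.full(4, 0.05)
        w = fit_maxent_weights(F_pres, F_bg, betas)
        s = F_bg @ w
        q = np.exp(s - s.max())
        q /= q.sum()
        gap = np.abs(F_pres.mean(axis=0) - q @ F_bg)
        assert (gap <= betas + 1e-6).all()


class TestFitMaxent:
    def test_zero_weights_give_uniform_raw_map(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([1.0, 0.0, 0.0]), 50, seed=1)
        model = fit_maxent(small_env, occ, background_size=400, seed=2)
        model.weights = np.zeros_like(model.weights)
        smap = project_model(model, small_env)
        n = small_env.n_unmasked
        np.testing.assert_allclose(smap.unmasked_values, 1.0 / n)

    def test_raw_map_sums_to_one(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([2.0, -1.0, 0.0]), 80, seed=3)
        model = fit_maxent(small_env, occ, background_size=400, seed=4)
        smap = project_model(model, small_env)
        assert smap.unmasked_values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_too_few_presences_rejected(self, small_env):
        occ = OccurrenceSet("t", [(10.1, 30.1)] * 3)
        with pytest.raises(ValueError, match=">= 5"):
            fit_maxent(small_env, occ, background_size=100)

    def test_single_cell_presences_rejected(self, small_env):
        occ = OccurrenceSet("t", [(10.101 + i * 1e-4, 30.101) for i in range(6)])
        with pytest.raises(ValueError, match="single cell"):
            fit_maxent(small_env, occ, background_size=100)

    def test_affine_rescaling_invariance(self, small_env):
        """Standardization absorbs affine rescaling of the input layers."""
        occ, _ = gen_occurrences(small_env, np.array([2.0, -1.0, 0.0]), 100, seed=5)
        m1 = fit_maxent(small_env, occ, background_size=400, seed=6)
        from conftest import make_grid

        scaled = make_grid(
            {n: 3.0 * small_env.layers[n].values + 7.0 for n in small_env.layer_names},
            xll=small_env.xllcorner, yll=small_env.yllcorner,
            cellsize=small_env.cellsize,
        )
        m2 = fit_maxent(scaled, occ, background_size=400, seed=6)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-4)

    def test_coefficient_sign_recovery(self):
        """Recovered linear weight signs match the simulating niche for
        |beta| >= 1, n = 200, in >= 90% of seeds."""
        beta = np.array([2.0, -1.0])
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            env, _ = gen_env_layers(SimConfig(seed=1000 + seed, grid_rows=25,
                                              grid_cols=25, n_layers=2))
            occ, _ = gen_occurrences(env, beta, 200, seed=seed)
            model = fit_maxent(env, occ, background_size=625, seed=seed)
            lin = model.weights[:2]
            if (np.sign(lin) == np.sign(beta)).all():
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_serialization_round_trip(self, small_env, tmp_path):
        occ, _ = gen_occurrences(small_env, np.array([1.0, 0.0, 0.0]), 50, seed=1)
        model = fit_maxent(small_env, occ, background_size=300, seed=2)
        path = tmp_path / "m.json"
        model.to_json(path)
        back = MaxentModel.from_json(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        np.testing.assert_array_equal(back.layer_means, model.layer_means)
        m1 = project_model(model, small_env)
        m2 = project_model(back, small_env)
        np.testing.assert_array_equal(m1.values, m2.values)


class TestProjection:
    def test_projection_onto_training_grid_identity(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([2.0, 0.0, 0.0]), 60, seed=1)
        model = fit_maxent(small_env, occ, background_size=400, seed=2)
        a = project_model(model, small_env)
        b = project_model(model, small_env)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shifted_layer_moves_map_with_weight_sign(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([2.0, 0.0, 0.0]), 150, seed=3)
        model = fit_maxent(small_env, occ, background_size=400, seed=4)
        from conftest import make_grid

        j = model.layer_names.index("BIO1")
        w_eff = model.weights[j]  # linear weight of the shifted layer
        shifted = make_grid(
            {
                n: small_env.layers[n].values + (1.0 if n == "BIO1" else 0.0)
                for n in small_env.layer_names
            },
            xll=small_env.xllcorner, yll=small_env.yllcorner,
            cellsize=small_env.cellsize,
        )
        base = project_model(model, small_env)
        moved = project_model(model, shifted)
        # positive weight on BIO1: mass moves toward (already favourable) high-score
        # cells; check the score of the best base cell changes in the weight's direction
        corr = np.corrcoef(base.unmasked_values, moved.unmasked_values)[0, 1]
        assert corr > 0  # same niche shape, shifted in intensity

    def test_missing_layer_error_names_it(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([1.0, 0.0, 0.0]), 50, seed=1)
        model = fit_maxent(small_env, occ, background_size=300, seed=2)
        from conftest import make_grid

        partial = make_grid({"BIO1": small_env.layers["BIO1"].values},
                            xll=small_env.xllcorner, yll=small_env.yllcorner,
                            cellsize=small_env.cellsize)
        with pytest.raises(KeyError, match="BIO2"):
            project_model(model, partial)


class TestAuc:
    def test_hand_enumerated_example(self):
        # pairs: (.9 vs .7, .8, .1) wins 3; (.8 vs .7) wins, (.8 vs .8) ties 0.5,
        # (.8 vs .1) wins -> 5.5 of 6
        assert auc_scores([0.9, 0.8], [0.7, 0.8, 0.1]) == pytest.approx(5.5 / 6)

    def test_perfect_separation(self):
        assert auc_scores([0.9, 0.8], [0.5, 0.1]) == 1.0

    def test_identical_sets_give_half(self):
        assert auc_scores([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.5)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            auc_scores([], [0.5])


class TestPermutationImportance:
    def test_informative_layer_dominates(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            env, _ = gen_env_layers(SimConfig(seed=2000 + seed, grid_rows=25,
                                              grid_cols=25, n_layers=2))
            occ, _ = gen_occurrences(env, np.array([3.0, 0.0]), 250, seed=seed)
            model = fit_maxent(env, occ, background_size=625, seed=seed)
            imp = permutation_importance(model, env, occ, n_reps=10, seed=seed)
            if imp["BIO1"] > 90.0 and imp["BIO2"] < 10.0:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_sums_to_hundred(self, small_env):
        occ, _ = gen_occurrences(small_env, np.array([2.0, -1.0, 0.0]), 100, seed=1)
        model = fit_maxent(small_env, occ, background_size=300, seed=2)
        imp = permutation_importance(model, small_env, occ, n_reps=3, seed=3)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)

    def test_constant_layer_zero_drop(self):
        from conftest import make_grid

        rng = np.random.default_rng(0)
        varying = rng.standard_normal((15, 15))
        env = make_grid({"BIO1": varying, "BIO2": np.full((15, 15), 5.0)})
        lon, lat = env.cell_center(*env.unmasked_indices())
        pick = varying.ravel() > 0.5
        occ = OccurrenceSet("t", list(zip(lon[pick], lat[pick])))
        model = fit_maxent(env, occ, background_size=225, seed=1)
        imp = permutation_importance(model, env, occ, n_reps=5, seed=2)
        assert imp["BIO2"] == 0.0
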