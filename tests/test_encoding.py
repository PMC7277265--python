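"""Ridge encoding, empirical chance, RDMs and model comparison."""

import numpy as np
import pandas as pd
import pytest

import semdepth as sd
from semdepth.encoding import (EncodingModel, EncodingSpec, compute_rdm,
                               empirical_chance, fit_encoding,
                               positive_voxel_report, compare_models)
from semdepth.simulate import (FeatureMatrix, expand_features_to_trials,
                               generate_features)


def planted_problem(n_trials=60, n_dims=20, n_voxels=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_trials, n_dims))
    W = rng.standard_normal((n_dims, n_voxels))
    Y = X @ W + noise * rng.standard_normal((n_trials, n_voxels))
    labels = np.array(["a", "b"] * (n_trials // 2))
    return X, Y, labels


class TestFitEncoding:
    def test_exact_linear_map_recovered_almost_perfectly(self):
        # Word-level features expanded to 8 repeats per word: the repeat
        # structure concentrates the design spectrum, so the ridge penalty
        # costs almost nothing and VE approaches its upper bound of 1.
        words = [f"w{i}" for i in range(36)]
        mats, fmap = generate_features(words, n_dims=300,
                                       voxel_target=sd.RoiSpec("A", 5),
                                       seed=0)
        ft = expand_features_to_trials(mats[0], np.tile(words, 8))
        Y = ft.matrix @ fmap
        labels = np.tile(["a"] * 18 + ["b"] * 18, 8)
        res = fit_encoding(ft, (Y, labels), EncodingSpec(n_folds=30, seed=0))
        assert 0.9 < res.aggregate_ve <= 1.0
        assert np.all(res.voxel_ve <= 1.0)

    def test_independent_targets_score_at_or_below_zero(self):
        rng = np.random.default_rng(1)
        X, _, labels = planted_problem(n_trials=120, seed=1)
        Y = rng.standard_normal((120, 6))
        res = fit_encoding(X, (Y, labels), EncodingSpec(n_folds=30, seed=1))
        assert res.aggregate_ve_all <= 0.0

    def test_fold_predictions_match_closed_form_ridge_oracle(self):
        # 10 trials, 1 voxel: prediction must equal the closed-form
        # solution of standardized ridge, fold by fold, to 1e-8.
        X, Y, labels = planted_problem(n_trials=10, n_dims=3, n_voxels=1,
                                       noise=0.5, seed=2)
        spec = EncodingSpec(alpha=100.0, n_folds=5, test_fraction=0.2, seed=2)
        res = fit_encoding(X, (Y, labels), spec, keep_fold_predictions=True)
        rng = np.random.default_rng(spec.seed)
        from semdepth.decoding import make_stratified_splits
        splits = make_stratified_splits(labels, n_splits=5,
                                        test_fraction=0.2, seed=rng)
        assert len(res.fold_predictions) == 5
        for split, (te, pred) in zip(splits, res.fold_predictions):
            tr = split.train_indices
            mu, sdv = X[tr].mean(axis=0), X[tr].std(axis=0)
            Z = (X[tr] - mu) / sdv
            Zt = (X[split.test_indices] - mu) / sdv
            # closed form with intercept: center targets on train mean
            yc = Y[tr] - Y[tr].mean(axis=0)
            beta = np.linalg.solve(Z.T @ Z + spec.alpha * np.eye(Z.shape[1]),
                                   Z.T @ yc)
            oracle = Zt @ beta + Y[tr].mean(axis=0)
            np.testing.assert_array_equal(te, split.test_indices)
            np.testing.assert_allclose(np.ravel(pred), np.ravel(oracle),
                                       atol=1e-8)

    def test_ve_decreases_with_target_noise(self):
        ves = []
        for noise in (0.0, 1.0, 4.0):
            X, Y, labels = planted_problem(n_trials=120, noise=noise, seed=3)
            res = fit_encoding(X, (Y, labels),
                               EncodingSpec(n_folds=20, seed=3))
            ves.append(res.aggregate_ve_all)
        assert ves[0] > ves[1] > ves[2]

    def test_word_level_features_expanded_to_trials(self):
        words = [f"w{i}" for i in range(12)]
        mats, fmap = generate_features(words, n_dims=8,
                                       voxel_target=sd.RoiSpec("A", 4),
                                       seed=4)
        trial_words = np.tile(words, 5)
        ft = expand_features_to_trials(mats[0], trial_words)
        Y = ft.matrix @ fmap
        labels = np.tile(["a"] * 6 + ["b"] * 6, 5)
        res = EncodingModel(mats[0], (Y, labels),
                            EncodingSpec(n_folds=10, seed=4))
        with pytest.raises(ValueError, match="aligned"):
            res.fit()  # word-level matrix cannot align without trial words
        res2 = fit_encoding(ft, (Y, labels), EncodingSpec(n_folds=10, seed=4))
        assert res2.aggregate_ve > 0.5

    def test_invalid_spec_rejected(self):
        X, Y, labels = planted_problem()
        with pytest.raises(ValueError, match="alpha"):
            fit_encoding(X, (Y, labels), EncodingSpec(alpha=0.0))
        with pytest.raises(ValueError, match="at least 10"):
            fit_encoding(X[:8], (Y[:8], labels[:8]))


class TestEmpiricalChance:
    def test_shuffled_training_destroys_planted_fit(self):
        X, Y, labels = planted_problem(n_trials=120, n_dims=30, seed=5)
        spec = EncodingSpec(n_folds=20, seed=5)
        true_fit = fit_encoding(X, (Y, labels), spec).aggregate_ve_all
        chance = empirical_chance(X, (Y, labels), spec)
        assert chance < true_fit
        assert chance <= 0.05

    def test_chance_reproducible_with_fixed_seed(self):
        X, Y, labels = planted_problem(n_trials=60, seed=6)
        spec = EncodingSpec(n_folds=10, seed=6)
        assert empirical_chance(X, (Y, labels), spec) == \
            empirical_chance(X, (Y, labels), spec)

    def test_null_simulations_give_nonpositive_mean_chance(self):
        # Over repeated null datasets the chance VE is not systematically
        # positive.
        rng = np.random.default_rng(7)
        chances = []
        for k in range(10):
            X = rng.standard_normal((40, 10))
            Y = rng.standard_normal((40, 3))
            labels = np.array(["a", "b"] * 20)
            chances.append(empirical_chance(
                X, (Y, labels), EncodingSpec(n_folds=10, seed=k)))
        assert np.mean(chances) <= 0.0
        assert np.mean(np.array(chances) > 0) <= 0.5


class TestRdm:
    def _fm(self, M, words=None):
        n = M.shape[0]
        return FeatureMatrix("m", "embedding", M,
                             np.array(words or [f"w{i}" for i in range(n)]))

    def test_matches_brute_force_double_loop(self, rng):
        M = rng.standard_normal((12, 30))
        rdm = compute_rdm(self._fm(M)).matrix
        C = M - M.mean(axis=0)
        for i in range(12):
            for j in range(12):
                expect = 0.0 if i == j else 1 - np.corrcoef(C[i], C[j])[0, 1]
                assert rdm[i, j] == pytest.approx(expect, abs=1e-10)

    def test_anti_proportional_vectors_have_dissimilarity_two(self):
        # two rows only, so centring across words leaves them exactly
        # anti-proportional
        v = np.array([1.0, -2.0, 3.0, 0.5])
        M = np.vstack([v, -v])
        rdm = compute_rdm(self._fm(M)).matrix
        assert rdm[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_identical_word_vectors_flagged_degenerate(self):
        M = np.vstack([np.ones(5), np.ones(5), np.zeros(5)])
        out = compute_rdm(self._fm(M, ["a", "b", "c"]))
        # after centring across words, rows a and b are identical constants
        assert np.isnan(out.matrix[0, 1])
        assert "a" in out.degenerate_words

    def test_invariant_to_affine_rescaling_of_dimensions(self, rng):
        M = rng.standard_normal((8, 15))
        scaled = M * rng.uniform(0.5, 2.0, size=15) + rng.normal(size=15)
        # correlation-distance RDM is computed after centring across words;
        # per-dimension scaling changes it, but adding per-dimension offsets
        # does not.
        shifted = M + rng.normal(size=15)
        a = compute_rdm(self._fm(M)).matrix
        b = compute_rdm(self._fm(shifted)).matrix
        np.testing.assert_allclose(a, b, atol=1e-10)
        assert scaled.shape == M.shape

    def test_symmetry_zero_diagonal_nonnegative(self, rng):
        M = rng.standard_normal((10, 20))
        rdm = compute_rdm(self._fm(M)).matrix
        np.testing.assert_allclose(rdm, rdm.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rdm), 0.0)
        assert np.nanmin(rdm) >= 0.0


class TestCompareModels:
    def _table(self, rng, advantage=0.0, interaction=0.0):
        rows = []
        for subj in range(10):
            for roi in ("A", "B"):
                for cond in ("deep", "shallow"):
                    for fam, models in (("vision", ("v1", "v2")),
                                        ("embedding", ("e1", "e2"))):
                        base = 0.1 + rng.normal(0, 0.01)
                        if fam == "vision":
                            base += advantage
                            if cond == "deep" and roi == "A":
                                base += interaction
                        for m in models:
                            # identical data across models within a family
                            rows.append({"subject": subj, "roi": roi,
                                         "condition": cond, "model": m,
                                         "family": fam, "ve": base})
        return pd.DataFrame(rows)

    def test_identical_models_yield_null_anova_and_pairwise(self, rng):
        tab = self._table(rng)
        out = compare_models(tab, seed=0)
        assert not out["anova"].reject.any()
        assert not out["pairwise"].reject.any()

    def test_planted_vision_advantage_detected_everywhere(self, rng):
        out = compare_models(self._table(rng, advantage=0.05), seed=0)
        pw = out["pairwise"]
        assert pw.reject.all()
        assert (pw.mean_diff > 0).all()

    def test_condition_interaction_localized_to_planted_roi(self, rng):
        out = compare_models(
            self._table(rng, advantage=0.03, interaction=0.05),
            alpha=0.01, seed=0)
        cc = out["condition_contrast"].set_index("roi")
        assert cc.loc["A", "reject"]
        assert not cc.loc["B", "reject"]
        assert cc.loc["A", "q"] < cc.loc["B", "q"]

    def test_bootstrap_ci_brackets_mean(self, rng):
        out = compare_models(self._table(rng, advantage=0.02), seed=0)
        ci = out["ci"]
        assert ((ci.ci_lo <= ci.mean_ve) & (ci.mean_ve <= ci.ci_hi)).all()

    def test_unbalanced_grid_rejected(self, rng):
        tab = self._table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|incomplete"):
            compare_models(tab)


class TestPositiveVoxelReport:
    def _result(self, ve):
        return sd.EncodingResult(roi="A", condition="deep", model_name="m",
                                 voxel_ve=np.asarray(ve, float), n_folds=1)

    def test_identical_models_have_zero_count_difference(self):
        res = {m: [self._result([0.2, -0.1, 0.3]) for _ in range(4)]
               for m in ("a", "b")}
        out = positive_voxel_report(res)
        assert (out["count_tests"].statistic == 0).all()
        assert out["overlap"].frac_also_positive.iloc[0] == 1.0

    def test_planted_model_explains_more_voxels(self, rng):
        res = {"planted": [self._result(rng.uniform(0.0, 0.4, 30))
                           for _ in range(6)],
               "noise": [self._result(rng.uniform(-0.3, 0.05, 30))
                         for _ in range(6)]}
        out = positive_voxel_report(res)
        row = out["count_tests"].iloc[0]
        assert row.mean_count_a > row.mean_count_b
        ov = out["overlap"]
        assert ((ov.frac_also_positive.dropna() >= 0)
                & (ov.frac_also_positive.dropna() <= 1)).all()
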