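"""The CPM core: standardization, selection, summary, SVR, CV, consensus."""

import numpy as np
import pytest
from scipy import stats

from eegcpm import cpm, synth


class TestStandardization:
    def test_hand_arithmetic(self):
        x = np.array([[0.2], [0.4], [0.6]])
        std = cpm.fit_standardization(x)
        assert np.isclose(std.means[0], 0.4)
        assert np.isclose(std.sds[0], 0.2)  # sample SD, n-1 denominator
        z = cpm.apply_standardization(std, x)
        assert np.allclose(z.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_edge_masked_to_zero(self):
        x = np.column_stack([np.full(4, 0.5), np.arange(4.0)])
        std = cpm.fit_standardization(x)
        assert std.constant_edge_mask.tolist() == [True, False]
        z = cpm.apply_standardization(std, np.array([0.9, 2.0]))
        assert z[0] == 0.0

    def test_held_out_uses_train_parameters(self):
        rng = np.random.default_rng(0)
        train, test = rng.uniform(0, 1, (20, 7)), rng.uniform(0, 1, (5, 7))
        std = cpm.fit_standardization(train)
        z = cpm.apply_standardization(std, test)
        m, s = train.mean(axis=0), train.std(axis=0, ddof=1)
        assert np.allclose(z, (test - m) / s, atol=1e-14, rtol=0)
        # training matrix itself standardizes to mean 0, sample SD 1
        zt = cpm.apply_standardization(std, train)
        assert np.abs(zt.mean(axis=0)).max() < 1e-12
        assert np.allclose(zt.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cpm.fit_standardization(np.ones((2, 3)))


class TestEdgeSelection:
    def test_perfect_correlations_split_into_tails(self):
        scores = np.array([1.0, 2.0, 3.0, 5.0])
        z = np.column_stack([scores, -scores, np.random.default_rng(0)
                             .standard_normal(4)])
        nets = cpm.select_edges(z, scores, alpha=0.01)
        assert 0 in nets.positive_edges
        assert 1 in nets.negative_edges

    def test_type_one_error_calibrated(self):
        # independent Gaussian edges and scores: the selected fraction
        # should match alpha on average (200 replicates, 3 SE tolerance)
        rng = np.random.default_rng(99)
        alpha, n, e, reps = 0.01, 50, 2000, 200
        count = 0
        for _ in range(reps):
            z = rng.standard_normal((n, e))
            y = rng.standard_normal(n)
            nets = cpm.select_edges(z, y, alpha=alpha)
            count += nets.positive_edges.size + nets.negative_edges.size
        frac = count / (reps * e)
        se = np.sqrt(alpha * (1 - alpha) / (reps * e))
        assert abs(frac - alpha) < 3 * se

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (30, 40))
        y = rng.standard_normal(30)
        raw = cpm.select_edges(x, y, alpha=0.1)
        scale = rng.uniform(0.5, 2.0, 40)
        shift = rng.normal(0, 1, 40)
        mapped = cpm.select_edges(x * scale + shift, y, alpha=0.1)
        assert np.array_equal(raw.positive_edges, mapped.positive_edges)
        assert np.array_equal(raw.negative_edges, mapped.negative_edges)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cpm.select_edges(np.random.default_rng(0).random((5, 3)),
                             np.ones(5))


class TestSummaryIndex:
    def test_hand_example(self):
        z = np.array([0.5, 0.3, 0.2])
        nets = cpm.PredictiveNetworks(np.array([0, 1]), np.array([2]))
        assert cpm.summary_index(z, nets, "combined").value == pytest.approx(0.6)
        assert cpm.summary_index(z, nets, "positive").value == pytest.approx(0.8)
        assert cpm.summary_index(z, nets, "negative").value == pytest.approx(0.2)

    def test_empty_tails_flagged_degenerate(self):
        nets = cpm.PredictiveNetworks(np.array([], dtype=int),
                                      np.array([], dtype=int))
        feat = cpm.summary_index(np.ones(5), nets, "combined")
        assert feat.value == 0.0 and feat.degenerate

    def test_combined_is_positive_minus_negative(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((8, 30))
        nets = cpm.PredictiveNetworks(np.array([1, 4, 9]), np.array([2, 20]))
        pos, _ = cpm.summary_features(z, nets, "positive")
        neg, _ = cpm.summary_features(z, nets, "negative")
        comb, _ = cpm.summary_features(z, nets, "combined")
        assert np.array_equal(comb, pos - neg)
        # brute-force loop oracle
        for s in range(8):
            expected = sum(z[s, i] for i in (1, 4, 9)) - sum(
                z[s, i] for i in (2, 20))
            assert abs(comb[s] - expected) < 1e-14


class TestSVR:
    def test_constant_target_within_epsilon_tube(self):
        f = np.linspace(-1, 1, 20)
        model = cpm.fit_svr(f, np.full(20, 0.5),
                            cpm.SVRHyper(epsilon=0.1))
        pred = cpm.predict_svr(model, f)
        assert np.all(np.abs(pred - 0.5) <= 0.1 + 1e-9)

    def test_noiseless_monotone_relation_fits_tightly(self):
        rng = np.random.default_rng(0)
        f = np.sort(rng.normal(0, 2, 90))
        y = 1.0 / (1.0 + np.exp(-f))
        pred = cpm.predict_svr(cpm.fit_svr(f, y), f)
        assert stats.pearsonr(y, pred).statistic >= 0.99

    def test_duplication_invariance(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=25)
        y = 0.3 * f + rng.normal(0, 0.05, 25)
        single = cpm.predict_svr(cpm.fit_svr(f, y), f)
        doubled = cpm.predict_svr(
            cpm.fit_svr(np.repeat(f, 2), np.repeat(y, 2)), f)
        assert np.allclose(single, doubled, atol=1e-9, rtol=0)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            cpm.SVRHyper(C=0.0)
        with pytest.raises(ValueError):
            cpm.SVRHyper(gamma=-1.0)


class TestFolds:
    def test_kfold_partition_properties(self):
        cfg = cpm.CVConfig(scheme="kfold", k=5, seed=4)
        folds = cpm.make_folds(23, cfg)
        tests = np.concatenate([t for _, t in folds])
        assert len(folds) == 5
        assert sorted(tests.tolist()) == list(range(23))
        sizes = [t.size for _, t in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, test in folds:
            assert np.intersect1d(train, test).size == 0

    def test_loo_config_validation(self):
        with pytest.raises(ValueError):
            cpm.CVConfig(scheme="kfold")  # k missing
        with pytest.raises(ValueError):
            cpm.CVConfig(scheme="jackknife")


class TestCrossValidation:
    def test_dynamic_and_generic_paths_identical(self, planted_cohort):
        X = planted_cohort["X"]
        y = planted_cohort["scores"]
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        a = cpm.run_internal_cv(X, y, cfg, modes=("combined",))["combined"]
        b = cpm.run_dynamic_cpm(X, y, cfg, modes=("combined",))["combined"]
        assert np.array_equal(a.predicted, b.predicted)
        assert a.r == b.r

    def test_kfold_reports_fold_mean_r(self, planted_cohort):
        cfg = cpm.CVConfig(scheme="kfold", k=5, seed=1)
        rep = cpm.run_internal_cv(planted_cohort["X"],
                                  planted_cohort["scores"], cfg,
                                  modes=("combined",))["combined"]
        assert rep.n_folds == 5
        assert rep.fold_mean_r is not None
        assert -1.0 <= rep.fold_mean_r <= 1.0

    def test_pooled_r_nondecreasing_in_effect_size(self):
        # planted-signal monotonicity, averaged over replicate cohorts
        means = []
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        for beta in (1e-9, 0.1, 0.2):
            rs = []
            for rep in range(6):
                y = synth.normalize_behavior(
                    synth.generate_behavior(40, 300 + rep))["c_total"].to_numpy()
                trait = synth.standardize_trait(y)
                pe = synth.PlantedEffect(tuple(range(5)), tuple(range(5, 10)),
                                         beta, 0.05)
                mats = synth.generate_connectomes(40, 10, pe, trait, 400 + rep)
                r = cpm.run_internal_cv(mats, y, cfg, modes=("combined",),
                                        keep_fold_details=False)["combined"].r
                rs.append(r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_all_zero_variance_features_flagged(self):
        X = np.full((12, 10), 0.5)
        y = np.random.default_rng(0).uniform(0.1, 1.0, 12)
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        rep = cpm.run_internal_cv(X, y, cfg, modes=("combined",))["combined"]
        assert rep.degenerate
        assert np.isnan(rep.p_param)


class TestPermutation:
    def test_counting_formula_can_reach_zero(self, planted_cohort):
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        res = cpm.permutation_test(planted_cohort["X"],
                                   planted_cohort["scores"], cfg,
                                   n_perm=20, seed=9)
        # strong planted signal: no permutation should match it
        assert np.all(res.null_r < res.r_observed)
        assert res.p_perm == 0.0
        smoothed = (np.sum(res.null_r >= res.r_observed) + 1) / 21
        res2 = cpm.permutation_test(planted_cohort["X"],
                                    planted_cohort["scores"], cfg,
                                    n_perm=20, seed=9,
                                    add_one_smoothing=True)
        assert res2.p_perm == pytest.approx(smoothed)

    def test_invalid_permutation_count(self, planted_cohort):
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        with pytest.raises(ValueError):
            cpm.permutation_test(planted_cohort["X"],
                                 planted_cohort["scores"], cfg, n_perm=0)


class TestConsensus:
    def test_threshold_is_inclusive_at_exact_fraction(self):
        full = cpm.PredictiveNetworks(np.array([3]), np.array([], dtype=int))
        partial = cpm.PredictiveNetworks(np.array([], dtype=int),
                                         np.array([], dtype=int))
        folds = [full] * 81 + [partial] * 9  # edge 3 in 81/90 = 0.9 exactly
        cons = cpm.consensus_networks(folds, threshold=0.9, n_edges=5)
        assert 3 in cons.positive_edges
        folds = [full] * 80 + [partial] * 10  # 80/90 = 0.889 -> dropped
        cons = cpm.consensus_networks(folds, threshold=0.9, n_edges=5)
        assert cons.positive_edges.size == 0
        assert cons.persistence_positive[3] == pytest.approx(80 / 90)

    def test_threshold_validation(self):
        nets = cpm.PredictiveNetworks(np.array([0]), np.array([], dtype=int))
        with pytest.raises(ValueError):
            cpm.consensus_networks([nets], threshold=0.0)


class TestModelBundle:
    @pytest.fixture()
    def bundle(self, planted_cohort):
        X, y = planted_cohort["X"], planted_cohort["scores"]
        cfg = cpm.CVConfig(scheme="loo", seed=0)
        reports = cpm.run_internal_cv(X, y, cfg, modes=("combined",))
        cons = cpm.consensus_networks(reports["combined"].fold_networks,
                                      0.9, n_edges=X.shape[1])
        return cpm.finalize_model(X, y, cons,
                                  provenance={"seed": 0, "threshold": 0.9})

    def test_standardization_fitted_on_full_cohort(self, bundle,
                                                   planted_cohort):
        X = planted_cohort["X"]
        assert np.allclose(bundle.standardization.means, X.mean(axis=0),
                           atol=1e-14, rtol=0)

    def test_serialization_round_trip_bit_identical(self, bundle,
                                                    planted_cohort):
        X = planted_cohort["X"]
        before = bundle.predict(X)
        restored = cpm.CPMModelBundle.from_json(bundle.to_json())
        assert np.array_equal(restored.predict(X), before)

    def test_numpy_predict_matches_reference_svr(self, bundle,
                                                 planted_cohort):
        # cross-check the bundle's own RBF evaluation against the
        # library solver it was fitted with
        from sklearn.svm import SVR
        X, y = planted_cohort["X"], planted_cohort["scores"]
        feats = bundle.summary(X)
        ref = SVR(kernel="rbf", C=bundle.hyper.C,
                  epsilon=bundle.hyper.epsilon, gamma=bundle.svr_gamma)
        ref.fit(feats.reshape(-1, 1), y)
        assert np.allclose(bundle.predict(X),
                           ref.predict(feats.reshape(-1, 1)),
                           atol=1e-10, rtol=0)

    def test_provenance_recorded(self, bundle):
        for key in ("mode", "alpha", "seed", "threshold"):
            assert key in bundle.provenance

    def test_external_self_application_matches_in_sample(self, bundle,
                                                         planted_cohort):
        X, y = planted_cohort["X"], planted_cohort["scores"]
        rep = cpm.external_validate(bundle, X, y, normalize=False)
        assert np.array_equal(rep.predicted, bundle.predict(X))

    def test_edge_count_mismatch_rejected(self, bundle):
        with pytest.raises(ValueError, match="mismatch"):
            cpm.external_validate(bundle, np.zeros((5, 10)), np.ones(5))

    def test_degenerate_consensus_rejected(self, planted_cohort):
        X, y = planted_cohort["X"], planted_cohort["scores"]
        empty = cpm.PredictiveNetworks(np.array([], dtype=int),
                                       np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            cpm.finalize_model(X, y, empty)
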