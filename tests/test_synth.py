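"""Synthetic-cohort generators: determinism, invariants, planted effects."""

import numpy as np
import pytest
from scipy import stats

from eegcpm import connectivity as conn
from eegcpm import synth


class TestBehavior:
    def test_seeded_determinism_and_additivity(self):
        a = synth.generate_behavior(10, seed=7)
        b = synth.generate_behavior(10, seed=7)
        assert a.equals(b)
        assert np.allclose(a["c_total"], a["c_act"] + a["c_ach"], atol=0)
        assert a["education"].isin(range(6)).all()
        assert set(a["gender"].unique()) <= {0, 1}

    def test_growing_cohort_preserves_existing_subjects(self):
        small = synth.generate_behavior(10, seed=3)
        big = synth.generate_behavior(14, seed=3)
        assert small.equals(big.iloc[:10])

    def test_sample_mean_matches_configured_distribution(self):
        # Monte-Carlo check of the score generator against its own
        # lognormal parameterization (3 SE tolerance at n = 10000).
        params = {"c_act": {"mean_log": 3.0, "sd_log": 0.4}}
        n = 10000
        df = synth.generate_behavior(n, seed=11, score_params=params)
        mu = synth.lognormal_mean(3.0, 0.4)
        sd = mu * np.sqrt(np.exp(0.4**2) - 1.0)
        assert abs(df["c_act"].mean() - mu) < 3 * sd / np.sqrt(n)

    def test_normalization_contract(self):
        df = synth.generate_behavior(25, seed=5)
        norm = synth.normalize_behavior(df)
        for col in ("c_act", "c_ach", "c_total"):
            assert norm[col].max() == 1.0
            assert norm[col].min() >= 0.0
            # ordering preserved
            assert (norm[col].rank() == df[col].rank()).all()
        assert norm.attrs["normalized"]

    def test_rejects_degenerate_cohort_size(self):
        with pytest.raises(ValueError):
            synth.generate_behavior(1, seed=0)


class TestPlantedEffect:
    def test_overlapping_tails_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.PlantedEffect((1, 2), (2, 3))

    def test_out_of_range_edge_rejected(self):
        pe = synth.PlantedEffect((44,), ())
        pe.validate_for(10)  # 45 edges: index 44 is the last valid one
        with pytest.raises(ValueError, match="out of range"):
            synth.PlantedEffect((45,), ()).validate_for(10)

    def test_json_round_trip(self):
        pe = synth.PlantedEffect((0, 3), (7,), 0.1, 0.05, 0.4)
        assert synth.PlantedEffect.from_dict(pe.to_dict()) == pe


class TestConnectomes:
    def _cohort(self, seed, n=90, n_rois=10, beta=0.2, noise=0.02, lvl=0.1):
        y = synth.normalize_behavior(
            synth.generate_behavior(n, seed=1000 + seed))["c_total"].to_numpy()
        trait = synth.standardize_trait(y)
        pe = synth.PlantedEffect(tuple(range(5)), tuple(range(5, 10)),
                                 beta, noise)
        mats = synth.generate_connectomes(n, n_rois, pe, trait, seed,
                                          subject_level_sd=lvl)
        return trait, pe, np.array([m.edge_vector() for m in mats])

    def test_matrices_are_valid_connectomes(self):
        _, _, X = self._cohort(0, n=12)
        assert X.shape == (12, 45)
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_determinism(self):
        _, _, a = self._cohort(4, n=8)
        _, _, b = self._cohort(4, n=8)
        assert np.array_equal(a, b)

    def test_planted_edges_track_trait_at_low_noise(self):
        trait, pe, X = self._cohort(1, beta=0.2, noise=0.01, lvl=0.0)
        for e in (*pe.positive_edges, *pe.negative_edges):
            r = stats.pearsonr(X[:, e], trait).statistic
            assert abs(r) > 0.9
        for e in pe.positive_edges:
            assert stats.pearsonr(X[:, e], trait).statistic > 0

    def test_null_effect_gives_null_correlations(self):
        # beta = 0: the fraction of edges nominally significant at 0.05
        # should match the level within binomial tolerance.
        n, n_rois = 90, 30
        y = synth.normalize_behavior(
            synth.generate_behavior(n, seed=600))["c_total"].to_numpy()
        trait = synth.standardize_trait(y)
        pe = synth.PlantedEffect((), (), 1e-12, 0.02)
        mats = synth.generate_connectomes(n, n_rois, pe, trait, 601,
                                          subject_level_sd=0.0)
        X = np.array([m.edge_vector() for m in mats])
        ps = np.array([stats.pearsonr(X[:, e], trait).pvalue
                       for e in range(X.shape[1])])
        n_edges = ps.size
        frac = np.mean(ps < 0.05)
        tol = 3 * np.sqrt(0.05 * 0.95 / n_edges)
        assert abs(frac - 0.05) < tol

    def test_effect_monotonicity(self):
        # mean |edge-trait r| of planted edges strictly increases in beta
        means = []
        for beta in (1e-12, 0.05, 0.2):
            accum = []
            for seed in range(3):
                trait, pe, X = self._cohort(seed, n=60, beta=beta,
                                            noise=0.05, lvl=0.0)
                accum += [abs(stats.pearsonr(X[:, e], trait).statistic)
                          for e in (*pe.positive_edges, *pe.negative_edges)]
            means.append(np.mean(accum))
        assert means[0] < means[1] < means[2]

    def test_clipping_rare_at_default_study_scale(self):
        n, n_rois = 90, 68
        y = synth.normalize_behavior(
            synth.generate_behavior(n, seed=42))["c_total"].to_numpy()
        trait = synth.standardize_trait(y)
        pe = synth.PlantedEffect(tuple(range(5)), tuple(range(5, 10)),
                                 0.2, 0.05)
        mats = synth.generate_connectomes(n, n_rois, pe, trait, 43)
        X = np.array([m.edge_vector() for m in mats])
        clipped = np.mean((X == 0.0) | (X == 1.0))
        assert clipped < 1e-3

    def test_unstandardized_trait_rejected(self):
        pe = synth.PlantedEffect((0,), ())
        with pytest.raises(ValueError, match="standardized"):
            synth.generate_connectomes(5, 5, pe, np.arange(5.0), 0)


class TestTimeSeries:
    band = conn.CANONICAL_BANDS["alpha"]

    def _make(self, coupling_a, seed=0, n=2, fs=200.0, epoch=4.0):
        trait = np.array([0.0] * n)
        pe = synth.PlantedEffect((0,), (), effect_size=0.0, noise_sd=0.02,
                                 baseline=coupling_a)
        return synth.generate_timeseries(n, 4, fs, epoch, 2, self.band, pe,
                                         trait, seed)

    def test_shape_matches_study_regime(self):
        # three epochs of 40 s each, as in the acquisition protocol
        pe = synth.PlantedEffect((), (), 0.1, 0.02)
        ts = synth.generate_timeseries(1, 2, 200.0, 40.0, 3, self.band, pe,
                                       np.array([0.0]), 0)
        assert ts.data.shape == (1, 3, 2, 8000)
        assert ts.epoch_len_s == 40.0

    def test_full_mixing_gives_unit_plv(self):
        # baseline 1 - epsilon is not allowed (open interval); use the mixing
        # formula directly: mixing 1 makes the pair identical signals.
        ts = self._make(coupling_a=0.999999999999)
        dyn = conn.sliding_plv(ts, self.band, window_len=100, step=100,
                               assume_filtered=True)[0]
        assert dyn.values[:, 0].min() > 1.0 - 1e-9

    def test_independent_pair_plv_below_resultant_bound(self):
        # uncoupled ROIs: mean PLV below 3 / sqrt(W) for W phase samples...
        # band-limited phases are autocorrelated, so W counts cycles, not
        # samples: use the number of center-frequency cycles per window.
        pe = synth.PlantedEffect((), (), 0.1, 0.02)
        ts = synth.generate_timeseries(4, 2, 200.0, 20.0, 1, self.band, pe,
                                       np.zeros(4), 3)
        w = 2000  # 10 s windows: ~105 alpha cycles
        dyn = conn.sliding_plv(ts, self.band, window_len=w, step=w,
                               assume_filtered=True)
        cycles = w / 200.0 * self.band.center
        mean_plv = np.mean([d.values.mean() for d in dyn])
        assert mean_plv < 3.0 / np.sqrt(cycles)

    def test_determinism(self):
        a = self._make(0.5, seed=9)
        b = self._make(0.5, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_nyquist_violation_rejected(self):
        pe = synth.PlantedEffect((), (), 0.1, 0.02)
        with pytest.raises(ValueError, match="Nyquist"):
            synth.generate_timeseries(1, 2, 20.0, 1.0, 1,
                                      conn.CANONICAL_BANDS["gamma"], pe,
                                      np.array([0.0]), 0)


class TestToyForward:
    def test_identity_projection(self):
        from eegcpm.containers import RegionalTimeSeries
        rng = np.random.default_rng(1)
        rts = RegionalTimeSeries(rng.standard_normal((2, 1, 6, 50)), 50.0,
                                 tuple("abcdef"), 1.0)
        lead, sens = synth.generate_toy_forward(rts, gain="identity",
                                                sensor_noise_sd=0.0)
        assert np.array_equal(sens.data, rts.data)

    def test_linearity_and_reproducibility(self):
        from eegcpm.containers import RegionalTimeSeries
        rng = np.random.default_rng(2)
        rts = RegionalTimeSeries(rng.standard_normal((1, 2, 5, 40)), 40.0,
                                 tuple("abcde"), 1.0)
        lead, sens = synth.generate_toy_forward(rts, n_sensors=8,
                                                sensor_noise_sd=0.0, seed=4)
        # doubling the gain doubles the sensor data
        lead2, sens2 = synth.generate_toy_forward(rts, n_sensors=8,
                                                  sensor_noise_sd=0.0,
                                                  gain=2 * lead.gain)
        assert np.allclose(sens2.data, 2 * sens.data, atol=1e-12, rtol=0)
        # direct matrix-product oracle
        expected = np.einsum("ns,best->bent", lead.gain, rts.data)
        assert np.allclose(sens.data, expected, atol=1e-12, rtol=0)

    def test_zero_gain_column_rejected(self):
        gain = np.ones((3, 3))
        gain[:, 1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            synth.LeadField(gain, np.arange(3))
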