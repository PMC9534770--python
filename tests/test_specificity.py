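import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from oracles import (naive_mad, naive_participation, naive_regression_mad)
from popassembly.events import PopulationEvent
from popassembly.preprocess import SpikeRaster
from popassembly.specificity import (SurrogateModelParams, bootstrap_compare,
                                     classify_neurons, mad, model_common_specific,
                                     model_equal, model_independent,
                                     participation_probs, regression_mad,
                                     sample_common_density,
                                     subset_reproducibility)
from popassembly.synthetic import make_protocol


class TestMad:
    @pytest.mark.parametrize("values,expected", [([1, 1, 1], 0.0), ([0, 2], 1.0)])
    def test_known_values(self, values, expected):
        assert mad(values) == pytest.approx(expected)

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 40))
            assert mad(x) == pytest.approx(naive_mad(x))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mad([])


class TestParticipationProbs:
    def _setup(self, rng):
        proto = make_protocol(3, 2, 0.5, 1.0, 30.0, (("stim", 30.0),), rng=0)
        spikes = (rng.random((8, proto.n_frames)) < 0.05).astype(np.uint8)
        raster = SpikeRaster(spikes, 30.0)
        events = [PopulationEvent(10, 20, 15, 30.0),
                  PopulationEvent(200, 230, 210, 30.0),
                  PopulationEvent(400, 420, 405, 30.0)]
        return raster, events, proto

    def test_extremes(self):
        proto = make_protocol(2, 1, 0.5, 1.0, 30.0, (("stim", 30.0),), rng=0)
        spikes = np.zeros((2, proto.n_frames), np.uint8)
        spikes[0] = 1  # fires everywhere
        raster = SpikeRaster(spikes, 30.0)
        events = [PopulationEvent(5, 10, 7, 30.0)]
        rec = participation_probs(raster, events, proto)
        assert rec.loc[0, "p_spont"] == 1.0 and rec.loc[0, "p_evoked"] == 1.0
        assert rec.loc[1, "p_spont"] == 0.0 and rec.loc[1, "p_evoked"] == 0.0

    def test_matches_bruteforce_counting(self, rng):
        raster, events, proto = self._setup(rng)
        rec = participation_probs(raster, events, proto)
        trials = [(int(r.sound_id), int(r.onset_frame))
                  for r in proto.trials.itertuples(index=False)]
        p_s, p_e = naive_participation(
            raster.spikes.tolist(), [(e.start, e.end) for e in events],
            trials, 15)
        assert np.allclose(rec["p_spont"], p_s)
        assert np.allclose(rec["p_evoked"], p_e)

    def test_no_events_raises(self, rng):
        raster, _, proto = self._setup(rng)
        with pytest.raises(ValueError, match="p_spont"):
            participation_probs(raster, [], proto)


class TestClassifyNeurons:
    def test_two_point_symmetric_boundaries(self):
        # diffs {-d, +d}: m.a.d. = d, boundary values go to the specific side
        rec = pd.DataFrame({"diff": [-0.2, -0.2, 0.2, 0.2]})
        labels, fractions = classify_neurons(rec)
        assert set(labels) == {"ongoing-preferring", "evoked-preferring"}
        assert fractions["nonspecific"] == 0.0

    def test_all_equal_single_class(self):
        rec = pd.DataFrame({"diff": [0.1] * 5})
        labels, fractions = classify_neurons(rec)
        assert fractions["nonspecific"] == 1.0

    def test_gaussian_nonspecific_fraction(self, rng):
        # P(|X - mu| < mad) with mad = sigma*sqrt(2/pi): 2*Phi(0.7979)-1 = 0.575
        rec = pd.DataFrame({"diff": rng.normal(0.0, 1.0, size=200000)})
        _, fractions = classify_neurons(rec)
        assert fractions["nonspecific"] == pytest.approx(0.5751, abs=0.01)


class TestSubsetReproducibility:
    def test_keep_all_is_identity(self, rng):
        vectors = (rng.random((10, 50)) < 0.3).astype(float)
        labels = np.repeat([0, 1], 5)
        trials = {1: [(rng.random(50) < 0.3).astype(float) for _ in range(4)]}
        full = subset_reproducibility(vectors, labels, trials, np.ones(50, bool))
        again = subset_reproducibility(vectors, labels, trials, np.ones(50, bool))
        assert full == again
        assert full["n_kept"] == 50

    def test_empty_subset_flagged(self, rng):
        vectors = np.zeros((4, 30))
        vectors[:, :10] = (np.random.default_rng(0).random((4, 10)) < 0.5)
        labels = np.zeros(4, int)
        trials = {1: [vectors[0].copy(), vectors[1].copy()]}
        keep = np.zeros(30, bool)
        keep[20:] = True    # neurons absent from every assembly
        out = subset_reproducibility(vectors, labels, trials, keep)
        assert np.isnan(out["mean_cluster_reproducibility"])

    def test_minimum_subset_size(self, rng):
        with pytest.raises(ValueError):
            subset_reproducibility(np.ones((2, 5)), np.zeros(2, int), {},
                                   np.array([True, False, False, False, False]))


class TestModelIndependent:
    def test_marginals_preserved(self, rng):
        rec = pd.DataFrame({"p_spont": rng.random(500),
                            "p_evoked": rng.random(500)})
        out = model_independent(rec, rng)
        assert sorted(out["p_spont"]) == sorted(rec["p_spont"])
        assert sorted(out["p_evoked"]) == sorted(rec["p_evoked"])

    def test_shuffle_destroys_correlation(self, rng):
        base = rng.random(3000)
        rec = pd.DataFrame({"p_spont": base + rng.normal(0, 0.05, 3000),
                            "p_evoked": base + rng.normal(0, 0.05, 3000)})
        out = model_independent(rec, rng)
        assert abs(np.corrcoef(out["p_spont"], out["p_evoked"])[0, 1]) < 0.05

    def test_diff_broadens_when_observed_correlated(self, rng):
        base = rng.random(3000)
        rec = pd.DataFrame({"p_spont": base, "p_evoked": base})
        rec["diff"] = 0.0
        out = model_independent(rec, rng)
        assert mad(out["diff"]) > mad(rec["diff"])


class TestModelEqual:
    def test_large_trial_counts_collapse_diff(self):
        params = SurrogateModelParams(n_neurons=2000, n_spont_events=10 ** 7,
                                      n_evoked_trials=10 ** 7)
        out = model_equal(params, rng=0)
        assert mad(out["diff"]) < 1e-3

    def test_true_probability_mean(self):
        """Sample mean of the true probability sits at the nominal 0.11, up
        to the small upward bias introduced by truncation to [0, 1]
        (analytically ~0.013 for these parameters)."""
        params = SurrogateModelParams()
        out = model_equal(params, rng=1)
        assert abs(out["p_true"].mean() - 0.11) < 0.02
        # exact check against the analytic truncated-normal moments
        tn = scipy.stats.truncnorm((0 - 0.11) / 0.08, (1 - 0.11) / 0.08,
                                   loc=0.11, scale=0.08)
        se = tn.std() / np.sqrt(len(out))
        assert abs(out["p_true"].mean() - tn.mean()) < 5 * se
        assert out["p_true"].std() == pytest.approx(tn.std(), rel=0.05)

    def test_diff_sd_matches_binomial_propagation(self):
        params = SurrogateModelParams(n_neurons=20000)
        out = model_equal(params, rng=2)
        p = out["p_true"].to_numpy()
        expected_var = np.mean(p * (1 - p)) * (1 / params.n_spont_events
                                               + 1 / params.n_evoked_trials)
        assert out["diff"].std() == pytest.approx(np.sqrt(expected_var), rel=0.05)


class TestModelCommonSpecific:
    def test_zero_specific_terms_give_equal_probs(self):
        params = SurrogateModelParams(v_sound=0.0, v_spont=0.0)
        out = model_common_specific(params, rng=0)
        assert np.allclose(out["p_spont"], out["p_evoked"])
        assert np.allclose(out["p_spont"], out["p_common"])

    def test_common_density_matches_target(self):
        """KS test of sampled p_common against exp(-(x/k)^2)/S on [0, 1]."""
        k = 0.1
        rng = np.random.default_rng(3)
        sample = sample_common_density(10 ** 5, k, rng)
        s_norm, _ = scipy.integrate.quad(lambda x: np.exp(-((x / k) ** 2)), 0, 1)

        def cdf(x):
            x = np.atleast_1d(x)
            return np.array([
                scipy.integrate.quad(lambda u: np.exp(-((u / k) ** 2)), 0, xi)[0]
                / s_norm for xi in x])

        grid_stat = scipy.stats.kstest(sample, cdf)
        assert grid_stat.pvalue > 0.01

    def test_shared_common_term_induces_correlation(self):
        out = model_common_specific(SurrogateModelParams(), rng=4)
        r = np.corrcoef(out["p_spont"], out["p_evoked"])[0, 1]
        assert r > 0.1

    def test_probabilities_clipped_and_reported(self):
        out = model_common_specific(SurrogateModelParams(), rng=5)
        assert out["p_spont"].between(0, 1).all()
        assert out["p_evoked"].between(0, 1).all()
        assert "clipped" in out


class TestRegressionMad:
    def test_collinear_points_zero(self):
        rec = pd.DataFrame({"p_evoked": [0.1, 0.2, 0.3, 0.4],
                            "p_spont": [0.2, 0.4, 0.6, 0.8]})
        assert regression_mad(rec) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_offsets_give_d(self):
        x = np.array([0.1, 0.2, 0.3, 0.4] * 2)
        line = 0.5 * x + 0.05
        d = 0.02
        y = np.concatenate([line[:4] + d, line[4:] - d])
        rec = pd.DataFrame({"p_evoked": x, "p_spont": y})
        assert regression_mad(rec) == pytest.approx(d)

    def test_matches_bruteforce_ols(self, rng):
        for _ in range(100):
            x = rng.random(20)
            y = 0.8 * x + rng.normal(0, 0.1, 20)
            rec = pd.DataFrame({"p_evoked": x, "p_spont": y})
            assert regression_mad(rec) == pytest.approx(
                naive_regression_mad(x, y))

    def test_degenerate_cloud_raises(self):
        rec = pd.DataFrame({"p_evoked": [0.5] * 5, "p_spont": np.arange(5) / 5})
        with pytest.raises(ValueError):
            regression_mad(rec)


class TestBootstrapCompare:
    def test_identical_samples_p_near_one(self, rng):
        x = rng.normal(size=200)
        _, p = bootstrap_compare(np.mean, x, x.copy(), n_boot=500, rng=rng)
        assert p > 0.5

    def test_separated_samples_hit_resampling_floor(self, rng):
        a = rng.normal(10, 1, 200)
        b = rng.normal(0, 1, 200)
        _, p = bootstrap_compare(np.mean, a, b, n_boot=1000, rng=rng)
        assert p <= 2 / 1001 + 1e-12

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for rep in range(60):
            r = np.random.default_rng(rep)
            a = r.normal(size=60)
            b = r.normal(size=60)
            _, p = bootstrap_compare(np.mean, a, b, n_boot=200, rng=r)
            ps.append(p)
        # calibration: false-positive rate at 0.1 near nominal
        assert 0.0 <= np.mean(np.array(ps) < 0.1) <= 0.25
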