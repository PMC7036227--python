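import numpy as np
import pytest

from bcrmix.em import BcrMixtureModel, classify, e_step, fit, m_step
from bcrmix.likelihood import joint_log_prob
from bcrmix.params import BG, NS, VS, default_init_params
from bcrmix.simulate import sample_dataset
from bcrmix.tensor import AbundanceTensor

from _oracles import enumerate_posteriors
from conftest import random_params


class TestEStep:
    def test_identical_class_distributions_give_prior_responsibilities(self, generic_params):
        params = generic_params.replace(
            p_vs=generic_params.p_bgns,
            q={"Q": 0.5, "A": 0.5},
            omega={"Q": 0.2, "A": 0.2},
            nb={"Q": generic_params.nb["Q"], "A": generic_params.nb["Q"]},
            gpd={"Q": generic_params.gpd["Q"], "A": generic_params.gpd["Q"]},
        )
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, size=(8, 2, 2))
        x[x.sum(axis=(1, 2)) == 0, 0, 0] = 1
        resp = e_step(x, params).responsibilities
        np.testing.assert_allclose(resp, np.tile(params.gamma_array(), (8, 1)), atol=1e-10)

    def test_degenerate_gamma_concentrates_responsibility(self, generic_params):
        params = generic_params.replace(gamma=(1.0, 0.0, 0.0))
        x = np.ones((4, 2, 2), dtype=int)
        resp = e_step(x, params).responsibilities
        np.testing.assert_allclose(resp[:, BG], 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = random_params(rng)
        x = rng.integers(0, 5, size=(5, 2, 2))
        x[x.sum(axis=(1, 2)) == 0, 0, 0] = 1
        resp = e_step(x, params).responsibilities
        expected, objective = enumerate_posteriors(x, params)
        np.testing.assert_allclose(resp, expected, atol=1e-10)
        assert joint_log_prob(x, params) == pytest.approx(objective, abs=1e-10)

    def test_rows_sum_to_one(self, generic_params):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 8, size=(20, 3, 3))
        x[x.sum(axis=(1, 2)) == 0, 0, 0] = 1
        resp = e_step(x, generic_params).responsibilities
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)

    def test_presence_certain_where_observed(self, generic_params):
        x = np.zeros((1, 2, 2), dtype=int)
        x[0, 0, 1] = 3
        es = e_step(x, generic_params)
        assert es.presence_post[0, 0, :] == pytest.approx(1.0)
        assert np.all(es.presence_post[0, 1, :] < 1.0)


class TestMStep:
    def test_hard_responsibilities_recover_class_frequencies(self, generic_params):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 3, size=(10, 2, 2))
        es = e_step(x, generic_params)
        es.responsibilities = np.zeros((10, 3))
        es.responsibilities[:7, BG] = 1.0
        es.responsibilities[7:, NS] = 1.0
        new = m_step(x, es, generic_params, truncation_correction=False)
        assert new.gamma[0] == pytest.approx(0.7, abs=1e-9)
        assert new.gamma[1] == pytest.approx(0.3, abs=1e-9)

    def test_presence_update_is_weighted_bernoulli_mle(self, generic_params):
        # with all clones fully observed in every individual, p updates to 1
        x = np.ones((6, 3, 2), dtype=int)
        es = e_step(x, generic_params)
        new = m_step(x, es, generic_params, truncation_correction=False)
        assert new.p_bgns == pytest.approx(1.0, abs=1e-9)
        assert new.p_vs == pytest.approx(1.0, abs=1e-9)

    def test_full_pass_from_truth_does_not_decrease_objective(self, hepb_params):
        sim = sample_dataset(hepb_params, 2000, 4, 3, seed=3)
        before = joint_log_prob(sim.tensor, hepb_params)
        es = e_step(sim.tensor, hepb_params)
        new = m_step(sim.tensor, es, hepb_params, truncation_correction=False)
        after = joint_log_prob(sim.tensor, new)
        assert after >= before - 1e-6


class TestFit:
    def test_single_class_data_recovers_dominant_gamma(self, generic_params):
        # with only background data the other components can mimic the
        # background distribution (their parameters are free), so Gamma is
        # only weakly identified; the MAP labelling is the sharp statement
        gen = generic_params.replace(gamma=(1.0, 0.0, 0.0))
        sim = sample_dataset(gen, 3000, 3, 2, seed=7)
        result = fit(sim.tensor, max_iter=60)
        assert result.params.gamma[0] > 0.9
        assert (classify(result) == "bg").all()

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_trace_monotone_on_random_instances(self, seed):
        rng = np.random.default_rng(200 + seed)
        gen = random_params(rng)
        sim = sample_dataset(gen, 60, 2, 2, seed=seed)
        result = fit(sim.tensor, max_iter=25, tol=1e-9)
        diffs = np.diff(result.objective_trace)
        assert np.all(diffs >= -1e-6)

    def test_monotone_without_truncation_correction_too(self):
        rng = np.random.default_rng(77)
        gen = random_params(rng)
        sim = sample_dataset(gen, 80, 2, 2, seed=8)
        result = fit(sim.tensor, max_iter=25, tol=1e-9, truncation_correction=False)
        assert np.all(np.diff(result.objective_trace) >= -1e-6)

    def test_label_anchoring_vs_class_rises_post_vaccination(self, hepb_params):
        sim = sample_dataset(hepb_params, 4000, 4, 3, seed=11)
        result = fit(sim.tensor, max_iter=80)
        p = result.params
        # expected abundance of a captured vs clone: higher post-vaccination
        def regime_mean(reg):
            nb, gp, w = p.nb[reg], p.gpd[reg], p.omega[reg]
            xs = np.arange(1, 20000)
            from bcrmix.distributions import log_pmf_dgpd, log_pmf_ztnb

            low = float((xs * np.exp(log_pmf_ztnb(xs, nb.mu, nb.r))).sum())
            high = float((xs[xs >= gp.u] * np.exp(
                log_pmf_dgpd(xs[xs >= gp.u], gp.xi, gp.sigma, gp.u))).sum())
            return (1 - w) * low + w * high

        assert p.q["A"] * regime_mean("A") > p.q["Q"] * regime_mean("Q")

    def test_degenerate_inputs_raise(self, generic_params):
        with pytest.raises(ValueError):
            fit(np.zeros((3, 2, 2), dtype=int))
        with pytest.raises(ValueError):
            fit(np.ones((3, 2, 1), dtype=int))  # single time point

    def test_deterministic_given_data_and_init(self, hepb_params):
        sim = sample_dataset(hepb_params, 500, 3, 2, seed=5)
        r1 = fit(sim.tensor, max_iter=15)
        r2 = fit(sim.tensor, max_iter=15)
        np.testing.assert_array_equal(r1.responsibilities, r2.responsibilities)
        assert r1.params.to_json() == r2.params.to_json()


class TestClassify:
    def _result_with(self, resp):
        from bcrmix.em import FitResult

        return FitResult(
            params=default_init_params(), responsibilities=np.asarray(resp, float),
            presence_post=np.zeros((len(resp), 1, 3)), map_label=None,
            objective_trace=[], converged=True, n_iter=1)

    def test_map_label(self):
        labels = classify(self._result_with([[0.98, 0.01, 0.01], [0.1, 0.2, 0.7]]))
        assert labels.tolist() == ["bg", "vs"]

    def test_exact_tie_prefers_least_specific_class(self):
        labels = classify(self._result_with([[1 / 3, 1 / 3, 1 / 3], [0.0, 0.5, 0.5]]))
        assert labels.tolist() == ["bg", "ns"]

    def test_posterior_threshold_marks_unassigned(self):
        labels = classify(self._result_with([[0.5, 0.3, 0.2]]), threshold=0.6)
        assert labels.tolist() == ["unassigned"]

    def test_label_counts_track_class_proportions(self, hepb_params):
        sim = sample_dataset(hepb_params, 20000, 4, 3, seed=13)
        result = fit(sim.tensor, max_iter=60)
        n_bg = (classify(result) == "bg").sum()
        # observed-clone bg fraction, allowing for truncation and noise
        true_frac = (sim.true_class == "bg").mean()
        assert abs(n_bg / sim.tensor.n_clones - true_frac) < 0.02


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        model = BcrMixtureModel(tol=1e-4)
        model.set_params(max_iter=10)
        assert model.get_params()["max_iter"] == 10
        with pytest.raises(ValueError):
            model.set_params(bogus=1)

    def test_predict_and_score_after_fit(self, hepb_params):
        sim = sample_dataset(hepb_params, 400, 3, 2, seed=21)
        model = BcrMixtureModel(max_iter=10).fit(sim.tensor)
        proba = model.predict_proba(sim.tensor)
        assert proba.shape == (400, 3)
        assert set(model.predict(sim.tensor)) <= {"bg", "ns", "vs"}
        assert np.isfinite(model.score(sim.tensor))

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            BcrMixtureModel().predict(np.ones((2, 2, 2), dtype=int))
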