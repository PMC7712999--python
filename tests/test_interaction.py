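import numpy as np
import pytest

from itemlens import (
    IMParams,
    RaschParams,
    ScoredMatrix,
    expected_moments,
    fit_interaction,
    im_itr,
    im_itr_table,
    im_loglik,
    item_facility,
    item_total_and_rest_correlations,
    rasch_itr,
    score_distribution,
    simulate_im,
)
from oracles import expected_given_total_enumerate, im_conditional_nll_enumerate


def binary_matrix(scores):
    scores = np.asarray(scores)
    return ScoredMatrix(
        persons=[f"p{k}" for k in range(scores.shape[0])],
        items=[f"i{k}" for k in range(scores.shape[1])],
        scores=scores,
        max_score=np.ones(scores.shape[1], dtype=int),
    )


class TestMomentReproduction:
    """The model's defining property: after convergence the fitted
    expectations reproduce the classical summary of the data exactly."""

    def test_facilities_reproduced(self, rasch_data, im_fit):
        _, mat = rasch_data
        mom = expected_moments(im_fit, mat)
        assert np.max(np.abs(mom["facility"] - item_facility(mat))) < 1e-6

    def test_item_total_inner_products_reproduced(self, rasch_data, im_fit):
        _, mat = rasch_data
        mom = expected_moments(im_fit, mat)
        observed = (mat.scores * mat.totals[:, None]).sum(axis=0)
        assert np.max(np.abs(mom["cross_moment"] - observed) / observed) < 1e-6

    def test_score_distribution_reproduced(self, rasch_data, im_fit):
        _, mat = rasch_data
        mom = expected_moments(im_fit, mat)
        assert np.allclose(mom["score_counts"], score_distribution(mat), atol=1e-9)

    def test_implied_rit_matches_observed(self, rasch_data, im_fit):
        # binary case: reproduced facilities + cross-moments + score
        # distribution pin down the item-total correlation completely
        _, mat = rasch_data
        mom = expected_moments(im_fit, mat)
        P = mat.n_persons
        counts = mom["score_counts"]
        s = np.arange(counts.size)
        mean_t = (counts * s).sum() / P
        var_t = (counts * (s - mean_t) ** 2).sum() / (P - 1)
        rit_obs, _, _ = item_total_and_rest_correlations(mat)
        for k in range(mat.n_items):
            p = mom["facility"][k]
            var_x = P * p * (1 - p) / (P - 1)  # binary: E[x^2] = E[x]
            cov = (mom["cross_moment"][k] - P * p * mean_t) / (P - 1)
            assert cov / np.sqrt(var_x * var_t) == pytest.approx(rit_obs[k], abs=1e-6)


class TestFit:
    def test_sigma_null_on_rasch_data(self, im_fit):
        assert np.all(np.abs(im_fit.sigma) <= 3 * im_fit.se_sigma)

    def test_sigma_recovered_from_own_simulation(self, spm01_im):
        sim = simulate_im(spm01_im, 5000, seed=2718)
        refit = fit_interaction(sim)
        assert np.all(np.abs(refit.sigma - spm01_im.sigma) <= 3 * refit.se_sigma)

    def test_exercise_item_sigma_stands_apart(self, spm01_im):
        # the planted low-discrimination item: effective difficulty must fall
        # with the total score more slowly than for its peers, so its sigma
        # (difficulty parameterisation) is the clear maximum, many SEs from 0
        z = spm01_im.sigma / spm01_im.se_sigma
        assert np.argmax(spm01_im.sigma) == 0
        assert z[0] > 3
        assert spm01_im.sigma[0] > spm01_im.sigma[1:].max() + 0.05

    def test_unidentified_sigma_raises(self):
        # every interior person shares total 1
        mat = binary_matrix([[1, 0], [0, 1], [0, 0], [1, 1], [1, 0]])
        with pytest.raises(ValueError, match="unidentified"):
            fit_interaction(mat)

    def test_lambda_is_observed_score_distribution(self, rasch_data, im_fit):
        _, mat = rasch_data
        assert np.allclose(im_fit.lambda_, score_distribution(mat) / mat.n_persons)

    def test_constraints_hold(self, im_fit):
        assert abs(np.concatenate(im_fit.beta).mean()) < 1e-10
        assert abs(im_fit.sigma.mean()) < 1e-10

    def test_json_round_trip(self, im_fit, tmp_path):
        path = tmp_path / "im.json"
        im_fit.to_json(path)
        back = IMParams.from_json(path)
        assert np.allclose(back.sigma, im_fit.sigma)
        assert np.allclose(back.lambda_, im_fit.lambda_)


class TestITR:
    def test_zero_sigma_reduces_to_rasch(self, rasch_fit):
        im = IMParams.binary(
            rasch_fit.items,
            rasch_fit.beta_flat,
            np.zeros(12),
            np.full(13, 1 / 13),
        )
        for s in range(13):
            assert np.allclose(im_itr(im, s), rasch_itr(rasch_fit, s), atol=1e-12)

    def test_endpoints_are_forced(self, im_fit):
        S = im_fit.S
        assert np.array_equal(im_itr(im_fit, 0), np.zeros(12))
        assert np.array_equal(im_itr(im_fit, S), im_fit.max_scores.astype(float))

    def test_conservation_of_conditioning_total(self, im_fit):
        table = im_itr_table(im_fit)
        assert np.max(np.abs(table.sum(axis=1) - np.arange(im_fit.S + 1))) < 1e-9

    def test_matches_enumeration_on_toy_parameters(self):
        beta = np.array([-0.6, 0.1, 0.5])
        sigma = np.array([-0.15, 0.05, 0.10])
        im = IMParams.binary(("a", "b", "c"), beta, sigma, np.full(4, 0.25))
        for s in range(4):
            w = [np.array([1.0, np.exp(-(b + g * s))]) for b, g in zip(beta, sigma)]
            oracle = expected_given_total_enumerate(w, s)
            assert np.allclose(im_itr(im, s), oracle, atol=1e-10)

    def test_location_invariance(self):
        beta = np.array([-0.6, 0.1, 0.5])
        sigma = np.array([-0.15, 0.05, 0.10])
        lam = np.full(4, 0.25)
        base = IMParams.binary(("a", "b", "c"), beta, sigma, lam)
        shifted = IMParams.binary(("a", "b", "c"), beta + 0.7, sigma - 0.3, lam)
        for s in range(4):
            assert np.allclose(im_itr(base, s), im_itr(shifted, s), atol=1e-12)


class TestLoglik:
    def test_nesting_on_fitted_models(self, rasch_fit, im_fit):
        assert im_fit.loglik >= rasch_fit.loglik

    def test_reduces_to_rasch_loglik_at_zero_sigma(self, rasch_data, rasch_fit):
        _, mat = rasch_data
        im = IMParams.binary(
            rasch_fit.items,
            rasch_fit.beta_flat,
            np.zeros(12),
            score_distribution(mat) / mat.n_persons,
        )
        assert im_loglik(im, mat) == pytest.approx(rasch_fit.loglik, abs=1e-9)

    def test_matches_hand_expanded_sum_on_toy_data(self):
        scores = np.array(
            [[1, 0, 0], [1, 1, 0], [0, 1, 1], [1, 1, 1], [0, 0, 1], [1, 0, 1]]
        )
        mat = binary_matrix(scores)
        beta = np.array([-0.4, 0.1, 0.3])
        sigma = np.array([0.05, -0.1, 0.05])
        im = IMParams.binary(("i0", "i1", "i2"), beta, sigma, np.full(4, 0.25))
        oracle = -im_conditional_nll_enumerate(beta, sigma, scores)
        assert im_loglik(im, mat) == pytest.approx(oracle, abs=1e-10)

    def test_fitted_value_consistent_with_loglik_function(self, rasch_data, im_fit):
        _, mat = rasch_data
        assert im_loglik(im_fit, mat) == pytest.approx(im_fit.loglik, abs=1e-8)
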