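import numpy as np
import pytest
from scipy.stats import binom

from itemlens import (
    AbilitySpec,
    ScoredMatrix,
    compare_itr,
    curtains,
    distractor_regression,
    empirical_itr,
    fit_interaction,
    fit_rasch_cml,
    im_itr_table,
    item_facility,
    rasch_itr_table,
    score_responses,
    simulate_choices,
    simulate_im,
    simulate_rasch,
    wrong_key_scenario,
)
from itemlens.pipeline import _interior_slope
from itemlens.simulate import ChoiceScenario, ItemScenario, OptionBehaviour, clean_scenario
from oracles import quantile_inverted_cdf


def binary_matrix(scores):
    scores = np.asarray(scores)
    return ScoredMatrix(
        persons=[f"p{k}" for k in range(scores.shape[0])],
        items=[f"i{k}" for k in range(scores.shape[1])],
        scores=scores,
        max_score=np.ones(scores.shape[1], dtype=int),
    )


class TestEmpiricalITR:
    def test_direct_counts(self):
        mat = binary_matrix([[1, 1], [1, 0], [0, 0]])
        grid, mean, n = empirical_itr(mat, "i0")
        assert np.array_equal(grid, [0, 1, 2])
        assert np.array_equal(n, [1, 1, 1])
        assert np.allclose(mean, [0.0, 1.0, 1.0])

    def test_perfect_total_forces_max_item_score(self, rasch_data):
        _, mat = rasch_data
        for item in mat.items[:3]:
            _, mean, n = empirical_itr(mat, item)
            if n[-1] > 0:
                assert mean[-1] == mat.max_score[mat.item_index(item)]

    def test_nan_where_no_persons(self):
        mat = binary_matrix([[1, 1], [1, 1], [0, 0]])
        _, mean, n = empirical_itr(mat, "i0")
        assert n[1] == 0 and np.isnan(mean[1])


class TestCurtains:
    def test_degenerate_distribution(self):
        counts = np.zeros(10)
        counts[4] = 37
        assert curtains(counts) == (4, 4)

    def test_totals_one_to_hundred(self):
        counts = np.bincount(np.arange(1, 101), minlength=101)
        assert curtains(counts) == (5, 95)

    def test_uniform_counts_match_oracle_quantiles(self):
        counts = np.full(11, 100)
        values = np.repeat(np.arange(11), 100)
        lo, hi = curtains(counts)
        assert lo == quantile_inverted_cdf(values, 0.05)
        assert hi == quantile_inverted_cdf(values, 0.95)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            curtains(np.ones(5), lower=0.0)
        with pytest.raises(ValueError):
            curtains(np.zeros(5))


class TestCompareITR:
    def test_all_three_curves_share_endpoints(self, rasch_data, rasch_fit, im_fit):
        _, mat = rasch_data
        curves = compare_itr(mat, rasch_fit, im_fit)
        assert np.allclose(curves.rasch[0], 0) and np.allclose(curves.im[0], 0)
        assert np.allclose(curves.rasch[-1], 1) and np.allclose(curves.im[-1], 1)
        if curves.n_s[0] > 0:
            assert np.allclose(curves.empirical[0], 0)
        if curves.n_s[-1] > 0:
            assert np.allclose(curves.empirical[-1], 1)

    def test_rasch_and_im_agree_on_rasch_data(self, rasch_data, rasch_fit, im_fit):
        _, mat = rasch_data
        curves = compare_itr(mat, rasch_fit, im_fit)
        sel = slice(curves.curtain_low, curves.curtain_high + 1)
        assert np.nanmax(np.abs(curves.im[sel] - curves.rasch[sel])) < 0.06

    def test_im_steeper_for_high_discrimination_item(self):
        # one 2PL item with slope 2.5 among unit-slope peers: the IM curve
        # crosses the Rasch curve from below
        rng = np.random.default_rng(314)
        theta = rng.normal(size=4000)
        slopes = np.concatenate(([2.5], np.ones(11)))
        diffs = np.linspace(-1.5, 1.5, 12)
        p = 1 / (1 + np.exp(-slopes * (theta[:, None] - diffs)))
        mat = binary_matrix((rng.random((4000, 12)) < p).astype(int))
        curves = compare_itr(mat, fit_rasch_cml(mat), fit_interaction(mat))
        gap = curves.im[:, 0] - curves.rasch[:, 0]
        assert gap[curves.curtain_low] < 0 < gap[curves.curtain_high]

    def test_empirical_points_average_to_facility(self, rasch_data, rasch_fit, im_fit):
        _, mat = rasch_data
        curves = compare_itr(mat, rasch_fit, im_fit)
        fac = item_facility(mat)
        w = curves.n_s.astype(float)
        for k in range(mat.n_items):
            y = np.where(np.isnan(curves.empirical[:, k]), 0.0, curves.empirical[:, k])
            assert (w * y).sum() / w.sum() == pytest.approx(fac[k], abs=1e-12)

    def test_empirical_within_binomial_bands_of_model(self, rasch_data, rasch_fit):
        # per-cell exact 99% binomial bands around the model curve; the
        # number of violating cells must stay inside the 99.5% envelope of
        # the nominal 1% per-cell error rate
        _, mat = rasch_data
        table = rasch_itr_table(rasch_fit)
        cells = violations = 0
        for k, item in enumerate(mat.items):
            _, mean, n = empirical_itr(mat, item)
            for s in range(1, mat.S):
                if n[s] >= 30:
                    cells += 1
                    lo = binom.ppf(0.005, n[s], table[s, k]) / n[s]
                    hi = binom.ppf(0.995, n[s], table[s, k]) / n[s]
                    if not lo <= mean[s] <= hi:
                        violations += 1
        assert cells > 50
        assert violations <= binom.ppf(0.995, cells, 0.01)

    def test_mismatched_parameters_rejected(self, rasch_data, rasch_fit, im_fit):
        _, mat = rasch_data
        small = ScoredMatrix(
            persons=mat.persons,
            items=mat.items[:6],
            scores=mat.scores[:, :6],
            max_score=mat.max_score[:6],
        )
        with pytest.raises(ValueError, match="items"):
            compare_itr(small, rasch_fit, im_fit)

    def test_empirical_converges_to_im_on_its_own_simulation(self, spm01_im):
        mat = simulate_im(spm01_im, 20000, seed=424242)
        table = im_itr_table(spm01_im)
        for k, item in enumerate(mat.items):
            _, mean, n = empirical_itr(mat, item)
            sel = n >= 1000
            # n-weighted RMS deviation: binomial noise at these cell sizes
            # stays well under 0.02 only in aggregate, not cell by cell
            rms = np.sqrt(np.average((mean[sel] - table[sel, k]) ** 2, weights=n[sel]))
            assert rms < 0.02


class TestDistractorRegression:
    def test_curves_sum_to_one_everywhere(self, spm01_run):
        records, rules, mat = spm01_run
        for item in mat.items[:4]:
            d = distractor_regression(records, rules, mat, item)
            total = np.sum([oc.probability for oc in d.options], axis=0)
            assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_option_chosen_by_everyone_has_unit_curve(self):
        import pandas as pd

        rules = pd.DataFrame(
            {"item": ["i0", "i0", "i1", "i1"], "response": ["k", "w", "k", "w"], "score": [1, 0, 1, 0]}
        )
        rng = np.random.default_rng(1)
        persons = [f"p{k}" for k in range(60)]
        rec = pd.DataFrame(
            {
                "person": persons * 2,
                "item": ["i0"] * 60 + ["i1"] * 60,
                "response": ["k"] * 60 + rng.choice(["k", "w"], 60).tolist(),
            }
        )
        mat = score_responses(rec, rules)
        d = distractor_regression(rec, rules, mat, "i0")
        assert len(d.options) == 1
        assert np.allclose(d.options[0].probability, 1.0)

    def test_flat_propensity_gives_flat_curves(self):
        # an item whose two always-wrong alternatives are chosen with fixed
        # probabilities (0.7, 0.3) independent of ability: curves must be
        # flat at those values inside the curtains
        flat_item = ItemScenario(
            "item00",
            "k",
            {
                "k": OptionBehaviour(-30.0, 0.0),  # key practically never chosen
                "a": OptionBehaviour(np.log(0.7), 0.0),
                "b": OptionBehaviour(np.log(0.3), 0.0),
            },
        )
        scenario = ChoiceScenario("flat", (flat_item,) + clean_scenario(11).items)
        records, rules, _ = simulate_choices(scenario, AbilitySpec(n_persons=10000), seed=5150)
        mat = score_responses(records, rules)
        d = distractor_regression(records, rules, mat, "item00")
        counts = np.bincount(mat.totals, minlength=mat.S + 1)
        lo, hi = curtains(counts)
        sel = np.zeros(mat.S + 1, dtype=bool)
        sel[lo : hi + 1] = True
        sel &= counts >= 100  # KDE ratios are only stable where the data live
        by_label = {oc.option: oc for oc in d.options}
        # per-cell envelope: four binomial standard errors of the option share
        env = 4 * np.sqrt(0.7 * 0.3 / counts[sel])
        assert np.all(np.abs(by_label["a"].probability[sel] - 0.7) < env)
        assert np.all(np.abs(by_label["b"].probability[sel] - 0.3) < env)

    def test_exercise_item_signature(self, spm01_run):
        # the dominant distractor rules the low totals and decays; the key rises
        records, rules, mat = spm01_run
        d = distractor_regression(records, rules, mat, "item01")
        lo, hi = curtains(np.bincount(mat.totals, minlength=mat.S + 1))
        by_label = {oc.option: oc for oc in d.options}
        key, dom = by_label["1"], by_label["2"]
        assert dom.probability[lo] > 0.5 > dom.probability[hi]
        assert key.probability[hi] > 0.8 > key.probability[lo]
        assert dom.probability[lo] > key.probability[lo]

    def test_never_chosen_options_are_omitted(self):
        import pandas as pd

        rules = pd.DataFrame(
            {
                "item": ["i0"] * 3 + ["i1"] * 2,
                "response": ["k", "w", "never", "k", "w"],
                "score": [1, 0, 0, 1, 0],
            }
        )
        rng = np.random.default_rng(8)
        persons = [f"p{k}" for k in range(40)]
        rec = pd.DataFrame(
            {
                "person": persons * 2,
                "item": ["i0"] * 40 + ["i1"] * 40,
                "response": rng.choice(["k", "w"], 80),
            }
        )
        mat = score_responses(rec, rules)
        d = distractor_regression(rec, rules, mat, "i0")
        assert {oc.option for oc in d.options} == {"k", "w"}

    def test_unknown_item_rejected(self, spm01_run):
        records, rules, mat = spm01_run
        with pytest.raises(KeyError, match="nope"):
            distractor_regression(records, rules, mat, "nope")


class TestWrongKeySlope:
    def test_mis_keyed_item_has_negative_interior_slope(self):
        records, rules, _ = simulate_choices(
            wrong_key_scenario(), AbilitySpec(n_persons=3000), seed=404
        )
        mat = score_responses(records, rules)
        curves = compare_itr(mat, fit_rasch_cml(mat), fit_interaction(mat))
        assert _interior_slope(curves, 5) < 0
        # clean neighbours keep positive slopes
        assert _interior_slope(curves, 3) > 0
        assert _interior_slope(curves, 8) > 0
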