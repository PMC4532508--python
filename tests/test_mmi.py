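import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from mmisdm import (
    AveragedModel,
    CandidateSet,
    FittedModel,
    aicc,
    akaike_weights,
    average_coefficients,
    confidence_set,
    enumerate_candidates,
    predict_averaged,
)

from conftest import irls_logistic, make_site_table


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(-21.02, 3, 102) == pytest.approx(42.04 + 6 + 24 / 98)

    def test_no_parameter_degenerate(self):
        assert aicc(-10.0, 0, 50) == pytest.approx(20.0)

    def test_limit_to_aic(self):
        aic = -2 * (-30.0) + 2 * 4
        assert aicc(-30.0, 4, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="n - K - 1"):
            aicc(-5.0, 10, 11)


class TestAkaikeWeights:
    def test_single_model(self):
        delta, w = akaike_weights([123.4])
        assert delta[0] == 0 and w[0] == 1.0

    def test_two_equal_models(self):
        _, w = akaike_weights([50.0, 50.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_all_infinite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.inf])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 500), min_size=1, max_size=30))
    def test_weight_axioms(self, values):
        delta, w = akaike_weights(values)
        assert delta.min() == 0.0
        assert np.all(w > 0) and np.all(w <= 1)
        assert w.sum() == pytest.approx(1.0)
        # weights ranked opposite to delta
        assert np.all(np.diff(w[np.argsort(delta)]) <= 1e-12)


class TestEnumeration:
    def test_six_predictors_yield_63_candidates(self, world):
        from mmisdm import screen_predictors, split_train_test

        _, _, sites = world
        retained = screen_predictors(sites).retained
        assert len(retained) == 6
        train, _ = split_train_test(sites, seed=0)
        cands = enumerate_candidates(train.select_predictors(retained))
        assert cands.n_models + len(cands.failed_subsets) == 63
        assert cands.n_models == 63
        assert np.all(np.diff(cands.aicc_values) >= 0)
        assert cands.delta[0] == 0.0
        assert cands.weights.sum() == pytest.approx(1.0)

    def test_single_predictor_single_model(self, trio_sites):
        cands = enumerate_candidates(trio_sites.select_predictors(["T1"]))
        assert cands.n_models == 1
        assert cands.weights[0] == 1.0 and cands.delta[0] == 0.0

    def test_brute_force_oracle_equivalence(self, trio_sites):
        """Ranking and weights match an independent subset-by-subset
        Newton refit to 1e-8 on the 3-predictor candidate set."""
        cands = enumerate_candidates(trio_sites)
        names = trio_sites.predictors
        x_all = trio_sites.predictor_matrix()
        y = trio_sites.presence
        n = trio_sites.n_sites
        oracle = []
        for size in range(1, 4):
            for subset in itertools.combinations(range(3), size):
                design = np.column_stack([np.ones(n), x_all[:, list(subset)]])
                _, _, llf = irls_logistic(design, y)
                k = len(subset) + 1
                oracle.append(
                    (tuple(names[i] for i in subset),
                     -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1))
                )
        oracle.sort(key=lambda t: t[1])
        assert [tuple(m.predictors) for m in cands.models] == [t[0] for t in oracle]
        np.testing.assert_allclose(cands.aicc_values,
                                   [t[1] for t in oracle], atol=1e-8)
        scores = np.array([t[1] for t in oracle])
        d = scores - scores.min()
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        np.testing.assert_allclose(cands.weights, w, atol=1e-8)


class TestConfidenceSet:
    def _cands(self, weights):
        weights = np.asarray(weights, dtype=float)
        models = [
            FittedModel([f"P{i}"], np.zeros(2), np.zeros((2, 2)), -1.0,
                        100, True, 1)
            for i in range(len(weights))
        ]
        delta = -2 * np.log(weights / weights.max())
        return CandidateSet(models=models, aicc_values=delta, delta=delta,
                            weights=weights)

    def test_prefix_reaching_level(self):
        cs = confidence_set(self._cands([0.6, 0.3, 0.08, 0.02]), 0.95)
        assert cs.in_confidence_set.tolist() == [True, True, True, False]
        np.testing.assert_allclose(cs.member_weight_values().sum(), 1.0)

    def test_level_one_keeps_all(self):
        cs = confidence_set(self._cands([0.6, 0.3, 0.08, 0.02]), 1.0)
        assert cs.in_confidence_set.all()

    def test_dominant_model_alone(self):
        cs = confidence_set(self._cands([0.96, 0.03, 0.01]), 0.95)
        assert cs.in_confidence_set.tolist() == [True, False, False]
        assert cs.member_weight_values()[0] == 1.0


def _hand_candidates():
    """Two single-predictor models on 'A' with known coefficients."""
    m1 = FittedModel(["A"], np.array([0.0, 1.0]), np.zeros((2, 2)),
                     -10.0, 100, True, 3)
    m2 = FittedModel(["A"], np.array([0.0, 3.0]), np.zeros((2, 2)),
                     -10.0, 100, True, 3)
    weights = np.array([0.5, 0.5])
    cands = CandidateSet(models=[m1, m2], aicc_values=np.zeros(2),
                         delta=np.zeros(2), weights=weights)
    return confidence_set(cands, 1.0)


class TestAveraging:
    def test_single_model_identity(self, trio_sites):
        cands = enumerate_candidates(trio_sites.select_predictors(["T1"]))
        cands = confidence_set(cands, 0.95)
        avg = average_coefficients(cands)
        m = cands.models[0]
        np.testing.assert_allclose(avg.estimates, m.coefficients)
        np.testing.assert_allclose(avg.unconditional_se, m.standard_errors,
                                   atol=1e-12)

    def test_two_model_hand_formulas(self):
        avg = average_coefficients(_hand_candidates())
        # θ̄ = 0.5·1 + 0.5·3 = 2 ; SE_u = sqrt(0.5·(1)² + 0.5·(1)²) = 1
        assert avg.estimates[1] == pytest.approx(2.0)
        assert avg.unconditional_se[1] == pytest.approx(1.0)
        np.testing.assert_allclose(avg.ci_lower[1], 2 - 1.96)
        np.testing.assert_allclose(avg.ci_upper[1], 2 + 1.96)

    def test_unconditional_se_dominates_within_only(self, trio_sites):
        cands = confidence_set(enumerate_candidates(trio_sites), 0.95)
        avg = average_coefficients(cands, order_hint=trio_sites.predictors)
        w = cands.member_weight_values()
        models = cands.member_models()
        for col, name in enumerate(["intercept"] + avg.predictors):
            ses = []
            for m in models:
                if name == "intercept":
                    ses.append(m.standard_errors[0])
                elif name in m.predictors:
                    ses.append(m.standard_errors[m.predictors.index(name) + 1])
                else:
                    ses.append(0.0)
            floor = np.sqrt(np.sum(w * np.square(ses)))
            assert avg.unconditional_se[col] >= floor - 1e-12

    def test_zero_substitution_shrinks_rare_predictor(self, trio_sites):
        cands = confidence_set(enumerate_candidates(trio_sites), 0.95)
        zero = average_coefficients(cands, mode="zero",
                                    order_hint=trio_sites.predictors)
        natural = average_coefficients(cands, mode="natural",
                                       order_hint=trio_sites.predictors)
        # T2 is a null predictor: zero-substitution pulls it toward 0
        j = zero.predictors.index("T2") + 1
        assert abs(zero.estimates[j]) <= abs(natural.estimates[j]) + 1e-12

    def test_averaged_estimate_within_member_range_without_zero_sub(self):
        avg = average_coefficients(_hand_candidates(), mode="natural")
        assert 1.0 <= avg.estimates[1] <= 3.0


class TestPredictAveraged:
    def test_single_model_weight_has_no_between_variance(self, trio_sites):
        cands = enumerate_candidates(trio_sites.select_predictors(["T1"]))
        cands = confidence_set(cands, 0.95)
        avg = average_coefficients(cands)
        pred = predict_averaged(cands, avg, {"T1": 0.3})
        assert pred.between_var == pytest.approx(0.0, abs=1e-15)
        assert pred.total_var == pytest.approx(pred.within_var)

    def test_identical_members_force_ci_width(self):
        m = FittedModel(["A"], np.array([-0.2, 0.5]),
                        np.array([[0.02, 0.0], [0.0, 0.05]]),
                        -10.0, 100, True, 3)
        cands = CandidateSet(models=[m, m], aicc_values=np.zeros(2),
                             delta=np.zeros(2), weights=np.array([0.5, 0.5]))
        cands = confidence_set(cands, 1.0)
        avg = average_coefficients(cands)
        pred = predict_averaged(cands, avg, {"A": 1.0})
        assert pred.between_var == pytest.approx(0.0, abs=1e-15)
        assert pred.ci_width == pytest.approx(
            2 * 1.96 * np.sqrt(pred.within_var)
        )

    def test_two_model_spreadsheet_oracle(self):
        cov1 = np.array([[0.04, 0.0], [0.0, 0.01]])
        cov2 = np.array([[0.09, 0.02], [0.02, 0.04]])
        m1 = FittedModel(["A"], np.array([-1.0, 2.0]), cov1, -10.0, 100, True, 3)
        m2 = FittedModel(["A"], np.array([0.5, -1.0]), cov2, -11.0, 100, True, 3)
        w = np.array([0.7, 0.3])
        cands = CandidateSet(models=[m1, m2], aicc_values=np.zeros(2),
                             delta=np.zeros(2), weights=w)
        cands = confidence_set(cands, 1.0)
        avg = average_coefficients(cands)
        x = 0.8
        pred = predict_averaged(cands, avg, {"A": x})
        # manual, term by term
        row = np.array([1.0, x])
        etas = np.array([row @ m1.coefficients, row @ m2.coefficients])
        ps = expit(etas)
        var_links = np.array([row @ cov1 @ row, row @ cov2 @ row])
        var_resp = var_links * (ps * (1 - ps)) ** 2
        within = float(w @ var_resp)
        p_bar = float(w @ ps)
        between = float(w @ (ps - p_bar) ** 2)
        mean = expit(avg.estimates[0] + avg.estimates[1] * x)
        assert pred.within_var == pytest.approx(within, abs=1e-12)
        assert pred.between_var == pytest.approx(between, abs=1e-12)
        assert pred.total_var == pytest.approx(within + between, abs=1e-12)
        assert pred.mean == pytest.approx(mean, abs=1e-12)
        lo = np.clip(mean - 1.96 * np.sqrt(within + between), 0, 1)
        hi = np.clip(mean + 1.96 * np.sqrt(within + between), 0, 1)
        assert pred.ci_lower == pytest.approx(lo) and pred.ci_upper == pytest.approx(hi)

    def test_variance_decomposition_invariants(self, trio_sites):
        cands = confidence_set(enumerate_candidates(trio_sites), 0.95)
        avg = average_coefficients(cands, order_hint=trio_sites.predictors)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 3))
        pred = predict_averaged(cands, avg, x)
        assert np.all(pred.within_var >= 0) and np.all(pred.between_var >= 0)
        assert np.all(pred.total_var >= pred.within_var - 1e-15)
        assert np.all(pred.total_var >= pred.between_var - 1e-15)
        assert np.all((pred.mean >= 0) & (pred.mean <= 1))
        assert np.all(pred.ci_lower <= pred.mean + 1e-12)
        assert np.all(pred.ci_upper >= pred.mean - 1e-12)
        assert np.all((pred.ci_lower >= 0) & (pred.ci_upper <= 1))


def test_empty_confidence_set_rejected():
    cands = CandidateSet(models=[], aicc_values=np.array([]),
                         delta=np.array([]), weights=np.array([]))
    with pytest.raises(ValueError):
        average_coefficients(cands)
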