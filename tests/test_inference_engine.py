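import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from potitecrm import (
    ObservedData,
    PriorBeta,
    beta_variance,
    build_adept_design,
    decide,
    estimate_dlt_probs,
    lowest_dose_overtox_prob,
    marginal_likelihood,
    ml_estimate,
    ordering_posteriors,
    posterior_mean_beta,
    psi,
    recommend_dose,
    select_ordering,
    weighted_likelihood,
)
from potitecrm.inference_engine import log_weighted_likelihood

from conftest import random_dataset

GRID, ORDERINGS, SKELETON = build_adept_design()
PRIOR = PriorBeta()


def brute_force_likelihood(beta, data, ordering=ORDERINGS[0], skeleton=SKELETON):
    """Term-by-term product, independent of the vectorised implementation."""
    alpha = skeleton.per_ordering_alpha(ordering)
    out = 1.0
    for x, y, w in zip(data.dose_idx, data.y, data.w):
        p = w * alpha[x] ** math.exp(beta)
        out *= p if y == 1 else (1.0 - p)
    return out


def grid_oracle_marginal(data, ordering, npts=20_001):
    """Trapezoid brute force on a fine grid over [-10, 10]."""
    b = np.linspace(-10, 10, npts)
    lik = np.array([brute_force_likelihood(bb, data, ordering) for bb in b])
    dens = lik * norm.pdf(b, 0.0, math.sqrt(PRIOR.variance))
    return np.trapezoid(dens, b), np.trapezoid(b * dens, b)


class TestWeightedLikelihood:
    def test_single_event_full_weight(self):
        data = ObservedData((4,), (1,), (1.0,))  # dose 2b, alpha 0.25
        assert weighted_likelihood(0.0, data, ORDERINGS[0], SKELETON) == pytest.approx(0.25)

    def test_single_nonevent_floor_weight(self):
        data = ObservedData((4,), (0,), (0.6,))
        assert weighted_likelihood(0.0, data, ORDERINGS[0], SKELETON) == pytest.approx(0.85)

    def test_empty_data_is_one(self):
        assert weighted_likelihood(1.3, ObservedData(), ORDERINGS[0], SKELETON) == 1.0

    def test_matches_brute_force_product(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = random_dataset(rng)
            beta = float(rng.uniform(-3, 3))
            got = weighted_likelihood(beta, data, ORDERINGS[1], SKELETON)
            want = brute_force_likelihood(beta, data, ORDERINGS[1])
            assert got == pytest.approx(want, rel=1e-10)

    def test_event_with_partial_weight_rejected(self):
        with pytest.raises(ValueError):
            ObservedData((0,), (1,), (0.8,))


class TestMarginalLikelihood:
    def test_empty_data_integrates_prior_to_one(self):
        assert marginal_likelihood(ObservedData(), ORDERINGS[0], SKELETON, PRIOR) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            data = random_dataset(rng)
            for o in ORDERINGS:
                want, _ = grid_oracle_marginal(data, o)
                got = marginal_likelihood(data, o, SKELETON, PRIOR)
                assert got == pytest.approx(want, rel=1e-6)

    def test_saturated_weights_reduce_to_binary_crm(self):
        # with w identically 1 the marginal equals the classic power-model
        # CRM evidence, computed here independently with adaptive quadrature
        data = ObservedData((1, 2, 3, 3), (0, 1, 0, 1), (1.0, 1.0, 1.0, 1.0))
        alpha = SKELETON.per_ordering_alpha(ORDERINGS[0])

        def integrand(b):
            p = alpha[np.array(data.dose_idx)] ** math.exp(b)
            y = np.array(data.y)
            lik = np.prod(p**y * (1 - p) ** (1 - y))
            return lik * norm.pdf(b, 0.0, math.sqrt(PRIOR.variance))

        want, _ = quad(integrand, -10, 10, epsrel=1e-10)
        got = marginal_likelihood(data, ORDERINGS[0], SKELETON, PRIOR)
        assert got == pytest.approx(want, rel=1e-7)


class TestOrderingPosteriors:
    def test_no_data_returns_prior(self):
        post = ordering_posteriors(ObservedData(), ORDERINGS, SKELETON, PRIOR)
        assert post == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_shared_doses_leave_prior_unchanged(self):
        # doses -1, 0, 1, 3 carry identical skeleton values under both orders
        data = ObservedData((0, 1, 2, 5), (0, 1, 0, 1), (0.8, 1.0, 0.65, 1.0))
        post = ordering_posteriors(data, ORDERINGS, SKELETON, PRIOR)
        assert post == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_dlt_at_2a_favours_2a_more_toxic(self):
        i2a, i2b = GRID.index("2a"), GRID.index("2b")
        data = ObservedData((i2a, i2b), (1, 0), (1.0, 0.8))
        post = ordering_posteriors(data, ORDERINGS, SKELETON, PRIOR)
        # ordering 2 ranks 2a above 2b in toxicity
        assert post[1] > 0.5
        # cross-check against the brute-force grid marginals
        m = [grid_oracle_marginal(data, o)[0] for o in ORDERINGS]
        want = 0.5 * m[1] / (0.5 * m[0] + 0.5 * m[1])
        assert post[1] == pytest.approx(want, rel=1e-6)

    def test_normalised(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            post = ordering_posteriors(random_dataset(rng), ORDERINGS, SKELETON, PRIOR)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)


class TestSelectOrdering:
    def test_argmax(self):
        rng = np.random.default_rng(0)
        assert select_ordering(np.array([0.7, 0.3]), rng) == 0
        assert select_ordering(np.array([0.3, 0.3, 0.4]), rng) == 2

    def test_tie_is_reproducible_under_seed(self):
        picks = {select_ordering(np.array([0.5, 0.5]), np.random.default_rng(99)) for _ in range(5)}
        assert len(picks) == 1

    def test_tie_uses_rng(self):
        picks = {
            select_ordering(np.array([0.5, 0.5]), np.random.default_rng(s)) for s in range(40)
        }
        assert picks == {0, 1}


class TestPosteriorMeanBeta:
    def test_empty_data_gives_prior_mean(self):
        assert posterior_mean_beta(ObservedData(), ORDERINGS[0], SKELETON, PRIOR) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            data = random_dataset(rng)
            z, zb = grid_oracle_marginal(data, ORDERINGS[0])
            got = posterior_mean_beta(data, ORDERINGS[0], SKELETON, PRIOR)
            assert got == pytest.approx(zb / z, abs=1e-6)

    def test_consistency_at_skeleton_rate(self):
        # heavy fully-weighted data whose DLT fraction equals the skeleton
        # value pins beta near 0
        n, events = 60, 15  # dose 2b: alpha = 0.25
        data = ObservedData((4,) * n, (1,) * events + (0,) * (n - events), (1.0,) * n)
        assert abs(posterior_mean_beta(data, ORDERINGS[0], SKELETON, PRIOR)) < 0.1


def test_estimate_dlt_probs_mirrors_psi_and_is_monotone():
    for ordering in ORDERINGS:
        for beta in (-0.5, 0.0, 1.2):
            r = estimate_dlt_probs(beta, ordering, SKELETON)
            alpha = SKELETON.per_ordering_alpha(ordering)
            assert r == pytest.approx(psi(alpha, beta))
            # increasing along the ordering's toxicity rank
            assert np.all(np.diff(r[list(ordering.rank)]) > 0)


class TestRecommendDose:
    def test_examples(self):
        r = np.array([0.05, 0.12, 0.24, 0.33, 0.45, 0.6])
        assert recommend_dose(r, 0.25) == 2

    def test_tie_prefers_less_toxic(self):
        r = np.array([0.05, 0.20, 0.30, 0.5, 0.6, 0.7])
        assert recommend_dose(r, 0.25, ORDERINGS[0]) == 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            r = rng.uniform(0, 1, 6)
            want = int(np.argmin(np.abs(r - 0.25)))
            assert recommend_dose(r, 0.25, ORDERINGS[0]) == want

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            r = rng.uniform(0, 1, 6)
            perm = rng.permutation(6)
            direct = recommend_dose(r, 0.25)
            permuted = recommend_dose(r[perm], 0.25)
            assert perm[permuted] == direct


class TestBetaVariance:
    @staticmethod
    def analytic_second_derivative(beta, data, ordering=ORDERINGS[0]):
        import sympy as sp

        b = sp.Symbol("b")
        alpha = SKELETON.per_ordering_alpha(ordering)
        ll = 0
        for x, y, w in zip(data.dose_idx, data.y, data.w):
            p = sp.Rational(1) * w * sp.Float(alpha[x]) ** sp.exp(b)
            ll += y * sp.log(p) + (1 - y) * sp.log(1 - p)
        return float(sp.diff(ll, b, 2).subs(b, beta))

    def test_matches_analytic_curvature(self):
        data = ObservedData((2, 3, 4, 4, 1), (0, 1, 0, 1, 0), (0.8, 1.0, 0.6, 1.0, 0.9))
        beta_hat = posterior_mean_beta(data, ORDERINGS[0], SKELETON, PRIOR)
        v, fallback = beta_variance(data, ORDERINGS[0], SKELETON, beta_hat, PRIOR)
        assert not fallback
        d2 = self.analytic_second_derivative(beta_hat, data)
        assert v == pytest.approx(-1.0 / d2, rel=1e-4)

    def test_information_additivity(self):
        data = ObservedData((2, 3, 4), (0, 1, 0), (0.8, 1.0, 0.6))
        double = ObservedData(data.dose_idx * 2, data.y * 2, data.w * 2)
        b = posterior_mean_beta(data, ORDERINGS[0], SKELETON, PRIOR)
        v1, _ = beta_variance(data, ORDERINGS[0], SKELETON, b, PRIOR)
        v2, _ = beta_variance(double, ORDERINGS[0], SKELETON, b, PRIOR)
        assert v2 == pytest.approx(v1 / 2, rel=1e-6)

    def test_no_information_falls_back_to_prior(self):
        v, fallback = beta_variance(ObservedData(), ORDERINGS[0], SKELETON, 0.0, PRIOR)
        assert fallback and v == PRIOR.variance


class TestOvertoxProbability:
    def test_point_mass_above_threshold(self):
        # psi at the lowest dose = 0.5 > 0.35 and vanishing variance
        b = math.log(math.log(0.5) / math.log(0.01))
        p = lowest_dose_overtox_prob(
            b, 1e-12, ORDERINGS[0], SKELETON, rng=np.random.default_rng(0)
        )
        assert p == 1.0

    def test_half_at_threshold_crossing(self):
        b = math.log(math.log(0.35) / math.log(0.01))
        p = lowest_dose_overtox_prob(
            b, 0.3, ORDERINGS[0], SKELETON, n_draws=40_000, rng=np.random.default_rng(1)
        )
        assert p == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / 40_000))

    def test_matches_closed_form_normal_cdf(self):
        # psi is monotone decreasing in beta, so the event is beta* < b_cross
        rng = np.random.default_rng(7)
        for _ in range(10):
            beta_hat = float(rng.uniform(-3, 1))
            v = float(rng.uniform(0.05, 1.5))
            n = 20_000
            got = lowest_dose_overtox_prob(
                beta_hat, v, ORDERINGS[0], SKELETON, n_draws=n, rng=np.random.default_rng(123)
            )
            b_cross = math.log(math.log(0.35) / math.log(0.01))
            want = norm.cdf((b_cross - beta_hat) / math.sqrt(v))
            se = math.sqrt(max(want * (1 - want), 1e-6) / n)
            assert got == pytest.approx(want, abs=max(3 * se, 1e-3))


def test_ml_estimate_maximises_likelihood():
    rng = np.random.default_rng(17)
    for _ in range(10):
        data = random_dataset(rng)
        b = ml_estimate(data, ORDERINGS[0], SKELETON)
        ll = log_weighted_likelihood(b, data, ORDERINGS[0], SKELETON)
        for step in (-0.01, 0.01):
            if -10 <= b + step <= 10:
                assert ll >= log_weighted_likelihood(b + step, data, ORDERINGS[0], SKELETON) - 1e-9


def test_decide_pipeline_consistency():
    rng = np.random.default_rng(9)
    data = random_dataset(rng, max_n=12)
    out = decide(data, ORDERINGS, SKELETON, 0.25, PRIOR, rng=np.random.default_rng(1))
    assert sum(out.ordering_probs) == pytest.approx(1.0, abs=1e-9)
    h = out.selected_ordering
    assert out.beta_hat == pytest.approx(
        posterior_mean_beta(data, ORDERINGS[h], SKELETON, PRIOR), abs=1e-12
    )
    r = np.asarray(out.dlt_prob_hat)
    assert recommend_dose(r, 0.25, ORDERINGS[h]) == out.recommended_dose
    assert np.all((r > 0) & (r < 1))
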