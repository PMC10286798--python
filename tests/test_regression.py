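"""Polynomial efficiency regression: features, fitting, metrics, selection."""

import json
import math

import numpy as np
import pytest

import spectragrow as sg
from spectragrow.datasets import sample_fractions
from spectragrow.errors import ConstraintError, OutOfDomainWarning, SingularDesignError
from spectragrow.regression import (
    CANDIDATE_TERM_SETS,
    PolynomialEfficiencyModel,
    TermSet,
    gaussian_log_likelihood,
)


class TestTermSets:
    @pytest.mark.parametrize(
        "terms, k",
        [
            (TermSet((1,)), 4),
            (TermSet((1, 2)), 8),
            (TermSet((1, 2, 3)), 12),
            (TermSet((1, 2), interactions=True), 14),
            (TermSet((1, 2, 3, 4)), 16),
            (TermSet((1, 2, 3, 4), interactions=True), 22),
        ],
    )
    def test_feature_counts(self, terms, k):
        assert terms.n_features == k
        assert len(terms.feature_names()) == k

    def test_candidate_families_cover_studied_sizes(self):
        assert sorted(t.n_features for t in CANDIDATE_TERM_SETS) == [4, 8, 12, 14, 16]


class TestBuildFeatures:
    def test_pure_red_activates_only_red_powers(self):
        feats = sg.build_features([0, 0, 1, 0], TermSet((1, 2, 3, 4)))
        assert feats.shape == (16,)
        red_idx = [2, 6, 10, 14]  # power-major: red is the third band in each block
        for i, val in enumerate(feats):
            assert val == (1.0 if i in red_idx else 0.0)

    def test_full_menu_has_22_terms_6_interactions(self):
        terms = TermSet((1, 2, 3, 4), interactions=True)
        feats = sg.build_features([0.25, 0.25, 0.25, 0.25], terms)
        assert feats.shape == (22,)
        np.testing.assert_allclose(feats[16:], 0.0625)

    @pytest.mark.parametrize(
        "bad", [[0.5, 0.5, 0.5, 0.5], [0.2, 0.2, 0.2, 0.2], [-0.1, 0.4, 0.4, 0.3]]
    )
    def test_closure_violations_raise(self, bad):
        with pytest.raises(ConstraintError):
            sg.build_features(bad, TermSet((1,)))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert sg.r2_score(y, y) == 1.0
        assert sg.mape(y, y) == 0.0

    def test_r2_hand_value(self):
        assert sg.r2_score([1, 2, 3], [1, 2, 2]) == pytest.approx(0.5)

    def test_mape_hand_value(self):
        assert sg.mape([1, 2], [1.1, 1.8]) == pytest.approx(0.10)

    def test_r2_undefined_for_constant_targets(self):
        with pytest.raises(ValueError):
            sg.r2_score([2.0, 2.0], [1.0, 3.0])

    def test_r2_matches_sklearn(self, rng):
        from sklearn.metrics import r2_score as sk_r2

        y = rng.normal(size=30)
        y_hat = y + rng.normal(scale=0.3, size=30)
        assert sg.r2_score(y, y_hat) == pytest.approx(sk_r2(y, y_hat))


class TestInformationCriteria:
    def test_hand_computed_gaussian_likelihood(self):
        residuals = [0.1, -0.1, 0.2, -0.2]
        n, k = 4, 2
        sigma2 = (0.01 + 0.01 + 0.04 + 0.04) / 4
        ll = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1)
        assert gaussian_log_likelihood(residuals) == pytest.approx(ll)
        aic, bic = sg.information_criteria(residuals, k)
        assert aic == pytest.approx(2 * (k + 1) - 2 * ll)
        assert bic == pytest.approx(math.log(n) * (k + 1) - 2 * ll)

    def test_swapped_mode_matches_published_convention(self):
        residuals = [0.3, -0.2, 0.15, -0.4, 0.1]
        aic_c, bic_c = sg.information_criteria(residuals, 3, mode="conventional")
        aic_p, bic_p = sg.information_criteria(residuals, 3, mode="as_printed")
        assert aic_p == pytest.approx(bic_c)
        assert bic_p == pytest.approx(aic_c)

    def test_both_modes_penalize_extra_features(self):
        residuals = [0.1, -0.2, 0.15, -0.05, 0.2, -0.1]
        for mode in ("conventional", "as_printed"):
            aic2, bic2 = sg.information_criteria(residuals, 2, mode=mode)
            aic5, bic5 = sg.information_criteria(residuals, 5, mode=mode)
            assert aic5 > aic2 and bic5 > bic2

    def test_zero_residuals_degenerate(self):
        with pytest.raises(ValueError):
            sg.information_criteria([0.0, 0.0, 0.0], 1)


def _jitter_closure(rng, fractions, scale=2e-7):
    """Perturb fractions within the closure tolerance.

    Exactly-closed compositions leave the intercept unidentified (it equals
    the sum of the first-order features), so coefficient-recovery checks use
    fractions whose sum deviates from one at rounding level, as integrated
    spectra do in practice."""
    return np.clip(fractions + rng.uniform(-scale, scale, size=fractions.shape), 0.0, 1.0)


class TestStructuralRank:
    @pytest.mark.parametrize(
        "terms, rank",
        [
            (TermSet((1,)), 4),
            (TermSet((1, 2)), 8),
            (TermSet((1, 2, 3)), 12),
            (TermSet((1, 2), interactions=True), 10),
            (TermSet((1, 2, 3, 4)), 16),
        ],
    )
    def test_closure_dependencies_counted(self, terms, rank):
        """Closure removes one coefficient; squares+interactions remove four
        more through F_i = F_i^2 + sum_j F_i F_j."""
        assert sg.structural_rank(terms) == rank


class TestFit:
    def _toy_data(self, rng, n, terms, coefs, intercept):
        fractions = _jitter_closure(rng, sample_fractions(rng, n))
        design = np.vstack([sg.build_features(row, terms) for row in fractions])
        y = intercept + design @ coefs
        return fractions, y

    def test_noiseless_weight_recovery(self, rng):
        terms = TermSet((1, 2))
        coefs = rng.normal(scale=1e-4, size=terms.n_features)
        fractions, y = self._toy_data(rng, 40, terms, coefs, 2e-5)
        model = sg.fit(fractions, y, terms).model
        assert model.intercept == pytest.approx(2e-5, rel=1e-6)
        np.testing.assert_allclose(model.coefficients, coefs, rtol=1e-6, atol=1e-12)

    def test_ols_matches_normal_equations_oracle(self, rng):
        # powers (2, 3) carry no closure dependency, so the normal equations
        # are well conditioned and give an independent reference solution
        terms = TermSet((2, 3))
        fractions = sample_fractions(rng, 25)
        y = rng.normal(loc=1.3e-5, scale=2e-6, size=25)
        fitted = sg.fit(fractions, y, terms)
        feats = np.vstack([sg.build_features(r, terms) for r in fractions])
        design = np.column_stack([np.ones(25), feats])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert fitted.model.intercept == pytest.approx(beta[0], rel=1e-9)
        np.testing.assert_allclose(fitted.model.coefficients, beta[1:], rtol=1e-9)

    def test_zero_ridge_equals_ols(self, rng):
        terms = TermSet((2,))
        fractions = sample_fractions(rng, 30)
        y = rng.normal(loc=1.3e-5, scale=2e-6, size=30)
        ols = sg.fit(fractions, y, terms)
        ridge = sg.fit(fractions, y, terms, penalty="ridge", penalty_weight=0.0)
        np.testing.assert_allclose(
            ridge.model.coefficients, ols.model.coefficients, rtol=1e-7
        )

    def test_underdetermined_without_penalty_raises(self, rng):
        terms = TermSet((1, 2, 3, 4))
        fractions = sample_fractions(rng, 10)
        with pytest.raises(SingularDesignError):
            sg.fit(fractions, np.ones(10) * 1e-5, terms)

    def test_ri_normalization_round_trip(self, rng):
        """Fitting c_eps/RI and predicting with RI rescaling is consistent."""
        truth = sg.published_model()
        fractions = sample_fractions(rng, 30, domain=truth.domain)
        irr = rng.uniform(30.0, 42.0, size=30)
        ce = truth.predict_many(fractions, irr)
        fitted = sg.fit(
            fractions, ce, truth.terms, irradiance_w_m2=irr, normalize="ri"
        )
        np.testing.assert_allclose(
            fitted.model.predict_many(fractions, irr), ce, rtol=1e-8
        )


class TestSelectModel:
    def test_single_candidate_is_best(self, rng):
        terms = TermSet((1,))
        fractions = sample_fractions(rng, 20)
        y = rng.normal(loc=1.3e-5, scale=1e-6, size=20)
        table, models = sg.select_model([terms], fractions, y)
        assert len(table) == 1 and models[0].terms == terms

    def test_quartic_truth_ranks_above_linear(self, rng):
        truth = sg.published_model()
        fractions = sample_fractions(rng, 60, domain=truth.domain)
        y = np.array([truth.polynomial_value(f) for f in fractions])
        y = y + rng.normal(scale=1e-8, size=60)
        idx = rng.permutation(60)
        table, _ = sg.select_model(
            [TermSet((1,)), TermSet((1, 2, 3, 4))],
            fractions, y, train_idx=idx[:45], test_idx=idx[45:],
        )
        assert table.iloc[0]["k"] == 16


class TestPublishedModel:
    def test_pure_red_reference_prediction(self):
        model = sg.published_model()
        assert model.predict([0, 0, 1, 0], 32.8) == pytest.approx(1.3e-5, rel=1e-9)

    def test_pure_blue_extrapolation_warns(self):
        model = sg.published_model()
        with pytest.warns(OutOfDomainWarning):
            value = model.predict([1, 0, 0, 0], 32.8)
        assert value == pytest.approx(3.15e-4, rel=1e-9)

    def test_closure_violation_raises(self):
        with pytest.raises(ConstraintError):
            sg.published_model().predict([0.5, 0.5, 0.5, 0.5], 32.8)

    def test_linear_in_total_irradiance(self):
        model = sg.published_model()
        f = [0.15, 0.13, 0.62, 0.10]
        base = model.predict(f, 32.8)
        assert model.predict(f, 65.6) == pytest.approx(2.0 * base)

    def test_polynomial_consistent_with_feature_ordering(self):
        """The packaged coefficients applied to build_features reproduce predict."""
        model = sg.published_model()
        f = np.array([0.157, 0.129, 0.615, 0.099])
        f = f / f.sum()
        by_hand = model.intercept + sg.build_features(f, model.terms) @ model.coefficients
        assert model.polynomial_value(f) == pytest.approx(by_hand, rel=1e-12)

    def test_json_round_trip(self, tmp_path):
        model = sg.published_model()
        d = model.to_dict()
        back = PolynomialEfficiencyModel.from_dict(json.loads(json.dumps(d)))
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.terms == model.terms
        assert back.i_ref_w_m2 == model.i_ref_w_m2
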