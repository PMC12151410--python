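"""Unit and property tests for the per-feature score layers."""

import statistics

import numpy as np
import pytest

from mwrds import (
    ExpressionMatrix,
    LabelVector,
    combine_scores,
    compute_feature_class_stats,
    compute_imbalance_profile,
    compute_stability_weights,
    fit_margin_weights,
    robust_discriminant_scores,
)
from mwrds.exceptions import (
    AlignmentError,
    ConfigurationError,
    InsufficientClassError,
    ValidationError,
)

from conftest import random_dataset


def brute_force_phi(X, labels, eps=1e-8):
    """Scalar-loop evaluation of the robust discriminant score.

    Independent of the vectorized implementation: plain Python loops and
    the statistics module only.
    """
    mask = labels.minority_mask
    n_min = int(mask.sum())
    n_maj = len(labels) - n_min
    tau = n_min / n_maj
    out = []
    for j in range(X.n_features):
        col = [float(v) for v in X.values[:, j]]
        minority = [v for v, m in zip(col, mask) if m]
        majority = [v for v, m in zip(col, mask) if not m]
        eta_p = statistics.median(minority)
        eta_m = statistics.median(majority)
        zeta = statistics.median(col)
        theta_p = sum(abs(v - eta_p) for v in minority) / len(minority)
        theta_m = sum(abs(v - eta_m) for v in majority) / len(majority)
        var_p = statistics.variance(minority)
        var_m = statistics.variance(majority)
        u_p = 1.0 / max(var_p, eps)
        u_m = 1.0 / max(var_m, eps)
        num = u_p * (1 + tau) * abs(eta_p - zeta) + u_m * abs(eta_m - zeta)
        den = u_p * (1 + tau) * theta_p + u_m * theta_m
        out.append(num / max(den, eps))
    return np.array(out)


def pipeline_phi(X, labels, eps=1e-8):
    profile = compute_imbalance_profile(labels)
    stats = compute_feature_class_stats(X, labels)
    weights = compute_stability_weights(stats, eps)
    return robust_discriminant_scores(stats, weights, profile, eps)


class TestImbalanceProfile:
    def test_counts_and_tau_on_9_to_1(self):
        labels = LabelVector(np.array(["p"] * 10 + ["n"] * 90), positive_label="p")
        prof = compute_imbalance_profile(labels)
        assert (prof.n_minority, prof.n_majority) == (10, 90)
        assert prof.tau == pytest.approx(10 / 90)

    def test_balanced_classes_give_tau_one_with_positive_as_minority(self):
        labels = LabelVector(np.array(["a"] * 5 + ["b"] * 5), positive_label="b")
        prof = compute_imbalance_profile(labels)
        assert prof.tau == 1.0
        assert labels.minority_label == "b"

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            LabelVector(np.array(["n"] * 100))


class TestFeatureClassStats:
    def test_toy_values(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        assert st.median_minority[0] == 2.0
        assert st.median_majority[0] == 9.0
        assert st.median_pooled[0] == 7.5
        assert st.mad_minority[0] == pytest.approx(2 / 3)
        assert st.mad_majority[0] == pytest.approx(1.2)
        assert st.var_minority[0] == pytest.approx(1.0)
        assert st.var_majority[0] == pytest.approx(2.5)

    def test_constant_feature_has_zero_spread(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        assert st.median_minority[1] == st.median_majority[1] == st.median_pooled[1] == 4.0
        assert st.mad_minority[1] == st.mad_majority[1] == 0.0
        assert st.var_minority[1] == st.var_majority[1] == 0.0

    @pytest.mark.parametrize("shift", [-3.5, 0.0, 11.0])
    def test_translation_shifts_medians_only(self, toy_matrix, shift):
        X, labels = toy_matrix
        st0 = compute_feature_class_stats(X, labels)
        Xs = ExpressionMatrix(X.values + shift, feature_ids=X.feature_ids)
        st1 = compute_feature_class_stats(Xs, labels)
        np.testing.assert_allclose(st1.median_pooled, st0.median_pooled + shift)
        np.testing.assert_allclose(st1.median_minority, st0.median_minority + shift)
        np.testing.assert_allclose(st1.mad_minority, st0.mad_minority)
        np.testing.assert_allclose(st1.var_majority, st0.var_majority)

    def test_tiny_class_rejected(self):
        X = ExpressionMatrix(np.arange(8.0).reshape(4, 2))
        labels = LabelVector(np.array(["m", "M", "M", "M"]), positive_label="m")
        with pytest.raises(InsufficientClassError):
            compute_feature_class_stats(X, labels)


class TestStabilityWeights:
    def test_reciprocal_of_variance(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        w = compute_stability_weights(st)
        assert w.weight_minority[0] == pytest.approx(1.0)
        assert w.weight_majority[0] == pytest.approx(0.4)

    def test_zero_variance_floored_by_eps(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        w = compute_stability_weights(st, eps=1e-8)
        assert w.weight_minority[1] == pytest.approx(1e8)

    def test_scaling_a_feature_divides_weights_by_a_squared(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        w0 = compute_stability_weights(st)
        X2 = ExpressionMatrix(X.values * 2.0, feature_ids=X.feature_ids)
        w2 = compute_stability_weights(compute_feature_class_stats(X2, labels))
        assert w2.weight_minority[0] == pytest.approx(w0.weight_minority[0] / 4)
        assert w2.weight_majority[0] == pytest.approx(w0.weight_majority[0] / 4)

    def test_nonpositive_eps_rejected(self, toy_matrix):
        X, labels = toy_matrix
        st = compute_feature_class_stats(X, labels)
        with pytest.raises(ConfigurationError):
            compute_stability_weights(st, eps=0.0)


class TestRobustDiscriminantScore:
    def test_toy_value(self, toy_matrix):
        # hand evaluation with tau=3/5: (1*1.6*5.5 + 0.4*1.5)/(1.6*(2/3) + 0.48)
        X, labels = toy_matrix
        phi = pipeline_phi(X, labels)
        assert phi.scores[0] == pytest.approx(9.4 / (1.6 * 2 / 3 + 0.48), rel=1e-12)
        assert phi.scores[0] == pytest.approx(6.0775862069, rel=1e-6)

    def test_symmetric_noise_scores_zero_when_medians_coincide(self):
        # minority and majority medians equal to pooled median -> numerator 0
        values = np.array([[-1.0], [1.0], [0.0], [-2.0], [2.0], [0.0]])
        X = ExpressionMatrix(values)
        labels = LabelVector(np.array(["m", "m", "m", "M", "M", "M"]),
                             positive_label="m")
        phi = pipeline_phi(X, labels)
        assert phi.scores[0] == 0.0

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_scalar_brute_force(self, seed):
        X, labels = random_dataset(seed)
        vec = pipeline_phi(X, labels).scores
        ref = brute_force_phi(X, labels)
        np.testing.assert_allclose(vec, ref, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        X, labels = random_dataset(seed)
        a = rng.uniform(0.1, 10.0, size=X.n_features)
        c = rng.normal(scale=5.0, size=X.n_features)
        Xt = ExpressionMatrix(X.values * a + c, feature_ids=X.feature_ids)
        np.testing.assert_allclose(
            pipeline_phi(Xt, labels).scores,
            pipeline_phi(X, labels).scores,
            rtol=0, atol=1e-9,
        )

    @pytest.mark.parametrize("seed", range(30))
    def test_non_negative(self, seed):
        X, labels = random_dataset(500 + seed)
        assert (pipeline_phi(X, labels).scores >= 0).all()

    def test_balanced_case_carries_minority_factor_two(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(10, 4))
        X = ExpressionMatrix(values)
        labels = LabelVector(np.array(["m"] * 5 + ["M"] * 5), positive_label="m")
        prof = compute_imbalance_profile(labels)
        assert prof.tau == 1.0
        st = compute_feature_class_stats(X, labels)
        w = compute_stability_weights(st)
        phi = robust_discriminant_scores(st, w, prof)
        # explicit factor-2 evaluation of the same statistic
        num = (
            w.weight_minority * 2.0 * np.abs(st.median_minority - st.median_pooled)
            + w.weight_majority * np.abs(st.median_majority - st.median_pooled)
        )
        den = w.weight_minority * 2.0 * st.mad_minority + w.weight_majority * st.mad_majority
        np.testing.assert_allclose(phi.scores, num / np.maximum(den, 1e-8))

    def test_signal_feature_outranks_null_feature_in_most_replicates(self):
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=(60, 2))
            values[:10, 0] += 1.5  # feature 1 shifted in the minority class
            X = ExpressionMatrix(values)
            labels = LabelVector(np.array(["m"] * 10 + ["M"] * 50),
                                 positive_label="m")
            phi = pipeline_phi(X, labels).scores
            wins += phi[0] > phi[1]
        assert wins > n_rep / 2

    def test_mismatched_feature_sets_rejected(self, toy_matrix):
        X, labels = toy_matrix
        prof = compute_imbalance_profile(labels)
        st = compute_feature_class_stats(X, labels)
        w = compute_stability_weights(st)
        other = ExpressionMatrix(X.values, feature_ids=("a", "b"))
        st2 = compute_feature_class_stats(other, labels)
        with pytest.raises(AlignmentError):
            robust_discriminant_scores(st2, w, prof)


class TestMarginWeights:
    def test_two_point_closed_form(self):
        # maximum-margin solution for points at 0 and 2 on axis 1: omega=(1, 0)
        values = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        X = ExpressionMatrix(values)
        labels = LabelVector(np.array(["n", "n", "p", "p"]), positive_label="p")
        m = fit_margin_weights(X, labels, cost=1e6, standardize=False)
        assert m.omega[0] == pytest.approx(1.0, rel=1e-6)
        assert m.omega[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_gets_zero_weight(self, toy_matrix):
        X, labels = toy_matrix
        m = fit_margin_weights(X, labels, standardize=False)
        assert m.omega[1] == pytest.approx(0.0, abs=1e-10)

    def test_refit_is_bit_identical(self, small_signal_dataset):
        sim = small_signal_dataset
        m1 = fit_margin_weights(sim.X, sim.labels)
        m2 = fit_margin_weights(sim.X, sim.labels)
        assert np.array_equal(m1.omega, m2.omega)
        assert np.array_equal(m1.support_indices, m2.support_indices)

    def test_omega_assembly_matches_primal_coefficients(self, small_signal_dataset):
        # sum_a gamma_a y_a x_a must equal the solver's primal weight vector
        from sklearn.svm import SVC

        sim = small_signal_dataset
        m = fit_margin_weights(sim.X, sim.labels, standardize=False)
        svc = SVC(kernel="linear", C=1.0).fit(sim.X.values, sim.labels.signed())
        np.testing.assert_allclose(m.omega, svc.coef_[0], atol=1e-10)

    def test_dual_coefficients_non_negative(self, small_signal_dataset):
        sim = small_signal_dataset
        m = fit_margin_weights(sim.X, sim.labels)
        assert (m.dual_coefs >= 0).all()
        assert m.n_support >= 2

    def test_bad_cost_rejected(self, toy_matrix):
        X, labels = toy_matrix
        with pytest.raises(ConfigurationError):
            fit_margin_weights(X, labels, cost=-1.0)


class TestCombinedScore:
    def test_absolute_product(self, toy_matrix):
        from mwrds.containers import MarginModel, ScoreVector

        phi = ScoreVector(np.array([2.0, 0.5]), ("f1", "f2"), "phi")
        margin = MarginModel(
            feature_ids=("f1", "f2"),
            omega=np.array([-3.0, 0.0]),
            dual_coefs=np.array([0.5, 0.5]),
            support_indices=np.array([0, 1]),
            intercept=0.0,
        )
        psi = combine_scores(phi, margin)
        np.testing.assert_allclose(psi.scores, [6.0, 0.0])

    def test_zero_phi_annihilates(self):
        from mwrds.containers import MarginModel, ScoreVector

        phi = ScoreVector(np.zeros(3), ("a", "b", "c"), "phi")
        margin = MarginModel(("a", "b", "c"), np.array([5.0, -2.0, 1e9]),
                             np.array([1.0, 1.0]), np.array([0, 1]), 0.0)
        assert (combine_scores(phi, margin).scores == 0).all()

    def test_invariant_to_global_sign_flip_of_omega(self, small_signal_dataset):
        sim = small_signal_dataset
        phi = pipeline_phi(sim.X, sim.labels)
        m = fit_margin_weights(sim.X, sim.labels)
        from dataclasses import replace

        flipped = replace(m, omega=-m.omega)
        np.testing.assert_array_equal(
            combine_scores(phi, m).scores, combine_scores(phi, flipped).scores
        )

    def test_alignment_checked(self, small_signal_dataset):
        from mwrds.containers import ScoreVector

        sim = small_signal_dataset
        m = fit_margin_weights(sim.X, sim.labels)
        phi = ScoreVector(np.ones(2), ("x", "y"), "phi")
        with pytest.raises(AlignmentError):
            combine_scores(phi, m)
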