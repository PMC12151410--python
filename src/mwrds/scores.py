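"""Robust discriminant and margin-weighted feature scores.

The scoring statistic works in three layers:

1. A robust discriminant score per feature,

       Phi_b = [v+_b (1+tau) |eta+_b - zeta_b| + v-_b |eta-_b - zeta_b|]
               / [v+_b (1+tau) theta+_b + v-_b theta-_b]

   where eta+/eta- are the class medians, zeta the pooled median, theta the
   mean absolute deviations about the class medians, v = 1/variance the
   class stability weights, and tau = k+/k- the minority amplification
   factor. The (1+tau) factor boosts the minority-class terms so that rare
   class structure is not swamped by the majority class.

2. A margin weight per feature, the linear soft-margin SVM primal vector
   assembled from dual coefficients and support vectors:
   omega = sum_a gamma_a y_a x_a.

3. The combined score Psi_b = |Phi_b * omega_b| used for ranking.

All operations validate feature alignment and are deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from .containers import (
    ExpressionMatrix,
    FeatureClassStats,
    ImbalanceProfile,
    LabelVector,
    MarginModel,
    ScoreVector,
    StabilityWeights,
)
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    FitFailureError,
    InsufficientClassError,
    ValidationError,
)

DEFAULT_EPS = 1e-8


def _check_paired(X: ExpressionMatrix, labels: LabelVector) -> None:
    if len(labels) != X.n_samples:
        raise ValidationError(
            f"{len(labels)} labels for {X.n_samples} samples"
        )


def compute_imbalance_profile(labels: LabelVector) -> ImbalanceProfile:
    """Class counts and amplification factor tau = n_minority / n_majority.

    The rarer mark is the minority class; with equal counts tau = 1 and the
    positive mark is treated as minority.
    """
    mask = labels.minority_mask
    n_min = int(mask.sum())
    n_maj = int((~mask).sum())
    return ImbalanceProfile(n_min, n_maj, n_min / n_maj)


def compute_feature_class_stats(
    X: ExpressionMatrix, labels: LabelVector
) -> FeatureClassStats:
    """Per-feature class medians, pooled median, MAD and sample variance.

    MAD is the *mean* absolute deviation about the class median. Variance
    uses denominator n-1, hence each class needs at least 2 samples.
    """
    _check_paired(X, labels)
    mask = labels.minority_mask
    for name, m in (("minority", mask), ("majority", ~mask)):
        if m.sum() < 2:
            raise InsufficientClassError(
                f"{name} class has {int(m.sum())} samples; need >= 2"
            )
    Xmin = X.values[mask]
    Xmaj = X.values[~mask]
    eta_min = np.median(Xmin, axis=0)
    eta_maj = np.median(Xmaj, axis=0)
    zeta = np.median(X.values, axis=0)
    return FeatureClassStats(
        feature_ids=X.feature_ids,
        median_minority=eta_min,
        median_majority=eta_maj,
        median_pooled=zeta,
        mad_minority=np.mean(np.abs(Xmin - eta_min), axis=0),
        mad_majority=np.mean(np.abs(Xmaj - eta_maj), axis=0),
        var_minority=np.var(Xmin, axis=0, ddof=1),
        var_majority=np.var(Xmaj, axis=0, ddof=1),
    )


def compute_stability_weights(
    stats: FeatureClassStats, eps: float = DEFAULT_EPS
) -> StabilityWeights:
    """Inverse within-class variance weights v = 1 / max(var, eps).

    Features that are tight within a class get large weights; the epsilon
    floor keeps constant features finite rather than dropping them.
    """
    if eps <= 0:
        raise ConfigurationError(f"eps must be positive, got {eps}")
    return StabilityWeights(
        feature_ids=stats.feature_ids,
        weight_minority=1.0 / np.maximum(stats.var_minority, eps),
        weight_majority=1.0 / np.maximum(stats.var_majority, eps),
    )


def robust_discriminant_scores(
    stats: FeatureClassStats,
    weights: StabilityWeights,
    profile: ImbalanceProfile,
    eps: float = DEFAULT_EPS,
) -> ScoreVector:
    """The robust discriminant score Phi per feature (kind='phi')."""
    if stats.feature_ids != weights.feature_ids:
        raise AlignmentError("stats and weights cover different feature sets")
    if eps <= 0:
        raise ConfigurationError(f"eps must be positive, got {eps}")
    amp = 1.0 + profile.tau
    num = (
        weights.weight_minority * amp * np.abs(stats.median_minority - stats.median_pooled)
        + weights.weight_majority * np.abs(stats.median_majority - stats.median_pooled)
    )
    den = (
        weights.weight_minority * amp * stats.mad_minority
        + weights.weight_majority * stats.mad_majority
    )
    phi = num / np.maximum(den, eps)
    return ScoreVector(phi, stats.feature_ids, "phi")


def fit_margin_weights(
    X: ExpressionMatrix,
    labels: LabelVector,
    cost: float = 1.0,
    standardize: bool = True,
) -> MarginModel:
    """Fit a linear soft-margin SVM and assemble the margin weight vector.

    The minority class is coded +1. With ``standardize`` (default) each
    feature is z-scaled before the fit so the omega entries are comparable
    across genes of different scales; the scaling is recorded in
    ``preprocessing``. omega is assembled explicitly from the dual
    coefficients and support vectors, omega = sum_a gamma_a y_a x_a.
    """
    _check_paired(X, labels)
    if cost <= 0:
        raise ConfigurationError(f"cost must be positive, got {cost}")
    y = labels.signed()
    if (y == 1).sum() < 1 or (y == -1).sum() < 1:
        raise InsufficientClassError("both classes must be present")

    values = X.values
    preprocessing: dict = {"standardize": bool(standardize)}
    if standardize:
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        safe_std = np.where(std > 0, std, 1.0)
        values = (values - mean) / safe_std
        preprocessing.update(mean=mean, std=safe_std)

    svc = SVC(kernel="linear", C=cost)
    try:
        svc.fit(values, y)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise FitFailureError(f"linear SVM fit failed: {exc!r}") from exc
    if svc.fit_status_ != 0:
        raise FitFailureError(
            f"linear SVM did not converge (libsvm fit_status={svc.fit_status_})"
        )

    support = svc.support_
    signed_duals = svc.dual_coef_[0]  # = gamma_a * y_a
    gamma = np.abs(signed_duals)
    omega = signed_duals @ values[support]
    return MarginModel(
        feature_ids=X.feature_ids,
        omega=omega,
        dual_coefs=gamma,
        support_indices=support,
        intercept=float(svc.intercept_[0]),
        preprocessing=preprocessing,
    )


def combine_scores(phi: ScoreVector, margin: MarginModel) -> ScoreVector:
    """Combined score Psi_b = |Phi_b * omega_b| (kind='psi')."""
    if phi.kind != "phi":
        raise AlignmentError(f"expected a phi score vector, got kind={phi.kind!r}")
    if phi.feature_ids != margin.feature_ids:
        raise AlignmentError("phi and margin model cover different feature sets")
    return ScoreVector(np.abs(phi.scores * margin.omega), phi.feature_ids, "psi")
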