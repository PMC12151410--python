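"""Feature ranking, L1-logistic redundancy refinement, and the full selector.

Features are ranked by the combined score Psi, the top-d pool is refined
with an L1-penalized logistic regression (redundant features shrink to
zero), and the final gene set is the intersection of the pool with the
nonzero-coefficient set, ordered by rank and optionally backfilled to the
requested size.

:class:`MWRDSSelector` packages the whole pipeline as a scikit-learn
feature selector (``fit`` / ``transform`` / ``get_support``); the
module-level functions mirror the individual stages and
:func:`mwrds_select` is a thin wrapper that fits the estimator and returns
the rich :class:`SelectionResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import (
    ExpressionMatrix,
    LabelVector,
    MarginModel,
    ScoreVector,
)
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    EmptyRefinementError,
    FitFailureError,
    InsufficientClassError,
    StageError,
    ValidationError,
)
from .scores import (
    DEFAULT_EPS,
    combine_scores,
    compute_feature_class_stats,
    compute_imbalance_profile,
    compute_stability_weights,
    fit_margin_weights,
    robust_discriminant_scores,
)

#: lambda grid used for cross-validation and the step-down rescue,
#: descending so ties in CV deviance resolve to the sparser model.
LAMBDA_GRID = tuple(np.logspace(2, -3, 11))


@dataclass(frozen=True)
class SelectorConfig:
    """Configuration of the full selection pipeline.

    ``n_candidates`` is the size d of the top-ranked pool passed to the L1
    refinement; it defaults to ``max(5 * n_final, 50)`` (clamped to p at
    run time). ``lambda_policy`` is ``"cross_validated"`` or ``"fixed"``
    (the latter requires ``fixed_lambda``).
    """

    n_final: int = 10
    n_candidates: Optional[int] = None
    lambda_policy: str = "cross_validated"
    fixed_lambda: Optional[float] = None
    cv_folds: int = 5
    seed: int = 0
    backfill: bool = True
    svm_cost: float = 1.0
    standardize: bool = True
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if self.n_final < 1:
            raise ConfigurationError(f"n_final must be >= 1, got {self.n_final}")
        if self.lambda_policy not in ("cross_validated", "fixed"):
            raise ConfigurationError(
                f"lambda_policy must be 'cross_validated' or 'fixed', "
                f"got {self.lambda_policy!r}"
            )
        if self.lambda_policy == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda <= 0:
                raise ConfigurationError(
                    "fixed lambda policy requires fixed_lambda > 0"
                )
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds must be >= 2, got {self.cv_folds}")

    def resolved_n_candidates(self, n_features: int) -> int:
        d = self.n_candidates
        if d is None:
            d = max(5 * self.n_final, 50)
        if d < self.n_final:
            raise ConfigurationError(
                f"n_candidates={d} smaller than n_final={self.n_final}"
            )
        return min(d, n_features)


@dataclass(frozen=True)
class RankedFeatures:
    """Descending-Psi ordering and the top-d candidate pool."""

    order: np.ndarray          # permutation of feature indices
    scores: np.ndarray         # Psi values aligned to `order`
    feature_ids: tuple         # full feature id set, original order
    candidate_set: tuple       # top-d feature ids, rank order

    @property
    def candidate_indices(self) -> np.ndarray:
        return self.order[: len(self.candidate_set)]


@dataclass(frozen=True)
class SparseRefinement:
    """L1-logistic fit over the candidate pool."""

    candidate_ids: tuple
    beta: np.ndarray
    intercept: float
    lambda_used: float
    nonzero_set: tuple
    fit_probabilities: np.ndarray

    def __post_init__(self):
        if not set(self.nonzero_set) <= set(self.candidate_ids):
            raise ValidationError("nonzero_set must be a subset of candidate_ids")
        if self.lambda_used <= 0:
            raise ValidationError("lambda_used must be positive")


@dataclass(frozen=True)
class SelectionResult:
    """Final gene set with full stage provenance."""

    final_set: tuple
    ranked: RankedFeatures
    refinement: Optional[SparseRefinement]
    provenance: dict
    phi: Optional[ScoreVector] = None
    margin: Optional[MarginModel] = None
    psi: Optional[ScoreVector] = None

    @property
    def backfilled(self) -> tuple:
        return tuple(self.provenance.get("backfilled", ()))


def rank_features(psi: ScoreVector, d: int) -> RankedFeatures:
    """Rank features by descending score, ties broken by ascending index.

    The candidate pool is the first ``min(d, p)`` features; d > p clamps
    with a warning.
    """
    if d < 1:
        raise ConfigurationError(f"d must be >= 1, got {d}")
    p = len(psi)
    if p == 0:
        raise ValidationError("empty score vector")
    if d > p:
        warnings.warn(
            f"requested candidate pool d={d} exceeds p={p}; clamping to {p}",
            stacklevel=2,
        )
        d = p
    # stable sort on negated scores: equal scores keep ascending index order
    order = np.argsort(-psi.scores, kind="stable")
    return RankedFeatures(
        order=order,
        scores=psi.scores[order],
        feature_ids=psi.feature_ids,
        candidate_set=tuple(psi.feature_ids[i] for i in order[:d]),
    )


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    return (values - mean) / np.where(std > 0, std, 1.0)


def _dedup_columns(values: np.ndarray):
    """Map byte-identical columns to their first occurrence.

    Returns (unique column indices, inverse map full->unique). Exactly
    collinear duplicates carry no extra information, and L1 solvers split
    weight arbitrarily among them, so one representative (the
    highest-ranked) enters the fit and the duplicates keep coefficient 0.
    """
    seen: dict = {}
    keep: list = []
    inverse = np.empty(values.shape[1], dtype=int)
    for j in range(values.shape[1]):
        key = values[:, j].tobytes()
        if key in seen:
            inverse[j] = seen[key]
        else:
            seen[key] = len(keep)
            inverse[j] = len(keep)
            keep.append(j)
    return np.asarray(keep, dtype=int), inverse


def _fit_l1_logistic(values: np.ndarray, y01: np.ndarray, lam: float) -> LogisticRegression:
    lr = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        C=1.0 / lam,
        max_iter=5000,
        random_state=0,
    )
    try:
        lr.fit(values, y01)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise FitFailureError(f"L1 logistic fit failed at lambda={lam}: {exc!r}") from exc
    return lr


def _cv_deviance(values, y01, lam, cv_folds, seed) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    losses = []
    for tr, va in skf.split(values, y01):
        lr = _fit_l1_logistic(values[tr], y01[tr], lam)
        prob = lr.predict_proba(values[va])[:, 1]
        losses.append(log_loss(y01[va], prob, labels=[0, 1]))
    return float(np.mean(losses))


def l1_refine(
    X_sub: ExpressionMatrix, labels: LabelVector, config: SelectorConfig
) -> SparseRefinement:
    """L1-penalized logistic refinement of the candidate pool.

    Candidates are standardized so the penalty is scale-fair, and
    byte-identical columns are collapsed to one representative before the
    fit. Lambda comes from stratified cross-validated deviance
    (``cross_validated`` policy, with a step-down rescue if every
    coefficient vanishes) or is taken as given (``fixed`` policy, where an
    all-zero fit raises :class:`EmptyRefinementError`).
    """
    if X_sub.n_features == 0:
        raise ValidationError("candidate set is empty")
    mask = labels.minority_mask
    y01 = mask.astype(int)
    values = _standardize_columns(X_sub.values)
    keep, inverse = _dedup_columns(values)
    vals_u = values[:, keep]

    if config.lambda_policy == "cross_validated":
        n_min = int(mask.sum())
        n_maj = int((~mask).sum())
        if min(n_min, n_maj) < config.cv_folds:
            raise InsufficientClassError(
                f"each class needs >= cv_folds={config.cv_folds} samples for "
                f"cross-validation (have {n_min}/{n_maj})"
            )
        deviances = [
            _cv_deviance(vals_u, y01, lam, config.cv_folds, config.seed)
            for lam in LAMBDA_GRID
        ]
        start = int(np.argmin(deviances))  # grid descends: ties -> sparser
        lam_used = None
        lr = None
        for lam in LAMBDA_GRID[start:]:
            lr = _fit_l1_logistic(vals_u, y01, lam)
            if np.any(lr.coef_[0] != 0):
                lam_used = lam
                break
        if lam_used is None:
            raise EmptyRefinementError(
                "all coefficients zero along the entire lambda grid"
            )
    else:
        lam_used = float(config.fixed_lambda)
        lr = _fit_l1_logistic(vals_u, y01, lam_used)
        if not np.any(lr.coef_[0] != 0):
            raise EmptyRefinementError(
                f"fixed lambda={lam_used} zeroed every coefficient"
            )

    beta_u = lr.coef_[0]
    beta = np.zeros(X_sub.n_features)
    beta[keep] = beta_u  # duplicates stay exactly zero
    nonzero = tuple(
        X_sub.feature_ids[j] for j in np.flatnonzero(beta)
    )
    prob = lr.predict_proba(vals_u)[:, 1]
    return SparseRefinement(
        candidate_ids=X_sub.feature_ids,
        beta=beta,
        intercept=float(lr.intercept_[0]),
        lambda_used=lam_used,
        nonzero_set=nonzero,
        fit_probabilities=prob,
    )


def finalize_selection(
    ranked: RankedFeatures,
    refinement: Optional[SparseRefinement],
    config: SelectorConfig,
) -> SelectionResult:
    """Intersect the candidate pool with the L1 survivors, in rank order.

    The final set is truncated to ``n_final``; when it falls short and
    ``backfill`` is on, the next-best ranked candidates are appended
    (flagged in provenance) until the requested size or pool exhaustion.
    """
    nonzero = set(refinement.nonzero_set) if refinement is not None else set()
    if refinement is not None and set(refinement.candidate_ids) != set(ranked.candidate_set):
        raise AlignmentError("refinement and ranking cover different candidate pools")
    final = [f for f in ranked.candidate_set if f in nonzero][: config.n_final]
    backfilled: list = []
    if len(final) < config.n_final and config.backfill:
        for f in ranked.candidate_set:
            if len(final) >= config.n_final:
                break
            if f not in final:
                final.append(f)
                backfilled.append(f)
        # keep rank order over the merged set
        rank_of = {f: i for i, f in enumerate(ranked.candidate_set)}
        final.sort(key=rank_of.__getitem__)
    elif not final and not config.backfill:
        warnings.warn("empty refinement and backfill disabled: empty final set",
                      stacklevel=2)
    provenance = {
        "config": config,
        "seed": config.seed,
        "backfilled": tuple(backfilled),
        "lambda_used": refinement.lambda_used if refinement is not None else None,
    }
    return SelectionResult(
        final_set=tuple(final),
        ranked=ranked,
        refinement=refinement,
        provenance=provenance,
    )


class MWRDSSelector(SelectorMixin, BaseEstimator):
    """Margin-weighted robust discriminant feature selector.

    Scores every feature with the robust discriminant statistic Phi
    (median/MAD based, minority terms amplified by 1 + tau), weights it by
    the linear-SVM margin vector omega, ranks by Psi = |Phi * omega|,
    refines the top-``n_candidates`` pool with L1-penalized logistic
    regression and keeps the intersection, backfilled by rank to
    ``n_final`` features.

    Parameters
    ----------
    n_final : int, default=10
        Number of features in the final set.
    n_candidates : int or None, default=None
        Size d of the ranked pool refined by the L1 step; ``None`` means
        ``max(5 * n_final, 50)``, clamped to the feature count.
    lambda_policy : {"cross_validated", "fixed"}, default="cross_validated"
        How the L1 penalty strength is chosen.
    fixed_lambda : float or None, default=None
        Penalty for the ``"fixed"`` policy.
    cv_folds : int, default=5
        Stratified folds for the cross-validated policy.
    backfill : bool, default=True
        Pad the final set with next-best ranked candidates when the L1
        intersection has fewer than ``n_final`` members.
    svm_cost : float, default=1.0
        Soft-margin cost C of the linear SVM.
    standardize : bool, default=True
        Z-scale features before the SVM fit.
    eps : float, default=1e-8
        Floor for variances and score denominators.
    random_state : int or None, default=None
        Seed for the cross-validation folds; the pipeline is otherwise
        deterministic.

    Attributes
    ----------
    phi_, omega_, psi_ : ndarray of shape (n_features,)
        The three score layers on the training data.
    ranking_ : ndarray of shape (n_features,)
        Feature indices in descending Psi order.
    tau_ : float
        Minority amplification factor of the training labels.
    selection_result_ : SelectionResult
        Full per-stage provenance.
    support_ : ndarray of bool, shape (n_features,)
        Mask of the selected features.

    Examples
    --------
    >>> from mwrds.simulate import SimConfig, simulate_dataset
    >>> sim = simulate_dataset(SimConfig(n_features=200, n_informative=5,
    ...                                  effect_size=3.0, seed=0))
    >>> sel = MWRDSSelector(n_final=5, random_state=0).fit(
    ...     sim.X.values, sim.labels.labels)
    >>> sel.transform(sim.X.values).shape
    (100, 5)
    """

    def __init__(
        self,
        n_final: int = 10,
        n_candidates: Optional[int] = None,
        lambda_policy: str = "cross_validated",
        fixed_lambda: Optional[float] = None,
        cv_folds: int = 5,
        backfill: bool = True,
        svm_cost: float = 1.0,
        standardize: bool = True,
        eps: float = DEFAULT_EPS,
        random_state: Optional[int] = None,
    ):
        self.n_final = n_final
        self.n_candidates = n_candidates
        self.lambda_policy = lambda_policy
        self.fixed_lambda = fixed_lambda
        self.cv_folds = cv_folds
        self.backfill = backfill
        self.svm_cost = svm_cost
        self.standardize = standardize
        self.eps = eps
        self.random_state = random_state

    def _make_config(self) -> SelectorConfig:
        return SelectorConfig(
            n_final=self.n_final,
            n_candidates=self.n_candidates,
            lambda_policy=self.lambda_policy,
            fixed_lambda=self.fixed_lambda,
            cv_folds=self.cv_folds,
            seed=self.random_state if self.random_state is not None else 0,
            backfill=self.backfill,
            svm_cost=self.svm_cost,
            standardize=self.standardize,
            eps=self.eps,
        )

    def fit(self, X, y):
        """Run the full selection pipeline on a training matrix.

        The rarer class in ``y`` is the minority; on a tie, ``classes_[1]``
        plays the minority role.
        """
        if isinstance(X, pd.DataFrame):
            feature_ids = tuple(str(c) for c in X.columns)
        else:
            feature_ids = ()
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError(
                f"{y.shape[0]} labels for {X.shape[0]} samples"
            )
        classes = np.unique(y)
        if classes.size != 2:
            raise ValidationError(
                f"need exactly 2 classes, got {classes.size}"
            )
        self.classes_ = classes
        counts = np.array([(y == c).sum() for c in classes])
        minority = classes[1] if counts[0] == counts[1] else classes[int(np.argmin(counts))]

        em = ExpressionMatrix(X, feature_ids=feature_ids)
        labels = LabelVector(y, positive_label=minority)
        result = _run_pipeline(em, labels, self._make_config())

        self.minority_class_ = minority
        self.tau_ = result.provenance["tau"]
        self.phi_ = result.phi.scores
        self.omega_ = result.margin.omega
        self.psi_ = result.psi.scores
        self.ranking_ = result.ranked.order
        self.candidate_indices_ = result.ranked.candidate_indices
        self.lambda_used_ = result.provenance["lambda_used"]
        self.selection_result_ = result

        id_to_idx = {f: i for i, f in enumerate(em.feature_ids)}
        self.selected_indices_ = np.array(
            [id_to_idx[f] for f in result.final_set], dtype=int
        )
        mask = np.zeros(em.n_features, dtype=bool)
        mask[self.selected_indices_] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def _run_pipeline(
    X: ExpressionMatrix, labels: LabelVector, config: SelectorConfig
) -> SelectionResult:
    """Execute every stage in order, naming the stage on failure."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (EmptyRefinementError, StageError):
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    profile = stage("imbalance_profile", compute_imbalance_profile, labels)
    stats = stage("feature_class_stats", compute_feature_class_stats, X, labels)
    weights = stage("stability_weights", compute_stability_weights, stats, config.eps)
    phi = stage(
        "robust_discriminant_scores",
        robust_discriminant_scores, stats, weights, profile, config.eps,
    )
    margin = stage(
        "margin_weights",
        fit_margin_weights, X, labels, config.svm_cost, config.standardize,
    )
    psi = stage("combine_scores", combine_scores, phi, margin)
    d = config.resolved_n_candidates(X.n_features)
    ranked = stage("rank_features", rank_features, psi, d)
    X_sub = X.subset_features(ranked.candidate_indices)
    try:
        refinement = stage("l1_refine", l1_refine, X_sub, labels, config)
    except EmptyRefinementError:
        if not config.backfill:
            raise
        refinement = None
    result = stage("finalize_selection", finalize_selection, ranked, refinement, config)
    result.provenance["tau"] = profile.tau
    return SelectionResult(
        final_set=result.final_set,
        ranked=result.ranked,
        refinement=result.refinement,
        provenance=result.provenance,
        phi=phi,
        margin=margin,
        psi=psi,
    )


def mwrds_select(
    X: ExpressionMatrix, labels: LabelVector, config: Optional[SelectorConfig] = None
) -> SelectionResult:
    """Run the full pipeline on validated containers.

    Thin wrapper over the same stages :class:`MWRDSSelector` executes;
    returns the rich :class:`SelectionResult` with feature identifiers
    taken from ``X``.
    """
    if config is None:
        config = SelectorConfig()
    return _run_pipeline(X, labels, config)
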