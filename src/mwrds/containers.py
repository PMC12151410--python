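"""Validated in-memory containers for expression data and per-feature scores.

The central objects are :class:`ExpressionMatrix` (a samples x features
numeric matrix with identifiers) and :class:`LabelVector` (binary class
marks with an explicit record of which mark is the minority class). All
downstream statistics are carried in small frozen dataclasses aligned to
the matrix's feature identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .exceptions import ValidationError


def _as_float_matrix(values: Any) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"non-finite value at sample index {bad[0]}, feature index {bad[1]}"
        )
    return arr


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x features numeric expression matrix.

    Parameters
    ----------
    values : array-like of shape (n_samples, n_features)
        Expression values; must be finite.
    sample_ids, feature_ids : sequences of str, optional
        Identifiers; generated as ``S{i}`` / ``G{j}`` (1-based) when omitted.
    """

    values: np.ndarray
    sample_ids: tuple = ()
    feature_ids: tuple = ()

    def __post_init__(self):
        arr = _as_float_matrix(self.values)
        object.__setattr__(self, "values", arr)
        n, p = arr.shape
        if n < 4:
            raise ValidationError(f"need at least 4 samples, got {n}")
        if p < 1:
            raise ValidationError("need at least 1 feature")
        sids = tuple(self.sample_ids) or tuple(f"S{i + 1}" for i in range(n))
        fids = tuple(self.feature_ids) or tuple(f"G{j + 1}" for j in range(p))
        if len(sids) != n:
            raise ValidationError(f"{len(sids)} sample ids for {n} samples")
        if len(fids) != p:
            raise ValidationError(f"{len(fids)} feature ids for {p} features")
        if len(set(fids)) != p:
            raise ValidationError("feature ids must be unique")
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "feature_ids", fids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            tuple(self.sample_ids[i] for i in idx),
            self.feature_ids,
        )

    def subset_features(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.sample_ids,
            tuple(self.feature_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class LabelVector:
    """Binary class marks paired with an :class:`ExpressionMatrix`.

    The rarer mark is the minority class; on a tie the mark given as
    ``positive_label`` is treated as minority. ``positive_is_minority``
    records whether the declared positive mark is the minority one, so
    results stay independent of label naming.
    """

    labels: np.ndarray
    positive_label: Any = None

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 1:
            raise ValidationError("labels must be 1-D")
        classes = np.unique(arr)
        if classes.size != 2:
            raise ValidationError(
                f"need exactly 2 classes, got {classes.size}: {classes.tolist()}"
            )
        pos = self.positive_label
        if pos is None:
            # default: the rarer mark is the positive/minority one
            counts = [(arr == c).sum() for c in classes]
            pos = classes[int(np.argmin(counts))]
        elif pos not in classes:
            raise ValidationError(f"positive label {pos!r} not among {classes.tolist()}")
        object.__setattr__(self, "labels", arr)
        object.__setattr__(self, "positive_label", pos)

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def minority_label(self) -> Any:
        """The rarer mark; ties resolve to the positive mark."""
        classes = self.classes
        counts = np.array([(self.labels == c).sum() for c in classes])
        if counts[0] == counts[1]:
            return self.positive_label
        return classes[int(np.argmin(counts))]

    @property
    def positive_is_minority(self) -> bool:
        return bool(self.minority_label == self.positive_label)

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    def signed(self) -> np.ndarray:
        """Labels as {-1, +1} with minority = +1."""
        return np.where(self.minority_mask, 1, -1)

    def subset(self, indices: Sequence[int]) -> "LabelVector":
        idx = np.asarray(indices, dtype=int)
        return LabelVector(self.labels[idx], self.positive_label)


@dataclass(frozen=True)
class ImbalanceProfile:
    """Class counts and the minority amplification factor tau = k+/k-."""

    n_minority: int
    n_majority: int
    tau: float

    def __post_init__(self):
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValidationError("both classes must be non-empty")
        if self.n_minority > self.n_majority:
            raise ValidationError("minority count exceeds majority count")
        expected = self.n_minority / self.n_majority
        if not np.isclose(self.tau, expected):
            raise ValidationError(
                f"tau={self.tau} inconsistent with counts ({expected})"
            )


@dataclass(frozen=True)
class FeatureClassStats:
    """Per-feature robust statistics for the two classes.

    All vectors are length p, aligned to ``feature_ids``. ``mad_*`` is the
    mean absolute deviation about the class median (expression units);
    ``var_*`` the within-class sample variance (denominator n-1).
    """

    feature_ids: tuple
    median_minority: np.ndarray
    median_majority: np.ndarray
    median_pooled: np.ndarray
    mad_minority: np.ndarray
    mad_majority: np.ndarray
    var_minority: np.ndarray
    var_majority: np.ndarray

    def __post_init__(self):
        p = len(self.feature_ids)
        for name in (
            "median_minority", "median_majority", "median_pooled",
            "mad_minority", "mad_majority", "var_minority", "var_majority",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({p},)")
            object.__setattr__(self, name, arr)
        for name in ("mad_minority", "mad_majority", "var_minority", "var_majority"):
            if (getattr(self, name) < 0).any():
                raise ValidationError(f"{name} contains negative entries")


@dataclass(frozen=True)
class StabilityWeights:
    """Inverse within-class variance weights, one pair per feature."""

    feature_ids: tuple
    weight_minority: np.ndarray
    weight_majority: np.ndarray

    def __post_init__(self):
        p = len(self.feature_ids)
        for name in ("weight_minority", "weight_majority"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (p,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({p},)")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValidationError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class MarginModel:
    """Linear soft-margin SVM fit summarized per feature.

    ``omega`` is the primal weight vector assembled from the dual
    coefficients and support vectors; ``dual_coefs`` are the non-negative
    gamma_a (class signs carried separately by the labels).
    """

    feature_ids: tuple
    omega: np.ndarray
    dual_coefs: np.ndarray
    support_indices: np.ndarray
    intercept: float
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if omega.shape != (len(self.feature_ids),):
            raise ValidationError("omega length must match feature_ids")
        gam = np.asarray(self.dual_coefs, dtype=float)
        if gam.size < 2:
            raise ValidationError("need at least 2 support vectors")
        if (gam < 0).any():
            raise ValidationError("dual coefficients must be non-negative")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "dual_coefs", gam)
        object.__setattr__(
            self, "support_indices", np.asarray(self.support_indices, dtype=int)
        )

    @property
    def n_support(self) -> int:
        return int(self.dual_coefs.size)


@dataclass(frozen=True)
class ScoreVector:
    """Per-feature scores of one kind: 'phi', 'omega_abs' or 'psi'."""

    scores: np.ndarray
    feature_ids: tuple
    kind: str

    def __post_init__(self):
        if self.kind not in ("phi", "omega_abs", "psi"):
            raise ValidationError(f"unknown score kind {self.kind!r}")
        arr = np.asarray(self.scores, dtype=float)
        if arr.shape != (len(self.feature_ids),):
            raise ValidationError("scores length must match feature_ids")
        if not np.isfinite(arr).all():
            raise ValidationError("scores must be finite")
        if self.kind in ("phi", "psi") and (arr < 0).any():
            raise ValidationError(f"{self.kind} scores must be non-negative")
        object.__setattr__(self, "scores", arr)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    def __len__(self) -> int:
        return len(self.feature_ids)
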