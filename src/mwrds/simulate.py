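"""Imbalanced multivariate-normal expression data generator.

Emulates the benchmark conditions the selector is designed for: kappa
samples split into minority/majority classes at a target ratio tau (class
sizes k+ = round(kappa * tau / (1 + tau)), k- = kappa - k+), features drawn
from a multivariate normal whose mean is zero in the majority class and
shifted by ``effect_size`` on the informative features in the minority
class. The covariance is identity by default, or block-equicorrelated.

Defaults match the simulation conditions the package is evaluated under:
100 samples, 5000 features, a 9:1 majority:minority split (tau = 1/9).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .containers import ExpressionMatrix, LabelVector
from .exceptions import ConfigurationError, ValidationError

MINORITY_MARK = "pos"
MAJORITY_MARK = "neg"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    ``ratio`` is the minority:majority ratio tau (default 1/9, i.e. a 9:1
    majority:minority split). ``effect_size`` is the minority-class mean
    shift on the informative features, in expression units (the noise SD
    is 1, so it doubles as a Cohen's d).
    """

    n_samples: int = 100
    n_features: int = 5000
    ratio: float = 1.0 / 9.0
    n_informative: int = 10
    effect_size: float = 1.0
    correlation: float = 0.0
    block_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")
        if not 1 <= self.n_features:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative cannot exceed n_features")
        if not 0 < self.ratio <= 1:
            raise ConfigurationError("ratio (tau) must lie in (0, 1]")
        if not -1 < self.correlation < 1:
            raise ConfigurationError("|correlation| must be < 1")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")


@dataclass(frozen=True)
class SimulatedDataset:
    X: ExpressionMatrix
    labels: LabelVector
    informative_ids: tuple
    config_echo: SimConfig

    def __post_init__(self):
        if not set(self.informative_ids) <= set(self.X.feature_ids):
            raise ValidationError("informative_ids must be a subset of feature_ids")


def imbalanced_sizes(n_samples: int, ratio: float) -> tuple[int, int]:
    """Class sizes (n_minority, n_majority) at ratio tau = minority/majority.

    n_minority = round(n * tau / (1 + tau)) (half-up, floored at 1) and
    n_majority is the remainder, so the two always sum to n_samples.
    """
    if n_samples < 2:
        raise ConfigurationError("n_samples must be >= 2")
    if not 0 < ratio <= 1:
        raise ConfigurationError(f"ratio must lie in (0, 1], got {ratio}")
    n_min = int(np.floor(n_samples * ratio / (1.0 + ratio) + 0.5))
    n_min = max(n_min, 1)
    return n_min, n_samples - n_min


def _block_cholesky(block_size: int, rho: float) -> np.ndarray:
    sigma = np.full((block_size, block_size), rho)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            f"equicorrelated block (size={block_size}, rho={rho}) is not "
            f"positive definite"
        ) from exc


def _draw(rng, n, p, correlation, block_size) -> np.ndarray:
    z = rng.standard_normal((n, p))
    if correlation == 0.0:
        return z
    out = np.empty_like(z)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        chol = _block_cholesky(stop - start, correlation)
        out[:, start:stop] = z[:, start:stop] @ chol.T
    return out


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one seeded imbalanced dataset.

    Minority rows come first (mark ``"pos"``), then majority rows
    (``"neg"``). The informative features are the first ``n_informative``
    columns; their identifiers are returned so recovery can be scored.
    """
    rng = np.random.default_rng(config.seed)
    n_min, n_maj = imbalanced_sizes(config.n_samples, config.ratio)
    p = config.n_features
    values = _draw(rng, config.n_samples, p, config.correlation, config.block_size)
    values[:n_min, : config.n_informative] += config.effect_size
    labels = np.array([MINORITY_MARK] * n_min + [MAJORITY_MARK] * n_maj)
    X = ExpressionMatrix(values)
    return SimulatedDataset(
        X=X,
        labels=LabelVector(labels, positive_label=MINORITY_MARK),
        informative_ids=X.feature_ids[: config.n_informative],
        config_echo=replace(config),
    )


def enforce_imbalance(
    X: ExpressionMatrix,
    labels: LabelVector,
    ratio: float,
    seed: Optional[int] = 0,
) -> tuple[ExpressionMatrix, LabelVector]:
    """Downsample the minority class to a target minority:majority ratio.

    Keeps every majority sample and uniformly subsamples the minority
    (seeded, without replacement) to ``round(n_majority * ratio)``. Never
    upsamples; a target below 2 minority samples is an error. Row order
    and sample ids are preserved.
    """
    if not 0 < ratio <= 1:
        raise ConfigurationError(f"ratio must lie in (0, 1], got {ratio}")
    mask = labels.minority_mask
    n_maj = int((~mask).sum())
    target = int(np.floor(n_maj * ratio + 0.5))
    if target < 2:
        raise ConfigurationError(
            f"target minority size {target} below the minimum of 2"
        )
    n_min = int(mask.sum())
    if n_min < target:
        raise ConfigurationError(
            f"minority class has {n_min} samples, below the target {target}; "
            f"refusing to upsample"
        )
    if n_min == target:
        return X, labels
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(mask)
    kept = rng.choice(minority_idx, size=target, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(~mask), kept]))
    return X.subset_samples(keep), labels.subset(keep)
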