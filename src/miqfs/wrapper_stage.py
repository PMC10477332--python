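"""QPSO wrapper stage: joint feature-mask and SVM hyperparameter search.

A particle encodes one candidate solution: the first ``n_features`` entries
live in (0, 1) and threshold at 0.5 into a boolean feature mask (0.5 counts
as selected), the last two entries are the soft-margin penalty C and the
Gaussian-kernel bandwidth sigma. Fitness combines cross-validated SVM
accuracy CA and the dimension-reduction rate DR as

    f = phi(d) * CA + (1 - phi(d)) * DR,    phi(d) = (9 + exp(-d/100)) / 10,

where d is the original (pre-filter) feature dimension: the larger the
original problem, the more weight dimensionality reduction receives, while
phi never drops below 0.9 so accuracy always dominates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import qpso
from .containers import FeatureMatrix


@dataclass(frozen=True)
class SvmParams:
    """Gaussian-kernel SVM hyperparameters (sklearn ``gamma = 1/(2 sigma^2)``)."""

    C: float
    sigma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be strictly positive")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma ** 2)


@dataclass
class FitnessConfig:
    """Wrapper-stage settings.

    ``d_original`` is the dimension of the feature space *before* any
    filtering, used by the accuracy weight phi; ``None`` means "use the
    candidate count". ``svm_bounds`` is (C_min, C_max, sigma_min, sigma_max);
    with ``log_scale`` the particle carries log10 values. ``cv_seed`` fixes
    the inner folds so fitness is a deterministic function of the particle.
    """

    d_original: int | None = None
    k_folds: int = 3
    svm_bounds: tuple[float, float, float, float] = (0.01, 100.0, 0.01, 100.0)
    selection_threshold: float = 0.5
    empty_mask_policy: str = "zero_fitness"
    log_scale: bool = False
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.d_original is not None and self.d_original < 1:
            raise ValueError("d_original must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.empty_mask_policy not in ("zero_fitness", "raise"):
            raise ValueError("empty_mask_policy must be 'zero_fitness' or 'raise'")


@dataclass
class SelectionResult:
    mask: np.ndarray
    svm: SvmParams
    fitness: float
    CA: float
    DR: float
    history: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


class EmptyMaskError(ValueError):
    """Raised when a particle selects no features under a 'raise' policy."""


def decode_particle(position: np.ndarray, n_features: int,
                    svm_bounds: tuple[float, float, float, float]
                    = (0.01, 100.0, 0.01, 100.0),
                    threshold: float = 0.5,
                    log_scale: bool = False) -> tuple[np.ndarray, SvmParams]:
    """Split a particle into (boolean mask, SvmParams).

    Entry i is selected iff ``position[i] >= threshold`` (the boundary value
    counts as selected). The last two entries map to C and sigma, optionally
    through a log10 scale.
    """
    position = np.asarray(position, dtype=float)
    if position.shape != (n_features + 2,):
        raise ValueError(
            f"particle must have length n_features + 2 = {n_features + 2}, "
            f"got {position.shape}")
    mask = position[:n_features] >= threshold
    c_raw, s_raw = position[n_features], position[n_features + 1]
    if log_scale:
        c_raw, s_raw = 10.0 ** c_raw, 10.0 ** s_raw
    c_min, c_max, s_min, s_max = svm_bounds
    C = float(np.clip(c_raw, c_min, c_max))
    sigma = float(np.clip(s_raw, s_min, s_max))
    return mask, SvmParams(C=C, sigma=sigma)


def phi_weight(d: int) -> float:
    """Accuracy weight ``(9 + exp(-d/100)) / 10``: 1 at d=0, decaying to 0.9."""
    if d < 0:
        raise ValueError("feature dimension d must be nonnegative")
    return (9.0 + np.exp(-d / 100.0)) / 10.0


def svm_cv_accuracy(F: FeatureMatrix, mask: np.ndarray, params: SvmParams,
                    k: int = 3, seed: int = 0) -> float:
    """Mean stratified k-fold accuracy of an RBF SVM on the masked features.

    Features are standardized per fold with statistics fit on the training
    portion only, so sigma acts on a common scale and no information leaks
    from the validation split.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise EmptyMaskError("the mask selects no features")
    classes, counts = np.unique(F.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} samples (min is {counts.min()})")
    X = F.values[:, mask]
    y = F.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(C=params.C, kernel="rbf", gamma=params.gamma)
        clf.fit(scaler.transform(X[train]), y[train])
        accs.append(clf.score(scaler.transform(X[test]), y[test]))
    return float(np.mean(accs))


def fitness(position: np.ndarray, F: FeatureMatrix,
            config: FitnessConfig) -> float:
    """Dimension-aware fitness of an encoded particle (to be maximized)."""
    n = F.n_features
    mask, params = decode_particle(position, n, config.svm_bounds,
                                   config.selection_threshold,
                                   config.log_scale)
    if mask.sum() == 0:
        if config.empty_mask_policy == "raise":
            raise EmptyMaskError("the particle selects no features")
        return 0.0
    ca = svm_cv_accuracy(F, mask, params, k=config.k_folds,
                         seed=config.cv_seed)
    dr = 1.0 - mask.sum() / n
    d = config.d_original if config.d_original is not None else n
    phi = phi_weight(d)
    return phi * ca + (1.0 - phi) * dr


def select(F: FeatureMatrix, config: FitnessConfig | None = None,
           n_particles: int = 200, t_max: int = 200,
           seed: int | None = None) -> SelectionResult:
    """Optimize the joint mask + (C, sigma) encoding with QPSO.

    Runs a maximizing QPSO over the ``(n_features + 2)``-dimensional box and
    returns the decoded best particle with its accuracy CA, dimension
    reduction DR, combined fitness, and the per-iteration fitness trace.
    """
    if F.n_features < 1:
        raise ValueError("need at least one candidate feature")
    config = config or FitnessConfig()
    n = F.n_features
    c_min, c_max, s_min, s_max = config.svm_bounds
    if config.log_scale:
        param_bounds = [(np.log10(c_min), np.log10(c_max)),
                        (np.log10(s_min), np.log10(s_max))]
    else:
        param_bounds = [(c_min, c_max), (s_min, s_max)]
    bounds = [(0.0, 1.0)] * n + param_bounds

    result = qpso.optimize(lambda p: fitness(p, F, config), bounds,
                           n_particles=n_particles, t_max=t_max, seed=seed,
                           sense="maximize")
    mask, params = decode_particle(result.best_position, n, config.svm_bounds,
                                   config.selection_threshold,
                                   config.log_scale)
    if mask.sum() == 0:
        ca, dr = 0.0, 1.0
    else:
        ca = svm_cv_accuracy(F, mask, params, k=config.k_folds,
                             seed=config.cv_seed)
        dr = 1.0 - mask.sum() / n
    return SelectionResult(mask=mask, svm=params,
                           fitness=float(result.best_fitness),
                           CA=float(ca), DR=float(dr),
                           history=result.history,
                           feature_names=[F.names[i]
                                          for i in np.flatnonzero(mask)])
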