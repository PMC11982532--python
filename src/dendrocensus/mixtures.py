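"""Gaussian-mixture specifications and synthetic embedding generators.

The cluster-versus-continuum analysis rests on synthetic 32-dimensional
Gaussian mixtures whose isotropic variance is swept from tightly separated
clusters (σ² = 0.005) to an essentially continuous distribution (σ² = 1.0).
Mixture means and weights are either extracted from a reference
diagonal-covariance GMM fit to real embeddings, or generated de novo with a
calibrated geometry: the mean Euclidean distance from a component mean to
its third-nearest neighboring mean is set to a target value (2.38, the
printed neighbor-graph distance threshold in embedding space), which
controls how much neighboring components overlap at a given σ².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

from .tables import EmbeddingSet

__all__ = [
    "MixtureSpec",
    "fit_reference_mixture",
    "generate_calibrated_means",
    "sample_mixture",
    "generate_toy_1d",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Means, weights and covariance description of a Gaussian mixture.

    ``sigma2`` is a positive scalar for isotropic covariance, a (K, d)
    positive array for diagonal covariance, or None when the variance has
    not been chosen yet (calibrated means awaiting a sweep value).
    """

    means: np.ndarray
    weights: np.ndarray
    covariance_kind: str = "isotropic"
    sigma2: Optional[np.ndarray | float] = None

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "weights", weights)
        if self.covariance_kind not in ("isotropic", "diagonal"):
            raise ValueError(f"unknown covariance_kind {self.covariance_kind!r}")
        if weights.shape != (means.shape[0],):
            raise ValueError("weights must have one entry per component")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1 (1e-12)")
        if means.shape[0] > 1:
            d = pdist(means)
            if d.min() == 0.0:
                raise ValueError("duplicate component means")
        if self.sigma2 is not None:
            s2 = np.asarray(self.sigma2, dtype=float)
            if self.covariance_kind == "isotropic":
                if s2.ndim != 0 or s2 <= 0:
                    raise ValueError("isotropic sigma2 must be a positive scalar")
            else:
                if s2.shape != means.shape or np.any(s2 <= 0):
                    raise ValueError("diagonal sigma2 must be positive, shape (K, d)")
            object.__setattr__(self, "sigma2", s2)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def with_sigma2(self, sigma2, covariance_kind="isotropic") -> "MixtureSpec":
        return replace(self, sigma2=sigma2, covariance_kind=covariance_kind)

    def component_std(self, k: int) -> np.ndarray:
        if self.sigma2 is None:
            raise ValueError("sigma2 not set")
        if self.covariance_kind == "isotropic":
            return np.full(self.dim, np.sqrt(float(self.sigma2)))
        return np.sqrt(self.sigma2[k])


def fit_reference_mixture(
    embeddings: EmbeddingSet | np.ndarray,
    n_components: int,
    seed: int,
    max_restarts: int = 5,
) -> MixtureSpec:
    """Diagonal-covariance EM fit; only means and weights are kept downstream."""
    X = embeddings.matrix if isinstance(embeddings, EmbeddingSet) else np.asarray(embeddings, float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} rows cannot support {n_components} components"
        )
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="diag",
            random_state=seed + attempt,
            reg_covar=1e-8,
            init_params="k-means++",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        resp = gm.predict_proba(X).sum(axis=0)
        if np.all(resp > 1e-10) and np.all(np.isfinite(gm.means_)):
            return MixtureSpec(
                means=gm.means_,
                weights=gm.weights_ / gm.weights_.sum(),
                covariance_kind="diagonal",
                sigma2=np.maximum(gm.covariances_, 1e-12),
            )
        last_err = RuntimeError(f"degenerate EM component on attempt {attempt}")
    raise RuntimeError(
        f"reference mixture fit failed after {max_restarts} restarts"
    ) from last_err


def _mean_nn3_distance(means: np.ndarray) -> float:
    D = squareform(pdist(means))
    np.fill_diagonal(D, np.inf)
    third = np.sort(D, axis=1)[:, 2]
    return float(third.mean())


def generate_calibrated_means(
    n_components: int,
    dim: int,
    target_nn3_distance: float,
    seed: int,
    weight_concentration: float = 10.0,
    max_attempts: int = 20,
) -> MixtureSpec:
    """Means with a calibrated third-nearest-neighbor geometry.

    Means are drawn i.i.d. from an isotropic Gaussian and rescaled so the
    average distance of each mean to its third-nearest neighbor equals the
    target exactly (distances scale linearly with the draw, so one rescale
    suffices).  Weights come from a Dirichlet with concentration 10 — mildly
    imbalanced, never degenerate.  σ² is left unset for the caller's sweep.
    """
    if n_components < 4:
        raise ValueError("need at least 4 components for a third neighbor")
    if dim < 2 or target_nn3_distance <= 0:
        raise ValueError("dim must be >= 2 and target distance positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        z = rng.standard_normal((n_components, dim))
        base = _mean_nn3_distance(z)
        if base == 0:
            continue
        means = z * (target_nn3_distance / base)
        achieved = _mean_nn3_distance(means)
        if abs(achieved - target_nn3_distance) <= 0.02 * target_nn3_distance:
            weights = rng.dirichlet(np.full(n_components, weight_concentration))
            weights = weights / weights.sum()
            return MixtureSpec(means=means, weights=weights)
    raise RuntimeError(
        "calibration failed: could not realize the requested spacing"
    )


def sample_mixture(
    spec: MixtureSpec, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` samples; returns (X, true component labels)."""
    if spec.sigma2 is None:
        raise ValueError("spec.sigma2 must be set before sampling")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(spec.n_components, size=n, p=spec.weights)
    X = np.empty((n, spec.dim))
    for k in range(spec.n_components):
        mask = labels == k
        m = int(mask.sum())
        if m:
            X[mask] = spec.means[k] + rng.standard_normal((m, spec.dim)) * spec.component_std(k)
    return X, labels


def generate_toy_1d(sd: float, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Balanced 1-d two-component toy: means -1 and +1, common SD ``sd``."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    n1 = n // 2
    labels = np.concatenate([np.zeros(n1, int), np.ones(n - n1, int)])
    x = np.where(labels == 0, -1.0, 1.0) + rng.standard_normal(n) * sd
    return x, labels
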