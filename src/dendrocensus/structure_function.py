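"""Structure-function statistics.

Links a neuron's functional embedding ("bar code" from a predictive model of
its visual responses) to a morphological property, and provides the
comparison statistics used for area contrasts:

* nested cross-validated elastic-net regression (hyperparameters selected on
  inner folds only; R² and Pearson r reported on concatenated outer-fold
  held-out predictions);
* Fisher's z-test for the difference of two Pearson correlations;
* two-tailed Student's t contrast with pooled-SD Cohen's d and Bonferroni
  correction of the significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "RegressionGrid",
    "RegressionResult",
    "CorrelationComparison",
    "AreaContrast",
    "nested_cv_regression",
    "fisher_z_test",
    "area_contrast",
]


@dataclass(frozen=True)
class RegressionGrid:
    alphas: tuple = (0.01, 0.1, 0.5, 1, 5, 10)
    l1_ratios: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.alphas or not self.l1_ratios:
            raise ValueError("empty hyperparameter grid")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class RegressionResult:
    predictions: np.ndarray     # out-of-fold predictions, row-aligned
    r2: float                   # 1 - SSE/SST on concatenated predictions
    pearson_r: float
    pearson_p: float
    chosen_params: list         # per outer fold


def nested_cv_regression(features, target, grid: RegressionGrid) -> RegressionResult:
    """Elastic net with nested CV; performance on held-out folds only."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and target differ in length")
    if X.shape[0] < grid.outer_folds:
        raise ValueError("fewer samples than outer folds")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite inputs")
    if np.std(y) == 0:
        raise ValueError("constant target: correlation undefined")

    outer = KFold(n_splits=grid.outer_folds, shuffle=True, random_state=grid.seed)
    preds = np.empty_like(y)
    chosen = []
    param_grid = {
        "model__alpha": list(grid.alphas),
        "model__l1_ratio": list(grid.l1_ratios),
    }
    for fold, (tr, te) in enumerate(outer.split(X)):
        pipe = Pipeline(
            [("scale", StandardScaler()),
             ("model", ElasticNet(max_iter=5000))]
        )
        inner = KFold(n_splits=grid.inner_folds, shuffle=True,
                      random_state=grid.seed + 1 + fold)
        search = GridSearchCV(pipe, param_grid, cv=inner,
                              scoring="neg_mean_squared_error", n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X[tr], y[tr])
            preds[te] = search.predict(X[te])
        chosen.append(search.best_params_)

    sse = float(np.sum((y - preds) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    r, p = stats.pearsonr(y, preds)
    return RegressionResult(preds, r2, float(r), float(p), chosen)


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p: float


def fisher_z_test(r1: float, r2: float, n1: int, n2: int) -> CorrelationComparison:
    """Two-tailed Fisher z-test for the difference of two correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r1, r2, n1, n2, float(z), float(p))


@dataclass(frozen=True)
class AreaContrast:
    t: float
    p: float
    cohens_d: float
    alpha: float
    corrected_alpha: float
    significant: bool
    n1: int
    n2: int


def area_contrast(sample_a, sample_b, n_tests: int, alpha: float = 0.01) -> AreaContrast:
    """Two-tailed Student t-test with pooled-SD Cohen's d and Bonferroni
    correction of the single-test level ``alpha`` for ``n_tests`` tests."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    corrected = alpha / n_tests
    return AreaContrast(
        t=float(t), p=float(p), cohens_d=float(d), alpha=alpha,
        corrected_alpha=corrected, significant=bool(p < corrected),
        n1=a.size, n2=b.size,
    )
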