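"""Quality control, annotation transfer and layer geometry.

Automatically reconstructed EM skeletons contain fragments, merge errors and
interneurons.  The QC cascade removes, in order: neurons too close to the
lateral volume faces (partly reconstructed), neurons a classifier flags as
fragmented (trained on expert-labeled examples), neurons lacking the
synapse/spine density features, and neurons classified as inhibitory.
Classifiers are grid-searched with 10-fold cross-validation over the
declared hyperparameter grids and refit on the full labeled set.

Cortical layers are assigned geometrically: a classifier first infers layer
labels from the embeddings, then a continuous piecewise-linear boundary
depth(x) is fit between each pair of adjacent layers by minimizing
misclassification, and final layer membership depends only on soma depth
relative to these boundaries.

Apical-termination filters remove suspect reconstructions layer by layer:
L4 neurons whose apical ends more than 96 μm below the pia, whole L5
clusters in which more than half the members have unnatural terminations,
and L6 neurons whose apical left the volume.  The 96 μm threshold is the
depth cutoff maximizing the F1 score of retaining naturally terminating
neurons on a manually validated set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .tables import EmbeddingSet

__all__ = [
    "ClassifierSpec",
    "TunedClassifier",
    "LayerBoundaryModel",
    "VolumeBounds",
    "QCReport",
    "tune_classifier",
    "filter_volume_boundary",
    "run_qc_cascade",
    "fit_layer_boundaries",
    "assign_layers",
    "apply_termination_filters",
    "select_f1_threshold",
]

LAYER_ORDER = ["L1", "L2/3", "L4", "L5", "L6"]


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameter grids for the supervised stages."""

    family: str = "svm"  # "logistic" or "svm"
    penalties: tuple = ("none", "l1", "l2", "elasticnet")
    C_grid: tuple = (0.5, 1, 3, 5, 10, 20, 30)
    kernels: tuple = ("linear", "rbf", "poly")
    degree_grid: tuple = (2, 3, 5, 7, 10, 20)
    class_weighting: tuple = ("balanced", None)
    folds: int = 10

    def __post_init__(self):
        if self.family not in ("logistic", "svm"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.C_grid or (self.family == "svm" and not self.kernels):
            raise ValueError("empty hyperparameter grid")

    def param_grid(self) -> list[dict]:
        cw = [
            ("balanced" if w == "balanced" else None)
            for w in self.class_weighting
        ]
        if self.family == "logistic":
            grid = []
            for pen in self.penalties:
                if pen == "none":
                    grid.append(
                        {"model__penalty": [None],
                         "model__class_weight": cw}
                    )
                elif pen == "elasticnet":
                    grid.append(
                        {"model__penalty": ["elasticnet"],
                         "model__C": list(self.C_grid),
                         "model__l1_ratio": [0.5],
                         "model__class_weight": cw}
                    )
                else:
                    grid.append(
                        {"model__penalty": [pen],
                         "model__C": list(self.C_grid),
                         "model__class_weight": cw}
                    )
            return grid
        grid = []
        for kernel in self.kernels:
            entry = {
                "model__kernel": [kernel],
                "model__C": list(self.C_grid),
                "model__class_weight": cw,
            }
            if kernel == "poly":
                entry["model__degree"] = list(self.degree_grid)
            grid.append(entry)
        return grid

    def n_configurations(self) -> int:
        return sum(
            int(np.prod([len(v) for v in entry.values()]))
            for entry in self.param_grid()
        )


@dataclass
class TunedClassifier:
    model: Pipeline
    best_params: dict
    cv_score: float
    scoring: str
    spec: ClassifierSpec
    seed: int

    def predict(self, X):
        return self.model.predict(np.asarray(X, dtype=float))


def tune_classifier(
    features,
    labels,
    spec: ClassifierSpec,
    seed: int = 0,
    scoring: str = "balanced_accuracy",
) -> TunedClassifier:
    """Exhaustive grid search with stratified 10-fold CV, refit on all data."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if counts.min() < spec.folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} members; "
            f"stratified {spec.folds}-fold CV needs at least {spec.folds}"
        )
    if spec.family == "logistic":
        base = LogisticRegression(solver="saga", max_iter=5000)
    else:
        base = SVC()
    pipe = Pipeline([("scale", StandardScaler()), ("model", base)])
    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        pipe, spec.param_grid(), scoring=scoring, cv=cv, refit=True, n_jobs=1
    )
    search.fit(X, y)
    return TunedClassifier(
        model=search.best_estimator_,
        best_params=search.best_params_,
        cv_score=float(search.best_score_),
        scoring=scoring,
        spec=spec,
        seed=seed,
    )


@dataclass(frozen=True)
class VolumeBounds:
    """Lateral extents of the imaged volume (x and z faces only)."""

    x: tuple[float, float]
    z: tuple[float, float]


def filter_volume_boundary(
    embeddings: EmbeddingSet, bounds: VolumeBounds, margin: float
) -> tuple[EmbeddingSet, np.ndarray]:
    """Drop neurons whose soma is within ``margin`` of a lateral face."""
    soma = embeddings.soma_positions()
    x, z = soma[:, 0], soma[:, 2]
    if margin >= 0.5 * min(bounds.x[1] - bounds.x[0], bounds.z[1] - bounds.z[0]):
        import warnings

        warnings.warn("margin covers the whole volume; output may be empty",
                      stacklevel=2)
    keep = (
        (x >= bounds.x[0] + margin)
        & (x <= bounds.x[1] - margin)
        & (z >= bounds.z[0] + margin)
        & (z <= bounds.z[1] - margin)
    )
    return embeddings.select(keep), embeddings.ids[~keep]


@dataclass
class QCReport:
    n_input: int
    removed_boundary: np.ndarray
    removed_fragment: np.ndarray
    removed_no_density: np.ndarray
    removed_inhibitory: np.ndarray
    retained: EmbeddingSet

    def counts(self) -> dict:
        return {
            "input": self.n_input,
            "removed_boundary": len(self.removed_boundary),
            "removed_fragment": len(self.removed_fragment),
            "removed_no_density": len(self.removed_no_density),
            "removed_inhibitory": len(self.removed_inhibitory),
            "retained": self.retained.n,
        }


_DENSITY_COLS = ["apical_shaft_synapse_density", "spine_density"]


def run_qc_cascade(
    embeddings: EmbeddingSet,
    fragment_model: TunedClassifier,
    ei_model: TunedClassifier,
    bounds: VolumeBounds,
    margin: float = 20.0,
) -> QCReport:
    """Ordered cascade: boundary -> fragment -> density availability -> E/I.

    The fragment stage classifies on the embeddings alone; the E/I stage on
    embeddings augmented with apical-shaft synapse density and spine density,
    removing first the rows that lack those columns.
    """
    n_input = embeddings.n
    kept, removed_boundary = filter_volume_boundary(embeddings, bounds, margin)

    frag_pred = fragment_model.predict(kept.matrix)
    frag_mask = np.asarray(frag_pred).astype(bool)
    removed_fragment = kept.ids[frag_mask]
    kept = kept.select(~frag_mask)

    missing_cols = [c for c in _DENSITY_COLS if c not in kept.metadata.columns]
    if missing_cols:
        raise ValueError(
            f"E/I stage requires density columns {missing_cols} for at least "
            "some rows"
        )
    dens = kept.metadata[_DENSITY_COLS].to_numpy(dtype=float)
    has_density = np.isfinite(dens).all(axis=1)
    removed_no_density = kept.ids[~has_density]
    kept = kept.select(has_density)

    feats = np.column_stack(
        [kept.matrix, kept.metadata[_DENSITY_COLS].to_numpy(dtype=float)]
    )
    inhib = np.asarray(ei_model.predict(feats)).astype(bool)
    removed_inhibitory = kept.ids[inhib]
    kept = kept.select(~inhib)

    return QCReport(
        n_input=n_input,
        removed_boundary=removed_boundary,
        removed_fragment=removed_fragment,
        removed_no_density=removed_no_density,
        removed_inhibitory=removed_inhibitory,
        retained=kept,
    )


@dataclass
class LayerBoundaryModel:
    """Ordered piecewise-linear boundaries depth(x) between adjacent layers."""

    layer_pairs: list                      # e.g. [("L2/3", "L4"), ...]
    knots_x: np.ndarray                    # shared breakpoints in x
    knots_depth: list                      # per boundary, depth at each knot

    def boundary_depth(self, pair_index: int, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.knots_x,
                         self.knots_depth[pair_index])

    def ordered(self) -> bool:
        grid = np.linspace(self.knots_x[0], self.knots_x[-1], 101)
        depths = [self.boundary_depth(i, grid) for i in range(len(self.layer_pairs))]
        return all(
            np.all(depths[i + 1] > depths[i]) for i in range(len(depths) - 1)
        )


def _fit_single_boundary(x, depth, above_mask, knots_x, seed):
    """Knot depths minimizing smoothed misclassification for one boundary.

    ``above_mask`` is True for neurons of the shallower layer (should be
    above the boundary, i.e. smaller depth).
    """
    sign = np.where(above_mask, 1.0, -1.0)
    scale = max(np.std(depth), 1.0)

    def loss(knots_depth):
        b = np.interp(x, knots_x, knots_depth)
        # margin > 0 when correctly placed; hinge on the smoothed margin
        margin = sign * (b - depth) / scale
        return np.maximum(0.0, 0.05 - margin).sum()

    shallow = depth[above_mask]
    deep = depth[~above_mask]
    init = np.full(knots_x.size, 0.5 * (shallow.mean() + deep.mean()))
    res = minimize(loss, init, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-3, "fatol": 1e-6})
    return res.x


def fit_layer_boundaries(
    soma_positions: np.ndarray,
    inferred_layer_labels: Sequence[str],
    n_segments: int = 3,
    layer_order: Optional[list] = None,
    seed: int = 0,
) -> LayerBoundaryModel:
    """Fit a continuous piecewise-linear boundary per adjacent layer pair.

    ``soma_positions`` holds (x, depth) per neuron (z pooled).  Breakpoints
    are equally spaced over the x range and shared across boundaries; knot
    depths minimize a hinge-smoothed misclassification loss.  Boundaries are
    post-processed to be strictly ordered in depth.
    """
    pos = np.asarray(soma_positions, dtype=float)
    x, depth = pos[:, 0], pos[:, 1]
    labels = np.asarray(inferred_layer_labels)
    order = layer_order or [l for l in LAYER_ORDER if l in set(labels)]
    for layer in order:
        if not (labels == layer).any():
            raise ValueError(f"layer {layer!r} absent; boundary undefined")
    knots_x = np.linspace(x.min(), x.max(), n_segments + 1)

    pairs, knot_depths = [], []
    for upper, lower_layer in zip(order, order[1:]):
        mask = (labels == upper) | (labels == lower_layer)
        kd = _fit_single_boundary(
            x[mask], depth[mask], labels[mask] == upper, knots_x, seed
        )
        pairs.append((upper, lower_layer))
        knot_depths.append(kd)
    # enforce strict ordering
    for i in range(1, len(knot_depths)):
        knot_depths[i] = np.maximum(knot_depths[i], knot_depths[i - 1] + 1e-6)
    return LayerBoundaryModel(pairs, knots_x, knot_depths)


def assign_layers(model: LayerBoundaryModel, soma_positions) -> np.ndarray:
    """Layer membership purely from soma depth vs the fitted boundaries."""
    pos = np.atleast_2d(np.asarray(soma_positions, dtype=float))
    x, depth = pos[:, 0], pos[:, 1]
    names = [model.layer_pairs[0][0]] + [p[1] for p in model.layer_pairs]
    out = np.array([names[0]] * len(x), dtype=object)
    for i in range(len(model.layer_pairs)):
        below = depth > model.boundary_depth(i, x)
        out[below] = names[i + 1]
    return out


def apply_termination_filters(
    records: pd.DataFrame,
    l4_depth_cutoff: float = 96.0,
    l5_cluster_fraction: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Layer-specific apical-termination exclusions.

    ``records`` columns: layer, apical_top_depth (μm below pia), cluster_id,
    flag_unnatural (bool), left_volume (bool); the index holds neuron ids.
    Returns (retained ids, per-rule removal counts).
    """
    df = records
    drop = pd.Series(False, index=df.index)

    l4_rule = (df["layer"] == "L4") & (df["apical_top_depth"] > l4_depth_cutoff)

    l5 = df[df["layer"] == "L5"]
    bad_clusters = []
    if len(l5):
        frac = l5.groupby("cluster_id")["flag_unnatural"].mean()
        bad_clusters = frac[frac > l5_cluster_fraction].index.tolist()
    l5_rule = (df["layer"] == "L5") & df["cluster_id"].isin(bad_clusters)

    l6_rule = (df["layer"] == "L6") & df["left_volume"].astype(bool)

    drop = l4_rule | l5_rule | l6_rule
    counts = {
        "removed_l4_deep_apical": int(l4_rule.sum()),
        "removed_l5_bad_cluster": int(l5_rule.sum()),
        "removed_l6_left_volume": int(l6_rule.sum()),
        "retained": int((~drop).sum()),
    }
    return df.index[~drop].to_numpy(), counts


def select_f1_threshold(labeled: pd.DataFrame) -> float:
    """Depth cutoff maximizing the F1 score of retaining natural terminations.

    ``labeled`` columns: depth (apical termination depth below pia) and
    is_natural (bool).  Neurons at or above the cutoff are retained.  All
    n+1 threshold positions at the observed depths are scanned; ties pick
    the shallower threshold.
    """
    depth = labeled["depth"].to_numpy(dtype=float)
    natural = labeled["is_natural"].to_numpy(dtype=bool)
    if natural.all() or not natural.any():
        raise ValueError("need both natural and unnatural examples")
    candidates = np.unique(depth)
    best_f1, best_t = -1.0, None
    for t in candidates:
        retained = depth <= t
        tp = int((retained & natural).sum())
        fp = int((retained & ~natural).sum())
        fn = int((~retained & natural).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, float(t)
    return best_t
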