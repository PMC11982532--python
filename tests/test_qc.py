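"""QC cascade, classifier tuning, layer boundaries and termination filters."""

import numpy as np
import pandas as pd
import pytest

from dendrocensus.qc import (
    ClassifierSpec,
    VolumeBounds,
    apply_termination_filters,
    assign_layers,
    filter_volume_boundary,
    fit_layer_boundaries,
    run_qc_cascade,
    select_f1_threshold,
    tune_classifier,
)
from dendrocensus.tables import EmbeddingSet

SMALL_SVM = ClassifierSpec(family="svm", kernels=("linear",),
                           C_grid=(1.0,), class_weighting=(None,), folds=5)
SMALL_LOGISTIC = ClassifierSpec(family="logistic", penalties=("l2",),
                                C_grid=(1.0,), class_weighting=(None,), folds=5)


def blob_data(rng, n=60, sep=8.0, d=6):
    X = np.vstack([rng.normal(0, 1, (n // 2, d)),
                   rng.normal(sep, 1, (n - n // 2, d))])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return X, y


class TestClassifierSpec:
    def test_svm_grid_enumerates_112_configurations(self):
        spec = ClassifierSpec(family="svm")
        # linear: 7C x 2 weights; rbf: 7 x 2; poly: 7 x 6 degrees x 2
        assert spec.n_configurations() == 112

    def test_invalid_family_and_folds(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="forest")
        with pytest.raises(ValueError):
            ClassifierSpec(folds=1)


class TestTuneClassifier:
    def test_separable_blobs_reach_perfect_cv(self, rng):
        X, y = blob_data(rng)
        tuned = tune_classifier(X, y, SMALL_SVM, seed=0)
        assert tuned.cv_score == pytest.approx(1.0)
        assert (tuned.predict(X) == y).all()

    def test_shuffled_labels_score_near_chance(self, rng):
        X, y = blob_data(rng, n=120)
        y = rng.permutation(y)
        tuned = tune_classifier(X, y, SMALL_LOGISTIC, seed=1)
        se = 0.5 / np.sqrt(len(y))  # binomial SE of balanced accuracy
        assert abs(tuned.cv_score - 0.5) < 4 * se

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ValueError, match="stratified"):
            tune_classifier(X, y, SMALL_SVM, seed=0)


def embedding_fixture(rng, n=200, d=8, frag_sep=6.0):
    is_frag = rng.random(n) < 0.10
    is_inhib = (~is_frag) & (rng.random(n) < 0.10)
    X = rng.normal(0, 1, (n, d))
    X[is_frag] += frag_sep
    meta = pd.DataFrame(
        {
            "soma_x": rng.uniform(0, 1000, n),
            "soma_y": rng.uniform(0, 800, n),
            "soma_z": rng.uniform(0, 1000, n),
            "apical_shaft_synapse_density": np.where(is_inhib, 3.0, 0.5)
            + rng.normal(0, 0.05, n),
            "spine_density": np.where(is_inhib, 0.1, 1.2)
            + rng.normal(0, 0.05, n),
        }
    )
    missing = rng.random(n) < 0.03
    meta.loc[missing, "spine_density"] = np.nan
    es = EmbeddingSet(np.arange(n), X, meta)
    return es, is_frag, is_inhib


class TestBoundaryFilter:
    def test_zero_margin_is_identity(self, rng):
        es, *_ = embedding_fixture(rng)
        kept, removed = filter_volume_boundary(
            es, VolumeBounds((0, 1000), (0, 1000)), margin=0.0
        )
        assert kept.n == es.n and removed.size == 0

    def test_soma_on_face_removed(self, rng):
        es, *_ = embedding_fixture(rng, n=50)
        es.metadata.loc[0, "soma_x"] = 0.0
        kept, removed = filter_volume_boundary(
            es, VolumeBounds((0, 1000), (0, 1000)), margin=5.0
        )
        assert es.ids[0] in removed

    def test_uniform_cube_retention_fraction(self, rng):
        n = 20000
        meta = pd.DataFrame(
            {
                "soma_x": rng.uniform(0, 1, n),
                "soma_y": rng.uniform(0, 1, n),
                "soma_z": rng.uniform(0, 1, n),
            }
        )
        es = EmbeddingSet(np.arange(n), rng.normal(size=(n, 2)), meta)
        kept, _ = filter_volume_boundary(es, VolumeBounds((0, 1), (0, 1)), 0.1)
        assert kept.n / n == pytest.approx(0.8**2, abs=0.01)

    def test_monotone_in_margin(self, rng):
        es, *_ = embedding_fixture(rng)
        bounds = VolumeBounds((0, 1000), (0, 1000))
        sizes = [
            filter_volume_boundary(es, bounds, m)[0].n for m in (0, 50, 150)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestCascade:
    def test_counts_conserved_and_fragments_removed(self, rng):
        es, is_frag, is_inhib = embedding_fixture(rng, n=300)
        frag_model = tune_classifier(es.matrix, is_frag.astype(int),
                                     SMALL_SVM, seed=0)
        dens = es.metadata[
            ["apical_shaft_synapse_density", "spine_density"]
        ].to_numpy()
        ok = np.isfinite(dens).all(axis=1)
        feats = np.column_stack([es.matrix, dens])[ok]
        ei_model = tune_classifier(feats, is_inhib[ok].astype(int),
                                   SMALL_LOGISTIC, seed=0)
        report = run_qc_cascade(
            es, frag_model, ei_model,
            VolumeBounds((0, 1000), (0, 1000)), margin=20.0,
        )
        c = report.counts()
        assert c["input"] == (
            c["retained"] + c["removed_boundary"] + c["removed_fragment"]
            + c["removed_no_density"] + c["removed_inhibitory"]
        )
        # planted fragments (away from the boundary) are nearly all caught
        frag_ids = set(es.ids[is_frag])
        caught = frag_ids & (
            set(report.removed_fragment) | set(report.removed_boundary)
        )
        assert len(caught) >= 0.95 * len(frag_ids)

    def test_all_pass_set_is_identity(self, rng):
        es, is_frag, is_inhib = embedding_fixture(rng, n=200)
        es.metadata["spine_density"] = 1.2  # no missing densities
        frag_model = tune_classifier(es.matrix, is_frag.astype(int),
                                     SMALL_SVM, seed=0)
        feats = np.column_stack(
            [es.matrix,
             es.metadata[["apical_shaft_synapse_density", "spine_density"]]]
        )
        ei_model = tune_classifier(feats, is_inhib.astype(int),
                                   SMALL_LOGISTIC, seed=0)
        clean = es.select(~(is_frag | is_inhib))
        report = run_qc_cascade(
            clean, frag_model, ei_model,
            VolumeBounds((-1e6, 1e6), (-1e6, 1e6)), margin=0.0,
        )
        c = report.counts()
        assert c["removed_boundary"] == 0 and c["removed_no_density"] == 0
        assert c["retained"] >= 0.97 * clean.n  # classifiers near-perfect


class TestLayerBoundaries:
    def test_clean_gap_yields_zero_misclassification(self, rng):
        n = 200
        x = rng.uniform(-300, 300, n)
        upper = rng.uniform(100, 380, n // 2)
        lower = rng.uniform(420, 700, n - n // 2)
        depth = np.concatenate([upper, lower])
        labels = np.array(["L2/3"] * (n // 2) + ["L4"] * (n - n // 2))
        model = fit_layer_boundaries(np.column_stack([x, depth]), labels,
                                     n_segments=1)
        assigned = assign_layers(model, np.column_stack([x, depth]))
        assert (assigned == labels).all()

    def test_slanted_boundary_recovered_within_10um_rms(self, rng):
        n = 1200
        x = rng.uniform(-400, 400, n)
        true_boundary = 350.0 + 0.05 * x
        above = rng.random(n) < 0.5
        offset = rng.uniform(8, 150, n)
        depth = np.where(above, true_boundary - offset, true_boundary + offset)
        depth = depth + rng.normal(0, 5, n)  # label noise at the boundary
        labels = np.where(above, "L2/3", "L4")
        model = fit_layer_boundaries(np.column_stack([x, depth]), labels,
                                     n_segments=3, seed=0)
        grid = np.linspace(-380, 380, 120)
        fitted = model.boundary_depth(0, grid)
        rms = np.sqrt(np.mean((fitted - (350.0 + 0.05 * grid)) ** 2))
        assert rms < 10.0

    def test_boundaries_strictly_ordered(self, rng):
        n = 600
        x = rng.uniform(-300, 300, n)
        layer = rng.choice(["L2/3", "L4", "L5"], n)
        centers = {"L2/3": 250, "L4": 420, "L5": 560}
        depth = np.array([centers[l] for l in layer]) + rng.normal(0, 30, n)
        model = fit_layer_boundaries(np.column_stack([x, depth]), layer,
                                     n_segments=2)
        assert model.ordered()

    def test_absent_layer_rejected(self, rng):
        pos = np.column_stack([rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)])
        with pytest.raises(ValueError, match="absent"):
            fit_layer_boundaries(pos, ["L4"] * 10, layer_order=["L4", "L5"])


def termination_fixture():
    """30 neurons with hand-computable rule outcomes."""
    rows = []
    # 10 L4 neurons: apical top depths 10..190; those > 96 are removed (5)
    for i, depth in enumerate(range(10, 200, 20)):
        rows.append(("L4-%d" % i, "L4", float(depth), 0, False, False))
    # 10 L5 neurons in 2 clusters: cluster 0 has 6/10... use 5+5 split:
    # cluster 0: 3 of 5 flagged (60% > 50% -> removed); cluster 1: 2 of 5 (kept)
    flags0 = [True, True, True, False, False]
    flags1 = [True, True, False, False, False]
    for i, f in enumerate(flags0):
        rows.append(("L5-a%d" % i, "L5", 50.0, 0, f, False))
    for i, f in enumerate(flags1):
        rows.append(("L5-b%d" % i, "L5", 50.0, 1, f, False))
    # 10 L6 neurons: 4 left the volume
    for i in range(10):
        rows.append(("L6-%d" % i, "L6", 50.0, 2, False, i < 4))
    df = pd.DataFrame(
        rows,
        columns=["id", "layer", "apical_top_depth", "cluster_id",
                 "flag_unnatural", "left_volume"],
    ).set_index("id")
    return df


class TestTerminationFilters:
    def test_hand_computed_retained_set(self):
        df = termination_fixture()
        retained, counts = apply_termination_filters(df)
        assert counts["removed_l4_deep_apical"] == 5   # depths 110..190
        assert counts["removed_l5_bad_cluster"] == 5   # whole cluster 0
        assert counts["removed_l6_left_volume"] == 4
        assert counts["retained"] == 16
        assert "L4-0" in retained and "L4-9" not in retained
        assert not any(r.startswith("L5-a") for r in retained)
        assert sum(r.startswith("L5-b") for r in retained) == 5

    def test_l4_threshold_semantics(self):
        df = pd.DataFrame(
            {
                "layer": ["L4", "L4", "L4"],
                "apical_top_depth": [50.0, 96.0, 100.0],
                "cluster_id": [0, 0, 0],
                "flag_unnatural": [False] * 3,
                "left_volume": [False] * 3,
            },
            index=["shallow", "at96", "deep"],
        )
        retained, _ = apply_termination_filters(df)
        assert set(retained) == {"shallow", "at96"}  # strictly more than 96

    def test_l5_majority_threshold_is_strict(self):
        df = termination_fixture()
        # exactly 50% flagged: cluster retained
        df.loc[df.index.str.startswith("L5-a"), "flag_unnatural"] = (
            [True, True, False, False, False]
        )
        retained, counts = apply_termination_filters(df)
        assert counts["removed_l5_bad_cluster"] == 0


class TestF1Threshold:
    def test_perfect_separation_yields_f1_one(self):
        df = pd.DataFrame(
            {"depth": [50, 60, 70, 110, 120, 130],
             "is_natural": [True, True, True, False, False, False]}
        )
        t = select_f1_threshold(df)
        assert 70 <= t < 110

    def test_single_natural_anchors_threshold(self):
        df = pd.DataFrame(
            {"depth": [96.0, 150, 180, 200],
             "is_natural": [True, False, False, False]}
        )
        assert select_f1_threshold(df) == 96.0

    def test_matches_exhaustive_scan(self, rng):
        depth = rng.uniform(0, 200, 40)
        natural = depth + rng.normal(0, 40, 40) < 100
        if natural.all() or not natural.any():
            natural[0] = not natural[0]
        df = pd.DataFrame({"depth": depth, "is_natural": natural})
        t = select_f1_threshold(df)

        def f1_at(th):
            retained = depth <= th
            tp = (retained & natural).sum()
            fp = (retained & ~natural).sum()
            fn = (~retained & natural).sum()
            return 2 * tp / (2 * tp + fp + fn) if tp else 0.0

        best = max(f1_at(th) for th in np.unique(depth))
        assert f1_at(t) == pytest.approx(best)
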