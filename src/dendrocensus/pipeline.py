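"""End-to-end study drivers with config, manifest and CSV outputs.

Two orchestrated runs mirror the figure-level analyses:

* ``run_continuum_study`` — for each (true component count, σ²) condition,
  generate a calibrated synthetic mixture, fit a GMM ensemble, and write the
  ARI consistency curves, per-pair dip tables, thresholded cluster-graph
  edge lists and the max-nearest-neighbor-dip summary.
* ``run_morphology_census`` — generate (or accept) a skeleton cohort, write
  the morphometric table, per-layer Spearman correlation matrices of the six
  descriptors, descriptor-vs-embedding predictive R², V1-vs-HVA style area
  contrasts and the apical-termination filter audit.

Every output is a deterministic function of (config, seed); the manifest
records all seeds and parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import continuum
from .mixtures import generate_calibrated_means, sample_mixture
from .morphometrics import morphometric_table
from .qc import apply_termination_filters
from .structure_function import area_contrast
from .synth_neurons import SyntheticVolumeSpec, generate_cohort, make_volume_frame

__all__ = ["ContinuumConfig", "CensusConfig", "run_continuum_study",
           "run_morphology_census"]

_DESCRIPTORS = ["soma_depth", "height", "total_apical_length",
                "apical_width", "total_basal_length", "basal_bias"]


@dataclass
class ContinuumConfig:
    k_true: tuple = (20,)
    sigma2: tuple = (0.005, 0.01, 0.03, 0.05, 0.07, 0.1, 0.3, 0.5, 0.7, 1.0)
    n_samples: int = 32571
    dim: int = 32
    nn3_target: float = 2.38
    component_counts: tuple = (7, 10, 15, 20, 40, 60, 80)
    n_runs: int = 100
    knn: int = 3
    seed: int = 0
    do_consistency: bool = True
    do_dip: bool = True

    @classmethod
    def from_yaml(cls, path) -> "ContinuumConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        return cfg


def run_continuum_study(config: ContinuumConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "conditions": []}

    curve_rows, dip_rows, edge_rows, maxdip_rows = [], [], [], []
    for K in config.k_true:
        spec0 = generate_calibrated_means(
            K, config.dim, config.nn3_target, seed=config.seed + 17 * K
        )
        for s2 in config.sigma2:
            spec = spec0.with_sigma2(float(s2))
            sample_seed = config.seed + 1013 * K + int(1e6 * s2) % 7919
            X, true_labels = sample_mixture(spec, config.n_samples, seed=sample_seed)
            cond = {"k_true": K, "sigma2": s2, "sample_seed": sample_seed}

            runs_at_ktrue = None
            if config.do_consistency:
                curve, runs = continuum.consistency_curve(
                    X, config.component_counts, n_runs=config.n_runs,
                    seed=config.seed + 31 * K, return_runs=True,
                )
                for row in curve.as_frame().itertuples(index=False):
                    curve_rows.append(
                        {"k_true": K, "sigma2": s2, **row._asdict()}
                    )
                runs_at_ktrue = runs.get(K)

            if config.do_dip:
                if runs_at_ktrue:
                    best = continuum.select_best_run(runs_at_ktrue)
                    labels = best.full_labels(X.shape[0])
                    means = best.means
                else:
                    run = continuum.fit_gmm(X, K, "isotropic",
                                            seed=config.seed + 31 * K)
                    labels = run.full_labels(X.shape[0])
                    means = run.means
                graph = continuum.build_cluster_graph(X, labels, means,
                                                      k=config.knn)
                for i, j, dist, dip in graph.edges:
                    edge_rows.append(
                        {"k_true": K, "sigma2": s2, "source": i, "target": j,
                         "distance": dist, "dip": dip}
                    )
                for i, dip in sorted(graph.nearest_neighbor_dip.items()):
                    dip_rows.append(
                        {"k_true": K, "sigma2": s2, "cluster": i,
                         "nn_dip": dip}
                    )
                maxdip_rows.append(
                    {"k_true": K, "sigma2": s2,
                     "max_neighbor_dip": continuum.max_neighbor_dip(graph),
                     "distance_threshold": graph.distance_threshold}
                )
            manifest["conditions"].append(cond)

    if curve_rows:
        pd.DataFrame(curve_rows).to_csv(out / "consistency_curves.csv", index=False)
    if config.do_dip:
        pd.DataFrame(edge_rows).to_csv(out / "cluster_graph_edges.csv", index=False)
        pd.DataFrame(dip_rows).to_csv(out / "nearest_neighbor_dips.csv", index=False)
        pd.DataFrame(maxdip_rows).to_csv(out / "max_neighbor_dip.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class CensusConfig:
    n_neurons: int = 200
    seed: int = 0
    depth_width_slope: float = -0.4
    volume: SyntheticVolumeSpec = field(default_factory=SyntheticVolumeSpec)
    layer_edges: tuple = (0.0, 320.0, 450.0, 600.0, 1e9)   # L2/3, L4, L5, L6
    layer_names: tuple = ("L2/3", "L4", "L5", "L6")
    embedding_noise: float = 0.5
    area_split_x: float = 0.0   # soma x >= split -> "HVA", else "V1"
    n_tests: int = 4
    alpha: float = 0.01


def run_morphology_census(config: CensusConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    specs, graphs = generate_cohort(
        config.n_neurons, seed=config.seed, volume=config.volume,
        depth_width_slope=config.depth_width_slope,
    )
    frame = make_volume_frame(config.volume)
    table = morphometric_table(graphs, frame=frame)
    table["layer"] = pd.cut(
        table["soma_depth"], bins=list(config.layer_edges),
        labels=list(config.layer_names),
    ).astype(str)
    table["area"] = np.where(
        [s.soma_position[0] >= config.area_split_x for s in specs], "HVA", "V1"
    )
    table.to_csv(out / "morphometrics.csv")

    # per-layer Spearman correlation matrices of the six descriptors
    spearman_rows = []
    for layer, sub in table.groupby("layer", observed=True):
        if len(sub) < 5:
            continue
        for a_i, a in enumerate(_DESCRIPTORS):
            for b in _DESCRIPTORS[a_i + 1:]:
                rho = stats.spearmanr(sub[a], sub[b]).statistic
                spearman_rows.append(
                    {"layer": layer, "descriptor_a": a, "descriptor_b": b,
                     "spearman_rho": float(rho), "n": len(sub)}
                )
    spearman = pd.DataFrame(spearman_rows)
    spearman.to_csv(out / "layer_spearman.csv", index=False)

    # descriptor-vs-embedding predictive R²: synthetic embeddings are a noisy
    # linear image of the standardized descriptors, so each descriptor's
    # cross-validated linear R² onto the embedding matrix gauges how much of
    # it the embedding carries
    Z = table[_DESCRIPTORS].to_numpy(dtype=float)
    Zs = (Z - Z.mean(0)) / Z.std(0)
    mix = rng.standard_normal((Zs.shape[1], 32))
    emb = Zs @ mix + config.embedding_noise * rng.standard_normal(
        (Zs.shape[0], 32)
    )
    from sklearn.linear_model import LinearRegression
    from sklearn.model_selection import cross_val_predict

    r2_rows = []
    for d_i, name in enumerate(_DESCRIPTORS):
        pred = cross_val_predict(LinearRegression(), emb, Zs[:, d_i], cv=5)
        ss = 1 - np.sum((Zs[:, d_i] - pred) ** 2) / np.sum(
            (Zs[:, d_i] - Zs[:, d_i].mean()) ** 2
        )
        r2_rows.append({"descriptor": name, "r2": float(ss)})
    pd.DataFrame(r2_rows).to_csv(out / "descriptor_embedding_r2.csv", index=False)

    # V1-vs-HVA apical-length contrasts per layer
    contrast_rows = []
    for layer, sub in table.groupby("layer", observed=True):
        a = sub.loc[sub.area == "V1", "total_apical_length"]
        b = sub.loc[sub.area == "HVA", "total_apical_length"]
        if len(a) < 2 or len(b) < 2:
            continue
        c = area_contrast(a, b, n_tests=config.n_tests, alpha=config.alpha)
        contrast_rows.append(
            {"layer": layer, "t": c.t, "p": c.p, "cohens_d": c.cohens_d,
             "corrected_alpha": c.corrected_alpha,
             "significant": c.significant, "n_v1": c.n1, "n_hva": c.n2}
        )
    pd.DataFrame(contrast_rows).to_csv(out / "area_contrasts.csv", index=False)

    # apical-termination filter audit on derived per-neuron records
    apical_top = table["soma_depth"] - np.array(
        [s.apical_total_length - s.apical_width for s in specs]
    )
    records = pd.DataFrame(
        {
            "layer": table["layer"].to_numpy(),
            "apical_top_depth": apical_top.to_numpy(),
            "cluster_id": rng.integers(0, 15, len(table)),
            "flag_unnatural": rng.random(len(table)) < 0.2,
            "left_volume": rng.random(len(table)) < 0.05,
        },
        index=table.index,
    )
    retained, audit = apply_termination_filters(records)
    with open(out / "termination_audit.json", "w") as fh:
        json.dump(audit, fh, indent=2)

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "volume"},
            "volume": asdict(config.volume),
        },
        "n_neurons": int(len(table)),
        "termination_audit": audit,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
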