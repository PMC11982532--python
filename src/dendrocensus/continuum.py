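"""Cluster-versus-continuum machinery.

Whether a population of embeddings is better described by discrete types or
a continuum is a matter of degree.  Three complementary measurements are
used:

* **Clustering consistency.**  Ensembles of isotropic-covariance Gaussian
  mixture models are fit with different seeds on a 90% training split; the
  mean pairwise adjusted Rand index (ARI) of their held-out-split labelings
  measures whether a given number of components can be recovered reliably.
* **Pairwise modality.**  All points of two neighboring clusters are
  projected onto the line connecting the cluster means; Hartigan's dip
  statistic of the projected 1-d sample, scaled by 4 so that two balanced
  point masses give exactly 1, quantifies how bimodal the pair is.
* **Cluster graph.**  Each cluster is connected to its k = 3 nearest
  neighbors in embedding space; edges farther than the mean third-neighbor
  distance are dropped, and each retained edge carries the scaled dip of the
  projected pair (display weight = inverse dip: thicker = more connected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.mixture import GaussianMixture

from .dip import dip_statistic, empirical_cdf

__all__ = [
    "ClusteringRun",
    "ConsistencyCurve",
    "ClusterGraph",
    "fit_gmm",
    "adjusted_rand_index",
    "consistency_curve",
    "project_cluster_pair",
    "scaled_dip",
    "build_cluster_graph",
    "max_neighbor_dip",
    "select_best_run",
]

_COV_MAP = {"isotropic": "spherical", "diagonal": "diag"}


@dataclass
class ClusteringRun:
    labels_train: np.ndarray
    labels_val: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    means: np.ndarray
    weights: np.ndarray
    covariance_kind: str
    train_loglik: float
    validation_loglik: float
    loglik_path: np.ndarray
    seed: int

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    def full_labels(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=int)
        out[self.train_idx] = self.labels_train
        out[self.val_idx] = self.labels_val
        return out


@dataclass
class ConsistencyCurve:
    component_counts: list
    mean_ari: list
    std_ari: list
    run_count: list

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_components": self.component_counts,
                "mean_ari": self.mean_ari,
                "std_ari": self.std_ari,
                "n_runs": self.run_count,
            }
        )


@dataclass
class ClusterGraph:
    means: np.ndarray
    k: int
    distance_threshold: float
    edges: list = field(default_factory=list)  # (i, j, distance, scaled dip)
    nearest_neighbor_dip: dict = field(default_factory=dict)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i in range(self.means.shape[0]):
            g.add_node(i, mean=self.means[i])
        for i, j, dist, dip in self.edges:
            width = np.inf if dip == 0 else 1.0 / dip
            g.add_edge(i, j, distance=dist, dip=dip, width=width)
        return g


def train_validation_split(n: int, seed: int, split_fraction: float = 0.1):
    """Deterministic 90/10 split shared across ensemble runs."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(split_fraction * n)))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def fit_gmm(
    data: np.ndarray,
    n_components: int,
    covariance_kind: str = "isotropic",
    seed: int = 0,
    split_fraction: float = 0.1,
    split: Optional[tuple[np.ndarray, np.ndarray]] = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_init: int = 3,
    max_restarts: int = 5,
) -> ClusteringRun:
    """EM fit on the training split with an explicit log-likelihood path.

    The model is stepped one EM iteration at a time (warm start) so the
    monotone per-sample training log-likelihood path is observable;
    convergence at ``tol`` on the average log-likelihood, k-means++
    initialization, variance floor 1e-8.  Each fit keeps the best of
    ``n_init`` initializations by training log-likelihood, which suppresses
    poor EM local optima without touching the data conditions.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if covariance_kind not in _COV_MAP:
        raise ValueError(f"unknown covariance_kind {covariance_kind!r}")
    if split is None:
        split = train_validation_split(X.shape[0], seed=seed ^ 0x5F5F5F,
                                       split_fraction=split_fraction)
    train_idx, val_idx = split
    Xtr, Xval = X[train_idx], X[val_idx]
    if Xtr.shape[0] < n_components:
        raise ValueError("fewer training rows than components")

    last_err: Exception | None = None
    best: tuple[float, GaussianMixture, list] | None = None
    attempts = 0
    inits = 0
    while inits < n_init and attempts < n_init + max_restarts:
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type=_COV_MAP[covariance_kind],
            random_state=seed + 1000003 * attempts,
            init_params="k-means++",
            reg_covar=1e-8,
            warm_start=True,
            max_iter=1,
            tol=0.0,  # convergence handled manually on the path
        )
        attempts += 1
        path = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(max_iter):
                gm.fit(Xtr)
                path.append(gm.lower_bound_)
                if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
                    break
        if not np.all(np.isfinite(gm.means_)):
            last_err = RuntimeError("EM diverged")
            continue
        inits += 1
        if best is None or path[-1] > best[0]:
            best = (path[-1], gm, path)
    if best is None:
        raise RuntimeError(
            f"EM failed after {attempts} attempts"
        ) from last_err
    _, gm, path = best
    return ClusteringRun(
        labels_train=gm.predict(Xtr),
        labels_val=gm.predict(Xval),
        train_idx=train_idx,
        val_idx=val_idx,
        means=gm.means_,
        weights=gm.weights_,
        covariance_kind=covariance_kind,
        train_loglik=float(gm.score(Xtr)),
        validation_loglik=float(gm.score(Xval)),
        loglik_path=np.asarray(path),
        seed=seed,
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index from the pair-counting contingency table."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("labelings differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    cont = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(a.size)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def consistency_curve(
    data: np.ndarray,
    component_counts: Sequence[int],
    n_runs: int = 100,
    seed: int = 0,
    split_fraction: float = 0.1,
    return_runs: bool = False,
):
    """Mean pairwise validation-split ARI of a GMM ensemble per K.

    One 90/10 split is fixed for the whole analysis so that every pairwise
    ARI compares labelings of identical held-out items.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for pairwise ARI")
    X = np.asarray(data, dtype=float)
    split = train_validation_split(X.shape[0], seed=seed ^ 0x5F5F5F,
                                   split_fraction=split_fraction)
    counts, means_, stds_, nruns_ = [], [], [], []
    runs_by_k = {}
    for K in component_counts:
        runs = []
        for r in range(n_runs):
            try:
                runs.append(
                    fit_gmm(X, K, "isotropic", seed=seed + 7919 * r + K,
                            split=split)
                )
            except RuntimeError:
                continue
        if len(runs) < 2:
            continue
        aris = [
            adjusted_rand_index(runs[i].labels_val, runs[j].labels_val)
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        counts.append(int(K))
        means_.append(float(np.mean(aris)))
        stds_.append(float(np.std(aris)))
        nruns_.append(len(runs))
        runs_by_k[int(K)] = runs
    curve = ConsistencyCurve(counts, means_, stds_, nruns_)
    if return_runs:
        return curve, runs_by_k
    return curve


def project_cluster_pair(
    data: np.ndarray, labels: np.ndarray, i: int, j: int, means: np.ndarray
) -> np.ndarray:
    """Signed coordinates of the points of clusters i and j along the line
    from mean_i to mean_j (origin at mean_i)."""
    if i == j:
        raise ValueError("need two distinct clusters")
    direction = means[j] - means[i]
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError(f"clusters {i} and {j} have coincident means")
    labels = np.asarray(labels)
    mask = (labels == i) | (labels == j)
    if not (labels == i).any() or not (labels == j).any():
        raise ValueError("both clusters must be nonempty")
    pts = np.asarray(data, dtype=float)[mask]
    return (pts - means[i]) @ (direction / norm)


def scaled_dip(sample_1d: np.ndarray, return_flag: bool = False):
    """4 x Hartigan's dip, so two balanced point masses score exactly 1.

    Degenerate samples (fewer than two distinct values) return 0 with a
    degeneracy flag available via ``return_flag``.
    """
    x = np.asarray(sample_1d, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 points for a meaningful dip")
    value = 4.0 * dip_statistic(x)
    if return_flag:
        return value, bool(np.unique(x).size < 2)
    return value


def pair_cdf(sample_1d: np.ndarray):
    """Empirical CDF of a projected pair (for CDF-inset style plots)."""
    return empirical_cdf(np.asarray(sample_1d, dtype=float))


def build_cluster_graph(
    data: np.ndarray,
    labels: np.ndarray,
    means: np.ndarray,
    k: int = 3,
) -> ClusterGraph:
    """k-nearest-neighbor graph over cluster means with dip-annotated edges.

    The distance threshold is the mean over clusters of the distance to
    their third-nearest neighbor; farther neighbor relations are dropped as
    spurious.  Each retained unordered pair carries the scaled dip of the
    pair projection; the per-cluster nearest-neighbor dip is stored for the
    continuum summary.
    """
    means = np.asarray(means, dtype=float)
    K = means.shape[0]
    if k >= K:
        raise ValueError("k must be smaller than the number of clusters")
    D = squareform(pdist(means))
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1)
    third = np.sort(D, axis=1)[:, min(2, k - 1)]
    threshold = float(third.mean())

    labels = np.asarray(labels)
    occupied = set(np.unique(labels).tolist())
    pair_dip: dict[tuple[int, int], float] = {}

    def dip_of(i, j):
        key = (min(i, j), max(i, j))
        if key not in pair_dip:
            proj = project_cluster_pair(data, labels, key[0], key[1], means)
            pair_dip[key] = scaled_dip(proj)
        return pair_dip[key]

    edges = []
    seen = set()
    nn_dip = {}
    for i in range(K):
        if i not in occupied:
            continue
        neighbors = [j for j in order[i, :k] if j in occupied]
        for rank, j in enumerate(neighbors):
            if D[i, j] > threshold * (1 + 1e-9):
                continue
            key = (min(i, int(j)), max(i, int(j)))
            if key in seen:
                continue
            seen.add(key)
            edges.append((key[0], key[1], float(D[i, j]), dip_of(*key)))
        if neighbors:
            nn_dip[i] = dip_of(i, int(neighbors[0]))
    return ClusterGraph(
        means=means,
        k=k,
        distance_threshold=threshold,
        edges=edges,
        nearest_neighbor_dip=nn_dip,
    )


def max_neighbor_dip(graph: ClusterGraph) -> float:
    """Maximum over clusters of the scaled dip to the nearest neighbor."""
    if not graph.nearest_neighbor_dip:
        raise ValueError("cluster graph has no occupied clusters")
    return float(max(graph.nearest_neighbor_dip.values()))


def select_best_run(runs: Sequence[ClusteringRun]) -> ClusteringRun:
    """Run with the best validation log-likelihood; ties -> lowest seed."""
    runs = list(runs)
    if not runs:
        raise ValueError("no runs given")
    ks = {r.n_components for r in runs}
    if len(ks) > 1:
        raise ValueError("runs mix different component counts")
    return min(runs, key=lambda r: (-r.validation_loglik, r.seed))
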