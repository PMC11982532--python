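"""Identity-preserving skeleton-graph augmentations.

Self-supervised embedding models are trained on pairs of randomly augmented
"views" of the same neuron.  A view is produced by composing: node
subsampling to 200 nodes (always retaining branch points, bridging dropped
pass-through nodes), a uniform rotation about the y-axis (the pia normal),
deletion of 5 terminal subbranches, Gaussian node-position jitter (σ = 1)
and a global Gaussian translation (σ = 1).  The same operations double as
robustness probes for the morphometrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import SkeletonGraph

__all__ = [
    "AugmentationConfig",
    "subsample_graph",
    "delete_subbranches",
    "make_view",
]


@dataclass(frozen=True)
class AugmentationConfig:
    n_keep: int = 200
    n_subbranches: int = 5
    jitter_sigma: float = 1.0
    translate_sigma: float = 1.0
    rotate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")
        if self.jitter_sigma < 0 or self.translate_sigma < 0:
            raise ValueError("sigmas must be nonnegative")


def _take_subset(graph: SkeletonGraph, keep_rows: np.ndarray) -> SkeletonGraph:
    """Restrict to ``keep_rows`` (must include the root), bridging dropped
    pass-through nodes by reattaching children to the nearest kept ancestor."""
    keep = np.zeros(graph.n_nodes, dtype=bool)
    keep[keep_rows] = True
    pidx = graph.parent_indices()

    new_parent_row = np.full(graph.n_nodes, -1, dtype=int)
    order = _topological_order(graph)
    nearest_kept = np.full(graph.n_nodes, -1, dtype=int)
    for r in order:
        p = pidx[r]
        if p == -1:
            nearest_kept[r] = r if keep[r] else -1
        else:
            nearest_kept[r] = r if keep[r] else nearest_kept[p]
        if keep[r] and p != -1:
            new_parent_row[r] = nearest_kept[p]

    rows = np.flatnonzero(keep)
    ids = graph.ids[rows]
    parent_ids = np.array(
        [
            -1 if new_parent_row[r] == -1 else int(graph.ids[new_parent_row[r]])
            for r in rows
        ]
    )
    return SkeletonGraph(
        ids=ids,
        positions=graph.positions[rows].copy(),
        radii=graph.radii[rows].copy(),
        compartments=graph.compartments[rows].copy(),
        parents=parent_ids,
        meta=dict(graph.meta),
    )


def _topological_order(graph: SkeletonGraph) -> list[int]:
    kids = graph.children_map()
    order, stack = [], [graph.root_index]
    while stack:
        r = stack.pop()
        order.append(r)
        stack.extend(kids[r])
    return order


def subsample_graph(graph: SkeletonGraph, n_keep: int = 200,
                    seed: int = 0) -> SkeletonGraph:
    """Randomly drop pass-through nodes down to ``n_keep``, keeping the root
    and every branch point; dropped nodes are bridged so the tree stays
    connected."""
    if graph.n_nodes <= n_keep:
        return graph.copy()
    kids = graph.children_map()
    mandatory = {graph.root_index}
    mandatory.update(r for r, ch in kids.items() if len(ch) >= 2)
    # terminal tips are kept too: dropping them would truncate, not bridge
    mandatory.update(r for r, ch in kids.items() if not ch)
    optional = np.array(
        [r for r in range(graph.n_nodes) if r not in mandatory], dtype=int
    )
    budget = n_keep - len(mandatory)
    rng = np.random.default_rng(seed)
    if budget > 0:
        chosen = rng.choice(optional, size=min(budget, optional.size),
                            replace=False)
        keep_rows = np.concatenate([np.fromiter(mandatory, int), chosen])
    else:
        keep_rows = np.fromiter(mandatory, int)
    return _take_subset(graph, keep_rows)


def delete_subbranches(graph: SkeletonGraph, n_subbranches: int = 5,
                       seed: int = 0) -> SkeletonGraph:
    """Remove terminal branches (leaf up to, not including, the nearest
    branch point); never removes the root."""
    if n_subbranches == 0:
        return graph.copy()
    g = graph
    rng = np.random.default_rng(seed)
    removed = 0
    while removed < n_subbranches:
        kids = g.children_map()
        root = g.root_index
        leaves = [r for r, ch in kids.items() if not ch and r != root]
        if len(leaves) <= 1:
            break  # keep at least one path to the root
        leaf = int(rng.choice(np.asarray(leaves)))
        pidx = g.parent_indices()
        seg = [leaf]
        cur = leaf
        while True:
            p = pidx[cur]
            if p == -1 or len(kids[p]) >= 2 or p == root:
                break
            seg.append(p)
            cur = p
        keep_rows = np.setdiff1d(np.arange(g.n_nodes), np.asarray(seg))
        g = _take_subset(g, keep_rows)
        removed += 1
    return g


def rotate_y(positions: np.ndarray, angle_rad: float,
             center: np.ndarray) -> np.ndarray:
    """Rotate about a vertical axis through ``center`` (y untouched)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rel = positions - center
    out = rel.copy()
    out[:, 0] = c * rel[:, 0] + s * rel[:, 2]
    out[:, 2] = -s * rel[:, 0] + c * rel[:, 2]
    return out + center


def make_view(graph: SkeletonGraph, config: AugmentationConfig) -> SkeletonGraph:
    """One augmented view: subsample -> y-rotation -> subbranch deletion ->
    node jitter -> global translation (all seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    g = subsample_graph(graph, config.n_keep,
                        seed=int(rng.integers(2**31 - 1)))
    if config.rotate:
        angle = rng.uniform(0.0, 2 * np.pi)
        soma = g.positions[g.root_index]
        g.positions = rotate_y(g.positions, angle, soma)
    g = delete_subbranches(g, config.n_subbranches,
                           seed=int(rng.integers(2**31 - 1)))
    if config.jitter_sigma > 0:
        g.positions = g.positions + rng.normal(
            0.0, config.jitter_sigma, g.positions.shape
        )
    if config.translate_sigma > 0:
        g.positions = g.positions + rng.normal(0.0, config.translate_sigma, 3)
    return g
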