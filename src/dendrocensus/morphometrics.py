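"""The six skeleton morphometrics for excitatory neurons.

All descriptors are computed on the standardized skeleton (depth relative to
the pia, pia = 0, depth increasing with y); axon nodes are ignored
throughout.  An edge inherits the compartment label of its child node.

* soma depth — depth of the soma node.
* height — depth extent (max - min node depth) over all non-axon nodes.
* total apical / basal length — summed Euclidean edge lengths per label.
* apical width — maximum pairwise distance between apical nodes projected
  onto the (x, z) plane (rotation-invariant "widest extent").
* basal bias — depth of the length-weighted basal center of mass (edge
  midpoints weighted by edge length) minus the soma depth; positive means
  the basal arbor sits below the soma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .coords import VolumeFrame, standardize_points
from .skeleton import Compartment, SkeletonGraph, SkeletonStructureError

__all__ = [
    "MorphometricRecord",
    "compartment_length",
    "apical_width",
    "compute_morphometrics",
    "morphometric_table",
]

_FIELDS = (
    "soma_depth",
    "height",
    "total_apical_length",
    "apical_width",
    "total_basal_length",
    "basal_bias",
)


@dataclass(frozen=True)
class MorphometricRecord:
    soma_depth: float
    height: float
    total_apical_length: float
    apical_width: float
    total_basal_length: float
    basal_bias: Optional[float]   # None when the neuron has no basal edges
    apical_present: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _FIELDS}


def _edge_arrays(graph: SkeletonGraph):
    edges = graph.edges()
    if edges.size == 0:
        return (np.empty((0, 3)),) * 2 + (np.empty(0, int),)
    p = graph.positions[edges[:, 0]]
    c = graph.positions[edges[:, 1]]
    labels = graph.compartments[edges[:, 1]]  # edge inherits child's label
    return p, c, labels


def compartment_length(graph: SkeletonGraph, compartment: Compartment) -> float:
    """Summed Euclidean length of edges assigned to ``compartment`` (μm)."""
    p, c, labels = _edge_arrays(graph)
    mask = labels == int(compartment)
    if not mask.any():
        return 0.0
    return float(np.linalg.norm(c[mask] - p[mask], axis=1).sum())


def _max_pairwise_xz(points_xz: np.ndarray) -> float:
    n = points_xz.shape[0]
    if n < 2:
        return 0.0
    uniq = np.unique(points_xz, axis=0)
    if uniq.shape[0] < 2:
        return 0.0
    if uniq.shape[0] > 64:
        try:
            hull = ConvexHull(uniq)
            uniq = uniq[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: brute force below
    return float(pdist(uniq).max())


def apical_width(graph: SkeletonGraph) -> float:
    """Widest extent of the apical tree in the (x, z) plane (μm)."""
    mask = graph.compartments == int(Compartment.APICAL)
    pts = graph.positions[mask][:, [0, 2]]
    return _max_pairwise_xz(pts)


def compute_morphometrics(
    graph: SkeletonGraph, frame: Optional[VolumeFrame] = None
) -> MorphometricRecord:
    """All six descriptors; standardizes through ``frame`` when given.

    Without a frame the skeleton is assumed already standardized with the
    pia at depth 0.
    """
    g = graph
    if frame is not None:
        g = graph.copy()
        g.positions = standardize_points(graph.positions, frame)
        g.positions[:, 1] -= frame.mean_pia_depth

    soma_rows = np.flatnonzero(g.compartments == int(Compartment.SOMA))
    if soma_rows.size != 1:
        raise SkeletonStructureError(
            f"expected exactly one soma node, found {soma_rows.size}"
        )
    soma_depth = float(g.positions[soma_rows[0], 1])

    keep = g.compartments != int(Compartment.AXON)
    depths = g.positions[keep, 1]
    height = float(depths.max() - depths.min())

    total_apical = compartment_length(g, Compartment.APICAL)
    total_basal = compartment_length(g, Compartment.BASAL)
    width = apical_width(g)

    p, c, labels = _edge_arrays(g)
    bmask = labels == int(Compartment.BASAL)
    if bmask.any():
        seg_len = np.linalg.norm(c[bmask] - p[bmask], axis=1)
        mid_y = 0.5 * (c[bmask, 1] + p[bmask, 1])
        com_depth = float(np.average(mid_y, weights=seg_len))
        basal_bias = com_depth - soma_depth
    else:
        basal_bias = None

    return MorphometricRecord(
        soma_depth=soma_depth,
        height=height,
        total_apical_length=total_apical,
        apical_width=width,
        total_basal_length=total_basal,
        basal_bias=basal_bias,
        apical_present=bool(
            (g.compartments == int(Compartment.APICAL)).any()
        ),
    )


def morphometric_table(graphs, frame: Optional[VolumeFrame] = None, ids=None):
    """Records for a cohort as a pandas DataFrame (one row per neuron)."""
    import pandas as pd

    rows = []
    for k, g in enumerate(graphs):
        rec = compute_morphometrics(g, frame=frame)
        row = rec.as_dict()
        row["neuron_id"] = ids[k] if ids is not None else k
        row["apical_present"] = rec.apical_present
        rows.append(row)
    return pd.DataFrame(rows).set_index("neuron_id")
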