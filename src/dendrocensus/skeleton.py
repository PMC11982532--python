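"""Compartment-labeled neuron skeletons and SWC input/output.

A skeleton is a rooted tree of 3-d nodes in micrometres.  Each node carries a
compartment label (soma, axon, basal, apical, oblique, or unlabeled
dendrite).  On disk the community-standard SWC format is used, one
whitespace-delimited line per node::

    id type x y z radius parent_id

with ``parent_id = -1`` for the root.  Type codes follow the declared
dialect: 1=soma, 2=axon, 3=basal dendrite, 4=apical dendrite, 5=oblique
dendrite (reusing the historical "fork point" slot, which SWC leaves
otherwise unassigned), and any other code maps to unlabeled dendrite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "Compartment",
    "SkeletonGraph",
    "SkeletonStructureError",
    "read_swc",
    "write_swc",
    "validate_skeleton",
]


class Compartment(IntEnum):
    DENDRITE_UNLABELED = 0
    SOMA = 1
    AXON = 2
    BASAL = 3
    APICAL = 4
    OBLIQUE = 5


_KNOWN_CODES = {int(c) for c in Compartment}


class SkeletonStructureError(ValueError):
    """Raised when a skeleton violates its tree invariants."""


@dataclass
class SkeletonGraph:
    """Rooted tree skeleton.

    Attributes
    ----------
    ids : (n,) int array of node identifiers (unique).
    positions : (n, 3) float array, micrometres (x, y, z); y is depth.
    radii : (n,) float array (NaN when unknown).
    compartments : (n,) int array of :class:`Compartment` values.
    parents : (n,) int array of parent *ids*; -1 for the root.
    """

    ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    compartments: np.ndarray
    parents: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.compartments = np.asarray(self.compartments, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    def index_of(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.ids)}

    @property
    def root_index(self) -> int:
        roots = np.flatnonzero(self.parents == -1)
        if roots.size != 1:
            raise SkeletonStructureError(
                f"expected exactly one root, found {roots.size}"
            )
        return int(roots[0])

    def parent_indices(self) -> np.ndarray:
        """Parent as row index (-1 for the root)."""
        lookup = self.index_of()
        out = np.empty(self.n_nodes, dtype=int)
        for k, p in enumerate(self.parents):
            out[k] = -1 if p == -1 else lookup[int(p)]
        return out

    def children_map(self) -> dict[int, list[int]]:
        """Row index -> list of child row indices."""
        kids: dict[int, list[int]] = {k: [] for k in range(self.n_nodes)}
        pidx = self.parent_indices()
        for k, p in enumerate(pidx):
            if p >= 0:
                kids[p].append(k)
        return kids

    def edges(self) -> np.ndarray:
        """(m, 2) array of (parent_row, child_row) for every non-root node."""
        pidx = self.parent_indices()
        child = np.flatnonzero(pidx >= 0)
        return np.column_stack([pidx[child], child])

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(
            self.ids.copy(),
            self.positions.copy(),
            self.radii.copy(),
            self.compartments.copy(),
            self.parents.copy(),
            dict(self.meta),
        )


def validate_skeleton(graph: SkeletonGraph) -> list[str]:
    """Return a list of invariant violations; empty iff the graph is valid."""
    problems: list[str] = []
    ids = graph.ids
    if np.unique(ids).size != ids.size:
        dup = ids[np.argmax(np.bincount(ids - ids.min()) > 1)]
        problems.append(f"duplicate node ids (e.g. {int(dup)})")
        return problems
    lookup = graph.index_of()

    roots = np.flatnonzero(graph.parents == -1)
    if roots.size == 0:
        problems.append("no root node (parent -1)")
    elif roots.size > 1:
        problems.append(
            "multiple roots: nodes "
            + ", ".join(str(int(ids[r])) for r in roots)
        )

    somas = np.flatnonzero(graph.compartments == Compartment.SOMA)
    if somas.size == 0:
        problems.append("no soma-labeled node")
    elif somas.size > 1:
        problems.append(
            "multiple soma nodes: "
            + ", ".join(str(int(ids[s])) for s in somas)
        )
    elif roots.size == 1 and somas[0] != roots[0]:
        problems.append("soma node is not the root")

    for k, p in enumerate(graph.parents):
        if p != -1 and int(p) not in lookup:
            problems.append(
                f"node {int(ids[k])} references missing parent {int(p)}"
            )
    if problems:
        return problems

    if not np.all(np.isfinite(graph.positions)):
        bad = np.flatnonzero(~np.isfinite(graph.positions).all(axis=1))
        problems.append(
            "non-finite positions at nodes "
            + ", ".join(str(int(ids[b])) for b in bad[:5])
        )

    # reachability / acyclicity from the root
    if roots.size == 1:
        kids = graph.children_map()
        seen = np.zeros(graph.n_nodes, dtype=bool)
        stack = [int(roots[0])]
        while stack:
            k = stack.pop()
            if seen[k]:
                problems.append(f"cycle involving node {int(ids[k])}")
                return problems
            seen[k] = True
            stack.extend(kids[k])
        if not seen.all():
            unreachable = np.flatnonzero(~seen)
            problems.append(
                "nodes unreachable from root: "
                + ", ".join(str(int(ids[u])) for u in unreachable[:5])
            )
    return problems


def read_swc(path) -> SkeletonGraph:
    """Parse an SWC file into a validated :class:`SkeletonGraph`."""
    path = Path(path)
    rows = []
    unknown_codes = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonStructureError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            rows.append([float(v) for v in parts])
    if not rows:
        raise SkeletonStructureError(f"{path.name}: no nodes")
    arr = np.asarray(rows, dtype=float)
    codes = arr[:, 1].astype(int)
    comp = codes.copy()
    for k, code in enumerate(codes):
        if code not in _KNOWN_CODES:
            unknown_codes.add(int(code))
            comp[k] = Compartment.DENDRITE_UNLABELED
    if unknown_codes:
        import warnings

        warnings.warn(
            f"{path.name}: unknown SWC type codes {sorted(unknown_codes)} "
            "mapped to unlabeled dendrite",
            stacklevel=2,
        )
    graph = SkeletonGraph(
        ids=arr[:, 0].astype(int),
        positions=arr[:, 2:5],
        radii=arr[:, 5],
        compartments=comp,
        parents=arr[:, 6].astype(int),
        meta={"source": str(path)},
    )
    problems = validate_skeleton(graph)
    if problems:
        raise SkeletonStructureError(f"{path.name}: " + "; ".join(problems))
    return graph


def write_swc(graph: SkeletonGraph, path) -> None:
    """Write a valid skeleton to SWC (refuses invalid graphs)."""
    problems = validate_skeleton(graph)
    if problems:
        raise SkeletonStructureError("refusing to write: " + "; ".join(problems))
    order = np.argsort(graph.ids)
    with open(path, "w") as fh:
        fh.write("# SWC skeleton; type codes: 1=soma 2=axon 3=basal 4=apical "
                 "5=oblique 0=unlabeled dendrite\n")
        fh.write("# columns: id type x y z radius parent\n")
        for k in order:
            r = graph.radii[k]
            fh.write(
                f"{int(graph.ids[k])} {int(graph.compartments[k])} "
                f"{graph.positions[k, 0]:.17g} {graph.positions[k, 1]:.17g} "
                f"{graph.positions[k, 2]:.17g} "
                f"{(0.0 if np.isnan(r) else r):.17g} {int(graph.parents[k])}\n"
            )
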