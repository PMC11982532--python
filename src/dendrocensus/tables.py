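"""Embedding tables: one row per neuron, d embedding columns plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["EmbeddingSet", "read_embeddings", "write_embeddings"]

_META_COLS = ["soma_x", "soma_y", "soma_z"]


@dataclass
class EmbeddingSet:
    """n neurons x d-dimensional morphological embedding plus metadata.

    ``metadata`` is row-aligned with ``matrix`` and indexed 0..n-1; it always
    carries soma coordinates (μm) and may carry ``area``, ``label``,
    ``layer`` and ``component_label`` columns.
    """

    ids: np.ndarray
    matrix: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-d")
        if self.ids.size != self.matrix.shape[0]:
            raise ValueError("ids and matrix row count differ")
        if pd.unique(self.ids).size != self.ids.size:
            dup = pd.Series(self.ids).value_counts()
            raise ValueError(
                f"duplicate neuron id: {dup.index[0]!r}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=range(self.ids.size))
        elif len(self.metadata) != self.ids.size:
            raise ValueError("metadata not row-aligned with matrix")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def soma_positions(self) -> np.ndarray:
        return self.metadata[_META_COLS].to_numpy(dtype=float)

    def select(self, mask) -> "EmbeddingSet":
        mask = np.asarray(mask)
        return EmbeddingSet(
            self.ids[mask],
            self.matrix[mask],
            self.metadata.loc[mask].reset_index(drop=True),
        )


def read_embeddings(path, dim: Optional[int] = None) -> EmbeddingSet:
    """Read a delimited embedding table (header row, columns e0..e{d-1})."""
    df = pd.read_csv(path)
    if "neuron_id" not in df.columns:
        raise ValueError(f"{path}: missing 'neuron_id' column")
    ecols = sorted(
        (c for c in df.columns if c.startswith("e") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if dim is not None:
        want = [f"e{i}" for i in range(dim)]
        missing = set(want) - set(ecols)
        if missing:
            raise ValueError(f"{path}: missing embedding columns {sorted(missing)}")
        ecols = want
    if not ecols:
        raise ValueError(f"{path}: no embedding columns e0..e{{d-1}} found")
    mat = df[ecols].to_numpy()
    bad = np.flatnonzero(~np.isfinite(mat).all(axis=1))
    if bad.size:
        raise ValueError(f"{path}: non-numeric/non-finite value in row {bad[0] + 2}")
    meta = df.drop(columns=ecols + ["neuron_id"])
    return EmbeddingSet(df["neuron_id"].to_numpy(), mat, meta)


def write_embeddings(es: EmbeddingSet, path) -> None:
    df = pd.DataFrame(es.matrix, columns=[f"e{i}" for i in range(es.dim)])
    df.insert(0, "neuron_id", es.ids)
    out = pd.concat([df, es.metadata.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")
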