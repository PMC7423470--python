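"""Labelled symmetric distance matrices.

All pairwise distances in the package — cophenetic (phylogenetic),
Gower (functional) and their weighted combination — are carried in a
single light container that tracks labels and whether the square-root
transform has been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal, nonnegative distance matrix.

    Parameters
    ----------
    labels
        Species names, one per row/column.
    values
        Square array of pairwise distances.
    transform
        ``"raw"`` or ``"sqrt"``; ``"sqrt"`` marks element-wise square
        roots of a raw cophenetic matrix.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    transform: str = "raw"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"values shape {vals.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if np.any(vals < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def distances_from(self, focal: str, others: list[str]) -> np.ndarray:
        i = self.index(focal)
        idx = [self.index(o) for o in others]
        return self.values[i, idx]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.index(lab) for lab in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.transform)

    # -- transforms --------------------------------------------------------
    def sqrt_transform(self) -> "DistanceMatrix":
        """Element-wise square root (used to place phylogenetic distances
        on a scale comparable with trait distances)."""
        if self.transform == "sqrt":
            raise ValueError("matrix is already sqrt-transformed")
        return DistanceMatrix(self.labels, np.sqrt(self.values), "sqrt")

    def max_offdiag(self) -> float:
        n = len(self)
        if n < 2:
            raise ValueError("need >= 2 labels for an off-diagonal maximum")
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].max())

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a flat vector."""
        i, j = np.tril_indices(len(self), k=-1)
        return self.values[i, j]

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, transform: str = "raw") -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("index and columns must match")
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float), transform)
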