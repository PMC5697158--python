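"""Container for single-cell mRNA snapshot data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["SnapshotData"]


@dataclass
class SnapshotData:
    """Cells × genes matrix of normalized mRNA levels with a missing mask.

    ``X[k, i]`` is the normalized mRNA level of gene i in cell k (in [0, 1]
    where observed).  ``mask[k, i]`` is True where the measurement is valid;
    masked entries are ignored by the likelihood.  Dropouts are *not*
    masked: a dropout is a spurious observed zero.
    """

    X: np.ndarray
    mask: Optional[np.ndarray] = None
    gene_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        m, n = self.X.shape
        if m < 1:
            raise ValueError("need at least one cell")
        if self.mask is None:
            self.mask = np.ones((m, n), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (m, n):
                raise ValueError("mask shape must match X")
        obs = self.X[self.mask]
        if obs.size and (np.any(obs < 0) or np.any(obs > 1) or not np.all(np.isfinite(obs))):
            raise ValueError("observed normalized mRNA values must lie in [0, 1]")
        self.gene_names = tuple(self.gene_names) or tuple(f"gene{i + 1}" for i in range(n))
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must equal gene count")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def drop_gene(self, i: int) -> "SnapshotData":
        """Remove gene i's column entirely (data and mask)."""
        keep = [j for j in range(self.n_genes) if j != i]
        return SnapshotData(
            X=self.X[:, keep],
            mask=self.mask[:, keep],
            gene_names=[self.gene_names[j] for j in keep],
        )
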