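"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class CellBasecallTable:
    """Per-cell x per-bin cytosine basecall counts, one context per key.

    ``counts[context] = (mc, cov)`` with integer arrays of shape
    (n_cells, n_bins); ``mc <= cov`` everywhere.  ``global_levels`` holds the
    per-cell genome-wide mCG/mCH/mCCC fractions used for posterior shrinkage
    and hypomethylation scoring.  Bin coordinates are 0-based half-open.
    """

    chrom: str
    bin_size: int
    bin_starts: np.ndarray
    counts: dict  # context -> (mc, cov) int arrays, cells x bins
    global_levels: pd.DataFrame  # index: cell ids; columns incl. mCG, mCH
    cell_meta: pd.DataFrame = None  # plate, region, ...

    def __post_init__(self):
        for ctx, (mc, cov) in self.counts.items():
            if mc.shape != cov.shape:
                raise ValueError(f"{ctx}: mc/cov shape mismatch")
            if np.any(mc > cov):
                raise ValueError(f"{ctx}: mc exceeds cov")
            if np.any(mc < 0):
                raise ValueError(f"{ctx}: negative counts")

    @property
    def n_cells(self) -> int:
        mc, _ = next(iter(self.counts.values()))
        return mc.shape[0]

    @property
    def n_bins(self) -> int:
        mc, _ = next(iter(self.counts.values()))
        return mc.shape[1]

    @property
    def cells(self) -> pd.Index:
        return self.global_levels.index

    def fractions(self, context: str) -> np.ndarray:
        """Raw mc/cov fractions; bins with cov == 0 are NaN."""
        mc, cov = self.counts[context]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = mc / cov
        f[cov == 0] = np.nan
        return f


@dataclass
class ContactMatrixSet:
    """Per-cell (or per-group) symmetric sparse cis contact matrices.

    Matrices are upper-triangular-stored CSR of shape (n_bins, n_bins) at one
    resolution; ``matrix(i)`` returns the symmetrized form.
    """

    chrom: str
    resolution: int
    n_bins: int
    cells: list
    _upper: list = field(default_factory=list)  # scipy.sparse CSR per cell

    def add(self, cell, coo: sparse.spmatrix) -> None:
        coo = sparse.triu(coo.tocoo())
        self.cells.append(cell)
        self._upper.append(coo.tocsr())

    def matrix(self, i: int) -> sparse.csr_matrix:
        u = self._upper[i]
        full = u + u.T
        full.setdiag(u.diagonal())
        return full.tocsr()

    def dense(self, i: int) -> np.ndarray:
        return np.asarray(self.matrix(i).todense())

    def __len__(self) -> int:
        return len(self.cells)

    def group_sum(self, indices) -> np.ndarray:
        """Dense sum of the symmetrized matrices of ``indices``."""
        acc = np.zeros((self.n_bins, self.n_bins))
        for i in indices:
            acc += self.dense(i)
        return acc


@dataclass
class Embedding:
    """A fitted low-dimensional representation (PCA / LSI / CCA).

    ``coords`` is cells x dims.  For LSI, ``basis``/``singular_values``/``idf``
    allow projecting new data with the stored model; for CCA the basis is the
    canonical-correlation loading used for query projection.
    """

    coords: np.ndarray
    singular_values: np.ndarray | None = None
    basis: np.ndarray | None = None
    provenance: str = "PCA"
    idf: np.ndarray | None = None
    mean_: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite values")
        n, d = self.coords.shape
        if d > n:
            raise ValueError("more dimensions than cells")
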