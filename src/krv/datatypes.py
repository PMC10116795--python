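"""Shared domain types: count tables, genotype matrices, covariate designs,
gene regions and kernel matrices.

All container types carry explicit sample identifiers so that data from
different sources can be aligned onto a common sample ordering before any
kernel is formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated."""


def _as_id_array(ids: Sequence) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValidationError("identifiers must be one-dimensional")
    if len(set(arr)) != len(arr):
        dupes = pd.Series(arr).value_counts()
        dupes = list(dupes.index[dupes > 1])[:5]
        raise ValidationError(f"duplicate identifiers: {dupes}")
    return arr


@dataclass
class CountTable:
    """Samples x taxa abundance matrix.

    Raw tables hold non-negative integer counts; transformed tables (CLR,
    PhILR output) hold real values and are flagged with ``is_transformed``.
    """

    sample_ids: np.ndarray
    taxon_ids: np.ndarray
    counts: np.ndarray
    is_transformed: bool = False

    def __post_init__(self):
        self.sample_ids = _as_id_array(self.sample_ids)
        self.taxon_ids = _as_id_array(self.taxon_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite abundance values")
        if not self.is_transformed:
            if np.any(self.counts < 0):
                raise ValidationError("raw count tables must be non-negative")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("raw count tables must be integer-valued")
            self.counts = np.round(self.counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_transformed: bool = False) -> "CountTable":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object),
                   df.to_numpy(float), is_transformed)

    def subset(self, indices: np.ndarray) -> "CountTable":
        return CountTable(self.sample_ids[indices], self.taxon_ids,
                          self.counts[indices], self.is_transformed)


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix with variant metadata.

    ``variants`` is a DataFrame with columns chrom, pos (1-based), id, ref,
    alt; ``v`` is the per-variant ratio of observed dosage variance to the
    expected binomial variance (1 for hard calls).
    """

    sample_ids: np.ndarray
    dosages: np.ndarray
    variants: pd.DataFrame
    v: np.ndarray = None

    def __post_init__(self):
        self.sample_ids = _as_id_array(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sample_ids):
            raise ValidationError("dosage matrix must be n_samples x n_variants")
        if np.any(self.dosages < -1e-9) or np.any(self.dosages > 2 + 1e-9):
            raise ValidationError("dosages must lie in [0, 2]")
        self.dosages = np.clip(self.dosages, 0.0, 2.0)
        required = {"chrom", "pos", "id"}
        if not required.issubset(self.variants.columns):
            raise ValidationError(f"variant metadata must include {sorted(required)}")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValidationError("one metadata record required per dosage column")
        self.variants = self.variants.reset_index(drop=True)
        if self.v is None:
            self.v = np.ones(self.dosages.shape[1])
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (self.dosages.shape[1],):
            raise ValidationError("v must have one entry per variant")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency, min(p, 1-p) with p = mean dosage / 2."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, indices: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids[indices], self.dosages[indices],
                              self.variants.copy(), self.v.copy())

    def select_variants(self, cols: np.ndarray) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(self.sample_ids, self.dosages[:, cols],
                              self.variants.iloc[cols].reset_index(drop=True),
                              self.v[cols])


@dataclass
class CovariateDesign:
    """Covariate matrix X with leading intercept column and its projectors.

    Projections onto the column space of X (and its orthocomplement) are
    formed from a thin QR decomposition rather than the normal equations.
    """

    sample_ids: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.sample_ids = _as_id_array(self.sample_ids)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, p1 = self.X.shape
        if n != len(self.sample_ids):
            raise ValidationError("X must have one row per sample")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValidationError("first column of X must be the intercept (all ones)")
        if np.linalg.matrix_rank(self.X) < p1:
            raise ValidationError(
                "covariate matrix is rank deficient; remove collinear columns"
            )
        if n <= p1:
            raise ValidationError("need more samples than covariate columns")
        # orthonormal basis of col(X)
        self._Q, _ = np.linalg.qr(self.X)

    @classmethod
    def intercept_only(cls, sample_ids: Sequence) -> "CovariateDesign":
        return cls(np.asarray(sample_ids, object), np.ones((len(sample_ids), 1)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, add_intercept: bool = True) -> "CovariateDesign":
        X = df.to_numpy(float)
        if add_intercept:
            X = np.column_stack([np.ones(len(df)), X])
        return cls(df.index.to_numpy(object), X)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    def projection(self) -> np.ndarray:
        """P_X = X (X'X)^-1 X'."""
        return self._Q @ self._Q.T

    def complement_projection(self) -> np.ndarray:
        """P_X-perp = I - P_X."""
        return np.eye(self.n_samples) - self.projection()

    def residualize_vector(self, y: np.ndarray) -> np.ndarray:
        """P_X-perp y without forming the n x n projector."""
        return y - self._Q @ (self._Q.T @ y)

    def residualize_matrix(self, M: np.ndarray) -> np.ndarray:
        """P_X-perp M P_X-perp for a symmetric matrix M, in O(n^2 p)."""
        QtM = self._Q.T @ M
        M1 = M - self._Q @ QtM          # (I - QQ') M
        return M1 - (M1 @ self._Q) @ self._Q.T

    def subset(self, indices: np.ndarray) -> "CovariateDesign":
        return CovariateDesign(self.sample_ids[indices], self.X[indices])


@dataclass
class GeneRegion:
    """A gene interval (1-based, inclusive) and the variant columns mapped to it."""

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = 0
    member_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        self.member_idx = np.asarray(self.member_idx, dtype=int)

    @property
    def window(self) -> tuple[int, int]:
        return self.start - self.flank, self.end + self.flank


@dataclass
class KernelMatrix:
    """An n x n sample-similarity matrix with bookkeeping flags."""

    sample_ids: np.ndarray
    K: np.ndarray
    label: str = "kernel"
    centered: bool = False
    psd_corrected: bool = False

    _SYM_TOL = 1e-8

    def __post_init__(self):
        self.sample_ids = _as_id_array(self.sample_ids)
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValidationError("kernel must be square over the sample ids")
        scale = max(np.abs(self.K).max(), 1.0)
        if np.abs(self.K - self.K.T).max() > self._SYM_TOL * scale:
            raise ValidationError("kernel matrix is not symmetric")
        self.K = (self.K + self.K.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: np.ndarray) -> "KernelMatrix":
        # a principal submatrix stays PSD but loses centering
        indices = np.asarray(indices)
        still_centered = self.centered and len(indices) == self.n_samples
        return KernelMatrix(self.sample_ids[indices],
                            self.K[np.ix_(indices, indices)],
                            self.label, still_centered, self.psd_corrected)
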