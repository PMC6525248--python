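"""Similarity matrices for kernel distance-covariance association testing.

The test compares two N x N subject-similarity matrices: one built from the
multivariate ordinal questionnaire (projection matrix or linear kernel on the
centered item scores) and one from the gene's variant dosages (weighted linear
kernel).  This module holds the data containers and the matrix plumbing:
column standardization, covariate residualization, kernel construction and
double-centering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeMatrix",
    "CovariateMatrix",
    "GenotypeMatrix",
    "WeightVector",
    "SimilarityMatrix",
    "DegenerateInputError",
    "center_and_scale_columns",
    "residualize",
    "phenotype_similarity",
    "genotype_kernel",
    "center_similarity",
]

#: relative singular-value cutoff for rank decisions in projection mode
RANK_TOL = 1e-8


class DegenerateInputError(ValueError):
    """Raised when an input has no usable variation (constant column, etc.)."""


@dataclass
class PhenotypeMatrix:
    """N x Q ordinal item responses (levels 0..L-1), one row per subject."""

    values: np.ndarray
    subject_ids: np.ndarray | None = None
    item_labels: list[str] | None = None
    n_levels: int = 4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be 2-D (subjects x items)")
        if np.any(np.isnan(self.values.astype(float))):
            raise ValueError("phenotype matrix contains missing entries")
        v = self.values
        if np.any(v < 0) or np.any(v > self.n_levels - 1):
            raise ValueError(f"item responses must lie in 0..{self.n_levels - 1}")
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.n_subjects)
        else:
            self.subject_ids = np.asarray(self.subject_ids)
        if self.item_labels is None:
            self.item_labels = [f"item_{j + 1}" for j in range(self.n_items)]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """N x C real covariates, without an intercept column (added internally)."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(self.values.shape[0] if self.values.ndim == 2 else 0, 0)
        if self.labels is None:
            self.labels = [f"cov_{j + 1}" for j in range(self.values.shape[1])]

    @classmethod
    def empty(cls, n_subjects: int) -> "CovariateMatrix":
        return cls(np.empty((n_subjects, 0)), labels=[])

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """N x V dosage matrix for one gene region.

    Dosages count minor alleles and lie in [0, 2]; missing entries (NaN) are
    mean-imputed per variant on construction.  ``maf`` is always recomputed
    from the sample dosages, and monomorphic variants are dropped.
    ``typed_mask`` marks variants present on the genotyping array: tests see
    only typed variants, while simulation models may place causal effects on
    untyped ones and rely on linkage disequilibrium.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray | None = None
    positions: np.ndarray | None = None
    typed_mask: np.ndarray | None = None
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.dosages, dtype=float))
        n, v = d.shape
        if self.variant_ids is None:
            self.variant_ids = np.array([f"snp_{j + 1}" for j in range(v)])
        else:
            self.variant_ids = np.asarray(self.variant_ids)
        if self.positions is None:
            self.positions = np.arange(1, v + 1)
        else:
            self.positions = np.asarray(self.positions)
        if self.typed_mask is None:
            self.typed_mask = np.ones(v, dtype=bool)
        else:
            self.typed_mask = np.asarray(self.typed_mask, dtype=bool)

        # mean-impute missing dosages per variant (standard dosage handling)
        if np.isnan(d).any():
            means = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = np.take(means, idx[1])
        if d.size and (d.min() < -1e-9 or d.max() > 2.0 + 1e-9):
            raise ValueError("dosages must lie within [0, 2]")
        d = np.clip(d, 0.0, 2.0)

        p = d.mean(axis=0) / 2.0
        keep = (p > 0.0) & (p < 1.0)
        if not keep.all():
            logger.info("dropping %d monomorphic variant(s)", int((~keep).sum()))
        self.dosages = d[:, keep]
        self.variant_ids = self.variant_ids[keep]
        self.positions = self.positions[keep]
        self.typed_mask = self.typed_mask[keep]
        p = p[keep]
        self.maf = np.minimum(p, 1.0 - p)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def typed(self) -> "GenotypeMatrix":
        """Restrict to array-typed variants (the test's view of the gene)."""
        m = self.typed_mask
        return GenotypeMatrix(
            self.dosages[:, m],
            variant_ids=self.variant_ids[m],
            positions=self.positions[m],
            typed_mask=np.ones(int(m.sum()), dtype=bool),
        )


@dataclass
class WeightVector:
    """Per-variant nonnegative weights entering the genotype kernel.

    Weights multiply the centered dosage columns, so they enter the kernel
    squared: K = (G_c W)(G_c W)^T with W = diag(w).
    """

    w: np.ndarray
    scheme: str = "none"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if self.scheme not in {"none", "maf", "external"}:
            raise ValueError(f"unknown weight scheme: {self.scheme}")
        if self.scheme == "none" and not np.allclose(self.w, 1.0):
            raise ValueError("scheme 'none' requires unit weights")

    @classmethod
    def flat(cls, n_variants: int) -> "WeightVector":
        return cls(np.ones(n_variants), scheme="none")

    @classmethod
    def from_maf(cls, maf: np.ndarray) -> "WeightVector":
        """Variance-standardizing weights w_v = 1 / sqrt(p_v (1 - p_v)).

        Gives every common variant equal influence on the kernel regardless
        of allele frequency; the weight function is pluggable, this is the
        default MAF-based scheme.
        """
        maf = np.asarray(maf, dtype=float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("MAF values must lie in (0, 0.5]")
        return cls(1.0 / np.sqrt(maf * (1.0 - maf)), scheme="maf")

    @classmethod
    def external(cls, values: np.ndarray) -> "WeightVector":
        """External per-variant weights, e.g. |log odds ratio| from a prior GWAS.

        Zero entries effectively drop the variant from the weighted kernel.
        """
        return cls(np.abs(np.asarray(values, dtype=float)), scheme="external")


@dataclass
class SimilarityMatrix:
    """N x N subject-similarity matrix with provenance flags."""

    values: np.ndarray
    kind: str  # "phenotype_projection" | "phenotype_linear" | "genotype_linear"
    centered: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8 * max(1.0, np.abs(v).max())):
            raise ValueError("similarity matrix must be symmetric")
        self.values = 0.5 * (v + v.T)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def center_and_scale_columns(M: np.ndarray) -> np.ndarray:
    """Standardize each column to mean 0 and unit sample variance (ddof=1)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("need at least two rows to standardize")
    sd = M.std(axis=0, ddof=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise DegenerateInputError(
            f"constant column(s) cannot be standardized: indices {dead.tolist()}"
        )
    return (M - M.mean(axis=0)) / sd


def residualize(M: np.ndarray, C: CovariateMatrix | None) -> np.ndarray:
    """OLS-residualize every column of ``M`` on [1, C].

    An intercept is always included, so with no covariates this is plain
    column-centering.  Output columns are orthogonal to the constant vector
    and to every covariate column.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n = M.shape[0]
    if C is None or C.n_covariates == 0:
        return M - M.mean(axis=0)
    X = np.column_stack([np.ones(n), C.values])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"covariate design is rank-deficient (rank {rank} < {X.shape[1]}); "
            f"check for collinear covariates among {C.labels}"
        )
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def phenotype_similarity(Yc: np.ndarray, mode: str = "projection") -> SimilarityMatrix:
    """Phenotypic similarity from a centered (residualized) item matrix.

    ``projection`` returns P = Yc (Yc^T Yc)^{-1} Yc^T, the orthogonal projector
    onto the column space of Yc (idempotent, eigenvalues 0/1, trace Q); it is
    invariant to any invertible linear recombination of the items.  ``linear``
    returns the Gram matrix Yc Yc^T.
    """
    Yc = np.atleast_2d(np.asarray(Yc, dtype=float))
    n, q = Yc.shape
    if mode == "linear":
        return SimilarityMatrix(Yc @ Yc.T, kind="phenotype_linear", centered=True)
    if mode != "projection":
        raise ValueError(f"unknown phenotype similarity mode: {mode}")
    if n < q:
        raise ValueError(f"projection mode needs N >= Q (got N={n}, Q={q})")
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    rank = int((s > RANK_TOL * s[0]).sum()) if s.size else 0
    if rank < q:
        warnings.warn(
            f"phenotype matrix is rank-deficient (rank {rank} < Q={q}); "
            "using pseudo-inverse projection",
            stacklevel=2,
        )
    Ur = U[:, :rank]
    return SimilarityMatrix(Ur @ Ur.T, kind="phenotype_projection", centered=True)


def genotype_kernel(G: GenotypeMatrix, w: WeightVector | None = None) -> SimilarityMatrix:
    """Weighted linear genotype kernel K = G_c diag(w^2) G_c^T on typed variants.

    ``G_c`` is the column-centered dosage matrix, so K is automatically
    double-centered (row and column sums 0).
    """
    Gt = G.typed()
    if Gt.n_variants == 0:
        raise DegenerateInputError("no typed variants available for the kernel")
    if w is None:
        w = WeightVector.flat(Gt.n_variants)
    if w.w.size != Gt.n_variants:
        raise ValueError(f"weight length {w.w.size} != typed variant count {Gt.n_variants}")
    if not np.any(w.w > 0):
        raise DegenerateInputError("all variant weights are zero")
    Gc = Gt.dosages - Gt.dosages.mean(axis=0)
    Gw = Gc * w.w
    return SimilarityMatrix(Gw @ Gw.T, kind="genotype_linear", centered=True)


def center_similarity(K: SimilarityMatrix) -> SimilarityMatrix:
    """Double-center: H K H with H = I - 11^T/N, zeroing row/column sums."""
    v = K.values
    row_means = v.mean(axis=1, keepdims=True)
    centered = v - row_means - row_means.T + v.mean()
    return SimilarityMatrix(centered, kind=K.kind, centered=True)
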