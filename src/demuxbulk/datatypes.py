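"""Shared data containers for pooled-sample donor deconvolution.

The containers here hold the three ingredients of the model: donor genotypes
at biallelic SNPs (:class:`GenotypeMatrix`), pooled allelic read counts
(:class:`AllelicCounts`, :class:`CellAllelicCounts`), and the model
parameters — the genotype-specific ALT-allele fractions
(:class:`AlleleFreqParams`) and the donor-proportion vector, which is kept as
a plain numpy array on the probability simplex (see :func:`check_simplex`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

#: Sentinel for a missing genotype call in :attr:`GenotypeMatrix.G`.
MISSING: int = -1

SIMPLEX_ATOL = 1e-9


class DemuxError(ValueError):
    """Raised for invalid or uninformative inputs (e.g. no usable SNPs)."""


class Variant(NamedTuple):
    """A biallelic SNP: single REF base, single ALT base, 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None


def check_simplex(phi: np.ndarray, *, name: str = "phi") -> np.ndarray:
    """Validate and return a donor-proportion vector.

    Entries must be non-negative and sum to 1 within ``SIMPLEX_ATOL``.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1:
        raise DemuxError(f"{name} must be a 1-D vector, got shape {phi.shape}")
    if np.any(phi < -SIMPLEX_ATOL):
        raise DemuxError(f"{name} has negative entries")
    if abs(phi.sum() - 1.0) > SIMPLEX_ATOL:
        raise DemuxError(f"{name} must sum to 1 (got {phi.sum():.12g})")
    return np.clip(phi, 0.0, None)


@dataclass(frozen=True)
class AlleleFreqParams:
    """Expected ALT-allele read fraction per genotype category.

    ``theta = (theta0, theta1, theta2)`` for hom-ref (BB), het (AB) and
    hom-alt (AA) genotypes. Nominally (0, 0.5, 1); the default
    (0.01, 0.5, 0.99) absorbs sequencing/genotyping noise.
    """

    theta: tuple[float, float, float] = (0.01, 0.5, 0.99)

    def __post_init__(self) -> None:
        t0, t1, t2 = self.theta
        if not (0.0 < t0 < t1 < t2 < 1.0):
            raise DemuxError(
                f"theta must satisfy 0 < theta0 < theta1 < theta2 < 1, got {self.theta}"
            )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)

    @property
    def is_symmetric(self) -> bool:
        """True when theta0 = 1 - theta2 and theta1 = 0.5 (REF/ALT relabel symmetry)."""
        t0, t1, t2 = self.theta
        return abs(t0 - (1.0 - t2)) < 1e-12 and abs(t1 - 0.5) < 1e-12


@dataclass
class GenotypeMatrix:
    """Genotype categories for N biallelic SNPs across K donors.

    ``G[i, k]`` is donor ``k``'s category at SNP ``i``: 0 hom-ref, 1 het,
    2 hom-alt, :data:`MISSING` (-1) for uncalled/half/haploid calls.
    """

    variants: list[Variant]
    donors: list[str]
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.variants), len(self.donors)):
            raise DemuxError(
                f"G shape {self.G.shape} does not match "
                f"{len(self.variants)} variants x {len(self.donors)} donors"
            )
        valid = np.isin(self.G, (MISSING, 0, 1, 2))
        if not valid.all():
            raise DemuxError("genotype categories must be in {-1, 0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        idx = _as_row_index(index, self.n_variants)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            donors=list(self.donors),
            G=self.G[idx],
        )

    def permute_donors(self, order: Sequence[int]) -> "GenotypeMatrix":
        order = list(order)
        if sorted(order) != list(range(self.n_donors)):
            raise DemuxError("order must be a permutation of donor indices")
        return GenotypeMatrix(
            variants=list(self.variants),
            donors=[self.donors[j] for j in order],
            G=self.G[:, order],
        )


@dataclass
class AllelicCounts:
    """Pooled allelic counts: ALT reads ``a[i]`` out of ``d[i]`` total at SNP i."""

    variants: list[Variant]
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        n = len(self.variants)
        if self.a.shape != (n,) or self.d.shape != (n,):
            raise DemuxError("a and d must be 1-D with one entry per variant")
        if np.any(self.a < 0) or np.any(self.a > self.d):
            raise DemuxError("counts must satisfy 0 <= a_i <= d_i")

    @property
    def b(self) -> np.ndarray:
        """REF-supporting read counts, d - a."""
        return self.d - self.a

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def total_reads(self) -> int:
        return int(self.d.sum())

    def subset_variants(self, index: np.ndarray) -> "AllelicCounts":
        idx = _as_row_index(index, self.n_variants)
        return AllelicCounts(
            variants=[self.variants[i] for i in idx], a=self.a[idx], d=self.d[idx]
        )


@dataclass
class CellAllelicCounts:
    """Per-cell allelic counts: sparse N x C ALT (``A``) and total (``D``) matrices.

    ``cell_labels`` optionally records each barcode's donor of origin
    (simulation truth); doublets are labelled "donorX+donorY".
    """

    variants: list[Variant]
    cells: list[str]
    A: sp.csr_matrix
    D: sp.csr_matrix
    cell_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A, dtype=np.int64)
        self.D = sp.csr_matrix(self.D, dtype=np.int64)
        shape = (len(self.variants), len(self.cells))
        if self.A.shape != shape or self.D.shape != shape:
            raise DemuxError(f"A and D must be {shape} sparse matrices")
        if (self.D - self.A).min() < 0 or self.A.min() < 0:
            raise DemuxError("counts must satisfy 0 <= A <= D elementwise")
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels, dtype=object)
            if self.cell_labels.shape != (len(self.cells),):
                raise DemuxError("cell_labels must have one entry per cell")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class FitResult:
    """Output of the EM fit: donor proportions, allele-frequency parameters,
    and the per-iteration log-likelihood trace."""

    phi: np.ndarray
    theta: AlleleFreqParams
    loglik_trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False
    donors: list[str] | None = None

    def __post_init__(self) -> None:
        self.phi = check_simplex(self.phi)
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _as_row_index(index: np.ndarray, n: int) -> np.ndarray:
    index = np.asarray(index)
    if index.dtype == bool:
        if index.shape != (n,):
            raise DemuxError("boolean mask length mismatch")
        return np.flatnonzero(index)
    return index.astype(np.intp)


def require_aligned(gm: GenotypeMatrix, counts: AllelicCounts) -> None:
    """Check that genotypes and counts cover the same SNPs in the same order."""
    if gm.n_variants != counts.n_variants:
        raise DemuxError(
            f"genotypes ({gm.n_variants} SNPs) and counts ({counts.n_variants} SNPs)"
            " are not aligned"
        )
    for v, w in zip(gm.variants, counts.variants):
        if (v.chrom, v.pos, v.ref, v.alt) != (w.chrom, w.pos, w.ref, w.alt):
            raise DemuxError(f"variant mismatch at {v.chrom}:{v.pos} vs {w.chrom}:{w.pos}")
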