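"""Synthetic pooled-sample data with the statistical structure the model assumes.

The generators mirror the generative model end to end: Hardy-Weinberg donor
genotypes at SNPs with population ALT frequency drawn from a minor-allele
window, pooled depths, and binomial ALT counts with success probability
``mu_i . phi``. Cell-level counts (each cell owned by one donor drawn from
``phi``), doublet injection (merging two cells' columns) and hypergeometric
read subsampling reproduce the standard validation experiments: pseudo-bulk
recovery, coverage down-sampling, doublet robustness, and gene-level
differential-expression power at chosen read depths.

Every stochastic operation derives its random stream from ``cfg.seed`` (or
an explicit ``seed`` argument) and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    AllelicCounts,
    AlleleFreqParams,
    CellAllelicCounts,
    DemuxError,
    GenotypeMatrix,
    Variant,
    check_simplex,
)
from .model import donor_allele_means

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_bulk",
    "simulate_cells",
    "inject_doublets",
    "subsample_reads",
    "simulate_deg",
    "block_gene_index",
]

# Distinct stream tags keep the draws of different generator stages
# decoupled while all deriving from one user seed.
_TAG_GENO, _TAG_BULK, _TAG_CELLS, _TAG_DOUBLET, _TAG_SUBSAMPLE, _TAG_DEG = range(6)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiments.

    Defaults follow the validation regime the model targets: tens of
    thousands of reads over N effective SNPs (per-SNP depth ~ Poisson(50)),
    common SNPs (population minor-allele frequency uniform on [0.05, 0.5]),
    and the default allele-fraction parameters (0.01, 0.5, 0.99).
    """

    K: int = 4
    N: int = 2000
    seed: int = 0
    phi_true: np.ndarray | None = None          # default uniform 1/K
    theta_true: AlleleFreqParams = field(default_factory=AlleleFreqParams)
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 50.0
    n_cells: int | None = None
    doublet_rate: float = 0.0
    gene_structure: Mapping[str, np.ndarray] | None = None  # gene -> w_{g,.}

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DemuxError("K must be >= 1")
        if self.phi_true is None:
            self.phi_true = np.full(self.K, 1.0 / self.K)
        self.phi_true = check_simplex(np.asarray(self.phi_true), name="phi_true")
        if self.phi_true.shape != (self.K,):
            raise DemuxError("phi_true length must equal K")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise DemuxError("maf_range must lie inside (0, 1)")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise DemuxError("doublet_rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise DemuxError("mean_depth must be positive")

    def rng(self, tag: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([tag, int(self.seed), *map(int, extra)])


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Hardy-Weinberg donor genotypes with guaranteed inter-donor contrast.

    Per SNP the population ALT frequency q is drawn from ``cfg.maf_range``
    and each donor's category from Binomial(2, q); SNPs on which all donors
    agree are redrawn (with a fresh q) so every returned row is informative.
    """
    if cfg.K < 2:
        raise DemuxError("simulate_genotypes needs K >= 2")
    rng = cfg.rng(_TAG_GENO)
    lo, hi = cfg.maf_range
    G = np.empty((cfg.N, cfg.K), dtype=np.int8)
    pending = np.arange(cfg.N)
    while pending.size:
        q = rng.uniform(lo, hi, size=pending.size)
        draw = rng.binomial(2, q[:, None], size=(pending.size, cfg.K))
        G[pending] = draw
        ok = np.ptp(draw, axis=1) > 0
        pending = pending[~ok]
    variants = [
        Variant(chrom="chr1", pos=1000 + 10 * i, ref="A", alt="G", id=f"snp{i}")
        for i in range(cfg.N)
    ]
    return GenotypeMatrix(
        variants=variants, donors=[f"donor{k}" for k in range(cfg.K)], G=G
    )


def simulate_bulk(
    cfg: SimConfig, gm: GenotypeMatrix
) -> tuple[AllelicCounts, np.ndarray]:
    """Pooled allelic counts from the mixture model; returns (counts, phi_true).

    Depths are Poisson(``cfg.mean_depth``) per SNP and ALT counts binomial
    with the donor-averaged allele rate ``mu_i . phi_true``.
    """
    rng = cfg.rng(_TAG_BULK)
    mu = donor_allele_means(gm, cfg.theta_true)
    p = mu @ cfg.phi_true
    d = rng.poisson(cfg.mean_depth, size=gm.n_variants)
    a = rng.binomial(d, p)
    counts = AllelicCounts(variants=list(gm.variants), a=a, d=d)
    return counts, cfg.phi_true.copy()


def simulate_cells(cfg: SimConfig, gm: GenotypeMatrix) -> CellAllelicCounts:
    """Cell-level allelic counts with per-cell donor labels.

    Each cell's donor is drawn from ``phi_true``; its per-SNP depth is
    Poisson(``mean_depth / n_cells``), so the pooled (pseudo-bulk) depth per
    SNP matches :func:`simulate_bulk`'s in expectation; ALT counts are
    binomial with the owning donor's allele rate.
    """
    if cfg.n_cells is None or cfg.n_cells < 1:
        raise DemuxError("cfg.n_cells must be set for simulate_cells")
    rng = cfg.rng(_TAG_CELLS)
    C = cfg.n_cells
    owners = rng.choice(cfg.K, size=C, p=cfg.phi_true)
    mu = donor_allele_means(gm, cfg.theta_true)          # (N, K)
    D = rng.poisson(cfg.mean_depth / C, size=(gm.n_variants, C))
    A = rng.binomial(D, mu[:, owners])
    labels = np.array([gm.donors[k] for k in owners], dtype=object)
    return CellAllelicCounts(
        variants=list(gm.variants),
        cells=[f"cell{j}" for j in range(C)],
        A=sp.csr_matrix(A),
        D=sp.csr_matrix(D),
        cell_labels=labels,
    )


def inject_doublets(
    cc: CellAllelicCounts, rate: float, seed: int
) -> CellAllelicCounts:
    """Merge random cell pairs into doublet barcodes.

    ``rate`` is the fraction of *output* barcodes that are doublets:
    ``n_d = round(rate * C / (1 + rate))`` pairs are drawn without
    replacement and their count columns summed. Reads are conserved exactly,
    so pseudo-bulk aggregation is bit-identical before and after injection;
    only per-cell labels (doublets marked "x+y") are distorted.
    """
    if not (0.0 <= rate < 0.5):
        raise DemuxError("doublet rate must be in [0, 0.5)")
    C = cc.n_cells
    n_d = int(round(rate * C / (1.0 + rate)))
    if rate > 0 and n_d == 0:
        raise DemuxError(f"rate {rate} too small to form a doublet among {C} cells")
    if 2 * n_d > C:
        raise DemuxError(f"rate {rate} too high for {C} cells")
    if n_d == 0:
        return CellAllelicCounts(
            variants=list(cc.variants), cells=list(cc.cells),
            A=cc.A.copy(), D=cc.D.copy(),
            cell_labels=None if cc.cell_labels is None else cc.cell_labels.copy(),
        )
    rng = np.random.default_rng([_TAG_DOUBLET, int(seed)])
    chosen = rng.choice(C, size=2 * n_d, replace=False)
    first, second = chosen[:n_d], chosen[n_d:]
    keep = np.setdiff1d(np.arange(C), chosen)

    A = sp.lil_matrix(cc.A[:, keep])
    D = sp.lil_matrix(cc.D[:, keep])
    A_dbl = cc.A[:, first] + cc.A[:, second]
    D_dbl = cc.D[:, first] + cc.D[:, second]
    A = sp.hstack([A.tocsr(), A_dbl], format="csr")
    D = sp.hstack([D.tocsr(), D_dbl], format="csr")

    cells = [cc.cells[j] for j in keep] + [
        f"{cc.cells[i]}+{cc.cells[j]}" for i, j in zip(first, second)
    ]
    labels = None
    if cc.cell_labels is not None:
        labels = np.concatenate(
            [
                cc.cell_labels[keep],
                np.array(
                    [
                        f"{cc.cell_labels[i]}+{cc.cell_labels[j]}"
                        for i, j in zip(first, second)
                    ],
                    dtype=object,
                ),
            ]
        )
    return CellAllelicCounts(
        variants=list(cc.variants), cells=cells, A=A, D=D, cell_labels=labels
    )


def subsample_reads(
    counts: AllelicCounts, fraction: float, seed: int
) -> AllelicCounts:
    """Down-sample coverage without replacement.

    New depth ~ Binomial(d_i, fraction); the ALT share of the retained reads
    ~ Hypergeometric(a_i, d_i - a_i, new depth), so ``a <= d`` holds exactly
    and expected totals scale by ``fraction``. ``fraction = 1`` returns the
    counts unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise DemuxError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return AllelicCounts(
            variants=list(counts.variants), a=counts.a.copy(), d=counts.d.copy()
        )
    rng = np.random.default_rng([_TAG_SUBSAMPLE, int(seed)])
    new_d = rng.binomial(counts.d, fraction)
    new_a = np.zeros_like(new_d)
    nz = new_d > 0
    new_a[nz] = rng.hypergeometric(counts.a[nz], counts.b[nz], new_d[nz])
    return AllelicCounts(variants=list(counts.variants), a=new_a, d=new_d)


def block_gene_index(
    n_variants: int, snps_per_gene: int, prefix: str = "gene"
) -> dict[str, np.ndarray]:
    """Partition SNPs into contiguous same-size gene blocks (last may be short)."""
    if snps_per_gene < 1:
        raise DemuxError("snps_per_gene must be >= 1")
    return {
        f"{prefix}{g}": np.arange(start, min(start + snps_per_gene, n_variants))
        for g, start in enumerate(range(0, n_variants, snps_per_gene))
    }


def simulate_deg(
    cfg: SimConfig,
    gm: GenotypeMatrix,
    gene_index: dict[str, np.ndarray],
    multipliers: Mapping[str, np.ndarray] | None = None,
    depth_by_gene: Mapping[str, float] | None = None,
) -> tuple[AllelicCounts, pd.DataFrame]:
    """Pooled counts with gene-level donor expression effects.

    Within gene g the effective proportions are
    ``phi_g = (w_g * phi_true) / sum(w_g * phi_true)`` with per-donor
    expression multipliers ``w_g`` (``multipliers`` overrides
    ``cfg.gene_structure``; genes absent from both are null, w == 1).
    Counts are drawn as in :func:`simulate_bulk` but with ``phi_g`` per
    gene; ``depth_by_gene`` optionally sets the per-SNP Poisson mean per
    gene (default ``cfg.mean_depth``).

    Returns the pooled counts and a truth table (gene, is_null, w_...,
    phi_g_... effective proportions).
    """
    w_map = dict(cfg.gene_structure or {})
    if multipliers is not None:
        w_map.update(multipliers)
    rng = cfg.rng(_TAG_DEG)
    mu = donor_allele_means(gm, cfg.theta_true)
    a = np.zeros(gm.n_variants, dtype=np.int64)
    d = np.zeros(gm.n_variants, dtype=np.int64)
    truth_rows = []
    for gene, idx in gene_index.items():
        w = np.asarray(w_map.get(gene, np.ones(cfg.K)), dtype=float)
        if w.shape != (cfg.K,) or np.any(w <= 0):
            raise DemuxError(f"gene {gene}: multipliers must be K positive values")
        phi_g = w * cfg.phi_true
        phi_g = phi_g / phi_g.sum()
        mean_depth = (depth_by_gene or {}).get(gene, cfg.mean_depth)
        d[idx] = rng.poisson(mean_depth, size=len(idx))
        a[idx] = rng.binomial(d[idx], mu[idx] @ phi_g)
        truth_rows.append(
            {
                "gene": gene,
                "is_null": bool(np.allclose(w, 1.0)),
                **{f"w_{gm.donors[k]}": w[k] for k in range(cfg.K)},
                **{f"phi_g_{gm.donors[k]}": phi_g[k] for k in range(cfg.K)},
            }
        )
    counts = AllelicCounts(variants=list(gm.variants), a=a, d=d)
    return counts, pd.DataFrame(truth_rows)
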