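"""Donor-differential expression from gene-level allelic abundance.

Re-fitting donor proportions on one gene's SNPs yields a gene-level
abundance ``phi_g`` that confounds donor cell numbers with the donors' mean
expression of that gene; when donors express the gene equally, ``phi_g``
matches the global donor abundance ``phi``. A likelihood-ratio test compares
the gene's read counts under the global proportions (null: no differential
expression) against the gene-level MLE (alternative), with the statistic
``lambda = -2 log(L0 / L1)`` referred to a chi-square distribution with
K - 1 degrees of freedom (one-tailed).

Since abundance is a proportion of the pool's reads, the test needs no
library-size normalisation. The genotype-specific allele fractions theta are
held fixed at the globally estimated (or default) values for every
gene-level fit: single-gene SNP sets are too small to re-learn them, and a
shared theta keeps the null and alternative likelihoods comparable.
"""

from __future__ import annotations

import logging
from os import PathLike

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AllelicCounts,
    AlleleFreqParams,
    DemuxError,
    GenotypeMatrix,
    Variant,
    check_simplex,
)
from .model import donor_allele_means, em_fit, log_likelihood

__all__ = [
    "build_gene_index",
    "read_gene_map",
    "gene_map_from_gtf",
    "gene_abundance",
    "lrt_gene",
    "deg_scan",
]

logger = logging.getLogger(__name__)

# Genes need enough reads across their SNPs for a usable abundance estimate;
# below roughly 32 pooled reads the gene-level fit is too noisy to interpret.
DEFAULT_MIN_READS = 32

GENE_FIT_TOL = 1e-8
GENE_FIT_MAX_ITER = 2000


def read_gene_map(path: str | PathLike) -> pd.DataFrame:
    """Read a SNP-to-gene map TSV with columns ``chrom``, ``pos``, ``gene``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "gene": str})
    missing = {"chrom", "pos", "gene"} - set(df.columns)
    if missing:
        raise DemuxError(f"gene map lacks columns: {sorted(missing)}")
    return df


def build_gene_index(
    variants: list[Variant],
    gene_map: pd.DataFrame,
    counts: AllelicCounts | None = None,
) -> dict[str, np.ndarray]:
    """Map gene id -> indices of its SNPs within the (filtered) variant list.

    ``gene_map`` pairs (chrom, pos) with a gene id; positions absent from
    ``variants`` are ignored, and genes left with zero SNPs are dropped. A
    gene *set* can be analysed by assigning one shared id to all its SNPs.
    """
    pos_index: dict[tuple[str, int], list[int]] = {}
    for i, v in enumerate(variants):
        pos_index.setdefault((v.chrom, v.pos), []).append(i)
    index: dict[str, list[int]] = {}
    for chrom, pos, gene in gene_map[["chrom", "pos", "gene"]].itertuples(index=False):
        for i in pos_index.get((str(chrom), int(pos)), ()):
            index.setdefault(str(gene), []).append(i)
    return {
        g: np.array(sorted(set(idx)), dtype=np.intp) for g, idx in index.items()
    }


def gene_map_from_gtf(
    gtf_path: str | PathLike, variants: list[Variant]
) -> pd.DataFrame:
    """Build a SNP-to-gene map by intersecting variants with GTF exons.

    Uses 1-based inclusive exon intervals; a SNP overlapping exons of several
    genes is assigned to each. Requires the optional ``gffutils`` dependency.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    rows = []
    exons = [
        (ex.seqid, ex.start, ex.end, ex.attributes.get("gene_id", ["?"])[0])
        for ex in db.features_of_type("exon")
    ]
    for v in variants:
        for seqid, start, end, gene in exons:
            if seqid == v.chrom and start <= v.pos <= end:
                rows.append({"chrom": v.chrom, "pos": v.pos, "gene": gene})
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene"]).drop_duplicates()


def gene_abundance(
    counts_g: AllelicCounts,
    gm_g: GenotypeMatrix,
    theta: AlleleFreqParams,
    phi0: np.ndarray | None = None,
) -> np.ndarray:
    """Gene-level donor abundance: EM fit on the gene's SNPs with theta fixed.

    ``phi0`` seeds the EM; starting from the global proportions speeds up
    convergence for genes whose expression does not differ between donors.
    """
    fit = em_fit(
        counts_g, gm_g, theta_mode="fixed", theta0=theta,
        tol=GENE_FIT_TOL, max_iter=GENE_FIT_MAX_ITER, phi0=phi0,
    )
    return fit.phi


def lrt_gene(
    counts_g: AllelicCounts,
    gm_g: GenotypeMatrix,
    phi_global: np.ndarray,
    phi_g: np.ndarray,
    theta: AlleleFreqParams,
) -> tuple[float, float]:
    """Likelihood-ratio test of gene-level vs global donor abundance.

    Both likelihoods are evaluated on the same SNP subset and theta;
    ``lambda = 2 (log L1 - log L0)`` is clipped at 0 and referred to
    chi2(K - 1), K the donor count, giving a one-tailed (upper) p-value.
    """
    phi_global = check_simplex(phi_global, name="phi_global")
    phi_g = check_simplex(phi_g, name="phi_g")
    if phi_global.shape != phi_g.shape:
        raise DemuxError("phi_global and phi_g differ in donor count")
    mu = donor_allele_means(gm_g, theta)
    ll0 = log_likelihood(counts_g, mu, phi_global)
    ll1 = log_likelihood(counts_g, mu, phi_g)
    lam = max(0.0, 2.0 * (ll1 - ll0))
    K = phi_global.shape[0]
    p = float(chi2.sf(lam, df=K - 1))
    return lam, p


def deg_scan(
    counts: AllelicCounts,
    gm: GenotypeMatrix,
    gene_index: dict[str, np.ndarray],
    phi_global: np.ndarray,
    theta: AlleleFreqParams,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Test every sufficiently covered gene for donor-differential expression.

    Parameters
    ----------
    counts, gm
        Effective-filtered pooled counts and aligned genotypes (the same set
        ``phi_global`` was estimated on).
    gene_index
        Gene -> SNP-index mapping from :func:`build_gene_index`.
    min_reads
        Minimum pooled reads across a gene's SNPs for the gene to be tested;
        untested genes appear in the output with a ``reason``.

    Returns
    -------
    DataFrame with one row per gene: ``gene, n_snps, total_reads,
    phi_<donor>..., lambda, pval, fdr, tested, reason``. FDR is
    Benjamini-Hochberg across the tested genes; rows are sorted by p-value
    (tested genes first).
    """
    if not gene_index:
        raise DemuxError("gene index is empty")
    phi_global = check_simplex(phi_global, name="phi_global")
    donors = gm.donors
    rows = []
    for gene, idx in gene_index.items():
        if len(idx) and (idx.min() < 0 or idx.max() >= gm.n_variants):
            raise DemuxError(f"gene {gene}: SNP index out of range")
        counts_g = counts.subset_variants(idx)
        row: dict = {
            "gene": gene,
            "n_snps": int(len(idx)),
            "total_reads": int(counts_g.d.sum()),
        }
        if len(idx) == 0:
            row.update(tested=False, reason="no_effective_snps")
        elif row["total_reads"] < min_reads:
            row.update(tested=False, reason=f"reads<{min_reads}")
        else:
            gm_g = gm.subset_variants(idx)
            phi_g = gene_abundance(counts_g, gm_g, theta, phi0=phi_global)
            lam, p = lrt_gene(counts_g, gm_g, phi_global, phi_g, theta)
            row.update(
                {f"phi_{d}": phi_g[k] for k, d in enumerate(donors)},
                **{"lambda": lam, "pval": p},
                tested=True,
                reason="",
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    if "pval" not in df.columns:
        df["pval"] = np.nan
        df["lambda"] = np.nan
    tested = df["tested"].to_numpy()
    df["fdr"] = np.nan
    if tested.any():
        _, fdr, _, _ = multipletests(
            df.loc[tested, "pval"].to_numpy(), method="fdr_bh"
        )
        df.loc[tested, "fdr"] = fdr
    df = df.sort_values(
        ["tested", "pval"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    logger.info(
        "deg_scan: tested %d / %d genes (min_reads=%d)",
        int(tested.sum()), len(df), min_reads,
    )
    return df
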