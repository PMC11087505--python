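"""Read donor genotypes from multi-sample VCF and select informative SNPs.

Deconvolution needs *effective* SNPs: biallelic sites where at least two
pooled donors carry different genotypes (otherwise the site says nothing
about the mixture) and where the pooled sample has enough coverage with a
non-trivial minor-allele fraction. :func:`read_genotypes` parses and screens
site classes; :func:`filter_effective_variants` applies the information and
coverage criteria jointly to genotypes and pooled counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np
import pysam

from .datatypes import (
    MISSING,
    AllelicCounts,
    DemuxError,
    GenotypeMatrix,
    Variant,
    require_aligned,
)

__all__ = [
    "GenotypeMatrix",
    "Variant",
    "read_genotypes",
    "filter_effective_variants",
    "VcfSkipCounts",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

# Defaults follow the common working rule for pooled RNA-seq: at least 100
# reads/UMIs at the site and >5% of reads from the minor allele.
DEFAULT_MIN_DEPTH = 100
DEFAULT_MIN_MINOR_FRAC = 0.05


@dataclass
class VcfSkipCounts:
    """Site classes excluded while reading a VCF, for logging/reporting."""

    multiallelic: int = 0
    indel_or_symbolic: int = 0

    @property
    def total(self) -> int:
        return self.multiallelic + self.indel_or_symbolic


def read_genotypes(
    vcf_path: str | PathLike,
    donor_subset: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, VcfSkipCounts]:
    """Read biallelic-SNP genotype categories from a multi-sample VCF.

    Parameters
    ----------
    vcf_path
        VCF 4.x file with a GT FORMAT field.
    donor_subset
        Sample names to keep (in this order); default: all samples.

    Returns
    -------
    A :class:`GenotypeMatrix` over all biallelic SNP rows (entries in
    {0, 1, 2, -1}; -1 marks missing, half or haploid calls) and the counts
    of skipped rows. Multiallelic, indel and symbolic-allele rows are
    skipped. Het calls are phase-insensitive ("0/1" == "1|0" == "1/0").

    Raises
    ------
    DemuxError
        If the file is missing, has no sample columns, a requested donor is
        absent, or no biallelic SNP rows remain.
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise DemuxError(f"cannot open VCF {vcf_path!s}: {exc}") from exc

    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise DemuxError(f"VCF {vcf_path!s} has no donor (sample) columns")
        if donor_subset is None:
            donors = samples
        else:
            missing = [s for s in donor_subset if s not in samples]
            if missing:
                raise DemuxError(f"donors not found in VCF: {missing}")
            donors = list(donor_subset)

        variants: list[Variant] = []
        rows: list[list[int]] = []
        skips = VcfSkipCounts()
        for rec in vcf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                skips.multiallelic += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                skips.indel_or_symbolic += 1
                continue
            row = [_gt_category(rec.samples[s].get("GT")) for s in donors]
            variants.append(Variant(rec.chrom, rec.pos, ref, alt, rec.id))
            rows.append(row)

    if not variants:
        raise DemuxError(f"no biallelic SNP rows in {vcf_path!s}")
    if skips.total:
        logger.info(
            "read_genotypes: skipped %d multiallelic and %d indel/symbolic rows",
            skips.multiallelic,
            skips.indel_or_symbolic,
        )
    gm = GenotypeMatrix(
        variants=variants, donors=donors, G=np.array(rows, dtype=np.int8)
    )
    return gm, skips


def _gt_category(gt: tuple | None) -> int:
    # Diploid GT -> category = number of ALT alleles. Half calls ("./1"),
    # haploid calls ("1") and allele indices other than 0/1 map to missing.
    if gt is None or len(gt) != 2:
        return MISSING
    x, y = gt
    if x not in (0, 1) or y not in (0, 1):
        return MISSING
    return x + y


def filter_effective_variants(
    gm: GenotypeMatrix,
    counts: AllelicCounts,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_minor_frac: float = DEFAULT_MIN_MINOR_FRAC,
) -> tuple[GenotypeMatrix, AllelicCounts]:
    """Restrict to effective SNPs: informative genotypes + sufficient coverage.

    A row is kept iff (a) no donor genotype is missing, (b) at least two
    donors differ in genotype category, (c) pooled depth ``d_i >= min_depth``,
    and (d) the pooled minor-allele fraction ``min(a_i, d_i - a_i)/d_i``
    strictly exceeds ``min_minor_frac``. Idempotent; preserves variant and
    donor order.

    Raises
    ------
    DemuxError
        If genotypes and counts are misaligned or no SNP survives
        ("no informative SNPs").
    """
    require_aligned(gm, counts)
    G = gm.G
    complete = ~np.any(G == MISSING, axis=1)
    contrast = np.ptp(np.where(G == MISSING, 0, G), axis=1) > 0
    # ptp over categories > 0 <=> >=2 distinct categories; only meaningful on
    # complete rows, which `complete` already guards.
    d = counts.d
    with np.errstate(divide="ignore", invalid="ignore"):
        minor = np.minimum(counts.a, counts.b) / np.where(d > 0, d, 1)
    covered = (d >= min_depth) & (d > 0) & (minor > min_minor_frac)
    keep = complete & contrast & covered
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise DemuxError(
            "no informative SNPs: every row fails the genotype-contrast, "
            f"missing-call, depth (>= {min_depth}) or minor-allele "
            f"(> {min_minor_frac:g}) criterion"
        )
    logger.info(
        "filter_effective_variants: kept %d / %d SNPs", n_kept, gm.n_variants
    )
    return gm.subset_variants(keep), counts.subset_variants(keep)
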