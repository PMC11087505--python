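"""Read pooled allelic counts (VCF AD tags or sparse cellSNP-style trios)
and aggregate cell-level counts into pseudo-bulk."""

from __future__ import annotations

import logging
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    AllelicCounts,
    CellAllelicCounts,
    DemuxError,
    Variant,
)

__all__ = [
    "AllelicCounts",
    "CellAllelicCounts",
    "read_bulk_counts",
    "read_cell_counts",
    "pseudobulk",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


def read_bulk_counts(
    source,
    dialect: str = "vcf_ad",
    *,
    ad_alt_only: bool = False,
) -> AllelicCounts:
    """Read pooled per-SNP allelic counts.

    Parameters
    ----------
    source
        For ``dialect="vcf_ad"``: path to a single-sample VCF whose FORMAT
        carries AD (allelic depths, REF then ALT) and optionally DP.
        For ``dialect="sparse_trio"``: either a directory containing
        ``cellSNP.base.vcf``, ``cellSNP.tag.AD.mtx`` and
        ``cellSNP.tag.DP.mtx``, or a (base_vcf, ad_mtx, dp_mtx) triple of
        paths. Matrix rows must match the base VCF's row order; columns are
        summed (bulk-mode matrices have a single column).
    ad_alt_only
        Treat AD as carrying only the ALT depth; total depth then comes
        from DP (some pileup dialects emit ALT-only AD).

    Rows with zero depth are retained (screened later by the effective-SNP
    filter). Rows whose AD has more than two alleles are skipped and counted.
    """
    if dialect == "vcf_ad":
        return _read_vcf_ad(source, ad_alt_only=ad_alt_only)
    if dialect == "sparse_trio":
        base_vcf, ad_path, dp_path = _resolve_trio(source)
        variants = _read_base_variants(base_vcf)
        A = sp.csr_matrix(scipy.io.mmread(str(ad_path)))
        D = sp.csr_matrix(scipy.io.mmread(str(dp_path)))
        n = len(variants)
        if A.shape[0] != n or D.shape[0] != n:
            raise DemuxError(
                f"sparse trio row mismatch: base VCF has {n} rows, "
                f"AD has {A.shape[0]}, DP has {D.shape[0]}"
            )
        if A.shape[1] != D.shape[1]:
            raise DemuxError("AD and DP matrices differ in column count")
        a = np.asarray(A.sum(axis=1)).ravel().astype(np.int64)
        d = np.asarray(D.sum(axis=1)).ravel().astype(np.int64)
        return AllelicCounts(variants=variants, a=a, d=d)
    raise DemuxError(f"unknown counts dialect: {dialect!r}")


def _read_vcf_ad(path: str | PathLike, *, ad_alt_only: bool) -> AllelicCounts:
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise DemuxError(f"cannot open VCF {path!s}: {exc}") from exc
    variants: list[Variant] = []
    a_list: list[int] = []
    d_list: list[int] = []
    skipped = 0
    with vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise DemuxError(
                f"pooled-counts VCF must have exactly one sample column, got {len(samples)}"
            )
        sample = samples[0]
        for rec in vcf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                skipped += 1
                continue
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            if ad is None:
                skipped += 1
                continue
            ad = tuple(0 if x is None else int(x) for x in np.atleast_1d(ad))
            if ad_alt_only:
                if len(ad) != 1:
                    skipped += 1
                    continue
                alt_n = ad[0]
                dp = fmt.get("DP")
                if dp is None:
                    raise DemuxError(
                        f"ALT-only AD at {rec.chrom}:{rec.pos} requires a DP tag"
                    )
                tot = int(dp)
            else:
                if len(ad) != 2:
                    skipped += 1
                    continue
                alt_n = ad[1]
                tot = ad[0] + ad[1]
            variants.append(Variant(rec.chrom, rec.pos, rec.ref, alts[0], rec.id))
            a_list.append(alt_n)
            d_list.append(tot)
    if skipped:
        logger.info("read_bulk_counts: skipped %d rows (multiallelic or no/odd AD)", skipped)
    if not variants:
        raise DemuxError(f"no usable count rows in {path!s}")
    return AllelicCounts(
        variants=variants,
        a=np.array(a_list, dtype=np.int64),
        d=np.array(d_list, dtype=np.int64),
    )


def _resolve_trio(source) -> tuple[Path, Path, Path]:
    if isinstance(source, (str, PathLike)):
        root = Path(source)
        if root.is_dir():
            trio = (
                root / "cellSNP.base.vcf",
                root / "cellSNP.tag.AD.mtx",
                root / "cellSNP.tag.DP.mtx",
            )
            for p in trio:
                if not p.exists():
                    raise DemuxError(f"sparse trio file missing: {p}")
            return trio
        raise DemuxError(
            "sparse_trio source must be a directory or a (vcf, ad, dp) triple"
        )
    paths = tuple(Path(p) for p in source)
    if len(paths) != 3:
        raise DemuxError("sparse_trio source must name base VCF, AD and DP files")
    return paths


def _read_base_variants(path: Path) -> list[Variant]:
    """Variant list from a base VCF (sites only; sample columns ignored)."""
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts
            alt = alts[0] if alts else "."
            variants.append(Variant(rec.chrom, rec.pos, rec.ref, alt, rec.id))
    if not variants:
        raise DemuxError(f"no variant rows in base VCF {path}")
    return variants


def read_cell_counts(
    source,
    barcodes: str | PathLike | Sequence[str] | None = None,
) -> CellAllelicCounts:
    """Read per-cell allelic counts from a cellSNP-style trio plus barcodes.

    ``source`` follows :func:`read_bulk_counts`'s sparse-trio convention; a
    directory may additionally hold ``cellSNP.samples.tsv`` with one barcode
    per line, used when ``barcodes`` is not given.
    """
    base_vcf, ad_path, dp_path = _resolve_trio(source)
    variants = _read_base_variants(base_vcf)
    A = sp.csr_matrix(scipy.io.mmread(str(ad_path)))
    D = sp.csr_matrix(scipy.io.mmread(str(dp_path)))
    if barcodes is None:
        bc_path = base_vcf.parent / "cellSNP.samples.tsv"
        if bc_path.exists():
            barcodes = bc_path
        else:
            barcodes = [f"cell{i}" for i in range(D.shape[1])]
    if isinstance(barcodes, (str, PathLike)):
        cells = Path(barcodes).read_text().split()
    else:
        cells = list(barcodes)
    if len(variants) != A.shape[0] or len(variants) != D.shape[0]:
        raise DemuxError("sparse trio row mismatch between base VCF and matrices")
    if len(cells) != D.shape[1]:
        raise DemuxError(
            f"{len(cells)} barcodes but matrices have {D.shape[1]} columns"
        )
    return CellAllelicCounts(variants=variants, cells=cells, A=A, D=D)


def pseudobulk(
    cc: CellAllelicCounts,
    cell_subset: Sequence[str] | None = None,
) -> AllelicCounts:
    """Sum cell-level allelic counts into a pooled (pseudo-bulk) profile.

    Additive over disjoint cell partitions, and invariant to merging any two
    cells' columns — pooled totals are conserved, which is why bulk-mode
    deconvolution is unaffected by doublets.

    Parameters
    ----------
    cell_subset
        Barcodes to aggregate (e.g. one annotated cell type); default all.
    """
    if cell_subset is None:
        cols = slice(None)
    else:
        if len(cell_subset) == 0:
            raise DemuxError("cell_subset is empty")
        index = {bc: j for j, bc in enumerate(cc.cells)}
        try:
            cols = [index[bc] for bc in cell_subset]
        except KeyError as exc:
            raise DemuxError(f"unknown barcode: {exc.args[0]}") from exc
    a = np.asarray(cc.A[:, cols].sum(axis=1)).ravel().astype(np.int64)
    d = np.asarray(cc.D[:, cols].sum(axis=1)).ravel().astype(np.int64)
    return AllelicCounts(variants=list(cc.variants), a=a, d=d)
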