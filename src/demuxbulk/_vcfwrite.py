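"""Minimal VCF 4.2 emitters for the dialects the readers accept.

Only the small subset needed here is written: biallelic SNP rows with GT
(genotype VCF) or AD/DP (pooled-counts VCF) FORMAT fields. Outputs
round-trip through the pysam-based readers.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .datatypes import AllelicCounts, CellAllelicCounts, GenotypeMatrix

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _header(contigs: list[str], fmt_lines: list[str], samples: list[str]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += fmt_lines
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
            "FORMAT", *samples]
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _contigs(variants) -> list[str]:
    seen: dict[str, None] = {}
    for v in variants:
        seen.setdefault(v.chrom)
    return list(seen)


def write_genotype_vcf(gm: GenotypeMatrix, path: str | PathLike) -> None:
    """Write donor genotypes as a multi-sample VCF with GT."""
    out = [_header(
        _contigs(gm.variants),
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
        gm.donors,
    )]
    for i, v in enumerate(gm.variants):
        gts = "\t".join(_GT_STR[int(g)] for g in gm.G[i])
        out.append(
            f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(out))


def write_counts_vcf(
    counts: AllelicCounts, path: str | PathLike, sample: str = "pool"
) -> None:
    """Write pooled allelic counts as a single-sample VCF with AD (REF,ALT) + DP."""
    out = [_header(
        _contigs(counts.variants),
        [
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ],
        [sample],
    )]
    for v, a, d in zip(counts.variants, counts.a, counts.d):
        out.append(
            f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\t"
            f"AD:DP\t{d - a},{a}:{d}\n"
        )
    Path(path).write_text("".join(out))


def write_sparse_trio(
    cc_or_counts, outdir: str | PathLike
) -> None:
    """Write cellSNP-style base VCF + AD/DP MatrixMarket files (+ barcodes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = cc_or_counts.variants
    # base VCF carries sites only (no FORMAT/sample columns)
    lines = ["##fileformat=VCFv4.2\n"]
    lines += [f"##contig=<ID={c}>\n" for c in _contigs(variants)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in variants:
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n")
    (outdir / "cellSNP.base.vcf").write_text("".join(lines))

    if isinstance(cc_or_counts, CellAllelicCounts):
        A, D = cc_or_counts.A, cc_or_counts.D
        (outdir / "cellSNP.samples.tsv").write_text(
            "\n".join(cc_or_counts.cells) + "\n"
        )
    else:
        A = sp.csr_matrix(np.asarray(cc_or_counts.a)[:, None])
        D = sp.csr_matrix(np.asarray(cc_or_counts.d)[:, None])
    scipy.io.mmwrite(str(outdir / "cellSNP.tag.AD.mtx"), sp.coo_matrix(A))
    scipy.io.mmwrite(str(outdir / "cellSNP.tag.DP.mtx"), sp.coo_matrix(D))
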