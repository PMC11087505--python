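import textwrap

import numpy as np
import pytest

from demuxbulk.datatypes import AllelicCounts, GenotypeMatrix, Variant


def write_vcf(path, body, fmt="GT", samples=("d1", "d2", "d3")):
    """Write a minimal VCF with the given FORMAT id and sample columns."""
    fmt_defs = {
        "GT": ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
        "AD": [
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ],
    }
    header_lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        "##contig=<ID=chr2>",
        *fmt_defs[fmt],
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    path.write_text("\n".join(header_lines) + "\n" + textwrap.dedent(body))
    return path


@pytest.fixture
def genotype_vcf(tmp_path):
    """3-donor VCF exercising biallelic parsing, phasing, and skip classes."""
    return write_vcf(
        tmp_path / "donors.vcf",
        """\
        chr1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
        chr1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1|0\t0/0\t0/0
        chr1\t300\trs3\tG\tA,T\t.\t.\t.\tGT\t0/1\t0/0\t0/0
        chr1\t400\trs4\tT\tTA\t.\t.\t.\tGT\t0/0\t0/1\t1/1
        chr1\t500\trs5\tA\tG\t.\t.\t.\tGT\t./1\t0/0\t1/1
        chr1\t600\trs6\tA\tG\t.\t.\t.\tGT\t1\t0/0\t1/1
        chr1\t700\trs7\tC\tG\t.\t.\t.\tGT\t1/1\t1/1\t1/1
        chr1\t800\trs8\tG\tC\t.\t.\t.\tGT\t0/0\t2/2\t1/1
        """,
    )


@pytest.fixture
def counts_vcf(tmp_path):
    """Single-sample pooled-counts VCF with AD=(ref,alt) and DP."""
    return write_vcf(
        tmp_path / "pool.vcf",
        """\
        chr1\t100\trs1\tA\tG\t.\t.\t.\tAD:DP\t30,70:100
        chr1\t200\trs2\tC\tT\t.\t.\t.\tAD:DP\t96,4:100
        chr1\t900\trs9\tT\tC\t.\t.\t.\tAD:DP\t0,0:0
        """,
        fmt="AD",
        samples=("pool",),
    )


def toy_instance(K=2, N=3, seed=0, depth=100):
    """A tiny aligned (GenotypeMatrix, AllelicCounts) pair with contrast."""
    rng = np.random.default_rng(seed)
    variants = [Variant("chr1", 100 + 10 * i, "A", "G") for i in range(N)]
    while True:
        G = rng.integers(0, 3, size=(N, K))
        if (np.ptp(G, axis=1) > 0).all():
            break
    d = rng.poisson(depth, size=N) + 1
    a = rng.binomial(d, 0.5)
    gm = GenotypeMatrix(variants, [f"d{k}" for k in range(K)], G)
    return gm, AllelicCounts(variants, a, d)
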