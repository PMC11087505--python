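# Methods

## The deconvolution model

A pooled bulk RNA-seq sample mixes reads from K genotyped donors in unknown
proportions `phi` (non-negative, summing to 1). The model uses only
*effective* SNPs: biallelic sites at which (a) at least two pooled donors
carry different diploid genotypes, (b) no donor's genotype is missing,
(c) pooled depth `d_i` reaches a minimum (default 100 reads/UMIs), and
(d) the pooled minor-allele fraction strictly exceeds a floor (default 5%).
Criteria (c)–(d) are evaluated on the pooled observed counts — the only
quantity available before deconvolution. The depth/minor-fraction defaults
are working rules, not model constants, and are exposed as parameters.

Donor k's expected ALT-read fraction at SNP i is `mu_ik = theta[g_ik]`,
where `g_ik` ∈ {0,1,2} counts ALT alleles and
`theta = (theta0, theta1, theta2)` are genotype-specific allele fractions
shared across SNPs and donors. Ideal values are (0, 0.5, 1); the default
(0.01, 0.5, 0.99) absorbs sequencing and genotyping error and mild
allele-specific expression. Marginalising each read's donor of origin, the
ALT count at SNP i is binomial with rate `mu_i · phi`; the pooled
log-likelihood is the sum over SNPs of
`a_i log(mu_i·phi) + (d_i − a_i) log(1 − mu_i·phi)`. The binomial
coefficient is constant in `(phi, theta)` and omitted, so reported
log-likelihoods are comparable across fits but not across datasets.

### Assumptions

- SNPs contribute independently given genotypes (linkage between nearby
  expressed SNPs is ignored).
- Averaged over many SNPs from genes across the genome, donors' relative
  expression levels cancel, so the genome-wide `phi` tracks donor *cell*
  proportions; on a single gene the same estimate instead mixes cell
  numbers with that gene's donor-specific expression — which is exactly
  what the differential-expression test exploits.
- `theta` is global: allele-specific expression at individual loci is
  noise, not signal, here.

## EM algorithm

The latent variable is each read's donor of origin. Reads of the same
allele class at one SNP are exchangeable, so responsibilities are computed
per (SNP, allele-class): for ALT reads `r_A[i,k] ∝ phi_k mu_ik`, for REF
reads `r_B[i,k] ∝ phi_k (1 − mu_ik)`. The M-step sets `phi_k` to the
responsibility-weighted read mass of donor k divided by total reads, and —
in adaptive mode — `theta_t` to the ALT share of the read mass assigned to
donor-SNP pairs with genotype t, clipped to [1e-4, 1 − 1e-4] and re-sorted
to keep `theta0 < theta1 < theta2` (the ordering resolves the label
switching that an unconstrained update could produce; ties after clipping
are nudged apart by 1e-4).

Numerical choices:

- Initialisation `phi = 1/K` (symmetric; no donor favoured) and
  `theta = (0.01, 0.5, 0.99)`. A user-supplied start is floored at 1e-6
  per coordinate because exact zeros are absorbing under EM.
- Convergence when the log-likelihood gain per iteration drops below
  `tol = 1e-6` (default), capped at 1000 iterations; both exposed. The
  trace is returned and checked non-decreasing (slack 1e-8 for the rare
  re-sort/clip step in adaptive mode).
- Mixture rates are clamped to [1e-12, 1 − 1e-12] before logs.
- `K = 1` returns `phi = [1.0]` without iteration; zero-depth SNPs
  contribute nothing and are harmless.

The fit is deterministic given its inputs: EM on this likelihood has no
random component, and in practice the likelihood is unimodal in `phi` for
informative SNP sets, so restarts are unnecessary (the test suite checks
the optimum against an exhaustive simplex grid search on small instances).

## Differential expression between donors

For gene g with SNP set S_g, `phi_g` is the EM maximiser restricted to
S_g, with `theta` frozen at the global estimate — per-gene SNP counts are
too small to re-learn three allele-fraction parameters, and a shared
`theta` keeps the null and alternative likelihoods on the same footing.
Gene fits are warm-started at the global `phi` (faster for the many
null-like genes) with a tighter tolerance (1e-8, up to 2000 iterations).

The LRT statistic is `lambda = 2(log L1 − log L0)`, clipped at 0, where L0
uses the global `phi` and L1 uses `phi_g` on the identical SNP subset;
p-values are the upper tail of chi-square with K − 1 degrees of freedom.
Genes with fewer than `min_reads` pooled reads (default 32) are reported
but not tested: below that the abundance estimate is too noisy to
interpret. Benjamini–Hochberg FDR is applied across tested genes. Because
the statistic is built from allelic *proportions*, no library-size
normalisation is required. Gene sets are handled by giving their SNPs one
shared id in the map; an optional helper intersects variant positions with
GTF exon intervals (1-based, inclusive) when no SNP→gene TSV is supplied.

The global LRT asks only whether *some* donor deviates; per-donor
contrasts are out of scope.

## Synthetic data generator

The generator mirrors the generative model and defines the standard study
conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| K | 4 | donors in the pool |
| N | 2000 | effective SNPs |
| phi_true | 0.4/0.3/0.2/0.1 (validation) | donor proportions |
| maf_range | U(0.05, 0.5) | population ALT frequency per SNP |
| mean_depth | 50 | per-SNP Poisson depth (bulk) |
| theta_true | (0.01, 0.5, 0.99) | generative allele fractions |
| n_cells | 3000 (doublet runs) | cells for cell-level simulation |

Genotypes are Hardy–Weinberg draws (`Binomial(2, q)` per donor) with
uninformative rows resampled so all N SNPs carry contrast — a stand-in for
real donor panels that keeps the package free of downloads; users may
supply a genotype VCF instead. Cell-level simulation assigns each cell a
donor drawn from `phi_true` and thins the bulk depth across cells, so
pseudo-bulk aggregation matches the bulk law at equal total depth. Doublet
injection merges random cell pairs (exactly two cells per doublet; the
`rate` is the doublet fraction among output barcodes,
`n_d = round(rate·C/(1+rate))` pairs); reads are conserved exactly, which
is the mechanism behind bulk-mode doublet robustness. Coverage
down-sampling is without replacement: new depth `Binomial(d_i, f)`, new
ALT count hypergeometric, so `a ≤ d` holds exactly. Gene-level effects
rescale proportions within a gene by donor multipliers
`phi_g ∝ w_g · phi`, the alternative the LRT targets.

What the generator does *not* emulate: transcriptome-wide expression
structure (gene length, GC, dispersion), ambient RNA, cell-type
composition shifts, linkage between SNPs, genotype errors, and
allele-specific expression beyond the global `theta`. Passing tests
therefore demonstrate correctness and statistical behaviour of the
*method under its own model*, not performance on any real dataset.

## Evaluation harness

Composition accuracy uses the Jensen–Shannon divergence with base-2
logarithms — bounded in [0, 1], so thresholds like "JSD < 0.2 per gene"
live on an interpretable scale — and the Pearson correlation across the
K donor entries (reported with its square; correlation of a constant
composition is undefined and reported as NaN). Presets repeat each
condition over ≥ 3 seeds and report the SD across reruns.

Problem sizes in the acceptance checks (chosen so the whole validation
runs in about two minutes on one CPU): 10 replicate pools of N=2000 SNPs
for recovery and 1%-coverage checks; 3000 cells over 300 SNPs for doublet
injection; 2000 null genes × 5 SNPs for LRT calibration; 1000 genes × 4
SNPs per read bin (8–16 … 64–128 reads) for power; 20 instances of N ≤ 50
for the grid-search comparison (simplex step 1e-3, refined to 1e-4).

## Known limitations

- Genotypes must be supplied; genotype calling, imputation and phasing are
  upstream concerns. Multiallelic sites are excluded, not decomposed, and
  SNPs with any missing donor genotype are dropped rather than imputed
  (imputation would bias `mu` toward the imputing donor's category).
- Haploid GT calls are treated as missing — sex chromosomes in male donors
  effectively drop out unless coded diploid.
- No confidence intervals on `phi`; the likelihood is sharply peaked at
  typical read totals, but uncertainty is not quantified.
- With few SNPs per gene and many donors, the gene-level test loses power;
  the chi-square reference is asymptotic in per-gene reads.
- Gene-level abundance confounds expression with cell-type composition
  shifts between donors; interpret donor-differential calls accordingly.
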