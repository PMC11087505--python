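import numpy as np
import pytest

from demuxbulk.count_io import pseudobulk
from demuxbulk.datatypes import AlleleFreqParams, DemuxError
from demuxbulk.model import em_fit
from demuxbulk.simulate import (
    SimConfig,
    block_gene_index,
    inject_doublets,
    simulate_bulk,
    simulate_cells,
    simulate_deg,
    simulate_genotypes,
    subsample_reads,
)

PHI4 = np.array([0.4, 0.3, 0.2, 0.1])


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(K=3, N=50, seed=42)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(SimConfig(K=3, N=50, seed=42))
        assert np.array_equal(g1.G, g2.G)
        assert np.any(g1.G != simulate_genotypes(SimConfig(K=3, N=50, seed=43)).G)

    def test_every_row_has_contrast(self):
        gm = simulate_genotypes(SimConfig(K=2, N=300, seed=0))
        assert (np.ptp(gm.G, axis=1) > 0).all()

    def test_hardy_weinberg_category_frequencies(self):
        """Pre-contrast-resampling HWE: check against the conditional law.

        With many donors the contrast filter rarely triggers, so empirical
        category frequencies over SNPs x donors should match the
        q-integrated HWE proportions within Monte-Carlo error.
        """
        cfg = SimConfig(K=12, N=4000, seed=7, maf_range=(0.3, 0.3))
        gm = simulate_genotypes(cfg)
        freqs = np.bincount(gm.G.ravel(), minlength=3) / gm.G.size
        q = 0.3
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        assert np.abs(freqs - expected).max() < 0.01


class TestSimulateBulk:
    def test_one_hot_mixture_mean_matches_theta2(self):
        phi = np.array([1.0, 0.0, 0.0])
        cfg = SimConfig(K=3, N=2000, seed=1, phi_true=phi, mean_depth=80)
        gm = simulate_genotypes(cfg)
        counts, _ = simulate_bulk(cfg, gm)
        hom_alt = gm.G[:, 0] == 2
        frac = counts.a[hom_alt].sum() / counts.d[hom_alt].sum()
        assert frac == pytest.approx(0.99, abs=0.01)

    def test_recovery_error_shrinks_with_depth(self):
        errs = []
        for depth in (5.0, 500.0):
            cfg = SimConfig(K=4, N=500, seed=3, phi_true=PHI4, mean_depth=depth)
            gm = simulate_genotypes(cfg)
            counts, phi = simulate_bulk(cfg, gm)
            fit = em_fit(counts, gm)
            errs.append(np.abs(fit.phi - phi).max())
        assert errs[1] < errs[0]


class TestSimulateCells:
    def test_labels_follow_phi_and_pseudobulk_matches_bulk(self):
        cfg = SimConfig(K=4, N=400, seed=5, phi_true=PHI4, mean_depth=200,
                        n_cells=5000)
        gm = simulate_genotypes(cfg)
        cells = simulate_cells(cfg, gm)
        props = np.array(
            [np.mean(cells.cell_labels == d) for d in gm.donors]
        )
        assert np.abs(props - PHI4).max() < 0.03
        # pseudo-bulk allele fractions track the generative mixture rates
        from demuxbulk.model import donor_allele_means

        pooled = pseudobulk(cells)
        expected = donor_allele_means(gm, cfg.theta_true) @ PHI4
        ok = pooled.d > 50
        frac_cells = pooled.a[ok] / pooled.d[ok]
        assert np.corrcoef(frac_cells, expected[ok])[0, 1] > 0.97

    def test_requires_n_cells(self):
        cfg = SimConfig(K=2, N=10, seed=0)
        gm = simulate_genotypes(cfg)
        with pytest.raises(DemuxError, match="n_cells"):
            simulate_cells(cfg, gm)


class TestInjectDoublets:
    @pytest.fixture
    def cells(self):
        cfg = SimConfig(K=3, N=100, seed=9, n_cells=400, mean_depth=200)
        gm = simulate_genotypes(cfg)
        return simulate_cells(cfg, gm)

    def test_rate_zero_is_identity(self, cells):
        out = inject_doublets(cells, 0.0, seed=1)
        assert out.cells == cells.cells
        assert (out.A != cells.A).nnz == 0

    def test_reads_conserved_exactly(self, cells):
        out = inject_doublets(cells, 0.25, seed=1)
        before, after = pseudobulk(cells), pseudobulk(out)
        assert np.array_equal(before.a, after.a)
        assert np.array_equal(before.d, after.d)

    def test_doublet_fraction_and_labels(self, cells):
        rate = 0.2
        out = inject_doublets(cells, rate, seed=2)
        n_dbl = sum("+" in lb for lb in out.cell_labels)
        assert n_dbl / out.n_cells == pytest.approx(rate, abs=0.01)
        assert out.n_cells == cells.n_cells - n_dbl

    def test_rate_too_high(self, cells):
        with pytest.raises(DemuxError):
            inject_doublets(cells, 0.6, seed=0)


class TestSubsampleReads:
    @pytest.fixture
    def counts(self):
        cfg = SimConfig(K=3, N=800, seed=2, mean_depth=100)
        gm = simulate_genotypes(cfg)
        return simulate_bulk(cfg, gm)[0]

    def test_fraction_one_identity(self, counts):
        out = subsample_reads(counts, 1.0, seed=0)
        assert np.array_equal(out.a, counts.a)
        assert np.array_equal(out.d, counts.d)

    def test_expected_totals_scale(self, counts):
        out = subsample_reads(counts, 0.1, seed=3)
        assert out.total_reads == pytest.approx(0.1 * counts.total_reads, rel=0.05)
        assert np.all(out.a <= out.d)
        assert np.all(out.d <= counts.d)

    def test_invalid_fraction(self, counts):
        with pytest.raises(DemuxError):
            subsample_reads(counts, 0.0, seed=0)


class TestSimulateDeg:
    def test_all_null_matches_bulk_distribution(self):
        cfg = SimConfig(K=4, N=500, seed=4, phi_true=PHI4, mean_depth=50)
        gm = simulate_genotypes(cfg)
        gene_index = block_gene_index(cfg.N, 5)
        counts, truth = simulate_deg(cfg, gm, gene_index)
        assert truth["is_null"].all()
        fit = em_fit(counts, gm)
        assert np.abs(fit.phi - PHI4).max() < 0.03

    def test_multiplier_shifts_effective_proportions(self):
        cfg = SimConfig(K=4, N=40, seed=4, phi_true=PHI4, mean_depth=2000)
        gm = simulate_genotypes(cfg)
        gene_index = block_gene_index(cfg.N, 40)
        w = np.array([2.0, 1.0, 1.0, 1.0])
        counts, truth = simulate_deg(cfg, gm, gene_index, {"gene0": w})
        expected = w * PHI4 / (w * PHI4).sum()
        assert truth.loc[0, "phi_g_donor0"] == pytest.approx(expected[0])
        # recovered gene-level abundance shifts toward donor 0
        fit = em_fit(counts, gm)
        assert np.abs(fit.phi - expected).max() < 0.03
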