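import numpy as np
import pytest

from demuxbulk.datatypes import (
    AllelicCounts,
    AlleleFreqParams,
    DemuxError,
    GenotypeMatrix,
    Variant,
)
from demuxbulk.model import donor_allele_means, em_fit, log_likelihood
from demuxbulk.simulate import SimConfig, simulate_bulk, simulate_genotypes

from conftest import toy_instance
from oracles import grid_search_mle, per_read_loglik

THETA = AlleleFreqParams()


def _single_snp(genotypes, a, d):
    v = [Variant("chr1", 100, "A", "G")]
    gm = GenotypeMatrix(v, [f"d{k}" for k in range(len(genotypes))],
                        np.array([genotypes]))
    return gm, AllelicCounts(v, np.array([a]), np.array([d]))


class TestDonorAlleleMeans:
    def test_theta_lookup_by_category(self):
        gm, _ = _single_snp([0, 1, 2], 0, 0)
        mu = donor_allele_means(gm, THETA)
        assert mu.tolist() == [[0.01, 0.5, 0.99]]

    def test_missing_rejected(self):
        gm, _ = _single_snp([0, -1], 0, 0)
        with pytest.raises(DemuxError, match="missing"):
            donor_allele_means(gm, THETA)

    def test_uninformative_row_is_constant(self):
        gm, _ = _single_snp([1, 1, 1], 0, 0)
        assert np.ptp(donor_allele_means(gm, THETA)) == 0


class TestLogLikelihood:
    def test_direct_evaluation_k1(self):
        gm, counts = _single_snp([1], a=1, d=2)
        mu = donor_allele_means(gm, THETA)
        # 0.5^1 * 0.5^1 = 0.25
        assert log_likelihood(counts, mu, np.array([1.0])) == pytest.approx(
            np.log(0.25)
        )

    def test_zero_depth_rows_contribute_nothing(self):
        gm, counts = toy_instance(K=3, N=4, seed=1)
        mu = donor_allele_means(gm, THETA)
        phi = np.array([0.5, 0.3, 0.2])
        ll = log_likelihood(counts, mu, phi)
        zeroed = AllelicCounts(
            counts.variants + [Variant("chr1", 999, "A", "G")],
            np.append(counts.a, 0),
            np.append(counts.d, 0),
        )
        mu2 = np.vstack([mu, [0.5, 0.5, 0.5]])
        assert log_likelihood(zeroed, mu2, phi) == pytest.approx(ll)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_read_product_oracle(self, seed):
        gm, counts = toy_instance(K=3, N=5, seed=seed, depth=20)
        mu = donor_allele_means(gm, THETA)
        rng = np.random.default_rng(seed)
        phi = rng.dirichlet(np.ones(3))
        assert log_likelihood(counts, mu, phi) == pytest.approx(
            per_read_loglik(counts, mu, phi), rel=1e-12
        )


class TestEmFit:
    def test_single_snp_closed_form(self):
        """K=2, genotypes (0,2): a/d = theta0*phi1 + theta2*phi2 inverts."""
        gm, counts = _single_snp([0, 2], a=70, d=100)
        fit = em_fit(counts, gm, tol=1e-12, max_iter=50_000)
        expected = (0.70 - 0.01) / 0.98
        assert fit.phi[1] == pytest.approx(expected, abs=1e-6)
        assert fit.phi[0] == pytest.approx(1 - expected, abs=1e-6)

    def test_k1_returns_unit_phi(self):
        gm, counts = _single_snp([1], a=3, d=10)
        fit = em_fit(counts, gm)
        assert fit.phi.tolist() == [1.0]
        assert fit.converged

    @pytest.mark.parametrize("K,seed", [(2, 0), (3, 1)])
    def test_matches_grid_search_oracle(self, K, seed):
        cfg = SimConfig(K=K, N=40, seed=seed, mean_depth=60)
        gm = simulate_genotypes(cfg)
        counts, _ = simulate_bulk(cfg, gm)
        fit = em_fit(counts, gm, tol=1e-10, max_iter=20_000)
        oracle = grid_search_mle(counts, gm, THETA)
        assert np.abs(fit.phi - oracle).max() < 1e-3

    def test_loglik_trace_nondecreasing(self):
        gm, counts = toy_instance(K=4, N=50, seed=7)
        for mode in ("fixed", "adaptive"):
            fit = em_fit(counts, gm, theta_mode=mode)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_phi_on_simplex(self):
        gm, counts = toy_instance(K=5, N=30, seed=11)
        fit = em_fit(counts, gm)
        assert fit.phi.min() >= 0
        assert fit.phi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_donor_permutation_equivariance(self):
        cfg = SimConfig(K=4, N=200, seed=5, phi_true=np.array([0.4, 0.3, 0.2, 0.1]))
        gm = simulate_genotypes(cfg)
        counts, _ = simulate_bulk(cfg, gm)
        order = [2, 0, 3, 1]
        fit = em_fit(counts, gm)
        fit_p = em_fit(counts, gm.permute_donors(order))
        assert np.allclose(fit_p.phi, fit.phi[order], atol=1e-9)

    def test_allele_relabel_invariance_under_symmetric_theta(self):
        """Flipping REF/ALT everywhere (a <-> b, categories 0 <-> 2) leaves
        phi unchanged when theta0 = 1 - theta2 and theta1 = 0.5."""
        cfg = SimConfig(K=3, N=150, seed=9, phi_true=np.array([0.5, 0.3, 0.2]))
        gm = simulate_genotypes(cfg)
        counts, _ = simulate_bulk(cfg, gm)
        assert THETA.is_symmetric
        flipped_gm = GenotypeMatrix(
            list(gm.variants), list(gm.donors), 2 - gm.G
        )
        flipped_counts = AllelicCounts(list(counts.variants), counts.b, counts.d)
        fit = em_fit(counts, gm)
        fit_f = em_fit(flipped_counts, flipped_gm)
        assert np.allclose(fit.phi, fit_f.phi, atol=1e-7)

    def test_count_scaling_leaves_estimate_unchanged(self):
        gm, counts = toy_instance(K=3, N=60, seed=13)
        scaled = AllelicCounts(list(counts.variants), counts.a * 7, counts.d * 7)
        fit = em_fit(counts, gm, tol=1e-10, max_iter=20_000)
        fit_s = em_fit(scaled, gm, tol=1e-10, max_iter=20_000)
        assert np.allclose(fit.phi, fit_s.phi, atol=1e-5)

    def test_adaptive_theta_stays_ordered(self):
        cfg = SimConfig(K=4, N=500, seed=21,
                        theta_true=AlleleFreqParams((0.05, 0.5, 0.95)))
        gm = simulate_genotypes(cfg)
        counts, _ = simulate_bulk(cfg, gm)
        fit = em_fit(counts, gm, theta_mode="adaptive")
        t0, t1, t2 = fit.theta.theta
        assert t0 < t1 < t2
        # learned values move toward the generating ones
        assert abs(t0 - 0.05) < 0.04 and abs(t2 - 0.95) < 0.04


def test_allele_freq_params_validated():
    with pytest.raises(DemuxError):
        AlleleFreqParams((0.5, 0.5, 0.9))
    with pytest.raises(DemuxError):
        AlleleFreqParams((0.0, 0.5, 0.99))
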