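"""Accuracy metrics and experiment harness for the validation presets.

Compositional accuracy is measured by the Jensen-Shannon divergence (base-2
logarithms, so JSD is bounded in [0, 1]) and by the Pearson correlation
across the donor entries of the true vs estimated proportion vectors.
:func:`run_experiment` orchestrates the standard simulate -> fit -> metric
loops: parameter recovery, a coverage down-sampling sweep, a doublet-rate
sweep, and gene-level test calibration/power, each repeated over several
seeds with the spread (SD) reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .datatypes import DemuxError, check_simplex
from .deg import deg_scan
from .count_io import pseudobulk
from .model import em_fit
from .simulate import (
    SimConfig,
    block_gene_index,
    inject_doublets,
    simulate_bulk,
    simulate_cells,
    simulate_deg,
    simulate_genotypes,
    subsample_reads,
)

__all__ = ["jsd", "composition_accuracy", "run_experiment", "PRESETS"]

PRESETS = ("recovery", "coverage", "doublets", "deg_calibration", "deg_power")

COVERAGE_FRACTIONS = (0.01, 0.05, 0.1, 0.5, 1.0)
DOUBLET_RATES = (0.05, 0.1, 0.2, 0.3, 0.4)
POWER_DEPTH_BINS = ((8, 16), (16, 32), (32, 64), (64, 128))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence between two composition vectors, base 2.

    Symmetric, bounded in [0, 1]; 0 iff the compositions are equal,
    1 for disjoint supports. Inputs off the simplex by more than 1e-6 are
    renormalised with a warning.
    """
    p = _as_composition(p)
    q = _as_composition(q)
    if p.shape != q.shape:
        raise DemuxError("composition vectors differ in length")
    # scipy returns the JS *distance* = sqrt(divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def _as_composition(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    s = v.sum()
    if abs(s - 1.0) > 1e-6:
        import warnings

        warnings.warn(f"renormalising composition with sum {s:.6g}", stacklevel=3)
    if np.any(v < 0) or s <= 0:
        raise DemuxError("compositions must be non-negative with positive sum")
    return v / s


def composition_accuracy(
    truth: np.ndarray, est: np.ndarray
) -> tuple[float, float]:
    """(JSD, Pearson r) between true and estimated donor compositions."""
    truth = check_simplex(np.asarray(truth), name="truth")
    est = check_simplex(np.asarray(est), name="est")
    if truth.shape[0] < 2:
        raise DemuxError("Pearson correlation needs at least 2 donors")
    if np.ptp(truth) == 0 or np.ptp(est) == 0:
        r = float("nan")  # correlation undefined for a constant composition
    else:
        r = float(pearsonr(truth, est).statistic)
    return jsd(truth, est), r


def run_experiment(
    preset: str,
    seeds: list[int],
    *,
    K: int = 4,
    N: int = 2000,
    phi_true: np.ndarray | None = None,
    mean_depth: float = 50.0,
    n_cells: int = 3000,
    n_genes: int = 400,
    snps_per_gene: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a validation preset over several seeds; one row per condition.

    Presets
    -------
    recovery
        Fit the simulated pool and report JSD / Pearson r between the true
        and estimated donor proportions.
    coverage
        Recovery after hypergeometric down-sampling to each fraction in
        ``COVERAGE_FRACTIONS`` (1% mimics typical bulk coverage relative to
        the deeply sequenced reference).
    doublets
        For each rate in ``DOUBLET_RATES``: verify pooled counts are
        conserved under doublet injection (``pseudobulk_max_diff``), fit the
        pooled counts (``jsd``), and contrast with naive singlet-label
        counting (``singlet_jsd``).
    deg_calibration
        Null genes only; reports the empirical rejection rate at ``alpha``.
    deg_power
        Genes with a 2-fold multiplier on donor 0 at per-gene read depths
        spanning ``POWER_DEPTH_BINS``; reports power per bin.
    """
    if preset not in PRESETS:
        raise DemuxError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if len(seeds) == 0:
        raise DemuxError("at least one seed required")
    phi_true = (
        np.array([0.4, 0.3, 0.2, 0.1]) if phi_true is None and K == 4
        else (np.full(K, 1.0 / K) if phi_true is None else np.asarray(phi_true))
    )

    rows: list[dict] = []
    if preset == "recovery":
        vals = [
            _recovery_once(seed, K, N, phi_true, mean_depth) for seed in seeds
        ]
        rows.append(_aggregate("recovery", vals))
    elif preset == "coverage":
        for frac in COVERAGE_FRACTIONS:
            vals = []
            for seed in seeds:
                cfg = SimConfig(K=K, N=N, seed=seed, phi_true=phi_true,
                                mean_depth=mean_depth)
                gm = simulate_genotypes(cfg)
                counts, _ = simulate_bulk(cfg, gm)
                sub = subsample_reads(counts, frac, seed=seed)
                fit = em_fit(sub, gm)
                vals.append(composition_accuracy(phi_true, fit.phi))
            row = _aggregate(f"coverage_{frac:g}", vals)
            row["fraction"] = frac
            row["neglog10_jsd"] = (
                float(-np.log10(row["jsd"])) if row["jsd"] > 0 else np.inf
            )
            rows.append(row)
    elif preset == "doublets":
        for rate in DOUBLET_RATES:
            vals, singlet_jsds, max_diffs = [], [], []
            for seed in seeds:
                cfg = SimConfig(K=K, N=N, seed=seed, phi_true=phi_true,
                                mean_depth=mean_depth, n_cells=n_cells)
                gm = simulate_genotypes(cfg)
                cells = simulate_cells(cfg, gm)
                dbl = inject_doublets(cells, rate, seed=seed)
                pb0, pb1 = pseudobulk(cells), pseudobulk(dbl)
                max_diffs.append(
                    int(max(np.abs(pb0.a - pb1.a).max(), np.abs(pb0.d - pb1.d).max()))
                )
                fit = em_fit(pb1, gm)
                vals.append(composition_accuracy(phi_true, fit.phi))
                singlet_jsds.append(
                    jsd(phi_true, _singlet_label_composition(dbl, gm.donors))
                )
            row = _aggregate(f"doublets_{rate:g}", vals)
            row.update(
                rate=rate,
                pseudobulk_max_diff=max(max_diffs),
                singlet_jsd=float(np.mean(singlet_jsds)),
            )
            rows.append(row)
    elif preset == "deg_calibration":
        for seed in seeds:
            rej, _ = _deg_run(seed, K, phi_true, n_genes, snps_per_gene,
                              mean_depth, alpha, effect=None)
            rows.append(
                {"condition": f"null_seed{seed}", "rejection_rate": rej,
                 "alpha": alpha, "n_genes": n_genes, "n_replicates": 1}
            )
        agg = {
            "condition": "null_mean",
            "rejection_rate": float(np.mean([r["rejection_rate"] for r in rows])),
            "alpha": alpha,
            "n_genes": n_genes * len(seeds),
            "n_replicates": len(seeds),
        }
        if len(seeds) >= 2:
            agg["sd"] = float(np.std([r["rejection_rate"] for r in rows], ddof=1))
        rows.append(agg)
    elif preset == "deg_power":
        for lo, hi in POWER_DEPTH_BINS:
            # Per-SNP Poisson mean that centres the per-gene total in the bin.
            depth = (lo + hi) / 2.0 / snps_per_gene
            powers = []
            for seed in seeds:
                p, _ = _deg_run(seed, K, phi_true, n_genes, snps_per_gene,
                                depth, alpha, effect=2.0, reads_range=(lo, hi))
                powers.append(p)
            row = {
                "condition": f"reads_{lo}_{hi}",
                "power": float(np.mean(powers)),
                "reads_lo": lo,
                "reads_hi": hi,
                "alpha": alpha,
                "n_replicates": len(seeds),
            }
            if len(seeds) >= 2:
                row["sd"] = float(np.std(powers, ddof=1))
            rows.append(row)

    return pd.DataFrame(rows)


def _recovery_once(seed, K, N, phi_true, mean_depth) -> tuple[float, float]:
    cfg = SimConfig(K=K, N=N, seed=seed, phi_true=phi_true, mean_depth=mean_depth)
    gm = simulate_genotypes(cfg)
    counts, _ = simulate_bulk(cfg, gm)
    fit = em_fit(counts, gm)
    return composition_accuracy(phi_true, fit.phi)


def _aggregate(condition: str, vals: list[tuple[float, float]]) -> dict:
    jsds = np.array([v[0] for v in vals])
    rs = np.array([v[1] for v in vals])
    row = {
        "condition": condition,
        "jsd": float(jsds.mean()),
        "pearson_r": float(rs.mean()),
        "r2": float((rs**2).mean()),
        "n_replicates": len(vals),
    }
    if len(vals) >= 2:
        row["sd"] = float(jsds.std(ddof=1))
    return row


def _singlet_label_composition(cc, donors) -> np.ndarray:
    """Donor composition by counting only cleanly labelled (singlet) cells."""
    if cc.cell_labels is None:
        raise DemuxError("cell labels required")
    labels = [lb for lb in cc.cell_labels if "+" not in lb]
    counts = np.array([labels.count(d) for d in donors], dtype=float)
    return counts / counts.sum()


def _deg_run(seed, K, phi_true, n_genes, snps_per_gene, mean_depth, alpha,
             effect, reads_range=None):
    """One gene-level simulation + scan; returns (rejection rate, table)."""
    N = n_genes * snps_per_gene
    cfg = SimConfig(K=K, N=N, seed=seed, phi_true=phi_true, mean_depth=mean_depth)
    gm = simulate_genotypes(cfg)
    gene_index = block_gene_index(N, snps_per_gene)
    if effect is None:
        multipliers = None
    else:
        w = np.ones(K)
        w[0] = effect
        multipliers = {g: w for g in gene_index}
    counts, _ = simulate_deg(cfg, gm, gene_index, multipliers=multipliers)
    # phi_global from an independent, deeper null pool: mirrors estimating
    # the global abundance on all genome-wide SNPs.
    cfg_glob = SimConfig(K=K, N=2000, seed=seed, phi_true=phi_true, mean_depth=50)
    gm_glob = simulate_genotypes(cfg_glob)
    counts_glob, _ = simulate_bulk(cfg_glob, gm_glob)
    phi_global = em_fit(counts_glob, gm_glob).phi
    table = deg_scan(counts, gm, gene_index, phi_global, cfg.theta_true,
                     min_reads=0)
    tested = table[table["tested"]]
    if reads_range is not None:
        lo, hi = reads_range
        tested = tested[(tested["total_reads"] >= lo) & (tested["total_reads"] < hi)]
    if len(tested) == 0:
        return float("nan"), table
    return float((tested["pval"] < alpha).mean()), table
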