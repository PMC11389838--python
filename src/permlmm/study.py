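"""Reference study designs: the simulation experiments run end to end.

These drivers wire the genotype simulator, the mixed-model scan, the maxT
permutation thresholds and the evaluation layer into the experiments the
package exists to support: family-wise error-rate calibration on null data,
the skew-versus-threshold/false-positive trends across noise families, maxT
threshold stability in the number of permutations, and REML heritability
recovery.  Every driver is deterministic given its seed and scales with its
size arguments, so the same designs run at quick-test and full scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import bonferroni_threshold, classify_hits
from .io import GenotypeMatrix, filter_maf
from .kinship import KinshipMatrix, cholesky_factor, compute_kinship, stabilize
from .lmm import association_scan, fit_null_model
from .permute import run_permutations
from .simulate import DEFAULT_SETTINGS, setting_label, simulate_genotypes, simulate_phenotype

logger = logging.getLogger(__name__)

#: panel defaults mirroring the simulation design: 200 samples, structured
#: genotypes, 2000 LD-free SNPs
PANEL_N = 200
PANEL_M = 2000
PANEL_SUBPOPS = 3
PANEL_FST = 0.2


def make_study_panel(
    n: int = PANEL_N,
    m: int = PANEL_M,
    n_subpops: int = PANEL_SUBPOPS,
    fst: float = PANEL_FST,
    seed: int = 0,
) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Structured genotype panel plus its stabilized kinship matrix."""
    geno = filter_maf(simulate_genotypes(n, m, n_subpops, fst, seed=seed), 0.0)
    K = stabilize(compute_kinship(geno))
    return geno, K


def simulate_null_phenotype(K: KinshipMatrix, seed: int,
                            background_fraction: float = 0.30) -> np.ndarray:
    """Phenotype with polygenic background and Gaussian noise but no causal SNP."""
    rng = np.random.default_rng(seed)
    n = K.n_samples
    b = cholesky_factor(K) @ rng.standard_normal(n)
    e = rng.standard_normal(n)
    var_b = float(np.var(b, ddof=1))
    e *= np.sqrt(var_b * (1.0 - background_fraction) / background_fraction / np.var(e, ddof=1))
    return b + e


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"snp_id": r.snp_id, "chromosome": r.chromosome, "position": r.position, "p_value": r.p_value}
            for r in results
        ]
    )


def fwer_experiment(
    n_datasets: int = 200,
    q: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n: int = PANEL_N,
    m: int = PANEL_M,
    strategy: str = "fixed_effects",
) -> float:
    """Empirical family-wise error rate of the maxT threshold on null data.

    Each dataset gets fresh structured genotypes and a null phenotype; the
    fraction of datasets whose smallest true-data p-value falls below that
    dataset's permutation threshold estimates the FWER, which should sit
    near ``alpha``.
    """
    rejections = 0
    for d in range(n_datasets):
        geno, K = make_study_panel(n, m, seed=seed + d)
        y = simulate_null_phenotype(K, seed=seed + 500_000 + d)
        null_fit = fit_null_model(y, None, K)
        results = association_scan(geno, y, None, null_fit)
        min_p = min(r.p_value for r in results)
        perm = run_permutations(
            geno, y, None, K, q=q, alpha=alpha, strategy=strategy,
            seed=seed + 900_000 + d, null_fit=null_fit,
        )
        rejections += int(min_p < perm.threshold)
    fwer = rejections / n_datasets
    logger.info("fwer_experiment: %d/%d datasets rejected (%.3f)", rejections, n_datasets, fwer)
    return fwer


@dataclass
class SkewTrendResult:
    """Per-setting summaries across the six noise families, least to most skewed."""

    settings: list[str]
    median_thresholds: list[float]
    mean_fp_bonferroni: list[float]

    def threshold_trend_rho(self) -> float:
        """Spearman rank correlation of skewness order vs threshold stringency."""
        from scipy.stats import spearmanr

        rank = np.arange(len(self.settings))
        return float(spearmanr(rank, -np.log10(self.median_thresholds)).statistic)

    def fp_trend_rho(self) -> float:
        """Spearman rank correlation of skewness order vs Bonferroni FP counts."""
        from scipy.stats import spearmanr

        rank = np.arange(len(self.settings))
        return float(spearmanr(rank, self.mean_fp_bonferroni).statistic)


def skew_trend_experiment(
    replicates: int = 10,
    q: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n: int = PANEL_N,
    m: int = PANEL_M,
    strategy: str = "fixed_effects",
) -> SkewTrendResult:
    """Thresholds and Bonferroni false positives across the six noise settings.

    All settings share one genotype panel (as in the underlying study design);
    per-setting phenotypes are replicated and scored against the ±10 kbp
    true-positive window.
    """
    geno, K = make_study_panel(n, m, seed=seed)
    bonf = bonferroni_threshold(alpha, geno.n_snps)
    labels, med_thr, mean_fp = [], [], []
    for si, (family, shape) in enumerate(DEFAULT_SETTINGS):
        thresholds, fp_counts = [], []
        for r in range(replicates):
            pheno, truth = simulate_phenotype(
                geno, K, noise_family=family, gamma_shape=shape, seed=seed + 10_000 * si + r
            )
            null_fit = fit_null_model(pheno, None, K)
            results = association_scan(geno, pheno, None, null_fit)
            hits = classify_hits(_results_frame(results), truth, bonf)
            fp_counts.append(hits.n_fp)
            perm = run_permutations(
                geno, pheno, None, K, q=q, alpha=alpha, strategy=strategy,
                seed=seed + 50_000 + 100 * si + r, null_fit=null_fit,
            )
            thresholds.append(perm.threshold)
        labels.append(setting_label(family, shape))
        med_thr.append(float(np.median(thresholds)))
        mean_fp.append(float(np.mean(fp_counts)))
        logger.info(
            "skew_trend_experiment: %s median threshold %.3g, mean FP %.2f",
            labels[-1], med_thr[-1], mean_fp[-1],
        )
    return SkewTrendResult(settings=labels, median_thresholds=med_thr, mean_fp_bonferroni=mean_fp)


def threshold_stability_experiment(
    q_values: tuple[int, ...] = (100, 500, 2000),
    runs: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    n: int = PANEL_N,
    m: int = PANEL_M,
    gamma_shape: float = 1.0,
    strategy: str = "fixed_effects",
) -> dict[int, float]:
    """Spread (max − min) of maxT thresholds over repeated runs, per q.

    One skewed phenotype is fixed; only the permutation seed varies between
    runs, so the spread isolates the Monte Carlo error of the threshold.
    """
    geno, K = make_study_panel(n, m, seed=seed)
    pheno, _ = simulate_phenotype(geno, K, noise_family="gamma", gamma_shape=gamma_shape, seed=seed + 1)
    null_fit = fit_null_model(pheno, None, K)
    spreads: dict[int, float] = {}
    for q in q_values:
        thresholds = [
            run_permutations(
                geno, pheno, None, K, q=q, alpha=alpha, strategy=strategy,
                seed=seed + 70_000 + 10 * q + r, null_fit=null_fit,
            ).threshold
            for r in range(runs)
        ]
        spreads[q] = float(max(thresholds) - min(thresholds))
        logger.info("threshold_stability_experiment: q=%d spread %.3g", q, spreads[q])
    return spreads


def heritability_recovery_experiment(
    replicates: int = 50,
    h2: float = 0.7,
    seed: int = 0,
    n: int = PANEL_N,
    m: int = PANEL_M,
) -> float:
    """Mean REML estimate of σg²/(σg²+σe²) for y ~ N(0, h2·K + (1−h2)·I)."""
    _, K = make_study_panel(n, m, seed=seed)
    L = np.linalg.cholesky(h2 * K.values + (1.0 - h2) * np.eye(n))
    rng = np.random.default_rng(seed + 1)
    ratios = [
        fit_null_model(L @ rng.standard_normal(n), None, K).heritability
        for _ in range(replicates)
    ]
    return float(np.mean(ratios))
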