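"""maxT permutation thresholds under two permutation strategies.

For each of q permutations all SNPs are scanned, the maximum F statistic is
taken and converted to the permutation's minimum p-value; the significance
threshold at level α is the ⌊αq⌋-th smallest of the q minimum p-values (the
Westfall–Young maxT convention).

Two strategies are implemented:

``phenotype_only``
    The phenotype vector is permuted.  This breaks the link between y and the
    kinship matrix, so the variance components are re-estimated for every
    permuted phenotype before scanning.

``fixed_effects``
    One shared row permutation is applied to the fixed-effects matrix
    (covariates and SNP columns jointly) while y and K — and hence the null
    fit — stay fixed.  This is equivalent to permuting y together with the
    rows and columns of the covariance σg²K + σe²I, and therefore respects
    the population structure encoded in K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DimensionError
from .io import GenotypeMatrix
from .lmm import (
    P_FLOOR,
    NullModelFit,
    _as_vector,
    _batch_fstats,
    _fit_components,
    _gls_context,
    fit_null_model,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("phenotype_only", "fixed_effects")

#: permutations rotated per matrix product in the fixed_effects scan
_PERM_CHUNK = 16


@dataclass
class PermutationResult:
    strategy: str
    n_permutations: int
    seed: int
    alpha: float
    min_p: np.ndarray  # one minimum p-value per permutation
    threshold: float


def permutation_plan(q: int, n: int, seed: int) -> np.ndarray:
    """q uniform random permutations of range(n), deterministic given seed."""
    if q < 1:
        raise ValueError("q must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n) for _ in range(q)])


def threshold_from_minp(min_p: np.ndarray, alpha: float) -> float:
    """The ⌊αq⌋-th smallest minimum p-value (k = 1 when ⌊αq⌋ = 0)."""
    min_p = np.asarray(min_p, dtype=float).ravel()
    if min_p.size == 0:
        raise ValueError("min_p is empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    q = min_p.size
    k = int(np.floor(alpha * q))
    if k == 0:
        k = 1
        logger.warning(
            "threshold_from_minp: alpha*q = %.3g < 1; q = %d permutations are "
            "underpowered for alpha = %g, using the smallest minimum p-value",
            alpha * q, q, alpha,
        )
    return float(np.sort(min_p)[k - 1])


def run_permutations(
    geno: GenotypeMatrix,
    y,
    covariates,
    K,
    q: int,
    alpha: float,
    strategy: str = "fixed_effects",
    seed: int = 0,
    batch_size: int = 1024,
    null_fit: NullModelFit | None = None,
) -> PermutationResult:
    """maxT permutation scan yielding a phenotype-specific significance threshold.

    A precomputed ``null_fit`` (for the unpermuted data) may be supplied to
    avoid refitting; it must come from the same (y, covariates, K).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if q < 20:
        raise ValueError(f"q = {q} permutations is too few for a meaningful threshold (need >= 20)")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    yv = _as_vector(y)
    n, m = geno.dosage.shape
    if yv.size != n:
        raise DimensionError(f"phenotype has {yv.size} values for {n} genotype samples")
    if null_fit is None:
        null_fit = fit_null_model(yv, covariates, K)
    plans = permutation_plan(q, n, seed)
    if strategy == "fixed_effects":
        min_p = _minp_fixed_effects(geno, null_fit, plans)
    else:
        min_p = _minp_phenotype_only(geno, yv, null_fit, plans)
    threshold = threshold_from_minp(min_p, alpha)
    logger.info(
        "run_permutations(%s): q=%d seed=%d alpha=%g -> threshold %.6g",
        strategy, q, seed, alpha, threshold,
    )
    return PermutationResult(
        strategy=strategy,
        n_permutations=q,
        seed=seed,
        alpha=alpha,
        min_p=min_p,
        threshold=threshold,
    )


def _minp_from_fmax(f_max: np.ndarray, df2: int) -> np.ndarray:
    """Minimum p-values from per-permutation maximum F statistics."""
    return np.maximum(stats.f.sf(f_max, 1, df2), P_FLOOR)


def _minp_fixed_effects(geno: GenotypeMatrix, null_fit: NullModelFit, plans: np.ndarray) -> np.ndarray:
    """Scan with the fixed-effects matrix row-permuted; y, K and the fit stay fixed.

    For a permutation π, the rotated permuted SNP block Uᵀ S[π] equals
    U[π⁻¹]ᵀ S, so whole chunks of permutations are rotated with one matrix
    product against the dosage matrix.
    """
    q, n = plans.shape
    m = geno.dosage.shape[1]
    c0 = null_fit.rotated_X0.shape[1]
    df2 = n - (c0 + 1)
    if df2 <= 0:
        raise DimensionError(f"no residual degrees of freedom: n = {n}, fixed effects = {c0 + 1}")
    U = null_fit.U
    G = geno.dosage
    has_cov = c0 > 1
    cov = U @ null_fit.rotated_X0[:, 1:] if has_cov else None  # original covariate block
    sw, Q0, ry0, rss00 = _gls_context(null_fit)
    inverse = np.argsort(plans, axis=1)
    f_max = np.empty(q)
    for start in range(0, q, _PERM_CHUNK):
        stop = min(start + _PERM_CHUNK, q)
        chunk = stop - start
        stacked = U[inverse[start:stop].reshape(-1), :].reshape(chunk, n, n)
        stacked = np.ascontiguousarray(stacked.transpose(1, 0, 2)).reshape(n, chunk * n)
        rotated = G.T @ stacked  # (m, chunk*n); per permutation: (Uᵀ G[π])ᵀ
        for t in range(chunk):
            perm = plans[start + t]
            if has_cov:
                # covariates are permuted jointly with the SNP; the intercept
                # is permutation invariant
                Xp = U.T @ np.column_stack([np.ones(n), cov[perm]])
                _, Qp, ryp, rss0p = _gls_context(null_fit, rotated_X0=Xp)
            else:
                Qp, ryp, rss0p = Q0, ry0, rss00
            S_tilde = rotated[:, t * n:(t + 1) * n].T * sw[:, None]
            _, _, F, _ = _batch_fstats(S_tilde, Qp, ryp, rss0p, df2)
            f_max[start + t] = float(np.max(F))
    return _minp_from_fmax(f_max, df2)


def _minp_phenotype_only(geno: GenotypeMatrix, yv: np.ndarray, null_fit: NullModelFit,
                         plans: np.ndarray) -> np.ndarray:
    """Scan with the phenotype permuted and variance components refitted per permutation."""
    q, n = plans.shape
    c0 = null_fit.rotated_X0.shape[1]
    df2 = n - (c0 + 1)
    if df2 <= 0:
        raise DimensionError(f"no residual degrees of freedom: n = {n}, fixed effects = {c0 + 1}")
    U = null_fit.U
    lam = null_fit.eigenvalues
    Xr = null_fit.rotated_X0
    rotG = U.T @ geno.dosage  # rotated once; the genotype is never permuted
    f_max = np.empty(q)
    for t in range(q):
        yr_p = U.T @ yv[plans[t]]
        sigma_g2, sigma_e2, _, _ = _fit_components(yr_p, Xr, lam)
        refit = NullModelFit(
            eigenvalues=lam, U=U, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
            delta=np.inf if sigma_g2 == 0 else sigma_e2 / sigma_g2,
            reml_loglik=np.nan, rotated_y=yr_p, rotated_X0=Xr,
        )
        sw, Qp, ryp, rss0p = _gls_context(refit)
        S_tilde = sw[:, None] * rotG
        _, _, F, _ = _batch_fstats(S_tilde, Qp, ryp, rss0p, df2)
        f_max[t] = float(np.max(F))
    return _minp_from_fmax(f_max, df2)


def write_threshold_report(result: PermutationResult, path: str | Path) -> None:
    """One-row TSV: strategy, q, seed, alpha, threshold and min-p quantiles."""
    quantiles = np.quantile(result.min_p, [0.0, 0.25, 0.5, 0.75, 1.0])
    pd.DataFrame(
        [
            {
                "strategy": result.strategy,
                "q": result.n_permutations,
                "seed": result.seed,
                "alpha": result.alpha,
                "threshold": result.threshold,
                "min_p_min": quantiles[0],
                "min_p_q25": quantiles[1],
                "min_p_median": quantiles[2],
                "min_p_q75": quantiles[3],
                "min_p_max": quantiles[4],
            }
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
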