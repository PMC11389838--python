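"""Linear mixed model: null-model REML fit and batched per-SNP F-tests.

The model is y = Xβ + u + ε with u ~ N(0, σg²K) and ε ~ N(0, σe²I), so that
y ~ N(Xβ, σg²K + σe²I).  Following the EMMAX/FaST-LMM approximation, the two
variance components are estimated once by REML under the null model (intercept
and covariates only, no SNP) and then held fixed for every marker test.

Writing K = U Λ Uᵀ, rotation by Uᵀ diagonalizes the covariance: in rotated
coordinates the model is a weighted least-squares problem with per-sample
weights 1/(σg²λᵢ + σe²).  Each SNP s is tested with X = [1 | covariates | s]
via the extra-sum-of-squares F statistic

    F = (RSS₀ − RSS₁) / (RSS₁ / (n − c)),   df = (1, n − c),

where c counts intercept, covariates and the tested SNP.  Because only the
SNP column changes between tests, whole batches of markers are tested with a
handful of matrix products; results are independent of the batch size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DimensionError, FitError
from .io import CovariateMatrix, GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

#: REML search grid for delta = sigma_e2 / sigma_g2
DELTA_GRID = np.logspace(-5.0, 5.0, 100)
#: lower pin for the residual variance in degenerate fits
SIGMA_E2_FLOOR = 1e-10
#: smallest reportable p-value (keeps p in (0, 1])
P_FLOOR = np.finfo(float).tiny


@dataclass
class NullModelFit:
    """Eigendecomposition of K plus REML variance components of the null model."""

    eigenvalues: np.ndarray  # λ, ascending
    U: np.ndarray  # n x n eigenvectors (columns)
    sigma_g2: float
    sigma_e2: float
    delta: float  # σe²/σg²; +inf when σg² = 0
    reml_loglik: float
    rotated_y: np.ndarray  # Uᵀ y
    rotated_X0: np.ndarray  # Uᵀ [1 | covariates]

    @property
    def n_samples(self) -> int:
        return self.eigenvalues.size

    @property
    def heritability(self) -> float:
        """Variance ratio σg² / (σg² + σe²)."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else math.nan

    def weights(self) -> np.ndarray:
        """Inverse rotated variances 1/(σg²λᵢ + σe²)."""
        v = self.sigma_g2 * self.eigenvalues + self.sigma_e2
        return 1.0 / v


@dataclass
class AssociationResult:
    snp_id: str
    chromosome: str
    position: int
    maf: float
    beta: float
    se: float
    f_stat: float
    p_value: float


# ---------------------------------------------------------------------------
# coercion helpers
# ---------------------------------------------------------------------------

def _as_vector(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def _as_covariate_block(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, CovariateMatrix):
        return covariates.values
    return np.atleast_2d(np.asarray(covariates, dtype=float))


def _as_kinship(K) -> np.ndarray:
    if isinstance(K, KinshipMatrix):
        return K.values
    return np.asarray(K, dtype=float)


def _design_null(y: np.ndarray, covariates) -> np.ndarray:
    n = y.size
    cov = _as_covariate_block(covariates, n)
    if cov.shape[0] != n:
        raise DimensionError(f"covariates have {cov.shape[0]} rows for {n} samples")
    X0 = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise DimensionError("fixed-effects matrix [1 | covariates] is rank deficient")
    return X0


# ---------------------------------------------------------------------------
# REML for the variance components
# ---------------------------------------------------------------------------

def _reml_loglik(log_delta: float, yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray,
                 logdet_xtx: float) -> tuple[float, float]:
    """Profile REML log-likelihood at δ = exp(log_delta).

    Returns ``(loglik, rss)`` where ``rss`` is the weighted residual sum of
    squares; the profiled genetic variance is σg² = rss / (n − c₀).
    """
    delta = math.exp(log_delta)
    n, c0 = Xr.shape
    v = lam + delta
    Xv = Xr / v[:, None]
    XtVX = Xr.T @ Xv
    try:
        beta = np.linalg.solve(XtVX, Xv.T @ yr)
    except np.linalg.LinAlgError:
        return -math.inf, math.nan
    resid = yr - Xr @ beta
    rss = float(np.sum(resid * resid / v))
    if rss <= 0:
        return math.inf, rss  # caller handles the degenerate zero-residual case
    df = n - c0
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -math.inf, rss
    ll = 0.5 * (
        df * math.log(df / (2.0 * math.pi))
        - df
        - df * math.log(rss)
        - float(np.sum(np.log(v)))
        - logdet_xvx
        + logdet_xtx
    )
    return ll, rss


def _fit_components(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray) -> tuple[float, float, float, float]:
    """Grid + bounded refinement REML search over δ.

    Returns ``(sigma_g2, sigma_e2, delta, reml_loglik)``.  Ties on the grid
    break toward smaller δ.
    """
    n, c0 = Xr.shape
    df = n - c0
    if df <= 0:
        raise DimensionError(f"n = {n} samples but {c0} null fixed effects: no residual degrees of freedom")
    sign, logdet_xtx = np.linalg.slogdet(Xr.T @ Xr)
    if sign <= 0:
        raise DimensionError("rotated fixed-effects matrix is rank deficient")
    if np.ptp(lam) < 1e-9 * max(1.0, float(np.max(np.abs(lam)))):
        logger.warning(
            "kinship eigenvalues are (near-)constant: only the total variance "
            "sigma_g2 + sigma_e2 is identifiable, delta is arbitrary"
        )

    ols_resid = yr - Xr @ np.linalg.lstsq(Xr, yr, rcond=None)[0]
    ols_rss = float(ols_resid @ ols_resid)
    if ols_rss <= 1e-12 * max(1.0, float(yr @ yr)):
        # zero residual: the null fixed effects explain y exactly
        logger.warning("null model has (near-)zero residual; sigma_e2 pinned at %g", SIGMA_E2_FLOOR)
        return 0.0, SIGMA_E2_FLOOR, math.inf, math.inf

    log_grid = np.log(DELTA_GRID)
    lls = np.empty(log_grid.size)
    for i, ld in enumerate(log_grid):
        lls[i], _ = _reml_loglik(ld, yr, Xr, lam, logdet_xtx)
    if not np.any(np.isfinite(lls)):
        raise FitError("REML log-likelihood is non-finite over the whole delta grid")

    best = int(np.argmax(lls))  # first max -> smallest delta on ties
    lo = log_grid[max(best - 1, 0)]
    hi = log_grid[min(best + 1, log_grid.size - 1)]
    best_ld, best_ll = log_grid[best], lls[best]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda ld: -_reml_loglik(ld, yr, Xr, lam, logdet_xtx)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ld, best_ll = float(res.x), float(-res.fun)
    ll, rss = _reml_loglik(best_ld, yr, Xr, lam, logdet_xtx)
    delta = math.exp(best_ld)
    sigma_g2 = rss / df
    sigma_e2 = max(sigma_g2 * delta, SIGMA_E2_FLOOR)
    return sigma_g2, sigma_e2, delta, ll


def fit_null_model(y, covariates, K) -> NullModelFit:
    """REML fit of the null mixed model y ~ [1 | covariates] with covariance σg²K + σe²I.

    The kinship matrix is eigendecomposed once; the resulting rotation is
    reused by every downstream association scan and permutation.
    """
    yv = _as_vector(y)
    Kv = _as_kinship(K)
    n = yv.size
    if Kv.shape != (n, n):
        raise DimensionError(f"kinship is {Kv.shape} for {n} phenotyped samples")
    X0 = _design_null(yv, covariates)
    lam, U = np.linalg.eigh(Kv)
    lam = np.maximum(lam, 0.0)
    yr = U.T @ yv
    Xr = U.T @ X0
    sigma_g2, sigma_e2, delta, ll = _fit_components(yr, Xr, lam)
    logger.info(
        "null model: sigma_g2=%.6g sigma_e2=%.6g delta=%.6g (h2=%.3f)",
        sigma_g2, sigma_e2, delta,
        sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else math.nan,
    )
    return NullModelFit(
        eigenvalues=lam,
        U=U,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=ll,
        rotated_y=yr,
        rotated_X0=Xr,
    )


# ---------------------------------------------------------------------------
# batched F-tests
# ---------------------------------------------------------------------------

#: relative tolerance below which a SNP is treated as collinear with the null design
COLLINEARITY_RTOL = 1e-10


def _gls_context(null_fit: NullModelFit, rotated_X0: np.ndarray | None = None,
                 rotated_y: np.ndarray | None = None):
    """Weighted, rotated null design shared by all SNP tests.

    Returns ``(sqrt_w, Q, ry, rss0)`` where Q is an orthonormal basis of the
    weighted null design and ry the weighted null residual of y.
    """
    w = null_fit.weights()
    sw = np.sqrt(w)
    Xr = null_fit.rotated_X0 if rotated_X0 is None else rotated_X0
    yr = null_fit.rotated_y if rotated_y is None else rotated_y
    Q, _ = np.linalg.qr(sw[:, None] * Xr)
    yt = sw * yr
    ry = yt - Q @ (Q.T @ yt)
    rss0 = float(ry @ ry)
    return sw, Q, ry, rss0


def _batch_fstats(S_tilde: np.ndarray, Q: np.ndarray, ry: np.ndarray, rss0: float,
                  df2: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """F statistics for a batch of weighted rotated SNP columns.

    ``S_tilde`` is n x b.  Returns ``(beta, se, F, collinear)`` arrays of
    length b; SNPs collinear with the null design get beta = 0, F = 0 and are
    flagged so callers can report p = 1.
    """
    Rs = S_tilde - Q @ (Q.T @ S_tilde)
    den = np.einsum("ij,ij->j", Rs, Rs)
    total = np.einsum("ij,ij->j", S_tilde, S_tilde)
    collinear = den <= COLLINEARITY_RTOL * np.maximum(total, 1.0)
    den_safe = np.where(collinear, 1.0, den)
    num = Rs.T @ ry
    explained = num * num / den_safe
    rss1 = rss0 - explained
    if np.any(rss1 < -1e-6 * max(rss0, 1.0)):
        raise FitError(
            "negative residual sum of squares in a batched F-test; the kinship "
            "matrix is ill-conditioned (stabilize it or increase jitter)"
        )
    rss1 = np.maximum(rss1, 0.0)
    beta = np.where(collinear, 0.0, num / den_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(collinear, 0.0, explained / (rss1 / df2))
        se = np.where(collinear, np.nan, np.sqrt(rss1 / df2 / den_safe))
    F = np.where(np.isfinite(F), F, np.inf)
    return beta, se, F, collinear


def f_to_p(f_stat, df1: int, df2: int):
    """Upper-tail F survival probability (vectorized over ``f_stat``)."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"degrees of freedom must be positive, got ({df1}, {df2})")
    f_arr = np.asarray(f_stat, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("F statistics must be non-negative")
    p = np.maximum(stats.f.sf(f_arr, df1, df2), P_FLOOR)
    return float(p) if np.isscalar(f_stat) or f_arr.ndim == 0 else p


def association_scan(
    geno: GenotypeMatrix,
    y,
    covariates,
    null_fit: NullModelFit,
    batch_size: int = 1024,
) -> list[AssociationResult]:
    """Batched per-SNP F-tests with variance components fixed from the null fit.

    Each SNP is tested as the last column of X = [1 | covariates | s] by
    generalized least squares in the rotated coordinates.  Results are
    identical for any ``batch_size`` ≥ 1.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    yv = _as_vector(y)
    n, m = geno.dosage.shape
    if yv.size != n:
        raise DimensionError(f"phenotype has {yv.size} values for {n} genotype samples")
    if null_fit.n_samples != n:
        raise DimensionError("null model fit does not match the genotype sample count")
    c0 = null_fit.rotated_X0.shape[1]
    c = c0 + 1  # intercept + covariates + tested SNP
    df2 = n - c
    if df2 <= 0:
        raise DimensionError(f"no residual degrees of freedom: n = {n}, fixed effects = {c}")

    sw, Q, ry, rss0 = _gls_context(null_fit)
    mafs = geno.maf()
    U = null_fit.U
    results: list[AssociationResult] = []
    n_collinear = 0
    for start in range(0, m, batch_size):
        stop = min(start + batch_size, m)
        S_tilde = sw[:, None] * (U.T @ geno.dosage[:, start:stop])
        beta, se, F, collinear = _batch_fstats(S_tilde, Q, ry, rss0, df2)
        p = np.maximum(stats.f.sf(F, 1, df2), P_FLOOR)
        p = np.where(collinear, 1.0, p)
        n_collinear += int(collinear.sum())
        for j in range(stop - start):
            k = start + j
            results.append(
                AssociationResult(
                    snp_id=geno.snp_ids[k],
                    chromosome=str(geno.chromosome[k]),
                    position=int(geno.position[k]),
                    maf=float(mafs[k]),
                    beta=float(beta[j]),
                    se=float(se[j]),
                    f_stat=float(F[j]),
                    p_value=float(p[j]),
                )
            )
    if n_collinear:
        logger.info(
            "association_scan: %d SNP(s) collinear with the null design reported with p = 1",
            n_collinear,
        )
    return results
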