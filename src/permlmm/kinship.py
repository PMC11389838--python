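"""Genetic-similarity (kinship) matrix: computation, stabilization, Cholesky.

The kernel is the standardized relationship matrix K = Z Zᵀ / m, where Z is
the dosage matrix with each SNP column centred and scaled to unit empirical
variance.  With this scaling the mean diagonal element is exactly 1, so the
genetic variance component σg² of the mixed model is on the same scale as the
residual variance, and a Cholesky factor C of K turns i.i.d. Gaussians into a
polygenic background with covariance σg²K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import ConditioningError, DimensionError

if TYPE_CHECKING:  # pragma: no cover
    from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: tolerated asymmetry / negative-eigenvalue slack before stabilization
SYMMETRY_TOL = 1e-10
MIN_EIGENVALUE = 1e-8
MAX_JITTER = 1e-2


@dataclass
class KinshipMatrix:
    """n x n symmetric positive semidefinite genetic-similarity matrix."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DimensionError(
                f"kinship matrix shape {self.values.shape} does not match {n} sample ids"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def compute_kinship(geno: "GenotypeMatrix") -> KinshipMatrix:
    """Standardized kernel K = Z Zᵀ / m over all (non-constant, imputed) SNPs."""
    dosage = np.asarray(geno.dosage, dtype=float)
    if not np.all(np.isfinite(dosage)):
        raise ValueError("genotype contains missing calls; mean-impute before computing kinship")
    n, m = dosage.shape
    if m < 2:
        raise ValueError("kinship needs at least 2 SNPs")
    mean = dosage.mean(axis=0)
    sd = dosage.std(axis=0)  # empirical SD (ddof=0) so that mean(diag K) = 1
    constant = sd == 0.0
    if constant.any():
        bad = [geno.snp_ids[i] for i in np.flatnonzero(constant)[:5]]
        raise ValueError(
            f"constant SNP column(s) present (e.g. {bad}); filter monomorphic SNPs first "
            "(filter_maf with min_maf=0)"
        )
    Z = (dosage - mean) / sd
    K = (Z @ Z.T) / m
    K = 0.5 * (K + K.T)  # enforce exact symmetry
    return KinshipMatrix(sample_ids=list(geno.sample_ids), values=K)


def stabilize(K: KinshipMatrix, jitter_start: float = 1e-8) -> KinshipMatrix:
    """Add δ·I, doubling δ from ``jitter_start``, until min eigenvalue ≥ 1e-8.

    A well-conditioned matrix is returned unchanged (δ = 0).  Raises
    :class:`ConditioningError` once δ would exceed 1e-2.
    """
    A = K.values
    if not np.allclose(A, A.T, atol=SYMMETRY_TOL):
        raise ValueError("kinship matrix is not symmetric")
    min_eig = float(np.linalg.eigvalsh(A)[0])
    if min_eig >= MIN_EIGENVALUE:
        return K
    delta = float(jitter_start)
    while delta <= MAX_JITTER:
        if min_eig + delta >= MIN_EIGENVALUE:
            logger.info("stabilize: added %.3g to the kinship diagonal (min eig was %.3g)", delta, min_eig)
            return KinshipMatrix(
                sample_ids=list(K.sample_ids),
                values=A + delta * np.eye(A.shape[0]),
            )
        delta *= 2.0
    raise ConditioningError(
        f"kinship matrix needs diagonal jitter > {MAX_JITTER} (min eigenvalue {min_eig:.3g}); "
        "check for duplicated or erroneous samples"
    )


def cholesky_factor(K: KinshipMatrix) -> np.ndarray:
    """Lower-triangular C with C Cᵀ = K.  Input must be stabilized."""
    try:
        C = np.linalg.cholesky(K.values)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "Cholesky factorization failed; stabilize() the kinship matrix first"
        ) from exc
    err = float(np.max(np.abs(C @ C.T - K.values)))
    if err >= 1e-8:
        raise ConditioningError(f"Cholesky reconstruction error {err:.3g} exceeds 1e-8")
    return C
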