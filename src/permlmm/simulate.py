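"""Synthetic genotypes with population structure and phenotypes with known truth.

Genotypes follow the Balding–Nichols model: an ancestral allele frequency is
drawn per SNP, each subpopulation's frequency is drawn from a Beta
distribution whose concentration is governed by the divergence parameter Fst,
and diploid dosages are binomial(2, p) draws.  SNPs are placed on 5
chromosomes at 1 kbp spacing, which makes the ±10 kbp true-positive window of
the evaluation module meaningful.

Phenotypes follow an additive mixed-model recipe, y = sβ + Cu + ε: a polygenic
background b = Cu (C the Cholesky factor of the kinship matrix, u standard
normal) scaled together with the noise ε so that the background explains
exactly 30% of the non-SNP variance, plus one causal SNP s (MAF > 5%) whose
effect β is scaled to explain exactly 20% of the total phenotypic variance.
The noise is either Gaussian or — to produce increasingly skewed phenotypes —
mean-centred gamma with shape k ∈ {4, 3, 2, 1, 0.5} (skewness 2/√k).  Variance
fractions are enforced on the realized vectors, so they hold exactly for every
replicate rather than only in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, PhenotypeVector
from .kinship import KinshipMatrix, cholesky_factor

logger = logging.getLogger(__name__)

N_CHROMOSOMES = 5
SNP_SPACING_BP = 1000

#: study defaults: background share of the non-SNP variance and causal-SNP
#: share of the total variance
BACKGROUND_FRACTION = 0.30
SNP_FRACTION = 0.20
CAUSAL_MIN_MAF = 0.05

GAMMA_SHAPES = (4.0, 3.0, 2.0, 1.0, 0.5)
#: the six simulation settings: Gaussian noise plus five gamma shapes
DEFAULT_SETTINGS = (("gaussian", None),) + tuple(("gamma", k) for k in GAMMA_SHAPES)
DEFAULT_REPLICATES = 100


@dataclass
class SimulationTruth:
    causal_snp_id: str
    causal_chromosome: str
    causal_position: int
    beta: float
    noise_family: str  # gaussian | gamma
    gamma_shape: float | None
    target_background_fraction: float
    target_snp_fraction: float
    seed: int


def simulate_genotypes(
    n: int,
    m: int,
    n_subpops: int = 1,
    fst: float = 0.0,
    seed: int = 0,
    ld_copy: float = 0.0,
) -> GenotypeMatrix:
    """Balding–Nichols diploid dosages for ``n`` samples and ``m`` SNPs.

    Samples are split evenly over ``n_subpops`` subpopulations.  With
    ``fst = 0`` (or one subpopulation) all samples share the ancestral
    frequencies and the genotypes are unstructured.  ``ld_copy`` introduces
    optional first-order local linkage: with that probability a sample's
    dosage at SNP j is copied from SNP j−1 instead of drawn fresh.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if m < 100:
        raise ValueError("m must be >= 100")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if not 0.0 <= fst < 0.5:
        raise ValueError(f"fst must be in [0, 0.5), got {fst}")
    if not 0.0 <= ld_copy < 1.0:
        raise ValueError(f"ld_copy must be in [0, 1), got {ld_copy}")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=m)
    subpop = np.arange(n) % n_subpops
    if fst > 0.0 and n_subpops > 1:
        a = ancestral * (1.0 - fst) / fst
        b = (1.0 - ancestral) * (1.0 - fst) / fst
        pop_freq = rng.beta(a[None, :], b[None, :], size=(n_subpops, m))
    else:
        pop_freq = np.tile(ancestral, (n_subpops, 1))
    freq = pop_freq[subpop, :]  # n x m per-sample allele frequency
    dosage = rng.binomial(2, freq).astype(float)
    if ld_copy > 0.0:
        copy = rng.random(size=(n, m)) < ld_copy
        copy[:, 0] = False
        for j in range(1, m):
            rows = copy[:, j]
            dosage[rows, j] = dosage[rows, j - 1]

    per_chrom = -(-m // N_CHROMOSOMES)  # ceil
    chrom_idx = np.arange(m) // per_chrom
    chromosome = np.array([str(c + 1) for c in chrom_idx], dtype=object)
    position = ((np.arange(m) % per_chrom) + 1) * SNP_SPACING_BP
    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chromosome, position)]
    return GenotypeMatrix(
        sample_ids=[f"sample{i:04d}" for i in range(n)],
        snp_ids=snp_ids,
        chromosome=chromosome,
        position=position.astype(np.int64),
        dosage=dosage,
    )


def _sample_variance(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1))


def simulate_phenotype(
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    noise_family: str = "gaussian",
    gamma_shape: float | None = None,
    seed: int = 0,
    background_fraction: float = BACKGROUND_FRACTION,
    snp_fraction: float = SNP_FRACTION,
) -> tuple[PhenotypeVector, SimulationTruth]:
    """One phenotype y = sβ + Cu + ε with exact realized variance fractions."""
    if noise_family not in ("gaussian", "gamma"):
        raise ValueError(f"noise_family must be gaussian or gamma, got {noise_family!r}")
    if noise_family == "gamma":
        if gamma_shape is None or gamma_shape <= 0:
            raise ValueError("gamma noise needs a positive gamma_shape")
    elif gamma_shape is not None:
        raise ValueError("gamma_shape is only meaningful for gamma noise")
    if not 0.0 < background_fraction < 1.0 or not 0.0 < snp_fraction < 1.0:
        raise ValueError("variance fractions must be in (0, 1)")

    rng = np.random.default_rng(seed)
    C = cholesky_factor(K)
    n = K.n_samples
    if geno.n_samples != n:
        raise ValueError("genotype and kinship sample counts differ")

    b = C @ rng.standard_normal(n)  # polygenic background, cov ~ K
    if noise_family == "gaussian":
        e = rng.standard_normal(n)
    else:
        e = rng.gamma(shape=gamma_shape, scale=1.0, size=n)
    e = e - e.mean()
    # scale the noise so the background explains `background_fraction` of the
    # non-SNP variance: var(b) / (var(b) + var(e)) = background_fraction
    var_b = _sample_variance(b)
    target_var_e = var_b * (1.0 - background_fraction) / background_fraction
    e = e * np.sqrt(target_var_e / _sample_variance(e))

    eligible = np.flatnonzero(geno.maf() > CAUSAL_MIN_MAF)
    if eligible.size == 0:
        raise ValueError(f"no SNP with MAF > {CAUSAL_MIN_MAF} to use as causal marker")
    causal = int(rng.choice(eligible))
    s = geno.dosage[:, causal]
    # scale the causal effect to `snp_fraction` of the total variance:
    # var(βs) / (var(βs) + var(b) + var(e)) = snp_fraction
    var_be = _sample_variance(b) + _sample_variance(e)
    beta = float(np.sqrt(snp_fraction / (1.0 - snp_fraction) * var_be / _sample_variance(s)))
    y = beta * s + b + e

    truth = SimulationTruth(
        causal_snp_id=geno.snp_ids[causal],
        causal_chromosome=str(geno.chromosome[causal]),
        causal_position=int(geno.position[causal]),
        beta=beta,
        noise_family=noise_family,
        gamma_shape=gamma_shape,
        target_background_fraction=background_fraction,
        target_snp_fraction=snp_fraction,
        seed=seed,
    )
    return PhenotypeVector(sample_ids=list(geno.sample_ids), values=y), truth


def simulation_suite(
    geno: GenotypeMatrix,
    K: KinshipMatrix,
    settings=DEFAULT_SETTINGS,
    replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
) -> list[tuple[PhenotypeVector, SimulationTruth]]:
    """The full simulation design: every setting × ``replicates`` phenotypes.

    Per-replicate seeds are derived from ``master_seed`` by fixed offsets
    (setting index × 10⁴ + replicate), so the suite is reproducible and each
    phenotype can be regenerated in isolation from its recorded seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out: list[tuple[PhenotypeVector, SimulationTruth]] = []
    for si, (family, shape) in enumerate(settings):
        for r in range(replicates):
            seed = int(master_seed) + si * 10_000 + r
            out.append(
                simulate_phenotype(geno, K, noise_family=family, gamma_shape=shape, seed=seed)
            )
    logger.info(
        "simulation_suite: %d phenotypes (%d settings x %d replicates)",
        len(out), len(settings), replicates,
    )
    return out


def setting_label(family: str, shape: float | None) -> str:
    """Human-readable setting name, e.g. ``gaussian`` or ``gamma_0.5``."""
    return family if family == "gaussian" else f"gamma_{shape:g}"
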