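"""Structured genotype simulation and the skewed-phenotype recipe."""

import numpy as np
import pytest
from scipy import stats

import permlmm as pl
from permlmm.simulate import DEFAULT_SETTINGS, GAMMA_SHAPES


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_genotype_determinism_and_layout():
    a = pl.simulate_genotypes(30, 250, 2, 0.1, seed=70)
    b = pl.simulate_genotypes(30, 250, 2, 0.1, seed=70)
    np.testing.assert_array_equal(a.dosage, b.dosage)
    assert set(np.unique(a.dosage)) <= {0.0, 1.0, 2.0}
    assert len(set(a.chromosome)) == 5
    # positions strictly increasing within each chromosome, 1 kbp spacing
    for c in set(a.chromosome):
        pos = a.position[a.chromosome == c]
        assert np.all(np.diff(pos) == 1000)


def test_genotype_parameter_validation():
    with pytest.raises(ValueError):
        pl.simulate_genotypes(10, 250, 2, 0.1, seed=1)  # n too small
    with pytest.raises(ValueError):
        pl.simulate_genotypes(30, 50, 2, 0.1, seed=1)  # m too small
    with pytest.raises(ValueError):
        pl.simulate_genotypes(30, 250, 2, 0.6, seed=1)  # fst out of range


def test_unstructured_genotypes_have_no_kinship_structure():
    geno = pl.filter_maf(pl.simulate_genotypes(200, 5000, 1, 0.0, seed=71), 0.0)
    K = pl.compute_kinship(geno).values
    off = K[~np.eye(K.shape[0], dtype=bool)]
    assert np.mean(np.abs(off)) < 0.1


def test_structured_genotypes_cluster_by_subpopulation():
    n = 100
    geno = pl.filter_maf(pl.simulate_genotypes(n, 2000, 2, 0.2, seed=72), 0.0)
    K = pl.compute_kinship(geno).values
    subpop = np.arange(n) % 2
    same = subpop[:, None] == subpop[None, :]
    mask_off = ~np.eye(n, dtype=bool)
    within = K[same & mask_off].mean()
    between = K[~same].mean()
    assert within > between


def test_ld_copy_induces_adjacent_correlation():
    plain = pl.simulate_genotypes(100, 500, 1, 0.0, seed=73)
    linked = pl.simulate_genotypes(100, 500, 1, 0.0, seed=73, ld_copy=0.8)

    def adjacent_corr(g):
        d = g.dosage
        keep = (d.std(axis=0)[:-1] > 0) & (d.std(axis=0)[1:] > 0)
        cors = [
            np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
            for j in np.flatnonzero(keep)
        ]
        return np.nanmean(cors)

    assert adjacent_corr(linked) > adjacent_corr(plain) + 0.3


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def test_variance_fractions_hold_exactly(small_panel):
    geno, K = small_panel
    y, truth = pl.simulate_phenotype(geno, K, "gamma", 1.0, seed=74)
    # reconstruct components from the recorded seed
    rng = np.random.default_rng(truth.seed)
    C = pl.cholesky_factor(K)
    b = C @ rng.standard_normal(K.n_samples)
    e = rng.gamma(1.0, 1.0, size=K.n_samples)
    e -= e.mean()
    var_b = np.var(b, ddof=1)
    e *= np.sqrt(var_b * 0.7 / 0.3 / np.var(e, ddof=1))
    background = var_b / (var_b + np.var(e, ddof=1))
    assert background == pytest.approx(0.30, abs=1e-10)

    s = geno.dosage[:, geno.snp_ids.index(truth.causal_snp_id)]
    var_snp = np.var(truth.beta * s, ddof=1)
    total = var_snp + var_b + np.var(e, ddof=1)
    assert var_snp / total == pytest.approx(0.20, abs=1e-10)
    np.testing.assert_allclose(y.values, truth.beta * s + b + e)


def test_phenotype_determinism(small_panel):
    geno, K = small_panel
    y1, t1 = pl.simulate_phenotype(geno, K, "gaussian", seed=75)
    y2, t2 = pl.simulate_phenotype(geno, K, "gaussian", seed=75)
    np.testing.assert_array_equal(y1.values, y2.values)
    assert t1 == t2


def test_causal_snp_has_common_minor_allele(small_panel):
    geno, K = small_panel
    for seed in range(5):
        _, truth = pl.simulate_phenotype(geno, K, "gaussian", seed=seed)
        j = geno.snp_ids.index(truth.causal_snp_id)
        assert geno.maf()[j] > 0.05


def test_noise_skewness_by_family():
    geno, K = pl.study.make_study_panel(n=200, m=500, seed=76)
    y_norm, _ = pl.simulate_phenotype(geno, K, "gaussian", seed=77)
    y_skew, _ = pl.simulate_phenotype(geno, K, "gamma", 0.5, seed=78)

    def noise_skew(truth_seed, family, shape):
        rng = np.random.default_rng(truth_seed)
        rng.standard_normal(200)  # background draw consumed first
        if family == "gaussian":
            e = rng.standard_normal(200)
        else:
            e = rng.gamma(shape, 1.0, size=200)
        return stats.skew(e - e.mean())

    assert abs(noise_skew(77, "gaussian", None)) < 0.35
    assert noise_skew(78, "gamma", 0.5) > 1.0
    del y_norm, y_skew


def test_noise_skewness_decreases_with_gamma_shape(small_panel):
    """Mean noise skewness over 50 replicates grows monotonically as the gamma
    shape drops 4 -> 0.5 (theoretical skewness is 2/sqrt(shape))."""
    geno, K = small_panel
    n = K.n_samples
    mean_skew = []
    for shape in GAMMA_SHAPES:
        skews = []
        for r in range(50):
            _, truth = pl.simulate_phenotype(geno, K, "gamma", shape, seed=1000 + r)
            # replay the generator stream: background draw first, then noise
            rng = np.random.default_rng(truth.seed)
            rng.standard_normal(n)
            e = rng.gamma(shape, 1.0, size=n)
            skews.append(stats.skew(e - e.mean()))
        mean_skew.append(np.mean(skews))
    assert np.all(np.diff(mean_skew) > 0)


def test_phenotype_input_validation(small_panel):
    geno, K = small_panel
    with pytest.raises(ValueError, match="gamma_shape"):
        pl.simulate_phenotype(geno, K, "gamma", None, seed=1)
    with pytest.raises(ValueError, match="gamma_shape"):
        pl.simulate_phenotype(geno, K, "gaussian", 2.0, seed=1)
    with pytest.raises(ValueError, match="noise_family"):
        pl.simulate_phenotype(geno, K, "lognormal", seed=1)


def test_no_eligible_causal_snp_raises():
    n = 40
    dosage = np.zeros((n, 3))
    dosage[0, :] = 1.0  # MAF 1/80 for every SNP
    geno = pl.GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=["a", "b", "c"],
        chromosome=np.array(["1", "1", "1"], dtype=object),
        position=np.array([1000, 2000, 3000]),
        dosage=dosage,
    )
    K = pl.KinshipMatrix(sample_ids=list(geno.sample_ids), values=np.eye(n))
    with pytest.raises(ValueError, match="MAF"):
        pl.simulate_phenotype(geno, K, "gaussian", seed=1)


def test_phenotype_tracks_top_kinship_eigenvector(small_panel):
    """Structured background: regressing y on K's top eigenvector gives R² > 0."""
    geno, K = small_panel
    lam, U = np.linalg.eigh(K.values)
    top = U[:, -1]
    r2 = []
    for r in range(10):
        y, _ = pl.simulate_phenotype(geno, K, "gaussian", seed=2000 + r)
        r2.append(np.corrcoef(top, y.values)[0, 1] ** 2)
    assert np.mean(r2) > 0


def test_power_at_study_scale(study_panel):
    """The 20%-variance causal SNP beats Bonferroni in >= 80% of replicates."""
    geno, K = study_panel
    bonf = pl.bonferroni_threshold(0.05, geno.n_snps)
    hits = 0
    n_rep = 50
    for r in range(n_rep):
        y, truth = pl.simulate_phenotype(geno, K, "gaussian", seed=3000 + r)
        fit = pl.fit_null_model(y, None, K)
        res = pl.association_scan(geno, y, None, fit)
        causal_p = next(x.p_value for x in res if x.snp_id == truth.causal_snp_id)
        hits += causal_p < bonf
    assert hits / n_rep >= 0.8


# ---------------------------------------------------------------------------
# suite
# ---------------------------------------------------------------------------

def test_suite_counts_and_reproducibility(small_panel):
    geno, K = small_panel
    suite = pl.simulation_suite(geno, K, replicates=10, master_seed=5)
    assert len(suite) == 60  # 6 settings x 10 replicates
    again = pl.simulation_suite(geno, K, replicates=10, master_seed=5)
    np.testing.assert_array_equal(suite[13][0].values, again[13][0].values)
    # settings enumerate gaussian plus the five gamma shapes
    families = {(t.noise_family, t.gamma_shape) for _, t in suite}
    assert families == set(DEFAULT_SETTINGS)


def test_suite_default_scale_is_600(small_panel):
    geno, K = small_panel
    suite = pl.simulation_suite(geno, K, master_seed=6)
    assert len(suite) == 600
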