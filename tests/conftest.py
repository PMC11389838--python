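"""Shared fixtures: small structured genotype panels generated at test time."""

import numpy as np
import pytest

import permlmm as pl


@pytest.fixture(scope="session")
def small_panel():
    """40 samples x ~300 structured SNPs with its stabilized kinship matrix."""
    geno = pl.filter_maf(pl.simulate_genotypes(40, 300, n_subpops=2, fst=0.2, seed=11), 0.0)
    K = pl.stabilize(pl.compute_kinship(geno))
    return geno, K


@pytest.fixture(scope="session")
def study_panel():
    """200 samples x ~2000 structured SNPs, the simulation-study scale."""
    geno, K = pl.study.make_study_panel(seed=21)
    return geno, K


@pytest.fixture()
def toy_genotype():
    """Tiny hand-checkable genotype: 4 samples x 5 SNPs on two chromosomes."""
    return pl.GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        snp_ids=["a", "b", "c", "d", "e"],
        chromosome=np.array(["1", "1", "1", "2", "2"], dtype=object),
        position=np.array([1000, 2000, 3000, 1000, 2000]),
        dosage=np.array(
            [
                [0, 1, 2, 0, 0],
                [1, 1, 0, 0, 2],
                [2, 0, 1, 0, 1],
                [0, 2, 1, 1, 1],
            ],
            dtype=float,
        ),
    )
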