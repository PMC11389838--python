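"""Comparator thresholds, TP/FP scoring, FDR/pFDR, normality test, categories."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import permlmm as pl
from permlmm.simulate import SimulationTruth


def _truth(chrom="1", pos=50_000):
    return SimulationTruth(
        causal_snp_id="causal", causal_chromosome=chrom, causal_position=pos,
        beta=1.0, noise_family="gaussian", gamma_shape=None,
        target_background_fraction=0.3, target_snp_fraction=0.2, seed=0,
    )


def _hits(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position", "p_value"])


# ---------------------------------------------------------------------------
# static thresholds
# ---------------------------------------------------------------------------

def test_bonferroni_reference_values():
    assert pl.bonferroni_threshold(0.05, 10**6) == pytest.approx(5e-8, rel=1e-12)
    # one significant figure beyond: 0.05 / 2.8e6 rounds to 1.79e-8
    assert pl.bonferroni_threshold(0.05, int(2.8e6)) == pytest.approx(1.79e-8, rel=5e-3)
    assert pl.bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        pl.bonferroni_threshold(0.05, 0)


def test_expected_null_hits_reference_values():
    assert pl.expected_null_hits(0.05, 1000) == 50
    assert pl.expected_null_hits(0.05, 10**6) == 50_000
    assert pl.expected_null_hits(0.05, 1) == 0.05


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def test_bh_step_up_worked_example():
    reject, threshold = pl.benjamini_hochberg([0.001, 0.01, 0.03, 0.04], alpha=0.05)
    assert reject.all()  # p(4) = 0.04 <= 4 * 0.05/4
    assert threshold == 0.04


def test_bh_no_rejections():
    reject, threshold = pl.benjamini_hochberg([0.5, 0.6, 0.9], alpha=0.05)
    assert not reject.any()
    assert threshold is None


def test_bh_single_p_reduces_to_unadjusted_test():
    reject, threshold = pl.benjamini_hochberg([0.04], alpha=0.05)
    assert reject.all() and threshold == 0.04


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(80)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 60)) ** 2
        ours, _ = pl.benjamini_hochberg(p, alpha=0.05)
        theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, theirs)


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        pl.benjamini_hochberg([], alpha=0.05)
    with pytest.raises(ValueError):
        pl.benjamini_hochberg([0.0, 0.5], alpha=0.05)


# ---------------------------------------------------------------------------
# hit classification
# ---------------------------------------------------------------------------

def test_classify_hits_window_boundaries():
    truth = _truth()
    hits = _hits(
        [
            ("h0", "1", 50_000, 1e-9),  # at the causal position
            ("h1", "1", 60_000, 1e-9),  # exactly +10 000 bp
            ("h2", "1", 60_001, 1e-9),  # one bp beyond
            ("h3", "2", 50_000, 1e-9),  # other chromosome
            ("h4", "1", 40_000, 1e-9),  # exactly -10 000 bp
            ("h5", "1", 55_000, 0.5),   # above threshold -> dropped
        ]
    )
    table = pl.classify_hits(hits, truth, threshold=1e-5)
    labels = dict(zip(table.table["snp_id"], table.table["label"]))
    assert labels == {"h0": "TP", "h1": "TP", "h2": "FP", "h3": "FP", "h4": "TP"}
    assert table.n_tp == 3 and table.n_fp == 2


# ---------------------------------------------------------------------------
# FDR / pFDR
# ---------------------------------------------------------------------------

def test_fdr_values():
    assert pl.fdr(1, 1) == 0.5
    assert pl.fdr(3, 0) == 0.0
    assert math.isnan(pl.fdr(0, 0))
    with pytest.raises(ValueError):
        pl.fdr(-1, 0)


def test_fdr_scale_free():
    for c in (2, 10, 137):
        assert pl.fdr(3 * c, 5 * c) == pl.fdr(3, 5)


def test_pfdr_values():
    outcomes = [(True, False)] * 8 + [(False, True)] * 4
    assert pl.pfdr(outcomes) == pytest.approx(4 / 12)
    assert pl.pfdr([(True, False), (True, False)]) == 0.0
    assert math.isnan(pl.pfdr([(False, False)]))
    # a replicate that is both TP and FP counts on both sides
    assert pl.pfdr([(True, True)]) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# independent loci
# ---------------------------------------------------------------------------

def test_count_independent_loci():
    assert pl.count_independent_loci(_hits([("a", "1", 1000, 0), ("b", "1", 5000, 0), ("c", "1", 20000, 0)])) == 2
    assert pl.count_independent_loci(_hits([("a", "1", 1000, 0)])) == 1
    assert pl.count_independent_loci(_hits([("a", "1", 0, 0), ("b", "1", 10_000, 0)])) == 1
    assert pl.count_independent_loci(_hits([("a", "1", 0, 0), ("b", "1", 10_001, 0)])) == 2
    assert pl.count_independent_loci(_hits([])) == 0
    # chromosomes never merge
    assert pl.count_independent_loci(_hits([("a", "1", 1000, 0), ("b", "2", 1000, 0)])) == 2


# ---------------------------------------------------------------------------
# Anderson–Darling
# ---------------------------------------------------------------------------

@pytest.mark.filterwarnings("ignore::FutureWarning")
def test_ad_statistic_matches_scipy():
    from scipy.stats import anderson

    rng = np.random.default_rng(81)
    x = rng.standard_normal(200)
    a2, _ = pl.anderson_darling_normality(x)
    assert a2 == pytest.approx(anderson(x, "norm").statistic, abs=1e-10)


def test_ad_calibration_under_normality():
    rng = np.random.default_rng(82)
    calibrated = sum(
        pl.anderson_darling_normality(rng.standard_normal(500))[1] > 0.01
        for _ in range(100)
    )
    assert calibrated >= 95


def test_ad_rejects_strong_skew():
    rng = np.random.default_rng(83)
    x = rng.gamma(0.5, 1.0, size=200)
    _, p = pl.anderson_darling_normality(x)
    assert p < 0.01


def test_ad_input_validation():
    with pytest.raises(ValueError):
        pl.anderson_darling_normality(np.arange(7.0))
    with pytest.raises(ValueError):
        pl.anderson_darling_normality(np.ones(20))


# ---------------------------------------------------------------------------
# outcome categories
# ---------------------------------------------------------------------------

def test_categorize_outcome_examples():
    assert pl.categorize_outcome(3, 0) == 1
    assert pl.categorize_outcome(0, 2) == 2
    assert pl.categorize_outcome(4, 7) == 3
    assert pl.categorize_outcome(5, 40) == 4
    assert pl.categorize_outcome(250, 4) == 5
    assert pl.categorize_outcome(30, 30) == 6
    assert pl.categorize_outcome(0, 0) == 7


@settings(max_examples=300, deadline=None)
@given(st.integers(min_value=0, max_value=1000), st.integers(min_value=0, max_value=1000))
def test_categories_partition_all_count_pairs(nb, np_):
    """Exactly one of the seven defining predicates holds for every pair."""
    cat = pl.categorize_outcome(nb, np_)
    predicates = {
        1: nb > 0 and np_ == 0,
        2: np_ > 0 and nb == 0,
        3: 1 <= nb <= 10 and 1 <= np_ <= 10,
        4: np_ > 10 and 1 <= nb <= 10,
        5: nb > 10 and 1 <= np_ <= 10,
        6: nb > 10 and np_ > 10,
        7: nb == 0 and np_ == 0,
    }
    assert sum(predicates.values()) == 1
    assert predicates[cat]


# ---------------------------------------------------------------------------
# setting summaries
# ---------------------------------------------------------------------------

def test_summary_table():
    s = pl.EvaluationSummary(setting="gamma_1", replicates=3, tp_counts=[1, 0, 2], fp_counts=[1, 0, 0])
    assert s.mean_tp == pytest.approx(1.0)
    assert s.mean_fp == pytest.approx(1 / 3)
    assert s.fdrs == [0.5, 0.0]  # the zero-hit replicate is excluded
    assert s.pfdr == pytest.approx(1 / 3)  # 2 TP phenotypes, 1 FP phenotype
    table = pl.summarize_settings([s])
    assert table.loc[0, "pfdr"] == pytest.approx(1 / 3)
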