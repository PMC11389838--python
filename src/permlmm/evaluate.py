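"""Scoring GWAS output against simulation truth, comparator thresholds, and
outcome classification.

A significant SNP within ±10 kbp of the causal marker (the approximate
distance over which linkage disequilibrium decays in Arabidopsis) counts as a
true positive; anything else below the threshold is a false positive.  The
per-replicate false discovery rate is FDR = FP/(TP+FP); the phenotype-wise
pFDR of a simulation setting is (# phenotypes with ≥1 FP) / (# with ≥1 TP +
# with ≥1 FP), so a phenotype can contribute to both counts.

Comparator thresholds: the static Bonferroni cut α/m and the data-dependent
Benjamini–Hochberg step-up threshold.  An Anderson–Darling normality test
(case 3: mean and variance estimated) supports stratifying phenotypes by how
badly the Gaussian-residual assumption is violated, and a seven-way outcome
classification compares hit counts under Bonferroni vs permutation thresholds
using "up to 10 independent loci is reasonable" as the yardstick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulationTruth

#: true-positive window half-width around the causal SNP, bp (±, inclusive)
TP_WINDOW_BP = 10_000
#: minimum gap between independent loci, bp (exclusive)
LOCUS_GAP_BP = 10_000
#: at most this many independent loci is considered a plausible GWAS outcome
REASONABLE_MAX_LOCI = 10


# ---------------------------------------------------------------------------
# static comparator thresholds
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """The static multiple-testing cut α/m for m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def expected_null_hits(alpha: float, m: int) -> float:
    """Expected number of chance discoveries among m independent null tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha * m


def benjamini_hochberg(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Step-up FDR procedure.

    Returns ``(reject, threshold)`` where ``reject`` is a boolean mask in the
    input order and ``threshold`` is the largest rejected p-value p(k), or
    ``None`` when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * alpha
    passing = np.flatnonzero(sorted_p <= crit)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), None
    k = int(passing[-1])  # largest index with p(k) <= k*alpha/m
    reject = np.zeros(m, dtype=bool)
    reject[order[: k + 1]] = True
    return reject, float(sorted_p[k])


# ---------------------------------------------------------------------------
# hit classification and FDR
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Significant SNPs labelled TP/FP against the simulation truth."""

    table: pd.DataFrame  # columns: snp_id, chromosome, position, p_value, label
    threshold: float

    @property
    def n_tp(self) -> int:
        return int((self.table["label"] == "TP").sum())

    @property
    def n_fp(self) -> int:
        return int((self.table["label"] == "FP").sum())


def classify_hits(hits: pd.DataFrame, truth: SimulationTruth, threshold: float,
                  window_bp: int = TP_WINDOW_BP) -> HitTable:
    """Label sub-threshold SNPs TP (within ±``window_bp`` of the causal SNP,
    same chromosome, boundary inclusive) or FP.

    ``hits`` needs columns chromosome, position, p_value (and snp_id if
    available); rows at or above ``threshold`` are dropped.
    """
    sig = hits[hits["p_value"] < threshold].copy()
    same_chrom = sig["chromosome"].astype(str) == str(truth.causal_chromosome)
    near = (sig["position"].astype(np.int64) - truth.causal_position).abs() <= window_bp
    sig["label"] = np.where(same_chrom & near, "TP", "FP")
    if "snp_id" not in sig.columns:
        sig.insert(0, "snp_id", "")
    cols = ["snp_id", "chromosome", "position", "p_value", "label"]
    return HitTable(table=sig[cols].reset_index(drop=True), threshold=threshold)


def fdr(tp_count: int, fp_count: int) -> float:
    """FP/(TP+FP); NaN (excluded from averages) when there are no hits."""
    if tp_count < 0 or fp_count < 0:
        raise ValueError("counts must be non-negative")
    total = tp_count + fp_count
    if total == 0:
        return math.nan
    return fp_count / total


def pfdr(replicate_outcomes) -> float:
    """Phenotype-wise FDR over replicates flagged ``(has_tp, has_fp)``.

    (# replicates with an FP) / (# with a TP + # with an FP); a replicate can
    count on both sides.  NaN when no replicate has any hit.
    """
    n_tp = sum(1 for has_tp, _ in replicate_outcomes if has_tp)
    n_fp = sum(1 for _, has_fp in replicate_outcomes if has_fp)
    if n_tp + n_fp == 0:
        return math.nan
    return n_fp / (n_tp + n_fp)


def count_independent_loci(hits: pd.DataFrame, min_gap_bp: int = LOCUS_GAP_BP) -> int:
    """Greedy per-chromosome clustering: a gap > ``min_gap_bp`` starts a new locus."""
    if len(hits) == 0:
        return 0
    n_loci = 0
    for _, group in hits.groupby(hits["chromosome"].astype(str), sort=False):
        pos = np.sort(group["position"].astype(np.int64).to_numpy())
        gaps = np.diff(pos)
        n_loci += 1 + int((gaps > min_gap_bp).sum())
    return n_loci


# ---------------------------------------------------------------------------
# Anderson–Darling normality test (case 3: mean and variance estimated)
# ---------------------------------------------------------------------------

def anderson_darling_normality(values) -> tuple[float, float]:
    """A² statistic and p-value for composite normality.

    The statistic uses the standard small-sample correction
    A²* = A²(1 + 0.75/n + 2.25/n²) and the piecewise exponential p-value
    approximation for the case of estimated mean and variance; p is clamped
    to [1e-12, 1].
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input has no defined normality statistic")
    from scipy import stats  # local import keeps module load light

    z = (x - x.mean()) / sd
    cdf = stats.norm.cdf(z)
    eps = 1e-15
    cdf = np.clip(cdf, eps, 1.0 - eps)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1.0 - cdf[::-1])))
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    return float(a2), float(min(max(p, 1e-12), 1.0))


# ---------------------------------------------------------------------------
# seven-way outcome classification
# ---------------------------------------------------------------------------

CATEGORY_DESCRIPTIONS = {
    1: "significant hits only with Bonferroni",
    2: "significant hits only with permutations",
    3: "reasonable amount with both methods",
    4: "inflation with permutations, reasonable with Bonferroni",
    5: "inflation with Bonferroni, reasonable with permutations",
    6: "visible inflation with both thresholds",
    7: "no hits independent of the threshold",
}


def categorize_outcome(n_loci_bonferroni: int, n_loci_permutation: int,
                       reasonable_max: int = REASONABLE_MAX_LOCI) -> int:
    """Map the pair of independent-locus counts to one of seven categories."""
    nb, np_ = n_loci_bonferroni, n_loci_permutation
    if nb < 0 or np_ < 0:
        raise ValueError("locus counts must be non-negative")
    if nb == 0 and np_ == 0:
        return 7
    if np_ == 0:
        return 1
    if nb == 0:
        return 2
    nb_ok = nb <= reasonable_max
    np_ok = np_ <= reasonable_max
    if nb_ok and np_ok:
        return 3
    if nb_ok and not np_ok:
        return 4
    if not nb_ok and np_ok:
        return 5
    return 6


# ---------------------------------------------------------------------------
# per-setting summaries
# ---------------------------------------------------------------------------

@dataclass
class EvaluationSummary:
    setting: str
    replicates: int
    tp_counts: list[int] = field(default_factory=list)
    fp_counts: list[int] = field(default_factory=list)

    @property
    def mean_tp(self) -> float:
        return float(np.mean(self.tp_counts)) if self.tp_counts else math.nan

    @property
    def mean_fp(self) -> float:
        return float(np.mean(self.fp_counts)) if self.fp_counts else math.nan

    @property
    def fdrs(self) -> list[float]:
        """Per-replicate FDR, restricted to replicates with at least one hit."""
        vals = [fdr(tp, fp) for tp, fp in zip(self.tp_counts, self.fp_counts)]
        return [v for v in vals if not math.isnan(v)]

    @property
    def pfdr(self) -> float:
        return pfdr([(tp > 0, fp > 0) for tp, fp in zip(self.tp_counts, self.fp_counts)])


def summarize_settings(summaries: list[EvaluationSummary]) -> pd.DataFrame:
    """Tabular per-setting summary (one row per setting and threshold rule)."""
    rows = []
    for s in summaries:
        fdrs = s.fdrs
        rows.append(
            {
                "setting": s.setting,
                "replicates": s.replicates,
                "mean_tp": s.mean_tp,
                "mean_fp": s.mean_fp,
                "fdr_median": float(np.median(fdrs)) if fdrs else math.nan,
                "fdr_q25": float(np.quantile(fdrs, 0.25)) if fdrs else math.nan,
                "fdr_q75": float(np.quantile(fdrs, 0.75)) if fdrs else math.nan,
                "pfdr": s.pfdr,
            }
        )
    return pd.DataFrame(rows)
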