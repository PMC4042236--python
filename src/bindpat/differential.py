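"""Wilcoxon rank tests on binned regions and differential-region calling.

For each binned enriched region the paired signed-rank test (default; bins
are positionally matched across samples) or the rank-sum test compares the
per-bin quantities x1 (sample A) and x2 (sample B).  Both one-sided
p-values are computed — H1: theta > 0 (A enriched) and H2: theta < 0
(B enriched) — exactly by enumeration of the null distribution for small
problems and by a tie-corrected, continuity-corrected normal approximation
otherwise.  A region is then called a differential enriched region (DER)
when its directional p-value, the ratio r = sum(x1)/sum(x2) and the
difference d = sum(x1) - sum(x2) all pass the user cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import false_discovery_control, norm, rankdata

from .binning import BinnedRegion

#: largest number of non-zero pairs for which the signed-rank null is enumerated
EXACT_SIGNED_RANK_LIMIT = 25
#: largest pooled size for which the rank-sum null is enumerated (no ties)
EXACT_RANK_SUM_LIMIT = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample rank test on a region's bin vectors."""

    statistic: float
    p_greater: float  # one-sided p for H1: theta > 0 (A enriched)
    p_less: float  # one-sided p for H2: theta < 0 (B enriched)
    method: str  # 'exact' | 'normal' | 'degenerate'

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


@dataclass(frozen=True)
class Cutoffs:
    """User thresholds for DER calling.

    alpha: one-sided p-value threshold; ratio_min (> 1): minimum r for
    A-enrichment, B-enrichment requires r <= 1/ratio_min; diff_min: minimum
    |d| on the reporting scale; paired selects signed-rank vs rank-sum.
    """

    alpha: float = 0.05
    ratio_min: float = 1.2
    diff_min: float = 0.8
    paired: bool = True
    correction: str = "none"  # 'none' | 'bh'

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.ratio_min <= 1.0:
            raise ValueError("ratio_min must be > 1")
        if self.diff_min < 0.0:
            raise ValueError("diff_min must be >= 0")
        if self.correction not in ("none", "bh"):
            raise ValueError("correction must be 'none' or 'bh'")


@dataclass
class DifferentialRegion:
    """A binned region annotated with its test outcome and call."""

    binned: BinnedRegion
    statistic: float
    p_value: float  # one-sided p in the source sample's direction
    r: float
    d: float
    enriched_in: str | None = None  # 'A', 'B', or None (not a DER)
    p_adjusted: float | None = None


def _tail_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Number of sign assignments reaching each achievable positive-rank sum.

    ``weights`` are doubled ranks (integers); the returned array ``counts``
    satisfies counts[s] = #{sign vectors : sum of + ranks*2 == s}.
    """
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for w in weights:
        counts[w:] += counts[:-w].copy()
    return counts


def wilcoxon_signed_rank(x1, x2) -> TestResult:
    """Paired Wilcoxon signed-rank test on aligned bin vectors.

    Zero differences are dropped before ranking; tied absolute differences
    receive average ranks.  The reported statistic is the signed-rank sum
    T+ = sum_i R_i * phi_i with phi_i = +1 for positive and -1 for negative
    differences.  The null distribution of the positive-rank sum is
    enumerated exactly (conditional on the observed tie pattern) for up to
    25 non-zero pairs; beyond that a tie-corrected normal approximation
    with continuity correction is used.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1 or x1.size == 0:
        raise ValueError("x1 and x2 must be equal-length 1-D vectors")
    z = x1 - x2
    z = z[z != 0]
    n = z.size
    if n == 0:
        return TestResult(0.0, 1.0, 1.0, "degenerate")
    ranks = rankdata(np.abs(z))
    signs = np.sign(z)
    t_signed = float(np.sum(ranks * signs))
    w_plus = float(ranks[z > 0].sum())

    if n <= EXACT_SIGNED_RANK_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(np.int64)
        total = int(doubled.sum())
        counts = _tail_counts(doubled, total)
        denom = 2.0**n
        obs = int(round(2.0 * w_plus))
        p_greater = float(counts[obs:].sum() / denom)
        p_less = float(counts[: obs + 1].sum() / denom)
        return TestResult(t_signed, min(p_greater, 1.0), min(p_less, 1.0), "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_sizes = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_sizes**3 - tie_sizes)) / 48.0
    if var <= 0:
        return TestResult(t_signed, 1.0, 1.0, "degenerate")
    sd = math.sqrt(var)
    p_greater = float(norm.sf((w_plus - mean - 0.5) / sd))
    p_less = float(norm.cdf((w_plus - mean + 0.5) / sd))
    return TestResult(t_signed, p_greater, p_less, "normal")


def _rank_sum_tail(n_total: int, n_b: int) -> np.ndarray:
    """counts[s] = number of n_b-subsets of ranks {1..n_total} summing to s."""
    max_sum = n_b * (2 * n_total - n_b + 1) // 2
    counts = np.zeros((n_b + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_b), 0, -1):
            counts[k, r:] += counts[k - 1, :-r]
    return counts[n_b]


def wilcoxon_rank_sum(x1, x2) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test on pooled bin values.

    The statistic W is the sum of the pooled ranks of sample B's values.
    A shift of A above B pushes W low, so the H1 (theta > 0) p-value is
    the lower tail of W.  Exact enumeration is used for pooled sizes up to
    20 when there are no ties; otherwise the tie-corrected normal
    approximation applies.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x1, x2])
    n1, n2 = x1.size, x2.size
    n_total = n1 + n2
    ranks = rankdata(pooled)
    w = float(ranks[n1:].sum())
    unique_vals, tie_sizes = np.unique(pooled, return_counts=True)
    has_ties = unique_vals.size < n_total

    if unique_vals.size == 1:
        return TestResult(w, 1.0, 1.0, "degenerate")

    if not has_ties and n_total <= EXACT_RANK_SUM_LIMIT:
        counts = _rank_sum_tail(n_total, n2)
        denom = math.comb(n_total, n2)
        obs = int(round(w))
        p_greater = float(counts[: obs + 1].sum() / denom)  # W small: A high
        p_less = float(counts[obs:].sum() / denom)
        return TestResult(w, min(p_greater, 1.0), min(p_less, 1.0), "exact")

    mean = n2 * (n_total + 1) / 2.0
    var = (
        n1
        * n2
        / 12.0
        * (
            (n_total + 1)
            - float(np.sum(tie_sizes**3 - tie_sizes)) / (n_total * (n_total - 1))
        )
    )
    if var <= 0:
        return TestResult(w, 1.0, 1.0, "degenerate")
    sd = math.sqrt(var)
    p_greater = float(norm.cdf((w - mean + 0.5) / sd))
    p_less = float(norm.sf((w - mean - 0.5) / sd))
    return TestResult(w, p_greater, p_less, "normal")


def region_ratio_difference(
    binned: BinnedRegion, scale: float = 1.0
) -> tuple[float, float]:
    """Ratio r = sum(x1)/sum(x2) and difference d = (sum(x1)-sum(x2))*scale.

    Conventions: sum(x2) == 0 with sum(x1) > 0 gives r = +inf; both sums
    zero gives r = 1 (and such degenerate regions are never DERs since
    their p-value is 1).
    """
    s1 = float(binned.x1.sum())
    s2 = float(binned.x2.sum())
    if s2 == 0.0:
        r = math.inf if s1 > 0.0 else 1.0
    else:
        r = s1 / s2
    return r, (s1 - s2) * scale


def call_ders(
    comparison_set: list[BinnedRegion],
    cutoffs: Cutoffs = Cutoffs(),
    scale: float = 1.0,
) -> list[DifferentialRegion]:
    """Test every region and flag those passing all three cutoffs as DERs.

    A source-A region is an A-DER iff p(theta>0) < alpha, r >= ratio_min
    and d >= diff_min; a source-B region is a B-DER iff p(theta<0) < alpha,
    r <= 1/ratio_min and -d >= diff_min.  Non-passing regions are retained
    with ``enriched_in`` unset.  With ``correction='bh'`` the directional
    p-values are Benjamini–Hochberg adjusted per source sample before the
    alpha cutoff.
    """
    test = wilcoxon_signed_rank if cutoffs.paired else wilcoxon_rank_sum
    results = []
    for br in comparison_set:
        res = test(br.x1, br.x2)
        r, d = region_ratio_difference(br, scale)
        p_dir = res.p_greater if br.source_sample == "A" else res.p_less
        results.append(
            DifferentialRegion(
                binned=br, statistic=res.statistic, p_value=p_dir, r=r, d=d
            )
        )

    if cutoffs.correction == "bh":
        for sample in ("A", "B"):
            group = [dr for dr in results if dr.binned.source_sample == sample]
            if group:
                adjusted = false_discovery_control(
                    np.array([dr.p_value for dr in group]), method="bh"
                )
                for dr, p_adj in zip(group, adjusted):
                    dr.p_adjusted = float(p_adj)

    for dr in results:
        p_eff = dr.p_adjusted if dr.p_adjusted is not None else dr.p_value
        if dr.binned.source_sample == "A":
            passes = (
                p_eff < cutoffs.alpha
                and dr.r >= cutoffs.ratio_min
                and dr.d >= cutoffs.diff_min
            )
            if passes:
                dr.enriched_in = "A"
        else:
            passes = (
                p_eff < cutoffs.alpha
                and dr.r <= 1.0 / cutoffs.ratio_min
                and -dr.d >= cutoffs.diff_min
            )
            if passes:
                dr.enriched_in = "B"
    return results
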