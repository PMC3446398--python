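"""Association between haplotype carriage and DAE status or magnitude.

Three tests:

* exact sign test (binomial tail at p = 1/2) for "all carriers of a
  haplotype show DAE"-type observations;
* Pearson chi-square on the 2x2 carriage x DAE table per haplotype;
* Wilcoxon rank-sum on normalized log2 ratios between carriers of low- and
  high-expression second haplotypes (exact null distribution for small
  samples, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError

EXACT_RANKSUM_MAX_N = 20


def sign_test(k: int, n: int, sided: str = "one") -> float:
    """Exact binomial sign-test p-value at success probability 1/2.

    One-sided: P(X >= k).  Two-sided: min(1, 2 * min(P(X >= k), P(X <= k))).
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    upper = float(stats.binom.sf(k - 1, n, 0.5))
    if sided == "one":
        return upper
    if sided == "two":
        lower = float(stats.binom.cdf(k, n, 0.5))
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    expected: np.ndarray
    defined: bool


def dae_proportion_test(
    table: Sequence[Sequence[float]], correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 carriers/non-carriers x DAE/no-DAE table.

    Continuity correction is off by default.  A zero row or column margin
    makes the statistic undefined; flagged, not raised.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise DataError("negative counts in contingency table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        expected = np.full((2, 2), np.nan)
        return ChiSquareResult(float("nan"), float("nan"), expected, False)
    chi2, p, _, expected = stats.chi2_contingency(arr, correction=correction)
    return ChiSquareResult(float(chi2), float(p), expected, True)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str


def ratio_by_group_test(
    low_group: Sequence[float], high_group: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two ratio groups.

    Exact null distribution when the combined sample size is at most
    20 and the data are tie-free; otherwise the normal approximation with
    tie correction.
    """
    x = np.asarray(low_group, dtype=float)
    y = np.asarray(high_group, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact = (len(x) + len(y)) <= EXACT_RANKSUM_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


@dataclass(frozen=True)
class HaplotypeDaeRow:
    haplotype: str
    n_dae: int
    n_no_dae: int
    chi2: float
    chi2_p: float
    sign_p_one: float
    sign_p_two: float


def dae_by_haplotype_report(
    counts: dict[str, tuple[int, int]],
    bonferroni: bool = False,
) -> list[HaplotypeDaeRow]:
    """Per-haplotype report of DAE counts with chi-square and sign tests.

    ``counts`` maps haplotype label -> (n_dae, n_no_dae) among carriers.  The
    chi-square compares each haplotype's carriers against all other samples
    pooled; the sign test treats each carrier as a trial with success = DAE.
    No multiplicity correction by default; ``bonferroni=True`` multiplies the
    p-values by the number of haplotypes tested.
    """
    if not counts:
        raise DataError("no haplotype counts supplied")
    total_dae = sum(v[0] for v in counts.values())
    total_no = sum(v[1] for v in counts.values())
    m = len(counts)
    rows = []
    for hap, (n_dae, n_no) in sorted(counts.items()):
        chi = dae_proportion_test(
            [[n_dae, n_no], [total_dae - n_dae, total_no - n_no]]
        )
        p1 = sign_test(n_dae, n_dae + n_no, "one")
        p2 = sign_test(n_dae, n_dae + n_no, "two")
        if bonferroni:
            p1, p2 = min(1.0, m * p1), min(1.0, m * p2)
            chi_p = min(1.0, m * chi.p_value) if chi.defined else chi.p_value
        else:
            chi_p = chi.p_value
        rows.append(
            HaplotypeDaeRow(hap, n_dae, n_no, chi.statistic, chi_p, p1, p2)
        )
    return rows
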