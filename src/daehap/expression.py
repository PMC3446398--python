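"""Expression normalization (qPCR ΔΔCt) and genotype/group association tests.

Two analysis routes, mirroring how haplotype effects on downstream gene
expression are usually tested:

1. per-SNP: one-way ANOVA of expression across genotype classes (0/1/2
   copies of the minor allele), with an additive-trend linear fit as a
   secondary output;
2. per-diplotype-group: two-sided t-test between expression groups
   (HH / HL / LL = number of low-expression haplotypes carried).

For qPCR data, Ct values are normalized with the ΔΔCt method against the
mean of the two most stable housekeeping genes; relative expression is
2^(-ΔΔCt).  Array log-intensities are taken as already normalized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)

CT_MODE = "ct"
LOG_INTENSITY_MODE = "log_intensity"


@dataclass
class ExpressionTable:
    """Samples x genes measurement matrix with annotations.

    ``data`` is indexed by sample id with gene-id columns.  ``mode`` is
    ``"ct"`` (qPCR cycle thresholds; higher Ct = lower expression) or
    ``"log_intensity"``.  ``annotations`` carries per-sample genotypes and
    the diplotype expression group, joined on the sample index.
    """

    data: pd.DataFrame
    mode: str
    housekeeping: tuple[str, ...] = ()
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.mode not in (CT_MODE, LOG_INTENSITY_MODE):
            raise DataError(f"unknown expression mode {self.mode!r}")
        missing = [g for g in self.housekeeping if g not in self.data.columns]
        if missing:
            raise DataError(f"housekeeping genes absent from table: {missing}")


def select_housekeeping_pair(
    table: ExpressionTable, candidates: Sequence[str]
) -> tuple[str, str]:
    """Pick the two housekeeping genes with the most stable pairwise ΔCt.

    For each candidate pair the per-sample Ct difference is computed and the
    pair minimizing sum(|ΔCt_i - median ΔCt|) is returned.  Candidates with
    missing values are dropped; ties break lexicographically.
    """
    complete = [
        g
        for g in candidates
        if g in table.data.columns and not table.data[g].isna().any()
    ]
    if len(complete) < 2:
        raise DataError(
            f"need >= 2 housekeeping candidates with complete data, have {complete}"
        )
    best: tuple[float, tuple[str, str]] | None = None
    for g1, g2 in itertools.combinations(sorted(complete), 2):
        d = table.data[g1].to_numpy() - table.data[g2].to_numpy()
        dist = float(np.abs(d - np.median(d)).sum())
        key = (dist, (g1, g2))
        if best is None or key < best:
            best = key
    return best[1]


def ddct_relative_expression(
    table: ExpressionTable,
    hk_pair: tuple[str, str],
    reference_samples: Sequence[str],
) -> pd.DataFrame:
    """ΔΔCt relative expression: 2^-(ΔCt - mean ΔCt of the reference group).

    ΔCt = Ct_gene - mean(Ct of the two housekeeping genes), per sample.  The
    housekeeping columns are excluded from the output.
    """
    if table.mode != CT_MODE:
        raise DataError("ΔΔCt requires Ct-mode data")
    ref = [s for s in reference_samples if s in table.data.index]
    if not ref:
        raise ValueError("reference group is empty")
    hk_mean = table.data[list(hk_pair)].mean(axis=1)
    genes = [g for g in table.data.columns if g not in hk_pair]
    dct = table.data[genes].sub(hk_mean, axis=0)
    ddct = dct - dct.loc[ref].mean(axis=0)
    return np.power(2.0, -ddct)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    class_means: dict[int, float]
    class_counts: dict[int, int]
    trend_slope: float
    trend_p: float
    defined: bool


def genotype_expression_anova(
    expr: Sequence[float], genotype: Sequence[int]
) -> AnovaResult:
    """One-way ANOVA of expression across genotype classes (0/1/2).

    Genotype is treated as a categorical factor.  A secondary additive-trend
    linear regression (expression ~ allele count) is reported alongside.
    A single genotype class present makes the test undefined (flagged).
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(genotype, dtype=int)
    if len(y) != len(g):
        raise DataError("expression and genotype vectors differ in length")
    if len(y) < 2:
        raise DataError("need at least 2 samples")
    classes = sorted(set(g.tolist()))
    means = {int(c): float(y[g == c].mean()) for c in classes}
    counts = {int(c): int((g == c).sum()) for c in classes}
    if len(classes) < 2:
        return AnovaResult(
            float("nan"), float("nan"), means, counts, float("nan"),
            float("nan"), False,
        )
    groups = [y[g == c] for c in classes]
    F, p = stats.f_oneway(*groups)
    lr = stats.linregress(g.astype(float), y)
    return AnovaResult(
        float(F), float(p), means, counts,
        float(lr.slope), float(lr.pvalue), True,
    )


@dataclass(frozen=True)
class GroupTTestResult:
    difference: float
    t: float
    p_value: float
    n1: int
    n2: int
    variant: str


def group_expression_ttest(
    expr: Sequence[float],
    groups: Sequence[str],
    pair: tuple[str, str],
    pooled: bool = False,
) -> GroupTTestResult:
    """Two-sided t-test of expression between two diplotype groups.

    ``pair`` names the groups compared, e.g. ("HH", "HL"); the reported
    difference is first-group mean minus second-group mean.  Welch (unequal
    variance) by default; ``pooled=True`` uses the classical equal-variance
    Student form.
    """
    y = np.asarray(expr, dtype=float)
    lab = np.asarray(groups)
    a = y[lab == pair[0]]
    b = y[lab == pair[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError(
            f"groups {pair} need >= 2 samples each, have {len(a)} and {len(b)}"
        )
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return GroupTTestResult(
        difference=float(a.mean() - b.mean()),
        t=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(a),
        n2=len(b),
        variant="pooled" if pooled else "welch",
    )


def group_pairwise_ttests(
    expr: Sequence[float], groups: Sequence[str], pooled: bool = False
) -> dict[tuple[str, str], GroupTTestResult]:
    """All pairwise group t-tests among HH/HL/LL; absent groups are skipped."""
    present = [g for g in ("HH", "HL", "LL") if (np.asarray(groups) == g).sum() >= 2]
    out = {}
    for pair in itertools.combinations(present, 2):
        out[pair] = group_expression_ttest(expr, groups, pair, pooled=pooled)
    skipped = {"HH", "HL", "LL"} - set(present)
    if skipped:
        log.info("groups absent or too small, skipped: %s", sorted(skipped))
    return out
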