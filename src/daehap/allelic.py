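"""Normalization of replicate allelic peak ratios and DAE calling.

Differential allelic expression (DAE) is assessed at a transcribed
heterozygous marker SNP.  For each sample the allele-A/allele-B peak ratio is
measured in replicate both in cDNA (expression) and in genomic DNA (where the
true ratio is 1:1, so the gDNA ratio captures assay bias).  The normalized
log2 ratio is

    mean(log2 cDNA ratios) - mean(log2 gDNA ratios)

and a sample is called DAE when its absolute normalized log2 ratio strictly
exceeds log2 of the fold threshold (default 1.2-fold, log2 = 0.263).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

DEFAULT_THRESHOLD_FOLD = 1.2


@dataclass(frozen=True)
class AllelicMeasurement:
    """Replicate cDNA and gDNA allelic peak ratios for one sample at one SNP.

    Ratios are allele_a-peak / allele_b-peak, in the allele order given by
    the record — alleles are never reordered.
    """

    sample_id: str
    snp_id: str
    allele_a: str
    allele_b: str
    cdna_ratios: tuple[float, ...]
    gdna_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, ratios in (("cdna", self.cdna_ratios), ("gdna", self.gdna_ratios)):
            if len(ratios) == 0:
                raise DataError(
                    f"sample {self.sample_id}: no {name} replicates"
                )
            for i, r in enumerate(ratios):
                if not (r > 0) or not math.isfinite(r):
                    raise DataError(
                        f"sample {self.sample_id}: non-positive {name} ratio "
                        f"{r!r} in replicate {i + 1}"
                    )


@dataclass(frozen=True)
class DaeCall:
    sample_id: str
    norm_log2_ratio: float
    se: float
    is_dae: bool
    direction: Optional[str]
    threshold_fold: float
    p_value: Optional[float] = None


def normalize_ratio(m: AllelicMeasurement) -> tuple[float, float]:
    """Normalize a sample's cDNA allelic ratio against its gDNA ratio.

    Returns ``(norm_log2_ratio, se)`` where the estimate is the difference of
    mean log2 ratios and the SE is the Welch combination of the two replicate
    variances (0 when both assays have a single replicate).
    """
    c = np.log2(np.asarray(m.cdna_ratios, dtype=float))
    g = np.log2(np.asarray(m.gdna_ratios, dtype=float))
    est = float(c.mean() - g.mean())
    var = 0.0
    if len(c) > 1:
        var += c.var(ddof=1) / len(c)
    if len(g) > 1:
        var += g.var(ddof=1) / len(g)
    return est, float(math.sqrt(var))


def call_dae(
    norm_log2_ratio: float,
    se: float,
    sample_id: str = "",
    allele_a: str = "A",
    allele_b: str = "B",
    threshold_fold: float = DEFAULT_THRESHOLD_FOLD,
    require_t_test: bool = False,
    n_replicates: int = 0,
    alpha: float = 0.05,
) -> DaeCall:
    """Call DAE when |norm_log2_ratio| strictly exceeds log2(threshold_fold).

    The fold-threshold rule is the default caller.  With
    ``require_t_test=True`` a one-sample t-test of the replicate mean against
    0 (using ``se`` on ``n_replicates`` log-ratio replicates) must also reject
    at ``alpha`` for the call to be positive.
    """
    if not threshold_fold > 1:
        raise ConfigError(f"threshold_fold must exceed 1, got {threshold_fold}")
    cut = math.log2(threshold_fold)
    exceeds = abs(norm_log2_ratio) > cut
    p_value = None
    if require_t_test:
        if n_replicates < 2 or se == 0:
            raise ConfigError(
                "t-test mode needs >= 2 replicates and a nonzero SE"
            )
        t = norm_log2_ratio / se
        p_value = float(2 * stats.t.sf(abs(t), df=n_replicates - 1))
        exceeds = exceeds and p_value < alpha
    direction = None
    if exceeds:
        direction = allele_a if norm_log2_ratio > 0 else allele_b
    return DaeCall(
        sample_id=sample_id,
        norm_log2_ratio=norm_log2_ratio,
        se=se,
        is_dae=exceeds,
        direction=direction,
        threshold_fold=threshold_fold,
        p_value=p_value,
    )


def call_dae_from_measurement(
    m: AllelicMeasurement,
    threshold_fold: float = DEFAULT_THRESHOLD_FOLD,
    require_t_test: bool = False,
    alpha: float = 0.05,
) -> DaeCall:
    est, se = normalize_ratio(m)
    return call_dae(
        est,
        se,
        sample_id=m.sample_id,
        allele_a=m.allele_a,
        allele_b=m.allele_b,
        threshold_fold=threshold_fold,
        require_t_test=require_t_test,
        n_replicates=len(m.cdna_ratios),
        alpha=alpha,
    )


@dataclass(frozen=True)
class DaeSummary:
    n_tested: int
    n_dae: int
    n_by_direction: dict[str, int]
    fraction_dae: float


def summarize_counts(n_tested: int, n_dae_by_direction: dict[str, int]) -> DaeSummary:
    """Summary from already-tabulated counts (e.g. a published count table).

    Equivalent to ``summarize_dae`` on a call set with the given totals.
    """
    n_dae = sum(n_dae_by_direction.values())
    if n_tested < 1 or n_dae > n_tested or any(v < 0 for v in n_dae_by_direction.values()):
        raise DataError("inconsistent DAE counts")
    return DaeSummary(
        n_tested=n_tested,
        n_dae=n_dae,
        n_by_direction={k: v for k, v in n_dae_by_direction.items() if v},
        fraction_dae=n_dae / n_tested,
    )


def summarize_dae(calls: Sequence[DaeCall]) -> DaeSummary:
    """Count DAE calls overall and per preferred allele."""
    if len(calls) == 0:
        raise DataError("no DAE calls to summarize")
    n_dae = sum(1 for c in calls if c.is_dae)
    by_dir: dict[str, int] = {}
    for c in calls:
        if c.is_dae and c.direction is not None:
            by_dir[c.direction] = by_dir.get(c.direction, 0) + 1
    return DaeSummary(
        n_tested=len(calls),
        n_dae=n_dae,
        n_by_direction=by_dir,
        fraction_dae=n_dae / len(calls),
    )
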