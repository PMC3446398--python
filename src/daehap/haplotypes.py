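"""Tag-SNP haplotype patterns, diplotype assignment, LD and EM phasing.

The built-in pattern table describes five common BRCA2 haplotypes over seven
tag SNPs.  Haplotype 1 is tagged by the G allele of the transcribed marker
rs144848, so every sample heterozygous G/T at the marker carries haplotype 1
and its second haplotype can be recovered by subtracting the anchored
pattern from the unphased genotypes.  Haplotypes 2 and 5 are associated with
lower expression of the gene, haplotypes 1, 3 and 4 with higher expression.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AmbiguousHaplotypeError,
    ConfigError,
    DataError,
    UnresolvableHaplotypeError,
)

log = logging.getLogger(__name__)

#: The seven tag SNPs, in pattern order.  rs144848 is the transcribed marker.
TAG_SNPS: tuple[str, ...] = (
    "rs1799943",
    "rs11571579",
    "rs9534174",
    "rs206070",
    "rs144848",
    "rs4942440",
    "rs9567576",
)

MARKER_SNP = "rs144848"

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class HaplotypePattern:
    """An ordered allele vector over the tag SNPs with an expression class."""

    label: str
    alleles: Mapping[str, str]
    expression_class: str

    def __post_init__(self) -> None:
        if self.expression_class not in (HIGH, LOW):
            raise ConfigError(
                f"expression_class must be 'high' or 'low', got {self.expression_class!r}"
            )

    def allele_vector(self, snps: Sequence[str]) -> tuple[str, ...]:
        return tuple(self.alleles[s] for s in snps)


def _pattern(label: str, vector: str, cls: str) -> HaplotypePattern:
    return HaplotypePattern(label, dict(zip(TAG_SNPS, vector.split())), cls)


#: Five common haplotypes: allele vectors over TAG_SNPS and expression class.
BUILTIN_PATTERNS: tuple[HaplotypePattern, ...] = (
    _pattern("hap1", "G T A C G G T", HIGH),
    _pattern("hap2", "A C G C T G G", LOW),
    _pattern("hap3", "G T A T T G T", HIGH),
    _pattern("hap4", "G T G C T A T", HIGH),
    _pattern("hap5", "G C G C T G G", LOW),
)

#: Population frequencies (%) of the built-in haplotypes (HapMap CEU).  They
#: sum to 87.2%; the remainder is rarer haplotypes not modelled here.
BUILTIN_FREQ_PERCENT: dict[str, float] = {
    "hap1": 27.5,
    "hap2": 24.2,
    "hap3": 18.8,
    "hap4": 11.7,
    "hap5": 5.0,
}


def builtin_frequencies() -> dict[str, float]:
    """Built-in haplotype frequencies renormalized to sum to 1."""
    total = sum(BUILTIN_FREQ_PERCENT.values())
    return {k: v / total for k, v in BUILTIN_FREQ_PERCENT.items()}


def patterns_by_label(
    patterns: Iterable[HaplotypePattern] = BUILTIN_PATTERNS,
) -> dict[str, HaplotypePattern]:
    return {p.label: p for p in patterns}


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of haplotype labels with the derived expression group.

    ``group`` counts low-expression haplotypes: 0 -> "HH", 1 -> "HL", 2 -> "LL".
    """

    labels: tuple[str, str]
    group: str = field(init=False)
    _classes: tuple[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        a, b = sorted(self.labels)
        object.__setattr__(self, "labels", (a, b))
        n_low = sum(1 for c in self._classes if c == LOW)
        object.__setattr__(self, "group", {0: "HH", 1: "HL", 2: "LL"}[n_low])


def make_diplotype(
    label_a: str,
    label_b: str,
    patterns: Iterable[HaplotypePattern] = BUILTIN_PATTERNS,
) -> Diplotype:
    by_label = patterns_by_label(patterns)
    classes = (by_label[label_a].expression_class, by_label[label_b].expression_class)
    return Diplotype(labels=(label_a, label_b), _classes=classes)


def classify_group(diplotype: Diplotype) -> str:
    """Expression group of a diplotype: HH, HL or LL."""
    return diplotype.group


def assign_second_haplotype(
    genotypes: Mapping[str, tuple[str, str]],
    anchored: str = "hap1",
    patterns: Iterable[HaplotypePattern] = BUILTIN_PATTERNS,
) -> Diplotype:
    """Resolve the diplotype of a sample anchored on a known haplotype.

    The anchored pattern's allele is subtracted from each unphased genotype;
    the residual allele vector is matched against the pattern table.  The
    sample must actually carry the anchored haplotype at every SNP.

    Raises
    ------
    UnresolvableHaplotypeError
        If the residual vector matches no pattern (or the anchored pattern is
        incompatible with the genotypes).
    AmbiguousHaplotypeError
        If the residual matches more than one pattern.
    """
    by_label = patterns_by_label(patterns)
    if anchored not in by_label:
        raise ConfigError(f"unknown anchored haplotype {anchored!r}")
    anchor = by_label[anchored]

    snps = [s for s in TAG_SNPS if s in genotypes]
    if not snps:
        raise DataError("no tag-SNP genotypes supplied")
    residual: dict[str, str] = {}
    for snp in snps:
        pair = tuple(genotypes[snp])
        if len(pair) != 2:
            raise DataError(f"genotype at {snp} is not a diploid pair: {pair!r}")
        a = anchor.alleles[snp]
        if a not in pair:
            raise UnresolvableHaplotypeError(
                f"sample lacks anchored allele {a} of {anchored} at {snp}"
            )
        rest = list(pair)
        rest.remove(a)
        residual[snp] = rest[0]

    matches = [
        p
        for p in by_label.values()
        if all(p.alleles[s] == residual[s] for s in snps)
    ]
    if not matches:
        raise UnresolvableHaplotypeError(
            "residual alleles "
            + "/".join(residual[s] for s in snps)
            + " match no known haplotype pattern"
        )
    if len(matches) > 1:
        raise AmbiguousHaplotypeError([p.label for p in matches])
    return make_diplotype(anchored, matches[0].label, patterns)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


@dataclass(frozen=True)
class LdResult:
    D: float
    Dprime: float
    r2: float
    defined: bool


def pairwise_ld(haplotypes: Sequence[tuple[str, str]]) -> LdResult:
    """Pairwise LD (D, D', r^2) from phased two-locus haplotypes.

    A monomorphic locus makes D'/r^2 undefined; the result is returned with
    ``defined=False`` and NaN statistics rather than raising.
    """
    if len(haplotypes) == 0:
        raise DataError("no haplotypes supplied")
    locus1 = sorted({h[0] for h in haplotypes})
    locus2 = sorted({h[1] for h in haplotypes})
    if len(locus1) > 2 or len(locus2) > 2:
        raise DataError("more than two alleles at a locus")
    if len(locus1) < 2 or len(locus2) < 2:
        return LdResult(float("nan"), float("nan"), float("nan"), False)

    n = len(haplotypes)
    A, B = locus1[0], locus2[0]
    p_a = sum(1 for h in haplotypes if h[0] == A) / n
    p_b = sum(1 for h in haplotypes if h[1] == B) / n
    p_ab = sum(1 for h in haplotypes if h == (A, B)) / n
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d == 0 else abs(d) / d_max
    return LdResult(d, dprime, r2, True)


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation


def _compatible_pairs(
    genotype: Sequence[tuple[str, str]]
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All phase resolutions (unordered haplotype pairs) of one genotype."""
    het_sites = [i for i, (a, b) in enumerate(genotype) if a != b]
    base_a = [min(p) for p in genotype]
    base_b = [max(p) for p in genotype]
    if not het_sites:
        h = tuple(base_a)
        return [(h, h)]
    # fix the phase at the first het site to avoid double-counting mirror pairs
    pairs = []
    for flips in itertools.product([False, True], repeat=len(het_sites) - 1):
        h1 = list(base_a)
        h2 = list(base_b)
        for site, flip in zip(het_sites[1:], flips):
            if flip:
                h1[site], h2[site] = h2[site], h1[site]
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


@dataclass
class EmResult:
    frequencies: dict[tuple[str, ...], float]
    posteriors: list[list[tuple[tuple[str, ...], tuple[str, ...], float]]]
    log_likelihood: float
    n_iter: int
    converged: bool


def em_haplotype_frequencies(
    genotypes: Sequence[Sequence[tuple[str, str]]],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EmResult:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Each genotype is a sequence of (allele, allele) pairs over the same SNPs.
    Haplotype space is the union of resolutions compatible with at least one
    sample; initial frequencies are uniform on that space.  The observed-data
    log-likelihood is monotone non-decreasing over iterations; convergence is
    declared when the largest frequency change drops below ``tol``.
    """
    if len(genotypes) == 0:
        raise DataError("no genotypes supplied")
    sample_pairs = [_compatible_pairs(g) for g in genotypes]
    hap_space = sorted({h for pairs in sample_pairs for pair in pairs for h in pair})
    idx = {h: i for i, h in enumerate(hap_space)}
    k = len(hap_space)
    freqs = np.full(k, 1.0 / k)

    # precompute index pairs per sample
    pair_idx = [
        [(idx[h1], idx[h2]) for h1, h2 in pairs] for pairs in sample_pairs
    ]

    loglik = -math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(k)
        loglik = 0.0
        for pairs in pair_idx:
            probs = np.array(
                [
                    (2.0 if i != j else 1.0) * freqs[i] * freqs[j]
                    for i, j in pairs
                ]
            )
            total = probs.sum()
            if total <= 0:
                # degenerate start; spread mass uniformly over the pairs
                probs = np.full(len(pairs), 1.0 / len(pairs))
                total = 1.0
                loglik += -math.inf
            else:
                probs = probs / total
                loglik += math.log(total)
            for (i, j), w in zip(pairs, probs):
                expected[i] += w
                expected[j] += w
        new_freqs = expected / (2.0 * len(genotypes))
        delta = float(np.abs(new_freqs - freqs).max())
        freqs = new_freqs
        if delta < tol:
            converged = True
            break

    posteriors: list[list[tuple[tuple[str, ...], tuple[str, ...], float]]] = []
    final_loglik = 0.0
    for pairs, ipairs in zip(sample_pairs, pair_idx):
        probs = np.array(
            [(2.0 if i != j else 1.0) * freqs[i] * freqs[j] for i, j in ipairs]
        )
        total = probs.sum()
        if total > 0:
            final_loglik += math.log(total)
            probs = probs / total
        else:
            probs = np.full(len(pairs), 1.0 / len(pairs))
        posteriors.append(
            [(h1, h2, float(w)) for (h1, h2), w in zip(pairs, probs)]
        )

    return EmResult(
        frequencies={h: float(freqs[idx[h]]) for h in hap_space},
        posteriors=posteriors,
        log_likelihood=final_loglik,
        n_iter=it,
        converged=converged,
    )
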