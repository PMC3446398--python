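"""PWM scanning with matrix/core similarity and allele-differential screening.

A position weight matrix is scored against every placement (offset and
strand) of a sequence window.  With f(i,b) the base frequencies and
I(i) = sum_b f(i,b) * ln(4 f(i,b)) the per-position information content,

    Current = sum_i I(i) * f(i, base_i)
    mss     = (Current - Min) / (Max - Min)

where Min/Max replace f(i, base_i) by the per-position worst/best base.  The
core similarity score (css) is the same quantity restricted to the matrix
core — the five consecutive positions with maximal total information.  Both
scores lie in [0, 1]; a consensus window scores 1.

Candidate cis-regulatory SNPs are screened with four criteria applied in
order: (1) the SNP lies inside an annotated regulatory element; (2) some
matrix matches the surrounding sequence above the similarity cutoffs;
(3) the matched site overlaps the SNP position; (4) the two alleles differ
in predicted binding (presence/absence at the cutoffs, or a score shift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.01  # per matrix row, spread evenly over the 4 bases
CORE_LENGTH = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Expects regularized frequencies (no zeros); a uniform row gives 0, a
    degenerate row approaches ln 4.
    """
    f = np.asarray(freqs, dtype=float)
    return np.sum(f * np.log(4.0 * f), axis=1)


def _core_start(info: np.ndarray) -> int:
    """Leftmost start of the CORE_LENGTH consecutive positions maximizing sum(I)."""
    L = len(info)
    width = min(CORE_LENGTH, L)
    sums = [info[i : i + width].sum() for i in range(L - width + 1)]
    return int(np.argmax(sums))  # argmax returns the first (leftmost) maximum


@dataclass(frozen=True)
class Pwm:
    """A nucleotide frequency matrix with its information vector and core.

    ``freqs`` has one row per motif position, columns ordered A, C, G, T,
    each row summing to 1 after pseudocount regularization.
    """

    name: str
    factor: str
    freqs: np.ndarray
    info: np.ndarray = field(init=False, repr=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise DataError(f"matrix {self.name}: expected Lx4 frequencies")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise DataError(f"matrix {self.name}: rows do not sum to 1")
        if (f <= 0).any():
            raise DataError(
                f"matrix {self.name}: zero frequencies; apply a pseudocount"
            )
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "info", information_vector(f))
        object.__setattr__(self, "core_start", _core_start(self.info))

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + min(CORE_LENGTH, len(self)))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    factor: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Pwm:
    """Build a Pwm from a count (or frequency) matrix with regularization.

    The pseudocount is spread evenly over the four bases of each row before
    normalization, so scores are invariant to scaling all counts by a
    constant only in the zero-pseudocount limit; with the small default the
    deviation is negligible for realistic counts.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise DataError(f"matrix {name}: expected Lx4 counts")
    if (c < 0).any():
        raise DataError(f"matrix {name}: negative counts")
    row_sums = c.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise DataError(f"matrix {name}: empty count row")
    # normalize first so the pseudocount strength is scale-free
    f = c / row_sums
    f = (f + pseudocount / 4.0) / (1.0 + pseudocount)
    return Pwm(name=name, factor=factor, freqs=f)


@dataclass(frozen=True)
class MatchResult:
    mss: float
    css: float
    offset: int
    strand: str
    length: int

    @property
    def span(self) -> range:
        """Window positions covered by the matched site (0-based)."""
        return range(self.offset, self.offset + self.length)


def _score_placement(pwm: Pwm, window: str, positions: Iterable[int]) -> float:
    """(Current-Min)/(Max-Min) over the given matrix positions."""
    info = pwm.info
    f = pwm.freqs
    current = 0.0
    min_s = 0.0
    max_s = 0.0
    for i in positions:
        w = info[i]
        row = f[i]
        base = window[i]
        j = _BASE_INDEX.get(base)
        if j is None:
            contrib = row.min()  # non-ACGT base contributes the worst value
        else:
            contrib = row[j]
        current += w * contrib
        min_s += w * row.min()
        max_s += w * row.max()
    if max_s == min_s:
        return 1.0  # uninformative matrix: every window is a perfect match
    return (current - min_s) / (max_s - min_s)


def match_similarity(
    seq: str,
    pwm: Pwm,
    must_cover: Optional[int] = None,
) -> MatchResult:
    """Best matrix-similarity placement of ``pwm`` over ``seq`` (both strands).

    Returns the placement maximizing mss; ties break toward the smaller
    offset, then the forward strand.  With ``must_cover`` set (0-based
    position in ``seq``), only placements whose span covers that position
    are considered.

    Raises ``ValueError`` when the window is shorter than the matrix, or no
    placement covers the required position.
    """
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(
            f"window of length {len(seq)} shorter than matrix {pwm.name} ({L})"
        )
    seq = seq.upper()
    if any(b not in "ACGTN" for b in seq):
        bad = sorted({b for b in seq if b not in "ACGTN"})
        raise DataError(f"sequence contains non-nucleotide characters: {bad}")
    if "N" in seq:
        log.warning("sequence contains N bases; they score as the worst base")
    best: Optional[MatchResult] = None
    all_pos = range(L)
    for offset in range(len(seq) - L + 1):
        if must_cover is not None and not (offset <= must_cover < offset + L):
            continue
        window_fwd = seq[offset : offset + L]
        for strand, window in (("+", window_fwd), ("-", reverse_complement(window_fwd))):
            mss = _score_placement(pwm, window, all_pos)
            if best is None or mss > best.mss:
                css = _score_placement(pwm, window, pwm.core_positions)
                best = MatchResult(mss, css, offset, strand, L)
    if best is None:
        raise ValueError(
            f"no placement of matrix {pwm.name} covers position {must_cover}"
        )
    return best


# ---------------------------------------------------------------------------
# SNP-centred windows and allele-differential screening


@dataclass(frozen=True)
class SnpContext:
    """A SNP with its surrounding sequence window and the two alleles.

    ``sequence`` carries the reference-allele window; ``offset`` is the
    0-based index of the SNP base within it.  ``position`` is the 1-based
    genomic coordinate used against BED intervals (which are 0-based
    half-open).
    """

    snp_id: str
    sequence: str
    offset: int
    allele_a: str
    allele_b: str
    chrom: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not (0 <= self.offset < len(seq)):
            raise DataError(
                f"{self.snp_id}: SNP offset {self.offset} outside window"
            )
        if self.allele_a == self.allele_b:
            raise DataError(f"{self.snp_id}: alleles must differ")
        if any(b not in "ACGTN" for b in seq):
            raise DataError(f"{self.snp_id}: window has non-nucleotide characters")
        object.__setattr__(self, "sequence", seq)

    def window_for(self, allele: str) -> str:
        return (
            self.sequence[: self.offset] + allele + self.sequence[self.offset + 1 :]
        )


@dataclass(frozen=True)
class DifferentialHit:
    snp_id: str
    pwm_name: str
    factor: str
    score_a: MatchResult
    score_b: MatchResult
    passes_a: bool
    passes_b: bool
    kind: str  # "presence_absence" or "score_shift"


def allele_differential_hits(
    ctx: SnpContext,
    pwm_library: Sequence[Pwm],
    min_core: float = 0.9,
    min_mss: float = 0.9,
    delta: float = 0.0,
) -> list[DifferentialHit]:
    """Matrices predicted to bind the two alleles differently.

    For each matrix both allele windows are scanned, restricted to
    placements overlapping the SNP.  A hit requires (a) at least one allele
    passing both similarity cutoffs, and (b) a difference between alleles:
    either discordant pass/fail status, or an mss difference exceeding
    ``delta`` (the default 0.0 counts any nonzero difference).
    """
    if len(pwm_library) == 0:
        raise ValueError("empty matrix library")
    if not (0 <= min_core <= 1 and 0 <= min_mss <= 1):
        raise ConfigError("similarity cutoffs must lie in [0, 1]")
    hits = []
    for pwm in pwm_library:
        if len(pwm) > len(ctx.sequence):
            continue
        res_a = match_similarity(ctx.window_for(ctx.allele_a), pwm, must_cover=ctx.offset)
        res_b = match_similarity(ctx.window_for(ctx.allele_b), pwm, must_cover=ctx.offset)
        pass_a = res_a.mss >= min_mss and res_a.css >= min_core
        pass_b = res_b.mss >= min_mss and res_b.css >= min_core
        if not (pass_a or pass_b):
            continue
        if pass_a != pass_b:
            kind = "presence_absence"
        elif abs(res_a.mss - res_b.mss) > delta:
            kind = "score_shift"
        else:
            continue
        hits.append(
            DifferentialHit(
                ctx.snp_id, pwm.name, pwm.factor, res_a, res_b, pass_a, pass_b, kind
            )
        )
    return hits


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def contains(self, chrom: str, position_1based: int) -> bool:
        return self.chrom == chrom and self.start <= position_1based - 1 < self.end


@dataclass(frozen=True)
class CandidateReport:
    snp_id: str
    passed: bool
    eliminated_at: Optional[int]  # 1..4, None if passed
    hits: tuple[DifferentialHit, ...]


def candidate_filter(
    contexts: Sequence[SnpContext],
    regulatory: Sequence[BedInterval],
    pwm_library: Sequence[Pwm],
    min_core: float = 0.9,
    min_mss: float = 0.9,
    delta: float = 0.0,
) -> list[CandidateReport]:
    """Apply the four candidate-selection criteria in order to each SNP.

    1. inside a regulatory element (BED, 0-based half-open);
    2. some matrix passes both cutoffs somewhere in either allele window;
    3. a passing match overlaps the SNP position;
    4. the alleles differ in predicted binding.

    SNPs failing criterion 1 are never scored.  The report records the first
    criterion that eliminated each SNP.
    """
    reports = []
    for ctx in contexts:
        if not any(iv.contains(ctx.chrom, ctx.position) for iv in regulatory):
            reports.append(CandidateReport(ctx.snp_id, False, 1, ()))
            continue
        hits = allele_differential_hits(
            ctx, pwm_library, min_core=min_core, min_mss=min_mss, delta=delta
        )
        if hits:
            reports.append(CandidateReport(ctx.snp_id, True, None, tuple(hits)))
            continue
        # attribute the failure: unrestricted pass anywhere? overlapping pass?
        criterion = 2
        for pwm in pwm_library:
            if len(pwm) > len(ctx.sequence):
                continue
            for allele in (ctx.allele_a, ctx.allele_b):
                res = match_similarity(ctx.window_for(allele), pwm)
                if res.mss >= min_mss and res.css >= min_core:
                    criterion = 3
                    res_cov = match_similarity(
                        ctx.window_for(allele), pwm, must_cover=ctx.offset
                    )
                    if res_cov.mss >= min_mss and res_cov.css >= min_core:
                        criterion = 4
                        break
            if criterion == 4:
                break
        reports.append(CandidateReport(ctx.snp_id, False, criterion, ()))
    return reports
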