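"""Deterministic planted-truth fixtures for the TFBS screen and demos.

Builds a small screen with known ground truth: 26 SNP windows of which
exactly 4 are genuine allele-differential binding-site candidates, the rest
planted to fail at a specific selection criterion.  Everything is
constructed from fixed sequences and toy matrices (labelled synthetic), so
the expected outcome is known by construction, not by running the filter.
"""

from __future__ import annotations

import numpy as np

from .tfbs import BedInterval, Pwm, SnpContext, pwm_from_counts

CHROM = "chr13"
WINDOW = 41
SNP_OFFSET = 20  # 0-based SNP position inside each window

#: Filler sequence free of any toy-motif 9-mer on either strand.
_FILLER = "TTGATCAAC" * 6

_M1_CONSENSUS = "GGGGCGGGG"  # sharp motif; SNP position 4 is the consensus C
_M2_CONSENSUS = "TTTACGTTT"  # position 4 split evenly between C and G
_M3_CONSENSUS = "ACACACACA"  # library padding, never planted near a SNP


def _sharp_counts(consensus: str) -> np.ndarray:
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 97.0
    return counts


def toy_pwm_library() -> list[Pwm]:
    """Three synthetic matrices: two sharp motifs and one split-position motif."""
    m1 = pwm_from_counts("M00001", _sharp_counts(_M1_CONSENSUS), factor="DBF1")
    m3 = pwm_from_counts("M00003", _sharp_counts(_M3_CONSENSUS), factor="DBF3")
    c2 = _sharp_counts(_M2_CONSENSUS)
    c2[4] = [1.0, 49.0, 49.0, 1.0]  # C/G equally preferred at the SNP position
    m2 = pwm_from_counts("M00002", c2, factor="DBF2")
    return [m1, m2, m3]


def _window(insert: str = "", at: int = -1) -> str:
    seq = list(_FILLER[:WINDOW])
    if insert:
        for i, b in enumerate(insert):
            seq[at + i] = b
    return "".join(seq)


def planted_tfbs_screen(
    n_outside: int = 8,
    n_no_motif: int = 6,
    n_off_snp: int = 4,
    n_no_diff: int = 4,
    n_true: int = 4,
) -> tuple[list[SnpContext], list[BedInterval], list[Pwm], dict[str, int | None]]:
    """A planted candidate screen: contexts, intervals, library, ground truth.

    Returns ``expected`` mapping snp_id -> eliminating criterion (1-4) or
    None for the planted true candidates.  Defaults give 26 SNPs with 4
    survivors.
    """
    contexts: list[SnpContext] = []
    expected: dict[str, int | None] = {}
    bed: list[BedInterval] = []
    idx = 0

    def add(seq: str, allele_a: str, allele_b: str, in_bed: bool, truth: int | None):
        nonlocal idx
        idx += 1
        snp_id = f"snp{idx:02d}"
        pos = 32_890_000 + idx * 100  # 1-based genomic coordinate
        contexts.append(
            SnpContext(
                snp_id=snp_id, sequence=seq, offset=SNP_OFFSET,
                allele_a=allele_a, allele_b=allele_b, chrom=CHROM, position=pos,
            )
        )
        if in_bed:
            bed.append(BedInterval(CHROM, pos - 1 - 10, pos - 1 + 11))
        expected[snp_id] = truth

    # criterion 1: outside every regulatory interval, never scored
    for _ in range(n_outside):
        add(_window(), "A", "T", in_bed=False, truth=1)
    # criterion 2: inside an interval but no matrix matches anywhere
    for _ in range(n_no_motif):
        add(_window(), "A", "T", in_bed=True, truth=2)
    # criterion 3: a strong site exists but does not overlap the SNP
    for _ in range(n_off_snp):
        add(_window(_M1_CONSENSUS, at=0), "A", "T", in_bed=True, truth=3)
    # criterion 4: site overlaps the SNP but both alleles bind identically
    for _ in range(n_no_diff):
        seq = _window(_M2_CONSENSUS, at=SNP_OFFSET - 4)
        add(seq, "C", "G", in_bed=True, truth=4)
    # true candidates: consensus allele binds, the other breaks the site
    for _ in range(n_true):
        seq = _window(_M1_CONSENSUS, at=SNP_OFFSET - 4)
        add(seq, "C", "T", in_bed=True, truth=None)

    return contexts, bed, toy_pwm_library(), expected
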