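"""Haplotype patterns, diplotype resolution, LD and EM phasing."""

import itertools
import math

import numpy as np
import pytest

from daehap.errors import (
    AmbiguousHaplotypeError,
    DataError,
    UnresolvableHaplotypeError,
)
from daehap.haplotypes import (
    BUILTIN_PATTERNS,
    TAG_SNPS,
    assign_second_haplotype,
    builtin_frequencies,
    classify_group,
    em_haplotype_frequencies,
    make_diplotype,
    pairwise_ld,
    patterns_by_label,
)
from daehap.simulate import SimConfig, gen_diplotypes


def _union_genotypes(label_a, label_b):
    by = patterns_by_label()
    return {
        snp: tuple(sorted((by[label_a].alleles[snp], by[label_b].alleles[snp])))
        for snp in TAG_SNPS
    }


def test_builtin_patterns_are_distinct_and_marker_tags_hap1():
    vectors = {p.allele_vector(TAG_SNPS) for p in BUILTIN_PATTERNS}
    assert len(vectors) == 5
    by = patterns_by_label()
    assert by["hap1"].alleles["rs144848"] == "G"
    assert all(by[h].alleles["rs144848"] == "T" for h in ("hap2", "hap3", "hap4", "hap5"))
    assert {h for h, p in by.items() if p.expression_class == "low"} == {"hap2", "hap5"}


@pytest.mark.parametrize("second", ["hap1", "hap2", "hap3", "hap4", "hap5"])
def test_second_haplotype_round_trip(second):
    dip = assign_second_haplotype(_union_genotypes("hap1", second))
    assert set(dip.labels) == {"hap1", second}


def test_hap1_hap2_pair_is_hl():
    dip = assign_second_haplotype(_union_genotypes("hap1", "hap2"))
    assert dip.labels == ("hap1", "hap2") and dip.group == "HL"


def test_unresolvable_residual_raises():
    genotypes = _union_genotypes("hap1", "hap2")
    genotypes["rs206070"] = ("C", "G")  # G at rs206070 exists in no pattern
    with pytest.raises(UnresolvableHaplotypeError):
        assign_second_haplotype(genotypes)


def test_ambiguous_residual_lists_candidates():
    # restrict to a SNP subset on which hap2 and hap5 are indistinguishable
    shared = [s for s in TAG_SNPS if s not in ("rs1799943", "rs11571579")]
    genotypes = {s: _union_genotypes("hap1", "hap2")[s] for s in shared}
    with pytest.raises(AmbiguousHaplotypeError) as err:
        assign_second_haplotype(genotypes)
    assert set(err.value.candidates) == {"hap2", "hap5"}


def test_missing_anchor_allele_is_unresolvable():
    with pytest.raises(UnresolvableHaplotypeError, match="lacks anchored allele"):
        assign_second_haplotype(_union_genotypes("hap2", "hap2"))


@pytest.mark.parametrize(
    "pair, group",
    [
        (("hap1", "hap3"), "HH"),
        (("hap2", "hap5"), "LL"),
        (("hap4", "hap5"), "HL"),
        (("hap1", "hap1"), "HH"),
    ],
)
def test_classify_group(pair, group):
    assert classify_group(make_diplotype(*pair)) == group


def test_generator_round_trip_recovers_diplotypes(cfg):
    """Assignment inverts the generator for every marker-heterozygous sample."""
    for d in gen_diplotypes(cfg):
        alleles = {d.genotypes["rs144848"]}
        if alleles != {("G", "T")}:
            continue
        dip = assign_second_haplotype(d.genotypes)
        assert set(dip.labels) == set(d.hap_pair)
        assert dip.group == d.diplotype.group


# ---------------------------------------------------------------------------
# LD


def test_perfect_coupling():
    res = pairwise_ld([("A", "B")] * 30 + [("a", "b")] * 70)
    assert res.r2 == pytest.approx(1.0) and res.Dprime == pytest.approx(1.0)


def test_equilibrium_independence():
    haps = [
        (x, y)
        for x, nx in (("A", 2), ("a", 3))
        for y, ny in (("B", 1), ("b", 4))
        for _ in range(nx * ny)
    ]
    assert pairwise_ld(haps).r2 == pytest.approx(0.0, abs=1e-12)


def test_monomorphic_locus_flagged_not_crashed():
    res = pairwise_ld([("A", "B"), ("A", "b")])
    assert not res.defined and math.isnan(res.r2)


def test_three_alleles_rejected():
    with pytest.raises(DataError):
        pairwise_ld([("A", "B"), ("C", "B"), ("G", "B")])


def test_r2_55_table_matches_direct_formula():
    """A 100-haplotype table found by integer brute force gives r2 = 0.55 (2 d.p.)."""
    n_ab, n_aB, n_Ab, n_AB = 13, 49, 37, 1  # counts for (a,b),(a,B),(A,b),(A,B)
    haps = (
        [("A", "B")] * n_AB + [("A", "b")] * n_Ab
        + [("a", "B")] * n_aB + [("a", "b")] * n_ab
    )
    res = pairwise_ld(haps)
    p_a, p_b, p_ab = 0.38, 0.50, 0.01
    d = p_ab - p_a * p_b
    assert res.D == pytest.approx(d)
    assert res.r2 == pytest.approx(d * d / (p_a * 0.62 * p_b * 0.50))
    assert round(res.r2, 2) == 0.55


def test_ld_invariant_under_allele_relabelling():
    rng = np.random.default_rng(4)
    haps = [
        ("A" if rng.random() < 0.6 else "a", "B" if rng.random() < 0.3 else "b")
        for _ in range(200)
    ]
    base = pairwise_ld(haps)
    relabel = {"A": "a", "a": "A"}
    flipped = pairwise_ld([(relabel[x], y) for x, y in haps])
    assert flipped.r2 == pytest.approx(base.r2)
    assert flipped.Dprime == pytest.approx(base.Dprime)
    assert flipped.D == pytest.approx(-base.D)


# ---------------------------------------------------------------------------
# EM phasing


def test_phase_unambiguous_em_equals_counting():
    genotypes = [
        [("A", "C"), ("G", "G")],  # single het site: phase known
        [("A", "A"), ("G", "G")],
        [("C", "C"), ("G", "G")],
    ]
    res = em_haplotype_frequencies(genotypes)
    assert res.frequencies == pytest.approx(
        {("A", "G"): 3 / 6, ("C", "G"): 3 / 6}
    )


def test_double_heterozygote_symmetric_posterior():
    res = em_haplotype_frequencies([[("A", "T"), ("C", "G")]])
    assert len(res.posteriors[0]) == 2
    for _, _, w in res.posteriors[0]:
        assert w == pytest.approx(0.5)


def _grid_loglik(genotypes, hap_space, freqs):
    from daehap.haplotypes import _compatible_pairs

    ll = 0.0
    f = dict(zip(hap_space, freqs))
    for g in genotypes:
        p = sum(
            (2.0 if h1 != h2 else 1.0) * f[h1] * f[h2]
            for h1, h2 in _compatible_pairs(g)
        )
        ll += math.log(p) if p > 0 else -math.inf
    return ll


def test_em_loglik_matches_grid_search_oracle():
    """EM attains (at least) the best log-likelihood on a coarse simplex grid."""
    genotypes = (
        [[("A", "T"), ("C", "G")]] * 3
        + [[("A", "A"), ("C", "G")]] * 4
        + [[("A", "T"), ("C", "C")]] * 2
        + [[("A", "A"), ("C", "C")]] * 5
    )
    res = em_haplotype_frequencies(genotypes)
    hap_space = sorted(res.frequencies)
    k = len(hap_space)
    step = 20  # grid resolution 1/20
    grid_best = -math.inf
    for combo in itertools.product(range(step + 1), repeat=k - 1):
        if sum(combo) > step:
            continue
        freqs = [c / step for c in combo] + [(step - sum(combo)) / step]
        grid_best = max(grid_best, _grid_loglik(genotypes, hap_space, freqs))
    assert res.log_likelihood >= grid_best - 1e-6  # EM's own stopping slack
    assert res.log_likelihood - grid_best < 0.2  # coarse-grid gap only


def test_em_recovers_simulated_frequencies():
    cfg = SimConfig(n_samples=200, seed=21)
    dips = gen_diplotypes(cfg)
    genotypes = [[d.genotypes[s] for s in TAG_SNPS] for d in dips]
    res = em_haplotype_frequencies(genotypes)
    by = patterns_by_label()
    truth = builtin_frequencies()
    for hap, p in truth.items():
        vec = by[hap].allele_vector(TAG_SNPS)
        se = math.sqrt(p * (1 - p) / (2 * len(dips)))
        assert abs(res.frequencies.get(vec, 0.0) - p) < 3 * se


def test_em_loglik_monotone_over_iterations():
    rng = np.random.default_rng(9)
    genotypes = [
        [tuple(sorted(rng.choice(["A", "G"], 2))) for _ in range(4)]
        for _ in range(30)
    ]
    lls = []
    for it in range(1, 12):
        lls.append(
            em_haplotype_frequencies(genotypes, tol=0.0, max_iter=it).log_likelihood
        )
    assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))
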