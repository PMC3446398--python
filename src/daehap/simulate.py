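"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: five haplotypes drawn
at their population frequencies under random mating; haplotype-dependent
allelic transcription levels measured as replicate cDNA/gDNA peak ratios
with multiplicative log-normal noise; diplotype-group-dependent downstream
gene expression; and a multi-study carrier cohort with a planted per-allele
log-hazard under Hardy-Weinberg genotypes, exponential event times and
independent exponential censoring.

All randomness flows from a single master seed through per-generator
substreams (numpy SeedSequence spawning), so each generator is reproducible
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allelic import AllelicMeasurement
from .errors import ConfigError
from .expression import CT_MODE, LOG_INTENSITY_MODE, ExpressionTable
from .haplotypes import (
    MARKER_SNP,
    TAG_SNPS,
    Diplotype,
    builtin_frequencies,
    make_diplotype,
    patterns_by_label,
)
from .risk import CarrierRecord

#: Relative transcription rate of each haplotype.  Low-expression haplotypes
#: (hap2, hap5) transcribe at 70% of the high-expression rate, giving a true
#: allelic ratio of 1/0.7 ~ 1.43 in marker heterozygotes carrying one of
#: them — comfortably past the 1.2-fold DAE threshold.
DEFAULT_EXPR_LEVELS: dict[str, float] = {
    "hap1": 1.0,
    "hap2": 0.7,
    "hap3": 1.0,
    "hap4": 1.0,
    "hap5": 0.7,
}

#: Per-gene (effect per low-expression haplotype carried, residual SD) on the
#: log2 expression scale.  SPP1's effect matches a 1.74-fold drop per low
#: haplotype (log2 1.74 ~ 0.80); MUC16 rises by 0.125 per low haplotype.
DEFAULT_GENE_EFFECTS: dict[str, tuple[float, float]] = {
    "SPP1": (-0.80, 0.5),
    "MUC16": (0.125, 0.05),
    "PAX8": (-0.20, 0.2),
    "IGFBP5": (0.15, 0.2),
    "BIRC5": (0.0, 0.3),
    "RRM2": (0.0, 0.3),
}

#: Housekeeping genes (zero diplotype effect) and their residual Ct SDs.
DEFAULT_HOUSEKEEPING_SDS: dict[str, float] = {
    "ACTB": 0.05,
    "HPRT1": 0.05,
    "RN18S": 0.5,
    "GAPDH": 0.5,
}


@dataclass
class CarrierSimConfig:
    """Carrier-cohort generator settings.

    Defaults emulate the genotyped carrier cohort: 2,754 carriers across 11
    studies, a protective per-allele log-hazard of ln 0.85 at minor-allele
    frequency 0.16, and exponential censoring scaled so roughly 59% of
    carriers are affected.
    """

    n: int = 2754
    log_hr: float = math.log(0.85)
    maf: float = 0.16
    baseline_hazard: float = 0.02
    censoring_scale: float = 70.0
    n_studies: int = 11

    def validate(self) -> None:
        if not 0 < self.maf < 1:
            raise ConfigError(f"minor-allele frequency must be in (0,1), got {self.maf}")
        if self.n < 1 or self.n_studies < 1:
            raise ConfigError("carrier n and n_studies must be >= 1")
        if self.baseline_hazard <= 0 or self.censoring_scale < 0:
            raise ConfigError("hazard must be > 0 and censoring scale >= 0")


@dataclass
class SimConfig:
    n_samples: int = 100
    hap_freqs: dict[str, float] = field(default_factory=builtin_frequencies)
    hap_expr_level: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPR_LEVELS)
    )
    meas_cv: float = 0.10
    n_reps: int = 3
    gene_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_EFFECTS)
    )
    housekeeping_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOUSEKEEPING_SDS)
    )
    carrier: CarrierSimConfig = field(default_factory=CarrierSimConfig)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.hap_freqs.values()):
            raise ConfigError("haplotype frequencies must be non-negative")
        known = set(patterns_by_label())
        unknown = set(self.hap_freqs) - known
        if unknown:
            raise ConfigError(f"unknown haplotype labels: {sorted(unknown)}")
        for h in self.hap_freqs:
            if h not in self.hap_expr_level or not self.hap_expr_level[h] > 0:
                raise ConfigError(f"haplotype {h} needs a positive expression level")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if self.meas_cv < 0:
            raise ConfigError("meas_cv must be >= 0")
        overlap = set(self.gene_effects) & set(self.housekeeping_sds)
        if overlap:
            raise ConfigError(
                f"genes cannot be both target and housekeeping: {sorted(overlap)}"
            )
        self.carrier.validate()

    def substream(self, index: int) -> np.random.Generator:
        """Per-generator RNG substream spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return np.random.default_rng(children[index])


@dataclass(frozen=True)
class SampleDiplotype:
    sample_id: str
    hap_pair: tuple[str, str]  # ordered as drawn
    diplotype: Diplotype
    genotypes: dict[str, tuple[str, str]]  # unphased, alleles sorted


def gen_diplotypes(config: SimConfig) -> list[SampleDiplotype]:
    """Draw haplotype pairs i.i.d. from the frequency pool (random mating)."""
    config.validate()
    rng = config.substream(0)
    labels = sorted(config.hap_freqs)
    probs = np.array([config.hap_freqs[h] for h in labels])
    by_label = patterns_by_label()
    draws = rng.choice(len(labels), size=(config.n_samples, 2), p=probs)
    out = []
    for i, (a, b) in enumerate(draws):
        ha, hb = labels[a], labels[b]
        pa, pb = by_label[ha], by_label[hb]
        genotypes = {
            snp: tuple(sorted((pa.alleles[snp], pb.alleles[snp])))
            for snp in TAG_SNPS
        }
        out.append(
            SampleDiplotype(
                sample_id=f"S{i + 1:04d}",
                hap_pair=(ha, hb),
                diplotype=make_diplotype(ha, hb),
                genotypes=genotypes,
            )
        )
    return out


def gen_allelic_measurements(
    diplotypes: Sequence[SampleDiplotype], config: SimConfig
) -> list[AllelicMeasurement]:
    """Replicate cDNA/gDNA peak ratios for marker-heterozygous samples.

    The marker alleles are G (tagging hap1) and T; the true cDNA ratio is
    level(G haplotype) / level(T haplotype) and the true gDNA ratio is 1.
    Replicates multiply the truth by log-normal noise with the configured
    coefficient of variation (median-unbiased on the log scale, so the mean
    log2 ratio is an unbiased estimate of the log2 truth).
    """
    config.validate()
    rng = config.substream(1)
    by_label = patterns_by_label()
    sigma = math.sqrt(math.log(1.0 + config.meas_cv**2))
    out = []
    for d in diplotypes:
        alleles = {by_label[h].alleles[MARKER_SNP] for h in d.hap_pair}
        if alleles != {"G", "T"}:
            continue  # marker-homozygous: assay uninformative
        g_hap = next(h for h in d.hap_pair if by_label[h].alleles[MARKER_SNP] == "G")
        t_hap = next(h for h in d.hap_pair if by_label[h].alleles[MARKER_SNP] == "T")
        true_ratio = config.hap_expr_level[g_hap] / config.hap_expr_level[t_hap]
        noise = lambda n: (
            np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)
        )
        out.append(
            AllelicMeasurement(
                sample_id=d.sample_id,
                snp_id=MARKER_SNP,
                allele_a="G",
                allele_b="T",
                cdna_ratios=tuple(true_ratio * noise(config.n_reps)),
                gdna_ratios=tuple(1.0 * noise(config.n_reps)),
            )
        )
    return out


def gen_expression_table(
    diplotypes: Sequence[SampleDiplotype],
    config: SimConfig,
    mode: str = LOG_INTENSITY_MODE,
    base_ct: float = 24.0,
) -> ExpressionTable:
    """Diplotype-group-dependent expression matrix with housekeeping genes.

    Expression (log2 scale) = effect x (number of low-expression haplotypes)
    + Normal(0, SD) per gene.  In Ct mode the sign inverts around ``base_ct``
    (higher expression = lower Ct).  Annotations carry the expression group
    and minor-allele counts at each tag SNP.
    """
    config.validate()
    if mode not in (CT_MODE, LOG_INTENSITY_MODE):
        raise ConfigError(f"unknown expression mode {mode!r}")
    rng = config.substream(2)
    n = len(diplotypes)
    n_low = np.array(
        [{"HH": 0, "HL": 1, "LL": 2}[d.diplotype.group] for d in diplotypes]
    )
    cols = {}
    for gene in sorted(config.gene_effects):
        effect, sd = config.gene_effects[gene]
        cols[gene] = effect * n_low + rng.normal(0.0, sd, size=n)
    for gene in sorted(config.housekeeping_sds):
        cols[gene] = rng.normal(0.0, config.housekeeping_sds[gene], size=n)
    data = pd.DataFrame(cols, index=[d.sample_id for d in diplotypes])
    if mode == CT_MODE:
        data = base_ct - data

    minor = _minor_alleles(config)
    ann = {
        "group": [d.diplotype.group for d in diplotypes],
        "n_low": n_low,
    }
    for snp in TAG_SNPS:
        ann[snp] = [
            sum(1 for a in d.genotypes[snp] if a == minor[snp]) for d in diplotypes
        ]
    annotations = pd.DataFrame(ann, index=data.index)
    return ExpressionTable(
        data=data,
        mode=mode,
        housekeeping=tuple(sorted(config.housekeeping_sds)),
        annotations=annotations,
    )


def _minor_alleles(config: SimConfig) -> dict[str, str]:
    """Frequency-weighted minor allele at each tag SNP under the pool."""
    by_label = patterns_by_label()
    minor = {}
    for snp in TAG_SNPS:
        freq: dict[str, float] = {}
        for hap, f in config.hap_freqs.items():
            a = by_label[hap].alleles[snp]
            freq[a] = freq.get(a, 0.0) + f
        minor[snp] = min(freq, key=lambda a: (freq[a], a))
    return minor


def gen_carrier_cohort(config: SimConfig) -> list[CarrierRecord]:
    """Multi-study carrier cohort with a planted per-allele log-hazard.

    Genotypes are Hardy-Weinberg at the configured minor-allele frequency;
    event times are exponential with hazard lambda0 * exp(log_hr * g);
    censoring times are independent exponential with the configured scale
    (a zero scale censors everyone immediately after entry).  Study labels
    are assigned round-robin.
    """
    config.validate()
    cc = config.carrier
    rng = config.substream(3)
    p = cc.maf
    genotypes = rng.choice(
        3, size=cc.n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]
    )
    rates = cc.baseline_hazard * np.exp(cc.log_hr * genotypes)
    event_times = rng.exponential(1.0 / rates)
    if cc.censoring_scale > 0:
        censor_times = rng.exponential(cc.censoring_scale, size=cc.n)
    else:
        censor_times = np.full(cc.n, 1e-9)
    status = event_times <= censor_times
    times = np.minimum(event_times, censor_times)
    times = np.maximum(times, 1e-12)  # CarrierRecord requires time > 0
    return [
        CarrierRecord(
            carrier_id=f"C{i + 1:05d}",
            study=f"study{(i % cc.n_studies) + 1:02d}",
            genotype=int(genotypes[i]),
            status=bool(status[i]),
            time=float(times[i]),
        )
        for i in range(cc.n)
    ]


def gen_haplotype_carrier_cohort(
    config: SimConfig,
    hap_log_hrs: Optional[dict[str, float]] = None,
) -> list[CarrierRecord]:
    """Carrier cohort with haplotype dosages and planted per-copy log-HRs.

    Haplotype pairs are drawn from the configured frequency pool; the hazard
    is lambda0 * exp(sum_h log_hr[h] * copies of h).  Haplotypes absent from
    ``hap_log_hrs`` have log-HR 0.  Dosages are the (phase-known) integer
    copy counts, the degenerate-posterior case of the phased analysis.
    """
    config.validate()
    cc = config.carrier
    hap_log_hrs = hap_log_hrs or {}
    unknown = set(hap_log_hrs) - set(config.hap_freqs)
    if unknown:
        raise ConfigError(f"log-HRs for unknown haplotypes: {sorted(unknown)}")
    rng = config.substream(3)
    labels = sorted(config.hap_freqs)
    probs = np.array([config.hap_freqs[h] for h in labels])
    pairs = rng.choice(len(labels), size=(cc.n, 2), p=probs)
    beta = np.array([hap_log_hrs.get(h, 0.0) for h in labels])
    eta = beta[pairs[:, 0]] + beta[pairs[:, 1]]
    rates = cc.baseline_hazard * np.exp(eta)
    event_times = rng.exponential(1.0 / rates)
    if cc.censoring_scale > 0:
        censor_times = rng.exponential(cc.censoring_scale, size=cc.n)
    else:
        censor_times = np.full(cc.n, 1e-9)
    status = event_times <= censor_times
    times = np.maximum(np.minimum(event_times, censor_times), 1e-12)
    out = []
    for i in range(cc.n):
        dosages = {h: 0.0 for h in labels}
        dosages[labels[pairs[i, 0]]] += 1.0
        dosages[labels[pairs[i, 1]]] += 1.0
        out.append(
            CarrierRecord(
                carrier_id=f"C{i + 1:05d}",
                study=f"study{(i % cc.n_studies) + 1:02d}",
                genotype=None,
                status=bool(status[i]),
                time=float(times[i]),
                dosages=dosages,
            )
        )
    return out
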