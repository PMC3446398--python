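# daehap

Differential allelic expression, expression haplotypes and carrier risk
analysis for *cis*-regulated tumour-suppressor genes.

Common regulatory variants can change how much mRNA each copy of a gene
produces. When a gene such as *BRCA2* is inactivated on one chromosome by a
germline mutation, the carrier depends entirely on the remaining wild-type
allele — so a *cis*-regulatory haplotype that lowers that allele's output may
modify cancer risk. `daehap` implements the complete analysis chain used to
investigate this mechanism:

1. **DAE calling** (`daehap.allelic`) — replicate allelic peak ratios from
   cDNA are normalized against genomic DNA and a sample is called as showing
   differential allelic expression (DAE) when
   `|mean(log2 cDNA ratio) − mean(log2 gDNA ratio)| > log2(1.2) ≈ 0.263`.
2. **Haplotypes** (`daehap.haplotypes`) — five common haplotypes over seven
   tag SNPs; second-haplotype resolution for marker heterozygotes anchored
   on the G-tagged haplotype; diplotype expression groups (HH/HL/LL);
   pairwise LD (D, D′, r²); EM haplotype-frequency estimation for unphased
   cohorts.
3. **DAE association** (`daehap.dae_assoc`) — exact sign test, Pearson
   chi-square on carriage × DAE tables, Wilcoxon rank-sum on DAE magnitude.
4. **Downstream expression** (`daehap.expression`) — ΔΔCt normalization for
   qPCR (with data-driven housekeeping-pair selection), genotype ANOVA and
   diplotype-group t-tests.
5. **TFBS screening** (`daehap.tfbs`) — position-weight-matrix scanning with
   matrix and core similarity scores
   (`mss = (Current − Min)/(Max − Min)` with information-weighted
   contributions, core = the five most conserved consecutive positions) and
   a four-criteria allele-differential candidate filter.
6. **Carrier risk** (`daehap.risk`) — Cox proportional-hazards cohort
   models fitted by Newton–Raphson on the partial likelihood (Breslow or
   Efron ties, optional study stratification and late entry): per-allele
   (multiplicative) HRs, genotype 2-df models, Cochran–Armitage trend test,
   between-study heterogeneity LRT, and per-copy haplotype HRs from
   posterior dosages.
7. **Synthetic cohorts** (`daehap.simulate`) — generators that emulate the
   full study design, so every stage is testable without external data.

All stages are also exposed through a `daehap` command-line tool
(`simulate`, `dae-call`, `assign-haplotypes`, `dae-assoc`, `expr-assoc`,
`tfbs-screen`, `risk`, `ld`, `phase-em`, and `pipeline` to run everything
from one config).

## Worked example

```python
import daehap as dh

cfg = dh.SimConfig(n_samples=100, seed=4)        # study-like defaults
dips = dh.gen_diplotypes(cfg)
measurements = dh.gen_allelic_measurements(dips, cfg)
calls = [dh.call_dae_from_measurement(m) for m in measurements]
s = dh.summarize_dae(calls)
print(f"{s.n_dae}/{s.n_tested} heterozygotes DAE "
      f"({100 * s.fraction_dae:.0f}%), by allele {s.n_by_direction}")

est = dh.cox_per_allele(dh.gen_carrier_cohort(cfg))
t = est.terms[0]
print(f"per-allele HR {t.hr:.3f} (95% CI {t.ci_low:.3f}-{t.ci_high:.3f})")
```

prints

```
22/47 heterozygotes DAE (47%), by allele {'G': 21, 'T': 1}
per-allele HR 0.857 (95% CI 0.779-0.942)
```

Of the 100 samples, 47 are heterozygous at the transcribed marker SNP and
therefore assayable. Heterozygotes carrying a low-expression second
haplotype (true allelic ratio 1/0.7 ≈ 1.43) exceed the 1.2-fold threshold
and over-express the G allele, which tags the reference haplotype; one
balanced sample crosses the threshold the other way on measurement noise
alone. The carrier cohort was simulated with a planted protective
per-allele hazard ratio of 0.85, which the Cox fit recovers.

The same analysis runs from the shell:

```sh
daehap --seed 4 pipeline --out-dir out/
```

writing per-stage TSV reports (`dae_calls.tsv`, `diplotypes.tsv`,
`dae_assoc.tsv`, `expr_assoc.tsv`, `tfbs_screen.tsv`,
`risk_per_allele.tsv`, `risk_heterogeneity.tsv`) into `out/`.

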