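"""Readers and writers for the pipeline's interchange formats.

TSV is the primary interchange (self-describing header rows).  Also
supported: a minimal unphased-GT VCF dialect via pysam, TRANSFAC flat-file
matrices via Bio.motifs, FASTA sequence windows via Bio.SeqIO, BED
regulatory intervals, and TOML simulation configs.  All writers go through
an atomic write-to-temp-then-rename so failures never leave partial output.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .allelic import AllelicMeasurement, DaeCall
from .errors import ConfigError, DataError
from .haplotypes import HaplotypePattern, TAG_SNPS
from .risk import CarrierRecord
from .tfbs import BedInterval, Pwm, SnpContext, pwm_from_counts

PathLike = Union[str, Path]

Genotypes = dict[str, dict[str, Optional[tuple[str, str]]]]


@contextmanager
def atomic_write(path: PathLike) -> Iterator:
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes_tsv(path: PathLike) -> Genotypes:
    """Sample x SNP table of unphased "A/G" genotype strings."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing sample_id column")
    out: Genotypes = {}
    for _, row in df.iterrows():
        rec: dict[str, Optional[tuple[str, str]]] = {}
        for snp in df.columns:
            if snp == "sample_id":
                continue
            val = row[snp]
            if pd.isna(val) or val in ("./.", "."):
                rec[snp] = None
                continue
            parts = str(val).split("/")
            if len(parts) != 2:
                raise DataError(
                    f"{path}: bad genotype {val!r} for {row['sample_id']} at {snp}"
                )
            rec[snp] = tuple(sorted(parts))
        out[row["sample_id"]] = rec
    return out


def write_genotypes_tsv(genotypes: Genotypes, path: PathLike) -> None:
    snps = sorted({s for rec in genotypes.values() for s in rec})
    # keep canonical tag-SNP order first where applicable
    snps = [s for s in TAG_SNPS if s in snps] + [s for s in snps if s not in TAG_SNPS]
    with atomic_write(path) as fh:
        fh.write("sample_id\t" + "\t".join(snps) + "\n")
        for sample in sorted(genotypes):
            cells = []
            for snp in snps:
                g = genotypes[sample].get(snp)
                cells.append("./." if g is None else "/".join(g))
            fh.write(sample + "\t" + "\t".join(cells) + "\n")


def read_genotypes_vcf(path: PathLike) -> Genotypes:
    """Minimal VCF dialect: biallelic sites, unphased GT, "./." = missing."""
    import pysam

    out: Genotypes = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            out[s] = {}
        for rec in vcf:
            snp = rec.id or f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise DataError(f"{path}: site {snp} is not biallelic")
            alleles = (rec.ref, rec.alts[0])
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt:
                    out[s][snp] = None
                else:
                    out[s][snp] = tuple(sorted(alleles[i] for i in gt))
    return out


def read_genotypes(path: PathLike, format: str = "tsv") -> Genotypes:
    if format == "tsv":
        return read_genotypes_tsv(path)
    if format == "vcf":
        return read_genotypes_vcf(path)
    raise ConfigError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Haplotype patterns


def read_patterns(path: PathLike) -> list[HaplotypePattern]:
    """Pattern file: TSV of label, snp_id, allele, expression_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"label", "snp_id", "allele", "expression_class"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: pattern file needs columns {sorted(required)}")
    patterns = []
    for label, grp in df.groupby("label", sort=True):
        classes = set(grp["expression_class"])
        if len(classes) != 1:
            raise DataError(f"{path}: inconsistent expression_class for {label}")
        patterns.append(
            HaplotypePattern(
                label=str(label),
                alleles=dict(zip(grp["snp_id"], grp["allele"])),
                expression_class=classes.pop(),
            )
        )
    return patterns


def write_patterns(patterns: Sequence[HaplotypePattern], path: PathLike) -> None:
    with atomic_write(path) as fh:
        fh.write("label\tsnp_id\tallele\texpression_class\n")
        for p in patterns:
            for snp, allele in p.alleles.items():
                fh.write(f"{p.label}\t{snp}\t{allele}\t{p.expression_class}\n")


# ---------------------------------------------------------------------------
# Allelic measurements and DAE calls


def read_allelic_measurements(path: PathLike) -> list[AllelicMeasurement]:
    """Long-format TSV: sample_id, snp_id, allele_a, allele_b, assay, replicate, ratio."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "snp_id", "allele_a", "allele_b", "assay", "replicate", "ratio"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: measurement file needs columns {sorted(required)}")
    bad_assay = set(df["assay"]) - {"cdna", "gdna"}
    if bad_assay:
        raise DataError(f"{path}: unknown assay values {sorted(bad_assay)}")
    out = []
    keys = ["sample_id", "snp_id", "allele_a", "allele_b"]
    for (sample, snp, a, b), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("replicate")
        cdna = tuple(grp.loc[grp["assay"] == "cdna", "ratio"].astype(float))
        gdna = tuple(grp.loc[grp["assay"] == "gdna", "ratio"].astype(float))
        out.append(
            AllelicMeasurement(
                sample_id=str(sample), snp_id=str(snp), allele_a=str(a),
                allele_b=str(b), cdna_ratios=cdna, gdna_ratios=gdna,
            )
        )
    return out


def write_allelic_measurements(
    measurements: Sequence[AllelicMeasurement], path: PathLike
) -> None:
    with atomic_write(path) as fh:
        fh.write("sample_id\tsnp_id\tallele_a\tallele_b\tassay\treplicate\tratio\n")
        for m in measurements:
            for assay, ratios in (("cdna", m.cdna_ratios), ("gdna", m.gdna_ratios)):
                for i, r in enumerate(ratios, start=1):
                    fh.write(
                        f"{m.sample_id}\t{m.snp_id}\t{m.allele_a}\t{m.allele_b}"
                        f"\t{assay}\t{i}\t{float(r)!r}\n"
                    )


def write_dae_calls(calls: Sequence[DaeCall], path: PathLike) -> None:
    with atomic_write(path) as fh:
        fh.write(
            "sample_id\tnorm_log2_ratio\tse\tis_dae\tdirection\tthreshold_fold\n"
        )
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.norm_log2_ratio:.6g}\t{c.se:.6g}"
                f"\t{int(c.is_dae)}\t{c.direction or '.'}\t{c.threshold_fold}\n"
            )


def read_dae_calls(path: PathLike) -> list[DaeCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        DaeCall(
            sample_id=str(r.sample_id),
            norm_log2_ratio=float(r.norm_log2_ratio),
            se=float(r.se),
            is_dae=bool(r.is_dae),
            direction=None if r.direction == "." else str(r.direction),
            threshold_fold=float(r.threshold_fold),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# TRANSFAC matrices


def read_pwms(path: PathLike, pseudocount: float = 0.01) -> list[Pwm]:
    """Parse TRANSFAC flat-file matrices (ID/NA, P0 header, count rows, //).

    Counts are regularized with the pseudocount and normalized to
    frequencies; information vectors and core blocks are precomputed.
    """
    from Bio import motifs

    try:
        with open(path) as fh:
            records = motifs.parse(fh, "TRANSFAC", strict=False)
    except Exception as exc:  # Bio raises bare ValueError with line context
        raise DataError(f"{path}: cannot parse TRANSFAC matrices: {exc}") from exc
    out = []
    for i, rec in enumerate(records):
        counts = np.array(
            [[rec.counts[b][i] for b in "ACGT"] for i in range(rec.length)],
            dtype=float,
        )
        name = rec.get("ID") or rec.get("AC") or f"matrix{i + 1}"
        factor = rec.get("NA") or ""
        out.append(pwm_from_counts(name, counts, factor=factor, pseudocount=pseudocount))
    if not out:
        raise DataError(f"{path}: no matrices found")
    return out


def write_pwm_counts(
    name: str, factor: str, counts: np.ndarray, fh
) -> None:
    """Write one matrix block in the TRANSFAC dialect read_pwms accepts."""
    fh.write(f"ID  {name}\nNA  {factor}\nP0      A      C      G      T\n")
    for i, row in enumerate(np.asarray(counts), start=1):
        cells = "  ".join(f"{v:6.2f}" for v in row)
        consensus = "ACGT"[int(np.argmax(row))]
        fh.write(f"{i:02d}  {cells}  {consensus}\n")
    fh.write("//\n")


# ---------------------------------------------------------------------------
# BED and FASTA windows


def read_bed(path: PathLike) -> list[BedInterval]:
    """Three-column BED (0-based half-open); parse errors carry line numbers."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end < start:
                raise DataError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            out.append(BedInterval(chrom=parts[0], start=start, end=end))
    return out


def read_snp_contexts(path: PathLike) -> list[SnpContext]:
    """FASTA windows with SNP metadata in the description.

    Header format: ``>rsID offset=<int> alleles=<A>/<B> chrom=<chr> pos=<int>``
    where offset is the 0-based SNP position within the window and pos the
    1-based genomic coordinate.
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, val = token.split("=", 1)
                meta[key] = val
        try:
            allele_a, allele_b = meta["alleles"].split("/")
            out.append(
                SnpContext(
                    snp_id=rec.id,
                    sequence=str(rec.seq),
                    offset=int(meta["offset"]),
                    allele_a=allele_a,
                    allele_b=allele_b,
                    chrom=meta.get("chrom", ""),
                    position=int(meta.get("pos", 0)),
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataError(
                f"{path}: window {rec.id} lacks offset=/alleles= metadata"
            ) from exc
    if not out:
        raise DataError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# Carriers


def read_carriers(path: PathLike) -> list[CarrierRecord]:
    """Carrier TSV: carrier_id, study, genotype, status, time[, entry_time]."""
    df = pd.read_csv(path, sep="\t")
    required = {"carrier_id", "study", "genotype", "status", "time"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: carrier file needs columns {sorted(required)}")
    out = []
    for r in df.itertuples():
        geno = None if pd.isna(r.genotype) else int(r.genotype)
        out.append(
            CarrierRecord(
                carrier_id=str(r.carrier_id),
                study=str(r.study),
                genotype=geno,
                status=bool(int(r.status)),
                time=float(r.time),
                entry_time=float(getattr(r, "entry_time", 0.0) or 0.0),
            )
        )
    return out


def write_carriers(carriers: Sequence[CarrierRecord], path: PathLike) -> None:
    with atomic_write(path) as fh:
        fh.write("carrier_id\tstudy\tgenotype\tstatus\ttime\tentry_time\n")
        for c in carriers:
            geno = "" if c.genotype is None else c.genotype
            fh.write(
                f"{c.carrier_id}\t{c.study}\t{geno}\t{int(c.status)}"
                f"\t{float(c.time)!r}\t{float(c.entry_time)!r}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables and configuration


def read_expression_tsv(
    path: PathLike,
    mode: str,
    housekeeping: Sequence[str] = (),
    annotations_path: Optional[PathLike] = None,
):
    """Samples x genes TSV (first column sample_id, gene ids in the header)."""
    from .expression import ExpressionTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return ExpressionTable(
        data=df, mode=mode, housekeeping=tuple(housekeeping), annotations=ann
    )


def write_expression_tsv(table, path: PathLike, annotations_path=None) -> None:
    with atomic_write(path) as fh:
        table.data.to_csv(fh, sep="\t", index_label="sample_id")
    if annotations_path is not None and table.annotations is not None:
        with atomic_write(annotations_path) as fh:
            table.annotations.to_csv(fh, sep="\t", index_label="sample_id")


def read_sim_config(path: PathLike):
    """Simulation config from a flat TOML file; omitted keys keep defaults."""
    import tomllib

    from .simulate import CarrierSimConfig, SimConfig

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    carrier = CarrierSimConfig(**raw.pop("carrier", {}))
    gene_effects = raw.pop("gene_effects", None)
    if gene_effects is not None:
        raw["gene_effects"] = {g: tuple(v) for g, v in gene_effects.items()}
    try:
        cfg = SimConfig(carrier=carrier, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: unknown configuration key ({exc})") from exc
    cfg.validate()
    return cfg
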