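"""Readers and writers for the pipeline's interchange formats.

Dialects
--------
* Genotype TSV: one row per sample, first column ``sample``, then one
  column per marker id holding 0/1/2 dosages (-1 missing); marker map TSV
  with columns ``id, chrom, pos, ref, alt``.
* PLINK text: ``.ped`` (6 leading columns, then two allele columns per
  marker, 0 = missing) with its ``.map``; the reference allele of each
  marker is the first non-missing allele encountered.
* VCF 4.2 (plain text, via pysam), one record per alternate allele —
  multi-allelic records are split on read.
* GFF3 gene models (gene/mRNA/exon/CDS), FASTA, minimal SAM, junction and
  assay TSVs, YAML key-value configs.

Coordinates are 1-based inclusive everywhere except BED output, which is
0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .autozygosity import MISSING, GenotypeMatrix, Interval
from .model import GeneModel
from .splicing import JunctionTable
from .varfilter import VariantRecord

__all__ = [
    "write_genotype_tsv", "read_genotype_tsv", "read_plink",
    "write_vcf", "read_vcf", "read_catalog",
    "write_gff3", "read_gff3",
    "write_bed", "parse_region",
    "write_fasta", "read_fasta",
    "write_junction_sam",
    "write_assay_tsv", "read_assay_tsv",
]


class FormatError(ValueError):
    """Malformed input, reported with file and line context."""


# --------------------------------------------------------------------- #
# genotype matrices

def write_genotype_tsv(gm: GenotypeMatrix, geno_path, map_path) -> None:
    df = pd.DataFrame(gm.genotypes, columns=gm.markers["id"])
    df.insert(0, "sample", gm.samples)
    df.to_csv(geno_path, sep="\t", index=False)
    gm.markers.to_csv(map_path, sep="\t", index=False)


def read_genotype_tsv(geno_path, map_path) -> GenotypeMatrix:
    markers = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    df = pd.read_csv(geno_path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError(f"{geno_path}: missing 'sample' column")
    samples = df["sample"].astype(str).tolist()
    want = markers["id"].astype(str).tolist()
    missing = [m for m in want if m not in df.columns]
    if missing:
        raise FormatError(
            f"{geno_path}: genotype columns missing for markers {missing[:5]}"
        )
    genos = df[want].to_numpy()
    return GenotypeMatrix(samples, markers, genos)


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a dosage matrix.

    The first non-missing allele seen at each marker becomes the reference
    allele; dosages count the other allele.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str},
    )
    n_markers = len(map_df)
    samples, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_markers} fields, "
                    f"got {len(fields)}"
                )
            samples.append(fields[1])
            rows.append(fields[6:])
    ref = [None] * n_markers
    alt = [None] * n_markers
    genos = []
    for alleles in rows:
        g = []
        for j in range(n_markers):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                g.append(MISSING)
                continue
            for a in (a1, a2):
                if ref[j] is None:
                    ref[j] = a
                elif a != ref[j] and alt[j] is None:
                    alt[j] = a
            g.append((a1 != ref[j]) + (a2 != ref[j]))
        genos.append(g)
    markers = pd.DataFrame(
        {
            "id": map_df["id"],
            "chrom": map_df["chrom"],
            "pos": map_df["pos"].astype(int),
            "ref": [r or "A" for r in ref],
            "alt": [a or "B" for a in alt],
        }
    )
    order = markers.sort_values(["chrom", "pos"]).index.to_numpy()
    return GenotypeMatrix(
        samples, markers.iloc[order].reset_index(drop=True),
        np.asarray(genos)[:, order],
    )


# --------------------------------------------------------------------- #
# VCF

def write_vcf(variants: list[VariantRecord], path,
              contigs: dict[str, int] | None = None) -> None:
    """Write plain-text VCF 4.2 with GT fields."""
    samples: list[str] = []
    for v in variants:
        for s in v.genotypes:
            if s not in samples:
                samples.append(s)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen_contigs = dict(contigs or {})
    for v in variants:
        seen_contigs.setdefault(v.chrom, v.pos + 1_000_000)
    for name, length in seen_contigs.items():
        header.contigs.add(name, length=length)
    for s in samples:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), id=v.vid or None, qual=v.qual,
            )
            for s in samples:
                rec.samples[s]["GT"] = gt_map[v.genotypes.get(s, MISSING)]
            out.write(rec)


def read_vcf(path) -> list[VariantRecord]:
    """Read VCF; multi-allelic records are split into biallelic records
    with per-alt dosages."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for ai, alt in enumerate(rec.alts or (), start=1):
                genos = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        genos[s] = MISSING
                    else:
                        genos[s] = sum(1 for a in gt if a == ai)
                out.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        genotypes=genos, vid=rec.id,
                    )
                )
    return out


def read_catalog(path) -> set[tuple[str, int, str, str]]:
    """Known-variant catalog from a VCF or a 4-column TSV
    (chrom, pos, ref, alt; '#' comments allowed)."""
    path = Path(path)
    if path.suffix == ".vcf":
        return {v.key for v in read_vcf(path)}
    keys = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            keys.add((parts[0], int(parts[1]), parts[2], parts[3]))
    return keys


def write_catalog_tsv(catalog: set, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(catalog):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


# --------------------------------------------------------------------- #
# GFF3 gene models

def write_gff3(model: GeneModel, path) -> None:
    lo, hi = model.span
    mrna_id = f"{model.gene_id}.t1"
    lines = [
        "##gff-version 3",
        f"{model.chrom}\trecsplice\tgene\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={model.gene_id}",
        f"{model.chrom}\trecsplice\tmRNA\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={mrna_id};Parent={model.gene_id}",
    ]
    cds_g = sorted(
        (model.t2g(model.cds_start_t), model.t2g(model.cds_end_t))
    )
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(
            f"{model.chrom}\trecsplice\texon\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={mrna_id}.exon{i};Parent={mrna_id}"
        )
        c_lo, c_hi = max(s, cds_g[0]), min(e, cds_g[1])
        if c_lo <= c_hi:
            lines.append(
                f"{model.chrom}\trecsplice\tCDS\t{c_lo}\t{c_hi}\t.\t"
                f"{model.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> GeneModel:
    """Read a single-transcript gene model from GFF3.

    Exons are normalized into transcript order (descending genomic on the
    minus strand); the CDS span is converted to transcript coordinates.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mrnas = list(db.features_of_type("mRNA"))
    if len(mrnas) != 1:
        raise FormatError(f"{path}: expected exactly 1 mRNA, found {len(mrnas)}")
    mrna = mrnas[0]
    exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
    cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
    if not exons:
        raise FormatError(f"{path}: mRNA has no exons")
    strand = mrna.strand
    exons.sort(key=lambda x: x[0], reverse=(strand == "-"))
    genes = list(db.features_of_type("gene"))
    gene_id = genes[0].id if genes else mrna.id
    model = GeneModel(
        gene_id=gene_id, chrom=mrna.seqid, strand=strand, exons=exons,
        cds_start_t=1, cds_end_t=sum(e - s + 1 for s, e in exons),
    )
    if cds:
        g_all = [g for s, e in cds for g in (s, e)]
        t_all = sorted(model.g2t(g) for g in g_all)
        model.cds_start_t, model.cds_end_t = t_all[0], t_all[-1]
    return model


# --------------------------------------------------------------------- #
# BED / regions

def write_bed(intervals: list[Interval], path, names=None) -> None:
    """Emit intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def parse_region(text: str) -> Interval:
    """Parse 'chrom:start-end' (1-based inclusive, commas tolerated)."""
    try:
        chrom, span = text.split(":")
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
    except ValueError as err:
        raise FormatError(f"malformed region {text!r}") from err
    return Interval(chrom, start, end)


# --------------------------------------------------------------------- #
# FASTA

def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in items
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------- #
# SAM emission for junction reads

def write_junction_sam(table: JunctionTable, path,
                       contigs: dict[str, int], anchor: int = 20) -> None:
    """Write one gapped read per junction count: ``{anchor}M{gap}N{anchor}M``
    starting ``anchor - 1`` bases left of the donor end."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": length} for c, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        k = 0
        for _, row in table.df.iterrows():
            gap = int(row["acceptor_start"]) - int(row["donor_end"]) - 1
            for _ in range(int(row["count"])):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{row['sample']}.jr{k:06d}"
                a.reference_name = str(row["chrom"])
                a.reference_start = int(row["donor_end"]) - anchor
                a.mapping_quality = 60
                a.cigarstring = f"{anchor}M{gap}N{anchor}M"
                out.write(a)
                k += 1


# --------------------------------------------------------------------- #
# assay tables

def write_assay_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_assay_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
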