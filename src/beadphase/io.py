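"""File-format glue: FASTA, gzipped FASTQ trios, BED, VCF v4.2,
SAM-like flat text, and report tables.

Conventions (bit-exact requirements of the pipeline's interfaces):
BED is 0-based half-open; VCF POS is 1-based with phased genotypes
written ``0|1`` plus a PS phase-set tag; the bead barcode travels as a
``BX`` tag; FASTQ trios share read ids across R1/R2/I1.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignedRead
from .errors import FormatError
from .evaluation import VariantPhase
from .simulate import ReadPair, ReadTruth

SAM_TSV_HEADER = "# beadphase sam-like v1: read_id mate ref pos cigar strand BX dup seq"


# -- FASTA ------------------------------------------------------------------

def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# -- FASTQ trio -------------------------------------------------------------

def _gzip_text_writer(path):
    # mtime pinned to 0 and no embedded filename: identical content
    # yields byte-identical .gz output, keeping runs reproducible.
    import io as _io
    return _io.TextIOWrapper(
        gzip.GzipFile(filename="", mode="wb",
                      fileobj=open(path, "wb"), mtime=0))


def write_fastq_trio(r1_path, r2_path, i1_path,
                     reads: Iterable[ReadPair]) -> None:
    """R1/R2 read pairs plus the I1 barcode read, identical ids across
    the trio, gzip-compressed."""
    with _gzip_text_writer(r1_path) as f1, _gzip_text_writer(r2_path) as f2, \
            _gzip_text_writer(i1_path) as fi:
        for pair in reads:
            q = pair.qual
            qbc = "I" * len(pair.observed_barcode)
            f1.write(f"@{pair.read_id}\n{pair.r1_seq}\n+\n{q}\n")
            f2.write(f"@{pair.read_id}\n{pair.r2_seq}\n+\n{q}\n")
            fi.write(f"@{pair.read_id}\n{pair.observed_barcode}\n+\n{qbc}\n")


def read_fastq_trio(r1_path, r2_path, i1_path) -> list[ReadPair]:
    """Rebuild read pairs from a FASTQ trio (no truth provenance)."""
    def _open(p):
        return gzip.open(p, "rt") if str(p).endswith(".gz") else open(p)

    pairs: list[ReadPair] = []
    with _open(r1_path) as f1, _open(r2_path) as f2, _open(i1_path) as fi:
        for rec1, rec2, reci in zip(SeqIO.parse(f1, "fastq"),
                                    SeqIO.parse(f2, "fastq"),
                                    SeqIO.parse(fi, "fastq")):
            if not (rec1.id == rec2.id == reci.id):
                raise FormatError(
                    f"read ids diverge across trio: {rec1.id}/{rec2.id}/{reci.id}")
            truth = ReadTruth(-1, -1, -1, "", False)
            pairs.append(ReadPair(rec1.id, str(rec1.seq), str(rec2.seq),
                                  str(reci.seq), truth))
    return pairs


# -- BED --------------------------------------------------------------------

def write_bed(path, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for ref, start, end in intervals:
            fh.write(f"{ref}\t{start}\t{end}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line with <3 fields: {line!r}")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


# -- VCF --------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedRecord:
    """One VCF data line: 0-based position, phased or unphased GT."""

    ref_id: str
    pos: int                  # 0-based; written 1-based
    ref_allele: str
    alt_alleles: str          # comma-joined ALT field
    gt: tuple[int, int]
    phased: bool
    ps: int | None            # 1-based phase-set id


def write_phased_vcf(path, records: Iterable[PhasedRecord],
                     contig_lengths: Mapping[str, int],
                     sample: str = "sample") -> None:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: (r.ref_id, r.pos)):
            line = vcf.new_record(
                contig=rec.ref_id, start=rec.pos,
                alleles=(rec.ref_allele, *rec.alt_alleles.split(",")))
            line.samples[sample]["GT"] = rec.gt
            line.samples[sample].phased = rec.phased
            if rec.ps is not None:
                line.samples[sample]["PS"] = rec.ps
            vcf.write(line)


def read_phased_vcf(path) -> dict[tuple[str, int], VariantPhase]:
    """Het sites of a single-sample VCF as a phase set keyed by
    (contig, 0-based position)."""
    out: dict[tuple[str, int], VariantPhase] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[next(iter(rec.samples))]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            if gt[0] == gt[1]:
                continue
            alleles = (rec.alleles[gt[0]], rec.alleles[gt[1]])
            if any(len(a) != 1 for a in alleles):
                continue  # SNVs only
            ps = sample.get("PS")
            out[(rec.contig, rec.start)] = VariantPhase(
                rec.contig, rec.start, alleles, bool(sample.phased),
                int(ps) if ps is not None else None)
    return out


# -- SAM-like flat text -----------------------------------------------------

def write_sam_tsv(path, reads: Iterable[AlignedRead]) -> None:
    with open(path, "w") as fh:
        fh.write(SAM_TSV_HEADER + "\n")
        for r in reads:
            fh.write("\t".join([
                r.read_id, str(r.mate), r.ref_id or "*", str(r.start),
                r.cigar, r.strand, r.barcode, str(int(r.is_dup)), r.seq,
            ]) + "\n")


def read_sam_tsv(path) -> list[AlignedRead]:
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"sam-like line with {len(f)} fields")
            ref = None if f[2] == "*" else f[2]
            reads.append(AlignedRead(
                read_id=f[0], mate=int(f[1]), ref_id=ref, start=int(f[3]),
                cigar=f[4], strand=f[5], barcode=f[6], mapped=ref is not None,
                is_dup=bool(int(f[7])), seq=f[8]))
    return reads


def read_sam(path) -> list[AlignedRead]:
    """Import externally produced alignments (SAM) with BX barcode tags."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            barcode = seg.get_tag("BX") if seg.has_tag("BX") else ""
            mapped = not seg.is_unmapped
            reads.append(AlignedRead(
                read_id=seg.query_name,
                mate=2 if seg.is_read2 else 1,
                ref_id=seg.reference_name if mapped else None,
                start=seg.reference_start if mapped else -1,
                cigar=seg.cigarstring if mapped else "*",
                strand=("-" if seg.is_reverse else "+") if mapped else ".",
                barcode=barcode,
                mapped=mapped,
                is_dup=seg.is_duplicate,
                seq=seg.query_sequence or "",
            ))
    return reads


# -- reports ----------------------------------------------------------------

def write_summary(path, values: Mapping[str, object]) -> None:
    """Machine-readable key-value summary (one ``key\\tvalue`` per line)."""
    with open(path, "w") as fh:
        fh.write("# beadphase summary v1\n")
        for key, value in values.items():
            fh.write(f"{key}\t{value}\n")


def write_table(path, df) -> None:
    df.to_csv(path, sep="\t", index=False)
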