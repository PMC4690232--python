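"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open, on the reference forward
strand.  Minus-strand MAF query coordinates are converted to forward-strand
coordinates at parse time and the original strand is kept as a flag; the
gapped alignment rows are stored exactly as aligned (for a minus-strand
block the query row is therefore the reverse complement of the forward
strand segment).  VCF emission converts to 1-based anchored positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "VcfRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_bed",
    "read_bed",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_IUPAC = re.compile(r"[^ACGTN]")
_NON_IUPAC_GAPPED = re.compile(r"[^ACGTN-]")


class FormatError(ValueError):
    """A file does not conform to the expected format."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence record with empty name")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentBlock:
    """One gapped pairwise alignment block (reference row vs query row).

    ``ref_row`` and ``query_row`` are equal-length gapped strings; a column
    is never a gap in both rows.  Query coordinates are always on the
    forward strand of the scaffold regardless of ``strand``.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_scaffold: str
    query_start: int
    query_end: int
    strand: str
    ref_row: str
    query_row: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise FormatError(f"bad reference span {self.ref_start}..{self.ref_end}")
        if not (0 <= self.query_start < self.query_end):
            raise FormatError(f"bad query span {self.query_start}..{self.query_end}")
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if len(self.ref_row) != len(self.query_row):
            raise FormatError("gapped rows differ in length")
        if len(self.ref_row) - self.ref_row.count("-") != self.ref_end - self.ref_start:
            raise FormatError("reference row inconsistent with coordinates")
        if (
            len(self.query_row) - self.query_row.count("-")
            != self.query_end - self.query_start
        ):
            raise FormatError("query row inconsistent with coordinates")
        if any(a == "-" and b == "-" for a, b in zip(self.ref_row, self.query_row)):
            raise FormatError("column gapped in both rows")

    def query_forward_segment(self) -> str:
        """Ungapped query sequence of this block on the forward strand."""
        seg = self.query_row.replace("-", "")
        return revcomp(seg) if self.strand == "-" else seg


def _clean_sequence(seq: str) -> str:
    return _NON_IUPAC.sub("N", seq.upper())


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences uppercased, non-ACGTN mapped to N."""
    records = [
        SequenceRecord(rec.id, _clean_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    bio = (_BioSeqRecord(Seq(r.sequence), id=r.name, description="") for r in records)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_maf(path) -> list[AlignmentBlock]:
    """Read pairwise MAF blocks (reference row first, query row second).

    Minus-strand query coordinates (MAF counts from the 3' end of the
    source) are converted to forward-strand coordinates.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as handle:
        for aln in AlignIO.parse(handle, "maf"):
            if len(aln) != 2:
                raise FormatError(
                    f"MAF paragraph with {len(aln)} sequence lines (expected 2)"
                )
            ref, qry = aln[0], aln[1]
            if ref.annotations["strand"] != 1:
                raise FormatError("reference row must be on the + strand")
            q = qry.annotations
            if q["strand"] == 1:
                q_start, q_end, strand = q["start"], q["start"] + q["size"], "+"
            else:
                q_start = q["srcSize"] - (q["start"] + q["size"])
                q_end = q["srcSize"] - q["start"]
                strand = "-"
            score = float(getattr(aln, "_annotations", {}).get("score", 0.0))
            blocks.append(
                AlignmentBlock(
                    ref_chrom=ref.id,
                    ref_start=ref.annotations["start"],
                    ref_end=ref.annotations["start"] + ref.annotations["size"],
                    query_scaffold=qry.id,
                    query_start=q_start,
                    query_end=q_end,
                    strand=strand,
                    ref_row=_NON_IUPAC_GAPPED.sub("N", str(ref.seq).upper()),
                    query_row=_NON_IUPAC_GAPPED.sub("N", str(qry.seq).upper()),
                    score=score,
                )
            )
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], path, src_sizes: dict[str, int]) -> None:
    """Write pairwise alignment blocks as MAF.

    ``src_sizes`` must give the full source length of every named sequence;
    minus-strand query coordinates are converted back to the MAF convention.
    """
    with open(path, "w") as out:
        out.write("##maf version=1\n")
        for b in blocks:
            out.write(f"a score={b.score:g}\n")
            rsize = b.ref_end - b.ref_start
            out.write(
                f"s {b.ref_chrom} {b.ref_start} {rsize} + "
                f"{src_sizes[b.ref_chrom]} {b.ref_row}\n"
            )
            qsize = b.query_end - b.query_start
            src = src_sizes[b.query_scaffold]
            qstart = b.query_start if b.strand == "+" else src - b.query_end
            out.write(
                f"s {b.query_scaffold} {qstart} {qsize} {b.strand} {src} {b.query_row}\n"
            )
            out.write("\n")


# --- VCF ------------------------------------------------------------------

#: INFO keys the writer knows about (key -> (Number, Type, Description)).
INFO_FIELDS: dict[str, tuple[str, str, str]] = {
    "SVTYPE": ("1", "String", "Type of structural variant"),
    "SVLEN": ("1", "Integer", "Signed length difference between ALT and REF"),
    "END": ("1", "Integer", "End position of the variant on the reference"),
    "CATEGORY": ("1", "String", "Raw alignment-derived category"),
    "ORIG_TYPE": ("1", "String", "Discovery-time type before ancestral rectification"),
    "AA_STATE": ("1", "String", "Ancestral state call from outgroup comparison"),
    "MECHANISM": ("1", "String", "Inferred formation mechanism"),
    "MECH_EVIDENCE": ("1", "String", "Evidence supporting the mechanism call"),
    "NCARRIER": ("1", "Integer", "Number of individuals the variant was assembled in"),
    "DOUBLEHIT": ("0", "Flag", "Identical breakpoints assembled in >=2 individuals"),
    "InbCoeff": ("1", "Float", "Inbreeding coefficient among unrelated individuals"),
    "NOVELSEQ": ("0", "Flag", "Inserted allele is novel sequence"),
}

FORMAT_FIELDS: dict[str, tuple[str, str, str]] = {
    "GT": ("1", "String", "Genotype"),
    "GQ": ("1", "Integer", "Phred-scale genotype quality"),
    "PL": ("G", "Integer", "Phred-scaled genotype likelihoods"),
    "RIN": ("1", "Float", "Reference allele intensity"),
    "AIN": ("1", "Float", "Alternative allele intensity"),
}


@dataclass
class VcfRecord:
    """A bi-allelic variant record with full (non-symbolic) allele sequences."""

    chrom: str
    pos: int  # 1-based anchor position
    id: str
    ref_allele: str
    alt_allele: str
    qual: float | None = None
    filter: str = "."
    info: dict = field(default_factory=dict)
    samples: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise FormatError("empty allele")
        unknown = set(self.info) - set(INFO_FIELDS)
        if unknown:
            raise FormatError(f"unknown INFO key(s): {sorted(unknown)}")

    @property
    def end(self) -> int:
        """1-based inclusive reference end: pos + len(ref) - 1."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def svlen(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def _check_sorted(records: Sequence[VcfRecord]) -> None:
    seen_chroms: list[str] = []
    for prev, cur in zip(records, records[1:]):
        if cur.chrom == prev.chrom:
            if cur.pos < prev.pos:
                raise FormatError(
                    f"records out of order at {cur.chrom}:{cur.pos}"
                )
        else:
            if cur.chrom in seen_chroms:
                raise FormatError(f"chromosome {cur.chrom} revisited; input unsorted")
            seen_chroms.append(prev.chrom)


def _build_header(samples: Sequence[str], contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for key, (number, vtype, desc) in INFO_FIELDS.items():
        header.info.add(key, number, vtype, desc)
    for key, (number, vtype, desc) in FORMAT_FIELDS.items():
        header.formats.add(key, number, vtype, desc)
    header.filters.add("FALSE", None, None, "Failed quality recalibration")
    header.filters.add("INBCOEFF", None, None, "Inbreeding coefficient out of range")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(records: Sequence[VcfRecord], samples: Sequence[str], path) -> None:
    """Write sorted bi-allelic records as VCF 4.2 with full allele sequences."""
    _check_sorted(records)
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    header = _build_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
                id=rec.id if rec.id != "." else None,
                qual=rec.qual,
            )
            if rec.filter and rec.filter != ".":
                for name in rec.filter.split(";"):
                    row.filter.add(name)
            for key, value in rec.info.items():
                if key == "END":
                    continue  # derived from pos + len(ref); pysam manages 'stop'
                if INFO_FIELDS[key][1] == "Flag":
                    if value:
                        row.info[key] = True
                else:
                    row.info[key] = value
            # anchored full-sequence alleles make stop self-consistent
            row.stop = rec.pos - 1 + len(rec.ref_allele)
            for sample in samples:
                fields = rec.samples.get(sample, {})
                for key, value in fields.items():
                    if key == "GT":
                        row.samples[sample].allele_indices = _parse_gt(value)
                        row.samples[sample].phased = "|" in value
                    else:
                        row.samples[sample][key] = value
            out.write(row)


def _parse_gt(gt: str) -> tuple:
    return tuple(None if a == "." else int(a) for a in re.split(r"[/|]", gt))


def _format_gt(indices, phased: bool) -> str:
    sep = "|" if phased else "/"
    return sep.join("." if a is None else str(a) for a in indices)


def read_vcf(path) -> tuple[list[VcfRecord], list[str]]:
    """Read a VCF into records; returns (records, sample names)."""
    records: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            if len(row.alts or ()) != 1:
                raise FormatError(f"non-bi-allelic record at {row.chrom}:{row.pos}")
            info = {}
            for key in row.info:
                if key == "END":
                    continue
                if key not in INFO_FIELDS:
                    raise FormatError(f"unknown INFO key {key}")
                value = row.info[key]
                info[key] = True if INFO_FIELDS[key][1] == "Flag" else value
            sample_fields: dict[str, dict] = {}
            for sample in samples:
                data = row.samples[sample]
                fields = {}
                for key in data:
                    if key == "GT":
                        if data.allele_indices is None or all(
                            a is None for a in data.allele_indices
                        ):
                            fields["GT"] = _format_gt(
                                data.allele_indices or (None, None), data.phased
                            )
                        else:
                            fields["GT"] = _format_gt(data.allele_indices, data.phased)
                    elif data[key] is not None:
                        value = data[key]
                        fields[key] = tuple(value) if isinstance(value, tuple) else value
                sample_fields[sample] = fields
            filt = ";".join(row.filter.keys()) if list(row.filter) else "."
            records.append(
                VcfRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    id=row.id or ".",
                    ref_allele=row.ref,
                    alt_allele=row.alts[0],
                    qual=row.qual,
                    filter=filt,
                    info=info,
                    samples=sample_fields,
                )
            )
    return records, samples


# --- pedigree and BED -----------------------------------------------------


@dataclass(frozen=True)
class Trio:
    family: str
    child: str
    father: str
    mother: str


def read_ped(path) -> list[Trio]:
    """Read a 6-column pedigree TSV; returns the complete trios it defines."""
    trios = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"pedigree line with {len(parts)} columns")
            fam, iid, father, mother = parts[0], parts[1], parts[2], parts[3]
            if father != "0" and mother != "0":
                trios.append(Trio(fam, iid, father, mother))
    return trios


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    with open(path, "w") as out:
        for iv in intervals:
            out.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> list[tuple]:
    rows = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return rows
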