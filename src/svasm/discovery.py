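"""Variant discovery from assembly-versus-reference alignment blocks.

Each scaffold of a de novo assembly is traversed 5'->3'.  Differences seen
inside one alignment block (mismatches, small indels) and breakpoints
between adjacent blocks (large indels, simultaneous gaps, inversions,
translocations) become categorized raw variants.  Unaligned scaffold
sequence is grouped into clipped (partially aligned scaffold) and nomadic
(fully unaligned scaffold) segments -- the novel-sequence candidates --
and uncovered reference intervals become inter-/intra-scaffold gaps.

Variants are left-normalized, complex variants re-anchored by
align-gap-excise realignment, and per-individual call sets merged into one
bi-allelic multi-sample population call set keyed on the exact normalized
(chrom, pos, ref, alt) tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .align import Scoring, DEFAULT_SCORING, age_realign
from .io_formats import AlignmentBlock, SequenceRecord, VcfRecord, revcomp

__all__ = [
    "RawVariant",
    "UnalignedSegment",
    "ReferenceGap",
    "CATEGORIES",
    "SEQUENCE_RESOLVED",
    "call_within_block",
    "call_between_blocks",
    "split_simultaneous_gap",
    "normalize_variant",
    "classify_unaligned",
    "find_reference_gaps",
    "merge_population",
    "find_double_hits",
    "discover_individual",
]

CATEGORIES = frozenset(
    {
        "SNP",
        "deletion",
        "insertion",
        "inversion",
        "simultaneous_gap",
        "block_substitution",
        "length_asymmetric_replacement",
        "intra_translocation",
        "inter_translocation",
        "no_solution",
    }
)

#: categories with full allele sequences, eligible for VCF emission/merging
SEQUENCE_RESOLVED = frozenset(
    {
        "SNP",
        "deletion",
        "insertion",
        "inversion",
        "block_substitution",
        "length_asymmetric_replacement",
        "simultaneous_gap",
    }
)

_SVTYPE = {
    "SNP": "SNP",
    "deletion": "DEL",
    "insertion": "INS",
    "inversion": "INV",
    "block_substitution": "REPL",
    "length_asymmetric_replacement": "REPL",
    "simultaneous_gap": "REPL",
}


@dataclass
class RawVariant:
    """One categorized difference between a scaffold and the reference.

    ``ref_pos`` is 0-based; for anchored representations it points at the
    shared anchor base.  Breakpoint-only categories (translocations,
    no_solution) carry the junction base as both alleles and are excluded
    from VCF merging.
    """

    category: str
    ref_chrom: str
    ref_pos: int
    ref_allele: str
    alt_allele: str
    scaffold: str
    scaffold_pos: int
    sample: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def key(self) -> tuple:
        return (self.ref_chrom, self.ref_pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class UnalignedSegment:
    scaffold: str
    start: int
    end: int
    kind: str  # clipped | nomadic


@dataclass(frozen=True)
class ReferenceGap:
    chrom: str
    start: int
    end: int
    kind: str  # inter_scaffold | intra_scaffold


def _check_projection(block: AlignmentBlock, ref: SequenceRecord, query: SequenceRecord):
    ref_seg = block.ref_row.replace("-", "")
    if ref.sequence[block.ref_start : block.ref_end] != ref_seg:
        raise ValueError(
            f"block does not project onto reference {block.ref_chrom}:"
            f"{block.ref_start}-{block.ref_end}"
        )
    if block.query_forward_segment() != query.sequence[
        block.query_start : block.query_end
    ]:
        raise ValueError(f"block does not project onto scaffold {block.query_scaffold}")


def _anchored(
    ref_seq: str, chrom: str, del_start: int, del_end: int, inserted: str
) -> tuple[int, str, str]:
    """VCF-style anchored alleles for replacing ref[del_start:del_end] with
    ``inserted``; anchors on the left, falling back to a right anchor at the
    chromosome start."""
    if del_start > 0:
        pos = del_start - 1
        return pos, ref_seq[pos:del_end], ref_seq[pos] + inserted
    if del_end < len(ref_seq):
        return del_start, ref_seq[del_start : del_end + 1], inserted + ref_seq[del_end]
    raise ValueError("variant spans the whole reference sequence")


def call_within_block(
    block: AlignmentBlock, ref: SequenceRecord, query: SequenceRecord
) -> list[RawVariant]:
    """SNPs and small indels from the gapped columns of one block.

    Columns containing N in either row are not called.  The column scan is
    vectorized: only mismatch/gap columns are visited individually.
    """
    _check_projection(block, ref, query)
    sample = ""
    variants: list[RawVariant] = []
    rrow, qrow = block.ref_row, block.query_row
    r = np.frombuffer(rrow.encode(), dtype=np.uint8)
    q = np.frombuffer(qrow.encode(), dtype=np.uint8)
    dash = ord("-")
    r_is_base = r != dash
    q_is_base = q != dash
    # ref/query bases consumed through each column (inclusive)
    rcount = np.cumsum(r_is_base)
    qcount = np.cumsum(q_is_base)
    interesting = np.nonzero(~r_is_base | ~q_is_base | (r != q))[0]

    def fwd_qpos(q_offset: int) -> int:
        if block.strand == "+":
            return block.query_start + q_offset
        return block.query_end - 1 - q_offset

    ncols = len(rrow)
    k = 0
    while k < len(interesting):
        i = int(interesting[k])
        rbase, qbase = rrow[i], qrow[i]
        if rbase != "-" and qbase != "-":  # mismatch column
            if rbase != "N" and qbase != "N":
                variants.append(
                    RawVariant(
                        "SNP",
                        block.ref_chrom,
                        block.ref_start + int(rcount[i]) - 1,
                        rbase,
                        qbase,
                        block.query_scaffold,
                        fwd_qpos(int(qcount[i]) - 1),
                        sample,
                    )
                )
            k += 1
            continue
        # extend a gap run over consecutive interesting columns of same kind
        j = i
        if qbase == "-":
            while j < ncols and qrow[j] == "-" and rrow[j] != "-":
                j += 1
            del_start = block.ref_start + int(rcount[i]) - 1
            del_end = del_start + (j - i)
            pos, ref_allele, alt_allele = _anchored(
                ref.sequence, block.ref_chrom, del_start, del_end, ""
            )
            if "N" not in ref_allele:
                variants.append(
                    RawVariant(
                        "deletion",
                        block.ref_chrom,
                        pos,
                        ref_allele,
                        alt_allele,
                        block.query_scaffold,
                        fwd_qpos(max(int(qcount[i]) - 1, 0)),
                        sample,
                    )
                )
        else:
            while j < ncols and rrow[j] == "-" and qrow[j] != "-":
                j += 1
            inserted = qrow[i:j]
            rpos = block.ref_start + int(rcount[i])
            pos, ref_allele, alt_allele = _anchored(
                ref.sequence, block.ref_chrom, rpos, rpos, inserted
            )
            if "N" not in ref_allele and "N" not in inserted:
                variants.append(
                    RawVariant(
                        "insertion",
                        block.ref_chrom,
                        pos,
                        ref_allele,
                        alt_allele,
                        block.query_scaffold,
                        fwd_qpos(int(qcount[i])),
                        sample,
                    )
                )
        while k < len(interesting) and interesting[k] < j:
            k += 1
    return variants


def _trim_query_start(block: AlignmentBlock, nbases: int) -> tuple[int, int]:
    """(ref_boundary, query_boundary) after trimming ``nbases`` query bases
    from the scaffold-forward start of the block."""
    if nbases == 0:
        if block.strand == "+":
            return block.ref_start, block.query_start
        return block.ref_end, block.query_start
    cols = zip(block.ref_row, block.query_row)
    if block.strand == "-":
        cols = zip(block.ref_row[::-1], block.query_row[::-1])
    consumed_q = consumed_r = 0
    for rbase, qbase in cols:
        if consumed_q >= nbases:
            break
        if qbase != "-":
            consumed_q += 1
        if rbase != "-":
            consumed_r += 1
    if block.strand == "+":
        return block.ref_start + consumed_r, block.query_start + nbases
    return block.ref_end - consumed_r, block.query_start + nbases


def call_between_blocks(
    blocks: Sequence[AlignmentBlock],
    ref_seqs: dict[str, SequenceRecord],
    query: SequenceRecord,
    sample: str = "",
    overlap_tolerance: int = 20,
    max_gap: int = 50_000,
) -> list[RawVariant]:
    """Classify the breakpoints between adjacent blocks of one scaffold.

    Blocks must be sorted by scaffold-forward coordinate.  A strand flip of
    an interior block flanked by same-strand blocks on the same chromosome
    is an inversion; chromosome changes are inter-chromosomal and
    non-collinear same-chromosome pairs intra-chromosomal translocation
    breakpoints; patterns that remain unresolvable are ``no_solution``.
    """
    variants: list[RawVariant] = []
    inversion_mid: set[int] = set()
    for k in range(1, len(blocks) - 1):
        a, b, c = blocks[k - 1], blocks[k], blocks[k + 1]
        if (
            a.strand == c.strand != b.strand
            and a.ref_chrom == b.ref_chrom == c.ref_chrom
        ):
            lo, hi = (a, c) if a.strand == "+" else (c, a)
            if lo.ref_end <= b.ref_start + overlap_tolerance and b.ref_end <= (
                hi.ref_start + overlap_tolerance
            ):
                ref_seq = ref_seqs[b.ref_chrom].sequence
                seg = ref_seq[b.ref_start : b.ref_end]
                pos, ref_allele, alt_allele = _anchored(
                    ref_seq, b.ref_chrom, b.ref_start, b.ref_end, revcomp(seg)
                )
                variants.append(
                    RawVariant(
                        "inversion",
                        b.ref_chrom,
                        pos,
                        ref_allele,
                        alt_allele,
                        b.query_scaffold,
                        b.query_start,
                        sample,
                    )
                )
                inversion_mid.add(k)

    for k in range(len(blocks) - 1):
        left, right = blocks[k], blocks[k + 1]
        junction_q = left.query_end
        qgap = right.query_start - left.query_end

        def breakpoint(category: str, reason: str = "") -> RawVariant:
            chrom = left.ref_chrom
            ref_seq = ref_seqs[chrom].sequence
            pos = min(left.ref_end, len(ref_seq)) - 1
            base = ref_seq[pos]
            return RawVariant(
                category, chrom, pos, base, base, left.query_scaffold,
                junction_q, sample, reason=reason,
            )

        if left.ref_chrom != right.ref_chrom:
            variants.append(breakpoint("inter_translocation"))
            continue
        if left.strand != right.strand:
            if k + 1 in inversion_mid or k in inversion_mid:
                continue  # clean inversion boundary already called
            variants.append(breakpoint("no_solution", "unpaired strand flip"))
            continue

        if qgap < -overlap_tolerance:
            variants.append(breakpoint("no_solution", "query overlap beyond tolerance"))
            continue
        overlap = max(-qgap, 0)
        ref_b, query_b = _trim_query_start(right, overlap)
        qgap = max(qgap, 0)
        ref_seq = ref_seqs[left.ref_chrom].sequence
        if left.strand == "+":
            rgap = ref_b - left.ref_end
            gap_lo = left.ref_end
        else:  # scaffold-forward order walks backwards along the reference
            rgap = left.ref_start - ref_b
            gap_lo = ref_b
        if rgap < -overlap_tolerance:
            variants.append(breakpoint("intra_translocation"))
            continue
        rgap = max(rgap, 0)
        if rgap == 0 and qgap == 0:
            continue
        if rgap > max_gap or qgap > max_gap:
            variants.append(breakpoint("no_solution", "gap exceeds size cap"))
            continue
        q_seg = query.sequence[left.query_end : left.query_end + qgap]
        if left.strand == "-":
            q_seg = revcomp(q_seg)
        if "N" in q_seg or "N" in ref_seq[gap_lo : gap_lo + rgap]:
            continue  # assembly/reference gap, not a variant call
        if qgap > 0 and rgap == 0:
            category = "insertion"
        elif rgap > 0 and qgap == 0:
            category = "deletion"
        else:
            category = "simultaneous_gap"
        pos, ref_allele, alt_allele = _anchored(
            ref_seq, left.ref_chrom, gap_lo, gap_lo + rgap, q_seg
        )
        variants.append(
            RawVariant(
                category,
                left.ref_chrom,
                pos,
                ref_allele,
                alt_allele,
                left.query_scaffold,
                junction_q,
                sample,
            )
        )
    return variants


def split_simultaneous_gap(v: RawVariant) -> RawVariant:
    """Refine a simultaneous gap into a block substitution (equal interior
    lengths) or a length-asymmetric replacement."""
    if v.category != "simultaneous_gap":
        raise ValueError("not a simultaneous gap")
    ref_int, alt_int = v.ref_allele[1:], v.alt_allele[1:]
    if ref_int == alt_int:
        raise ValueError("identical interiors: not a variant")
    category = (
        "block_substitution"
        if len(ref_int) == len(alt_int)
        else "length_asymmetric_replacement"
    )
    return replace(v, category=category)


def normalize_variant(
    v: RawVariant,
    ref: SequenceRecord,
    scoring: Scoring = DEFAULT_SCORING,
) -> RawVariant:
    """Left-shift indels and re-anchor complex variants; idempotent.

    Complex (replacement) alleles are first passed through align-gap-excise
    realignment to strip shared flanks, then all variants are shifted to
    their leftmost equivalent representation.
    """
    if v.category not in SEQUENCE_RESOLVED or v.category in ("SNP", "inversion"):
        return v
    ref_seq = ref.sequence
    pos, ra, aa = v.ref_pos, v.ref_allele, v.alt_allele
    if v.category in (
        "simultaneous_gap",
        "block_substitution",
        "length_asymmetric_replacement",
    ) and len(ra) >= 2 and len(aa) >= 2:
        i1, i2, j1, j2, exc_r, exc_a = age_realign(ra, aa, scoring)
        if exc_r != exc_a and (exc_r or exc_a):
            pos2, ra2, aa2 = pos + i1, ra[i1:i2], aa[j1:j2]
            if not ra2 or not aa2:
                pos2, ra2, aa2 = _anchored(ref_seq, v.ref_chrom, pos + i1, pos + i2, aa[j1:j2])
            pos, ra, aa = pos2, ra2, aa2
    # right-trim with left extension, then left-trim: canonical left alignment
    while True:
        if len(ra) > 1 and len(aa) > 1 and ra[-1] == aa[-1]:
            ra, aa = ra[:-1], aa[:-1]
        elif ra[-1] == aa[-1] and pos > 0:
            pos -= 1
            ra = ref_seq[pos] + ra[:-1]
            aa = ref_seq[pos] + aa[:-1]
        else:
            break
    while len(ra) > 1 and len(aa) > 1 and ra[0] == aa[0]:
        ra, aa = ra[1:], aa[1:]
        pos += 1
    category = v.category
    if category in ("simultaneous_gap", "block_substitution", "length_asymmetric_replacement"):
        if len(ra) == 1 and len(aa) > 1:
            category = "insertion"
        elif len(aa) == 1 and len(ra) > 1:
            category = "deletion"
        elif len(ra) == len(aa) == 1:
            category = "SNP"
    if ref_seq[pos : pos + len(ra)] != ra:
        raise ValueError("normalized allele no longer matches the reference")
    return replace(v, category=category, ref_pos=pos, ref_allele=ra, alt_allele=aa)


def classify_unaligned(
    scaffold: SequenceRecord,
    blocks: Sequence[AlignmentBlock],
    min_length: int = 100,
) -> list[UnalignedSegment]:
    """Unaligned spans of one scaffold, as clipped or nomadic segments."""
    blocks = [b for b in blocks if b.query_scaffold == scaffold.name]
    if not blocks:
        if len(scaffold) >= min_length:
            return [UnalignedSegment(scaffold.name, 0, len(scaffold), "nomadic")]
        return []
    spans = sorted((b.query_start, b.query_end) for b in blocks)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    segments = []
    cursor = 0
    for s, e in merged + [[len(scaffold), len(scaffold)]]:
        if s - cursor >= min_length:
            segments.append(UnalignedSegment(scaffold.name, cursor, s, "clipped"))
        cursor = max(cursor, e)
    return segments


def find_reference_gaps(
    blocks: Sequence[AlignmentBlock], ref_lengths: dict[str, int]
) -> list[ReferenceGap]:
    """Reference intervals uncovered by one individual's assembly.

    A gap whose two flanking covered intervals come from the same scaffold
    is intra-scaffold; gaps flanked by different scaffolds or by a
    chromosome end are inter-scaffold.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in ref_lengths}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(
            (b.ref_start, b.ref_end, b.query_scaffold)
        )
    gaps: list[ReferenceGap] = []
    for chrom, length in ref_lengths.items():
        spans = sorted(by_chrom.get(chrom, []))
        merged: list[list] = []
        for s, e, scaf in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].add(scaf)
            else:
                merged.append([s, e, {scaf}])
        cursor = 0
        left_scafs: set | None = None
        for s, e, scafs in merged + [[length, length, None]]:
            if s > cursor:
                right_scafs = scafs
                if (
                    left_scafs is not None
                    and right_scafs is not None
                    and left_scafs & right_scafs
                ):
                    kind = "intra_scaffold"
                else:
                    kind = "inter_scaffold"
                gaps.append(ReferenceGap(chrom, cursor, s, kind))
            cursor = max(cursor, e)
            if scafs is not None:
                left_scafs = scafs
    return gaps


def merge_population(
    per_individual: dict[str, Sequence[RawVariant]],
    prior_records: Sequence[VcfRecord] = (),
) -> list[VcfRecord]:
    """Collapse identical normalized variants across individuals into one
    bi-allelic multi-sample record each; distinct overlapping alleles stay
    separate records.  Carrier presence is recorded as GT ``1/.``."""
    merged: dict[tuple, VcfRecord] = {}
    order: list[str] = list(per_individual.keys())

    def add_carrier(key: tuple, category: str, carriers: Iterable[str]) -> None:
        chrom, pos0, ra, aa = key
        rec = merged.get(key)
        if rec is None:
            rec = VcfRecord(
                chrom=chrom,
                pos=pos0 + 1,
                id=".",
                ref_allele=ra,
                alt_allele=aa,
                filter=".",
                info={
                    "SVTYPE": _SVTYPE[category],
                    "CATEGORY": category,
                    "SVLEN": len(aa) - len(ra),
                    "NCARRIER": 0,
                },
                samples={},
            )
            merged[key] = rec
        for sample in carriers:
            if sample not in order:
                order.append(sample)
            if sample not in rec.samples:
                rec.samples[sample] = {"GT": "1/."}
                rec.info["NCARRIER"] += 1

    for sample, variants in per_individual.items():
        for v in variants:
            if v.category not in SEQUENCE_RESOLVED:
                continue
            add_carrier(v.key(), v.category, [sample or v.sample])
    for rec in prior_records:
        key = (rec.chrom, rec.pos - 1, rec.ref_allele, rec.alt_allele)
        add_carrier(key, rec.info.get("CATEGORY", "insertion"), rec.samples.keys())

    records = sorted(merged.values(), key=VcfRecord.sort_key)
    by_pos: dict[tuple, str] = {}
    for rec in records:
        anchor = by_pos.setdefault((rec.chrom, rec.pos), rec.ref_allele)
        short, long_ = sorted((anchor, rec.ref_allele), key=len)
        if not long_.startswith(short):
            raise ValueError(
                f"conflicting reference alleles at {rec.chrom}:{rec.pos}"
            )
    for rec in records:
        for sample in order:
            rec.samples.setdefault(sample, {"GT": "./."})
    return records


def find_double_hits(records: Sequence[VcfRecord], threshold: int = 2) -> list[VcfRecord]:
    """Variants with identical breakpoints independently assembled in at
    least ``threshold`` individuals; flagged as positive-training candidates."""
    flagged = []
    for rec in records:
        if rec.info.get("NCARRIER", 0) >= threshold:
            rec.info["DOUBLEHIT"] = True
            flagged.append(rec)
    return flagged


def discover_individual(
    blocks: Sequence[AlignmentBlock],
    ref_records: Sequence[SequenceRecord],
    scaffold_records: Sequence[SequenceRecord],
    sample: str,
    min_unaligned: int = 100,
    overlap_tolerance: int = 20,
    max_gap: int = 50_000,
) -> tuple[list[RawVariant], list[UnalignedSegment], list[ReferenceGap]]:
    """Run the full per-individual discovery pass over one alignment set."""
    refs = {r.name: r for r in ref_records}
    scaffolds = {s.name: s for s in scaffold_records}
    variants: list[RawVariant] = []
    segments: list[UnalignedSegment] = []
    by_scaffold: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_scaffold.setdefault(b.query_scaffold, []).append(b)
    for name, scaffold in scaffolds.items():
        scaf_blocks = sorted(
            by_scaffold.get(name, ()), key=lambda b: (b.query_start, b.query_end)
        )
        for b in scaf_blocks:
            variants.extend(
                replace(v, sample=sample)
                for v in call_within_block(b, refs[b.ref_chrom], scaffold)
            )
        variants.extend(
            call_between_blocks(
                scaf_blocks, refs, scaffold, sample, overlap_tolerance, max_gap
            )
        )
        segments.extend(classify_unaligned(scaffold, scaf_blocks, min_unaligned))
    out: list[RawVariant] = []
    for v in variants:
        if v.category == "simultaneous_gap":
            v = split_simultaneous_gap(v)
        if v.category in SEQUENCE_RESOLVED:
            v = normalize_variant(v, refs[v.ref_chrom])
        out.append(v)
    gaps = find_reference_gaps(blocks, {r.name: len(r) for r in ref_records})
    return out, segments, gaps
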