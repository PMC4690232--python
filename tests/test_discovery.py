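import random
from dataclasses import replace

import pytest

from oracles import column_scan_variants, leftmost_indel_position
from svasm.discovery import (
    RawVariant,
    call_between_blocks,
    call_within_block,
    classify_unaligned,
    find_double_hits,
    find_reference_gaps,
    merge_population,
    normalize_variant,
    split_simultaneous_gap,
)
from svasm.io_formats import AlignmentBlock, SequenceRecord, revcomp


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def block_from_rows(ref_seq, query_seq, ref_row, query_row, ref_start=0, q_start=0):
    return AlignmentBlock(
        "chr1", ref_start, ref_start + len(ref_row) - ref_row.count("-"),
        "scaf", q_start, q_start + len(query_row) - query_row.count("-"),
        "+", ref_row, query_row,
    )


class TestWithinBlock:
    def test_single_mismatch_is_a_snp(self):
        ref = SequenceRecord("chr1", "ACGT")
        qry = SequenceRecord("scaf", "ACTT")
        (v,) = call_within_block(block_from_rows(None, None, "ACGT", "ACTT"), ref, qry)
        assert (v.category, v.ref_pos, v.ref_allele, v.alt_allele) == ("SNP", 2, "G", "T")

    def test_reference_only_column_is_a_deletion(self):
        ref = SequenceRecord("chr1", "ACGGT")
        qry = SequenceRecord("scaf", "ACGT")
        (v,) = call_within_block(
            block_from_rows(None, None, "ACGGT", "AC-GT"), ref, qry
        )
        assert v.category == "deletion"
        assert (v.ref_pos, v.ref_allele, v.alt_allele) == (1, "CG", "C")

    def test_inconsistent_block_rejected(self):
        ref = SequenceRecord("chr1", "TTTT")
        qry = SequenceRecord("scaf", "ACGT")
        with pytest.raises(ValueError):
            call_within_block(block_from_rows(None, None, "ACGT", "ACGT"), ref, qry)

    @pytest.mark.parametrize("trial", range(10))
    def test_random_blocks_match_column_scan_oracle(self, trial):
        rng = random.Random(500 + trial)
        ref_seq = random_seq(rng, 400)
        # mutate a copy: substitutions plus short indels, then rebuild rows
        ref_row, q_row = [], []
        i = 10
        ref_row.append(ref_seq[:10]); q_row.append(ref_seq[:10])
        while i < 390:
            roll = rng.random()
            if roll < 0.05:
                base = rng.choice([b for b in "ACGT" if b != ref_seq[i]])
                ref_row.append(ref_seq[i]); q_row.append(base); i += 1
            elif roll < 0.08:
                k = rng.randint(1, 4)
                ref_row.append(ref_seq[i : i + k]); q_row.append("-" * k); i += k
            elif roll < 0.11:
                k = rng.randint(1, 4)
                ins = random_seq(rng, k)
                ref_row.append("-" * k); q_row.append(ins)
            else:
                ref_row.append(ref_seq[i]); q_row.append(ref_seq[i]); i += 1
        ref_row.append(ref_seq[i:400]); q_row.append(ref_seq[i:400])
        ref_row, q_row = "".join(ref_row), "".join(q_row)
        query_seq = q_row.replace("-", "")
        block = block_from_rows(None, None, ref_row, q_row)
        ref = SequenceRecord("chr1", ref_seq)
        qry = SequenceRecord("scaf", query_seq)
        variants = call_within_block(block, ref, qry)
        expected = column_scan_variants(ref_row, q_row, 0)
        got = []
        for v in variants:
            if v.category == "SNP":
                got.append(("snp", v.ref_pos, v.ref_allele, v.alt_allele))
            elif v.category == "deletion":
                got.append(("del", v.ref_pos + 1, v.ref_allele[1:], ""))
            else:
                got.append(("ins", v.ref_pos + 1, "", v.alt_allele[1:]))
        assert got == expected


class TestBetweenBlocks:
    def _ref(self, rng, n=3_000):
        return SequenceRecord("chr1", random_seq(rng, n))

    def test_reference_gap_is_a_deletion(self):
        rng = random.Random(1)
        ref = self._ref(rng)
        q_left, q_right = ref.sequence[:1000], ref.sequence[1500:2500]
        query = SequenceRecord("scaf", q_left + q_right)
        blocks = [
            block_from_rows(None, None, q_left, q_left, 0, 0),
            AlignmentBlock("chr1", 1500, 2500, "scaf", 1000, 2000, "+", q_right, q_right),
        ]
        (v,) = call_between_blocks(blocks, {"chr1": ref}, query)
        assert v.category == "deletion"
        assert len(v.ref_allele) - len(v.alt_allele) == 500
        assert v.ref_pos == 999

    def test_strand_flip_of_interior_block_is_an_inversion(self):
        rng = random.Random(2)
        ref = self._ref(rng)
        seg = ref.sequence[1000:1600]
        query_seq = ref.sequence[:1000] + revcomp(seg) + ref.sequence[1600:]
        query = SequenceRecord("scaf", query_seq)
        a = ref.sequence[:1000]
        c = ref.sequence[1600:]
        blocks = [
            AlignmentBlock("chr1", 0, 1000, "scaf", 0, 1000, "+", a, a),
            AlignmentBlock("chr1", 1000, 1600, "scaf", 1000, 1600, "-", seg, seg),
            AlignmentBlock("chr1", 1600, 3000, "scaf", 1600, 3000, "+", c, c),
        ]
        variants = call_between_blocks(blocks, {"chr1": ref}, query)
        inversions = [v for v in variants if v.category == "inversion"]
        assert len(inversions) == 1
        v = inversions[0]
        assert v.alt_allele[1:] == revcomp(seg)

    def test_chromosome_change_is_inter_translocation(self):
        rng = random.Random(3)
        ref1, ref2 = self._ref(rng), SequenceRecord("chr2", random_seq(rng, 3000))
        a, b = ref1.sequence[:1000], ref2.sequence[:1000]
        query = SequenceRecord("scaf", a + b)
        blocks = [
            AlignmentBlock("chr1", 0, 1000, "scaf", 0, 1000, "+", a, a),
            AlignmentBlock("chr2", 0, 1000, "scaf", 1000, 2000, "+", b, b),
        ]
        (v,) = call_between_blocks(blocks, {"chr1": ref1, "chr2": ref2}, query)
        assert v.category == "inter_translocation"

    def test_large_query_overlap_is_no_solution(self):
        rng = random.Random(4)
        ref = self._ref(rng)
        a = ref.sequence[:1000]
        b = ref.sequence[1000:2000]
        query = SequenceRecord("scaf", a + b)
        blocks = [
            AlignmentBlock("chr1", 0, 1000, "scaf", 0, 1000, "+", a, a),
            # claims query 900..1900: 100 bp overlap, beyond tolerance
            AlignmentBlock("chr1", 1000, 2000, "scaf", 900, 1900, "+", b, b),
        ]
        (v,) = call_between_blocks(blocks, {"chr1": ref}, query)
        assert v.category == "no_solution"
        assert "overlap" in v.reason


class TestSimultaneousGap:
    def _gap_variant(self, ref_int, alt_int):
        return RawVariant(
            "simultaneous_gap", "chr1", 9, "A" + ref_int, "A" + alt_int, "s", 0, ""
        )

    def test_equal_interiors_are_block_substitution(self):
        v = split_simultaneous_gap(self._gap_variant("ACGT", "TTTT"))
        assert v.category == "block_substitution"

    def test_unequal_interiors_are_length_asymmetric(self):
        v = split_simultaneous_gap(self._gap_variant("AC", "TTTTT"))
        assert v.category == "length_asymmetric_replacement"

    def test_identical_interiors_rejected(self):
        with pytest.raises(ValueError):
            split_simultaneous_gap(self._gap_variant("ACGT", "ACGT"))


class TestNormalize:
    def test_homopolymer_deletion_left_shifts(self):
        ref = SequenceRecord("chr1", "ATTTTC")
        v = RawVariant("deletion", "chr1", 3, "TT", "T", "s", 0, "")
        n = normalize_variant(v, ref)
        assert (n.ref_pos, n.ref_allele, n.alt_allele) == (0, "AT", "A")

    def test_idempotent(self):
        ref = SequenceRecord("chr1", "ATTTTC")
        v = RawVariant("deletion", "chr1", 3, "TT", "T", "s", 0, "")
        once = normalize_variant(v, ref)
        assert normalize_variant(once, ref) == once

    @pytest.mark.parametrize("trial", range(15))
    def test_position_matches_exhaustive_shift_oracle(self, trial):
        rng = random.Random(600 + trial)
        # repetitive context makes shifts likely
        unit = random_seq(rng, rng.randint(1, 3))
        ref_seq = random_seq(rng, 20) + unit * 10 + random_seq(rng, 20)
        pos = rng.randint(5, len(ref_seq) - 10)
        if rng.random() < 0.5:
            size = rng.randint(1, 4)
            deleted, inserted = ref_seq[pos : pos + size], ""
            category = "deletion"
        else:
            deleted, inserted = "", unit * rng.randint(1, 3)
            category = "insertion"
        anchor = pos - 1
        v = RawVariant(
            category, "chr1", anchor,
            ref_seq[anchor : pos + len(deleted)],
            ref_seq[anchor] + inserted,
            "s", 0, "",
        )
        n = normalize_variant(v, SequenceRecord("chr1", ref_seq))
        expected = leftmost_indel_position(ref_seq, pos, deleted, inserted)
        # the anchored representation sits one base left of the edit
        assert n.ref_pos + 1 == expected or (expected == 0 and n.ref_pos == 0)

    def test_allele_content_preserved(self):
        ref = SequenceRecord("chr1", "GGATATATATCC")
        v = RawVariant("deletion", "chr1", 7, "TAT", "T", "s", 0, "")
        n = normalize_variant(v, ref)
        applied_orig = ref.sequence[:8] + "T"[1:] + ref.sequence[10:]
        applied_norm = (
            ref.sequence[: n.ref_pos] + n.alt_allele
            + ref.sequence[n.ref_pos + len(n.ref_allele) :]
        )
        assert applied_norm == ref.sequence[:7] + "T" + ref.sequence[10:]


class TestUnalignedAndGaps:
    def test_scaffold_without_blocks_is_nomadic(self):
        scaffold = SequenceRecord("s", "A" * 500)
        (seg,) = classify_unaligned(scaffold, [])
        assert (seg.kind, seg.start, seg.end) == ("nomadic", 0, 500)

    def test_unaligned_tail_is_clipped(self):
        scaffold = SequenceRecord("s", "A" * 3_000)
        row = "A" * 1_000
        block = AlignmentBlock("chr1", 0, 1000, "s", 0, 1000, "+", row, row)
        (seg,) = classify_unaligned(scaffold, [block])
        assert (seg.kind, seg.start, seg.end) == ("clipped", 1000, 3000)

    def test_segments_and_blocks_tile_the_scaffold(self):
        scaffold = SequenceRecord("s", "A" * 5_000)
        rows = ["A" * 800, "A" * 600]
        blocks = [
            AlignmentBlock("chr1", 0, 800, "s", 1000, 1800, "+", rows[0], rows[0]),
            AlignmentBlock("chr1", 900, 1500, "s", 3000, 3600, "+", rows[1], rows[1]),
        ]
        segments = classify_unaligned(scaffold, blocks, min_length=1)
        covered = sorted(
            [(b.query_start, b.query_end) for b in blocks]
            + [(s.start, s.end) for s in segments]
        )
        cursor = 0
        for s, e in covered:
            assert s == cursor
            cursor = e
        assert cursor == len(scaffold)

    def test_intra_vs_inter_scaffold_gaps(self):
        row = "A" * 100
        same = [
            AlignmentBlock("chr1", 0, 100, "s1", 0, 100, "+", row, row),
            AlignmentBlock("chr1", 200, 300, "s1", 100, 200, "+", row, row),
            AlignmentBlock("chr1", 400, 500, "s2", 0, 100, "+", row, row),
        ]
        gaps = find_reference_gaps(same, {"chr1": 500})
        assert [(g.start, g.end, g.kind) for g in gaps] == [
            (100, 200, "intra_scaffold"),
            (300, 400, "inter_scaffold"),
        ]

    def test_gaps_and_coverage_partition_the_reference(self):
        rng = random.Random(9)
        row = "A" * 50
        blocks = []
        for _ in range(20):
            start = rng.randrange(0, 950)
            blocks.append(
                AlignmentBlock("chr1", start, start + 50, f"s{rng.randrange(5)}",
                               0, 50, "+", row, row)
            )
        gaps = find_reference_gaps(blocks, {"chr1": 1_000})
        covered = set()
        for b in blocks:
            covered.update(range(b.ref_start, b.ref_end))
        gap_positions = set()
        for g in gaps:
            gap_positions.update(range(g.start, g.end))
        assert covered | gap_positions == set(range(1_000))
        assert covered & gap_positions == set()


class TestMergeAndDoubleHits:
    def _variant(self, sample, pos=9, alt="A"):
        return RawVariant("deletion", "chr1", pos, "AT", alt, "s", 0, sample)

    def test_identical_deletion_collapses_across_individuals(self):
        per = {s: [self._variant(s)] for s in ("i1", "i2", "i3")}
        (rec,) = merge_population(per)
        assert rec.info["NCARRIER"] == 3
        assert rec.samples["i2"]["GT"] == "1/."

    def test_distinct_alts_stay_separate_biallelic_records(self):
        per = {
            "i1": [RawVariant("SNP", "chr1", 5, "A", "C", "s", 0, "i1")],
            "i2": [RawVariant("SNP", "chr1", 5, "A", "G", "s", 0, "i2")],
        }
        records = merge_population(per)
        assert len(records) == 2
        assert {r.alt_allele for r in records} == {"C", "G"}

    def test_merge_is_associative(self, small_study):
        truth = small_study.truth_records()
        a, b, c = truth[::3], truth[1::3], truth[2::3]

        def keyset(records):
            return {
                (r.sort_key(), frozenset(
                    s for s, f in r.samples.items() if "1" in f.get("GT", "")
                ))
                for r in records
            }

        left = merge_population({}, prior_records=merge_population(
            {}, prior_records=list(a) + list(b)) + list(c))
        right = merge_population({}, prior_records=list(a) + merge_population(
            {}, prior_records=list(b) + list(c)))
        assert keyset(left) == keyset(right)

    def test_double_hit_flagging_matches_tabulation(self):
        per = {
            "i1": [self._variant("i1"), self._variant("i1", pos=99)],
            "i2": [self._variant("i2")],
            "i3": [self._variant("i3", pos=199)],
        }
        records = merge_population(per)
        flagged = find_double_hits(records, threshold=2)
        counts = {}
        for sample, variants in per.items():
            for v in variants:
                counts[v.key()] = counts.get(v.key(), 0) + 1
        expected = {k for k, n in counts.items() if n >= 2}
        assert {(r.chrom, r.pos - 1, r.ref_allele, r.alt_allele) for r in flagged} == expected
        assert all(r.info.get("DOUBLEHIT") for r in flagged)

    def test_single_carrier_not_flagged(self):
        records = merge_population({"i1": [self._variant("i1")]})
        assert find_double_hits(records, threshold=2) == []
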