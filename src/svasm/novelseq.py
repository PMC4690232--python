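"""Novel sequence detection: inserted alleles and nomadic scaffolds absent
from the reference.

Inserted alleles longer than 100 bp whose interior does not align well to
the reference (identity >= 0.95 and aligned ratio >= 0.95 both failing)
are novel sequence insertions, anchored at their breakpoint.  Unaligned
scaffold segments (clipped/nomadic) longer than 100 bp are kept as nomadic
novel sequence only when corroborated by high similarity (>= 0.95/0.95) to
at least one other genome, which screens out contamination and assembly
artifacts.  Every novel sequence can be linked to its closest relative
among a set of named assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import Scoring, DEFAULT_SCORING, identity_and_aligned_ratio, local_align
from .io_formats import SequenceRecord
from .discovery import UnalignedSegment

__all__ = [
    "NovelSequence",
    "find_novel_insertions",
    "classify_nomadic",
    "link_closest_relative",
]

MIN_NOVEL_LENGTH = 100
SIMILARITY_THRESHOLD = 0.95


@dataclass
class NovelSequence:
    kind: str  # novel_insertion | nomadic
    sequence: str
    anchor_chrom: str | None = None
    anchor_pos: int | None = None  # 0-based breakpoint for insertions
    source: str = ""
    closest_relative: str | None = None
    closest_identity: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.sequence) <= MIN_NOVEL_LENGTH:
            raise ValueError("novel sequences must be longer than 100 bp")
        if self.kind == "novel_insertion" and self.anchor_chrom is None:
            raise ValueError("insertions must carry an anchor")
        if self.kind == "nomadic" and self.anchor_chrom is not None:
            raise ValueError("nomadic sequences carry no anchor")


def find_novel_insertions(
    insertions,
    reference: Sequence[SequenceRecord],
    min_length: int = MIN_NOVEL_LENGTH,
    threshold: float = SIMILARITY_THRESHOLD,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[NovelSequence]:
    """Insertion alleles whose interior fails to align to the reference at
    identity >= threshold and aligned ratio >= threshold."""
    out = []
    for v in insertions:
        interior = v.alt_allele[len(v.ref_allele):] if v.alt_allele.startswith(
            v.ref_allele
        ) else v.alt_allele[1:]
        if len(interior) <= min_length:
            continue
        known = False
        for chrom in reference:
            identity, ratio = identity_and_aligned_ratio(
                interior, chrom.sequence, scoring
            )
            if identity >= threshold and ratio >= threshold:
                known = True
                break
        if not known:
            out.append(
                NovelSequence(
                    "novel_insertion",
                    interior,
                    anchor_chrom=v.ref_chrom,
                    anchor_pos=v.ref_pos,
                    source=v.sample,
                )
            )
    return out


def classify_nomadic(
    segments: Sequence[UnalignedSegment],
    scaffolds: dict[str, SequenceRecord],
    other_genomes: Sequence[SequenceRecord],
    min_length: int = MIN_NOVEL_LENGTH,
    threshold: float = SIMILARITY_THRESHOLD,
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[list[NovelSequence], list[tuple[UnalignedSegment, str]]]:
    """Partition unaligned segments into corroborated nomadic novel
    sequences and discards with a machine-readable reason."""
    kept: list[NovelSequence] = []
    discarded: list[tuple[UnalignedSegment, str]] = []
    for seg in segments:
        seq = scaffolds[seg.scaffold].sequence[seg.start : seg.end]
        if len(seq) <= min_length:
            discarded.append((seg, "too short"))
            continue
        if not other_genomes:
            discarded.append((seg, "no corroborating genome"))
            continue
        supported = False
        for genome in other_genomes:
            identity, ratio = identity_and_aligned_ratio(seq, genome.sequence, scoring)
            if identity >= threshold and ratio >= threshold:
                supported = True
                break
        if supported:
            kept.append(NovelSequence("nomadic", seq, source=seg.scaffold))
        else:
            discarded.append((seg, "no similar sequence in corroborating genomes"))
    return kept, discarded


def link_closest_relative(
    novel: NovelSequence,
    assemblies: dict[str, Sequence[SequenceRecord]],
    floor_identity: float = 0.5,
    floor_coverage: float = 0.5,
    scoring: Scoring = DEFAULT_SCORING,
) -> NovelSequence:
    """Attach the assembly whose best local alignment to the novel sequence
    has the highest identity (ties break by assembly name order).

    Hits covering less than ``floor_coverage`` of the novel sequence are
    ignored (short spurious local hits are trivially high-identity), and no
    link is made below the identity floor.
    """
    best_name, best_identity = None, 0.0
    for name in sorted(assemblies):
        for rec in assemblies[name]:
            hit = local_align(novel.sequence, rec.sequence, scoring)
            if hit.aligned_ratio < floor_coverage:
                continue
            if hit.identity > best_identity + 1e-12:
                best_name, best_identity = name, hit.identity
    if best_name is not None and best_identity >= floor_identity:
        novel.closest_relative = best_name
        novel.closest_identity = best_identity
    return novel
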