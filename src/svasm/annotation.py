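"""Ancestral-state and formation-mechanism characterization of variants.

Ancestral state: the reference and alternative alleles (each with 500 bp
flanks) are compared against one or more outgroup genomes by local
alignment.  The allele with substantially higher identity and aligned
ratio (both > 0.95) to an outgroup is taken as ancestral, which labels the
*event*: if the longer allele is ancestral the variant arose by deletion
of sequence, if the shorter allele is ancestral it arose by insertion.
Both alleles passing in every outgroup is 'Common' (e.g. a variant inside
a repeat), alignable-but-below-threshold is 'NA', nothing alignable is
'NONE', and outgroups disagreeing between Deletion and Insertion is
'Conflict'.  Discovery-time insertion/deletion labels are then rectified
to match the ancestral event.

Formation mechanism: variants >= 50 bp are tested in the precedence order
CCC -> TEI -> VNTR -> NAHR -> NHR (first match wins); shorter variants are
'UNSURE' and variants matching no rule 'NA'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import Scoring, DEFAULT_SCORING, identity_and_aligned_ratio, local_align
from .io_formats import SequenceRecord

__all__ = [
    "AncestralCall",
    "MechanismCall",
    "build_alleles",
    "classify_ancestral",
    "rectify_type",
    "classify_mechanism",
]

ANCESTRAL_STATES = ("NONE", "NA", "Common", "Deletion", "Insertion", "Conflict")
MECHANISMS = ("VNTR", "TEI", "NAHR", "NHR", "CCC", "UNSURE", "NA")


@dataclass
class AncestralCall:
    state: str
    #: outgroup name -> {"ref": (identity, ratio), "alt": (identity, ratio)}
    measurements: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )


@dataclass
class MechanismCall:
    mechanism: str
    repeat_name: str = ""
    breakpoint_identity: float = float("nan")
    microhomology: int = 0


def build_alleles(
    variant,
    reference: SequenceRecord,
    flank: int = 500,
) -> tuple[str, str]:
    """Reference and alternative allele sequences with up to ``flank`` bp of
    reference context on each side (truncated at sequence ends)."""
    ref_seq = reference.sequence
    start = variant.ref_pos
    end = start + len(variant.ref_allele)
    if start < 0 or end > len(ref_seq):
        raise ValueError("variant outside the reference sequence")
    if ref_seq[start:end] != variant.ref_allele:
        raise ValueError("variant REF does not match the reference")
    left = ref_seq[max(start - flank, 0) : start]
    right = ref_seq[end : end + flank]
    return left + variant.ref_allele + right, left + variant.alt_allele + right


def _passes(measure: tuple[float, float], id_thr: float, ratio_thr: float) -> bool:
    return measure[0] > id_thr and measure[1] > ratio_thr


def classify_ancestral(
    ref_allele_seq: str,
    alt_allele_seq: str,
    outgroups: dict[str, str] | list[SequenceRecord],
    id_thr: float = 0.95,
    ratio_thr: float = 0.95,
    alignable_floor: float = 0.5,
    scoring: Scoring = DEFAULT_SCORING,
) -> AncestralCall:
    """Ancestral-state call from per-outgroup allele similarity.

    An allele is *alignable* to an outgroup when both identity and aligned
    ratio reach ``alignable_floor``, and *ancestral-grade* when both exceed
    the 0.95 thresholds.
    """
    if not outgroups:
        raise ValueError("at least one outgroup is required")
    if isinstance(outgroups, list):
        outgroups = {rec.name: rec.sequence for rec in outgroups}
    longer_is_ref = len(ref_allele_seq) >= len(alt_allele_seq)
    measurements: dict[str, dict[str, tuple[float, float]]] = {}
    votes: list[str] = []
    any_alignable = False
    common_everywhere = True
    for name, seq in outgroups.items():
        m_ref = identity_and_aligned_ratio(ref_allele_seq, seq, scoring)
        m_alt = identity_and_aligned_ratio(alt_allele_seq, seq, scoring)
        measurements[name] = {"ref": m_ref, "alt": m_alt}
        for m in (m_ref, m_alt):
            if m[0] >= alignable_floor and m[1] >= alignable_floor:
                any_alignable = True
        ref_pass = _passes(m_ref, id_thr, ratio_thr)
        alt_pass = _passes(m_alt, id_thr, ratio_thr)
        longer_pass, shorter_pass = (
            (ref_pass, alt_pass) if longer_is_ref else (alt_pass, ref_pass)
        )
        if not (ref_pass and alt_pass):
            common_everywhere = False
        if longer_pass and not shorter_pass:
            votes.append("Deletion")
        elif shorter_pass and not longer_pass:
            votes.append("Insertion")
    if not any_alignable:
        return AncestralCall("NONE", measurements)
    if common_everywhere:
        return AncestralCall("Common", measurements)
    if "Deletion" in votes and "Insertion" in votes:
        return AncestralCall("Conflict", measurements)
    if "Deletion" in votes:
        return AncestralCall("Deletion", measurements)
    if "Insertion" in votes:
        return AncestralCall("Insertion", measurements)
    return AncestralCall("NA", measurements)


def rectify_type(variant, ancestral: AncestralCall):
    """Flip insertion/deletion labels that contradict the ancestral event.

    A discovered insertion whose ancestral state says the (longer, assembly)
    allele is ancestral was really a deletion from the ancestral sequence,
    and symmetrically.  The discovery-time category is kept in a provenance
    attribute ``orig_category``.
    """
    category = variant.category
    final = category
    if category == "insertion" and ancestral.state == "Deletion":
        final = "deletion"
    elif category == "deletion" and ancestral.state == "Insertion":
        final = "insertion"
    out = replace(variant, category=final)
    out.orig_category = category
    return out


def _repeat_hit(
    variant_seq: str,
    library: list[SequenceRecord],
    repeat_class: str,
    min_identity: float,
    min_coverage: float,
    scoring: Scoring,
) -> str | None:
    """Name of the best library record of the given class whose local hit
    covers the variant sequence well enough, else None."""
    best_name, best_score = None, 0.0
    for rec in library:
        if f"class={repeat_class}" not in rec.name and repeat_class not in rec.name:
            continue
        hit = local_align(variant_seq, rec.sequence, scoring)
        coverage = (hit.query_end - hit.query_start) / len(variant_seq)
        if hit.identity >= min_identity and coverage >= min_coverage:
            if hit.score > best_score:
                best_name, best_score = rec.name, hit.score
    return best_name


def classify_mechanism(
    variant_seq: str,
    left_flank: str,
    right_flank: str,
    repeat_library: list[SequenceRecord] | None = None,
    min_sv: int = 50,
    flank_window: int = 200,
    repeat_identity: float = 0.80,
    repeat_coverage: float = 0.80,
    nahr_identity: float = 0.85,
    min_microhomology: int = 2,
    scoring: Scoring = DEFAULT_SCORING,
) -> MechanismCall:
    """Formation mechanism of one inserted/deleted allele interior.

    Tests, in order: CCC (variant exactly equals the same-length sequence
    immediately 3' of the right breakpoint), TEI (mobile-element library
    hit), VNTR (simple-repeat library hit), NAHR (reciprocal breakpoint
    flank identity > 0.85), NHR (microhomology of >= 2 bp between the
    variant and a flank).
    """
    if not variant_seq:
        raise ValueError("empty variant sequence")
    if len(variant_seq) < min_sv:
        return MechanismCall("UNSURE")
    if right_flank[: len(variant_seq)] == variant_seq:
        return MechanismCall("CCC")
    library = repeat_library or []
    hit = _repeat_hit(
        variant_seq, library, "mobile_element", repeat_identity, repeat_coverage, scoring
    )
    if hit:
        return MechanismCall("TEI", repeat_name=hit)
    hit = _repeat_hit(
        variant_seq, library, "simple_repeat", repeat_identity, repeat_coverage, scoring
    )
    if hit:
        return MechanismCall("VNTR", repeat_name=hit)
    left = left_flank[-flank_window:]
    right = right_flank[:flank_window]
    if left and right:
        aln = local_align(left, right, scoring)
        span = aln.query_end - aln.query_start
        if aln.identity > nahr_identity and span >= min(
            50, len(left), len(right)
        ):
            return MechanismCall("NAHR", breakpoint_identity=aln.identity)
    mh = 0
    limit = min(len(variant_seq) - 1, len(right_flank))
    while mh < limit and variant_seq[mh] == right_flank[mh]:
        mh += 1
    mh_left = 0
    limit = min(len(variant_seq) - 1, len(left_flank))
    while (
        mh_left < limit
        and variant_seq[-1 - mh_left] == left_flank[-1 - mh_left]
    ):
        mh_left += 1
    micro = max(mh, mh_left)
    if micro >= min_microhomology:
        return MechanismCall("NHR", microhomology=micro)
    return MechanismCall("NA")
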