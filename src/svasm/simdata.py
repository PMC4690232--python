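"""Synthetic-data generator with known ground truth for every pipeline input.

The generator emulates a population assembly study: a random reference
genome seeded with repeat structure (Alu-like 300 bp and LINE-like 6 kb
mobile-element copies, tandem-repeat arrays, tandem duplications and
homologous segment pairs), planted variants of every discoverable category
whose sequence context encodes a formation mechanism (TEI = repeat copy,
VNTR = tandem-unit count change, CCC = copy of the adjacent 3' sequence,
NAHR = deletion between homologous flanks, NHR = junction microhomology),
trio-structured genotypes drawn under Hardy-Weinberg equilibrium with
Mendelian transmission, error-free split alignment blocks for each
individual's assembled haplotype, binomially sampled read intensities,
two-class recalibration features, and outgroup genomes carrying the
designated ancestral allele plus background divergence.

Everything is deterministic given the seed.  The generator does not
emulate read-level sequencing error or assembler behaviour beyond block
and gap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import RawVariant, normalize_variant, split_simultaneous_gap
from .io_formats import (
    AlignmentBlock,
    SequenceRecord,
    Trio,
    VcfRecord,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "PlantedVariant",
    "SimulatedStudy",
    "simulate_reference",
    "simulate_study",
    "simulate_intensities",
    "simulate_features",
    "simulate_outgroups",
    "simulate_genotype_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Defaults mirror a ten-trio population study with SV size peaks at the
    mobile-element scales (~300 bp and ~6 kb); chromosome sizes are desk
    scale.
    """

    seed: int = 0
    chrom_count: int = 2
    chrom_length: int = 1_000_000
    gc: float = 0.41
    # repeat structure per chromosome
    alu_copies: int = 20
    line_copies: int = 2
    tandem_arrays: int = 15
    tandem_duplications: int = 12
    nahr_pairs: int = 6
    repeat_divergence: float = 0.03
    # planted variant counts (whole genome)
    n_snp: int = 400
    n_small_indel: int = 250
    n_tei_del: int = 30
    n_tei_ins: int = 30
    n_vntr: int = 40
    n_ccc: int = 40
    n_nahr: int = 12
    n_nhr: int = 60
    n_inversion: int = 20
    n_block_substitution: int = 40
    n_replacement: int = 40
    min_spacing: int = 600
    # population structure
    trio_count: int = 10
    # read model
    depth: int = 30
    mismap_noise: float = 0.02
    neither_rate: float = 0.05
    # outgroups: per-outgroup background divergence (primate-like ladder)
    outgroup_divergence: tuple[float, ...] = (0.013, 0.017, 0.018, 0.064)
    # ancestral designation: P(alt allele is ancestral) per event type
    p_alt_ancestral_deletion: float = 0.28
    p_alt_ancestral_insertion: float = 0.09
    # contamination / nomadic structure
    contaminant_scaffolds: int = 3
    nomadic_scaffolds: int = 3
    nomadic_length: int = 2_000


@dataclass
class PlantedVariant:
    """Ground truth for one planted event.

    ``start``/``end`` delimit the replaced reference interval (0-based,
    half-open; ``start == end`` for insertions) and ``alt_seq`` the
    replacement on the alternative haplotype.  ``norm`` is the canonical
    left-aligned anchored representation the pipeline emits.
    """

    id: str
    chrom: str
    start: int
    end: int
    alt_seq: str
    category: str
    mechanism: str  # expected mechanism call; UNSURE below 50 bp
    ancestral: str  # "ref" or "alt"
    af: float
    norm: RawVariant | None = None
    genotypes: dict[str, int] = field(default_factory=dict)  # sample -> alt dose
    hap1: set[str] = field(default_factory=set)  # samples whose assembly carries it

    @property
    def size(self) -> int:
        return max(self.end - self.start, len(self.alt_seq))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    reference: list[SequenceRecord]
    repeat_table: pd.DataFrame
    repeat_library: list[SequenceRecord]
    events: list[PlantedVariant]
    samples: list[str]
    trios: list[Trio]
    contaminants: list[SequenceRecord]
    nomadics: list[SequenceRecord]
    other_genome: SequenceRecord

    def truth_records(self) -> list[VcfRecord]:
        """The planted variants as sorted multi-sample VCF records."""
        records = []
        svtype = {
            "SNP": "SNP",
            "deletion": "DEL",
            "insertion": "INS",
            "inversion": "INV",
            "block_substitution": "REPL",
            "length_asymmetric_replacement": "REPL",
        }
        for ev in self.events:
            v = ev.norm
            gts = {0: "0/0", 1: "0/1", 2: "1/1"}
            records.append(
                VcfRecord(
                    chrom=v.ref_chrom,
                    pos=v.ref_pos + 1,
                    id=ev.id,
                    ref_allele=v.ref_allele,
                    alt_allele=v.alt_allele,
                    info={
                        "SVTYPE": svtype[v.category],
                        "CATEGORY": v.category,
                        "SVLEN": len(v.alt_allele) - len(v.ref_allele),
                        "MECHANISM": ev.mechanism,
                    },
                    samples={
                        s: {"GT": gts[ev.genotypes[s]]} for s in self.samples
                    },
                )
            )
        return sorted(records, key=VcfRecord.sort_key)

    def haplotype(self, sample: str, chrom: str) -> str:
        ref = next(r for r in self.reference if r.name == chrom).sequence
        events = sorted(
            (e for e in self.events if e.chrom == chrom and sample in e.hap1),
            key=lambda e: e.start,
        )
        parts = []
        cursor = 0
        for ev in events:
            parts.append(ref[cursor : ev.start])
            parts.append(ev.alt_seq)
            cursor = ev.end
        parts.append(ref[cursor:])
        return "".join(parts)

    def scaffold_records(self, sample: str) -> list[SequenceRecord]:
        return [
            SequenceRecord(f"{sample}.{r.name}", self.haplotype(sample, r.name))
            for r in self.reference
        ]

    def alignment_blocks(self, sample: str, split_size: int = 50) -> list[AlignmentBlock]:
        return simulate_assembly_alignment(self, sample, split_size)

    def genotype_table(self) -> dict[str, dict[str, str]]:
        names = {0: "RR", 1: "RA", 2: "AA"}
        return {
            ev.id: {s: names[d] for s, d in ev.genotypes.items()}
            for ev in self.events
        }


# --- reference ------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


class _Occupancy:
    """Non-overlapping interval bookkeeping with a spacing buffer."""

    def __init__(self, length: int, spacing: int):
        self.length = length
        self.spacing = spacing
        self.intervals: list[tuple[int, int]] = []

    def free(self, start: int, end: int) -> bool:
        if start < self.spacing or end > self.length - self.spacing:
            return False
        for s, e in self.intervals:
            if start < e + self.spacing and s < end + self.spacing:
                return False
        return True

    def claim(self, start: int, end: int) -> None:
        self.intervals.append((start, end))

    def place(self, rng: np.random.Generator, length: int, tries: int = 300,
              predicate=None):
        """Claim a random free interval of ``length``; ``predicate(start)``
        can veto a candidate before it is claimed."""
        for _ in range(tries):
            start = int(rng.integers(self.spacing, self.length - length - self.spacing))
            if self.free(start, start + length) and (
                predicate is None or predicate(start)
            ):
                self.claim(start, start + length)
                return start
        return None


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Random genome with planted repeat families.

    Returns (records, repeat_table, repeat_library, occupancy_per_chrom).
    The repeat table lists every planted structure with its coordinates;
    the library holds the consensus sequences tagged by repeat class for
    mechanism classification.
    """
    rng = rng or np.random.default_rng(config.seed)
    alu = _random_seq(rng, 300, config.gc)
    line = _random_seq(rng, 6_000, config.gc)
    units = [_random_seq(rng, int(rng.integers(3, 12))) for _ in range(5)]
    library = [
        SequenceRecord("ALU.class=mobile_element", alu),
        SequenceRecord("LINE.class=mobile_element", line),
    ] + [
        # long enough for a local hit to cover any planted expansion
        SequenceRecord(f"TR{i}.class=simple_repeat", u * (3_000 // len(u) + 1))
        for i, u in enumerate(units)
    ]
    records: list[SequenceRecord] = []
    rows = []
    occupancy: dict[str, _Occupancy] = {}
    for c in range(config.chrom_count):
        chrom = f"chr{c + 1}"
        seq = np.frombuffer(
            _random_seq(rng, config.chrom_length, config.gc).encode(), dtype=np.uint8
        ).copy()
        occ = _Occupancy(config.chrom_length, config.min_spacing)

        def plant(payload: str, family: str, name: str, **extra):
            start = occ.place(rng, len(payload))
            if start is None:
                return None
            seq[start : start + len(payload)] = np.frombuffer(
                payload.encode(), dtype=np.uint8
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + len(payload),
                    "family": family,
                    "name": name,
                    **extra,
                }
            )
            return start

        for i in range(config.alu_copies):
            plant(_mutate(rng, alu, config.repeat_divergence), "alu", f"{chrom}.alu{i}")
        for i in range(config.line_copies):
            plant(
                _mutate(rng, line, config.repeat_divergence), "line", f"{chrom}.line{i}"
            )
        for i in range(config.tandem_arrays):
            unit = units[int(rng.integers(len(units)))]
            count = int(rng.integers(20, 60))
            plant(unit * count, "tandem", f"{chrom}.tr{i}", unit_len=len(unit), count=count)
        for i in range(config.tandem_duplications):
            copy = _random_seq(rng, int(rng.integers(60, 200)), config.gc)
            plant(copy + copy, "tandem_dup", f"{chrom}.dup{i}", copy_len=len(copy))
        for i in range(config.nahr_pairs):
            homolog = _random_seq(rng, 200, config.gc)
            middle = _random_seq(rng, int(rng.integers(300, 1_500)), config.gc)
            payload = homolog + middle + _mutate(rng, homolog, 0.08)
            plant(payload, "nahr_pair", f"{chrom}.nahr{i}", copy_len=200)
        records.append(SequenceRecord(chrom, seq.tobytes().decode()))
        occupancy[chrom] = occ
    table = pd.DataFrame(rows)
    return records, table, library, occupancy


# --- variant planting -----------------------------------------------------


def _boundary_distinct(payload: str, seg: str) -> str:
    """Force the payload to differ from ``seg`` at both boundaries so the
    planted coordinates are already the canonical representation."""
    first = next(b for b in "ACGT" if b != seg[0])
    last = next(b for b in "ACGT" if b != seg[-1])
    if payload[0] == seg[0]:
        payload = first + payload[1:]
    if payload[-1] == seg[-1]:
        payload = payload[:-1] + last
    return payload


def _canonical(ev: PlantedVariant, ref: SequenceRecord) -> RawVariant:
    """Canonical left-aligned representation of a planted event."""
    ref_seq = ref.sequence
    if ev.category == "SNP":
        raw = RawVariant(
            "SNP", ev.chrom, ev.start, ref_seq[ev.start], ev.alt_seq, "", 0, ""
        )
        return raw
    if ev.category == "inversion":
        seg = ref_seq[ev.start : ev.end]
        pos = ev.start - 1
        return RawVariant(
            "inversion",
            ev.chrom,
            pos,
            ref_seq[pos : ev.end],
            ref_seq[pos] + revcomp(seg),
            "",
            0,
            "",
        )
    pos = ev.start - 1
    ref_allele = ref_seq[pos : ev.end]
    alt_allele = ref_seq[pos] + ev.alt_seq
    if len(ref_allele) > 1 and len(alt_allele) > 1 and ev.start != ev.end:
        category = "simultaneous_gap"
    elif len(ref_allele) > len(alt_allele):
        category = "deletion"
    else:
        category = "insertion"
    raw = RawVariant(category, ev.chrom, pos, ref_allele, alt_allele, "", 0, "")
    if raw.category == "simultaneous_gap":
        raw = split_simultaneous_gap(raw)
    return normalize_variant(raw, ref)


def _draw_genotypes(
    rng: np.random.Generator, q: float, trios: list[Trio]
) -> tuple[dict[str, int], set[str]]:
    """Mendelian-consistent genotypes: parental haplotypes under HWE, child
    haplotypes by transmission.  Returns (dose per sample, hap-1 carriers)."""
    doses: dict[str, int] = {}
    hap1: set[str] = set()
    for trio in trios:
        f1, f2 = rng.random() < q, rng.random() < q
        m1, m2 = rng.random() < q, rng.random() < q
        cf = f1 if rng.random() < 0.5 else f2
        cm = m1 if rng.random() < 0.5 else m2
        doses[trio.father] = int(f1) + int(f2)
        doses[trio.mother] = int(m1) + int(m2)
        doses[trio.child] = int(cf) + int(cm)
        if f1:
            hap1.add(trio.father)
        if m1:
            hap1.add(trio.mother)
        if cf:
            hap1.add(trio.child)
    return doses, hap1


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the full study: reference, planted variants, genotypes."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    records, table, library, occupancy = simulate_reference(config, rng)
    refs = {r.name: r for r in records}
    chroms = list(refs)
    trios = [
        Trio(f"fam{i}", f"child{i}", f"father{i}", f"mother{i}")
        for i in range(config.trio_count)
    ]
    samples = [s for t in trios for s in (t.father, t.mother, t.child)]

    events: list[PlantedVariant] = []
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"sv{counter[0]:05d}"

    def add_event(chrom, start, end, alt_seq, category, mechanism, size_hint=None):
        ref_seq = refs[chrom].sequence
        if start <= 0 or end >= len(ref_seq):
            return False
        if ref_seq[start:end] == alt_seq:
            return False
        if category in ("deletion", "insertion"):
            p_alt = (
                config.p_alt_ancestral_deletion
                if category == "deletion"
                else config.p_alt_ancestral_insertion
            )
            ancestral = "alt" if rng.random() < p_alt else "ref"
        else:
            ancestral = "ref"
        q = float(rng.uniform(0.1, 0.9))
        doses, hap1 = _draw_genotypes(rng, q, trios)
        if not hap1:  # every planted event must be assembled at least once;
            # forcing a parental haplotype keeps the trios Mendelian-consistent
            trio = trios[int(rng.integers(len(trios)))]
            forced = trio.father if rng.random() < 0.5 else trio.mother
            doses[forced] = max(doses[forced], 1)
            hap1 = {forced}
        ev = PlantedVariant(
            next_id(), chrom, start, end, alt_seq, category, mechanism,
            ancestral, q, genotypes=doses, hap1=hap1,
        )
        ev.norm = _canonical(ev, refs[chrom])
        events.append(ev)
        return True

    def place(chrom, length):
        return occupancy[chrom].place(rng, max(length, 1))

    def rand_chrom() -> str:
        return chroms[int(rng.integers(len(chroms)))]

    # SNPs
    placed = 0
    while placed < config.n_snp:
        chrom = rand_chrom()
        start = place(chrom, 1)
        if start is None:
            break
        ref_base = refs[chrom].sequence[start]
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        if add_event(chrom, start, start + 1, alt, "SNP", ""):
            placed += 1

    # small indels (1-10 bp; mechanisms below 50 bp are UNSURE)
    placed = 0
    while placed < config.n_small_indel:
        chrom = rand_chrom()
        size = int(rng.integers(1, 11))
        deletion = rng.random() < 0.5
        start = place(chrom, size if deletion else 1)
        if start is None:
            break
        if deletion:
            ok = add_event(chrom, start, start + size, "", "deletion", "UNSURE")
        else:
            ok = add_event(
                chrom, start, start, _random_seq(rng, size, config.gc),
                "insertion", "UNSURE",
            )
        placed += ok

    # TEI deletions: remove a planted mobile-element copy exactly
    mobile = table[table.family.isin(["alu", "line"])].sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    for row in mobile.itertuples():
        if sum(e.mechanism == "TEI" and not e.alt_seq for e in events) >= config.n_tei_del:
            break
        add_event(row.chrom, row.start, row.end, "", "deletion", "TEI")

    # TEI insertions: insert a fresh mutated consensus copy
    alu_seq = library[0].sequence
    line_seq = library[1].sequence
    placed = 0
    while placed < config.n_tei_ins:
        chrom = rand_chrom()
        start = place(chrom, 1)
        if start is None:
            break
        consensus = line_seq if rng.random() < 0.1 else alu_seq
        payload = _mutate(rng, consensus, config.repeat_divergence)
        placed += add_event(chrom, start, start, payload, "insertion", "TEI")

    # VNTR: change the unit count of a tandem array.  Contractions remove
    # more than half the units and expansions at least double the array so
    # the copy-count-change (CCC) exact-copy test cannot fire first.
    arrays = table[table.family == "tandem"].sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    placed = 0
    for row in arrays.itertuples():
        if placed >= config.n_vntr:
            break
        unit_len, count = int(row.unit_len), int(row.count)
        if rng.random() < 0.5:  # contraction of the trailing units
            k = int(count // 2 + 1 + rng.integers(0, count // 4 + 1))
            k = min(k, count - 2)
            if k * unit_len < 50:
                continue
            start = int(row.end) - k * unit_len
            placed += add_event(row.chrom, start, int(row.end), "", "deletion", "VNTR")
        else:  # expansion: insert at least a full array's worth of units
            k = count + int(rng.integers(1, count))
            if k * unit_len < 50:
                continue
            unit = refs[row.chrom].sequence[int(row.start) : int(row.start) + unit_len]
            placed += add_event(
                row.chrom, int(row.end), int(row.end), unit * k, "insertion", "VNTR"
            )

    # CCC: interior exactly equal to the adjacent 3' sequence
    dups = table[table.family == "tandem_dup"].sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    placed = 0
    for row in dups.itertuples():  # delete the first copy of a planted dup
        if placed >= config.n_ccc // 2:
            break
        copy_len = int(row.copy_len)
        placed += add_event(
            row.chrom, int(row.start), int(row.start) + copy_len, "", "deletion", "CCC"
        )
    placed = 0
    while placed < config.n_ccc - config.n_ccc // 2:
        chrom = rand_chrom()
        size = int(rng.integers(50, 200))
        start = place(chrom, size)
        if start is None:
            break
        ref_seq = refs[chrom].sequence
        placed += add_event(
            chrom, start, start, ref_seq[start : start + size], "insertion", "CCC"
        )

    # NAHR: delete the spacer between two planted homologous segments
    pairs = table[table.family == "nahr_pair"].sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    placed = 0
    for row in pairs.itertuples():
        if placed >= config.n_nahr:
            break
        copy_len = int(row.copy_len)
        placed += add_event(
            row.chrom,
            int(row.start) + copy_len,
            int(row.end) - copy_len,
            "",
            "deletion",
            "NAHR",
        )

    # NHR: random indels >= 50 bp with a 2+ bp junction microhomology.
    # Deletions search the reference for a spot where the deleted interior
    # naturally starts with the bases that follow it (and stays leftmost);
    # insertions construct the microhomology in the payload.
    placed = 0
    while placed < config.n_nhr:
        chrom = rand_chrom()
        size = int(round(50 * 10 ** (rng.random() * 1.6)))
        deletion = rng.random() < 0.5
        ref_seq = refs[chrom].sequence
        if deletion:

            def has_microhomology(start: int) -> bool:
                seg = ref_seq[start : start + size]
                follow = ref_seq[start + size : start + size + 2]
                return seg[:2] == follow and seg[-1] != ref_seq[start - 1]

            start = occupancy[chrom].place(rng, size, predicate=has_microhomology)
            if start is None:
                break
            placed += add_event(chrom, start, start + size, "", "deletion", "NHR")
        else:
            start = place(chrom, 1)
            if start is None:
                break
            mh = int(rng.integers(2, 9))
            core = _random_seq(rng, size - mh, config.gc)
            follow = ref_seq[start : start + mh]
            # keep the representation leftmost and the microhomology exact
            last = [b for b in "ACGT" if b != ref_seq[start - 1]]
            mid = [b for b in "ACGT" if b != ref_seq[start + mh]]
            payload = follow + mid[0] + core[1:-1] + last[0]
            placed += add_event(chrom, start, start, payload, "insertion", "NHR")

    # inversions
    placed = 0
    while placed < config.n_inversion:
        chrom = rand_chrom()
        size = int(rng.integers(100, 1_000))
        start = place(chrom, size)
        if start is None:
            break
        seg = refs[chrom].sequence[start : start + size]
        if revcomp(seg) == seg:
            continue
        placed += add_event(chrom, start, start + size, revcomp(seg), "inversion", "")

    # block substitutions (equal interior lengths) and length-asymmetric
    # replacements; interiors differ at both boundaries so the planted
    # coordinates are already canonical
    placed = 0
    while placed < config.n_block_substitution:
        chrom = rand_chrom()
        size = int(rng.integers(4, 60))
        start = place(chrom, size)
        if start is None:
            break
        seg = refs[chrom].sequence[start : start + size]
        payload = _boundary_distinct(_random_seq(rng, size, config.gc), seg)
        placed += add_event(
            chrom, start, start + size, payload, "block_substitution",
            "UNSURE" if size < 50 else "NA",
        )
    placed = 0
    while placed < config.n_replacement:
        chrom = rand_chrom()
        ref_len = int(rng.integers(2, 300))
        alt_len = int(rng.integers(2, 300))
        if ref_len == alt_len:
            continue
        start = place(chrom, ref_len)
        if start is None:
            break
        seg = refs[chrom].sequence[start : start + ref_len]
        payload = _boundary_distinct(_random_seq(rng, alt_len, config.gc), seg)
        placed += add_event(
            chrom, start, start + ref_len, payload, "length_asymmetric_replacement",
            "UNSURE" if max(ref_len, alt_len) < 50 else "NA",
        )

    contaminants = [
        SequenceRecord(f"contaminant{i}", _random_seq(rng, config.nomadic_length, 0.55))
        for i in range(config.contaminant_scaffolds)
    ]
    nomadic_seqs = [
        _random_seq(rng, config.nomadic_length, config.gc)
        for _ in range(config.nomadic_scaffolds)
    ]
    nomadics = [
        SequenceRecord(f"nomadic{i}", seq) for i, seq in enumerate(nomadic_seqs)
    ]
    other_parts = []
    for seq in nomadic_seqs:
        other_parts.append(_random_seq(rng, 3_000, config.gc))
        other_parts.append(_mutate(rng, seq, 0.01))
    other_parts.append(_random_seq(rng, 3_000, config.gc))
    other_genome = SequenceRecord("other_assembly", "".join(other_parts))

    events.sort(key=lambda e: (e.chrom, e.start))
    return SimulatedStudy(
        config=config,
        reference=records,
        repeat_table=table,
        repeat_library=library,
        events=events,
        samples=samples,
        trios=trios,
        contaminants=contaminants,
        nomadics=nomadics,
        other_genome=other_genome,
    )


# --- alignment emission ---------------------------------------------------


def simulate_assembly_alignment(
    study: SimulatedStudy, sample: str, split_size: int = 50
) -> list[AlignmentBlock]:
    """Error-free split alignment blocks of one individual's assembly.

    SNPs and indels shorter than ``split_size`` are represented inside
    blocks as mismatch/gap columns; larger indels, all replacements and
    inversions split the alignment into separate blocks with the
    corresponding reference/query gap or strand-flip structure.
    """
    blocks: list[AlignmentBlock] = []
    for ref in study.reference:
        chrom = ref.name
        scaffold = f"{sample}.{chrom}"
        events = sorted(
            (e for e in study.events if e.chrom == chrom and sample in e.hap1),
            key=lambda e: e.start,
        )
        ref_rows: list[str] = []
        q_rows: list[str] = []
        block_r = block_q = 0
        r_cur = q_cur = 0

        def flush(r_end: int, q_end: int) -> None:
            nonlocal block_r, block_q
            if r_end > block_r and q_end > block_q:
                rrow = "".join(ref_rows)
                qrow = "".join(q_rows)
                blocks.append(
                    AlignmentBlock(
                        ref_chrom=chrom,
                        ref_start=block_r,
                        ref_end=r_end,
                        query_scaffold=scaffold,
                        query_start=block_q,
                        query_end=q_end,
                        strand="+",
                        ref_row=rrow,
                        query_row=qrow,
                        score=float(r_end - block_r),
                    )
                )
            ref_rows.clear()
            q_rows.clear()

        for ev in events:
            seg = ref.sequence[r_cur : ev.start]
            ref_rows.append(seg)
            q_rows.append(seg)
            r_cur, q_cur = ev.start, q_cur + len(seg)
            rlen, alen = ev.end - ev.start, len(ev.alt_seq)
            within = (
                ev.category in ("SNP", "deletion", "insertion")
                and max(rlen, alen) < split_size
                and min(rlen, alen) == (1 if ev.category == "SNP" else 0)
            )
            if within:
                if ev.category == "SNP":
                    ref_rows.append(ref.sequence[ev.start])
                    q_rows.append(ev.alt_seq)
                elif rlen:  # deletion: reference-only columns
                    ref_rows.append(ref.sequence[ev.start : ev.end])
                    q_rows.append("-" * rlen)
                else:  # insertion: query-only columns
                    ref_rows.append("-" * alen)
                    q_rows.append(ev.alt_seq)
            elif ev.category == "inversion":
                flush(r_cur, q_cur)
                seg = ref.sequence[ev.start : ev.end]
                blocks.append(
                    AlignmentBlock(
                        ref_chrom=chrom,
                        ref_start=ev.start,
                        ref_end=ev.end,
                        query_scaffold=scaffold,
                        query_start=q_cur,
                        query_end=q_cur + rlen,
                        strand="-",
                        ref_row=seg,
                        query_row=seg,
                        score=float(rlen),
                    )
                )
                block_r, block_q = ev.end, q_cur + rlen
            else:  # between-block gap structure
                flush(r_cur, q_cur)
                block_r, block_q = ev.end, q_cur + alen
            r_cur, q_cur = ev.end, q_cur + alen
        seg = ref.sequence[r_cur:]
        ref_rows.append(seg)
        q_rows.append(seg)
        flush(len(ref.sequence), q_cur + len(seg))
    return blocks


# --- read intensities -----------------------------------------------------


def simulate_intensities(
    genotypes: dict[str, dict[str, str]],
    depth: int = 30,
    mismap_noise: float = 0.02,
    neither_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial read sampling per locus per individual.

    Heterozygotes draw allele-supporting reads from Binomial(n, 0.5);
    homozygotes leak ``mismap_noise`` of reads to the other allele; a
    ``neither_rate`` fraction of reads supports neither allele.
    """
    rng = np.random.default_rng(seed)
    p_alt = {"RR": mismap_noise, "RA": 0.5, "AA": 1.0 - mismap_noise}
    rows = []
    for vid, per_sample in genotypes.items():
        for sample, gt in per_sample.items():
            n = int(rng.poisson(depth))
            if n == 0 or gt not in p_alt:
                rows.append((vid, sample, 0, 0, 0))
                continue
            neither = rng.binomial(n, neither_rate)
            informative = n - neither
            a = rng.binomial(informative, p_alt[gt])
            rows.append((vid, sample, informative - a, a, n))
    return pd.DataFrame(
        rows, columns=["variant_id", "sample", "r_count", "a_count", "depth"]
    )


def simulate_genotype_cohort(
    n: int, af: float, seed: int = 0
) -> dict[str, str]:
    """Hardy-Weinberg genotypes for ``n`` unrelated individuals."""
    rng = np.random.default_rng(seed)
    doses = rng.binomial(2, af, size=n)
    names = {0: "RR", 1: "RA", 2: "AA"}
    return {f"ind{i}": names[int(d)] for i, d in enumerate(doses)}


# --- recalibration features ----------------------------------------------

_FEATURE_MODEL = {
    # feature: (positive mean, negative mean, sd)
    "gap_ratio": (0.02, 0.25, 0.05),
    "alt_depth": (15.0, 4.0, 4.0),
    "neither_depth": (1.0, 8.0, 2.5),
    "misalign_prob": (0.02, 0.30, 0.06),
    "align_score": (800.0, 300.0, 150.0),
    "local_identity": (0.99, 0.90, 0.02),
    "scaffold_position": (0.5, 0.5, 0.25),
    "proper_read_ratio": (0.95, 0.60, 0.08),
    "improper_read_ratio": (0.05, 0.40, 0.08),
}


def simulate_features(
    n_positive: int,
    n_negative: int,
    seed: int = 0,
    separation: float = 1.0,
) -> pd.DataFrame:
    """Two-class feature vectors from distinct multivariate normals.

    ``separation`` scales the class mean difference (0 = identical
    classes).  Ratio-like features are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, count in ((1, n_positive), (0, n_negative)):
        for i in range(count):
            row = {"variant_id": f"{'pos' if label else 'neg'}{i}", "label": label}
            for name, (mu_pos, mu_neg, sd) in _FEATURE_MODEL.items():
                center = mu_neg + (mu_pos - mu_neg) * (
                    separation if label else 0.0
                )
                value = rng.normal(center, sd)
                if name in ("gap_ratio", "proper_read_ratio", "improper_read_ratio"):
                    value = min(max(value, 0.0), 1.0)
                row[name] = value
            rows.append(row)
    return pd.DataFrame(rows)


# --- outgroups ------------------------------------------------------------


def simulate_outgroups(
    study: SimulatedStudy, flank: int = 500
) -> dict[str, dict[str, dict[str, str]]]:
    """Outgroup orthologous windows for every planted event.

    For each outgroup (one per configured divergence rate) and event, the
    window carries the designated ancestral allele with ``flank`` bp of
    context, mutated at the outgroup's background divergence.  Returns
    outgroup name -> event id -> window sequence.
    """
    refs = {r.name: r.sequence for r in study.reference}
    out: dict[str, dict[str, str]] = {}
    for k, divergence in enumerate(study.config.outgroup_divergence):
        name = f"outgroup{k + 1}"
        rng = np.random.default_rng(study.config.seed + 7_919 * (k + 1))
        windows: dict[str, str] = {}
        for ev in study.events:
            ref_seq = refs[ev.chrom]
            left = ref_seq[max(ev.start - flank, 0) : ev.start]
            right = ref_seq[ev.end : ev.end + flank]
            allele = ref_seq[ev.start : ev.end] if ev.ancestral == "ref" else ev.alt_seq
            windows[ev.id] = _mutate(rng, left + allele + right, divergence)
        out[name] = windows
    return out
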