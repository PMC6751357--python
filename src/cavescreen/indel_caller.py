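"""Indel extraction from read alignments and per-population pileup.

Events are read off CIGAR strings: one event per I/D operator.  Coordinate
convention (1-based): a deletion is positioned at the first deleted
reference base; an insertion at the reference base immediately left of the
insertion point.  Before merging, events are left-aligned against the
reference so that repeat-context indels collapse onto a single key.

Depth at a site counts reads whose alignment spans the site position with
reference-consuming bases: both flanking bases for an insertion, the first
deleted base plus its left flank for a deletion.  Counting a read as
*supporting* an event is stricter: the read must span the whole event
(deleted interval plus one flank on each side), so support is always a
subset of depth.  N (splice) operators break a read into independent
spanning segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .gene_models import ReferenceGenome

INSERTION = "insertion"
DELETION = "deletion"

# CIGAR operator codes (pysam): which consume reference / query
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X


class CigarError(ValueError):
    pass


@dataclass(frozen=True)
class RawIndelEvent:
    scaffold: str
    genomic_pos: int  # 1-based; see module docstring
    kind: str  # INSERTION or DELETION
    sequence: str  # inserted / deleted bases, genome-forward orientation
    read_id: str


@dataclass
class IndelSite:
    scaffold: str
    genomic_pos: int
    kind: str
    sequence: str
    population: str
    depth: int
    alt_count: int

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must be within [0, depth]")

    @property
    def allele_fraction(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.scaffold, self.genomic_pos, self.kind, self.sequence)


def extract_events(read: pysam.AlignedSegment) -> list[RawIndelEvent]:
    """One RawIndelEvent per I/D CIGAR operator of a mapped read."""
    if read.is_unmapped:
        return []
    if read.cigartuples is None:
        raise CigarError(f"read {read.query_name} has no CIGAR")
    events: list[RawIndelEvent] = []
    rpos = read.reference_start  # 0-based
    qpos = 0
    seq = read.query_sequence or ""
    for op, length in read.cigartuples:
        if length <= 0:
            raise CigarError(f"non-positive CIGAR length in {read.query_name}")
        if op == 1:  # I
            events.append(
                RawIndelEvent(
                    scaffold=read.reference_name,
                    genomic_pos=rpos,  # 1-based pos of base left of insertion
                    kind=INSERTION,
                    sequence=seq[qpos : qpos + length],
                    read_id=read.query_name,
                )
            )
        elif op == 2:  # D
            events.append(
                RawIndelEvent(
                    scaffold=read.reference_name,
                    genomic_pos=rpos + 1,  # 1-based first deleted base
                    kind=DELETION,
                    # deleted bases live on the reference; "N" placeholders are
                    # replaced with the reference slice during normalization
                    sequence="N" * length,
                    read_id=read.query_name,
                )
            )
        if op in _REF_CONSUMING or op == 3:
            rpos += length
        if op in _QUERY_CONSUMING:
            qpos += length
    return events


def spanning_segments(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Maximal reference intervals (1-based, closed) covered by M/D/=/X runs.

    N operators split a spliced read into independent segments; insertions do
    not consume reference and do not split.
    """
    segs: list[tuple[int, int]] = []
    rpos = read.reference_start  # 0-based
    start = None
    for op, length in read.cigartuples or []:
        if op in _REF_CONSUMING:
            if start is None:
                start = rpos
            rpos += length
        elif op == 3:  # N splits
            if start is not None:
                segs.append((start + 1, rpos))
                start = None
            rpos += length
    if start is not None:
        segs.append((start + 1, rpos))
    return segs


def left_align(
    genome: ReferenceGenome, scaffold: str, kind: str, pos: int, length: int, seq: str
) -> tuple[int, str]:
    """Left-normalize an indel event against the reference.

    Returns (pos, sequence) with the deletion sequence taken from the
    reference.  Shifting repeats the standard rotation: an event may move one
    base left whenever the reference base preceding it equals the event's
    last base.
    """
    ref = genome.sequences[scaffold]
    if kind == DELETION:
        seq = ref[pos - 1 : pos - 1 + length]
        while pos >= 2 and ref[pos - 2] == seq[-1]:
            pos -= 1
            seq = ref[pos - 1 : pos - 1 + length]
        return pos, seq
    # insertion after `pos`
    while pos >= 1 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


class PopulationAlignment:
    """All indel evidence from one population's alignment.

    Holds merged, left-aligned event counts plus every read's spanning
    segments so that depth can be measured at arbitrary loci (including loci
    where this population carries no variant).
    """

    def __init__(self, population: str, genome: ReferenceGenome):
        self.population = population
        self.genome = genome
        self.support: dict[tuple[str, int, str, str], int] = {}
        self.segments: dict[str, list[tuple[int, int]]] = {}
        self.n_reads = 0

    @classmethod
    def from_sam(
        cls,
        path,
        population: str,
        genome: ReferenceGenome,
        min_mapq: int = 0,
    ) -> "PopulationAlignment":
        self = cls(population, genome)
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for read in sam:
                self.add_read(read, min_mapq=min_mapq)
        for segs in self.segments.values():
            segs.sort()
        return self

    def add_read(self, read: pysam.AlignedSegment, min_mapq: int = 0) -> None:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return
        if read.mapping_quality < min_mapq:
            return
        self.n_reads += 1
        read_segs = spanning_segments(read)
        for ev in extract_events(read):
            pos, seq = left_align(
                self.genome, ev.scaffold, ev.kind, ev.genomic_pos, len(ev.sequence),
                ev.sequence,
            )
            # only events the read itself spans (flanking aligned bases on
            # both sides) count as support; an indel at a read edge does not
            a, b = self._support_interval(ev.kind, pos, len(seq))
            if not any(s <= a and e >= b for s, e in read_segs):
                continue
            key = (ev.scaffold, pos, ev.kind, seq)
            self.support[key] = self.support.get(key, 0) + 1
        segs = self.segments.setdefault(read.reference_name, [])
        segs.extend(read_segs)

    def _support_interval(self, kind: str, pos: int, length: int) -> tuple[int, int]:
        """Interval a read must span to count as *carrying* the event."""
        if kind == INSERTION:
            return pos, pos + 1
        return pos - 1, pos + length

    def _depth_interval(self, kind: str, pos: int) -> tuple[int, int]:
        """Interval a read must span to count toward *depth* at the site
        position (two reference bases around the breakpoint)."""
        if kind == INSERTION:
            return pos, pos + 1
        return pos - 1, pos

    def depth_at(self, scaffold: str, kind: str, pos: int, length: int) -> int:
        """Reads spanning the site position per the module's flank convention."""
        a, b = self._depth_interval(kind, pos)
        return sum(
            1 for s, e in self.segments.get(scaffold, []) if s <= a and e >= b
        )

    def alt_count(self, scaffold: str, kind: str, pos: int, seq: str) -> int:
        return self.support.get((scaffold, pos, kind, seq), 0)

    def sites(self) -> list[IndelSite]:
        """Merged per-site records, sorted by (scaffold, pos, kind, seq)."""
        out = []
        for (scaffold, pos, kind, seq), alt in sorted(self.support.items()):
            depth = self.depth_at(scaffold, kind, pos, len(seq))
            out.append(
                IndelSite(
                    scaffold=scaffold,
                    genomic_pos=pos,
                    kind=kind,
                    sequence=seq,
                    population=self.population,
                    depth=depth,
                    alt_count=alt,
                )
            )
        return out


def pileup_sites(path, population: str, genome: ReferenceGenome) -> list[IndelSite]:
    """Convenience wrapper: SAM/BAM path -> merged IndelSite list."""
    return PopulationAlignment.from_sam(path, population, genome).sites()
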