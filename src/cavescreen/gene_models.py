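"""Reference genome and gene-model containers with exact coordinate arithmetic.

All coordinates are 1-based and fully closed (genomic, cDNA and protein),
matching the GFF3 convention; no half-open conversion happens at the API
surface.  A gene model holds a single transcript: an ordered list of exons
in transcript orientation (for minus-strand genes exon ordinal 1 has the
highest genomic coordinates), a spliced cDNA length, and an optional CDS
offset (0-based offset of the first coding base on the cDNA).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

INTRONIC = None  # sentinel returned by genomic_to_cdna for intronic positions


class GenomeError(ValueError):
    """Raised for malformed or inconsistent genome / annotation input."""


@dataclass
class ReferenceGenome:
    """Scaffold sequences keyed by scaffold id."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, scaffold: str, start: int, end: int) -> str:
        """Return the closed interval [start, end] (1-based) of a scaffold."""
        seq = self.sequences[scaffold]
        if start < 1 or end > len(seq) or start > end:
            raise GenomeError(
                f"interval {start}-{end} out of bounds for {scaffold} (len {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass(frozen=True)
class Exon:
    genomic_start: int  # 1-based, inclusive
    genomic_end: int  # 1-based, inclusive
    ordinal: int  # 1-based index in transcript order

    def __post_init__(self):
        if self.genomic_start > self.genomic_end:
            raise GenomeError(f"exon start {self.genomic_start} > end {self.genomic_end}")

    def __len__(self) -> int:
        return self.genomic_end - self.genomic_start + 1


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    scaffold: str
    strand: str  # "+" or "-"
    exons: list[Exon]  # ordered by ordinal (transcript orientation)
    cds_offset: int = 0
    _cum: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise GenomeError(f"bad strand {self.strand!r}")
        ordinals = [e.ordinal for e in self.exons]
        if ordinals != list(range(1, len(self.exons) + 1)):
            raise GenomeError(f"exon ordinals not consecutive from 1: {ordinals}")
        # transcript orientation: ordinal 1 is 5'-most, i.e. lowest genomic
        # coordinate on "+" and highest on "-"
        starts = [e.genomic_start for e in self.exons]
        if self.strand == "+" and starts != sorted(starts):
            raise GenomeError("plus-strand exons not in ascending genomic order")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise GenomeError("minus-strand exon ordinal 1 must be genomically last")
        ivs = sorted((e.genomic_start, e.genomic_end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise GenomeError("overlapping exons")
        cum = [0]
        for e in self.exons:
            cum.append(cum[-1] + len(e))
        self._cum = cum

    @property
    def cdna_length(self) -> int:
        return self._cum[-1]

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (
            min(e.genomic_start for e in self.exons),
            max(e.genomic_end for e in self.exons),
        )

    def cdna_spans(self) -> list[tuple[int, int]]:
        """Closed cDNA interval of each exon, in ordinal order."""
        return [(self._cum[i] + 1, self._cum[i + 1]) for i in range(len(self.exons))]


def load_genome(path) -> ReferenceGenome:
    """Load a FASTA file into memory, rejecting duplicate scaffold ids."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeError(f"duplicate scaffold id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise GenomeError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences)


def load_gene_models(
    path, genome: ReferenceGenome, cds_offsets: dict[str, int] | None = None
) -> list[GeneModel]:
    """Load gene/mRNA/exon features from GFF3 into one GeneModel per gene.

    If a gene carries several transcripts the longest (by spliced length) is
    kept with a warning.  Exons outside their scaffold raise.
    """
    cds_offsets = cds_offsets or {}
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [gene.id])[0]
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            transcripts = [gene]
        best = None
        for tx in transcripts:
            exons = list(db.children(tx, featuretype="exon"))
            if not exons:
                continue
            total = sum(e.end - e.start + 1 for e in exons)
            if best is None or total > best[0]:
                best = (total, tx, exons)
        if best is None:
            raise GenomeError(f"gene {gene.id} has no exons")
        if len(transcripts) > 1:
            log.warning(
                "gene %s has %d transcripts; keeping longest (%s)",
                gene.id, len(transcripts), best[1].id,
            )
        _, tx, exons = best
        if gene.seqid not in genome.sequences:
            raise GenomeError(f"unknown scaffold {gene.seqid!r} for gene {gene.id}")
        slen = len(genome.sequences[gene.seqid])
        for e in exons:
            if e.start < 1 or e.end > slen:
                raise GenomeError(
                    f"exon {e.start}-{e.end} of {gene.id} outside scaffold "
                    f"{gene.seqid} (len {slen})"
                )
        strand = gene.strand
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        model = GeneModel(
            gene_id=gene.id,
            gene_name=name,
            scaffold=gene.seqid,
            strand=strand,
            exons=[
                Exon(e.start, e.end, i + 1) for i, e in enumerate(exons)
            ],
            cds_offset=cds_offsets.get(name, 0),
        )
        models.append(model)
    return models


def genomic_to_cdna(model: GeneModel, gpos: int) -> int | None:
    """Map a genomic position to its 1-based cDNA position, or INTRONIC (None).

    Positions off the gene's scaffold span still return INTRONIC when outside
    every exon; positions outside the scaffold itself are the caller's error.
    """
    if gpos < 1:
        raise GenomeError(f"genomic position {gpos} < 1")
    for exon, (cs, _) in zip(model.exons, model.cdna_spans()):
        if exon.genomic_start <= gpos <= exon.genomic_end:
            if model.strand == "+":
                return cs + (gpos - exon.genomic_start)
            return cs + (exon.genomic_end - gpos)
    return INTRONIC


def cdna_to_genomic(model: GeneModel, cpos: int) -> int:
    """Inverse of :func:`genomic_to_cdna` over exonic bases."""
    if not 1 <= cpos <= model.cdna_length:
        raise GenomeError(f"cDNA position {cpos} outside 1..{model.cdna_length}")
    for exon, (cs, ce) in zip(model.exons, model.cdna_spans()):
        if cs <= cpos <= ce:
            if model.strand == "+":
                return exon.genomic_start + (cpos - cs)
            return exon.genomic_end - (cpos - cs)
    raise AssertionError("unreachable: cumulative spans cover 1..cdna_length")


def exon_of(model: GeneModel, cpos: int) -> tuple[int, int]:
    """Return (exon ordinal containing cpos, total exon count)."""
    if not 1 <= cpos <= model.cdna_length:
        raise GenomeError(f"cDNA position {cpos} outside 1..{model.cdna_length}")
    for exon, (cs, ce) in zip(model.exons, model.cdna_spans()):
        if cs <= cpos <= ce:
            return exon.ordinal, len(model.exons)
    raise AssertionError("unreachable")


def exon_boundary_distance(
    model: GeneModel, cpos: int, *, transcript_ends_are_boundaries: bool = False
) -> float:
    """Distance (cDNA bp; 0 = on the boundary base) to the nearest splice
    boundary of the exon containing ``cpos``.

    The transcript termini (cDNA 1 and cdna_length) are splice boundaries only
    when ``transcript_ends_are_boundaries`` is set; a single-exon transcript
    with the flag off has no boundaries and yields ``inf``.
    """
    ordinal, total = exon_of(model, cpos)
    cs, ce = model.cdna_spans()[ordinal - 1]
    dists = []
    if ordinal > 1 or transcript_ends_are_boundaries:
        dists.append(cpos - cs)
    if ordinal < total or transcript_ends_are_boundaries:
        dists.append(ce - cpos)
    return min(dists) if dists else math.inf


def transcript_sequence(model: GeneModel, genome: ReferenceGenome) -> str:
    """Spliced cDNA sequence in transcript orientation."""
    parts = []
    for exon in model.exons:
        s = genome.fetch(model.scaffold, exon.genomic_start, exon.genomic_end)
        if model.strand == "-":
            s = reverse_complement(s)
        parts.append(s)
    return "".join(parts)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
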