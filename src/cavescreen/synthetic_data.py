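"""Deterministic synthetic test universe for the indel screen.

Generates a toy multi-scaffold genome whose gene models carry the seven
validated cavefish lesions (packaged in ``data/lesion_catalog.tsv``), plus
per-population allele sequences, spliced simulated reads in SAM format, an
outgroup ortholog FASTA, QTL marker fixtures, and a truth table — so every
stage of the pipeline is testable without any external download.

The reference genome carries the cave (Pachón) haplotype wherever the
lesion is shared by both cave lineages, so those lesions surface as
variants in the *surface* alignment, mirroring the original screen.  Two
decoys are planted: a clean lesion on an undersized (0.5 Mb) scaffold and a
splice-artifact lesion 2 bp from an exon boundary; both must be removed by
the filter cascade.

Lesion coordinates follow the naming convention used throughout the
package: inserted bases are numbered by the positions they occupy in the
cDNA of the insertion-bearing allele; deleted bases by their positions in
the allele that carries them.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .gene_models import (
    Exon,
    GeneModel,
    ReferenceGenome,
    cdna_to_genomic,
    reverse_complement,
    transcript_sequence,
)
from .indel_caller import DELETION, INSERTION

POPULATIONS = ("Surface", "Pachon", "Tinaja")
CAVE_POPULATIONS = ("Pachon", "Tinaja")

_BASES = "ACGT"
_MARGIN = 15  # bp kept between planted lesions and splice boundaries
_MIN_EXON = 40
_MIN_READ = 30


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class LesionSpec:
    """One row of the lesion specification (cave/surface-oriented)."""

    gene: str
    kind: str  # INSERTION / DELETION (of the cave allele relative to surface)
    cdna_start: int
    cdna_end: int
    sequence: str
    exon_ordinal: int
    exon_count: int
    cdna_length: int
    strand: str
    carriers: tuple[str, ...]  # cave populations carrying the lesion
    reference_carries: bool  # reference genome holds the cave haplotype
    boundary_margin: int | None = None  # decoys force a near-boundary placement
    expect_survival: bool = True
    fail_reason: str | None = None

    def __post_init__(self):
        n = self.cdna_end - self.cdna_start + 1
        if n < 1 or len(self.sequence) != n:
            raise FixtureError(
                f"{self.gene}: lesion interval {self.cdna_start}-{self.cdna_end} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )
        if self.cdna_end > self.cdna_length:
            raise FixtureError(
                f"{self.gene}: lesion at cDNA {self.cdna_end} exceeds "
                f"cDNA length {self.cdna_length}"
            )
        if not 1 <= self.exon_ordinal <= self.exon_count:
            raise FixtureError(
                f"{self.gene}: exon ordinal {self.exon_ordinal} outside "
                f"1..{self.exon_count}"
            )
        if not self.carriers:
            raise FixtureError(f"{self.gene}: empty carrier set")

    @property
    def expected_name(self) -> str:
        tag = "Ins" if self.kind == INSERTION else "Δ"
        if self.cdna_start == self.cdna_end:
            return f"{self.gene}^{tag}{self.cdna_start}"
        return f"{self.gene}^{tag}{self.cdna_start}–{self.cdna_end}"

    @property
    def frame_class(self) -> str:
        return "in-frame" if len(self.sequence) % 3 == 0 else "frameshift"


@dataclass
class ObservedEvent:
    """A lesion as it appears in an alignment against the reference."""

    spec: LesionSpec
    kind: str  # observed orientation (variant vs reference)
    ref_cdna_start: int  # deletions: first deleted ref base; insertions: anchor
    ref_cdna_len: int
    seq_transcript: str  # transcript orientation
    carrier_pops: tuple[str, ...]  # populations whose reads show the event
    genomic_pos: int = 0  # site key (caller convention), genome-forward
    genomic_seq: str = ""


@dataclass
class TruthEntry:
    gene: str
    scaffold: str
    genomic_pos: int
    kind: str
    sequence: str  # genome-forward
    ref_cdna_start: int
    carrier_pops: tuple[str, ...]
    expect_survival: bool
    fail_reason: str | None
    expected_name: str
    expected_frame_class: str
    expected_sharing: str


@dataclass
class GeneBuild:
    specs: list[LesionSpec]
    model: GeneModel
    events: list[ObservedEvent]
    ref_cdna: str = ""
    # alignment map per carrier population: list of map items (see _map_items)
    _alleles: dict[str, str] = field(default_factory=dict)

    @property
    def gene(self) -> str:
        return self.specs[0].gene


@dataclass
class Fixture:
    outdir: Path
    seed: int
    genome: ReferenceGenome
    builds: dict[str, GeneBuild]
    gene_order: list[str]
    truth: list[TruthEntry]
    genome_path: Path = None
    gff_path: Path = None
    outgroup_path: Path = None
    allele_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def models(self) -> list[GeneModel]:
        return [self.builds[g].model for g in self.gene_order]

    def allele_cdna(self, gene: str, population: str) -> str:
        return self.builds[gene]._alleles[population]

    def expected_sharing(self, gene: str) -> str:
        return _expected_sharing(self.builds[gene].specs[0])


def _expected_sharing(spec: LesionSpec) -> str:
    if spec.reference_carries or len(spec.carriers) > 1:
        return "shared-cave"
    return f"single-cave({spec.carriers[0]})"


def default_lesion_specs() -> list[LesionSpec]:
    """The packaged seven-gene lesion specification."""
    path = resources.files("cavescreen.data") / "lesion_catalog.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            LesionSpec(
                gene=row.gene,
                kind=row.kind,
                cdna_start=int(row.cdna_start),
                cdna_end=int(row.cdna_end),
                sequence=row.sequence,
                exon_ordinal=int(row.exon_ordinal),
                exon_count=int(row.exon_count),
                cdna_length=int(row.cdna_length),
                strand=row.strand,
                carriers=tuple(row.carriers.split(",")),
                reference_carries=row.reference_carries == "yes",
            )
        )
    return specs


def packaged_domains_path() -> str:
    return str(resources.files("cavescreen.data") / "domains.tsv")


def _decoy_specs() -> list[LesionSpec]:
    return [
        LesionSpec(
            gene="decoy_small",
            kind=INSERTION,
            cdna_start=450,
            cdna_end=452,
            sequence="ACA",
            exon_ordinal=2,
            exon_count=3,
            cdna_length=900,
            strand="+",
            carriers=CAVE_POPULATIONS,
            reference_carries=True,
            expect_survival=False,
            fail_reason="scaffold_size",
        ),
        LesionSpec(
            gene="decoy_splice",
            kind=INSERTION,
            cdna_start=500,
            cdna_end=502,
            sequence="GTG",
            exon_ordinal=3,
            exon_count=5,
            cdna_length=1200,
            strand="+",
            carriers=CAVE_POPULATIONS,
            reference_carries=True,
            boundary_margin=2,
            expect_survival=False,
            fail_reason="exonic",
        ),
    ]


def _observed_events(specs: list[LesionSpec]) -> list[ObservedEvent]:
    """Convert cave/surface-oriented lesion rows to reference-space events.

    ``delta`` tracks the running reference-vs-other-allele coordinate shift
    so that compound lesions (plg, mki67) land on the correct anchors.
    """
    events = []
    delta = 0
    ref_carries = specs[0].reference_carries
    for spec in sorted(specs, key=lambda s: s.cdna_start):
        n = len(spec.sequence)
        if ref_carries:
            carrier = ("Surface",)
            if spec.kind == INSERTION:  # cave ins, coords already reference cDNA
                ev = ObservedEvent(spec, DELETION, spec.cdna_start, n,
                                   spec.sequence, carrier)
                delta += n
            else:  # cave deletion in surface coords -> obs insertion
                anchor = spec.cdna_start - 1 + delta
                ev = ObservedEvent(spec, INSERTION, anchor, n,
                                   spec.sequence, carrier)
                delta -= n
        else:
            carrier = spec.carriers
            if spec.kind == INSERTION:  # cave coords -> obs insertion anchor
                anchor = spec.cdna_start - 1 - delta
                ev = ObservedEvent(spec, INSERTION, anchor, n,
                                   spec.sequence, carrier)
                delta += n
            else:  # surface(=ref) coords -> obs deletion
                ev = ObservedEvent(spec, DELETION, spec.cdna_start, n,
                                   spec.sequence, carrier)
                delta -= n
        events.append(ev)
    return events


def _place_exon_boundaries(
    L: int,
    n: int,
    k: int | None = None,
    lo: int | None = None,
    hi: int | None = None,
    margin: int = _MARGIN,
    force_start: bool = False,
) -> list[int]:
    """Cumulative cDNA boundaries b[0]=0 < ... < b[n]=L with exon k
    containing [lo, hi] at >= margin bp from its splice boundaries."""
    b = [round(i * L / n) for i in range(n + 1)]
    if k is not None:
        if force_start:
            b[k - 1] = lo - 1 - margin
        else:
            b[k - 1] = min(b[k - 1], lo - 1 - margin)
        b[k] = max(b[k], hi + margin) if k < n else L
        for i in range(k - 2, 0, -1):
            b[i] = min(b[i], b[i + 1] - _MIN_EXON)
        for i in range(k + 1, n):
            b[i] = max(b[i], b[i - 1] + _MIN_EXON)
    b[0], b[n] = 0, L
    for i in range(1, n + 1):
        if b[i] <= b[i - 1]:
            raise FixtureError(
                f"cannot place {n} exons over {L} bp honoring lesion at "
                f"{lo}-{hi} in exon {k}"
            )
    return b


def _constraint(events: list[ObservedEvent]) -> tuple[int, int]:
    los, his = [], []
    for ev in events:
        if ev.kind == DELETION:
            los.append(ev.ref_cdna_start - 1)
            his.append(ev.ref_cdna_start + ev.ref_cdna_len)
        else:
            los.append(ev.ref_cdna_start)
            his.append(ev.ref_cdna_start + 1)
    return min(los), max(his)


def _build_gene(
    specs: list[LesionSpec], scaffold: str, offset: int, rng: np.random.Generator
) -> GeneBuild:
    spec0 = specs[0]
    events = _observed_events(specs)
    lo, hi = _constraint(events)
    margin = spec0.boundary_margin if spec0.boundary_margin is not None else _MARGIN
    b = _place_exon_boundaries(
        spec0.cdna_length,
        spec0.exon_count,
        k=spec0.exon_ordinal,
        lo=lo,
        hi=hi,
        margin=margin,
        force_start=spec0.boundary_margin is not None,
    )
    exon_lengths = [b[i + 1] - b[i] for i in range(spec0.exon_count)]
    introns = rng.integers(200, 801, size=max(spec0.exon_count - 1, 1))
    # genomic blocks ascending; for minus strand transcript order is reversed
    genomic_lengths = (
        exon_lengths if spec0.strand == "+" else list(reversed(exon_lengths))
    )
    blocks = []
    pos = offset
    for i, elen in enumerate(genomic_lengths):
        blocks.append((pos, pos + elen - 1))
        pos += elen
        if i < len(genomic_lengths) - 1:
            pos += int(introns[i])
    if spec0.strand == "-":
        blocks = list(reversed(blocks))
    exons = [Exon(s, e, i + 1) for i, (s, e) in enumerate(blocks)]
    model = GeneModel(
        gene_id=f"gene:{spec0.gene}",
        gene_name=spec0.gene,
        scaffold=scaffold,
        strand=spec0.strand,
        exons=exons,
    )
    return GeneBuild(specs=specs, model=model, events=events)


def _scaffold_layout(gene_names: list[str]) -> dict[str, tuple[str, int, int]]:
    """gene -> (scaffold, length, offset).  plg sits alone on its scaffold
    (it plays the unplaced-gene role in QTL fixtures); decoy_small sits on
    the undersized scaffold."""
    layout: dict[str, tuple[str, int, int]] = {}
    fill: list[str] = []
    scaffold_no = 0
    slots = [150_000, 250_000]
    for gene in gene_names:
        if gene == "decoy_small":
            layout[gene] = ("scaffold_small", 500_000, 100_000)
        elif gene == "plg":
            layout[gene] = ("scaffold_plg", 2_000_000, 150_000)
        else:
            if not fill:
                scaffold_no += 1
            layout[gene] = (
                f"scaffold_{scaffold_no}", 2_000_000, slots[len(fill)]
            )
            fill.append(gene)
            if len(fill) == len(slots):
                fill = []
    return layout


def _set_base(buf: bytearray, pos1: int, value: str) -> None:
    buf[pos1 - 1] = ord(value)


def _get_base(buf: bytearray, pos1: int) -> str:
    return chr(buf[pos1 - 1])


def _different_base(*avoid: str) -> str:
    for base in _BASES:
        if base not in avoid:
            return base
    raise AssertionError


def _plant_gene(build: GeneBuild, buf: bytearray) -> None:
    """Write lesion sequences and anti-left-shift guard bases into the
    reference scaffold buffer."""
    model = build.model
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def write_cdna(cpos: int, base: str) -> None:
        g = cdna_to_genomic(model, cpos)
        _set_base(buf, g, base if model.strand == "+" else comp[base])

    for ev in build.events:
        if ev.kind == DELETION:
            # the 'deleted' bases exist on the reference: plant them
            for i, base in enumerate(ev.seq_transcript):
                write_cdna(ev.ref_cdna_start + i, base)
    for ev in build.events:
        if ev.kind == DELETION:
            cpos = [ev.ref_cdna_start, ev.ref_cdna_start + ev.ref_cdna_len - 1]
            gpos = sorted(cdna_to_genomic(model, c) for c in cpos)
            ev.genomic_pos = gpos[0]
            ev.genomic_seq = "".join(
                _get_base(buf, g) for g in range(gpos[0], gpos[1] + 1)
            )
            # guard: base left of the deletion must differ from its last base
            guard_pos = gpos[0] - 1
            if _get_base(buf, guard_pos) == ev.genomic_seq[-1]:
                _set_base(
                    buf, guard_pos, _different_base(ev.genomic_seq[-1])
                )
        else:
            r = ev.ref_cdna_start  # transcript-space anchor
            g_left = cdna_to_genomic(model, r)
            g_right = cdna_to_genomic(model, r + 1)
            anchor = min(g_left, g_right)
            seq_fwd = (
                ev.seq_transcript
                if model.strand == "+"
                else reverse_complement(ev.seq_transcript)
            )
            ev.genomic_pos = anchor
            ev.genomic_seq = seq_fwd
            if _get_base(buf, anchor) == seq_fwd[-1]:
                _set_base(buf, anchor, _different_base(seq_fwd[-1]))


def _map_items(ref_len: int, events: list[ObservedEvent]) -> list[tuple]:
    """Allele->reference alignment map for a carrier allele.

    Items: ('M', allele_start, ref_start, len), ('I', allele_start, len, ev),
    ('D', allele_gap_pos, ref_start, len, ev); coordinates 1-based.
    """
    items = []
    a, r = 1, 1
    for ev in sorted(events, key=lambda e: e.ref_cdna_start):
        if ev.kind == DELETION:
            mlen = ev.ref_cdna_start - r
            if mlen:
                items.append(("M", a, r, mlen))
            a += mlen
            r += mlen
            items.append(("D", a - 1, r, ev.ref_cdna_len, ev))
            r += ev.ref_cdna_len
        else:
            mlen = ev.ref_cdna_start - r + 1  # include the anchor base
            if mlen:
                items.append(("M", a, r, mlen))
            a += mlen
            r += mlen
            items.append(("I", a, ev.ref_cdna_len, ev))
            a += ev.ref_cdna_len
    if r <= ref_len:
        items.append(("M", a, r, ref_len - r + 1))
    return items


def _apply_map(ref_cdna: str, items: list[tuple]) -> str:
    parts = []
    for it in items:
        if it[0] == "M":
            _, a, r, n = it
            parts.append(ref_cdna[r - 1 : r - 1 + n])
        elif it[0] == "I":
            parts.append(it[3].seq_transcript)
    return "".join(parts)


def build_fixture(
    specs: list[LesionSpec] | None = None,
    seed: int = 1,
    outdir: str | Path = ".",
    include_decoys: bool = True,
) -> Fixture:
    """Generate genome FASTA + GFF3 + per-population allele FASTAs + truth.

    Deterministic: identical (specs, seed) yield byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = default_lesion_specs()
    if include_decoys:
        specs = list(specs) + _decoy_specs()
    rng = np.random.default_rng(seed)

    by_gene: dict[str, list[LesionSpec]] = {}
    for spec in specs:
        by_gene.setdefault(spec.gene, []).append(spec)
    for gene, rows in by_gene.items():
        base = rows[0]
        for row in rows[1:]:
            if (row.exon_count, row.cdna_length, row.strand) != (
                base.exon_count, base.cdna_length, base.strand
            ):
                raise FixtureError(f"{gene}: inconsistent gene-level fields")

    gene_order = list(by_gene)
    layout = _scaffold_layout(gene_order)
    builds = {
        gene: _build_gene(by_gene[gene], layout[gene][0], layout[gene][2], rng)
        for gene in gene_order
    }

    # random scaffolds, then plant lesions and guards
    scaffold_lengths: dict[str, int] = {}
    for gene in gene_order:
        name, length, _ = layout[gene]
        scaffold_lengths[name] = length
    buffers: dict[str, bytearray] = {}
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    for name in sorted(scaffold_lengths):
        codes = rng.integers(0, 4, size=scaffold_lengths[name])
        buffers[name] = bytearray(base_lut[codes].tobytes())
    for gene in gene_order:
        _plant_gene(builds[gene], buffers[builds[gene].model.scaffold])

    genome = ReferenceGenome(
        {name: buffers[name].decode() for name in sorted(buffers)}
    )
    truth: list[TruthEntry] = []
    for gene in gene_order:
        build = builds[gene]
        build.ref_cdna = transcript_sequence(build.model, genome)
        carrier_items = _map_items(len(build.ref_cdna), build.events)
        variant_cdna = _apply_map(build.ref_cdna, carrier_items)
        for pop in POPULATIONS:
            is_carrier = pop in build.events[0].carrier_pops
            build._alleles[pop] = variant_cdna if is_carrier else build.ref_cdna
        for ev, spec in zip(build.events, sorted(
            build.specs, key=lambda s: s.cdna_start
        )):
            truth.append(
                TruthEntry(
                    gene=gene,
                    scaffold=build.model.scaffold,
                    genomic_pos=ev.genomic_pos,
                    kind=ev.kind,
                    sequence=ev.genomic_seq,
                    ref_cdna_start=ev.ref_cdna_start,
                    carrier_pops=ev.carrier_pops,
                    expect_survival=spec.expect_survival,
                    fail_reason=spec.fail_reason,
                    expected_name=spec.expected_name,
                    expected_frame_class=spec.frame_class,
                    expected_sharing=_expected_sharing(spec),
                )
            )

    fx = Fixture(
        outdir=outdir,
        seed=seed,
        genome=genome,
        builds=builds,
        gene_order=gene_order,
        truth=truth,
    )
    _write_fasta(outdir / "genome.fa", genome.sequences)
    fx.genome_path = outdir / "genome.fa"
    fx.gff_path = outdir / "genes.gff3"
    _write_gff3(fx.gff_path, [builds[g].model for g in gene_order])
    for pop in POPULATIONS:
        path = outdir / f"alleles_{pop}.fa"
        _write_fasta(path, {g: builds[g]._alleles[pop] for g in gene_order})
        fx.allele_paths[pop] = path
    fx.outgroup_path = outdir / "outgroup.fa"
    _write_fasta(
        fx.outgroup_path, _make_outgroup(fx, rng, divergence=0.02, window=60)
    )
    _write_truth(outdir / "truth.tsv", truth)
    return fx


def _make_outgroup(
    fx: Fixture, rng: np.random.Generator, divergence: float, window: int
) -> dict[str, str]:
    """Outgroup ortholog = ancestral (surface) allele with random
    substitutions outside the lesion window."""
    out = {}
    for gene in fx.gene_order:
        build = fx.builds[gene]
        seq = list(build._alleles["Surface"])
        # protected window in surface-allele coordinates
        lo = min(ev.ref_cdna_start for ev in build.events) - window
        hi = max(ev.ref_cdna_start + ev.ref_cdna_len for ev in build.events) + window
        hits = rng.random(len(seq)) < divergence
        for i in np.flatnonzero(hits):
            if lo <= i + 1 <= hi:
                continue
            choices = [b for b in _BASES if b != seq[i]]
            seq[i] = choices[int(rng.integers(0, 3))]
        out[gene] = "".join(seq)
    return out


def _write_fasta(path: Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.genomic_span
            fh.write(
                f"{m.scaffold}\tcavescreen\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Name={m.gene_name}\n"
            )
            fh.write(
                f"{m.scaffold}\tcavescreen\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID=tx:{m.gene_name};Parent={m.gene_id}\n"
            )
            for e in sorted(m.exons, key=lambda e: e.genomic_start):
                fh.write(
                    f"{m.scaffold}\tcavescreen\texon\t{e.genomic_start}\t"
                    f"{e.genomic_end}\t.\t{m.strand}\t.\t"
                    f"ID=exon:{m.gene_name}.{e.ordinal};Parent=tx:{m.gene_name}\n"
                )


def _write_truth(path: Path, truth: list[TruthEntry]) -> None:
    rows = [
        {
            "gene": t.gene,
            "scaffold": t.scaffold,
            "genomic_pos": t.genomic_pos,
            "kind": t.kind,
            "sequence": t.sequence,
            "ref_cdna_start": t.ref_cdna_start,
            "carrier_pops": ",".join(t.carrier_pops),
            "expect_survival": t.expect_survival,
            "fail_reason": t.fail_reason or "",
            "expected_name": t.expected_name,
            "expected_frame_class": t.expected_frame_class,
            "expected_sharing": t.expected_sharing,
        }
        for t in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read simulation


def _read_ops(items: list[tuple], s: int, e: int) -> list[tuple]:
    """Transcript-space ops of the read [s, e] (allele coords) vs ref cDNA."""
    tops = []
    for it in items:
        if it[0] == "M":
            _, a, r, n = it
            lo, hi = max(s, a), min(e, a + n - 1)
            if lo <= hi:
                tops.append(("M", hi - lo + 1, r + (lo - a)))
        elif it[0] == "I":
            _, a, n, _ev = it
            lo, hi = max(s, a), min(e, a + n - 1)
            if lo <= hi:
                tops.append(("I", hi - lo + 1, None))
        else:
            _, gap, r, n, _ev = it
            if s <= gap and e >= gap + 1:
                tops.append(("D", n, r))
    return tops


def _genomic_blocks(model: GeneModel, ra: int, rb: int) -> list[tuple[int, int]]:
    """Genomic intervals of ref cDNA [ra, rb], transcript order."""
    blocks = []
    for exon, (cs, ce) in zip(model.exons, model.cdna_spans()):
        lo, hi = max(ra, cs), min(rb, ce)
        if lo > hi:
            continue
        if model.strand == "+":
            blocks.append(
                (exon.genomic_start + (lo - cs), exon.genomic_start + (hi - cs))
            )
        else:
            blocks.append(
                (exon.genomic_end - (hi - cs), exon.genomic_end - (lo - cs))
            )
    return blocks


def _build_cigar(
    model: GeneModel, tops: list[tuple]
) -> tuple[int, list[tuple[int, int]]]:
    """(0-based SAM POS, cigartuples) for transcript-space ops.

    Ops are expanded across exons (N gaps), flipped to genome order for
    minus-strand genes, and edge insertions are soft-clipped.
    """
    expanded = []  # (op_char, length, genomic interval or None)
    for op, n, r in tops:
        if op == "I":
            expanded.append(("I", n, None))
            continue
        for gs, ge in _genomic_blocks(model, r, r + n - 1):
            expanded.append((op, ge - gs + 1, (gs, ge)))
    if model.strand == "-":
        expanded = list(reversed(expanded))
    # insert N gaps between consecutive reference blocks
    out: list[tuple[str, int]] = []
    pos0 = None
    prev_end = None
    for op, n, iv in expanded:
        if iv is not None:
            gs, ge = iv
            if pos0 is None:
                pos0 = gs
            elif prev_end is not None and gs > prev_end + 1:
                out.append(("N", gs - prev_end - 1))
            prev_end = ge
        out.append((op, n))
    # soft-clip edge insertions; drop edge D/N
    while out and out[0][0] in ("D", "N"):
        n = out.pop(0)[1]
        pos0 += n
    while out and out[-1][0] in ("D", "N"):
        out.pop()
    if out and out[0][0] == "I":
        out[0] = ("S", out[0][1])
    if out and out[-1][0] == "I":
        out[-1] = ("S", out[-1][1])
    # merge adjacent same ops
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    codes = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}
    return pos0 - 1, [(codes[op], n) for op, n in merged]


def simulate_reads(
    fx: Fixture,
    population: str,
    out_path: str | Path,
    depth: int = 60,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 1,
) -> dict[str, list[tuple]]:
    """Simulate spliced, genome-aligned reads for one population.

    Reads tile each transcript to mean coverage ~= depth; fragments are
    clipped at the transcript 3' end (short clips < 30 bp are dropped).
    Substitution errors are applied uniformly at ``error_rate``.

    Returns the truth read map: read id -> list of carried lesion site keys
    (scaffold, genomic_pos, kind, genome-forward sequence).
    """
    if depth < 1:
        raise FixtureError("depth must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise FixtureError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(
        (seed, zlib.crc32(population.encode()) % (2**31))
    )
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": len(seq)}
            for name, seq in sorted(fx.genome.sequences.items())
        ],
    }
    truth_map: dict[str, list[tuple]] = {}
    records = []
    for gene in fx.gene_order:
        build = fx.builds[gene]
        model = build.model
        allele = build._alleles[population]
        La = len(allele)
        if read_length > La:
            raise FixtureError(
                f"read_length {read_length} exceeds transcript {gene} ({La} bp)"
            )
        is_carrier = population in build.events[0].carrier_pops
        items = (
            _map_items(len(build.ref_cdna), build.events)
            if is_carrier
            else [("M", 1, 1, len(build.ref_cdna))]
        )
        # allele-space extents of each event for carrier truth bookkeeping;
        # inserted bases are shielded from substitution errors so the error
        # model perturbs alignments without mutating the lesion allele itself
        ev_spans = []
        shielded: set[int] = set()
        if is_carrier:
            for it in items:
                if it[0] == "I":
                    _, a, n, ev = it
                    ev_spans.append((ev, a - 1, a + n))  # need flanks
                    shielded.update(range(a, a + n))
                elif it[0] == "D":
                    _, gap, _r, _n, ev = it
                    ev_spans.append((ev, gap, gap + 1))
        n_reads = max(2, math.ceil(depth * La / read_length))
        for i in range(n_reads):
            s = 1 + int(i * (La - 1) / (n_reads - 1))
            e = min(s + read_length - 1, La)
            if e - s + 1 < _MIN_READ:
                continue
            seq = allele[s - 1 : e]
            if error_rate:
                hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
                hits = [j for j in hits if (s + j) not in shielded]
                if hits:
                    chars = list(seq)
                    for j in hits:
                        alts = [b for b in _BASES if b != chars[j]]
                        chars[j] = alts[int(rng.integers(0, 3))]
                    seq = "".join(chars)
            tops = _read_ops(items, s, e)
            pos0, cigar = _build_cigar(model, tops)
            if model.strand == "-":
                seq = reverse_complement(seq)
            rid = f"{population}.{gene}.{i:05d}"
            carried = [
                (build.model.scaffold, ev.genomic_pos, ev.kind, ev.genomic_seq)
                for ev, lo, hi in ev_spans
                if s <= lo and e >= hi
            ]
            truth_map[rid] = carried
            records.append(
                (model.scaffold, pos0, rid, 16 if model.strand == "-" else 0,
                 cigar, seq)
            )
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    out_path = Path(out_path)
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        for scaffold, pos0, rid, flag, cigar, seq in records:
            aln = pysam.AlignedSegment(sam.header)
            aln.query_name = rid
            aln.flag = flag
            aln.reference_name = scaffold
            aln.reference_start = pos0
            aln.mapping_quality = 60
            aln.cigartuples = cigar
            aln.query_sequence = seq
            records_ok = sum(n for op, n in cigar if op in (0, 1, 4))
            assert records_ok == len(seq), (rid, cigar, len(seq))
            sam.write(aln)
    return truth_map


def make_marker_fixture(
    fx: Fixture, outdir: str | Path | None = None
) -> tuple[Path, pd.DataFrame, set[str]]:
    """QTL marker TSV with planted, known distances to fixture genes.

    Returns (marker path, expected-distance table, unplaced scaffold set);
    plg's dedicated scaffold stands in for an unplaced chromosome.
    """
    outdir = Path(outdir or fx.outdir)
    spans = {
        g: (fx.builds[g].model.scaffold, *fx.builds[g].model.genomic_span)
        for g in fx.gene_order
    }
    markers = []

    def add(name, trait, chrom, pos):
        markers.append(
            {"marker": name, "trait": trait, "chrom": chrom, "pos": pos,
             "source": "fixture"}
        )

    if "ghrb" in spans:
        sc, lo, hi = spans["ghrb"]
        add("129b", "jaw morphology", sc, (lo + hi) // 2)  # inside span -> 0
    if "mia3" in spans:
        sc, lo, hi = spans["mia3"]
        add("203f", "eye morphology", sc, hi + 600_000)
        add("218d", "body morphology", sc, hi + 1_200_000)
    if "wdr1" in spans:
        sc, lo, hi = spans["wdr1"]
        add("229a", "body morphology", sc, hi + 25_000)
    if "mlf1" in spans:
        sc, lo, hi = spans["mlf1"]
        add("208a", "body morphology", sc, max(1, lo - 50_000))
    if "decoy_small" in spans:
        add("decoyM", "pigmentation", spans["decoy_small"][0], 250_000)

    path = outdir / "markers.tsv"
    pd.DataFrame(markers).to_csv(path, sep="\t", index=False)

    unplaced = {spans["plg"][0]} if "plg" in spans else set()
    expected_rows = []
    for g, (sc, lo, hi) in spans.items():
        if g.startswith("decoy"):
            continue
        if sc in unplaced:
            expected_rows.append({"gene": g, "marker": "", "distance": "unplaced"})
            continue
        for m in markers:
            if m["chrom"] != sc:
                continue
            p = m["pos"]
            d = 0 if lo <= p <= hi else min(abs(lo - p), abs(hi - p))
            expected_rows.append(
                {"gene": g, "marker": m["marker"], "distance": d}
            )
    expected = pd.DataFrame(expected_rows)
    expected.to_csv(outdir / "expected_distances.tsv", sep="\t", index=False)
    return path, expected, unplaced
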