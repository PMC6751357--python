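"""Reading-frame classification, protein coordinate mapping and naming.

A lesion is in-frame iff its length is divisible by 3.  Compound lesions on
one transcript are combined by walking a cumulative frame-offset track: a
+1 insertion followed by a -1 deletion shifts the frame only over the
interval between them and restores it at the second lesion.  cDNA
positions map to protein residues by residue = ceil((cpos - cds_offset)/3).

Mutation names follow the ``gene^Ins{a}-{b}`` / ``gene^Δ{a}-{b}`` style
(en dash; single-position lesions omit the range); an ASCII alias mode
substitutes ``del`` for the Greek delta and a hyphen for the en dash.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .gene_models import GeneModel, reverse_complement
from .indel_caller import DELETION, INSERTION
from .screen_filters import CandidateIndel

IN_FRAME = "in-frame"
FRAMESHIFT = "frameshift"

EN_DASH = "–"
DELTA = "Δ"


@dataclass(frozen=True)
class Lesion:
    kind: str  # INSERTION or DELETION
    cdna_start: int  # 1-based inclusive, positions in the allele carrying the bases
    cdna_end: int
    sequence: str  # transcript orientation

    def __post_init__(self):
        n = self.cdna_end - self.cdna_start + 1
        if n < 1:
            raise ValueError("empty lesion interval")
        if len(self.sequence) != n:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length {n}"
            )

    @property
    def signed_length(self) -> int:
        n = len(self.sequence)
        return n if self.kind == INSERTION else -n


@dataclass
class FrameReport:
    classes: list[str]
    track: list[tuple[int, int]]  # (lesion cDNA position, cumulative offset mod 3)
    net_offset: int
    restoration_pos: int | None


@dataclass(frozen=True)
class DomainInterval:
    gene: str
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if self.aa_start > self.aa_end:
            raise ValueError("domain aa_start > aa_end")


@dataclass
class AnnotatedIndel:
    gene_name: str
    model: GeneModel | None
    candidates: list[CandidateIndel]
    lesions: list[Lesion]
    frame_report: FrameReport
    aa_start: int
    aa_end: int
    names: list[str]
    impacted_domains: list[DomainInterval] = field(default_factory=list)

    @property
    def name(self) -> str:
        return " and ".join(self.names)


def classify_frame(lesion: Lesion) -> str:
    """IN_FRAME iff the lesion length is a multiple of 3."""
    n = abs(lesion.signed_length)
    if n == 0:
        raise ValueError("zero-length lesion")
    return IN_FRAME if n % 3 == 0 else FRAMESHIFT


def compound_frame(lesions: list[Lesion]) -> FrameReport:
    """Cumulative frame-offset track over ordered, non-overlapping lesions.

    ``restoration_pos`` is the cDNA position of the first lesion at which the
    cumulative offset returns to 0 after having been nonzero.
    """
    ordered = sorted(lesions, key=lambda l: l.cdna_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.cdna_start <= a.cdna_end:
            raise ValueError(
                f"overlapping lesions at {a.cdna_start}-{a.cdna_end} and "
                f"{b.cdna_start}-{b.cdna_end}"
            )
    offset = 0
    track: list[tuple[int, int]] = []
    restoration = None
    was_shifted = False
    for lesion in ordered:
        offset = (offset + lesion.signed_length) % 3
        track.append((lesion.cdna_start, offset))
        if offset == 0 and was_shifted and restoration is None:
            restoration = lesion.cdna_start
        if offset != 0:
            was_shifted = True
    return FrameReport(
        classes=[classify_frame(l) for l in ordered],
        track=track,
        net_offset=offset,
        restoration_pos=restoration,
    )


def cdna_to_protein(cpos: int, cds_offset: int = 0) -> int:
    """1-based protein residue containing a cDNA base."""
    if cpos <= cds_offset:
        raise ValueError(f"cDNA position {cpos} is 5' of the CDS (offset {cds_offset})")
    return math.ceil((cpos - cds_offset) / 3)


def residue_gain(lesion: Lesion) -> int:
    """Residues gained (insertion) or lost (deletion) by an in-frame lesion."""
    if classify_frame(lesion) != IN_FRAME:
        raise ValueError("residue count undefined for frameshift lesions")
    return abs(lesion.signed_length) // 3


def name_mutation(gene_name: str, lesion: Lesion, ascii_alias: bool = False) -> str:
    tag = "Ins" if lesion.kind == INSERTION else ("del" if ascii_alias else DELTA)
    dash = "-" if ascii_alias else EN_DASH
    if lesion.cdna_start == lesion.cdna_end:
        pos = str(lesion.cdna_start)
    else:
        pos = f"{lesion.cdna_start}{dash}{lesion.cdna_end}"
    return f"{gene_name}^{tag}{pos}"


_NAME_RE = re.compile(
    rf"^(?P<gene>.+)\^(?P<tag>Ins|{DELTA}|del)(?P<a>\d+)(?:[{EN_DASH}-](?P<b>\d+))?$"
)


def parse_mutation_name(name: str) -> tuple[str, str, int, int]:
    """Inverse of :func:`name_mutation`: (gene, kind, cdna_start, cdna_end)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparsable mutation name {name!r}")
    kind = INSERTION if m["tag"] == "Ins" else DELETION
    a = int(m["a"])
    b = int(m["b"]) if m["b"] else a
    return m["gene"], kind, a, b


def protein_interval(lesion: Lesion, cds_offset: int = 0) -> tuple[int, int]:
    """Residues touched by the lesion's cDNA interval (closed, 1-based)."""
    return (
        cdna_to_protein(lesion.cdna_start, cds_offset),
        cdna_to_protein(lesion.cdna_end, cds_offset),
    )


def protein_label(lesion: Lesion, cds_offset: int = 0, ascii_alias: bool = False) -> str:
    """Table-style residue label, e.g. ``Ins475`` or ``Δ349–350``."""
    tag = "Ins" if lesion.kind == INSERTION else ("del" if ascii_alias else DELTA)
    dash = "-" if ascii_alias else EN_DASH
    a, b = protein_interval(lesion, cds_offset)
    return f"{tag}{a}" if a == b else f"{tag}{a}{dash}{b}"


def domain_overlap(
    aa_start: int, aa_end: int, domains: list[DomainInterval]
) -> list[DomainInterval]:
    """Closed-interval intersection; touching at one residue counts."""
    if aa_start > aa_end:
        raise ValueError("aa_start > aa_end")
    return [d for d in domains if not (aa_end < d.aa_start or aa_start > d.aa_end)]


def load_domains(path) -> dict[str, list[DomainInterval]]:
    """Domain table TSV (columns: gene, domain_name, aa_start, aa_end)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "domain_name": str})
    out: dict[str, list[DomainInterval]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, []).append(
            DomainInterval(row.gene, row.domain_name, int(row.aa_start), int(row.aa_end))
        )
    return out


def lesion_from_candidate(cand: CandidateIndel) -> Lesion:
    """Express a screened site as a cDNA-space lesion (observed orientation).

    The event sequence is reverse-complemented for minus-strand genes so the
    lesion reads in transcript orientation.
    """
    seq = cand.site.sequence
    if cand.model.strand == "-":
        seq = reverse_complement(seq)
    return Lesion(
        kind=cand.site.kind,
        cdna_start=cand.cdna_start,
        cdna_end=cand.cdna_end,
        sequence=seq,
    )


def annotate(
    candidates: list[CandidateIndel],
    domains: dict[str, list[DomainInterval]] | None = None,
    lesions: list[Lesion] | None = None,
    cds_offset: int | None = None,
    ascii_alias: bool = False,
) -> AnnotatedIndel:
    """Annotate one transcript's candidate group as a single record.

    ``lesions`` may be supplied directly (e.g. after population-orientation
    re-expression); otherwise they are derived from the candidates in the
    observed (variant-vs-reference) orientation.
    """
    if not candidates:
        raise ValueError("empty candidate group")
    model = candidates[0].model
    if any(c.model is not model for c in candidates):
        raise ValueError("candidates span multiple transcripts")
    if lesions is None:
        lesions = [lesion_from_candidate(c) for c in candidates]
    lesions = sorted(lesions, key=lambda l: l.cdna_start)
    offset = model.cds_offset if cds_offset is None else cds_offset
    report = compound_frame(lesions)
    intervals = [protein_interval(l, offset) for l in lesions]
    aa_start = min(a for a, _ in intervals)
    aa_end = max(b for _, b in intervals)
    gene = model.gene_name
    impacted = domain_overlap(aa_start, aa_end, (domains or {}).get(gene, []))
    return AnnotatedIndel(
        gene_name=gene,
        model=model,
        candidates=list(candidates),
        lesions=lesions,
        frame_report=report,
        aa_start=aa_start,
        aa_end=aa_end,
        names=[name_mutation(gene, l, ascii_alias) for l in lesions],
        impacted_domains=impacted,
    )
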