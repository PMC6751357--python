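"""Gene–QTL marker distances and colocalization report.

Markers are peak linkage markers from published QTL studies, each tagged
with one of six broad trait categories.  The distance between a gene and a
same-chromosome marker is measured from the marker to the nearest gene-span
boundary (0 if the marker falls inside the span); a midpoint mode is
available for users who prefer gene-center distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gene_models import GeneModel

TRAIT_CATEGORIES = frozenset(
    {
        "pigmentation",
        "body morphology",
        "sensory",
        "craniofacial morphology",
        "eye morphology",
        "jaw morphology",
    }
)

DIFFERENT_CHROMOSOME = "different-chromosome"
UNPLACED = "unplaced"


@dataclass(frozen=True)
class QTLMarker:
    name: str
    trait: str
    chrom: str
    pos: int
    source: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"marker {self.name}: position must be >= 1")
        if self.trait not in TRAIT_CATEGORIES:
            raise ValueError(
                f"marker {self.name}: unknown trait category {self.trait!r} "
                f"(expected one of {sorted(TRAIT_CATEGORIES)})"
            )


@dataclass
class ColocRecord:
    gene: str
    marker: QTLMarker | None
    distance: int | str  # bp, DIFFERENT_CHROMOSOME, or UNPLACED
    rank: int | None  # 1 = nearest same-chromosome marker


def load_markers(path) -> list[QTLMarker]:
    """Marker TSV with columns marker, trait, chrom, pos, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "trait", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    markers = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            markers.append(
                QTLMarker(
                    name=row.marker,
                    trait=row.trait,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    source=getattr(row, "source", "") or "",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return markers


def gene_marker_distance(
    gene: GeneModel,
    marker: QTLMarker,
    mode: str = "boundary",
    unplaced_scaffolds: frozenset[str] = frozenset(),
) -> int | str:
    """bp distance, DIFFERENT_CHROMOSOME, or UNPLACED.

    ``boundary`` mode measures to the nearest gene-span edge (0 inside the
    span); ``midpoint`` measures to the span midpoint.
    """
    if gene.scaffold in unplaced_scaffolds:
        return UNPLACED
    if gene.scaffold != marker.chrom:
        return DIFFERENT_CHROMOSOME
    lo, hi = gene.genomic_span
    if mode == "midpoint":
        return abs((lo + hi) // 2 - marker.pos)
    if mode != "boundary":
        raise ValueError(f"unknown distance mode {mode!r}")
    if lo <= marker.pos <= hi:
        return 0
    return min(abs(lo - marker.pos), abs(hi - marker.pos))


def colocalize(
    genes: list[GeneModel],
    markers: list[QTLMarker],
    mode: str = "boundary",
    unplaced_scaffolds: frozenset[str] = frozenset(),
) -> list[ColocRecord]:
    """Per-gene ranked distance records for every same-chromosome marker.

    Unplaced genes and genes with no same-chromosome marker are reported
    once with a sentinel distance so no gene silently disappears.
    """
    records: list[ColocRecord] = []
    for gene in genes:
        if gene.scaffold in unplaced_scaffolds:
            records.append(ColocRecord(gene.gene_name, None, UNPLACED, None))
            continue
        same = [m for m in markers if m.chrom == gene.scaffold]
        if not same:
            records.append(
                ColocRecord(gene.gene_name, None, DIFFERENT_CHROMOSOME, None)
            )
            continue
        dists = sorted(
            (gene_marker_distance(gene, m, mode=mode), m.name, m) for m in same
        )
        for rank, (d, _, m) in enumerate(dists, start=1):
            records.append(ColocRecord(gene.gene_name, m, d, rank))
    return records


def coloc_table(records: list[ColocRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "gene": r.gene,
                "marker": r.marker.name if r.marker else "",
                "trait": r.marker.trait if r.marker else "",
                "chrom": r.marker.chrom if r.marker else "",
                "marker_pos": r.marker.pos if r.marker else "",
                "distance_bp": r.distance,
                "rank": r.rank if r.rank is not None else "",
            }
        )
    return pd.DataFrame(rows)
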