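"""The fixed-difference filter cascade applied to indel pileup sites.

Candidate lesions must lie on a large scaffold (>= 1 Mb by default), be
covered by at least 50 spanning reads, be carried by >= 98% of those reads,
and sit inside an exon away from splice boundaries (misassembly around
intron/exon junctions is a known source of false positives).  Every site
receives a machine-readable filter trace so the cascade is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gene_models import (
    GeneModel,
    GenomeError,
    ReferenceGenome,
    exon_boundary_distance,
    exon_of,
    genomic_to_cdna,
)
from .indel_caller import DELETION, INSERTION, IndelSite


@dataclass
class ScreenConfig:
    min_scaffold_bp: int = 1_000_000
    min_depth: int = 50
    min_allele_fraction: float = 0.98
    min_exon_boundary_bp: int = 10
    coding_only: bool = True
    transcript_ends_are_boundaries: bool = False

    def __post_init__(self):
        if min(self.min_scaffold_bp, self.min_depth, self.min_exon_boundary_bp) < 0:
            raise ValueError("thresholds must be >= 0")
        # values > 1 are permitted as a deliberate "nothing passes" setting
        if self.min_allele_fraction < 0:
            raise ValueError("min_allele_fraction must be >= 0")


@dataclass
class FilterResult:
    name: str
    passed: bool
    measured: object


@dataclass
class CandidateIndel:
    site: IndelSite
    model: GeneModel
    cdna_start: int  # 1-based; insertions: first base the insert occupies
    cdna_end: int
    trace: list[FilterResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.trace)


def filter_scaffold(
    site: IndelSite, genome: ReferenceGenome, cfg: ScreenConfig
) -> FilterResult:
    if site.scaffold not in genome.sequences:
        raise GenomeError(f"unknown scaffold {site.scaffold!r}")
    length = len(genome.sequences[site.scaffold])
    return FilterResult("scaffold_size", length >= cfg.min_scaffold_bp, length)


def filter_depth(site: IndelSite, cfg: ScreenConfig) -> FilterResult:
    return FilterResult("depth", site.depth >= cfg.min_depth, site.depth)


def filter_genotype(site: IndelSite, cfg: ScreenConfig) -> FilterResult:
    af = site.allele_fraction
    return FilterResult("allele_fraction", af >= cfg.min_allele_fraction, af)


def locate_site(
    site: IndelSite, models: list[GeneModel]
) -> tuple[GeneModel, int, int] | None:
    """Map a site onto a gene model's cDNA, or None if not cleanly exonic.

    Returns (model, cdna_start, cdna_end).  For deletions the interval is
    the deleted reference bases in cDNA coordinates; both ends must fall in
    the same exon.  For insertions the interval is the positions the
    inserted bases would occupy in the variant transcript (anchor+1 ..
    anchor+len); both genomic flanks must fall in the same exon.
    """
    for model in models:
        if model.scaffold != site.scaffold:
            continue
        if site.kind == DELETION:
            c1 = genomic_to_cdna(model, site.genomic_pos)
            c2 = genomic_to_cdna(model, site.genomic_pos + len(site.sequence) - 1)
            if c1 is None or c2 is None:
                continue
            lo, hi = min(c1, c2), max(c1, c2)
            if exon_of(model, lo)[0] != exon_of(model, hi)[0]:
                continue  # spans a splice junction: not a clean coding lesion
            return model, lo, hi
        # insertion between genomic pos and pos+1
        cl = genomic_to_cdna(model, site.genomic_pos)
        cr = genomic_to_cdna(model, site.genomic_pos + 1)
        if cl is None or cr is None:
            continue
        anchor = min(cl, cr)  # transcript-orientation base left of the insert
        if abs(cl - cr) != 1 or exon_of(model, cl)[0] != exon_of(model, cr)[0]:
            continue
        return model, anchor + 1, anchor + len(site.sequence)
    return None


def filter_exonic(
    site: IndelSite, models: list[GeneModel], cfg: ScreenConfig
) -> tuple[FilterResult, tuple[GeneModel, int, int] | None]:
    """Pass iff the site is exonic and far enough from splice boundaries."""
    located = locate_site(site, models)
    if located is None:
        return FilterResult("exonic", False, "non-exonic"), None
    model, lo, hi = located
    if site.kind == DELETION:
        probes = (lo, hi)
    else:
        probes = (lo - 1, lo)  # the two exonic flanks of the insertion point
    dist = min(
        exon_boundary_distance(
            model, p,
            transcript_ends_are_boundaries=cfg.transcript_ends_are_boundaries,
        )
        for p in probes
    )
    ok = dist >= cfg.min_exon_boundary_bp
    return FilterResult("exonic", ok, dist), located


def run_screen(
    sites: list[IndelSite],
    genome: ReferenceGenome,
    models: list[GeneModel],
    cfg: ScreenConfig | None = None,
) -> tuple[list[CandidateIndel], pd.DataFrame]:
    """Apply the cascade (scaffold -> depth -> genotype -> exonic) to every site.

    Returns surviving candidates plus an audit table with one row per input
    site and the measured value behind every pass/fail decision.
    """
    cfg = cfg or ScreenConfig()
    survivors: list[CandidateIndel] = []
    audit_rows = []
    for site in sites:
        trace = [
            filter_scaffold(site, genome, cfg),
            filter_depth(site, cfg),
            filter_genotype(site, cfg),
        ]
        exonic, located = filter_exonic(site, models, cfg)
        trace.append(exonic)
        row = {
            "scaffold": site.scaffold,
            "genomic_pos": site.genomic_pos,
            "kind": site.kind,
            "sequence": site.sequence,
            "population": site.population,
        }
        for r in trace:
            row[f"{r.name}_pass"] = r.passed
            row[f"{r.name}_value"] = r.measured
        audit_rows.append(row)
        if all(r.passed for r in trace):
            model, lo, hi = located
            survivors.append(
                CandidateIndel(
                    site=site, model=model, cdna_start=lo, cdna_end=hi, trace=trace
                )
            )
    audit = pd.DataFrame(audit_rows)
    return survivors, audit
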