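"""End-to-end screen: alignments in, classified coding lesions out.

Stages: load reference + gene models, extract and left-align indel events
from each population's alignment, run the filter cascade on each
population's merged sites, group surviving candidates by transcript,
annotate frames/names/domains, classify cross-population sharing with
outgroup polarization, and (optionally) measure QTL marker distances.

The per-stage counts recorded in the manifest satisfy
``called >= screened >= annotated == compared``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .frame_annotator import load_domains
from .gene_models import GeneModel, ReferenceGenome, load_gene_models, load_genome
from .indel_caller import IndelSite, PopulationAlignment
from .population_compare import PopulationComparison, compare_all
from .qtl_coloc import ColocRecord, colocalize, load_markers
from .report import RunManifest, write_outputs
from .screen_filters import CandidateIndel, ScreenConfig, run_screen

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    genome: ReferenceGenome
    models: list[GeneModel]
    alignments: dict[str, PopulationAlignment]
    sites: dict[str, list[IndelSite]]  # per population
    candidates: list[CandidateIndel]  # unique screened sites
    audit: pd.DataFrame
    groups: dict[str, list[CandidateIndel]]  # gene -> candidates
    comparisons: list[PopulationComparison]
    coloc: list[ColocRecord] | None
    manifest: RunManifest
    output_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return self.manifest.counts


def load_outgroup(path) -> dict[str, str]:
    """FASTA of outgroup ortholog cDNAs keyed by gene symbol."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def _dedupe_candidates(
    per_pop: list[list[CandidateIndel]],
) -> list[CandidateIndel]:
    """Unique screened sites; if several populations pass the cascade at the
    same locus keep the first (population input order is deterministic)."""
    seen: set[tuple] = set()
    unique = []
    for cands in per_pop:
        for cand in cands:
            key = cand.site.key
            if key in seen:
                continue
            seen.add(key)
            unique.append(cand)
    return unique


def run_pipeline(
    genome_path,
    gff_path,
    sam_paths: dict[str, object],
    outgroup_path=None,
    domains_path=None,
    markers_path=None,
    cfg: ScreenConfig | None = None,
    outdir=None,
    surface_label: str = "Surface",
    cave_labels: tuple[str, ...] = ("Pachon", "Tinaja"),
    unplaced_scaffolds: frozenset[str] = frozenset(),
    cds_offsets: dict[str, int] | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the whole screen; writes the standard output set when ``outdir``
    is given.

    ``sam_paths`` maps population labels to SAM/BAM paths and must include
    the surface label and every cave label.
    """
    cfg = cfg or ScreenConfig()
    for label in (surface_label, *cave_labels):
        if label not in sam_paths:
            raise ValueError(f"missing alignment for population {label!r}")

    genome = load_genome(genome_path)
    models = load_gene_models(gff_path, genome, cds_offsets=cds_offsets)
    domains = load_domains(domains_path) if domains_path else None
    outgroup = load_outgroup(outgroup_path) if outgroup_path else None

    manifest = RunManifest(config=cfg, seed=seed)
    for path in (genome_path, gff_path, outgroup_path, domains_path,
                 markers_path, *sam_paths.values()):
        if path:
            manifest.add_input(path)

    alignments: dict[str, PopulationAlignment] = {}
    sites: dict[str, list[IndelSite]] = {}
    for label in (surface_label, *cave_labels):
        aln = PopulationAlignment.from_sam(sam_paths[label], label, genome)
        alignments[label] = aln
        sites[label] = aln.sites()
        log.info("%s: %d reads, %d distinct indel sites",
                 label, aln.n_reads, len(sites[label]))

    per_pop_survivors = []
    audits = []
    for label in (surface_label, *cave_labels):
        survivors, audit = run_screen(sites[label], genome, models, cfg)
        per_pop_survivors.append(survivors)
        audits.append(audit)
    audit = (
        pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
    )
    candidates = _dedupe_candidates(per_pop_survivors)

    groups: dict[str, list[CandidateIndel]] = {}
    for cand in candidates:
        groups.setdefault(cand.model.gene_name, []).append(cand)

    comparisons = compare_all(
        groups,
        alignments,
        genome,
        cfg=cfg,
        outgroup=outgroup,
        domains=domains,
        surface_label=surface_label,
        cave_labels=cave_labels,
    )

    coloc = None
    if markers_path:
        markers = load_markers(markers_path)
        screened_models = [
            next(c.model for c in groups[g]) for g in sorted(groups)
        ]
        coloc = colocalize(
            screened_models, markers, unplaced_scaffolds=frozenset(unplaced_scaffolds)
        )

    n_called = sum(len(s) for s in sites.values())
    n_screened = sum(len(s) for s in per_pop_survivors)
    manifest.counts.update(
        {
            "reads": sum(a.n_reads for a in alignments.values()),
            "called_sites": n_called,
            "screened_sites": n_screened,
            "unique_candidates": len(candidates),
            "annotated_groups": len(groups),
            "compared_groups": len(comparisons),
        }
    )
    assert n_called >= n_screened >= len(candidates)
    assert len(groups) == len(comparisons)

    result = PipelineResult(
        genome=genome,
        models=models,
        alignments=alignments,
        sites=sites,
        candidates=candidates,
        audit=audit,
        groups=groups,
        comparisons=comparisons,
        coloc=coloc,
        manifest=manifest,
    )
    if outdir is not None:
        all_sites = [s for label in sites for s in sites[label]]
        result.output_paths = write_outputs(
            outdir, comparisons, genome, all_sites, audit, coloc, manifest
        )
    return result
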