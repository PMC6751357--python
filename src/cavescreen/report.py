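"""Result serialization: VCF, summary tables, and the run manifest.

The VCF writer follows the VCF 4.2 anchor-base convention: an insertion
after reference base ``p`` is written at POS ``p`` with REF = that base and
ALT = REF + inserted bases; a deletion of ``[p, p+L-1]`` is written at POS
``p-1`` with REF covering the anchor plus the deleted bases.  Mutation
names carried in INFO use the ASCII alias form (``del`` / hyphen) so the
file stays 7-bit clean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .frame_annotator import classify_frame, name_mutation
from .gene_models import ReferenceGenome
from .indel_caller import DELETION, INSERTION, IndelSite
from .population_compare import PopulationComparison
from .qtl_coloc import ColocRecord, coloc_table
from .screen_filters import ScreenConfig


@dataclass(frozen=True)
class VCFEntry:
    scaffold: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str
    info: tuple[tuple[str, object], ...] = ()


def vcf_entry(
    site: IndelSite, genome: ReferenceGenome, info: dict | None = None
) -> VCFEntry:
    """Express a caller-convention site as an anchored VCF record."""
    info = dict(info or {})
    info.setdefault("DP", site.depth)
    info.setdefault("AF", round(site.allele_fraction, 6))
    if site.kind == INSERTION:
        anchor = genome.fetch(site.scaffold, site.genomic_pos, site.genomic_pos)
        return VCFEntry(
            site.scaffold, site.genomic_pos, anchor, anchor + site.sequence,
            tuple(sorted(info.items())),
        )
    if site.kind != DELETION:
        raise ValueError(f"unknown event kind {site.kind!r}")
    if site.genomic_pos < 2:
        raise ValueError("cannot anchor a deletion at scaffold position 1")
    ref = genome.fetch(
        site.scaffold,
        site.genomic_pos - 1,
        site.genomic_pos + len(site.sequence) - 1,
    )
    return VCFEntry(
        site.scaffold, site.genomic_pos - 1, ref, ref[0],
        tuple(sorted(info.items())),
    )


def entry_to_site_key(entry: VCFEntry) -> tuple[str, int, str, str]:
    """Inverse of :func:`vcf_entry` (caller site key, no counts)."""
    if len(entry.alt) > len(entry.ref):  # insertion
        if not entry.alt.startswith(entry.ref):
            raise ValueError(f"non-anchored ALT {entry.alt!r} vs REF {entry.ref!r}")
        return (
            entry.scaffold, entry.pos, INSERTION, entry.alt[len(entry.ref):],
        )
    if len(entry.ref) > len(entry.alt):  # deletion
        if not entry.ref.startswith(entry.alt):
            raise ValueError(f"non-anchored REF {entry.ref!r} vs ALT {entry.alt!r}")
        return (
            entry.scaffold, entry.pos + len(entry.alt), DELETION,
            entry.ref[len(entry.alt):],
        )
    raise ValueError("entry is not an indel")


_INFO_DEFS = {
    "DP": ("1", "Integer", "Spanning-read depth in the observing population"),
    "AF": ("1", "Float", "Indel allele fraction among spanning reads"),
    "GENE": ("1", "String", "Gene symbol of the containing transcript"),
    "NAME": ("1", "String", "Mutation name (ASCII alias form)"),
    "FRAME": ("1", "String", "Reading-frame class of the lesion"),
    "SHARING": ("1", "String", "Cross-population sharing class"),
    "POP": ("1", "String", "Population whose alignment shows the variant"),
}


def write_vcf(path, entries: list[VCFEntry], genome: ReferenceGenome) -> None:
    """Minimal, deterministic VCF 4.2 writer (sites only, no genotypes)."""
    lines = ["##fileformat=VCFv4.2", f"##source=cavescreen {__version__}"]
    for name, length in sorted(genome.lengths.items()):
        lines.append(f"##contig=<ID={name},length={length}>")
    for key, (num, typ, desc) in _INFO_DEFS.items():
        lines.append(
            f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for e in sorted(entries, key=lambda e: (e.scaffold, e.pos, e.alt)):
        info = ";".join(
            f"{k}={str(v).replace(' ', '_')}" for k, v in e.info
        ) or "."
        lines.append(
            f"{e.scaffold}\t{e.pos}\t.\t{e.ref}\t{e.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def comparison_table(comparisons: list[PopulationComparison]) -> pd.DataFrame:
    """One row per screened transcript group (the headline results table)."""
    rows = []
    for comp in comparisons:
        ann = comp.annotated
        model = ann.model
        pol = comp.polarization
        rows.append(
            {
                "gene": ann.gene_name,
                "scaffold": model.scaffold,
                "strand": model.strand,
                "name": ann.name,
                "observed_name": comp.observed.name,
                "sharing_class": comp.sharing_class,
                "cave_carries": comp.cave_carries,
                "frame_classes": "+".join(ann.frame_report.classes),
                "net_frame_offset": ann.frame_report.net_offset,
                "restoration_pos": ann.frame_report.restoration_pos,
                "lesion_lengths": "+".join(
                    str(len(l.sequence)) for l in ann.lesions
                ),
                "aa_start": ann.aa_start,
                "aa_end": ann.aa_end,
                "domains": ";".join(
                    d.domain_name for d in ann.impacted_domains
                ),
                **{
                    f"{p}_depth": s.depth for p, s in sorted(comp.states.items())
                },
                **{
                    f"{p}_af": round(s.allele_fraction, 4)
                    for p, s in sorted(comp.states.items())
                },
                "ancestral": pol.ancestral,
                "surface_outgroup_identity": (
                    round(pol.surface_identity, 4)
                    if pol.surface_identity is not None else ""
                ),
                "cave_outgroup_identity": (
                    round(pol.cave_identity, 4)
                    if pol.cave_identity is not None else ""
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene", "scaffold", "strand", "name", "observed_name",
                "sharing_class", "cave_carries", "frame_classes",
                "net_frame_offset", "restoration_pos", "lesion_lengths",
                "aa_start", "aa_end", "domains", "ancestral",
                "surface_outgroup_identity", "cave_outgroup_identity",
            ]
        )
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)


def sites_table(sites: list[IndelSite]) -> pd.DataFrame:
    rows = [
        {
            "scaffold": s.scaffold,
            "genomic_pos": s.genomic_pos,
            "kind": s.kind,
            "sequence": s.sequence,
            "population": s.population,
            "depth": s.depth,
            "alt_count": s.alt_count,
            "allele_fraction": round(s.allele_fraction, 6),
        }
        for s in sites
    ]
    return pd.DataFrame(rows)


def comparison_vcf_entries(
    comparisons: list[PopulationComparison], genome: ReferenceGenome
) -> list[VCFEntry]:
    entries = []
    for comp in comparisons:
        ann = comp.observed
        for cand, lesion in zip(ann.candidates, ann.lesions):
            entries.append(
                vcf_entry(
                    cand.site,
                    genome,
                    {
                        "GENE": ann.gene_name,
                        "NAME": name_mutation(
                            ann.gene_name, lesion, ascii_alias=True
                        ),
                        "FRAME": classify_frame(lesion),
                        "SHARING": comp.sharing_class,
                        "POP": cand.site.population,
                    },
                )
            )
    return entries


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output set."""

    config: ScreenConfig
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": dataclasses.asdict(self.config),
                "inputs": dict(sorted(self.inputs.items())),
                "counts": self.counts,
            },
            indent=2,
            sort_keys=False,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def write_outputs(
    outdir,
    comparisons: list[PopulationComparison],
    genome: ReferenceGenome,
    sites: list[IndelSite],
    audit: pd.DataFrame,
    coloc: list[ColocRecord] | None,
    manifest: RunManifest,
) -> dict[str, Path]:
    """Write the standard output set; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.tsv",
        "audit": outdir / "filter_audit.tsv",
        "comparisons": outdir / "comparisons.tsv",
        "vcf": outdir / "lesions.vcf",
        "manifest": outdir / "manifest.json",
    }
    sites_table(sites).to_csv(paths["sites"], sep="\t", index=False)
    audit.to_csv(paths["audit"], sep="\t", index=False)
    comparison_table(comparisons).to_csv(
        paths["comparisons"], sep="\t", index=False
    )
    write_vcf(paths["vcf"], comparison_vcf_entries(comparisons, genome), genome)
    if coloc is not None:
        paths["coloc"] = outdir / "qtl_coloc.tsv"
        coloc_table(coloc).to_csv(paths["coloc"], sep="\t", index=False)
    manifest.write(paths["manifest"])
    return paths
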