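"""Cross-population sharing classes and outgroup polarization.

The reference genome in this screen carries the cave (Pachón) haplotype, so
a lesion shared by both cave lineages shows up as a *variant in the surface
alignment*: surface reads disagree with the reference while cave reads match
it.  This module makes that inversion explicit — every locus is reported
both in variant-vs-reference orientation and in cave-vs-surface orientation
— and polarizes the two alleles against an outgroup ortholog (zebrafish in
the original screen) by global pairwise alignment identity.

Sharing classes partition all loci:

* shared-cave      — both cave lineages carry one allele, surface the other
* single-cave(X)   — exactly one cave lineage differs from the other two
* surface-specific — a shared-cave genotype pattern whose polarization calls
                     the cave allele ancestral (the change happened on the
                     surface branch)
* uninformative    — any polymorphic or low-coverage population, or no
                     between-morph difference
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .frame_annotator import AnnotatedIndel, Lesion, annotate, lesion_from_candidate
from .gene_models import ReferenceGenome, transcript_sequence
from .indel_caller import DELETION, INSERTION, PopulationAlignment
from .screen_filters import CandidateIndel, ScreenConfig

VARIANT_FIXED = "variant-fixed"
REFERENCE_FIXED = "reference-fixed"
POLYMORPHIC = "polymorphic"
LOW_COVERAGE = "low-coverage"

SHARED_CAVE = "shared-cave"
SINGLE_CAVE = "single-cave"  # reported as "single-cave(<population>)"
SURFACE_SPECIFIC = "surface-specific"
UNINFORMATIVE = "uninformative"

SURFACE_LIKE = "surface-like"
CAVE_LIKE = "cave-like"
UNRESOLVED = "unresolved"


@dataclass
class PopulationState:
    population: str
    depth: int
    alt_count: int
    state: str

    @property
    def allele_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class PolarizationResult:
    ancestral: str
    surface_identity: float | None
    cave_identity: float | None


@dataclass
class PopulationComparison:
    annotated: AnnotatedIndel  # cave/surface-oriented lesions and names
    observed: AnnotatedIndel  # variant-vs-reference orientation
    states: dict[str, PopulationState]
    sharing_class: str
    cave_carries: str  # kind summary of the cave allele's lesions
    polarization: PolarizationResult = field(
        default_factory=lambda: PolarizationResult(UNRESOLVED, None, None)
    )


def genotype_state(depth: int, alt_count: int, cfg: ScreenConfig) -> str:
    """Classify one population's evidence at one locus."""
    if depth < cfg.min_depth:
        return LOW_COVERAGE
    af = alt_count / depth
    if af >= cfg.min_allele_fraction:
        return VARIANT_FIXED
    if af <= 1 - cfg.min_allele_fraction:
        return REFERENCE_FIXED
    return POLYMORPHIC


def sharing_class(
    states: dict[str, str],
    surface_label: str = "Surface",
    cave_labels: tuple[str, ...] = ("Pachon", "Tinaja"),
) -> str:
    """Locus sharing class from per-population genotype states."""
    for label in (surface_label, *cave_labels):
        if label not in states:
            raise KeyError(f"missing population {label!r}")
    if any(
        states[p] in (POLYMORPHIC, LOW_COVERAGE)
        for p in (surface_label, *cave_labels)
    ):
        return UNINFORMATIVE
    surface_v = states[surface_label] == VARIANT_FIXED
    caves_v = [states[c] == VARIANT_FIXED for c in cave_labels]
    if surface_v and not any(caves_v):
        return SHARED_CAVE  # cave allele == reference
    if not surface_v and all(caves_v):
        return SHARED_CAVE  # reference carries the surface allele
    if not surface_v and sum(caves_v) == 1:
        which = cave_labels[caves_v.index(True)]
        return f"{SINGLE_CAVE}({which})"
    return UNINFORMATIVE


def polarize(
    surface_seq: str, cave_seq: str, outgroup_seq: str
) -> PolarizationResult:
    """Call the ancestral allele by global-alignment identity to the outgroup.

    Identity = matched columns / alignment columns under match +1,
    mismatch -1, gap open -2, gap extend -0.5.  Ties are unresolved.
    """
    if not (surface_seq and cave_seq and outgroup_seq):
        raise ValueError("empty sequence passed to polarize")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5

    def identity(a: str, b: str) -> float:
        aln = aligner.align(a.upper(), b.upper())[0]
        counts = aln.counts()
        return counts.identities / aln.length

    s_id = identity(surface_seq, outgroup_seq)
    c_id = identity(cave_seq, outgroup_seq)
    if s_id > c_id:
        call = SURFACE_LIKE
    elif c_id > s_id:
        call = CAVE_LIKE
    else:
        call = UNRESOLVED
    return PolarizationResult(call, s_id, c_id)


def oriented_lesions(candidates: list[CandidateIndel], flip: bool) -> list[Lesion]:
    """Re-express observed events in the lesion-carrying allele's coordinates.

    With ``flip`` the reference carries the cave allele: observed deletions
    become cave insertions (keeping reference cDNA coordinates — the inserted
    bases are reference bases) and observed insertions become cave deletions
    whose coordinates are shifted into the surface allele's cDNA by the net
    length of upstream events.  Without ``flip`` kinds are kept and the same
    shift places inserted bases in the variant allele's cDNA.
    """
    out: list[Lesion] = []
    shift = 0
    for cand in sorted(candidates, key=lambda c: c.cdna_start):
        lesion = lesion_from_candidate(cand)
        n = len(lesion.sequence)
        if lesion.kind == DELETION:
            kind = INSERTION if flip else DELETION
            out.append(Lesion(kind, lesion.cdna_start, lesion.cdna_end, lesion.sequence))
            shift -= n
        else:
            kind = DELETION if flip else INSERTION
            anchor = lesion.cdna_start - 1  # reference-space anchor
            # place the bases in the allele that carries them
            start = anchor + shift + 1
            out.append(Lesion(kind, start, start + n - 1, lesion.sequence))
            shift += n
    return out


def apply_observed_events(
    ref_cdna: str, candidates: list[CandidateIndel]
) -> str:
    """Variant-allele cDNA obtained by applying observed events to the
    reference transcript."""
    parts = []
    cur = 1
    for cand in sorted(candidates, key=lambda c: c.cdna_start):
        lesion = lesion_from_candidate(cand)
        if lesion.kind == DELETION:
            parts.append(ref_cdna[cur - 1 : lesion.cdna_start - 1])
            cur = lesion.cdna_end + 1
        else:
            anchor = lesion.cdna_start - 1
            parts.append(ref_cdna[cur - 1 : anchor])
            parts.append(lesion.sequence)
            cur = anchor + 1
    parts.append(ref_cdna[cur - 1 :])
    return "".join(parts)


def compare_all(
    candidate_groups: dict[str, list[CandidateIndel]],
    alignments: dict[str, PopulationAlignment],
    genome: ReferenceGenome,
    cfg: ScreenConfig | None = None,
    outgroup: dict[str, str] | None = None,
    domains=None,
    surface_label: str = "Surface",
    cave_labels: tuple[str, ...] = ("Pachon", "Tinaja"),
    polarization_window: int = 60,
) -> list[PopulationComparison]:
    """One PopulationComparison per screened transcript group."""
    cfg = cfg or ScreenConfig()
    results = []
    for gene, cands in sorted(candidate_groups.items()):
        cands = sorted(cands, key=lambda c: c.cdna_start)
        model = cands[0].model
        # per-population combined state over the group's sites
        states: dict[str, PopulationState] = {}
        for label in (surface_label, *cave_labels):
            aln = alignments[label]
            site_states, depth_min, alt_min = [], None, None
            for cand in cands:
                site = cand.site
                depth = aln.depth_at(
                    site.scaffold, site.kind, site.genomic_pos, len(site.sequence)
                )
                alt = aln.alt_count(
                    site.scaffold, site.kind, site.genomic_pos, site.sequence
                )
                site_states.append(genotype_state(depth, alt, cfg))
                if depth_min is None or depth < depth_min:
                    depth_min, alt_min = depth, alt
            if len(set(site_states)) == 1:
                combined = site_states[0]
            elif LOW_COVERAGE in site_states:
                combined = LOW_COVERAGE
            else:
                combined = POLYMORPHIC
            states[label] = PopulationState(label, depth_min or 0, alt_min or 0, combined)

        share = sharing_class(
            {p: s.state for p, s in states.items()}, surface_label, cave_labels
        )
        # orientation: reference carries the cave allele exactly when the
        # variant is fixed in the surface population alone
        flip = (
            share == SHARED_CAVE
            and states[surface_label].state == VARIANT_FIXED
        )
        lesions = oriented_lesions(cands, flip)
        observed = annotate(cands, domains)
        reoriented = annotate(cands, domains, lesions=lesions)

        # polarization over a window spanning all of the group's events
        polar = PolarizationResult(UNRESOLVED, None, None)
        if outgroup and gene in outgroup and share != UNINFORMATIVE:
            ref_cdna = transcript_sequence(model, genome)
            variant_cdna = apply_observed_events(ref_cdna, cands)
            lo = min(c.cdna_start for c in cands)
            hi = max(c.cdna_end for c in cands)
            net = len(variant_cdna) - len(ref_cdna)
            ws, we = max(1, lo - polarization_window), min(
                len(ref_cdna), hi + polarization_window
            )
            ref_win = ref_cdna[ws - 1 : we]
            var_win = variant_cdna[ws - 1 : we + net]
            surface_is_variant = states[surface_label].state == VARIANT_FIXED
            surface_win = var_win if surface_is_variant else ref_win
            cave_win = ref_win if surface_is_variant else var_win
            out_seq = outgroup[gene]
            out_win = out_seq[ws - 1 : min(len(out_seq), we + max(net, 0))]
            if out_win:
                polar = polarize(surface_win, cave_win, out_win)
        final_share = share
        if share == SHARED_CAVE and polar.ancestral == CAVE_LIKE:
            final_share = SURFACE_SPECIFIC

        cave_kinds = sorted({l.kind for l in lesions})
        results.append(
            PopulationComparison(
                annotated=reoriented,
                observed=observed,
                states=states,
                sharing_class=final_share,
                cave_carries="+".join(cave_kinds),
                polarization=polar,
            )
        )
    return results
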