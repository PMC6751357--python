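import pytest

from cavescreen.frame_annotator import Lesion
from cavescreen.gene_models import Exon, GeneModel, ReferenceGenome
from cavescreen.indel_caller import DELETION, INSERTION, IndelSite
from cavescreen.pipeline import run_pipeline
from cavescreen.population_compare import (
    CAVE_LIKE,
    LOW_COVERAGE,
    POLYMORPHIC,
    REFERENCE_FIXED,
    SHARED_CAVE,
    SURFACE_LIKE,
    UNINFORMATIVE,
    UNRESOLVED,
    VARIANT_FIXED,
    apply_observed_events,
    genotype_state,
    oriented_lesions,
    polarize,
    sharing_class,
)
from cavescreen.screen_filters import CandidateIndel, ScreenConfig
from cavescreen.synthetic_data import LesionSpec, POPULATIONS


class TestGenotypeState:
    def setup_method(self):
        self.cfg = ScreenConfig()

    def test_low_coverage_overrides(self):
        assert genotype_state(30, 30, self.cfg) == LOW_COVERAGE
        assert genotype_state(49, 0, self.cfg) == LOW_COVERAGE

    def test_fixed_states(self):
        assert genotype_state(100, 99, self.cfg) == VARIANT_FIXED
        assert genotype_state(100, 98, self.cfg) == VARIANT_FIXED
        assert genotype_state(100, 1, self.cfg) == REFERENCE_FIXED
        assert genotype_state(100, 2, self.cfg) == REFERENCE_FIXED

    def test_polymorphic_between(self):
        assert genotype_state(100, 50, self.cfg) == POLYMORPHIC
        assert genotype_state(100, 97, self.cfg) == POLYMORPHIC
        assert genotype_state(100, 3, self.cfg) == POLYMORPHIC


class TestSharingClass:
    def classify(self, surface, pachon, tinaja):
        return sharing_class(
            {"Surface": surface, "Pachon": pachon, "Tinaja": tinaja}
        )

    def test_reference_carries_cave_allele(self):
        # variant fixed in surface only: lesion shared by both caves
        assert self.classify(
            VARIANT_FIXED, REFERENCE_FIXED, REFERENCE_FIXED
        ) == SHARED_CAVE

    def test_reference_carries_surface_allele(self):
        assert self.classify(
            REFERENCE_FIXED, VARIANT_FIXED, VARIANT_FIXED
        ) == SHARED_CAVE

    def test_single_cave(self):
        assert self.classify(
            REFERENCE_FIXED, REFERENCE_FIXED, VARIANT_FIXED
        ) == "single-cave(Tinaja)"
        assert self.classify(
            REFERENCE_FIXED, VARIANT_FIXED, REFERENCE_FIXED
        ) == "single-cave(Pachon)"

    def test_uninformative_patterns(self):
        assert self.classify(
            VARIANT_FIXED, VARIANT_FIXED, VARIANT_FIXED
        ) == UNINFORMATIVE  # no between-morph difference
        assert self.classify(
            REFERENCE_FIXED, REFERENCE_FIXED, REFERENCE_FIXED
        ) == UNINFORMATIVE
        assert self.classify(
            VARIANT_FIXED, VARIANT_FIXED, REFERENCE_FIXED
        ) == UNINFORMATIVE  # mixed, not a clean morph split
        assert self.classify(
            POLYMORPHIC, REFERENCE_FIXED, VARIANT_FIXED
        ) == UNINFORMATIVE
        assert self.classify(
            VARIANT_FIXED, LOW_COVERAGE, REFERENCE_FIXED
        ) == UNINFORMATIVE

    def test_missing_population_rejected(self):
        with pytest.raises(KeyError):
            sharing_class({"Surface": VARIANT_FIXED, "Pachon": REFERENCE_FIXED})


class TestPolarize:
    def test_surface_closer_to_outgroup(self):
        out = "ACGTACGTACGTACGTACGT"
        surface = "ACGTACGTACGTACGTACGT"
        cave = "ACGTACGTTTTACGTACGT"
        res = polarize(surface, cave, out)
        assert res.ancestral == SURFACE_LIKE
        assert res.surface_identity == 1.0
        assert res.cave_identity < 1.0

    def test_cave_closer_to_outgroup(self):
        out = "ACGTACGTACGTACGTACGT"
        res = polarize("ACGTACGTTTTACGTACGT", out, out)
        assert res.ancestral == CAVE_LIKE

    def test_tie_unresolved(self):
        res = polarize("ACGTAAAA", "ACGTAAAA", "ACGTAAAA")
        assert res.ancestral == UNRESOLVED

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            polarize("", "ACGT", "ACGT")


def make_candidates(events, cdna_length=7000):
    """events: list of (kind, cdna_start, cdna_end, seq) on a + strand gene."""
    model = GeneModel("g", "g", "s", "+", [Exon(1, cdna_length, 1)])
    cands = []
    for kind, lo, hi, seq in events:
        gpos = lo if kind == DELETION else lo - 1
        site = IndelSite("s", gpos, kind, seq, "Surface", 60, 60)
        cands.append(CandidateIndel(site, model, lo, hi))
    return cands


class TestOrientedLesions:
    def test_plg_compound_reorientation(self):
        cands = make_candidates(
            [(DELETION, 290, 290, "T"), (INSERTION, 295, 295, "C")]
        )
        out = oriented_lesions(cands, flip=True)
        assert [(l.kind, l.cdna_start, l.cdna_end, l.sequence) for l in out] == [
            (INSERTION, 290, 290, "T"),
            (DELETION, 294, 294, "C"),
        ]

    def test_mki67_compound_reorientation(self):
        ins36 = "CCCAAAACCCCTTCACCATCCTCATGCCCAGCAATG"
        cands = make_candidates(
            [(DELETION, 1957, 1992, ins36), (INSERTION, 2190, 2192, "TTG")]
        )
        out = oriented_lesions(cands, flip=True)
        assert [(l.kind, l.cdna_start, l.cdna_end) for l in out] == [
            (INSERTION, 1957, 1992),
            (DELETION, 2154, 2156),
        ]

    def test_no_flip_keeps_observed_kinds(self):
        cands = make_candidates([(INSERTION, 626, 631, "TGAGAT")])
        out = oriented_lesions(cands, flip=False)
        assert [(l.kind, l.cdna_start, l.cdna_end) for l in out] == [
            (INSERTION, 626, 631)
        ]


class TestApplyObservedEvents:
    def test_round_trip_against_generator_alleles(self, universe):
        # applying the called events to the reference transcript must rebuild
        # the carrier population's allele exactly
        fx = universe.fixture
        for gene, build in fx.builds.items():
            carriers = build.events[0].carrier_pops
            events = [
                (
                    ev.kind,
                    ev.ref_cdna_start if ev.kind == DELETION
                    else ev.ref_cdna_start + 1,
                    (ev.ref_cdna_start + ev.ref_cdna_len - 1)
                    if ev.kind == DELETION
                    else ev.ref_cdna_start + ev.ref_cdna_len,
                    ev.seq_transcript,
                )
                for ev in build.events
            ]
            cands = make_candidates(events, cdna_length=len(build.ref_cdna))
            rebuilt = apply_observed_events(build.ref_cdna, cands)
            assert rebuilt == build._alleles[carriers[0]], gene


class TestEndToEndComparisons:
    def test_sharing_classes_match_truth(self, universe, pipeline_result):
        expected = {
            t.gene: t.expected_sharing
            for t in universe.fixture.truth if t.expect_survival
        }
        got = {
            c.annotated.gene_name: c.sharing_class
            for c in pipeline_result.comparisons
        }
        assert got == expected

    def test_polarization_calls_surface_ancestral(self, pipeline_result):
        for comp in pipeline_result.comparisons:
            assert comp.polarization.ancestral == SURFACE_LIKE
            assert comp.polarization.surface_identity \
                > comp.polarization.cave_identity

    def test_oriented_names_match_truth(self, universe, pipeline_result):
        expected = {}
        for t in universe.fixture.truth:
            if t.expect_survival:
                expected.setdefault(t.gene, []).append(t.expected_name)
        got = {
            c.annotated.gene_name: sorted(c.annotated.names)
            for c in pipeline_result.comparisons
        }
        assert got == {g: sorted(names) for g, names in expected.items()}


class TestReferenceInversionMetamorphic:
    def run_single_gene(self, tmp_path, reference_carries):
        spec = LesionSpec(
            gene="genx",
            kind=INSERTION,
            cdna_start=500,
            cdna_end=505,
            sequence="TGACCA",
            exon_ordinal=2,
            exon_count=4,
            cdna_length=1200,
            strand="+",
            carriers=("Pachon", "Tinaja"),
            reference_carries=reference_carries,
        )
        from cavescreen.synthetic_data import (
            build_fixture,
            make_marker_fixture,
            simulate_reads,
        )
        tag = "cave_ref" if reference_carries else "surface_ref"
        outdir = tmp_path / tag
        fx = build_fixture([spec], seed=7, outdir=outdir, include_decoys=False)
        sams = {}
        for pop in POPULATIONS:
            sams[pop] = outdir / f"{pop}.sam"
            simulate_reads(fx, pop, sams[pop], seed=7)
        return run_pipeline(
            genome_path=fx.genome_path,
            gff_path=fx.gff_path,
            sam_paths=sams,
            outgroup_path=fx.outgroup_path,
        )

    def test_inverting_the_reference_leaves_the_biology_invariant(self, tmp_path):
        res_cave_ref = self.run_single_gene(tmp_path, reference_carries=True)
        res_surface_ref = self.run_single_gene(tmp_path, reference_carries=False)
        (a,) = res_cave_ref.comparisons
        (b,) = res_surface_ref.comparisons
        # observed orientations differ ...
        assert a.observed.lesions[0].kind == DELETION
        assert b.observed.lesions[0].kind == INSERTION
        # ... but the cave-vs-surface report is identical
        assert a.sharing_class == b.sharing_class == SHARED_CAVE
        assert a.annotated.name == b.annotated.name == "genx^Ins500–505"
        assert a.annotated.frame_report.classes \
            == b.annotated.frame_report.classes
        assert a.polarization.ancestral == b.polarization.ancestral == SURFACE_LIKE
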