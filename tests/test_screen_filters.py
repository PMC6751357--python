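import pytest
from hypothesis import given
from hypothesis import strategies as st

from cavescreen.gene_models import Exon, GeneModel, GenomeError, ReferenceGenome
from cavescreen.indel_caller import DELETION, INSERTION, IndelSite
from cavescreen.screen_filters import (
    ScreenConfig,
    filter_depth,
    filter_exonic,
    filter_genotype,
    filter_scaffold,
    locate_site,
    run_screen,
)


@pytest.fixture
def mini():
    genome = ReferenceGenome(
        {"big": "ACGT" * 300_000, "small": "ACGT" * 100}  # 1.2 Mb / 400 bp
    )
    # two exons: cDNA 1-100 at genomic 101-200, cDNA 101-200 at genomic 301-400
    model = GeneModel(
        "g", "g", "big", "+", [Exon(101, 200, 1), Exon(301, 400, 2)]
    )
    return genome, model


def site(scaffold="big", pos=150, kind=INSERTION, seq="TGT",
         depth=60, alt=60, pop="Surface"):
    return IndelSite(scaffold, pos, kind, seq, pop, depth, alt)


class TestThresholdBoundaries:
    def test_depth_50_passes_49_fails(self):
        cfg = ScreenConfig()
        assert filter_depth(site(depth=50, alt=50), cfg).passed
        assert not filter_depth(site(depth=49, alt=49), cfg).passed

    def test_fraction_098_passes_0979_fails(self):
        cfg = ScreenConfig()
        assert filter_genotype(site(depth=1000, alt=980), cfg).passed
        assert not filter_genotype(site(depth=1000, alt=979), cfg).passed

    def test_scaffold_1mb_passes_999999_fails(self):
        cfg = ScreenConfig()
        genome = ReferenceGenome({"a": "A" * 1_000_000, "b": "A" * 999_999})
        assert filter_scaffold(site("a", 10), genome, cfg).passed
        assert not filter_scaffold(site("b", 10), genome, cfg).passed

    def test_unknown_scaffold_errors(self):
        with pytest.raises(GenomeError):
            filter_scaffold(site("nope"), ReferenceGenome({"a": "ACGT"}),
                            ScreenConfig())


class TestConfig:
    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(min_depth=-1)
        with pytest.raises(ValueError):
            ScreenConfig(min_allele_fraction=-0.1)

    def test_fraction_above_one_allowed_as_nothing_passes(self):
        cfg = ScreenConfig(min_allele_fraction=1.01)
        assert not filter_genotype(site(depth=100, alt=100), cfg).passed


class TestLocateSite:
    def test_deletion_maps_to_cdna(self, mini):
        _, model = mini
        located = locate_site(site(pos=150, kind=DELETION, seq="ACG"), [model])
        assert located is not None
        _, lo, hi = located
        assert (lo, hi) == (50, 52)

    def test_insertion_interval_is_anchor_plus(self, mini):
        _, model = mini
        located = locate_site(site(pos=150, kind=INSERTION, seq="TGT"), [model])
        _, lo, hi = located
        assert (lo, hi) == (51, 53)

    def test_intronic_site_unlocated(self, mini):
        _, model = mini
        assert locate_site(site(pos=250, kind=DELETION, seq="A"), [model]) is None

    def test_junction_spanning_deletion_rejected(self, mini):
        _, model = mini
        # deletion from exon 1 into the intron
        assert locate_site(
            site(pos=195, kind=DELETION, seq="ACGTACGTAC"), [model]
        ) is None

    def test_intron_boundary_insertion_rejected(self, mini):
        _, model = mini
        # anchor at last exon-1 base: right flank is intronic
        assert locate_site(site(pos=200, kind=INSERTION, seq="T"), [model]) is None

    def test_wrong_scaffold_skipped(self, mini):
        _, model = mini
        assert locate_site(site(scaffold="small", pos=150), [model]) is None


class TestExonicFilter:
    def test_distance_measured_and_thresholded(self, mini):
        genome, model = mini
        cfg = ScreenConfig()
        # exon 2 (cDNA 101-200): only its upstream splice boundary counts
        res, _ = filter_exonic(site(pos=350, kind=DELETION, seq="A"), [model], cfg)
        assert res.passed and res.measured == 49
        res, _ = filter_exonic(site(pos=305, kind=DELETION, seq="A"), [model], cfg)
        assert not res.passed and res.measured == 4

    def test_insertion_probes_flanks(self, mini):
        genome, model = mini
        cfg = ScreenConfig(min_exon_boundary_bp=10)
        # anchor at genomic 310 -> cDNA flanks 110, 111; distance 9 from exon start
        res, _ = filter_exonic(site(pos=310, kind=INSERTION, seq="T"), [model], cfg)
        assert not res.passed and res.measured == 9
        res, _ = filter_exonic(site(pos=311, kind=INSERTION, seq="T"), [model], cfg)
        assert res.passed and res.measured == 10


class TestRunScreen:
    def test_audit_has_row_per_site_and_trace(self, mini):
        genome, model = mini
        sites = [
            site(pos=150, kind=DELETION, seq="A"),
            site(scaffold="small", pos=150, kind=DELETION, seq="A"),
            site(pos=150, depth=49, alt=49, kind=DELETION, seq="A"),
        ]
        survivors, audit = run_screen(sites, genome, [model])
        assert len(audit) == 3
        assert len(survivors) == 1
        assert set(audit.columns) >= {
            "scaffold_size_pass", "depth_pass", "allele_fraction_pass",
            "exonic_pass", "depth_value", "allele_fraction_value",
        }
        assert audit.scaffold_size_pass.tolist() == [True, False, True]
        assert audit.depth_pass.tolist() == [True, True, False]

    def test_filters_are_conjunctive(self, mini):
        genome, model = mini
        s = site(pos=150, kind=DELETION, seq="A", depth=49, alt=48)
        survivors, audit = run_screen([s], genome, [model])
        assert survivors == []
        row = audit.iloc[0]
        assert not row.depth_pass and not row.allele_fraction_pass

    @given(
        depth_thr=st.integers(min_value=1, max_value=120),
        af_thr=st.floats(min_value=0.5, max_value=1.0),
        boundary=st.integers(min_value=0, max_value=60),
    )
    def test_monotone_in_thresholds(self, depth_thr, af_thr, boundary, ):
        genome = ReferenceGenome({"big": "ACGT" * 300_000})
        model = GeneModel(
            "g", "g", "big", "+", [Exon(101, 200, 1), Exon(301, 400, 2)]
        )
        sites = [
            site(pos=p, kind=DELETION, seq="A", depth=d, alt=a)
            for p, d, a in [(150, 60, 60), (110, 55, 54), (190, 80, 79), (305, 52, 52)]
        ]
        base = ScreenConfig()
        tighter = ScreenConfig(
            min_depth=max(base.min_depth, depth_thr),
            min_allele_fraction=max(base.min_allele_fraction, af_thr),
            min_exon_boundary_bp=max(base.min_exon_boundary_bp, boundary),
        )
        pass_base, _ = run_screen(sites, genome, [model], base)
        pass_tight, _ = run_screen(sites, genome, [model], tighter)
        keys = lambda cands: {c.site.key for c in cands}
        assert keys(pass_tight) <= keys(pass_base)

    def test_depth_sweep_matches_threshold_set(self, mini):
        genome, model = mini
        cfg = ScreenConfig()
        for d in range(10, 101):
            s = site(pos=150, kind=DELETION, seq="A", depth=d, alt=d)
            survivors, _ = run_screen([s], genome, [model], cfg)
            assert bool(survivors) == (d >= 50)

    def test_decoys_fail_for_expected_reasons(self, universe, pipeline_result):
        audit = pipeline_result.audit
        truth = {t.gene: t for t in universe.fixture.truth}
        small = truth["decoy_small"]
        rows = audit[(audit.scaffold == small.scaffold)
                     & (audit.genomic_pos == small.genomic_pos)]
        assert not rows.empty and not rows.scaffold_size_pass.any()
        splice = truth["decoy_splice"]
        rows = audit[(audit.scaffold == splice.scaffold)
                     & (audit.genomic_pos == splice.genomic_pos)]
        assert not rows.empty and not rows.exonic_pass.any()
        assert rows.depth_pass.all() and rows.allele_fraction_pass.all()

    def test_survivors_match_truth_expectations(self, universe, pipeline_result):
        expected = {
            (t.scaffold, t.genomic_pos, t.kind, t.sequence)
            for t in universe.fixture.truth if t.expect_survival
        }
        got = {c.site.key for c in pipeline_result.candidates}
        assert got == expected
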