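"""Shared fixtures: one session-scoped synthetic universe plus a full
pipeline run over it, so expensive generation happens once."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cavescreen.pipeline import PipelineResult, run_pipeline
from cavescreen.synthetic_data import (
    POPULATIONS,
    Fixture,
    build_fixture,
    make_marker_fixture,
    packaged_domains_path,
    simulate_reads,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@dataclass
class Universe:
    fixture: Fixture
    outdir: Path
    sam_paths: dict[str, Path]
    truth_reads: dict[str, dict[str, list[tuple]]]  # population -> read map
    markers_path: Path
    expected_distances: pd.DataFrame
    unplaced: set[str]


def make_universe(outdir: Path, seed: int = 1, **read_kwargs) -> Universe:
    fx = build_fixture(seed=seed, outdir=outdir)
    sam_paths, truth_reads = {}, {}
    for pop in POPULATIONS:
        path = outdir / f"{pop}.sam"
        truth_reads[pop] = simulate_reads(fx, pop, path, seed=seed, **read_kwargs)
        sam_paths[pop] = path
    markers_path, expected, unplaced = make_marker_fixture(fx)
    return Universe(fx, outdir, sam_paths, truth_reads, markers_path, expected, unplaced)


@pytest.fixture(scope="session")
def universe(tmp_path_factory) -> Universe:
    return make_universe(tmp_path_factory.mktemp("universe"), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(universe, tmp_path_factory) -> PipelineResult:
    return run_pipeline(
        genome_path=universe.fixture.genome_path,
        gff_path=universe.fixture.gff_path,
        sam_paths=universe.sam_paths,
        outgroup_path=universe.fixture.outgroup_path,
        domains_path=packaged_domains_path(),
        markers_path=universe.markers_path,
        unplaced_scaffolds=frozenset(universe.unplaced),
        outdir=tmp_path_factory.mktemp("results"),
        seed=1,
    )
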