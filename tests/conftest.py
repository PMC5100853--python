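"""Shared fixtures: a small synthetic reference/truth and one simulated library."""

from __future__ import annotations

import pathlib

import pytest

from srnapipe import align, isomir
from srnapipe.synthetic import SimulationConfig, generate_truth, simulate_library


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, library_depth_mean=20_000.0)


@pytest.fixture(scope="session")
def truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def bundle(truth):
    return truth.bundle


@pytest.fixture(scope="session")
def genome_index(bundle):
    return align.ExactIndex(bundle.genome)


@pytest.fixture(scope="session")
def mirna_refs(bundle):
    return isomir.build_mirna_refs_from_bundle(bundle)


@pytest.fixture(scope="session")
def sim_library(truth, tmp_path_factory):
    """One simulated wild-type 2-4 hr library: (fastq path, sidecar DataFrame)."""
    d = tmp_path_factory.mktemp("sim")
    fastq = d / "lib.fastq"
    sidecar = simulate_library(truth, ("wt", "F2_4h", 1), fastq, d / "lib.truth.tsv")
    return fastq, sidecar


@pytest.fixture(scope="session")
def ref_dir(bundle, tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("ref")
    bundle.write(d)
    return d
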