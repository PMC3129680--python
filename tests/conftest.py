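"""Shared fixtures: a small reference library and generated test genomes.

Everything is generated programmatically and deterministically; no data files
ship with the tests.
"""

from __future__ import annotations

import pytest

from isannot.config import PipelineConfig
from isannot.reference_library import write_reference_library
from isannot.synthetic_fixtures import (
    generate_reference_library,
    generate_test_genome,
    small_scenario,
)

SEED = 11


@pytest.fixture(scope="session")
def lib():
    return generate_reference_library(n_families=2, n_is=4, seed=SEED)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small genome with three complete implants, on disk with its library."""
    spec, lib = small_scenario(SEED)
    out = tmp_path_factory.mktemp("small_fixture")
    rep, truths = generate_test_genome(spec, SEED, out)
    write_reference_library(lib, out / "library")
    return {"spec": spec, "lib": lib, "rep": rep, "truths": truths, "dir": out}


@pytest.fixture(scope="session")
def transposase(lib):
    """(reference, orf, protein) for the first transposase in the library."""
    ref = lib[sorted(lib.references)[0]]
    orf = ref.transposase_orfs()[0]
    return ref, orf, orf.protein
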