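"""Shared synthetic fixtures: a reference, environment samples and trees."""
from __future__ import annotations

import numpy as np
import pytest

from mcss.cli import _build_reference_tree, learn_from_reads
from mcss.fixtures import FixtureConfig, make_reference, make_samples
from mcss.reference_io import ReferenceDB


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=11, genome_length=(2000, 3000))


@pytest.fixture(scope="session")
def reference(fixture_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("reference")
    return make_reference(fixture_config, out)


@pytest.fixture(scope="session")
def samples(reference, fixture_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("samples")
    return make_samples(reference, fixture_config, out)


@pytest.fixture(scope="session")
def db(reference) -> ReferenceDB:
    paths = reference["paths"]
    return ReferenceDB.load(paths["taxonomy"], paths["tree"])


@pytest.fixture(scope="session")
def t_ref(db):
    return _build_reference_tree(db)


@pytest.fixture(scope="session")
def learned(samples, db):
    reports = [s["report"] for s in samples["samples"]]
    return learn_from_reads(reports, db)


# A smaller reference for exhaustive-search comparisons (every node has few
# children so brute-force enumeration stays cheap).
SEARCH_CONFIG = dict(
    families_per_domain=(2, 3),
    genera_per_family=(2, 3),
    species_per_genus=(1, 4),
    strains_per_species=(1, 2),
    genome_length=(500, 800),
    n_samples=1,
    species_per_sample=(5, 12),
)


def make_search_db(seed: int, tmp_path, ultrametric: bool = False):
    config = FixtureConfig(seed=seed, ultrametric=ultrametric, **SEARCH_CONFIG)
    manifest = make_reference(config, tmp_path / f"search_ref_{seed}")
    paths = manifest["paths"]
    return ReferenceDB.load(paths["taxonomy"], paths["tree"]), manifest


@pytest.fixture(scope="session")
def search_db(tmp_path_factory):
    return make_search_db(21, tmp_path_factory.mktemp("search"))[0]
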