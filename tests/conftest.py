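from __future__ import annotations

import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")

from amf_lsu.align import ScoringScheme
from amf_lsu.simdata import SimConfig, make_fixture


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_fixture():
    """A compact study: 4 families x ~3 tips, 6 outgroups, 16 queries, 4 junk."""
    cfg = SimConfig(n_amf_tips=12, n_families=4, n_outgroup_tips=6,
                    n_queries=16, n_junk_reads=4, seed=11)
    return make_fixture(cfg)


@pytest.fixture(scope="session")
def small_fixture_paths(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return small_fixture.write(outdir)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
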