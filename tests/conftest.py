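"""Shared fixtures: toy folding setups and memoized energy functions."""

from __future__ import annotations

import numpy as np
import pytest

from tisopt.accessibility import FoldConfig, ToyEngine, opening_energy
from tisopt.core_seq import CodingConstruct, RegionSpec


@pytest.fixture(scope="session")
def toy_config() -> FoldConfig:
    return FoldConfig(engine="toy")


@pytest.fixture(scope="session")
def toy_engine(toy_config) -> ToyEngine:
    return ToyEngine(toy_config)


def make_energy_fn(construct: CodingConstruct, region: RegionSpec,
                   config: FoldConfig, engine=None):
    """Opening-energy objective over candidate CDS strings, memoized.

    Annealing revisits sequences constantly on small search spaces; caching
    keeps the toy engine affordable in tests.
    """
    cache: dict[str, float] = {}

    def energy_fn(cds: str) -> float:
        if cds not in cache:
            cache[cds] = opening_energy(
                construct.with_cds(cds), region, config, engine=engine
            )
        return cache[cds]

    return energy_fn


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
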