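"""Shared fixtures: small simulated NAM panels reused across tests.

Everything is generated at test time from fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wheatnam import simdata as sd
from wheatnam.core import GenotypeMatrix


@pytest.fixture(scope="session")
def small_map() -> sd.GeneticMap:
    """7 chromosomes x 40 markers, 600 Mb / 150 cM each."""
    return sd.make_genetic_map(7, 40, 600_000_000, 150.0)


@pytest.fixture(scope="session")
def nam_small(small_map):
    """4 nested populations of 60 BC1F5 genotypes plus parents."""
    founders = sd.make_founders(small_map, n_donors=4, seed=11)
    plan = sd.CrossPlan(n_populations=4, target_size=60)
    G, ped = sd.build_nam(plan, founders, small_map, seed=12)
    return G, ped, founders, small_map


@pytest.fixture(scope="session")
def two_locus_map() -> sd.GeneticMap:
    chroms = pd.DataFrame(
        {"length_bp": [100_000_000], "length_cM": [50.0]},
        index=pd.Index(["1A"], name="chrom"),
    )
    markers = pd.DataFrame(
        {"chrom": ["1A", "1A"], "bp": [1, 100_000_000], "cM": [0.0, 50.0]},
        index=pd.Index(["m1", "m2"], name="marker"),
    )
    return sd.GeneticMap(chroms, markers)


def random_genotype_matrix(
    n: int, m: int, seed: int, missing: float = 0.0
) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    if missing:
        d[rng.random(d.shape) < missing] = np.nan
    return GenotypeMatrix(
        pd.DataFrame(
            d,
            index=[f"g{i:03d}" for i in range(n)],
            columns=[f"mk{j:03d}" for j in range(m)],
        )
    )
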