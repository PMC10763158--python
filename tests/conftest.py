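from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from capripop import Dataset
from capripop.simulate import demo_config, simulate


def make_dataset(
    genotypes,
    populations=None,
    chroms=None,
    pos_bp=None,
    groups=None,
    a1=None,
    a2=None,
) -> Dataset:
    """Small-dataset builder for hand-written fixtures."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_variants = g.shape
    if populations is None:
        populations = ["POP"] * n_samples
    if chroms is None:
        chroms = ["1"] * n_variants
    if pos_bp is None:
        pos_bp = [1000 * (j + 1) for j in range(n_variants)]
    return Dataset.from_arrays(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        populations=populations,
        snp_ids=[f"snp{j}" for j in range(n_variants)],
        chroms=chroms,
        pos_bp=pos_bp,
        genotypes=g,
        groups=groups,
        a1=a1,
        a2=a2,
    )


@pytest.fixture(scope="session")
def demo_sim():
    """One shared demo simulation (4 breeds, 2 chromosomes, 5000 SNPs,
    one sweep + one tract)."""
    return simulate(demo_config(7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240103)


def random_dataset(rng, n_samples=12, n_variants=40, missing_rate=0.05, n_pops=2):
    pops = [f"P{k}" for k in range(n_pops) for _ in range(n_samples // n_pops)]
    pops += [f"P{n_pops - 1}"] * (n_samples - len(pops))
    g = rng.integers(0, 3, size=(n_samples, n_variants)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = -1
    return make_dataset(g, populations=pops)
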