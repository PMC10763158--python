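"""Multi-breed SNP-array simulator with known drift, sweeps and ROH tracts.

The generator emulates a medium-density (50K-class) genotyping array on a
set of related breeds that diverged from a single ancestral gene pool by
drift, the situation of island livestock populations:

* ancestral allele frequencies ``p ~ Uniform(0.05, 0.95)`` per SNP;
* breed frequencies follow the Balding-Nichols model,
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` with a per-breed drift coefficient F;
* genotypes are Hardy-Weinberg draws from the breed frequency;
* *sweeps* shift the frequencies of every breed of a target metapopulation
  by delta at the member SNPs (toward the boundary farther from the
  ancestral frequency, so the inter-group differential survives clipping to
  [0.01, 0.99]) — ground truth for FST-outlier scans;
* *tracts* overwrite the genotypes of a carrier subset of one breed with a
  single shared homozygous haplotype over a >= 2 Mb interval — ground truth
  for ROH and ROH-island detection;
* uniform missingness is applied last.

Everything is reproducible from the integer seed in :class:`SimConfig`, and
the realized frequencies/carrier assignments are returned as a
:class:`SimTruth` for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset
from .plinkio import write_plink


@dataclass(frozen=True)
class BreedSpec:
    """One simulated breed: label, metapopulation and sample size."""

    population: str
    group: str  # wet / dry / none
    n: int


@dataclass(frozen=True)
class SweepSpec:
    """A differentiated region: the target group's allele frequencies are
    shifted by ``delta`` over [start_bp, end_bp]."""

    chrom: str
    start_bp: int
    end_bp: int
    target_group: str  # wet or dry
    delta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")


@dataclass(frozen=True)
class TractSpec:
    """A shared homozygous tract: carriers of one breed become homozygous
    for one shared haplotype over [start_bp, end_bp]."""

    population: str
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")


#: Default breed design: four island breeds in two environments, at the
#: census-scale sample sizes of a realistic SNP-array survey.
DEFAULT_BREEDS = (
    BreedSpec("PAL", "wet", 61),
    BreedSpec("TIN", "wet", 64),
    BreedSpec("MAJ", "dry", 60),
    BreedSpec("TIS", "dry", 39),
)

#: Approximate lengths of the six largest goat autosomes (bp).
DEFAULT_CHROM_LENGTHS = {
    "1": 157_000_000,
    "2": 136_000_000,
    "3": 121_000_000,
    "4": 118_000_000,
    "5": 112_000_000,
    "6": 115_000_000,
}

MIN_SPACING_BP = 5_000  # avoids duplicate positions; far below array density


@dataclass(frozen=True)
class SimConfig:
    """Complete, serializable description of one simulated dataset."""

    seed: int
    breeds: tuple[BreedSpec, ...] = DEFAULT_BREEDS
    chrom_lengths_bp: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_snps: int = 30_000
    drift_f: dict[str, float] = field(
        default_factory=lambda: {"PAL": 0.10, "TIN": 0.05, "MAJ": 0.05, "TIS": 0.05}
    )
    missing_rate: float = 0.01
    sweeps: tuple[SweepSpec, ...] = ()
    roh_tracts: tuple[TractSpec, ...] = ()

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        raw = json.loads(text)
        raw["breeds"] = tuple(BreedSpec(**b) for b in raw["breeds"])
        raw["sweeps"] = tuple(SweepSpec(**s) for s in raw.get("sweeps", ()))
        raw["roh_tracts"] = tuple(TractSpec(**t) for t in raw.get("roh_tracts", ()))
        return cls(**raw)


@dataclass
class SimTruth:
    """Generator bookkeeping sufficient to score any called signal."""

    config: SimConfig
    ancestral_freq: np.ndarray
    breed_freq: dict[str, np.ndarray]  # post-sweep frequencies
    sweep_snps: list[np.ndarray]  # variant indices per sweep
    tract_snps: list[np.ndarray]  # variant indices per tract
    tract_carriers: list[list[str]]  # sample_ids per tract


def demo_config(seed: int) -> SimConfig:
    """Small end-to-end demonstration: 4 breeds, 2 chromosomes, 5000 SNPs,
    one sweep and one shared homozygous tract."""
    return SimConfig(
        seed=seed,
        breeds=DEFAULT_BREEDS,
        chrom_lengths_bp={"1": 100_000_000, "2": 80_000_000},
        n_snps=5_000,
        sweeps=(SweepSpec("1", 40_000_000, 40_500_000, "dry", 0.6),),
        roh_tracts=(TractSpec("PAL", "2", 30_000_000, 32_500_000, 0.8),),
    )


def _draw_positions(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    total = sum(config.chrom_lengths_bp.values())
    chroms, positions = [], []
    remaining = config.n_snps
    items = list(config.chrom_lengths_bp.items())
    for k, (chrom, length) in enumerate(items):
        n = remaining if k == len(items) - 1 else int(round(config.n_snps * length / total))
        n = min(n, remaining)
        remaining -= n
        span = length - (n - 1) * MIN_SPACING_BP
        if span <= 0:
            raise ValueError(f"chromosome {chrom} too short for {n} SNPs")
        # sorted uniforms plus a cumulative offset guarantee min spacing
        base = np.sort(rng.integers(1, span + 1, size=n))
        pos = base + np.arange(n) * MIN_SPACING_BP
        chroms.extend([chrom] * n)
        positions.extend(pos.tolist())
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos_bp": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
        }
    )


def _snps_in(variants: pd.DataFrame, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
    mask = (
        (variants["chrom"] == chrom)
        & (variants["pos_bp"] >= start_bp)
        & (variants["pos_bp"] <= end_bp)
    )
    return np.flatnonzero(mask.to_numpy())


def simulate(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Draw one dataset (and its ground truth) from the generative model."""
    rng = np.random.default_rng(config.seed)
    variants = _draw_positions(rng, config)
    n_snps = len(variants)
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)

    breed_freq: dict[str, np.ndarray] = {}
    for breed in config.breeds:
        f = config.drift_f.get(breed.population, 0.05)
        if not 0.0 < f < 1.0:
            raise ValueError(f"drift_f for {breed.population} must be in (0, 1)")
        scale = (1.0 - f) / f
        breed_freq[breed.population] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    sweep_snps: list[np.ndarray] = []
    for sweep in config.sweeps:
        idx = _snps_in(variants, sweep.chrom, sweep.start_bp, sweep.end_bp)
        if len(idx) == 0:
            raise ValueError(f"sweep {sweep} contains no SNPs at realized spacing")
        sweep_snps.append(idx)
        # shift toward the boundary farther from the ancestral frequency so
        # clipping cannot erase the differential
        direction = np.where(p_anc[idx] <= 0.5, 1.0, -1.0)
        for breed in config.breeds:
            if breed.group == sweep.target_group:
                fr = breed_freq[breed.population]
                fr[idx] = np.clip(fr[idx] + direction * sweep.delta, 0.01, 0.99)

    sample_ids, populations, groups = [], [], []
    blocks = []
    for breed in config.breeds:
        fr = breed_freq[breed.population]
        blocks.append(
            rng.binomial(1, fr, size=(breed.n, n_snps)).astype(np.int8)
            + rng.binomial(1, fr, size=(breed.n, n_snps)).astype(np.int8)
        )
        sample_ids.extend(f"{breed.population}_{i:03d}" for i in range(breed.n))
        populations.extend([breed.population] * breed.n)
        groups.extend([breed.group] * breed.n)
    genotypes = np.vstack(blocks)
    pop_arr = np.asarray(populations)

    tract_snps: list[np.ndarray] = []
    tract_carriers: list[list[str]] = []
    for tract in config.roh_tracts:
        idx = _snps_in(variants, tract.chrom, tract.start_bp, tract.end_bp)
        if len(idx) < 20:
            raise ValueError(
                f"tract {tract} spans only {len(idx)} SNPs at realized spacing "
                "(need >= 20 to be detectable)"
            )
        rows = np.flatnonzero(pop_arr == tract.population)
        if len(rows) == 0:
            raise ValueError(f"tract {tract} names an unknown population")
        n_carriers = max(1, int(round(tract.carrier_fraction * len(rows))))
        carriers = rng.choice(rows, size=n_carriers, replace=False)
        haplotype = rng.binomial(1, breed_freq[tract.population][idx]).astype(np.int8)
        genotypes[np.ix_(carriers, idx)] = 2 * haplotype
        tract_snps.append(idx)
        tract_carriers.append([sample_ids[r] for r in np.sort(carriers)])

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = MISSING

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": populations, "group": groups}
    )
    ds = Dataset(samples, variants, genotypes)
    truth = SimTruth(
        config=config,
        ancestral_freq=p_anc,
        breed_freq=breed_freq,
        sweep_snps=sweep_snps,
        tract_snps=tract_snps,
        tract_carriers=tract_carriers,
    )
    return ds, truth


def write_fixture(
    config: SimConfig, path_prefix: str | Path, dialect: str = "binary"
) -> tuple[Dataset, SimTruth]:
    """Simulate, write PLINK files and a truth JSON next to them.

    The truth JSON embeds the config, so ``simulate(SimConfig.from_json(...))``
    regenerates the identical fixture.
    """
    ds, truth = simulate(config)
    write_plink(ds, path_prefix, dialect)
    prefix = Path(path_prefix)
    truth_doc = {
        "config": json.loads(config.to_json()),
        "sweeps": [
            {
                "spec": dataclasses.asdict(s),
                "n_snps": int(len(idx)),
            }
            for s, idx in zip(config.sweeps, truth.sweep_snps)
        ],
        "roh_tracts": [
            {
                "spec": dataclasses.asdict(t),
                "n_snps": int(len(idx)),
                "carriers": carriers,
            }
            for t, idx, carriers in zip(
                config.roh_tracts, truth.tract_snps, truth.tract_carriers
            )
        ],
    }
    (prefix.parent / (prefix.name + ".truth.json")).write_text(
        json.dumps(truth_doc, indent=2)
    )
    return ds, truth
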