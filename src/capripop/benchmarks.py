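"""Reference simulation experiments: signal recovery and null calibration.

These are the package's standing benchmarks for the selection-scan
pipeline, run both by the test suite and by the results-reproduction
script.  One replicate simulates four breeds (two per environment, n = 40
each) on a 30,000-SNP array spanning six autosomes, with one planted sweep
(allele-frequency differential 0.6 between the wet and dry metapopulations)
and one planted shared homozygous tract (2.5 Mb, carrier fraction 0.8) —
the detection-threshold regime for both scan procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .diversity import breed_diversity
from .roh import RohParams, detect_roh_all
from .selection import (
    roh_islands,
    significant_windows,
    snp_roh_frequency,
    wc_components,
    windowed_fst,
)
from .simulate import BreedSpec, SimConfig, SimTruth, SweepSpec, TractSpec, simulate

RECOVERY_BREEDS = (
    BreedSpec("W1", "wet", 40),
    BreedSpec("W2", "wet", 40),
    BreedSpec("D1", "dry", 40),
    BreedSpec("D2", "dry", 40),
)

#: Sweep at the differential the scan is expected to catch.
RECOVERY_SWEEP = SweepSpec("2", 40_000_000, 40_400_000, "dry", 0.6)
#: 2.5 Mb shared homozygous tract in one dry breed.
RECOVERY_TRACT = TractSpec("D1", "3", 50_000_000, 52_500_000, 0.8)


def recovery_config(seed: int, with_signals: bool = True) -> SimConfig:
    """Benchmark replicate configuration (optionally signal-free for nulls)."""
    return SimConfig(
        seed=seed,
        breeds=RECOVERY_BREEDS,
        n_snps=30_000,
        drift_f={b.population: 0.05 for b in RECOVERY_BREEDS},
        missing_rate=0.01,
        sweeps=(RECOVERY_SWEEP,) if with_signals else (),
        roh_tracts=(RECOVERY_TRACT,) if with_signals else (),
    )


def _overlaps(df, chrom: str, start_bp: int, end_bp: int):
    return df[
        (df["chrom"] == chrom) & (df["end_bp"] >= start_bp) & (df["start_bp"] <= end_bp)
    ]


@dataclass
class RecoveryResult:
    sweep_recovered: bool
    island_recovered: bool


def run_recovery_replicate(seed: int) -> RecoveryResult:
    """Simulate one benchmark replicate and score both planted signals.

    The sweep counts as recovered when at least one significant window of
    the wet-vs-dry metapopulation contrast overlaps the swept interval; the
    tract when at least one called ROH island of the carrier breed overlaps
    the tract interval.
    """
    ds, truth = simulate(recovery_config(seed))
    sweep, tract = truth.config.sweeps[0], truth.config.roh_tracts[0]

    comp = wc_components(ds, ("W1", "W2"), ("D1", "D2"))
    windows = windowed_fst(comp, "metapopulation")
    sig = significant_windows(windows)
    sweep_ok = len(_overlaps(sig, sweep.chrom, sweep.start_bp, sweep.end_bp)) > 0

    breed_ds = ds.subset(sample_idx=ds.sample_index(tract.population))
    segments = detect_roh_all(breed_ds, RohParams())
    freqs = snp_roh_frequency(segments, breed_ds, tract.population)
    islands = roh_islands(freqs)
    island_ok = len(_overlaps(islands, tract.chrom, tract.start_bp, tract.end_bp)) > 0
    return RecoveryResult(sweep_ok, island_ok)


def recovery_rates(seed: int, n_replicates: int = 100) -> tuple[float, float]:
    """(sweep, island) recovery fractions over independent replicates."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    results = [run_recovery_replicate(int(s)) for s in rep_seeds]
    return (
        sum(r.sweep_recovered for r in results) / n_replicates,
        sum(r.island_recovered for r in results) / n_replicates,
    )


@dataclass
class NullCalibration:
    fis: dict[str, float]
    fis_se: dict[str, float]  # delta-method Monte-Carlo standard errors
    n_windows: int
    n_significant: int
    n_significant_filter_first: int
    expected_count_filter_first: int


def fis_standard_error(ho_l: np.ndarray, uhe_l: np.ndarray) -> float:
    """Delta-method SE of FIS = 1 - mean(Ho)/mean(uHe) across loci."""
    n = len(ho_l)
    mh, mu = ho_l.mean(), uhe_l.mean()
    vh, vu = ho_l.var(ddof=1) / n, uhe_l.var(ddof=1) / n
    cov = float(np.cov(ho_l, uhe_l, ddof=1)[0, 1]) / n
    var = vh / mu**2 + (mh**2 / mu**4) * vu - 2.0 * (mh / mu**3) * cov
    return float(np.sqrt(max(var, 0.0)))


def percentile_implied_count(n: int, top_fraction: float = 0.0005) -> int:
    """How many of ``n`` distinct values lie at or above their
    ``100*(1-top_fraction)`` linear-interpolation percentile."""
    h = (n - 1) * (1.0 - top_fraction)
    i = int(np.floor(h))
    return n - i if h == i else n - 1 - i


def run_null_calibration(seed: int) -> NullCalibration:
    """One signal-free replicate: breed FIS and the significant-window count.

    With nothing planted, the FIS of every breed should vanish up to
    Monte-Carlo error, and the number of significant windows should match
    what the percentile rule alone implies.
    """
    ds, _ = simulate(recovery_config(seed, with_signals=False))
    fis, fis_se = {}, {}
    from .diversity import _per_locus_matrix

    for pop in ds.populations:
        fis[pop] = breed_diversity(ds, pop).fis
        ho_l, uhe_l, n_called = _per_locus_matrix(ds.genotypes_for(pop))
        keep = n_called > 0
        fis_se[pop] = fis_standard_error(ho_l[keep], uhe_l[keep])
    comp = wc_components(ds, ("W1", "W2"), ("D1", "D2"))
    windows = windowed_fst(comp, "metapopulation")
    sig = significant_windows(windows)
    sig_ff = significant_windows(windows, filter_first=True)
    n_dense = int((windows["n_snps"] >= 5).sum())
    return NullCalibration(
        fis=fis,
        fis_se=fis_se,
        n_windows=len(windows),
        n_significant=len(sig),
        n_significant_filter_first=len(sig_ff),
        expected_count_filter_first=percentile_implied_count(n_dense),
    )
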