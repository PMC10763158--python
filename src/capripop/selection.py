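"""Selection-signature scans: ROH islands and windowed Weir-Cockerham FST.

Two complementary procedures:

* **ROH islands** — for one breed, each SNP's *occurrence* is the fraction
  of the breed's animals whose ROH cover it.  SNPs at or above the 99.9th
  percentile of the breed's occurrence distribution (linear-interpolation
  percentile; ties included) are kept, and maximal runs of map-consecutive
  kept SNPs form the islands.

* **Windowed FST** — per biallelic locus the Weir & Cockerham (1984)
  variance components a (among populations), b (among individuals within
  populations) and c (within individuals) are estimated for two
  (meta)populations; windows of 500 kb advancing in 250-kb steps are scored
  with the ratio-of-sums ("weighted") estimator sum(a)/sum(a+b+c), and
  windows at or above the 99.95th percentile with at least five SNPs are
  called significant.

The wet/dry contrast design pools breeds into two environment-defined
metapopulations and additionally tests each wet x dry breed pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset

logger = logging.getLogger(__name__)

ISLAND_COLUMNS = ("population", "chrom", "start_bp", "end_bp", "n_snps", "length_mb")
WINDOW_COLUMNS = ("contrast", "chrom", "start_bp", "end_bp", "n_snps", "weighted_fst")


@dataclass(frozen=True)
class Contrast:
    """One FST comparison: two disjoint sets of populations."""

    label: str
    pops_a: tuple[str, ...]
    pops_b: tuple[str, ...]


def island_length_mb(start_bp: int, end_bp: int) -> float:
    """Genomic span in Mb between the first and last SNP of a region."""
    return (end_bp - start_bp) / 1e6


# --------------------------------------------------------------------------- #
# ROH occurrence and islands
# --------------------------------------------------------------------------- #
def snp_roh_frequency(
    segments: pd.DataFrame, ds: Dataset, population: str
) -> pd.DataFrame:
    """Per-SNP ROH occurrence for one breed.

    A SNP is covered by a segment iff ``start_bp <= pos_bp <= end_bp`` on the
    same chromosome; the denominator is every genotyped animal of the breed
    (animals without any ROH count in the denominator).

    Returns columns ``population, snp_id, chrom, pos_bp, occurrence``.
    """
    breed_samples = set(
        ds.samples.loc[ds.sample_index(population), "sample_id"]
    )
    n_animals = len(breed_samples)
    seg = segments[segments["sample_id"].isin(breed_samples)]
    counts = np.zeros(ds.n_variants, dtype=np.int64)
    chrom_arr = ds.variants["chrom"].to_numpy()
    pos_arr = ds.variants["pos_bp"].to_numpy()
    for chrom, sub in seg.groupby("chrom", sort=False):
        vidx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[vidx]
        # each animal's segments are non-overlapping, so summing segment
        # coverage counts animals exactly once per SNP
        left = np.searchsorted(pos, sub["start_bp"].to_numpy(), side="left")
        right = np.searchsorted(pos, sub["end_bp"].to_numpy(), side="right")
        delta = np.zeros(len(pos) + 1, dtype=np.int64)
        np.add.at(delta, left, 1)
        np.add.at(delta, right, -1)
        counts[vidx] += np.cumsum(delta[:-1])
    return pd.DataFrame(
        {
            "population": population,
            "snp_id": ds.variants["snp_id"],
            "chrom": chrom_arr,
            "pos_bp": pos_arr,
            "occurrence": counts / n_animals,
        }
    )


def roh_islands(freqs: pd.DataFrame, top_fraction: float = 0.001) -> pd.DataFrame:
    """Call ROH islands from one breed's per-SNP occurrence table.

    The threshold is the ``100*(1-top_fraction)`` percentile (linear
    interpolation) of the occurrence distribution; SNPs with occurrence >=
    threshold (ties included) are merged into maximal runs of map-consecutive
    SNPs within a chromosome.
    """
    occ = freqs["occurrence"].to_numpy(dtype=float)
    if len(occ) == 0:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    if np.all(occ == occ[0]):
        warnings.warn(
            "degenerate occurrence distribution (all values equal); "
            "no islands called",
            stacklevel=2,
        )
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    threshold = np.percentile(occ, 100.0 * (1.0 - top_fraction))
    hot = occ >= threshold
    rows = []
    chrom_arr = freqs["chrom"].to_numpy()
    pos_arr = freqs["pos_bp"].to_numpy()
    pop = freqs["population"].iat[0]
    new_chrom = np.concatenate(([True], chrom_arr[1:] != chrom_arr[:-1]))
    run_start = hot & (new_chrom | ~np.concatenate(([False], hot[:-1])))
    run_id = np.where(hot, np.cumsum(run_start), 0)
    for rid in range(1, run_id.max() + 1):
        idx = np.flatnonzero(run_id == rid)
        start, end = int(pos_arr[idx[0]]), int(pos_arr[idx[-1]])
        rows.append(
            (pop, chrom_arr[idx[0]], start, end, len(idx), island_length_mb(start, end))
        )
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


# --------------------------------------------------------------------------- #
# Weir-Cockerham variance components
# --------------------------------------------------------------------------- #
def _pop_locus_stats(g: np.ndarray):
    """Per-locus called sample size, A1 frequency and het frequency of one
    population sub-matrix."""
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
        h = (g == 1).sum(axis=0) / n
    return n, p, h


def _resolve_pops(ds: Dataset, pops: str | Sequence[str]) -> np.ndarray:
    return ds.sample_index([pops] if isinstance(pops, str) else list(pops))


def wc_components(
    ds: Dataset,
    pop_a: str | Sequence[str],
    pop_b: str | Sequence[str],
) -> pd.DataFrame:
    """Weir & Cockerham (1984) two-population variance components per locus.

    Either argument may name a single population or a list of populations to
    pool (the metapopulation design).  Loci where either side has fewer than
    two called individuals are skipped (``defined = False``, logged count);
    loci monomorphic across both sides get components (0, 0, 0) and are
    likewise flagged undefined for window sums.

    Returns columns ``snp_id, chrom, pos_bp, a, b, c, theta, defined``.
    """
    ga = ds.genotypes[_resolve_pops(ds, pop_a), :]
    gb = ds.genotypes[_resolve_pops(ds, pop_b), :]
    n1, p1, h1 = _pop_locus_stats(ga)
    n2, p2, h2 = _pop_locus_stats(gb)

    r = 2.0
    enough = (n1 >= 2) & (n2 >= 2)
    n_skipped = int((~enough).sum())
    if n_skipped:
        logger.info("%d loci skipped (fewer than 2 called per side)", n_skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    mono = enough & ((pbar == 0.0) | (pbar == 1.0))
    defined = enough & ~mono
    a = np.where(defined, a, 0.0)
    b = np.where(defined, b, 0.0)
    c = np.where(defined, c, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(defined & (a + b + c != 0), a / (a + b + c), np.nan)
    return pd.DataFrame(
        {
            "snp_id": ds.variants["snp_id"],
            "chrom": ds.variants["chrom"],
            "pos_bp": ds.variants["pos_bp"],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "defined": defined,
        }
    )


# --------------------------------------------------------------------------- #
# windows
# --------------------------------------------------------------------------- #
def windowed_fst(
    components: pd.DataFrame,
    contrast_label: str = "contrast",
    window_kb: float = 500.0,
    step_kb: float = 250.0,
) -> pd.DataFrame:
    """Ratio-of-sums FST in sliding genomic windows.

    Windows start at bp 1 on every chromosome: [1, window], [step+1,
    step+window], ...; a window is emitted while its start does not exceed
    the chromosome's last SNP position.  A SNP belongs to every window whose
    inclusive bounds contain its position.  ``weighted_fst`` is
    sum(a)/sum(a+b+c) over the window's defined loci; windows whose
    denominator is zero (or that contain no defined locus) are dropped.
    """
    win = int(round(window_kb * 1000))
    step = int(round(step_kb * 1000))
    rows = []
    for chrom, sub in components.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        defined = sub["defined"].to_numpy()
        a = np.where(defined, sub["a"].to_numpy(), 0.0)
        abc = np.where(defined, (sub["a"] + sub["b"] + sub["c"]).to_numpy(), 0.0)
        ndef = defined.astype(np.int64)
        max_pos = int(pos.max())
        starts = np.arange(1, max_pos + 1, step, dtype=np.int64)
        ends = starts + win - 1
        a_cs = np.concatenate(([0.0], np.cumsum(a)))
        abc_cs = np.concatenate(([0.0], np.cumsum(abc)))
        n_cs = np.concatenate(([0], np.cumsum(ndef)))
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for k in range(len(starts)):
            denom = abc_cs[hi[k]] - abc_cs[lo[k]]
            n_snps = int(n_cs[hi[k]] - n_cs[lo[k]])
            if n_snps == 0 or denom == 0.0:
                continue
            rows.append(
                (
                    contrast_label,
                    chrom,
                    int(starts[k]),
                    int(ends[k]),
                    n_snps,
                    float((a_cs[hi[k]] - a_cs[lo[k]]) / denom),
                )
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def significant_windows(
    windows: pd.DataFrame,
    min_snps: int = 5,
    top_fraction: float = 0.0005,
    filter_first: bool = False,
) -> pd.DataFrame:
    """Windows at or above the top-``top_fraction`` FST percentile with at
    least ``min_snps`` member SNPs.

    By default the percentile threshold is computed over *all* defined
    windows and the SNP-count rule applied afterwards; ``filter_first=True``
    restricts the percentile to windows already satisfying the SNP-count
    rule.
    """
    if len(windows) == 0:
        return windows.copy()
    pool = windows[windows["n_snps"] >= min_snps] if filter_first else windows
    values = pool["weighted_fst"].to_numpy(dtype=float)
    if len(values) == 0:
        return windows.iloc[0:0].copy()
    if len(values) < 1.0 / top_fraction:
        logger.warning(
            "only %d windows for a top fraction of %g; threshold is near the maximum",
            len(values),
            top_fraction,
        )
    if np.all(values == values[0]):
        warnings.warn(
            "degenerate window FST distribution (all values equal); "
            "no windows called significant",
            stacklevel=2,
        )
        return windows.iloc[0:0].copy()
    threshold = np.percentile(values, 100.0 * (1.0 - top_fraction))
    out = windows[
        (windows["weighted_fst"] >= threshold) & (windows["n_snps"] >= min_snps)
    ]
    return out.reset_index(drop=True)


def build_contrasts(ds: Dataset) -> list[Contrast]:
    """The environment-contrast design: one pooled wet-vs-dry metapopulation
    comparison plus every wet-breed x dry-breed pair."""
    pops = ds.samples[["population", "group"]].drop_duplicates()
    wet = [p for p, g in pops.itertuples(index=False) if g == "wet"]
    dry = [p for p, g in pops.itertuples(index=False) if g == "dry"]
    if not wet or not dry:
        raise ValueError(
            f"both metapopulations need at least one breed (wet={wet}, dry={dry})"
        )
    contrasts = [Contrast("metapopulation", tuple(wet), tuple(dry))]
    for w in wet:
        for d in dry:
            contrasts.append(Contrast(f"{w}_{d}", (w,), (d,)))
    return contrasts


def fst_scan(
    ds: Dataset,
    window_kb: float = 500.0,
    step_kb: float = 250.0,
    min_snps: int = 5,
    top_fraction: float = 0.0005,
    contrasts: Iterable[Contrast] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every contrast end to end.

    Returns ``(all_windows, significant)`` with the contrast label in the
    first column of both tables.
    """
    if contrasts is None:
        contrasts = build_contrasts(ds)
    all_windows, sig = [], []
    for ct in contrasts:
        comp = wc_components(ds, ct.pops_a, ct.pops_b)
        win = windowed_fst(comp, ct.label, window_kb, step_kb)
        all_windows.append(win)
        sig.append(significant_windows(win, min_snps, top_fraction))
    def _concat(frames):
        non_empty = [f for f in frames if len(f)]
        if not non_empty:
            return pd.DataFrame(columns=WINDOW_COLUMNS)
        return pd.concat(non_empty, ignore_index=True)

    return _concat(all_windows), _concat(sig)
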