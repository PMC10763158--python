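"""Scanning-window detection of runs of homozygosity (ROH) and FROH.

The detector reproduces the classic PLINK ``--homozyg`` scanning-window
procedure.  Per chromosome and individual:

1. every contiguous window of ``window_snp`` SNPs is scored a *hit* iff it
   contains at most ``window_het`` heterozygous and ``window_missing``
   missing calls;
2. each SNP's hit proportion is the fraction of the windows covering it
   that are hits (SNPs near chromosome ends have fewer covering windows;
   the denominator is the actual count);
3. SNPs with hit proportion >= ``window_hit_frac`` whose own call is not
   heterozygous (missing allowed) are run candidates;
4. maximal runs of map-consecutive candidates are split wherever the gap
   between consecutive SNPs exceeds ``max_gap_kb``;
5. runs failing the final segment constraints (``min_snp``, ``min_kb``,
   density ``length_kb / n_snps <= min_density_kb_per_snp``) are discarded.

Boundary comparisons are inclusive: a run of exactly ``min_kb`` passes.
Segment length is the bp span between the outermost SNPs of the run.

The genomic inbreeding coefficient is FROH = L_ROH / L_aut with L_aut the
autosomal genome length, 2522 Mb for the goat autosomes by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset

logger = logging.getLogger(__name__)

#: Autosomal genome length (Mb) used as the FROH denominator (goat autosomes).
L_AUT_MB: float = 2522.0

SEGMENT_COLUMNS = ("sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb")


@dataclass(frozen=True)
class RohParams:
    """The seven scanning-window ROH criteria (defaults: 50K-chip livestock
    practice)."""

    window_snp: int = 20
    window_het: int = 0
    window_missing: int = 2
    window_hit_frac: float = 0.05
    min_snp: int = 20
    min_kb: float = 2000.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 500.0

    def __post_init__(self) -> None:
        if self.window_snp < 1 or self.min_snp < 1:
            raise ValueError("window_snp and min_snp must be positive")
        if self.window_het > self.window_snp:
            raise ValueError("window_het cannot exceed window_snp")


def _sliding_counts(indicator: np.ndarray, w: int) -> np.ndarray:
    """Row-wise sliding-window sums of width ``w`` (samples x snps -> samples
    x windows)."""
    cs = np.cumsum(indicator, axis=1, dtype=np.int32)
    cs = np.concatenate([np.zeros((indicator.shape[0], 1), dtype=np.int32), cs], axis=1)
    return cs[:, w:] - cs[:, :-w]


def _candidate_matrix(g: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean samples x snps matrix of run-candidate SNPs for one chromosome."""
    n_samples, n_snps = g.shape
    w = params.window_snp
    het = g == 1
    if n_snps < w:
        return np.zeros_like(het, dtype=bool)
    mis = g == MISSING
    hit = (_sliding_counts(het, w) <= params.window_het) & (
        _sliding_counts(mis, w) <= params.window_missing
    )
    n_windows = n_snps - w + 1
    # windows covering SNP j: indices [max(0, j-w+1), min(j, n_windows-1)]
    j = np.arange(n_snps)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, n_windows - 1)
    hit_cs = np.concatenate(
        [np.zeros((n_samples, 1), dtype=np.int32), np.cumsum(hit, axis=1, dtype=np.int32)],
        axis=1,
    )
    covering_hits = hit_cs[:, hi + 1] - hit_cs[:, lo]
    n_covering = hi - lo + 1
    frac = covering_hits / n_covering
    return (frac >= params.window_hit_frac) & ~het


def _runs_from_candidates(
    cand: np.ndarray, pos: np.ndarray, params: RohParams
) -> list[tuple[int, int]]:
    """Maximal candidate runs (first_idx, last_idx) for one sample, split at
    large gaps and filtered by the final segment constraints."""
    if not cand.any():
        return []
    gap_break = np.zeros(len(pos), dtype=bool)
    if len(pos) > 1:
        gap_break[1:] = np.diff(pos) > params.max_gap_kb * 1000.0
    new_run = cand & np.concatenate(([True], (~cand[:-1]))) | (cand & gap_break)
    run_id = np.where(cand, np.cumsum(new_run), 0)
    out = []
    for rid in range(1, run_id.max() + 1):
        idx = np.flatnonzero(run_id == rid)
        first, last = idx[0], idx[-1]
        n_snps = last - first + 1
        length_kb = (pos[last] - pos[first]) / 1000.0
        if (
            n_snps >= params.min_snp
            and length_kb >= params.min_kb
            and length_kb / n_snps <= params.min_density_kb_per_snp
        ):
            out.append((int(first), int(last)))
    return out


def detect_roh_all(ds: Dataset, params: RohParams = RohParams()) -> pd.DataFrame:
    """Detect ROH for every individual in the dataset.

    Returns a DataFrame with columns ``sample_id, chrom, start_bp, end_bp,
    n_snps, length_kb`` (the de-facto .hom table layout), sorted by sample
    then genome position.
    """
    rows: list[tuple] = []
    sample_ids = ds.samples["sample_id"].to_numpy()
    chrom_arr = ds.variants["chrom"].to_numpy()
    pos_arr = ds.variants["pos_bp"].to_numpy()
    for chrom in ds.chromosomes:
        vmask = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[vmask]
        if len(vmask) < params.window_snp:
            logger.info(
                "chromosome %s has %d SNPs (< window of %d): no windows",
                chrom,
                len(vmask),
                params.window_snp,
            )
            continue
        cand = _candidate_matrix(ds.genotypes[:, vmask], params)
        for i in np.flatnonzero(cand.any(axis=1)):
            for first, last in _runs_from_candidates(cand[i], pos, params):
                rows.append(
                    (
                        sample_ids[i],
                        chrom,
                        int(pos[first]),
                        int(pos[last]),
                        last - first + 1,
                        (pos[last] - pos[first]) / 1000.0,
                    )
                )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    order = {s: i for i, s in enumerate(sample_ids)}
    if len(df):
        df = df.sort_values(
            by=["sample_id", "chrom", "start_bp"],
            key=lambda col: col.map(order) if col.name == "sample_id" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def detect_roh(
    ds: Dataset, sample_id: str, params: RohParams = RohParams()
) -> pd.DataFrame:
    """ROH segments of a single individual (same columns as
    :func:`detect_roh_all`)."""
    idx = np.flatnonzero(ds.samples["sample_id"].to_numpy() == sample_id)
    if len(idx) == 0:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    return detect_roh_all(ds.subset(sample_idx=idx), params)


def froh(segments: pd.DataFrame, l_aut_mb: float = L_AUT_MB) -> float:
    """FROH = total ROH length / autosomal genome length for one individual's
    (or one pooled set of) segments."""
    if len(segments) == 0:
        return 0.0
    return float(segments["length_kb"].sum() / 1000.0 / l_aut_mb)


def froh_table(
    ds: Dataset,
    segments: pd.DataFrame,
    l_aut_mb: float = L_AUT_MB,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual and per-breed FROH.

    Breed FROH is the mean of its individuals' FROH; because every
    individual shares the same autosomal denominator this equals the
    breed's total ROH length over its total genome length.
    """
    per_sample = segments.groupby("sample_id")["length_kb"].sum() / 1000.0 / l_aut_mb
    ind = ds.samples[["sample_id", "population"]].copy()
    ind["f_roh"] = ind["sample_id"].map(per_sample).fillna(0.0)
    breed_df = (
        ind.groupby("population", sort=False)["f_roh"].mean().reset_index()
    )
    return ind, breed_df
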