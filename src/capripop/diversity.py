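"""Per-population heterozygosity and the inbreeding coefficient FIS.

For one locus within one population, with ``n`` non-missing diploid calls
and A1 frequency ``p`` among them:

    Ho   = (# heterozygotes) / n
    He   = 1 - p^2 - q^2
    uHe  = He * 2n / (2n - 1)          (small-sample "unbiased" correction)

Breed-level summaries are means and standard deviations of these per-locus
values across loci, and

    FIS = 1 - mean(Ho) / mean(uHe)

computed from the unrounded means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset


@dataclass
class DiversityRecord:
    """One breed's diversity summary (one table row)."""

    population: str
    n: int
    ho_mean: float
    ho_sd: float
    uhe_mean: float
    uhe_sd: float
    fis: float  # NaN when uhe_mean == 0


def fis_from_means(ho_mean: float, uhe_mean: float) -> float:
    """FIS = 1 - mean(Ho)/mean(uHe); NaN when the denominator is zero."""
    if uhe_mean == 0:
        return math.nan
    return 1.0 - ho_mean / uhe_mean


def _per_locus_matrix(g: np.ndarray):
    """Vectorized per-locus (ho, uhe, n_called) over a population sub-matrix."""
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, (g == 1).sum(axis=0) / n_called, np.nan)
        p = np.where(n_called > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * n_called), np.nan)
        he = 1.0 - p**2 - (1.0 - p) ** 2
        uhe = np.where(
            n_called > 0, he * 2.0 * n_called / np.maximum(2.0 * n_called - 1.0, 1.0), np.nan
        )
    return ho, uhe, n_called


def per_locus_het(genotypes: np.ndarray) -> tuple[float, float, int]:
    """Observed and unbiased expected heterozygosity of one locus.

    Parameters
    ----------
    genotypes
        1-D array of codes {0, 1, 2, MISSING} for one population at one locus.

    Returns
    -------
    (ho, uhe, n_called); raises ``ValueError`` when every call is missing.
    """
    g = np.asarray(genotypes).reshape(-1, 1)
    ho, uhe, n_called = _per_locus_matrix(g)
    if n_called[0] == 0:
        raise ValueError("all calls missing at this locus")
    return float(ho[0]), float(uhe[0]), int(n_called[0])


def breed_diversity(
    ds: Dataset, population: str, include_monomorphic: bool = True
) -> DiversityRecord:
    """Across-locus diversity summary for one population.

    Loci with no non-missing call in the population are excluded from the
    means; loci monomorphic within the population contribute zeros unless
    ``include_monomorphic`` is False.  SDs are population standard deviations
    (divisor = number of loci).
    """
    idx = ds.sample_index(population)
    ho, uhe, n_called = _per_locus_matrix(ds.genotypes[idx, :])
    keep = n_called > 0
    if not include_monomorphic:
        keep &= uhe > 0
    ho, uhe = ho[keep], uhe[keep]
    if ho.size == 0:
        raise ValueError(f"population {population!r} has no informative loci")
    return DiversityRecord(
        population=population,
        n=len(idx),
        ho_mean=float(ho.mean()),
        ho_sd=float(ho.std(ddof=0)),
        uhe_mean=float(uhe.mean()),
        uhe_sd=float(uhe.std(ddof=0)),
        fis=fis_from_means(float(ho.mean()), float(uhe.mean())),
    )


def diversity_table(ds: Dataset, include_monomorphic: bool = True) -> pd.DataFrame:
    """Diversity summary for every population, one row per breed."""
    rows = [
        breed_diversity(ds, pop, include_monomorphic).__dict__
        for pop in ds.populations
    ]
    return pd.DataFrame(rows)
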