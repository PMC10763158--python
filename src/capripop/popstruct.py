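"""Population structure summaries: Reynolds and IBS distances, classical MDS.

Reynolds' distance between two populations, summing over biallelic loci l
with allele-frequency vectors x1, x2 (two alleles per locus):

    D = sqrt( sum_l sum_u (x1_lu - x2_lu)^2
              / (2 * sum_l (1 - sum_u x1_lu * x2_lu)) )

a coancestry-based divergence that assumes pure drift.  The IBS distance
between two individuals is one minus the mean proportion of alleles shared
at loci called in both.  Classical (metric) MDS is principal-coordinate
analysis of the double-centred squared distance matrix, with
variance-explained fractions taken as eigenvalue shares over the positive
eigenvalues.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix has non-finite entries")

    # ------------------------------------------------------------------ #
    # standard-format export (for external tree/network software)
    # ------------------------------------------------------------------ #
    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fh.write(
                    f"{label[:10]:<10s}" + "  ".join(f"{x:.6f}" for x in row) + "\n"
                )

    def to_nexus(self, path: str | Path) -> None:
        """NEXUS DISTANCES block."""
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(self.labels)};\n  TAXLABELS\n")
            for label in self.labels:
                fh.write(f"    {label}\n")
            fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
            fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n  MATRIX\n")
            for label, row in zip(self.labels, self.d):
                fh.write(f"    {label} " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("  ;\nEND;\n")


@dataclass
class MdsResult:
    """Principal-coordinate embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def variance_explained(self) -> np.ndarray:
        """Eigenvalue share of each kept axis over all positive eigenvalues."""
        return self.eigenvalues / self._positive_sum

    _positive_sum: float = 1.0

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"dim{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# distances
# --------------------------------------------------------------------------- #
def _population_frequencies(ds: Dataset):
    """Per-population A1 frequency matrix (pops x loci; NaN where no calls)."""
    pops = ds.populations
    freqs = np.empty((len(pops), ds.n_variants))
    for i, pop in enumerate(pops):
        g = ds.genotypes_for(pop)
        called = g != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * n), np.nan)
    return pops, freqs


def reynolds_distance(ds: Dataset) -> DistanceMatrix:
    """Reynolds' coancestry distance between every pair of populations.

    Only loci with defined allele frequencies in both populations of a pair
    enter that pair's sums.  A population with zero called genotypes at
    every locus is an error.
    """
    pops, freqs = _population_frequencies(ds)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for i, pop in enumerate(pops):
        if np.isnan(freqs[i]).all():
            raise ValueError(f"population {pop!r} has no called genotypes")
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p1, p2 = freqs[i], freqs[j]
            ok = ~(np.isnan(p1) | np.isnan(p2))
            q1, q2 = 1.0 - p1[ok], 1.0 - p2[ok]
            num = np.sum((p1[ok] - p2[ok]) ** 2 + (q1 - q2) ** 2)
            den = 2.0 * np.sum(1.0 - (p1[ok] * p2[ok] + q1 * q2))
            d[i, j] = d[j, i] = np.sqrt(num / den) if den > 0 else 0.0
    return DistanceMatrix(list(pops), d)


def ibs_distance(ds: Dataset) -> DistanceMatrix:
    """1 - mean allele-sharing between every pair of individuals.

    Per locus called in both individuals, genotype codes sharing 2, 1 or 0
    alleles score similarity 1, 0.5 or 0, i.e. per-locus distance
    |g_i - g_j| / 2; the pair distance is the mean over jointly called
    loci.  A pair with zero jointly-called loci is an error naming the pair.

    The masked sum of |g_i - g_j| decomposes into matrix products
    (|d| = d^2 - 2*[opposite homozygotes]), so the whole matrix is computed
    without materialising a samples x samples x loci tensor.
    """
    g = ds.genotypes
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least two individuals")
    m = (g != MISSING).astype(np.float64)
    x = np.where(g == MISSING, 0, g).astype(np.float64)
    x2 = x**2
    hom_a1 = (g == 2).astype(np.float64)
    hom_a2 = (g == 0).astype(np.float64)
    shared = m @ m.T
    sq_sum = x2 @ m.T + m @ x2.T - 2.0 * (x @ x.T)
    opp_hom = hom_a1 @ hom_a2.T + hom_a2 @ hom_a1.T
    abs_sum = sq_sum - 2.0 * opp_hom
    off_diag = ~np.eye(n, dtype=bool)
    if (shared[off_diag] == 0).any():
        i0, j0 = next(zip(*np.nonzero((shared == 0) & off_diag)))
        raise ValueError(
            "no jointly called loci for pair "
            f"({ds.samples['sample_id'].iat[i0]}, "
            f"{ds.samples['sample_id'].iat[j0]})"
        )
    d = abs_sum / (2.0 * np.maximum(shared, 1.0))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ds.samples["sample_id"]), np.clip(d, 0.0, None))


# --------------------------------------------------------------------------- #
# classical MDS (principal coordinates)
# --------------------------------------------------------------------------- #
def classical_mds(dm: DistanceMatrix, k: int = 2) -> MdsResult:
    """Principal-coordinate analysis of a distance matrix.

    The doubly centred matrix -0.5 * J D^2 J is eigendecomposed; coordinates
    are the top-``k`` eigenvectors scaled by the square roots of their
    (positive) eigenvalues.  Negative eigenvalues (non-Euclidean input) are
    excluded from the variance-explained denominator with a logged count;
    ``k`` is truncated with a warning if it exceeds the number of positive
    eigenvalues.
    """
    n = len(dm.labels)
    if k > n - 1:
        raise ValueError(f"k={k} must be <= n-1 = {n - 1}")
    d2 = dm.d**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    n_pos = int((evals > tol).sum())
    n_neg = int((evals < -tol).sum())
    if n_neg:
        logger.info("dropping %d negative eigenvalues (non-Euclidean input)", n_neg)
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating k from {k} to {k_eff}",
            stacklevel=2,
        )
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    result = MdsResult(
        labels=list(dm.labels),
        coordinates=coords,
        eigenvalues=evals[:k_eff],
    )
    result._positive_sum = float(evals[:n_pos].sum()) if n_pos else 1.0
    return result
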