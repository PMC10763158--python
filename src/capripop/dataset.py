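"""Core in-memory container for diploid biallelic SNP-array data.

A :class:`Dataset` bundles a sample table, a variant map and a genotype
matrix.  Genotypes are coded as the count of the A1 allele (0, 1, 2) with
:data:`MISSING` (-1) for no-calls, the convention used by PLINK-style
tooling, so every downstream statistic in this package consumes the same
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Genotype code for a missing call.
MISSING: int = -1

SAMPLE_COLUMNS = ("sample_id", "population", "group")
VARIANT_COLUMNS = ("snp_id", "chrom", "pos_bp", "a1", "a2")

#: Valid metapopulation labels for a sample.
GROUPS = ("wet", "dry", "none")


class DatasetError(ValueError):
    """Raised when a Dataset violates its structural invariants."""


def _chrom_sort_key(label: str):
    """Numeric-first ordering of chromosome labels ("1" < "2" < ... < "10")."""
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class Dataset:
    """Samples x variants genotype matrix with its metadata tables.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``population``, ``group``.
    variants
        DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``, ``a1``,
        ``a2``; within each chromosome positions must be strictly increasing.
    genotypes
        ``int8`` array of shape ``(n_samples, n_variants)`` holding A1-allele
        counts, ``MISSING`` for no-calls.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_arrays(
        cls,
        sample_ids: Sequence[str],
        populations: Sequence[str],
        snp_ids: Sequence[str],
        chroms: Sequence[str],
        pos_bp: Sequence[int],
        genotypes: np.ndarray,
        groups: Sequence[str] | None = None,
        a1: Sequence[str] | None = None,
        a2: Sequence[str] | None = None,
    ) -> "Dataset":
        n_var = len(snp_ids)
        samples = pd.DataFrame(
            {
                "sample_id": list(sample_ids),
                "population": list(populations),
                "group": list(groups) if groups is not None else "none",
            }
        )
        variants = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "chrom": [str(c) for c in chroms],
                "pos_bp": np.asarray(pos_bp, dtype=np.int64),
                "a1": list(a1) if a1 is not None else ["A"] * n_var,
                "a2": list(a2) if a2 is not None else ["G"] * n_var,
            }
        )
        return cls(samples, variants, np.asarray(genotypes, dtype=np.int8))

    # ------------------------------------------------------------------ #
    # invariants
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise DatasetError(f"samples table missing column {col!r}")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise DatasetError(f"variants table missing column {col!r}")
        ns, nv = len(self.samples), len(self.variants)
        if self.genotypes.shape != (ns, nv):
            raise DatasetError(
                f"genotype matrix shape {self.genotypes.shape} != ({ns}, {nv})"
            )
        if nv and self.genotypes.size:
            bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
            if bad.any():
                raise DatasetError("genotype codes must be 0/1/2/MISSING")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise DatasetError(f"duplicated sample_id: {sorted(set(dup))[:5]}")
        if self.variants["snp_id"].duplicated().any():
            dup = self.variants["snp_id"][self.variants["snp_id"].duplicated()]
            raise DatasetError(f"duplicated snp_id: {sorted(set(dup))[:5]}")
        bad_group = ~self.samples["group"].isin(GROUPS)
        if bad_group.any():
            raise DatasetError(
                f"unknown group labels: {sorted(set(self.samples['group'][bad_group]))}"
            )
        if (np.asarray(self.variants["pos_bp"]) < 1).any():
            raise DatasetError("pos_bp must be >= 1 (1-based coordinates)")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise DatasetError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["population"]))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.variants["chrom"]))

    def sample_index(self, populations: str | Iterable[str]) -> np.ndarray:
        """Row indices of the samples belonging to one or more populations."""
        if isinstance(populations, str):
            populations = [populations]
        mask = self.samples["population"].isin(list(populations)).to_numpy()
        if not mask.any():
            raise KeyError(f"no samples for population(s) {list(populations)}")
        return np.flatnonzero(mask)

    def genotypes_for(self, populations: str | Iterable[str]) -> np.ndarray:
        """Genotype sub-matrix (copy-free view by row fancy-index) of one or
        more populations."""
        return self.genotypes[self.sample_index(populations), :]

    # ------------------------------------------------------------------ #
    # subsetting
    # ------------------------------------------------------------------ #
    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        variant_idx: np.ndarray | None = None,
    ) -> "Dataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx)
        )
        return Dataset(
            self.samples.iloc[si].reset_index(drop=True),
            self.variants.iloc[vi].reset_index(drop=True),
            self.genotypes[np.ix_(si, vi)],
        )

    def sort_variants(self) -> "Dataset":
        """Return a copy with chromosomes in numeric-first order and positions
        ascending within each chromosome."""
        order = sorted(
            range(self.n_variants),
            key=lambda i: (
                _chrom_sort_key(self.variants["chrom"].iat[i]),
                int(self.variants["pos_bp"].iat[i]),
            ),
        )
        return self.subset(variant_idx=np.asarray(order, dtype=np.int64))

    def with_groups(self, group_map: dict[str, str]) -> "Dataset":
        """Return a copy whose metapopulation labels follow ``group_map``
        (population -> wet/dry/none); unmapped populations get ``none``."""
        samples = self.samples.copy()
        samples["group"] = [
            group_map.get(p, "none") for p in samples["population"]
        ]
        return Dataset(samples, self.variants, self.genotypes)

    # ------------------------------------------------------------------ #
    # equality (used heavily by round-trip tests)
    # ------------------------------------------------------------------ #
    def equals(self, other: "Dataset") -> bool:
        return (
            self.samples[list(SAMPLE_COLUMNS)].equals(
                other.samples[list(SAMPLE_COLUMNS)]
            )
            and self.variants[list(VARIANT_COLUMNS)].equals(
                other.variants[list(VARIANT_COLUMNS)]
            )
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - thin alias
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.equals(other)


def allele_flip(ds: Dataset) -> Dataset:
    """Swap A1/A2 labels and flip genotype codes 0<->2 at every variant.

    Every statistic in this package is invariant under this relabeling; the
    helper exists so tests can assert exactly that.
    """
    variants = ds.variants.copy()
    variants[["a1", "a2"]] = variants[["a2", "a1"]].to_numpy()
    g = ds.genotypes.copy()
    called = g != MISSING
    g[called] = 2 - g[called]
    return Dataset(ds.samples, variants, g)
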