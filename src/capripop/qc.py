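"""Quality-control filtering of SNP-array datasets.

The filter order is fixed: SNP call rate, then minor-allele frequency
(computed on the retained SNPs over all samples), then per-individual
missingness (computed on the retained SNPs).  Counts of everything removed
are returned in a :class:`QcReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import MISSING, Dataset

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Removal counts and the thresholds that produced them."""

    n_snps_removed_callrate: int
    n_snps_removed_maf: int
    n_samples_removed_missing: int
    snp_call_rate: float
    maf_min: float
    ind_max_missing: float
    n_snps_in: int
    n_samples_in: int

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - self.n_snps_removed_callrate - self.n_snps_removed_maf

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed_missing

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.__dict__.items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"n_snps_out\t{self.n_snps_out}\n")
            fh.write(f"n_samples_out\t{self.n_samples_out}\n")


def allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant A1 allele frequency over non-missing calls (NaN if none)."""
    called = genotypes != MISSING
    n_called = called.sum(axis=0)
    a1_count = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, a1_count / (2.0 * n_called), np.nan)


def qc_filter(
    ds: Dataset,
    snp_call_rate: float = 0.90,
    maf_min: float = 0.05,
    ind_max_missing: float = 0.10,
) -> tuple[Dataset, QcReport]:
    """Apply the standard three-stage SNP-array QC.

    1. Remove SNPs with genotyping call rate below ``snp_call_rate``.
    2. Remove SNPs with minor-allele frequency <= ``maf_min`` (MAF over
       non-missing calls of all samples; sites kept must have MAF strictly
       above the threshold, so monomorphic SNPs always go).
    3. Remove individuals whose missing fraction over the retained SNPs
       exceeds ``ind_max_missing``.
    """
    g = ds.genotypes
    called = g != MISSING
    n_samples = ds.n_samples

    call_rate = (
        called.sum(axis=0) / n_samples if n_samples else np.zeros(ds.n_variants)
    )
    keep_cr = call_rate >= snp_call_rate
    n_cr = int((~keep_cr).sum())

    freq = allele_frequency(g[:, keep_cr]) if keep_cr.any() else np.empty(0)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf_local = ~(np.isnan(maf) | (maf <= maf_min))
    n_maf = int((~keep_maf_local).sum())
    keep_var = np.flatnonzero(keep_cr)[keep_maf_local]

    g2 = g[:, keep_var]
    if g2.shape[1]:
        ind_missing = (g2 == MISSING).sum(axis=1) / g2.shape[1]
    else:
        ind_missing = np.zeros(n_samples)
    keep_ind = np.flatnonzero(ind_missing <= ind_max_missing)
    n_ind = n_samples - len(keep_ind)

    report = QcReport(
        n_snps_removed_callrate=n_cr,
        n_snps_removed_maf=n_maf,
        n_samples_removed_missing=n_ind,
        snp_call_rate=snp_call_rate,
        maf_min=maf_min,
        ind_max_missing=ind_max_missing,
        n_snps_in=ds.n_variants,
        n_samples_in=n_samples,
    )
    logger.info(
        "QC: -%d SNPs (call rate), -%d SNPs (MAF), -%d individuals (missingness)",
        n_cr,
        n_maf,
        n_ind,
    )
    return ds.subset(sample_idx=keep_ind, variant_idx=keep_var), report
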