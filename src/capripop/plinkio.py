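"""Reading, writing and merging PLINK-format SNP-array genotypes.

Supports the binary dialect (.bed v1.0 SNP-major + .bim + .fam) and the
text dialect (.ped/.map).  The .bed codec implements the standard 2-bit
packing: per variant, samples are packed four to a byte, least-significant
bits first, with

    ``00`` = homozygous A1 (code 2), ``01`` = missing, ``10`` = heterozygous
    (code 1), ``11`` = homozygous A2 (code 0).

Population labels ride in the family-ID column; metapopulation (wet/dry)
labels are not part of the PLINK formats and are attached afterwards via
``Dataset.with_groups`` or a ``group_map`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset, DatasetError

logger = logging.getLogger(__name__)


def _ext(prefix: Path, suffix: str) -> Path:
    # not Path.with_suffix: prefixes may themselves contain dots
    return prefix.parent / (prefix.name + suffix)

BED_MAGIC = bytes((0x6C, 0x1B))
BED_SNP_MAJOR = 0x01

# 2-bit value -> genotype code (A1-allele count)
_BITS_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# genotype code (indexed at code+1 so MISSING=-1 maps to slot 0) -> 2-bit value
_CODE_TO_BITS = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)

_NON_AUTOSOMES = {"0", "X", "Y", "XY", "MT", "M"}


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, truncated payload, ...)."""


class PlinkConsistencyError(ValueError):
    """Mutually inconsistent companion files (dimension mismatch, ...)."""


@dataclass
class MergeReport:
    """Bookkeeping from :func:`merge_datasets`."""

    n_shared_snps: int
    n_allele_mismatch_dropped: int
    n_strand_flipped: int


# --------------------------------------------------------------------------- #
# binary dialect
# --------------------------------------------------------------------------- #
def _read_bed_matrix(path: Path, n_samples: int, n_variants: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != BED_MAGIC:
        raise PlinkFormatError(f"{path}: not a PLINK .bed file (magic bytes)")
    if raw[2] != BED_SNP_MAJOR:
        raise PlinkFormatError(f"{path}: only SNP-major .bed (mode 0x01) supported")
    bytes_per_variant = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_variant * n_variants:
        raise PlinkConsistencyError(
            f"{path}: payload of {len(body)} bytes does not match "
            f"{n_variants} variants x {n_samples} samples"
        )
    body = body.reshape(n_variants, bytes_per_variant)
    # expand each byte into its four 2-bit fields, low bits first
    pairs = np.empty((n_variants, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        pairs[:, k::4] = (body >> (2 * k)) & 0b11
    codes = _BITS_TO_CODE[pairs[:, :n_samples]]
    return np.ascontiguousarray(codes.T)  # samples x variants


def _write_bed_matrix(path: Path, genotypes: np.ndarray) -> None:
    n_samples, n_variants = genotypes.shape
    bytes_per_variant = (n_samples + 3) // 4
    bits = _CODE_TO_BITS[genotypes.T.astype(np.int16) + 1]  # variants x samples
    padded = np.full((n_variants, bytes_per_variant * 4), 0b01, dtype=np.uint8)
    padded[:, :n_samples] = bits
    # PLINK pads trailing sample slots with zeros (hom A1 bit-pattern 00)
    padded[:, n_samples:] = 0
    packed = np.zeros((n_variants, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(path, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(bytes((BED_SNP_MAJOR,)))
        packed.tofile(fh)


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    return pd.DataFrame(
        {"sample_id": fam["iid"], "population": fam["fid"], "group": "none"}
    )


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    return pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos_bp": bim["pos_bp"].astype(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )


# --------------------------------------------------------------------------- #
# text dialect
# --------------------------------------------------------------------------- #
def _read_map(path: Path) -> pd.DataFrame:
    mp = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    return pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chrom": mp["chrom"],
            "pos_bp": mp["pos_bp"].astype(np.int64),
        }
    )


def _read_ped(path: Path, n_variants: int):
    sample_rows: list[tuple[str, str]] = []
    allele_rows: list[np.ndarray] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_variants:
                raise PlinkConsistencyError(
                    f"{path}:{line_no}: expected {6 + 2 * n_variants} fields "
                    f"for {n_variants} variants, got {len(fields)}"
                )
            sample_rows.append((fields[0], fields[1]))
            allele_rows.append(np.array(fields[6:], dtype=object))
    samples = pd.DataFrame(
        {
            "sample_id": [iid for _, iid in sample_rows],
            "population": [fid for fid, _ in sample_rows],
            "group": "none",
        }
    )
    alleles = (
        np.array(allele_rows, dtype=object).reshape(len(sample_rows), n_variants, 2)
        if sample_rows
        else np.empty((0, n_variants, 2), dtype=object)
    )
    return samples, alleles


def _alleles_to_codes(alleles: np.ndarray):
    """Infer per-SNP (a1, a2) and A1-count codes from a .ped allele array.

    The text dialect does not record allele orientation, so A1 is assigned as
    the minor allele (ties broken lexicographically), matching PLINK.
    """
    n_samples, n_variants, _ = alleles.shape
    codes = np.full((n_samples, n_variants), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_variants):
        col = alleles[:, j, :]
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        flat = col[called].ravel()
        counts: dict[str, int] = {}
        for al in flat:
            counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise DatasetError(
                f"variant column {j}: more than two alleles {sorted(counts)}"
            )
        if not counts:
            a1, a2 = "0", "0"
        elif len(counts) == 1:
            a1, a2 = "0", next(iter(counts))
        else:
            (a1, _), (a2, _) = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        a1_list.append(a1)
        a2_list.append(a2)
        codes[called, j] = (col[called, 0] == a1).astype(np.int8) + (
            col[called, 1] == a1
        ).astype(np.int8)
    return a1_list, a2_list, codes


# --------------------------------------------------------------------------- #
# public API
# --------------------------------------------------------------------------- #
def _drop_non_autosomes(variants: pd.DataFrame, genotypes: np.ndarray):
    is_auto = variants["chrom"].map(
        lambda c: str(c).isdigit() and str(c) not in _NON_AUTOSOMES and int(c) >= 1
    )
    n_drop = int((~is_auto).sum())
    if n_drop:
        logger.info("dropping %d non-autosomal variants", n_drop)
        keep = np.flatnonzero(is_auto.to_numpy())
        variants = variants.iloc[keep].reset_index(drop=True)
        genotypes = genotypes[:, keep]
    return variants, genotypes


def read_plink(
    path_prefix: str | Path,
    dialect: str = "binary",
    group_map: dict[str, str] | None = None,
) -> Dataset:
    """Read a PLINK fileset into a :class:`Dataset`.

    Parameters
    ----------
    path_prefix
        Path stem; ``.bed/.bim/.fam`` or ``.ped/.map`` are appended.
    dialect
        ``"binary"`` or ``"text"``.
    group_map
        Optional population -> wet/dry metapopulation assignment.

    Variants are returned per-chromosome position-sorted (numeric chromosome
    order); non-autosomal chromosome labels are dropped with a logged count.
    """
    prefix = Path(path_prefix)
    if dialect == "binary":
        samples = _read_fam(_ext(prefix, ".fam"))
        variants = _read_bim(_ext(prefix, ".bim"))
        genotypes = _read_bed_matrix(
            _ext(prefix, ".bed"), len(samples), len(variants)
        )
    elif dialect == "text":
        variants = _read_map(_ext(prefix, ".map"))
        samples, alleles = _read_ped(_ext(prefix, ".ped"), len(variants))
        a1, a2, genotypes = _alleles_to_codes(alleles)
        variants = variants.assign(a1=a1, a2=a2)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    variants, genotypes = _drop_non_autosomes(variants, genotypes)
    order = sorted(
        range(len(variants)),
        key=lambda i: (int(variants["chrom"].iat[i]), int(variants["pos_bp"].iat[i])),
    )
    if order != list(range(len(variants))):
        variants = variants.iloc[order].reset_index(drop=True)
        genotypes = genotypes[:, order]
    ds = Dataset(samples, variants, genotypes)
    if group_map:
        ds = ds.with_groups(group_map)
    return ds


def write_plink(ds: Dataset, path_prefix: str | Path, dialect: str = "binary") -> None:
    """Write a :class:`Dataset` as a PLINK fileset (inverse of :func:`read_plink`)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        with open(_ext(prefix, ".fam"), "w") as fh:
            for row in ds.samples.itertuples(index=False):
                fh.write(f"{row.population} {row.sample_id} 0 0 0 -9\n")
        with open(_ext(prefix, ".bim"), "w") as fh:
            for v in ds.variants.itertuples(index=False):
                fh.write(f"{v.chrom} {v.snp_id} 0 {v.pos_bp} {v.a1} {v.a2}\n")
        _write_bed_matrix(_ext(prefix, ".bed"), ds.genotypes)
    elif dialect == "text":
        with open(_ext(prefix, ".map"), "w") as fh:
            for v in ds.variants.itertuples(index=False):
                fh.write(f"{v.chrom} {v.snp_id} 0 {v.pos_bp}\n")
        a1 = ds.variants["a1"].to_numpy()
        a2 = ds.variants["a2"].to_numpy()
        with open(_ext(prefix, ".ped"), "w") as fh:
            for i, row in enumerate(ds.samples.itertuples(index=False)):
                g = ds.genotypes[i]
                pairs = np.empty((len(g), 2), dtype=object)
                pairs[g == 2] = np.column_stack((a1, a1))[g == 2]
                pairs[g == 1] = np.column_stack((a1, a2))[g == 1]
                pairs[g == 0] = np.column_stack((a2, a2))[g == 0]
                pairs[g == MISSING] = "0"
                fh.write(
                    f"{row.population} {row.sample_id} 0 0 0 -9 "
                    + " ".join(pairs.ravel())
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def merge_datasets(a: Dataset, b: Dataset) -> tuple[Dataset, MergeReport]:
    """Merge two datasets on shared snp_ids, harmonizing allele orientation.

    The merged variant set is the snp_id intersection in ``a``'s order; where
    ``b`` records the same SNP with A1/A2 swapped its codes are flipped
    0<->2; SNPs whose allele pairs do not match even after the swap check are
    dropped and counted.  Sample rows are concatenated (duplicate sample_ids
    are an error).
    """
    dup = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if dup:
        raise DatasetError(f"duplicate sample_id across inputs: {sorted(dup)[:5]}")
    b_index = {s: j for j, s in enumerate(b.variants["snp_id"])}
    keep_a, keep_b, flip_b = [], [], []
    n_mismatch = 0
    for i, snp in enumerate(a.variants["snp_id"]):
        j = b_index.get(snp)
        if j is None:
            continue
        va, vb = a.variants.iloc[i], b.variants.iloc[j]
        if (va["a1"], va["a2"]) == (vb["a1"], vb["a2"]):
            keep_a.append(i), keep_b.append(j), flip_b.append(False)
        elif (va["a1"], va["a2"]) == (vb["a2"], vb["a1"]):
            keep_a.append(i), keep_b.append(j), flip_b.append(True)
        else:
            n_mismatch += 1
    keep_a = np.asarray(keep_a, dtype=np.int64)
    keep_b = np.asarray(keep_b, dtype=np.int64)
    flip_b = np.asarray(flip_b, dtype=bool)
    gb = b.genotypes[:, keep_b].copy()
    if flip_b.any():
        cols = gb[:, flip_b]
        called = cols != MISSING
        cols[called] = 2 - cols[called]
        gb[:, flip_b] = cols
    merged = Dataset(
        pd.concat([a.samples, b.samples], ignore_index=True),
        a.variants.iloc[keep_a].reset_index(drop=True),
        np.vstack([a.genotypes[:, keep_a], gb]),
    )
    report = MergeReport(
        n_shared_snps=len(keep_a),
        n_allele_mismatch_dropped=n_mismatch,
        n_strand_flipped=int(flip_b.sum()),
    )
    if n_mismatch:
        logger.info("merge dropped %d SNPs with irreconcilable alleles", n_mismatch)
    return merged, report
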