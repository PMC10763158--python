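"""PLINK I/O: codec correctness, round trips, merging, QC plumbing."""

from __future__ import annotations

import numpy as np
import pytest

from capripop import Dataset, merge_datasets, read_plink, write_plink
from capripop.dataset import MISSING, DatasetError, allele_flip
from capripop.plinkio import PlinkConsistencyError, PlinkFormatError

from conftest import make_dataset


def _write_text_fixture(tmp_path):
    """2 samples x 3 SNPs, alleles chosen so the minor allele is unambiguous."""
    (tmp_path / "fix.map").write_text(
        "1 snp1 0 1000\n1 snp2 0 2000\n1 snp3 0 3000\n"
    )
    # snp1: s1=AA s2=AG -> minor G: codes 0, 1
    # snp2: s1=CC s2=CC -> monomorphic: codes 0, 0 (a1 is the absent allele)
    # snp3: s1=TT s2=00 -> missing for s2: codes 0, MISSING
    (tmp_path / "fix.ped").write_text(
        "FAM1 s1 0 0 0 -9 A A C C T T\n"
        "FAM1 s2 0 0 0 -9 A G C C 0 0\n"
    )
    return tmp_path / "fix"


def test_ped_map_hand_decoding(tmp_path):
    ds = read_plink(_write_text_fixture(tmp_path), "text")
    assert ds.n_samples == 2 and ds.n_variants == 3
    assert list(ds.samples["sample_id"]) == ["s1", "s2"]
    assert list(ds.samples["population"]) == ["FAM1", "FAM1"]
    expected = np.array([[0, 0, 0], [1, 0, MISSING]], dtype=np.int8)
    np.testing.assert_array_equal(ds.genotypes, expected)
    assert list(ds.variants["a1"]) == ["G", "0", "0"]
    assert list(ds.variants["a2"]) == ["A", "C", "T"]


def test_text_to_binary_round_trip(tmp_path):
    ds = read_plink(_write_text_fixture(tmp_path), "text")
    write_plink(ds, tmp_path / "bin", "binary")
    ds2 = read_plink(tmp_path / "bin", "binary")
    assert ds.equals(ds2)


def test_bed_missing_code_decoded_by_hand(tmp_path):
    """One variant, four samples with codes (2, 1, 0, missing): the packed
    byte is 00 | 10<<2 | 11<<4 | 01<<6 = 0x78."""
    (tmp_path / "m.fam").write_text(
        "".join(f"P s{i} 0 0 0 -9\n" for i in range(4))
    )
    (tmp_path / "m.bim").write_text("1 snp1 0 500 A G\n")
    (tmp_path / "m.bed").write_bytes(bytes((0x6C, 0x1B, 0x01, 0x78)))
    ds = read_plink(tmp_path / "m", "binary")
    np.testing.assert_array_equal(
        ds.genotypes.ravel(), np.array([2, 1, 0, MISSING], dtype=np.int8)
    )


def test_bad_magic_bytes(tmp_path):
    (tmp_path / "m.fam").write_text("P s0 0 0 0 -9\n")
    (tmp_path / "m.bim").write_text("1 snp1 0 500 A G\n")
    (tmp_path / "m.bed").write_bytes(bytes((0x00, 0x1B, 0x01, 0x78)))
    with pytest.raises(PlinkFormatError):
        read_plink(tmp_path / "m", "binary")


def test_bed_dimension_mismatch(tmp_path):
    (tmp_path / "m.fam").write_text("P s0 0 0 0 -9\n")
    (tmp_path / "m.bim").write_text("1 snp1 0 500 A G\n1 snp2 0 900 A G\n")
    (tmp_path / "m.bed").write_bytes(bytes((0x6C, 0x1B, 0x01, 0x78)))
    with pytest.raises(PlinkConsistencyError):
        read_plink(tmp_path / "m", "binary")


def test_duplicate_snp_id_rejected(tmp_path):
    (tmp_path / "m.fam").write_text("P s0 0 0 0 -9\n")
    (tmp_path / "m.bim").write_text("1 snp1 0 500 A G\n1 snp1 0 900 A G\n")
    (tmp_path / "m.bed").write_bytes(bytes((0x6C, 0x1B, 0x01, 0x00, 0x00)))
    with pytest.raises(DatasetError):
        read_plink(tmp_path / "m", "binary")


def test_binary_round_trip_random(tmp_path, rng):
    g = rng.integers(-1, 3, size=(17, 33)).astype(np.int8)
    ds = make_dataset(g, populations=["A"] * 9 + ["B"] * 8)
    write_plink(ds, tmp_path / "r", "binary")
    assert read_plink(tmp_path / "r", "binary").equals(ds)


def test_empty_variant_round_trip(tmp_path):
    ds = make_dataset(np.zeros((3, 0), dtype=np.int8))
    for dialect in ("binary", "text"):
        write_plink(ds, tmp_path / f"e_{dialect}", dialect)
        back = read_plink(tmp_path / f"e_{dialect}", dialect)
        assert back.n_variants == 0 and back.n_samples == 3


def test_survey_scale_round_trip(tmp_path, rng):
    """A 1231 x 45,149 matrix survives the 2-bit packing element-wise."""
    n_samples, n_variants = 1231, 45_149
    g = rng.integers(0, 3, size=(n_samples, n_variants)).astype(np.int8)
    g[rng.random(g.shape) < 0.01] = MISSING
    ds = make_dataset(
        g,
        populations=["P"] * n_samples,
        chroms=["1"] * n_variants,
        pos_bp=list(range(1000, 1000 * (n_variants + 1), 1000)),
    )
    write_plink(ds, tmp_path / "big", "binary")
    back = read_plink(tmp_path / "big", "binary")
    np.testing.assert_array_equal(back.genotypes, ds.genotypes)
    assert back.equals(ds)


def test_non_autosomes_dropped(tmp_path):
    (tmp_path / "m.fam").write_text("P s0 0 0 0 -9\n")
    (tmp_path / "m.bim").write_text(
        "1 snp1 0 500 A G\nX snpX 0 900 A G\n0 snp0 0 100 A G\n"
    )
    # 3 variants x 1 sample: one byte per variant
    (tmp_path / "m.bed").write_bytes(bytes((0x6C, 0x1B, 0x01, 0x00, 0x00, 0x00)))
    ds = read_plink(tmp_path / "m", "binary")
    assert list(ds.variants["snp_id"]) == ["snp1"]


def test_variants_position_sorted_on_read(tmp_path):
    (tmp_path / "m.fam").write_text("P s0 0 0 0 -9\n")
    (tmp_path / "m.bim").write_text(
        "2 a 0 900 A G\n1 b 0 500 A G\n1 c 0 100 A G\n"
    )
    (tmp_path / "m.bed").write_bytes(bytes((0x6C, 0x1B, 0x01, 0x00, 0x00, 0x00)))
    ds = read_plink(tmp_path / "m", "binary")
    assert list(ds.variants["snp_id"]) == ["c", "b", "a"]


# --------------------------------------------------------------------------- #
# merging
# --------------------------------------------------------------------------- #
def test_merge_flip_symmetry(rng):
    """Merging with an A1/A2-swapped copy equals concatenating flipped codes."""
    g = rng.integers(-1, 3, size=(5, 12)).astype(np.int8)
    a = make_dataset(g, populations=["A"] * 5, a1=["A"] * 12, a2=["G"] * 12)
    b_flipped = allele_flip(
        make_dataset(g, populations=["B"] * 5, a1=["A"] * 12, a2=["G"] * 12)
    )
    b = Dataset(
        b_flipped.samples.assign(sample_id=[f"t{i}" for i in range(5)]),
        b_flipped.variants,
        b_flipped.genotypes,
    )
    merged, report = merge_datasets(a, b)
    assert report.n_shared_snps == 12 and report.n_strand_flipped == 12
    np.testing.assert_array_equal(merged.genotypes, np.vstack([g, g]))


def test_merge_disjoint_snp_sets(rng):
    a = random_a = make_dataset(
        rng.integers(0, 3, size=(3, 4)).astype(np.int8), populations=["A"] * 3
    )
    b = make_dataset(
        rng.integers(0, 3, size=(2, 4)).astype(np.int8), populations=["B"] * 2
    )
    b = Dataset(
        b.samples.assign(sample_id=["x0", "x1"]),
        b.variants.assign(snp_id=[f"other{j}" for j in range(4)]),
        b.genotypes,
    )
    merged, report = merge_datasets(a, b)
    assert merged.n_variants == 0 and merged.n_samples == 5
    assert report.n_shared_snps == 0


def test_merge_allele_mismatch_dropped(rng):
    g = rng.integers(0, 3, size=(2, 3)).astype(np.int8)
    a = make_dataset(g, populations=["A"] * 2, a1=["A", "A", "A"], a2=["C", "C", "C"])
    b = make_dataset(g, populations=["B"] * 2, a1=["A", "C", "A"], a2=["C", "A", "G"])
    b = Dataset(b.samples.assign(sample_id=["y0", "y1"]), b.variants, b.genotypes)
    merged, report = merge_datasets(a, b)
    # snp0 matches, snp1 is a swap, snp2 has alleles {A,G} vs {A,C} -> dropped
    assert report.n_shared_snps == 2
    assert report.n_allele_mismatch_dropped == 1
    assert report.n_strand_flipped == 1
    assert list(merged.variants["snp_id"]) == ["snp0", "snp1"]


def test_merge_idempotent_on_variants(rng):
    g = rng.integers(0, 3, size=(3, 6)).astype(np.int8)
    a = make_dataset(g, populations=["A"] * 3)
    renamed = Dataset(
        a.samples.assign(sample_id=["r0", "r1", "r2"]), a.variants, a.genotypes
    )
    merged, _ = merge_datasets(a, renamed)
    assert list(merged.variants["snp_id"]) == list(a.variants["snp_id"])


def test_merge_duplicate_sample_ids_rejected(rng):
    a = make_dataset(rng.integers(0, 3, size=(2, 3)).astype(np.int8))
    with pytest.raises(DatasetError):
        merge_datasets(a, a)
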