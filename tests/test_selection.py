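"""ROH islands, Weir-Cockerham components, windowed FST and the contrast
design."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from capripop import (
    build_contrasts,
    island_length_mb,
    roh_islands,
    significant_windows,
    snp_roh_frequency,
    wc_components,
    windowed_fst,
)
from capripop.dataset import MISSING

from conftest import make_dataset
from oracles import wc84_oracle_from_stats


# --------------------------------------------------------------------------- #
# per-SNP ROH occurrence
# --------------------------------------------------------------------------- #
def _occurrence_fixture():
    g = np.zeros((4, 5), dtype=np.int8)
    ds = make_dataset(
        g, populations=["B"] * 4, pos_bp=[100, 200, 300, 400, 500]
    )
    segments = pd.DataFrame(
        {
            "sample_id": ["s0", "s1", "s2"],
            "chrom": ["1", "1", "1"],
            "start_bp": [100, 150, 100],
            "end_bp": [300, 300, 250],
            "n_snps": [3, 2, 2],
            "length_kb": [0.2, 0.15, 0.15],
        }
    )
    return ds, segments


def test_occurrence_counts_animals():
    ds, segments = _occurrence_fixture()
    freqs = snp_roh_frequency(segments, ds, "B")
    # SNP at 200 is inside all three segments; denominator is all 4 animals
    assert freqs.loc[freqs["pos_bp"] == 200, "occurrence"].iat[0] == pytest.approx(0.75)
    assert freqs.loc[freqs["pos_bp"] == 400, "occurrence"].iat[0] == 0.0


def test_occurrence_segment_end_inclusive():
    ds, segments = _occurrence_fixture()
    freqs = snp_roh_frequency(segments, ds, "B")
    # 300 is the end_bp of two segments and inside none other
    assert freqs.loc[freqs["pos_bp"] == 300, "occurrence"].iat[0] == pytest.approx(0.5)


def test_occurrence_bruteforce_interval_stabbing(rng):
    g = np.zeros((6, 30), dtype=np.int8)
    pos = np.sort(rng.choice(np.arange(1000, 100_000), size=30, replace=False))
    ds = make_dataset(g, populations=["B"] * 6, pos_bp=pos.tolist())
    rows = []
    for i in range(6):
        # segments of one animal must be non-overlapping (detector invariant)
        bounds = np.sort(rng.choice(np.arange(1000, 100_000), size=4, replace=False))
        for a, b in ((bounds[0], bounds[1]), (bounds[2], bounds[3])):
            if rng.random() < 0.7:
                rows.append((f"s{i}", "1", int(a), int(b), 1, (b - a) / 1000.0))
    segments = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]
    )
    freqs = snp_roh_frequency(segments, ds, "B")
    for j, p in enumerate(pos):
        covered = {
            sid
            for sid, _, a, b, _, _ in segments.itertuples(index=False)
            if a <= p <= b
        }
        assert freqs["occurrence"].iat[j] == pytest.approx(len(covered) / 6.0)


# --------------------------------------------------------------------------- #
# islands
# --------------------------------------------------------------------------- #
def _freq_frame(occ, chroms=None, pos=None):
    n = len(occ)
    return pd.DataFrame(
        {
            "population": "B",
            "snp_id": [f"snp{i}" for i in range(n)],
            "chrom": chroms or ["1"] * n,
            "pos_bp": pos or [1000 * (i + 1) for i in range(n)],
            "occurrence": occ,
        }
    )


def test_single_hot_block_one_island():
    occ = np.zeros(10_000)
    occ[500:512] = 0.9
    islands = roh_islands(_freq_frame(occ.tolist()))
    assert len(islands) == 1
    row = islands.iloc[0]
    assert row["n_snps"] == 12
    assert row["start_bp"] == 1000 * 501 and row["end_bp"] == 1000 * 512


def test_hot_block_split_across_chromosomes():
    occ = np.zeros(10_000)
    occ[4997:5009] = 0.9  # straddles the 5000-SNP chromosome boundary
    chroms = ["1"] * 5000 + ["2"] * 5000
    pos = [1000 * (i + 1) for i in range(5000)] * 2
    islands = roh_islands(_freq_frame(occ.tolist(), chroms, pos))
    assert len(islands) == 2
    assert list(islands["chrom"]) == ["1", "2"]
    assert list(islands["n_snps"]) == [3, 9]


def test_degenerate_occurrence_warns_and_returns_none():
    with pytest.warns(UserWarning, match="degenerate"):
        islands = roh_islands(_freq_frame([0.5] * 100))
    assert len(islands) == 0


def test_island_length_from_printed_style_bounds():
    assert island_length_mb(37_746_029, 39_150_759) == pytest.approx(1.40, abs=0.005)


# --------------------------------------------------------------------------- #
# Weir-Cockerham components
# --------------------------------------------------------------------------- #
def _two_pop_ds(g1, g2):
    g = np.vstack([g1, g2]).astype(np.int8)
    n1 = len(g1)
    return make_dataset(
        g, populations=["A"] * n1 + ["B"] * (len(g) - n1)
    )


def test_fixed_difference_components():
    """p1=1 vs p2=0 with n=10 each: a=0.5, b=c=0, theta=1."""
    ds = _two_pop_ds(np.full((10, 1), 2), np.zeros((10, 1)))
    comp = wc_components(ds, "A", "B")
    assert comp["a"].iat[0] == pytest.approx(0.5, abs=1e-12)
    assert comp["b"].iat[0] == pytest.approx(0.0, abs=1e-12)
    assert comp["c"].iat[0] == pytest.approx(0.0, abs=1e-12)
    assert comp["theta"].iat[0] == pytest.approx(1.0, abs=1e-12)


def test_negative_theta_hand_value():
    """Identical half-heterozygous populations give the textbook negative
    estimate -0.0556 (oracle transcription of the published equations)."""
    a, b, c = wc84_oracle_from_stats(10, 0.5, 0.5, 10, 0.5, 0.5)
    assert a / (a + b + c) == pytest.approx(-1.0 / 18.0, abs=1e-12)
    assert a / (a + b + c) == pytest.approx(-0.0556, abs=5e-5)


def test_monomorphic_locus_excluded():
    ds = _two_pop_ds(np.full((5, 1), 2), np.full((5, 1), 2))
    comp = wc_components(ds, "A", "B")
    assert not comp["defined"].iat[0]
    assert (comp[["a", "b", "c"]].iloc[0] == 0).all()


def test_small_side_skipped():
    g = np.array([[2], [0], [1]], dtype=np.int8)
    ds = make_dataset(g, populations=["A", "A", "B"])
    comp = wc_components(ds, "A", "B")
    assert not comp["defined"].iat[0]


def test_components_match_oracle_with_missingness(rng):
    g = rng.integers(-1, 3, size=(25, 50)).astype(np.int8)
    ds = make_dataset(g, populations=["A"] * 12 + ["B"] * 13)
    comp = wc_components(ds, "A", "B")
    from oracles import wc84_oracle_from_genotypes

    for j in range(50):
        if not comp["defined"].iat[j]:
            continue
        a, b, c = wc84_oracle_from_genotypes(g[:12, j].tolist(), g[12:, j].tolist())
        assert comp["a"].iat[j] == pytest.approx(a, abs=1e-12)
        assert comp["b"].iat[j] == pytest.approx(b, abs=1e-12)
        assert comp["c"].iat[j] == pytest.approx(c, abs=1e-12)


def test_metapopulation_pools_individuals():
    """Pooling two breeds per side equals relabeling them as one population."""
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
    ds = make_dataset(g, populations=["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
    pooled = wc_components(ds, ["A", "B"], ["C", "D"])
    relabeled = make_dataset(g, populations=["W"] * 10 + ["E"] * 10)
    direct = wc_components(relabeled, "W", "E")
    np.testing.assert_allclose(pooled[["a", "b", "c"]], direct[["a", "b", "c"]])


# --------------------------------------------------------------------------- #
# windows
# --------------------------------------------------------------------------- #
def _components_frame(pos, a, b, c, chrom="1"):
    n = len(pos)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos_bp": pos,
            "a": a,
            "b": b,
            "c": c,
            "theta": np.asarray(a) / (np.asarray(a) + np.asarray(b) + np.asarray(c)),
            "defined": [True] * n,
        }
    )


def test_window_weighted_fst_arithmetic():
    comp = _components_frame(
        pos=[100_000, 200_000],
        a=[0.5, -0.0139],
        b=[0.0, 0.0139],
        c=[0.0, 0.25],
    )
    win = windowed_fst(comp)
    first = win[win["start_bp"] == 1].iloc[0]
    assert first["n_snps"] == 2
    assert first["weighted_fst"] == pytest.approx(0.4861 / 0.75, abs=1e-9)


def test_snp_in_overlapping_windows():
    comp = _components_frame(pos=[400_000], a=[0.2], b=[0.1], c=[0.1])
    win = windowed_fst(comp)
    starts = set(win["start_bp"])
    assert starts == {1, 250_001}
    assert (win["n_snps"] == 1).all()
    assert (win["end_bp"] - win["start_bp"] == 499_999).all()


def test_single_snp_window_equals_theta(rng):
    a, b, c = 0.3, 0.2, 0.4
    comp = _components_frame(pos=[100_000], a=[a], b=[b], c=[c])
    win = windowed_fst(comp)
    assert win["weighted_fst"].iloc[0] == pytest.approx(a / (a + b + c))


def test_equal_frequency_populations_nonpositive_windows(rng):
    """Identical genotype blocks in both populations force a <= 0 at every
    locus, hence every window FST <= 0."""
    block = rng.integers(0, 3, size=(15, 300)).astype(np.int8)
    g = np.vstack([block, block])
    pos = np.cumsum(rng.integers(5_000, 40_000, size=300)).tolist()
    ds = make_dataset(g, populations=["A"] * 15 + ["B"] * 15, pos_bp=pos)
    comp = wc_components(ds, "A", "B")
    win = windowed_fst(comp)
    assert len(win) > 0
    assert (win["weighted_fst"] <= 1e-12).all()


def test_windows_not_emitted_past_last_snp():
    comp = _components_frame(pos=[600_000], a=[0.1], b=[0.1], c=[0.1])
    win = windowed_fst(comp)
    assert win["start_bp"].max() <= 600_000


# --------------------------------------------------------------------------- #
# significance rule
# --------------------------------------------------------------------------- #
def _window_frame(values, n_snps=6):
    n = len(values)
    return pd.DataFrame(
        {
            "contrast": "c",
            "chrom": "1",
            "start_bp": np.arange(n) * 250_000 + 1,
            "end_bp": np.arange(n) * 250_000 + 500_000,
            "n_snps": n_snps if np.isscalar(n_snps) else n_snps,
            "weighted_fst": values,
        }
    )


def test_top_windows_selected():
    rng = np.random.default_rng(0)
    values = rng.uniform(0.0, 0.1, size=10_000)
    values[:5] = 0.5
    sig = significant_windows(_window_frame(values.tolist()))
    assert len(sig) == 5
    assert (sig["weighted_fst"] == 0.5).all()


def _sparse_top_frame():
    rng = np.random.default_rng(1)
    values = rng.uniform(0.0, 0.1, size=10_000)
    values[0] = 0.9  # extreme but sparse window
    n_snps = [4] + [6] * 9999
    return _window_frame(values.tolist(), n_snps)


def test_snp_count_rule_excludes_sparse_window():
    sig = significant_windows(_sparse_top_frame())
    assert 0.9 not in set(sig["weighted_fst"])


def test_filter_first_changes_pool():
    default = significant_windows(_sparse_top_frame())
    filtered = significant_windows(_sparse_top_frame(), filter_first=True)
    # with the sparse extreme window out of the percentile pool, the
    # threshold drops and at least as many dense windows qualify
    assert len(filtered) >= len(default)
    assert 0.9 not in set(filtered["weighted_fst"])


def test_degenerate_windows_warn_and_return_none():
    with pytest.warns(UserWarning, match="degenerate"):
        sig = significant_windows(_window_frame([0.2] * 100))
    assert len(sig) == 0


# --------------------------------------------------------------------------- #
# contrast design
# --------------------------------------------------------------------------- #
def _design_ds(pops_groups):
    pops = [p for p, _, n in pops_groups for _ in range(n)]
    groups = [g for _, g, n in pops_groups for _ in range(n)]
    g = np.zeros((len(pops), 3), dtype=np.int8)
    return make_dataset(g, populations=pops, groups=groups)


def test_four_breed_design_gives_five_contrasts():
    ds = _design_ds(
        [("PAL", "wet", 2), ("TIN", "wet", 2), ("MAJ", "dry", 2), ("TIS", "dry", 2)]
    )
    contrasts = build_contrasts(ds)
    assert len(contrasts) == 5
    assert contrasts[0].label == "metapopulation"
    assert set(contrasts[0].pops_a) == {"PAL", "TIN"}
    assert set(contrasts[0].pops_b) == {"MAJ", "TIS"}
    labels = {c.label for c in contrasts[1:]}
    assert labels == {"PAL_MAJ", "PAL_TIS", "TIN_MAJ", "TIN_TIS"}


def test_two_breed_design_gives_two_contrasts():
    ds = _design_ds([("A", "wet", 2), ("B", "dry", 2)])
    contrasts = build_contrasts(ds)
    assert len(contrasts) == 2


def test_ungrouped_breed_excluded():
    ds = _design_ds([("A", "wet", 2), ("B", "dry", 2), ("C", "none", 2)])
    labels = {c.label for c in build_contrasts(ds)}
    assert not any("C" in lbl for lbl in labels)


def test_missing_group_raises():
    ds = _design_ds([("A", "wet", 2), ("C", "none", 2)])
    with pytest.raises(ValueError, match="wet|dry"):
        build_contrasts(ds)
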