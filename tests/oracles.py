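"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written as plain Python loops directly from
the definitions, sharing no code with the package, so agreement is a real
check and not a tautology.
"""

from __future__ import annotations

import math

MISSING = -1


# --------------------------------------------------------------------------- #
# ROH scanning-window detector
# --------------------------------------------------------------------------- #
def roh_oracle(genotypes, pos, params):
    """All maximal candidate runs satisfying the final segment constraints,
    for one individual on one chromosome.

    Returns a list of (start_bp, end_bp, n_snps) tuples.
    """
    g = list(genotypes)
    pos = list(pos)
    n = len(g)
    w = params.window_snp
    cand = [False] * n
    if n >= w:
        hits = []
        for s in range(n - w + 1):
            window = g[s : s + w]
            n_het = sum(1 for x in window if x == 1)
            n_mis = sum(1 for x in window if x == MISSING)
            hits.append(n_het <= params.window_het and n_mis <= params.window_missing)
        for j in range(n):
            covering = [
                hits[s] for s in range(max(0, j - w + 1), min(j, n - w) + 1)
            ]
            frac = sum(covering) / len(covering)
            cand[j] = frac >= params.window_hit_frac and g[j] != 1
    segments = []
    i = 0
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and cand[j + 1]
            and (pos[j + 1] - pos[j]) <= params.max_gap_kb * 1000.0
        ):
            j += 1
        n_snps = j - i + 1
        length_kb = (pos[j] - pos[i]) / 1000.0
        if (
            n_snps >= params.min_snp
            and length_kb >= params.min_kb
            and length_kb / n_snps <= params.min_density_kb_per_snp
        ):
            segments.append((pos[i], pos[j], n_snps))
        i = j + 1
    return segments


# --------------------------------------------------------------------------- #
# Weir & Cockerham (1984) two-population components
# --------------------------------------------------------------------------- #
def wc84_oracle_from_stats(n1, p1, h1, n2, p2, h2):
    """Variance components (a, b, c) from per-population sample size, allele
    frequency and observed heterozygote frequency, transcribed equation by
    equation from the 1984 description for r = 2 populations."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc84_oracle_from_genotypes(geno1, geno2):
    """(a, b, c) from two genotype-code lists, counting everything by loops."""

    def stats(geno):
        called = [g for g in geno if g != MISSING]
        n = len(called)
        p = sum(called) / (2.0 * n)
        h = sum(1 for g in called if g == 1) / n
        return n, p, h

    n1, p1, h1 = stats(geno1)
    n2, p2, h2 = stats(geno2)
    return wc84_oracle_from_stats(n1, p1, h1, n2, p2, h2)


# --------------------------------------------------------------------------- #
# QC three-pass reference
# --------------------------------------------------------------------------- #
def qc_oracle(genotypes, snp_call_rate, maf_min, ind_max_missing):
    """Row/column keep lists after the three filters, by direct recount.

    ``genotypes`` is a list of per-sample lists of codes.
    """
    n_samples = len(genotypes)
    n_snps = len(genotypes[0]) if n_samples else 0
    keep_snps = []
    for j in range(n_snps):
        col = [genotypes[i][j] for i in range(n_samples)]
        called = [g for g in col if g != MISSING]
        if n_samples == 0 or len(called) / n_samples < snp_call_rate:
            continue
        keep_snps.append(j)
    keep_snps2 = []
    for j in keep_snps:
        col = [genotypes[i][j] for i in range(n_samples)]
        called = [g for g in col if g != MISSING]
        if not called:
            continue
        p = sum(called) / (2.0 * len(called))
        if min(p, 1.0 - p) <= maf_min:
            continue
        keep_snps2.append(j)
    keep_samples = []
    for i in range(n_samples):
        row = [genotypes[i][j] for j in keep_snps2]
        if not row:
            keep_samples.append(i)
            continue
        missing_frac = sum(1 for g in row if g == MISSING) / len(row)
        if missing_frac <= ind_max_missing:
            keep_samples.append(i)
    return keep_samples, keep_snps2


# --------------------------------------------------------------------------- #
# distances
# --------------------------------------------------------------------------- #
def reynolds_oracle(freqs1, freqs2):
    """Reynolds D from two per-locus A1 frequency lists (None = undefined)."""
    num = 0.0
    den = 0.0
    for p1, p2 in zip(freqs1, freqs2):
        if p1 is None or p2 is None:
            continue
        q1, q2 = 1.0 - p1, 1.0 - p2
        num += (p1 - p2) ** 2 + (q1 - q2) ** 2
        den += 2.0 * (1.0 - (p1 * p2 + q1 * q2))
    return math.sqrt(num / den) if den > 0 else 0.0


def ibs_oracle(geno1, geno2):
    """1 - allele-sharing proportion between two individuals."""
    num = 0.0
    n_shared = 0
    for g1, g2 in zip(geno1, geno2):
        if g1 == MISSING or g2 == MISSING:
            continue
        n_shared += 1
        num += abs(g1 - g2) / 2.0
    if n_shared == 0:
        raise ValueError("no shared called loci")
    return num / n_shared


# --------------------------------------------------------------------------- #
# dispersion
# --------------------------------------------------------------------------- #
def two_pass_sd(values):
    """Population standard deviation by the textbook two-pass algorithm."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)
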