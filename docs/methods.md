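# Methods

`capripop` implements the genome-wide analysis workflow used in SNP-array
surveys of structured livestock populations: per-breed diversity, runs of
homozygosity (ROH) and the FROH inbreeding coefficient, ROH-island and
windowed-FST selection scans with environment-defined metapopulation
contrasts, and drift-based distance summaries.  This note records the
models, the parameters that matter, and the design decisions taken where
more than one convention exists.

## Data model

A `Dataset` is a samples x variants matrix of A1-allele counts
(0/1/2, -1 for missing) with a variant map (chromosome, 1-based bp
position, allele labels) and a sample table (breed, wet/dry metapopulation
label).  Only autosomes are modelled; non-autosomal chromosome labels are
dropped on input with a logged count.  All intervals are reported as
inclusive `[start_bp, end_bp]`.  Every statistic in the package is
invariant under swapping the A1/A2 labels of any variant (verified by
property tests), so allele orientation is bookkeeping, not substance.

PLINK binary (.bed v1.0 SNP-major, bit-exact 2-bit packing) and text
(.ped/.map) dialects are both supported.  The text dialect carries no
allele orientation, so on read A1 is assigned as the minor allele (the
PLINK convention); binary round trips are exact.

## Quality control

Filters run in a fixed order: (1) SNP call rate >= 0.90; (2) minor allele
frequency strictly > 0.05, computed from non-missing calls of all retained
samples (monomorphic sites always fail); (3) individual missingness <=
0.10 over the retained SNPs.  The order matters — MAF is computed after
low-call-rate SNPs are gone, individual missingness after both SNP filters
— and the report records the three removal counts separately.  Because the
filter thresholds are exposed, MAF can equally be applied before or after
merging datasets; the package takes no position on which is correct.

## Diversity

For one locus in one breed with `n` called genotypes and A1 frequency `p`:
`Ho = n_het / n`, `He = 1 - p^2 - q^2`, and the small-sample correction
`uHe = He * 2n/(2n - 1)`, so `uHe >= He` always, converging as `n` grows.
Breed summaries are means and population SDs (divisor = number of loci)
across all loci with at least one call; loci monomorphic within the breed
contribute zeros by default (genome-wide means are over all retained SNPs;
a flag excludes them).  The inbreeding coefficient is computed from the
unrounded means:

    FIS = 1 - mean(Ho) / mean(uHe)

undefined (NaN) when every locus is monomorphic.  The SD columns are
across-locus dispersions of the per-locus values — the only dispersion
available from a single genotyping pass.

## Runs of homozygosity

The detector reproduces the scanning-window procedure of PLINK
`--homozyg`, with seven criteria (defaults in parentheses): window size in
SNPs (20), heterozygous calls tolerated per window (0), missing calls
tolerated per window (2), the per-SNP window hit fraction (0.05), minimum
SNPs per run (20), minimum run length (2000 kb), minimum density (<= 100
kb/SNP) and maximum gap between consecutive SNPs (500 kb).  The hit
fraction is not part of the published criteria lists in most studies; 0.05
is the detection software's own default and it is exposed as a parameter.

Decisions that needed fixing where the convention is ambiguous:

- A SNP near a chromosome end is covered by fewer than 20 windows; its hit
  proportion uses the actual number of covering windows as denominator.
- A candidate SNP must itself be non-heterozygous; missing calls do not
  break a run (consistent with windows tolerating 2 of them).
- Segment length is `end_bp - start_bp` of the outermost SNPs; density is
  `length_kb / n_snps`; boundary comparisons are inclusive (a 2.000 Mb run
  passes).
- Chromosomes with fewer SNPs than one window yield no windows and no
  segments.

FROH is total ROH length over the autosomal genome length, 2522 Mb for the
goat autosome set (the constant is a parameter).  Breed FROH is the mean
over individuals, which — because every individual shares the same
denominator — is identical to the breed's total ROH length over its total
autosomal length, closing the question of which of the two the convention
intends.

## Selection scans

**ROH islands.**  Per breed, each SNP's occurrence is the fraction of that
breed's genotyped animals (all animals, not only those with at least one
ROH) whose ROH cover it, with inclusive segment bounds.  The threshold is
the 99.9th percentile (numpy's linear-interpolation definition) of the
breed's occurrence distribution; ties at the threshold are all retained.
Maximal runs of map-consecutive retained SNPs become islands — no gap
allowance, and chromosome boundaries always split.  A fully degenerate
distribution (all occurrences equal, e.g. a breed with no ROH at all)
would qualify the whole genome, so it warns and returns no islands.

**Windowed Weir-Cockerham FST.**  Per biallelic locus the Weir &
Cockerham (1984) variance components for r = 2 populations are computed
from the per-side called sample sizes, allele frequencies and observed
heterozygote frequencies: `a` (among populations), `b` (among individuals
within populations), `c` (within individuals), with the estimator
`theta = a/(a+b+c)` (negative estimates are legitimate and kept).  Loci
with fewer than two called individuals on either side are skipped; loci
monomorphic across both sides carry zero components and are excluded from
window sums.  The metapopulation contrast pools individuals of all breeds
of one environment into one population (r stays 2) rather than averaging
breed-level estimates.

Windows are 500 kb advancing in 250-kb steps, the grid anchored at bp 1 of
each chromosome (matching the quarter-megabase boundaries that window
tools emit), emitted while the window start does not exceed the last SNP
position; a SNP belongs to every window containing it.  The window score
is the ratio of sums `sum(a)/sum(a+b+c)` over defined loci — the "weighted"
FST — and windows with a zero denominator are dropped.  Significant
windows lie at or above the 99.95th percentile of window scores and
contain at least five SNPs; the percentile is computed over all defined
windows by default, with a `filter_first` flag restricting the pool to
>= 5-SNP windows first (the sentence defining the rule is ambiguous between
the two orders, so both exist; the default mirrors the reading "windows in
the top 0.05% that have five SNPs").

The contrast design is one pooled wet-vs-dry comparison plus every
wet-breed x dry-breed pair: five contrasts for the canonical four-breed
design.  Pairwise labels are emitted in wet_dry order.

## Distances and MDS

Reynolds' distance between populations uses the across-loci ratio form

    D = sqrt( sum_l sum_u (x1_lu - x2_lu)^2
              / (2 sum_l (1 - sum_u x1_lu x2_lu)) )

summing both alleles of each biallelic locus over loci with defined
frequencies in both populations (the `-ln(1-theta)` variant is out of
scope).  IBS distance between individuals is `mean(|g_i - g_j|)/2` over
jointly called loci.  Classical MDS is principal-coordinate analysis:
eigendecomposition of the double-centred `-D^2/2`, coordinates scaled by
square-rooted positive eigenvalues, variance explained as eigenvalue
shares; negative eigenvalues (non-Euclidean input) are dropped from the
denominator with a logged count.  Matrices export to PHYLIP square format
and a NEXUS DISTANCES block for external network/tree software; the
package does not build trees itself.

## Synthetic data

The generator emulates a 50K-class genotyping array on breeds that
diverged from a single ancestral gene pool by drift — the island-livestock
situation — using the Balding-Nichols model: ancestral frequencies
`p ~ U(0.05, 0.95)`, breed frequencies `Beta(p(1-F)/F, (1-p)(1-F)/F)` with
one drift coefficient F per breed, Hardy-Weinberg genotype draws, and
uniform missingness applied last.  Defaults: four breeds at realistic
survey sample sizes (61/64/60/39, two per environment), F = 0.05 with
0.10 for the most isolated breed, 30,000 SNPs over six autosomes totalling
~760 Mb (about 25 kb spacing — denser than a 50K chip on a full genome,
because compressing the genome rather than thinning the SNPs keeps
ROH/window arithmetic realistic), 1% missing calls, minimum SNP spacing
5 kb.

Planted signals give every scan a ground truth: *sweeps* shift the target
metapopulation's frequencies by `delta` toward the boundary farther from
the ancestral frequency (clipped to [0.01, 0.99]; the far boundary is
chosen so that clipping cannot erase the differential — shifting toward
the near boundary would cap the achievable differential at the distance to
that boundary, silently breaking the generator's contract for
`delta >= 0.5`); *tracts* overwrite a carrier subset of one breed with a
single shared homozygous haplotype drawn from the breed's frequencies,
forcing homozygosity while approximately preserving allele frequencies —
a detector test, not a pedigree-inbreeding model.  What the generator does
*not* emulate: linkage disequilibrium outside planted tracts, ascertainment
bias of array SNPs, genotyping-error structure, or admixture.  Passing
recovery tests therefore show that the detectors find what their models
define, not that real data are this clean.

## Benchmarks and their problem sizes

The standing benchmarks (`capripop.benchmarks`, run by both the test suite
and `scripts/acceptance.py`) use one replicate design: four breeds (two
wet, two dry), n = 40 each, 30,000 SNPs, one sweep of delta = 0.6 over a
400-kb interval and one 2.5-Mb tract with carrier fraction 0.8 — both at
the detection-threshold regime their recovery criteria name.  Recovery is
scored over 100 independent replicates: a sweep counts when a significant
window of the metapopulation contrast overlaps it, a tract when a called
island of the carrier breed overlaps it.  The null calibration repeats the
design with nothing planted and checks that every breed's FIS vanishes
within delta-method Monte-Carlo error and that the significant-window
count equals the count implied by the percentile rule alone.

## Known limitations

- The ROH detector is the scanning-window heuristic, not an HMM; very
  sparse or very dense maps interact with the density and gap rules.
- Weir-Cockerham components are implemented for two (meta)populations,
  which is all the contrast design needs; the r > 2 generalisation is not
  exposed.
- Text-dialect PLINK round trips are exact only up to allele orientation
  (the format does not record it); binary round trips are bit-exact.
- The merge operation intersects on SNP identifiers and harmonises
  A1/A2 swaps; it does not attempt strand flips (A/T, C/G ambiguity).
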