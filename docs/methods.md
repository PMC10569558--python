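# Methods

## Scope and data model

`methylhet` analyses per-read methylation calls in the TSV dialect written
by `nanopolish call-methylation`. A row reports one *motif group* — one or
more CpGs (or GpCs) within 10 bp that share a single log-likelihood ratio
(LLR) of methylated vs unmethylated. Rows are expanded to per-site calls by
locating motif occurrences in the reference context string; every site in a
group inherits the group's state. States are ternary: methylated
(LLR ≥ t), unmethylated (LLR ≤ −t), unassigned otherwise, with t = 2 by
default (configurable). Unassigned sites are dropped before any statistic
is computed; no LLR value escapes the input module. Coordinates are 0-based
half-open; a site is identified by the forward-strand position of its C.
Duplicate calls for one (read, site) keep the call with the larger |LLR|;
malformed rows are skipped and counted, never fatal.

## Per-read statistics

A read's assigned sites form an ordered binary vector. We compute the mean
methylation, the coefficient of variation (sample s.d. over mean; undefined
at mean 0), the nearest-neighbour correlation ρ (Pearson coefficient of the
two lag-1 subvectors, using each subvector's own mean; undefined when
either subvector is constant), and the read transition score (fraction of
adjacent site pairs with differing states). Undefined values propagate as
missing and are excluded from any mean; they are never imputed as 0. Reads
need ≥ 100 assigned sites (after unassigned-site removal) to be retained —
the same floor as the study design this package operationalises — so that
sample estimates of ρ are stable.

## Windows, bulk statistics and nulls

Chromosomes are tiled with non-overlapping fixed-width windows (50/100/200
kb supported; terminal windows truncated). A read contributes to a window
only if its span is fully contained (half-open containment); boundary-
spanning reads are unassigned. Window-level single-read statistics are
unweighted means over contributing reads.

Bulk statistics per window apply the *same* statistics kernel to the
ordered series of per-site methylation levels m_i (methylated calls over
assigned calls; sites need ≥ 10 assigned calls, CpGs whose C and G fall in
different windows are removed, windows need ≥ 100 retained sites). Sharing
the kernel guarantees that a bulk series equal to a binary read vector
yields identical numbers, which the tests assert exactly.

The shuffled null re-draws each window's N_w reads without replacement from
the global retained pool (pool restored between windows, windows processed
in ascending order under one seeded generator), preserving the multiset of
per-window read counts. Real and shuffled distributions of window means are
compared with a two-sided two-sample KS test. Inter-molecular heterogeneity
uses d_i = |m_i − 0.5|; extreme-window d_i distributions are compared
against the rest of the genome by two-sided KS tests, and per-window mean
d_i is correlated (Spearman) with the window's mean read correlation. All
statistical tests in the package are two-sided.

Single-vs-bulk comparisons report, per statistic: Spearman correlation,
paired t-test, an OLS fit of bulk on single-read values, and the mean
absolute relative difference mean(|bulk − single| / single).

## Read classification and enrichment

The read-level ρ distribution over a mammalian genome is bimodal. A
two-component Gaussian mixture is fitted by EM with k-means initialisation
(scikit-learn backend, fixed seed, retried with a fresh initialisation on
degenerate fits). Components are ordered μ₁ < μ₂. Reads within one s.d. of
μ₁ form the high-heterogeneity (low-correlation) group, within one s.d. of
μ₂ the low-heterogeneity group; reads satisfying neither are discarded, and
reads satisfying both (possible when the bands overlap) go to the component
with the smaller standardised distance — the count of such ambiguous reads
is logged. A small standardised separation |μ₂ − μ₁| between components
flags the grouping as unreliable (effectively unimodal input).

Enrichment of a window subset in an annotation is the ratio of base-overlap
proportions P_sub/P_all, with significance from a two-sided Wilcoxon
rank-sum test of per-window overlap fractions, subset vs the full window
set — the subset deliberately remains part of the background, mirroring the
analysis this package reproduces. Quintile analyses split ranked windows
into five equal groups (rank-ceiling boundaries for non-divisible counts).
Interval arithmetic (merge, intersect, subtract, Jaccard, per-window
overlap) is implemented directly on integer arrays and is cross-checked in
the tests against per-base set arithmetic.

## Distance-dependent correlation and spectra

For each read, all within-read site pairs exactly d bp apart (d from 2 up
to 500 or 2000 bp) are gathered by sorted-position range search; for each d
with ≥ 2 pairs the Pearson correlation between first- and second-member
states gives ρ_{r,d}, and profiles average ρ_{r,d} over reads where
defined. Cross-motif (CpG–GpC) profiles pool both orientations at absolute
distance d, with the CpG state always the first pair member. An exhaustive
O(N²) pair enumeration serves as the test oracle (agreement to 1e−12).

The dominant wavelength comes from the power spectrum of the mean-removed
profile: a periodogram zero-padded 32× for a dense frequency grid, with
quadratic interpolation around the peak and linearly interpolated
half-maximum band edges, reported as λ = 2π/ω to 0.1 bp. Frequencies
implying wavelengths beyond 3000 bp — longer than the profile itself — are
non-physical and excluded, and the retained peak must be a local maximum
inside the band (a monotone leakage shoulder from the excluded region does
not qualify). Peak significance against a white-noise null uses Fisher's
g-test on the unpadded periodogram restricted to the band (α = 0.01): a
profile of pure noise yields "no retained peak" rather than an arbitrary
argmax. Missing profile values are linearly interpolated before the FFT
and counted.

Bulk-derived synthetic reads redraw every site of every read independently
from that site's trinomial (unmethylated/methylated/unassigned) call
proportions, preserving positions and marginals while severing within-read
correlation. Recurrence plots binarise a profile's similarity structure
(|ρ_x − ρ_y| ≤ ε; ε = 0.06 by default, selectable from a grid of
0.005–0.20 in 0.005 steps by maximising the real-vs-synthetic recurrence
distance, ties to the smallest ε); distance between plots is
√(#disagreements). Oscillation-magnitude comparisons pair per-cycle
peak-to-trough amplitudes (cycles delimited by successive local maxima of
the real profile, at least 100 bp apart) and apply a two-sided Wilcoxon
signed-rank test; fewer than three cycles flags the report as underpowered.
The cycle-amplitude pairing is this package's operationalisation of
"oscillation magnitude" — the underlying study does not pin down the paired
quantity.

## Nucleosome occupancy models

Two generative models link methylation periodicity to nucleosome
organisation. Molecules of n = 2000 bp carry nucleosomes of 147 bp
separated by linkers uniform on {10..90} bp; the first nucleosome starts
uniformly within the first 90 bp (0-based {0..89}). Every base is treated
as methylatable: occupied bases are unmethylated with probability p = 0.8,
linker bases methylated with probability p = 0.8. m = 200 molecules are
simulated; PHASED shares one occupancy track across molecules, UNPHASED
draws an independent track per molecule. Terminal truncated
nucleosomes/linkers are retained. Per-molecule lagged correlations
(d = 1..500) are averaged into profiles; bulk per-base methylation
probabilities generate synthetic molecules by independent Bernoulli draws.

The models' assertable content: single-molecule profiles oscillate at the
repeat length (≈ 197 bp) under *both* phasings — the per-molecule process
is identical — while only the phased model's bulk-synthetic profile keeps
the oscillation; the recurrence distance between single-molecule and
bulk-synthetic profiles is therefore systematically larger for the
unphased model. Two numerical caveats, both asserted in tests: the phased
model's wavelength estimate inherits the single shared track's realised
mean repeat (s.d. ≈ 4%), and because every molecule anchors its first
nucleosome within the first 90 bp, the unphased bulk retains a decaying
phase-locked oscillation near the molecule start.

## Synthetic data generator

The generator emulates the features of real nanopore methylation data that
the analysis relies on, at desk scale. Defaults (chosen once, as the
package's study conditions):

- **Genome**: two chromosomes of 5 Mb; CpG positions with geometric spacing
  of mean 100 bp (minimum gap 2 bp); regions alternate between ORDERED and
  HETEROGENEOUS with lengths uniform on [200, 500] kb, so region boundaries
  are unaligned with window boundaries and per-window annotation overlaps
  take non-degenerate values. Two 2 Mb chromosomes were considered but give
  only ~80 windows at 50 kb, too few for stable rank-based window tests;
  5 Mb keeps the full pipeline run in the low minutes.
- **Reads**: lognormal lengths (median 25 kb, σ = 0.25, floor 2 kb), 30×
  depth, uniform placement.
- **ORDERED regime** (euchromatin-like): a copy-or-redraw chain —
  each site copies the previous state with probability 0.9, else redraws
  Bernoulli(0.9) — giving stationary methylation 0.9 and population lag-1
  correlation 0.9. The copy probability is deliberately not higher: beyond
  ~0.95 a large fraction of reads degenerates to constant vectors whose
  sample correlation is undefined or ≈ 0, which would blur the designed
  ordered/disordered contrast.
- **HETEROGENEOUS regime** (PMD-like): methylation driven by the nucleosome
  occupancy process (147 bp / 10–90 bp linkers), linker bases methylated
  with probability 0.95, occupied bases with probability 0.5 — landing mean
  methylation near 0.6 (intermediate, PMD-like) while keeping a linker/
  nucleosome contrast that produces the ~197 bp periodicity at CpG
  resolution. A phasing probability φ = 0.5 shares the region's reference
  occupancy track across that fraction of molecules.
- **LLR emission**: a mixture of confident calls at N(±4, 1.5²), signed by
  the true state, and ambiguous calls at N(0, 1²); the ambiguous weight is
  solved in closed form so the overall unassigned fraction (|LLR| < 2) hits
  the 24% target while the sign-flip (miscall) rate stays below ~0.5%.
  A single symmetric-Gaussian emission cannot reach 24% unassigned at
  |mean| = 4 without a miscall rate that destroys the ordered regime's
  correlation structure, which is why the two-component emission is used.
  Sites within 10 bp are grouped into one call row sharing one LLR,
  reproducing the caller's motif-group artifact.
- **NOMe mode**: GpC sites (geometric spacing, default mean 40 bp) driven by
  the same occupancy tracks — linker GpCs methylated with probability 0.9,
  occupied with 0.1. GpC positions colliding with CpG positions (GCG
  contexts, where native and exogenous methylation are indistinguishable)
  are excluded from the ground truth.

Ground truth comprises per-read regime labels (regime at the read
midpoint), a PMD-like BED of heterogeneous regions, an ordered-state BED,
and chromosome sizes.

What the generator does **not** emulate: sequence-dependent nucleosome
positioning, CpG islands and promoter hypomethylation, haplotype effects,
mapping errors, and coverage biases. Tests passing on this data show the
pipeline recovers structure it is designed to detect under its own
assumptions; they do not certify performance on real tissue data.

## Problem sizes and numerical choices

The default synthetic dataset (2 × 5 Mb, 30×) yields ≈ 12,000 reads and
≈ 3 M site calls and runs through the full pipeline in ~2–3 minutes; unit
tests use a 2 × 400 kb variant. End-to-end analyses use 50 kb windows (200
windows) so rank-based window tests have adequate group sizes; the window
width remains a parameter. Mixture fits use `reg_covar = 1e−8` and up to 5
re-initialisations. Periodogram padding is 32×; the wavelength grid
resolution at λ ≈ 197 bp is well below 1 bp. Ties in window rankings break
by genomic coordinate so all subset selections are deterministic. Every
stochastic step takes an explicit seed or `numpy.random.Generator`;
repeated runs with one seed are byte-identical.

## Known limitations

- Enrichment significance uses the subset-vs-all rank-sum comparison
  (subset included in background), which is conservative relative to a
  subset-vs-complement design.
- ρ_{r,d} profiles treat each read as one observation regardless of its
  pair count at distance d; no weighting is applied.
- The spectral half-maximum band assumes a single dominant peak; multimodal
  spectra report only the tallest retained peak.
- Strand handling assumes the caller reports forward-strand C positions for
  the palindromic CpG; strand-ambiguous callers would need pre-processing.
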