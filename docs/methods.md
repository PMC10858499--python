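# Methods

## The simulator

The generative model is a population of `n_cells` diploid cells with
nucleosomes on a fixed grid (`nucleosome_spacing`, default 200 bp; no
positional jitter, so truth intervals are exact). Non-overlapping regions
are placed uniformly at random with at least two fragment lengths of
clearance and carry one of five states; every other base is background.

Per (cell, allele, nucleosome) the two marks are drawn independently:

| state          | H3K4me3            | H3K27me3           |
|----------------|--------------------|--------------------|
| `K4_ONLY`      | prob *m*           | —                  |
| `K27_ONLY`     | —                  | prob *m*           |
| `BIVALENT`     | prob *m*           | prob *m*           |
| `ALLELIC_HET`  | allele 0: prob *m* | allele 1: prob *m* |
| `CELLULAR_HET` | *f*·n cells: *m*   | rest: prob *m*     |
| background     | prob *ε*           | prob *ε*           |

Both histone tails travel with the fragment through capture, which is the
mechanism that makes two rounds specific for true bivalency. Round 1
captures a fragment with probability *e* (`capture_specific`) when it
carries the antibody's target mark, otherwise *b*
(`capture_nonspecific`); an IgG round always captures at *b*. A captured
fragment survives elution into round 2 with probability *η*; round 2
applies the same capture rule, OR retains the fragment with the
mark-independent carry-over probability *c*. The output is a seeded
subsample of survivors of size `min(depth, survivors)` (without
replacement; when fewer survive than `depth`, all survivors are emitted
with a logged warning rather than resampled).

Defaults — *m* = 0.8, *ε* = 10⁻³, *e* = 0.3, *b* = 3·10⁻³, *η* = 0.8,
*c* = 2·10⁻³, 2 chromosomes × 5 Mb, 2,000 cells, 280 regions, depth
500,000 — are the package's study conditions. No quantitative estimates
of antibody efficiency or carry-over exist for the experiment being
emulated; these values were chosen once so the qualitative control
behaviour holds (IgG–IgG FRiP well below 0.1, strong reciprocal reChIP
signal only at bivalent regions, visible carry-over peaks in single
orientations) and are all config-exposed, not claims about any real
antibody.

Two perturbation modes: `TAZ` erases all H3K27me3 after assignment
(emulating Ezh2 inhibition), and `DKO` treats a seeded
`dko_dependent_fraction` (default 10%) of bivalent regions as background
(emulating loss of the priming factors that maintain bivalency there).
The dependent subset is drawn from the config seed in every mode so a WT
and a DKO study generated from the same seed share one truth map.

What the simulator does *not* model: PCR duplicates, sequencing error,
mappability, fragment-length variation, antibody cross-reactivity with
H3K4me2, and elution-chemistry differences (collapsed into the single
*η*). Passing tests on simulated data therefore demonstrate the logic and
statistics of the pipeline, not robustness to those real-data artefacts.

## Peak calling

A Poisson island caller structured like the classic broad-mark island
strategy: fragments are midpoint-assigned to `bin_size` (100 bp) bins
(midpoint assignment keeps count conservation exact for the Poisson
model; reads may first be 5′-extended to `fragment_size`). The per-bin
expectation is the control count rescaled by the library-size ratio,
floored at the uniform background rate λ_floor = T·bin/genome so
zero-count control bins cannot generate infinite enrichment; with an
empty control the caller falls back to the uniform floor with a warning.
Bins with Poisson upper tail < `window_p0` (0.2, the classical eligibility
threshold) are stitched into islands bridging at most `gaps_allowed`
consecutive ineligible bins; the island p-value is the Poisson upper tail
of the summed treatment count against the summed expectation over the
island's span; BH correction is applied across islands and islands with
FDR < 0.05 are kept. Fold change uses a symmetric pseudocount of 0.5.
Post-filters: log2FC strictly greater than 2, FDR < 0.05, no blacklist
overlap. This is an equivalent-in-structure reimplementation validated by
null simulations and analytic fixtures, not a bit-compatible clone of any
named tool; an effective-genome-fraction correction is deliberately
omitted because simulated genomes are fully mappable.

## Interval conventions

All coordinates are 0-based half-open (BED); touching intervals do not
overlap; every classification step uses "any ≥ 1 bp" overlap semantics.
The representative interval for a reciprocally supported bivalent region
is the K4→K27 peak (one anchor side must be chosen; the choice is
recorded so counts are auditable), and a K4→K27 peak overlapping several
K27→K4 peaks counts once. Genes with multiple TSS records keep the first.
Fragment files are not deduplicated.

## Quantification

CPM/bp = (fragments overlapping the region / library size × 10⁶) / region
width; log₂ values are floored at 2⁻¹⁰ so empty regions score exactly
−10 (a min-value clamp; config-exposed). FRiP counts each fragment at
most once however many peaks it touches, which forces the score into
[0, 1]. Profile matrices re-center regions to ±5 kb, use 100 equal bins,
cap at the 99th percentile and scale to [0, 1]; each region weighs
equally in the average profile.

## Differential bivalency

TMM factors are computed on 10 kb genome bins (all-zero rows dropped and
reported): reference = sample whose upper-quartile count proportion is
closest to the mean; M- and A-values over bins positive in both sample
and reference; 30% of M and 5% of A trimmed per tail (the method's
classical defaults); factor = 2^(precision-weighted mean M), rescaled to
geometric mean 1. The implementation agrees with the Bioconductor
reference implementation to a fraction of a percent on shared fixtures
(asserted in the test suite).

The per-region test is a negative-binomial likelihood-ratio test:
effective library sizes (library × TMM factor) enter as offsets; each
region's method-of-moments dispersion is shrunk toward the count-weighted
common dispersion with 20 pseudo-observations; group means are fitted by
damped Newton on the monotone score equation and H₀ (equal means) is
tested by 1-df chi-square. Empirical type-I error at nominal 0.05 is
≈ 0.06 on null simulations (2 vs 2, dispersion 0.1) — the mild liberality
expected of an LRT at this sample size — and is asserted to stay within
[0.03, 0.07]. This is deliberately an equivalent-in-spirit test rather
than a quasi-likelihood clone: the scientific content is the
two-orientation rule — a region is differentially bivalent only when
significant (|log2FC| > 1, FDR < 0.05) with *concordant sign* in both
reChIP orientations — plus the thresholds, not any package's internals.
Concordant sign is enforced explicitly because joint significance alone
would admit contradictory calls.

## Sequence features

GC fraction = (#C + #G)/(length − #N); N bases are excluded from both
numerator and denominator. CpG frequency = #CG dinucleotides /
(length − 1) — the number of dinucleotide positions, the natural
denominator when the count is of dinucleotides. Matched controls
preserve the query's width multiset exactly and match GC by seeded
nearest-neighbour selection without replacement from same-width
candidates drawn uniformly outside the query (and optional blacklist);
nearest-neighbour on a single covariate is the concrete algorithm chosen
for the matching step. Class comparisons use Welch t-tests with BH
correction. A synthetic genome generator (labelled synthetic; i.i.d.
bases with optional GC/CpG-enriched regions) supports end-to-end testing
of these metrics.

## Problem sizes and determinism

The default simulated study (10 Mb genome, 2,000 cells, depth 5·10⁵) was
chosen so a full analysis — including the matched knockout condition and
differential testing — completes in seconds on a single CPU while
keeping per-region counts in the regime where the Poisson and NB
approximations are comfortable. Unit tests use a 1 Mb single-chromosome
version with the same probability parameters. Every stochastic step takes
an explicit seed; per-sample seeds derive from the study seed plus a
CRC32 of the sample id, and all outputs are byte-reproducible from
(config, seed).

## Known limitations

- The IgG–IgG control is shared across replicates (as in the emulated
  design), so replicate peak calls are not fully independent.
- The caller's island significance is computed against control-derived
  expectations; with a very shallow control the floor dominates and
  sensitivity at ultra-low depth is optimistic (visible as island
  fragmentation in downsampling curves).
- Carry-over is a single mark-independent pass-through probability; real
  carry-over may be chromatin-state dependent.
- `CELLULAR_HET` splits cells deterministically by index, which is
  equivalent to a random split for all read-level statistics but means
  the same cells are in the K4 subpopulation across samples.
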