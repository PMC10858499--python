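# rebivalent

Analysis toolkit for **sequential ChIP (reChIP) mapping of bivalent
chromatin** — promoters that carry both the active mark H3K4me3 and the
repressive mark H3K27me3 on the same nucleosome — together with a
generative simulator of the sequential immunoprecipitation experiment.

## The problem

Overlapping independently generated H3K4me3 and H3K27me3 peak sets *in
silico* cannot distinguish true bivalency (both marks on one nucleosome)
from **allelic heterogeneity** (marks on different alleles of one cell) or
**cellular heterogeneity** (marks in different cells of a mixed
population). A sequential ChIP — immunoprecipitating first with one
antibody, then re-precipitating the eluate with the other — retains only
fragments carrying both marks, so reciprocal reChIP in both orientations
(K4→K27 and K27→K4) is the discriminating experiment. This package
implements the complete downstream analysis:

- **Island peak calling**: fragments are binned (100 bp), bins enriched
  over a control-derived Poisson expectation are stitched into islands
  (allowing one internal gap), islands are scored by the Poisson upper
  tail of their summed counts, Benjamini–Hochberg corrected, and
  post-filtered at log2FC > 2 and FDR < 0.05.
- **Reciprocal bivalency**: regions with ≥ 1 bp peak support in *both*
  reChIP orientations.
- **Confidence classes**: each bivalent region is stratified by overlap
  with total single-ChIP peak sets into HC (both), K4-biased, K27-biased
  or LC (neither); promoters (TSS ± 1.5 kb) inherit the highest-priority
  class (HC > K4b > K27b > LC).
- **QC**: FRiP, log2 CPM/bp enrichment matrices, relative-distribution
  profiles, downsampling curves, and the in-silico-vs-reChIP comparison
  with its false-positive accounting.
- **Differential bivalency**: 10 kb-bin TMM normalization, per-region
  negative-binomial likelihood-ratio test (|log2FC| > 1, FDR < 0.05),
  with a region called differential only when significant with concordant
  sign in both orientations.
- **Simulator**: a population of diploid cells whose nucleosomes carry
  marks by region state (K4-only, K27-only, bivalent, allelically or
  cellularly split), passed through one or two antibody-capture rounds
  with nonspecific background `b`, specific capture `e`, elution loss `η`
  and mark-independent carry-over `c` — with the ground truth written
  alongside, so every pipeline stage is testable without sequencing data.

## Worked example

```bash
rebivalent simulate --out study --seed 7 --replicates 2
rebivalent run-all --sample-sheet study/samples.tsv \
    --chrom-sizes study/chrom.sizes --out study/summary.json --seed 7
```

or, in Python, a single-replicate sketch:

```python
from rebivalent import SimulatorConfig, build_truth, simulate_sample
from rebivalent.peaks import PeakCallConfig, call_islands, filter_peaks
from rebivalent import bivalency

cfg = SimulatorConfig(seed=1)
truth = build_truth(cfg)
igg = simulate_sample(truth, cfg, ("IGG", "IGG"), seed=2)
k4k27 = simulate_sample(truth, cfg, ("K4", "K27"), seed=3)
k27k4 = simulate_sample(truth, cfg, ("K27", "K4"), seed=4)
pc = PeakCallConfig()
p1 = filter_peaks(call_islands(k4k27, igg, pc, cfg.chrom_sizes), pc)
p2 = filter_peaks(call_islands(k27k4, igg, pc, cfg.chrom_sizes), pc)
rec = bivalency.reciprocal_bivalent(p1.intervals(), p2.intervals())
print(rec.n_k4k27, rec.n_k27k4, rec.n_shared)
```

prints `110 107 81`: 110 K4→K27 peaks and 107 K27→K4 peaks, of which 81
are reciprocally supported, and those cover all 80 truly bivalent regions
of the simulated genome while touching none of the 80
allelic/cellular-heterogeneity regions (the extra single-orientation
peaks are carry-over from the first immunoprecipitation, which the
reciprocal intersection removes). On the same run the IgG–IgG control
has FRiP 0.011 over the bivalent regions versus 0.94 for the reChIP
libraries.

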