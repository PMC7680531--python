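# Methods

This note documents the models behind `bsaqtl`: what the simulator
emulates, how the scan statistics are defined, the numerical conventions
at boundaries, and what the package's tests do and do not demonstrate
about real sequencing data.

## The experiment being modelled

A biparental cross between an early-flowering (Cabriolet) and a
late-flowering (Darmor) winter oilseed-rape variety is selfed to a large
F2 population (720 lines by default) segregating at tens of thousands of
parent-distinguishing variants across the 19 *B. napus* chromosomes.
Flowering time is scored under two treatments — six weeks of
vernalization (VERN) or none (NVERN) — for up to 170 days; plants that
never flower receive the censor value as a "did not flower" (DNF) score.
DNA from the ~5% earliest- and ~5% latest-flowering lines is pooled into
an early and a late bulk, and both bulks plus the parents are sequenced
at ~30× mean depth. Allele-frequency differences between the bulks then
localise flowering-time loci.

## Simulator

**Variant map.** Physical positions are uniform per chromosome (30 Mbp
default length) and the genetic map is linear at `map_length_cM`/
`chromosome_length_bp` (100 cM per chromosome by default, the order of
magnitude of *B. napus* linkage-group lengths). A supplied map table can
replace the linear relation simply by constructing the DataFrame
directly; all downstream code reads only the `position_cM` column.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the variant span in Morgans, positions uniform on the cM scale, starting
phase Bernoulli(1/2) — the Haldane no-interference model, chosen because
it is the analytic standard: the recombination fraction between loci
d Morgans apart is r = (1 − e^(−2d))/2, which the tests verify at 1, 10
and 50 cM. Crossovers outside the variant span are unobservable, so
simulating the Poisson process on the span only is exact (thinning). An
F2 line is the sum of two independent gametes, giving 1:2:1 segregation.
Real recombination shows positive interference and pericentromeric
suppression; neither affects the scan statistics tested here beyond the
effective number of independent linkage blocks.

**Phenotype model.** Flowering time is

    days = baseline(treatment) + Σ_loci [ a·(1 − dosage) + d·1{het} ] + ε,

with dosage the Cabriolet-allele count, ε ~ N(0, noise_sd²) and
right-censoring at `censor_days` (170). Units are days; `noise_sd`
defaults to 8 d. The default model has two loci on A02 at the positions
of the study's validation markers (136,553 and 6,375,504 bp), with
effects solved exactly from the four parental means:

| parameter | VERN | NVERN |
|---|---|---|
| baseline (het-free midpoint) | 57.085 | 128 |
| additive, major (FLC-like) locus | 11.165 | 28 |
| additive, minor (FT-like) locus | 3.0 | 22 |
| dominance, major locus | 0 | +15 |

so that an all-Cabriolet genotype averages 42.92 d (VERN) / 78 d (NVERN)
and an all-Darmor genotype 71.25 d (VERN) / 178 d (NVERN, i.e. censored
DNF). The +15 d dominance at the major locus under NVERN makes lateness
partially dominant without vernalization, which yields a bimodal NVERN
distribution with roughly a tenth of lines censored — the qualitative
structure of the real population (86 of 708 lines DNF). Gaussian noise
does not reproduce the right skew of the real VERN distribution; the
skew is irrelevant to rank-based bulk selection, which is all the
pipeline consumes.

**Bulk selection.** Bulk size is round(fraction·n) with fraction 0.05.
Censored lines are eligible only for the late bulk (a DNF plant cannot
be called early). When lines tied at a bulk boundary exceed the
remaining capacity — typically the censored lines competing for late
slots — members are drawn among the tied lines by seeded uniform
sampling; the real study does not state how its 86 DNF lines were
reduced to a 36-line bulk, so this rule is this package's documented
choice. Bulks are always disjoint.

**Read model.** Per variant, depth ~ Poisson(mean_depth = 30×,
independent across variants) and the Cabriolet read count is
Binomial(depth, f(1−e) + (1−f)e), where f is the pool's Cabriolet allele
frequency and e (default 0.001) a symmetric per-read allele-flip error.
This ignores GC-dependent coverage, mapping bias and base-quality
structure; it reproduces exactly the two noise sources the scan
statistics integrate over (depth variation and binomial allele
sampling), which is what passing tests certify. Results on real data
additionally depend on alignment artefacts the simulator does not model.

## Variant calling

A position is a high-confidence variant when depth ≥ 20, the alternative
allele carries ≥ 95% of reads, the alternative differs from the
reference, and any indel is at most 8 bp (i.e. < 9 bp). Both boundary
comparisons are inclusive. Multi-allelic positions keep the single
most-supported alternative. Counts are treated as already
quality-filtered. Background subtraction takes each parent's allele as
its called alternative where it varies from the reference and the
reference allele otherwise, and keeps positions where the two inferred
parental alleles differ — removing shared (reference-vs-Darmor
background) variation. At a 1% error rate a false call at a monomorphic
position requires ≥ 95% of ≥ 20 reads flipped (probability < 10⁻³⁰),
so the caller is effectively error-free at these settings.

## Scan statistics and numerical conventions

- SNP indices exist only where depth ≥ `min_depth` (20) in **both**
  bulks; Δ = index_late − index_early throughout, so Δ → −1 when the
  early bulk fixes Cabriolet alleles.
- The low-index exclusion drops a variant only when **both** indices are
  strictly below 0.3; (0.30, 0.30) is retained.
- The top-1% threshold is the nearest-rank (1 − f) empirical quantile of
  |Δ| (ascending rank ⌈(1−f)·n⌉), computed genome-wide per treatment
  **after** the low-index exclusion. Flagging is inclusive (|Δ| ≥
  threshold), so the degenerate all-equal case flags everything instead
  of nothing; with distinct values this flags the ⌈f·n⌉ largest plus any
  values equal to the quantile itself.
- Windows are runs of exactly `window_size` (100) consecutive retained
  variants of one chromosome, advancing by `window_step` (default 1,
  i.e. sliding; 100 gives tumbling windows). The original analysis does
  not state its step; interval widths depend on this choice, which is
  why it is configurable.
- QTL intervals merge maximal runs of **consecutive** above-threshold
  windows in window order. Merging by bp overlap would fuse runs
  separated by a single below-threshold window (adjacent sliding windows
  share 99 variants), so window-order adjacency is the semantics that
  lets the scan statistic itself delimit intervals. Interval coordinates
  are 1-based inclusive first/last-variant positions; the peak is the
  window with the largest |mean Δ| (leftmost on ties), reported at its
  bp midpoint. BED export converts to 0-based half-open at the boundary
  only.

## Validation statistics

On paired binary homozygosity indicators the Wilcoxon matched-pairs
procedure degenerates (all nonzero differences have magnitude 1), so the
test is implemented as what it reduces to: an exact two-sided binomial
sign test on the discordant pairs, ties dropped, p = 1 with no
discordant pairs. Rank-sum comparisons use full enumeration (midrank U
over all C(m+n, m) assignments, tie-safe) when both groups have ≤ 8
observations and the tie-corrected normal approximation otherwise; no
multiple-testing correction is applied across pairs, matching the
per-comparison α = 0.05 convention of the validation analyses this
mirrors. The compact letter display assigns one letter to each maximal
run of mutually non-significant groups in median order — adequate for
the near-monotone significance patterns arising here, not a general
graph-colouring CLD.

## Homeologous-exchange screen

Per-gene coverage is normalised by its subgenome median (so calls are
invariant to sequencing effort); a homeolog pair is exchange-like when
one copy's normalised coverage is below 0.25 while the other's exceeds
1.5, and runs of ≥ 3 consecutive same-direction pairs become segments.
These thresholds are screen defaults chosen for a clear 2×/0× reciprocal
signature against σ ≈ 0.1 background noise; they are not literature
values, and the screen is a simplified stand-in for full published HE
methodology.

## Seeds and reproducibility

Every operation takes an integer seed and uses `numpy`'s PCG64
generator. A pipeline run expands its global seed via
`stage_seed(seed, name) = (seed·0x9E3779B1 + crc32(name)) mod 2³¹`, so
each stage is independently reproducible and the manifest records all
derived seeds. Identical configuration and seed give byte-identical
output files.

## Problem sizes and calibration of the null check

The test suite runs at desk scale: study-scale maps (19 × 2000 variants)
for end-to-end checks, 10⁴–10⁵ positions for law-of-large-numbers
checks, and 10 seeded replicates for recovery experiments. Under the
null (random, unselected 36-line bulks from 720 lines), the genome-wide
mean Δ is unbiased but its sampling sd is ≈ 0.015: it is dominated not
by read noise but by bulk-composition noise integrated over ~19
chromosome-scale linkage blocks — analytically
√(2 · 1/(8·36) · 0.568 / 19) ≈ 0.0144, where 0.568 is the mean pairwise
dosage correlation over a 1-Morgan chromosome. A ±0.02 band on a single
replicate is therefore a ~1.4 σ statement that individual seeds can
miss; the property test accordingly asserts |mean| < 0.045 (3 σ) per
replicate and ±0.02 on the ensemble mean of ten replicates, alongside
the absence of any ≥ 10-window run beyond the fixed 0.686 reference
threshold (no such run is observed in any replicate).

## Known limitations

- No crossover interference; no segregation distortion.
- Phenotype noise is Gaussian and homoscedastic; no
  genotype-by-environment structure beyond treatment-specific effects.
- Read depth is independent across positions; no mapping bias, GC bias
  or base-quality model, and no FASTQ/alignment layer.
- The reciprocal-cross structure of the real population (10 F1 parents)
  is not modelled; the real study found no maternal effect.
- The HE screen detects only clean reciprocal coverage signatures and is
  not a substitute for dedicated HE callers.
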