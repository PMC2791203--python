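# Methods

## Model and assumptions

The input is a panel of T samples with probe-level relative copy-number
measurements (log2 ratios of tumor vs. normal signal).  The method assumes
that (i) the log2 ratio is a graded measure of aberration intensity worth
preserving — no discretization into gain/loss calls is performed; (ii) true
co-occurrence is a *smooth* function of genomic position, so neighboring
locus pairs carry shared signal that local averaging can exploit; and
(iii) chromosome arms are the natural unit of analysis: no aberration signal
is propagated across a centromere or a chromosome boundary, which makes the
genome-wide problem decompose exactly into independent arm-pair tasks.

The co-occurrence score for two grid loci with channel columns u, v across
samples is `S = M · C` with `M = Σ_t min(u_t, v_t)` and `C = cov(u, v)`.
M is the continuous analogue of Boolean AND — large only when both loci are
aberrated in the same samples with high amplitude.  M alone is maximized by
loci aberrated in *every* sample regardless of their partner; the covariance
weight C is near zero for such constitutive signals and negative for
mutually exclusive ones, so the product isolates concerted, recurrently
co-varying aberration.  Scores scale as amplitude cubed (M ∝ c, C ∝ c²),
which is intentional: ranking, not absolute magnitude, is the output.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid spacing Δg | 20 kb | resolution of the genomic grid; also the triangular kernel's half-width and the dominant memory lever (an arm-pair matrix is P_a × P_b doubles) |
| scales | 2, 10, 20 Mb | Gaussian kernel width 6σ; the expected aberration size. Multiple scales maximize the chance of catching aberrations of any size |
| kernel truncation | 3σ | the sampled Gaussian has decayed to ~1% of its peak; half-width in grid points is ceil(3σ/Δg) |
| top N | 50 | primary ranked list length per comparison and scale; a conservative extreme-tail cut in lieu of a significance threshold |
| network top N | 500 | co-occurrences fed into network clustering (smallest scale) |
| gene window | ±σ | genes assigned to a peak locus by midposition, boundary inclusive |
| interaction threshold | 0.9 (strict >) | minimum confidence for a functional interaction to count |
| cluster cutoff | 10 Mb | single-linkage cut (5 kernel widths at scale 2 Mb); merging is strict (< cutoff) |
| off-arm distance | 10⁸ bp | placeholder distance between loci on different arms; always above the cutoff, so arms never merge |
| core fraction | 5 % | edges supported by fewer than this fraction of the co-occurrence list are pruned ("less than": support exactly at the threshold survives) |
| covariance denominator | 1/T | population convention; `ddof=1` available. Ranking is invariant to the choice |

## Numerical choices

* **Grid anchoring.** Each arm's grid starts at the arm's start coordinate;
  coordinates are 0-based, intervals half-open.  Grid points with no probe
  strictly within Δg are masked and set to 0 rather than NaN, so downstream
  minima and covariances stay finite; the mask is carried along.  A probe at
  exactly Δg from a grid point gets weight 0 (open kernel support).
* **Kernel normalization.** The sampled Gaussian is normalized to sum 1.
  This does not change rank order and makes a flat score field an exact
  fixed point of the convolution.
* **Mirror padding.** Reflection about the boundary without repeating the
  edge sample.  When the kernel half-width exceeds an arm's grid extent the
  reflection depth is clamped to the available data (tiled), with a warning.
* **Convolution** is FFT-based; the kernel is symmetric, so convolution and
  correlation coincide.  Agreement with direct double summation is ~1e-15.
* **Peak extraction** is greedy: take the CCM maximum, zero a square
  neighborhood of half-width 2σ, repeat until the requested count or no
  positive value remains.  This guarantees distinct loci without a local-
  maxima heuristic.  Ties break by (row, column) ascending; global ranking
  ties break by genomic coordinates, then arm labels — all deterministic.
* **Negative scores** (anti-covarying pairs) are retained in S for
  diagnostics but can never rank, since extraction stops at ≤ 0.
* **Mode merge.** Four mode matrices are computed, three comparisons are
  reported: gain–loss and loss–gain peaks are pooled into one ranked
  "gain-loss" list, each peak keeping its direction in the mode field.
* **Single-linkage clustering** is computed as connected components of the
  graph with edges where distance < cutoff — mathematically identical to
  cutting a single-linkage dendrogram strictly below the cutoff, and
  cross-checked against a hierarchical-clustering implementation in the
  test suite.  Cluster labels are ordered by each cluster's leftmost locus.
* **Fisher tests** are two-sided throughout (category enrichment and the
  interaction-ratio control), computed exactly via the hypergeometric
  distribution.

## Synthetic data: what it emulates and what it does not

The generator emulates probe-level log2-ratio data from clonal samples:
baseline 0, planted lesions adding ±amplitude over an interval for a carrier
subset, i.i.d. Gaussian noise, and probes jittered off the grid by less than
half the probe spacing so the triangular-kernel regression is exercised
nontrivially.  Lesions sharing a `group_id` are planted in identical carrier
sets, which expresses lineage structure: the bundled two-lineage scenario
gives half the samples co-deletions at two loci on chromosomes 1–2 and the
other half at three loci on chromosomes 3–5, a stand-in for the
lineage-specific V(D)J co-deletions at T-cell receptor and immunoglobulin
loci used as a positive control.  Its defaults — 60 samples, amplitude 1.0,
noise sd 0.2 (amplitude-to-noise 5), 2 Mb lesions on 20 Mb arms — are the
study conditions used by the test suite and the acceptance script.

Not modeled: allele-specific SNP-array signals, GC waves, segmentation
artifacts, tumor-cell-fraction dilution (a purity factor exists but defaults
to 1), correlated noise, and whole-arm or whole-genome events.  Passing
tests therefore demonstrate that the pipeline recovers planted concerted
aberrations over independent Gaussian noise at realistic amplitude ratios —
not that it is robust to the structured artifacts of real array data.

## Problem sizes

The test suite and acceptance script run the full pipeline on toy genomes of
two to five 8–20 Mb arms at 20 kb spacing (up to ~1000 grid points per arm,
60 samples) and verify the arm-pair task decomposition (8892 tasks for 39
arms × 3 scales × 4 modes) combinatorially; oracle comparisons use 10×10 to
30×30 matrices where brute-force summation is exact and fast.  These sizes
were chosen so every check recomputes from scratch in seconds while still
exercising the same code paths a genome-scale run uses; a real 39-arm,
20 kb-grid analysis is embarrassingly parallel over its tasks, with at most
one arm-pair score matrix resident per task.

## Known limitations

* No significance estimate per peak: a permutation null would require
  re-running the full analysis thousands of times, and the min-plus-
  smoothing pipeline has no tractable analytical null; top-N lists are the
  intended output.
* The isotropic kernel assumes both co-occurring regions have similar size;
  asymmetric region pairs are handled indirectly by clustering small-scale
  results, not by an ellipsoidal kernel.
* Same-chromosome co-occurrences are computed but excluded from ranked
  lists; intra-chromosomal structure is out of scope.
* The interaction ratio depends on the supplied interaction table's coverage
  and confidence calibration; the random-loci control shares the table, so
  coverage bias affects both arms of the comparison but enrichment p-values
  remain conditional on that table.
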