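# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Erosion-shell radial positioning

**Model.** A nucleus mask is partitioned into *N* concentric shells of equal
pixel area; the radial position of a painted chromosome territory is
summarized by the per-shell ratio of probe-signal percentage to DNA-signal
percentage. Dividing by the DNA percentage normalizes for chromatin content
per shell, so 1.0 in every shell is the "distributed like bulk chromatin"
null.

**Shell construction.** Shells are distance-transform quantiles, not
iterative morphological erosion: every mask pixel is ranked by ascending
Euclidean distance to the background, ties broken deterministically by
row-major pixel order, and the ranking is cut into *N* contiguous groups of
size ⌊A/N⌋ or ⌈A/N⌉ with remainder pixels assigned to the outermost shells.
This guarantees max−min shell area ≤ 1 pixel on any mask (iterative erosion
overshoots the 20% boundaries on small nuclei) while preserving erosion
semantics — shell index is monotone in depth from the edge. An independent
sort-free implementation (per-pixel pairwise rank + cumulative-size lookup)
is kept in the test suite as an oracle.

**Quantification.** Raw intensities are summed per shell — no thresholding —
because intensity summation degrades gracefully for diffuse paint probes; a
binarized mode is deliberately out of scope for the default path. Pixels
outside the mask never contribute. Degenerate conventions: ratio = 0 when a
shell has neither probe nor DNA percentage; NaN (undefined) if DNA
percentage alone is 0; a nucleus with zero total DNA signal is an error.

**Segmentation** is the minimal standard chain — global Otsu on the DNA
channel, hole filling, 4-connected labelling, border/area filtering — with
every piece configurable. A constant image yields an empty result with a
warning rather than an error.

**Statistics.** Per-shell means and SEM (sample SD/√n, n−1 denominator) per
condition, with a warning below the recommended 50 nuclei per condition.
Between-condition comparison is a two-sided Welch *t*-test per shell at
α = 0.05 with no multiple-testing correction across shells, matching the
field's reporting convention for these bar-graph profiles. Zero-variance
degeneracies use p = 1 (equal means) / p = 0 (unequal means) conventions.

## Synthetic FISH fields

Nuclei are ellipses (semi-major axis 12–18 px, axis ratio 0.7–1.0, random
orientation) placed without overlap and away from the field border; DNA is a
uniform 16-bit-range level (20 000) plus Gaussian texture noise (σ = 300)
over a low background, matching CCD capture. Probe signal is placed as
`n_probe_spots` (default 150) Gaussian point-spread blobs (σ = 2 px) whose
centres are sampled with probability ∝ `((d_max−d)/d_max)^β` for peripheral
bias β > 0 or `(d/d_max)^|β|` for interior bias β < 0, where d is the
distance from the nucleus boundary. The fraction of centres per equal-area
shell is recorded as ground truth, so truth rows sum to 1 exactly for
probe-bearing nuclei. Generators are pure functions of (spec, seed).

**Known systematic.** With σ = 2 blobs on default-size nuclei the outermost
shell is only ≈1.6 px wide, so a substantial part of a peripheral blob's
mass leaves the mask and is lost; under uniform placement the measured mean
ratio vector is ≈(0.69, 0.95, 1.10, 1.13, 1.12) rather than all-ones. This
is a property of the image model (diffuse paint at a sharp mask edge), not
of the quantifier — in the point-probe limit (σ → 0) uniform ratios are 1
within sampling error, which the tests verify, and the β = 0 truth fractions
are exactly uniform by construction. Because both compared conditions share
the attenuation, the Welch comparison remains correctly calibrated under the
null (flag rate ≈ 5%) and highly powered for radial shifts. Not emulated:
optical aberrations, 3-D z-stacks, chromatic shift, nucleoli, or touching
nuclei — so passing tests demonstrate correctness of the quantification, not
robustness to segmentation pathologies of real imagery.

## Transcriptome comparison

The quantification order is fixed and enforced by one-way state flags:
raw counts → RPM (scale 10⁶/raw column total) → pseudocount (default 0.05)
→ log/fold-change. The pseudocount is applied after RPM so the floor is
comparable across libraries; the constant is configurable. Per-condition
gene values are arithmetic means over replicates (the underlying studies
report a single fold change per gene from two biological replicates without
naming a combination rule). Direction thresholds are inclusive:
up ⇔ treated/baseline ≥ k, down ⇔ baseline/treated ≥ k; the default k = 2
mirrors the usual ≥2-fold reporting cut-off, with ≥5-fold as the stringent
variant. There is deliberately no distributional differential-expression
test — the pipeline reproduces threshold-based calling, not DESeq-style
inference.

**Overlaps.** `overlap_sets` reports every exclusive Venn segment, the union
and `shared_percent = 100·|∩|/|∪|`. With two sets of sizes 379 and 438
sharing 200, the union is 617 and the shared percentage 32.4 (printed as
32%). Note one published up-regulated worked example prints "125/552" while
its own set sizes give 361 + 318 − 125 = 554 by inclusion–exclusion; the
package uses the set-arithmetic union (554, 22.6%). Printed-percentage
rounding in the literature is inconsistent (4/14 → "28%", 4/15 → "27%"), so
percentages are reported unrounded to one decimal and any integer rounding
is presentation-layer only.

**PCA** treats samples as observations on gene-wise centred (not scaled)
log2 values, via SVD, with a deterministic sign convention (the
largest-magnitude gene loading of each component is positive). Correlations
are Pearson on log2 values after pseudocounting.

**Synthetic counts.** Negative-binomial with mean library 10⁶, dispersion
0.05, two replicates per condition, lognormal(σ = 0.15) library-size
factors. Relative abundances are a mixture: a silent fraction (default 35%)
with abundance exactly 0 — the unexpressed portion of an annotated
transcriptome, which produces the dense pseudocount corner of real
log-log replicate scatters and their ≈0.996 correlations — and expressed
genes with Gamma(shape 2) abundances, which keeps per-gene counts high
enough that the ≥2-fold cut-off yields sub-percent false-positive rates at
this dispersion. Planted fold changes are always assigned to expressed
genes. A single-component abundance model cannot reproduce both properties
at once. Not emulated: GC/length bias, batch effects, or count correlation
structure between genes.

## Promoter motif analysis

Matrices are parsed from JASPAR count format (a small reader so that parse
errors carry line numbers; round-trips are cross-checked against Bio.motifs
in the tests). Probabilities use a pseudocount expressed as a fraction α
(default 0.01) of each column total, spread by the background frequencies:
`p = (c + α·N·bg) / (N·(1+α))`; weights are `log2(p/bg)` against a uniform
background by default (overridable, e.g. from observed promoter
composition). A window hits when its min–max normalized score
`(s − s_min)/(s_max − s_min)` reaches the relative threshold (default 0.8);
both strands are scanned and windows containing N are excluded. Relative
thresholding makes the headline readout — the fraction of genes whose
1050-bp upstream region contains the motif — transparent and monotone in
the threshold; no claim is made to reproduce likelihood-averaging,
threshold-free enrichment statistics of dedicated motif tools.

Over-representation is a one-sided hypergeometric test on hit-containing
gene counts, supporting both a superset background (target drawn from it)
and a disjoint background (population = union). Because exact-test p-values
are discrete and conservative by construction, they cannot be uniform under
the null; the result therefore also carries the mid-p variant
(p − pmf(k)/2). The null-uniformity (KS) validation uses the randomized
p-value `P(X > k) + U·P(X = k)` — exactly Uniform(0,1) precisely when the
hypergeometric null law of the hit count is correct, so the KS check
validates the test's sampling model rather than the discretization
artefact. An optional label-permutation
p-value provides a model-free cross-check and agrees with the hypergeometric
value to <0.01 in the tests.

The built-in `forkhead_like_pwm()` is a synthetic, low-entropy
forkhead-family-style matrix (14 bp, GTAAACAA core with extended flank) used
for planted-recovery studies; it is not a database matrix. Its width keeps
the chance per-promoter hit rate at the percent level in 1050 bp of
background at threshold 0.8 (the relative threshold admits ⌊0.2·width⌋
mismatches, so very short matrices are unavoidably promiscuous).

## qPCR statistics

**ΔΔCt.** The reference Ct per condition is the arithmetic mean of the
reference genes' replicate-mean Cts — equivalent to geometric-mean
normalization of their linear abundances, the defensible default when a
multi-reference panel (here five normalizers) is named without an
aggregation rule. ΔCt = Ct_target − Ct_ref per condition, ΔΔCt is the
treated−baseline difference, fold = 2^(−ΔΔCt). The SEM is first-order
(delta-method): replicate-mean variances combine through the linear form of
ΔΔCt, and the Ct-scale SD maps to the linear scale as ln2·fold·sd. Swapping
conditions inverts the fold change exactly. No amplification-efficiency
correction is applied (plain ΔΔCt).

With per-replicate Ct noise σ, n replicates and k references, the estimator
error is Gaussian with `sd(ΔΔCt) = σ·sqrt((2/n)(1 + 1/k))`; at σ = 0.1,
n = 3, k = 5 this is 0.0894 cycles, so the probability that the estimate
falls within ±5% of a true fold change of 2 is 2Φ(log2(1.05)/0.0894)−1 ≈
0.57 for *any* unbiased estimator — the Monte-Carlo validation checks the
simulated rate against this closed form rather than against an unreachable
bound.

**Percent input.** `100·2^((Ct_input − log2(1/f)) − Ct_IP)` where f is the
fraction of chromatin used as input relative to the IP. f is a required
parameter with no default: the dilution factor is experiment-specific and
not recoverable from typical protocol volume descriptions.

**Doubling time** is `t·ln2/ln(N_t/N_0)`, defined only for growth.

## Degenerate inputs and tie-breaking (summary)

- Equal-distance shell pixels: deterministic row-major order.
- Welch with two zero-variance samples: p = 1 if means equal, else p = 0.
- Correlation of a zero-variance sample: NaN with a warning.
- Pseudocount and RPM guards reject out-of-order application.
- Placement failure (field too small for the requested nuclei) raises an
  error naming the constraint rather than returning a partial field.

## Problem sizes used in validation

The validation studies use 50 nuclei/condition × 200 repetitions for
radial-shift recovery and null calibration, 2000-gene tables with 50 planted
genes for fold-change recovery, 200 promoters (plus 1000–2000 background)
for motif recovery and null calibration, and 500 Monte-Carlo repetitions for
ΔΔCt — the smallest sizes at which the binomial/KS acceptance intervals are
meaningfully tight for the planted effect sizes.
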