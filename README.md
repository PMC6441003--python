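# fibroquant

Quantitative analyses of genome organization and function in cultured
fibroblasts, built as a tested, reusable pipeline with matched synthetic-data
generators. The package covers four experiment classes that commonly appear
together in studies of growth-modulating treatments (caloric-restriction
mimetics, nutrient deprivation and the like):

1. **Erosion-shell radial positioning of chromosome territories** from
   two-channel 2D-FISH images (DNA counterstain + whole-chromosome paint).
   Each segmented nucleus is divided into *N* = 5 concentric shells of equal
   pixel area (shell 1 = periphery, shell 5 = interior) and the normalized
   signal ratio is computed per shell:

   `ratio_k = (% probe intensity in shell k) / (% DNA intensity in shell k)`

   A ratio of 1 everywhere means the territory is distributed like bulk
   chromatin. Per-shell condition differences are tested with Welch's
   unequal-variance *t*-test. Threshold-based percent-positive scoring
   (Ki67/EdU-style immunolabelling counts) is included.
2. **Fold-change/overlap transcriptome comparison** on gene-level count
   tables: RPM normalization (10⁶/library total), a 0.05 pseudocount floor,
   inclusive ≥*k*-fold up/down calls against a baseline condition, Venn
   overlaps of gene sets with union-based shared percentages, log-scale
   replicate correlation, and sample-level PCA.
3. **Promoter motif enrichment**: JASPAR count matrices → log-odds PWMs,
   both-strand scanning of fixed-length upstream regions (default 1050 bp)
   at a min–max relative score threshold, the fraction of genes containing a
   motif, and one-sided hypergeometric over-representation of a target gene
   set versus background (with mid-p and permutation cross-checks).
4. **qPCR quantification**: multi-reference ΔΔCt fold changes
   (`fold = 2^(−ΔΔCt)`, references aggregated as the mean of their Cts ≡
   geometric mean of abundances, delta-method SEM), ChIP-qPCR percent-input
   normalization, and population doubling times
   (`PDT = t·ln2 / ln(N_t/N_0)`).

Every input class has a synthetic generator with recorded ground truth
(radially biased probe placement in elliptical nuclei, negative-binomial
counts with planted log2 fold changes, promoters with a planted motif
fraction, Ct tables with known true changes), so each stage is validated
end-to-end without any external data.

## Worked example

```python
import numpy as np
from fibroquant import fish
from fibroquant.synthetic import FieldSpec, generate_nucleus_field

field = generate_nucleus_field(FieldSpec(n_nuclei=50, radial_bias=3.0, seed=1))
ratios = []
for nucleus in fish.segment_nuclei(field.dna_channel, min_area=100):
    shells = fish.erode_equal_area_shells(nucleus, n_shells=5)
    ratios.append(fish.quantify_shells(shells, field.dna_channel,
                                       field.probe_channel).ratio)
print(np.round(np.mean(ratios, axis=0), 2))
```

prints `[1.36 1.54 1.24 0.66 0.2 ]` — the peripherally biased probe (β = +3)
concentrates in shells 1–2 and is depleted from the interior. Against a
uniform (β = 0) control of the same size, `fish.compare_conditions` flags
every shell at p ≤ 0.05 (shell 1 and 5 at p < 1e-100 for 100 nuclei per
condition).

The numbered scripts under `analysis/` run the full story: `01` simulates
one demonstration set of every input class, `02`–`05` run the four analysis
stages and print what they find, writing tables under `results/`. For
example `analysis/05_qpcr_quantification.py` reports a ΔΔCt estimate of
1.920 ± 0.094 for a target with true fold change 2.0, and Monte-Carlo
estimator spread matching the closed-form prediction.

A console script exposes the same stages on files:
`fibroquant simulate fish|counts|promoters|ct`, `fibroquant analyze-fish`,
`foldchange`, `overlap`, `pca`, `scan-motifs`, `ddct`, `percent-input`.

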