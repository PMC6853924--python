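# clonesweep

Quantitative inference of clonal architecture and selective-sweep dynamics
of driver-mutation-bearing subclones from bulk tumor sequencing summaries.

Bulk sequencing of a tumor yields, per mutation, a variant-allele fraction
(VAF): the fraction of reads supporting the variant. `clonesweep` turns these
allele fractions — together with copy-number segments and sample purity —
into population-genetic quantities: the cancer cell fraction of each
mutation, the number of variant copies per cancer cell, the phylogenetic
order of point mutation versus copy gain, the entropy of the tumor's clonal
frequency distribution, and, by fitting an analytic hitch-hiker model, the
strength of selection acting on the driver subclone in an *individual*
tumor. A synthetic tumor generator with planted ground truth makes every
stage testable with no external data.

It is written for cancer genomicists working with MAF-style mutation tables,
SEG copy-number files and purity estimates (the standard outputs of somatic
pipelines), and for method developers who want a tested reference
implementation of these estimators.

## Models

**Cancer cell fraction.** For an SNV in a region of total copy number
`ploidy_CNV` carried by a fraction `CCF_CNV` of cancer cells, in a sample of
purity `p`,

    CCF = VAF · (2 + (ploidy_CNV − 2) · CCF_CNV) / p

Copy number comes from log2 segment means (`CN = 2 · 2^seg_mean`). The
allele fraction also implies a continuous multiplicity
`m = VAF · (p·CN + 2(1−p)) / p` (variant copies per cancer cell); the CCF is
corrected by the nearest integer multiplicity and clipped to [0, 1]. A
mutation is *clonal* when its CCF strictly exceeds 0.95. The purity-only
corrected fraction `cVAF = min(VAF/p, 1)` exceeds 0.5 at a gained locus only
when the mutation preceded a gain of the variant allele, giving a
phylogenetic ordering call.

**Sweep dynamics.** A subclone with relative growth rate `s` follows
`x(t) = e^{st} / (e^t + e^{st})`; an established driver in a population of
`N` cells follows `n(t) = e^{st} / (e^{st} + 2Ns)` starting from the
establishment frequency `≈ 1/(2Ns)`; the `i`-th neutral hitch-hiker arising
on the sweeping clone at rate `μ` per generation reaches
`n_i(t) = e^{−μt} (μ/(is))^{1−μ/s}`. Fast ("hard", e.g. `s = 2.0`) sweeps
leave fewer and rarer hitch-hikers than slow ("soft", `s = 1.1`) sweeps
stopped at the same driver CCF; `estimate_selection` inverts this spectrum
by grid search to estimate `s` per tumor and label its regime.

**Architecture.** Genetic diversity is the Shannon entropy
`H = −Σ p_i ln p_i` of the 10-bin CCF histogram; clone trees carry linearity
and branching indices — the proportions of cross-clone mutation pairs in
ancestor–descendant versus incomparable branches.

**Expression signatures.** Up/down gene signatures are built by
median/SD normalization, MAD-based variable-gene selection, and
compactness pruning with a PC1-sign up/down split; a sample's score is
`(mean(up) − mean(down)) / SD(signature genes)` within the sample. The
information coefficient `IC = sqrt(1 − e^{−2I})` rescales the divergence `I`
between class-conditional profile densities to [0, 1), with significance
from a label-permutation test.

## Worked example

```python
import numpy as np
from clonesweep import (SimTumorConfig, simulate_cohort, assemble_tumor_sample,
                        annotate_sample, diversity_index, estimate_selection,
                        SelectionFitConfig)

cohort = simulate_cohort(
    {"HARD": 1},
    SimTumorConfig(mu=0.05, N=1000, mean_depth=10_000.0,
                   n_background_mutations=20, purity=1.0, driver_ccf=0.9),
    seed=202,
)
sample, truth = cohort[0]
joined = assemble_tumor_sample(sample.mutations, sample.segments,
                               sample.purity, sample.sample_id)
records = annotate_sample(joined)

ccfs = [r.ccf for r in records if r.ccf is not None]
h, _ = diversity_index(ccfs)
passengers = [r for r in records if r.mutation.gene is None]
driver = max(r.ccf for r in records if r.mutation.gene)
est = estimate_selection(passengers, driver,
                         SelectionFitConfig(mu=0.05, N=1000))
print(f"true s = {truth.s}, fitted s = {est.s_hat:.2f}, regime = {est.regime.value}")
print(f"diversity H = {h:.3f} nats over {len(ccfs)} mutations")
```

prints

```
true s = 2.0, fitted s = 2.23, regime = HARD
diversity H = 0.670 nats over 51 mutations
```

The fitted fitness 2.23 recovers the planted hard-sweep value 2.0 from read
counts alone, and the low entropy reflects the collapse of subclonal
diversity around the swept driver.

The same stages are available from the shell via the `clonesweep` CLI
(`simulate`, `ccf`, `sweep-sim`, `sweep-fit`, `tree-metrics`, `signature`,
`assoc`); every run writes a JSON manifest with the resolved parameters and
seed.

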