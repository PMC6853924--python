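# Methods

This note records the models implemented by `clonesweep`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions made where the design was open.

## Cancer cell fraction and multiplicity

The CCF rescaling `CCF = VAF·(2 + (ploidy−2)·CCF_CNV)/purity` assumes the
variant sits on one copy per cancer cell and that normal cells contribute
two reference copies. `CCF_CNV` defaults to 1 (clonal copy-number events);
segments with subclonal CNVs can set it lower. Local copy number is
`2·2^seg_mean`, rounded to the nearest integer by default so that
multiplicity has an integer ceiling; a flag preserves fractional values.

When the variant occupies several copies (amplification of the mutant
allele) the one-copy formula overshoots 1. The correction first computes the
continuous multiplicity `m_cont = VAF·(purity·CN + 2(1−purity))/purity`,
takes `m = clamp(round(m_cont), 1, round(CN))`, and reports
`CCF = clip(m_cont/m, 0, 1)`. Rounding the continuous multiplicity — rather
than choosing the smallest integer whose implied CCF is feasible — matters
under read noise: at a clonal heterozygous locus a VAF a hair above 0.5
implies `m_cont ≈ 1.02`, and the nearest-integer rule keeps `m = 1`
(CCF clipped to 1) where a feasibility rule would flip to `m = 2` and halve
the CCF. Loci with `CN = 0` but positive VAF are flagged inconsistent and
given no CCF.

Clonality is strict: `CCF > 0.95`. The boundary value 0.95 itself is
subclonal. `cVAF = min(VAF/purity, 1)` corrects for purity only; at a gained
locus (`CN > 2`), `cVAF > 0.5` is attainable only if the point mutation
preceded a gain that amplified the variant allele, which is the basis of the
ordering call. Both cutoffs (0.95, 0.5) are parameters of their functions.

Mutations falling outside every copy-number segment are flagged and
defaulted to diploid (`CN = 2`), under which the rescaling reduces to
`2·VAF/purity`; how such mutations should be treated is genuinely
underdetermined by the inputs, and the flag lets callers drop them instead.
When several segments overlap a position the smallest is used (it carries
the most local estimate) and the tie is logged.

## Sweep dynamics

Three deterministic trajectories, all evaluated in logit/log space so large
`s·t` cannot overflow (`x(t) = expit((s−1)t)` and analogues; log-space and
naive evaluation agree to 1e−10 wherever the naive form is finite):

* subclone fraction `x(t) = e^{st}/(e^t + e^{st})`, equal clone sizes at
  `t = 0`; a generalized form with origin time `t_sc` and initial fraction
  `f0` reduces to it at `f0 = 0.5, t_sc = 0`;
* adaptive driver frequency `n(t) = e^{st}/(e^{st} + 2Ns)`, the logistic
  path of a variant that has escaped stochastic loss; its `t = 0` value is
  within a factor of the establishment frequency `1/(2Ns)`;
* hitch-hiker spectrum `n_i(t) = e^{−μt}(μ/(is))^{1−μ/s}`, restricted to
  `0 < μ ≤ s` (beyond `μ = s` the exponent changes sign and the expression
  leaves its derivation regime; such calls raise).

Fixation is operationalized as subclone fraction above 0.95 — the same
cutoff as clonality — because "present in all tumor cells" has no exact
finite-precision meaning. Defaults: `N = 10⁶` cells (never measurable from
a single bulk sample; configurable), `μ = 0.001` per generation on the
sweeping clone, `s = 2.0` for hard and `1.1` for soft sweeps. Inverting the
driver trajectory for the observation time uses Brent root-finding
bracketed from zero with tolerance 1e−10; a requested driver frequency of
1 (the asymptote) is replaced by `1 − 1e−9` with a warning, and frequencies
at or below establishment raise.

### Selection-strength estimation

`estimate_selection` grid-searches `s ∈ [1, 5]` in steps of 0.01 (`μ` fixed,
optionally profiled over a grid). For each candidate `s` the driver CCF
fixes the observation time; the model's hitch-hiker frequencies for ranks
`1..K` are compared against the `K` observed subclonal CCFs sorted in
decreasing order, and the default objective is the mean squared difference
of log frequencies by rank. This rank-spectrum objective inverts noise-free
spectra exactly. A binned alternative (multinomial likelihood of the 10-bin
CCF histogram against binned model mass) is provided, but at small `μ` every
model frequency falls into the lowest bin for every `s`, leaving that
objective flat — hence the rank objective as default. An observed driver CCF
above the clonality threshold is capped at the threshold before inversion:
a clonal driver says only that the sweep has completed, and the spectrum
model describes variation generated during the sweep.

Regime labels: NEUTRAL when `ŝ − 1 < 0.05`, HARD when `ŝ ≥ 1.5`, SOFT in
between. Tumors with fewer than 5 subclonal passengers return a flagged
estimate with no regime.

**What recovery can and cannot show.** At `μ = 0.001` the hitch-hiker
frequencies are `~μ/(is)` ≈ 5×10⁻⁴–10⁻³. Read sampling at depths of a few
hundred cannot resolve frequencies this small: across 100 such loci a tumor
yields a fraction of one expected supporting read, and the distance between
the hard- and soft-sweep read-level models is a few hundredths of a nat —
no estimator can classify such tumors reliably, and the pipeline honestly
returns NEUTRAL/flagged fits there. Parameter recovery is therefore
demonstrated in two regimes: exactly, on noise-free spectra; and from
read counts, at settings where the spectrum is resolvable (e.g. `μ = 0.05`,
`N = 10³`, depth 10⁴, driver observed mid-sweep at CCF 0.9), where regime
accuracy exceeds 90% and median fitted `s` lands within a few percent of
truth. Real tumors occupy the resolvable regime in practice because the
effective `μ` aggregates neutral mutations genome-wide rather than at a
single locus.

## Architecture metrics

Diversity is Shannon entropy (nats) over ten equal CCF bins, half-open with
the last bin closed (`[0.9, 1.0]`) so clonal mutations occupy the top bin;
`0·ln 0 = 0`; the driver's own CCF is included (a flag excludes it). The
index depends only on bin proportions, so it is invariant to sample size
and permutation.

Tree linearity/branching count unordered pairs of mutations in *distinct*
nodes: a pair is linear when one node is an ancestor of the other, branched
when the nodes are incomparable. Same-node pairs are excluded — the indices
measure relations between lineage positions, not within a clone — so the
two indices sum to 1 over cross-node pairs. Trees with fewer than two
mutation-bearing nodes report (0, 0) with a degenerate flag. Among sampled
trees, the "best" tree takes the lowest normalized log-likelihood value by
default — ranking sampled reconstructions by a normalized likelihood admits
either sign convention, so `best="highest"` is available — with ties broken
toward fewer nodes, then input order. Averaged indices are unweighted means
over the top-k trees by the same ranking.

Associations between per-tumor summaries (e.g. entropy on driver
multiplicity) use ordinary least squares with the standard t-test on the
slope; a zero-variance predictor returns a degenerate flag rather than a
fit.

## Expression signatures and the information coefficient

Genes are normalized to standard deviations from their median across
samples (sample SD, ddof 1; zero-variance genes are flagged and zeroed).
Variable genes rank by median absolute deviation with lexicographic
tie-breaks. Pruning is greedy backward elimination: the gene whose removal
most increases mean absolute inter-gene correlation is dropped (equivalently
the gene with the smallest summed absolute correlation, maintained
incrementally) until the first principal component's variance share stops
improving or a target size is reached; the up/down split follows the sign
of the PC1 loading. Note that after per-gene standardization every gene has
unit variance, so MAD ranking discriminates only distribution shape; on
planted block structure the correlation-based pruning, not the MAD filter,
is what isolates the signature.

The score is `(mean(up) − mean(down)) / SD(signature genes)` within each
sample — the minimal reading of a difference "relative to the variation in
each sample"; the SD is taken over the signature genes (a flag switches to
all genes) in a fixed gene order, making the score exactly antisymmetric
under swapping the up and down sets and invariant to adding a constant to a
sample. Within-sample SD of zero yields an undefined (NaN) score with a
warning.

The information coefficient compares the two class-conditional profile
densities (Gaussian KDE, Scott bandwidth; a degenerate single-point class
falls back to a Gaussian bump with a pooled-spread bandwidth) with the
symmetrized Kullback–Leibler divergence `I`, integrated by the trapezoid
rule on a 2048-point grid padded by three pooled SDs, and reports
`IC = sqrt(1 − e^{−2I})`. The divergence form is used deliberately: the
mutual information between a *binary* label and a profile is bounded by
ln 2, which would cap the rescaled coefficient at √0.75 ≈ 0.87 and could
never reach 1 for perfectly separated classes; the class-conditional
divergence is unbounded, vanishes when the classes share a distribution,
and is invariant under affine transforms of the profile. Permutation
p-values permute the labels with a seeded generator and use the add-one
estimator `p = (1 + hits)/(1 + n_perm)`, comparing permutations on the
divergence scale, which does not saturate in floating point the way the
coefficient does near 1.

## Synthetic data generator

The generator plants truth and observes it through the read model the
analysis assumes: `E[VAF] = purity·ccf·m/(purity·cn + 2(1−purity))`, depth
Poisson with configurable mean, alt counts binomial (beta-binomial
overdispersion behind a flag). Regimes: HARD/SOFT place the driver at a
clonal CCF (default 0.98) with hitch-hiker CCFs from the analytic sweep
spectrum at the configured `(s, μ)`; NEUTRAL draws subclonal CCFs from a
1/f-shaped (log-uniform) spectrum truncated at a detection floor of 0.05,
giving the low-frequency tail swept tumors lack; SUBCLONAL_DRIVER draws the
driver CCF uniformly in (0.1, 0.6). Every tumor also carries clonal truncal
mutations (default 30) so regimes are compared at similar mutation counts.
Defaults mirror the study conditions elsewhere in the package: purity 0.8,
mean depth 200, 100 background mutations, diploid driver locus unless a
gain is configured.

Cohorts derive per-tumor seeds from a master seed via
`SeedSequence.spawn`, making them byte-reproducible and stable under
partial regeneration. Clone-tree fixtures (chain, star, random-parent) set
prevalences multiplicatively down the tree so parent ≥ child always holds.
Expression fixtures shift planted up/down genes by ±effect·SD in the "high"
class over standard-normal noise.

What the generator does not emulate: sequence-level errors and mapping
artifacts, subclonal copy-number segments, whole-genome doubling, clonal
interference between drivers, spatial sampling, and realistic chromosomal
CNV landscapes. Passing tests therefore certify the estimators under the
stated observation model, not robustness to these real-data complications.

## Problem sizes

Test and reproduction runs use cohorts of 20–100 tumors, 50–130 mutations
per tumor, depths of 200–10⁴, 100 random trees of ≤ 8 nodes, 200-replicate
permutation-null calibrations at 100 permutations each, and expression
matrices of 200 genes × 50 samples — sizes at which every stage's behavior
is measurable while the full suite runs in minutes on one core.
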