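# Methods and design notes

## Data model and filtering

The unit of observation is a sequencing library (species, treatment arm
∈ {control, cold, hot}, biome of origin ∈ {arid, alpine, temperate}).
Expression is TPM from per-species de novo gene sets; gene identifiers are
opaque strings and are never matched across species directly.

A gene is retained when its mean TPM across **all** of its species' libraries
(treatments pooled) is ≥ 10, boundary inclusive. One filter per species — not
per treatment — because the retained set must be common to all contrasts and
each species reports a single retained-gene count. Raising the threshold can
only shrink the retained set (tested as a property).

Treatment means are unweighted arithmetic means over the libraries of a
species × treatment cell; TPM is already depth-normalised, so no library
weighting is applied. Single-library arms (present in the real design) return
that library's value.

Fold change is log2((mean_treat + c) / (mean_control + c)) with pseudocount
c = 0.5 TPM added to both numerator and denominator. Retained genes can still
have a zero mean in one arm, and how such genes were originally handled is
not documented anywhere; the pseudocount keeps every retained gene's FC
finite while barely perturbing values at the ≥10 TPM scale (log2 bias
< 0.07 at the threshold). Setting c = 0 is allowed: ±inf is then propagated
as missing and excluded from downstream medians.

## Gene-set catalog

GO biological-process terms come from Trinotate-style reports, taking the
union over every GO-bearing column and over transcripts of a gene; only the
biological_process branch is kept. A term is retained when its member count
among **retained** genes is ≥ 10 in *every* species. This per-species reading
(rather than "≥ 10 summed over species") is deliberate: the subset-size rule
divides 75% of the *minimum* cross-species count, which is only meaningful
when that minimum is bounded below, and the point of the statistic is to
control for annotation-depth differences between species. The alternative
total-count reading is available via `go_mode: total`. Counts are taken after
the expression filter because the bootstrap samples expressed genes.

The bootstrap subset size is round(0.75 · min_s count_s), rounded half-up
(7.5 → 8, 10.5 → 11; the rounding direction is not prescribed anywhere, so
it is documented and configurable) and floored at 1.

Orthogroups pass a two-stage filter: present (≥ 1 gene, before the expression
filter) in ≥ 15 species, then expressed (≥ 1 retained gene) in ≥ 12 species.
Both quorums are parameters so reduced synthetic designs can scale them.

## The bootstrapped median

For each retained term × species, `n_resamples` (default 1,000) gene subsets
of the catalog's subset size are drawn **without replacement** — "resampling
subsets" strictly smaller than the member pool is subsampling, not the
classic with-replacement bootstrap; a with-replacement mode exists behind a
flag for sensitivity analysis. The estimate is the mean of the subset
medians (even-sized subsets use the midpoint of the two central order
statistics). Per-library estimates reuse the same subsets across the
libraries of a species, so between-library differences reflect expression
only.

Randomness: every (term, species[, contrast]) pair gets its own RNG
substream derived by hashing the keys into a `SeedSequence` with the master
seed. Results are therefore independent of term ordering and identical
across reruns — verified down to byte-identical output tables.

Correctness is anchored to an exhaustive enumeration oracle: for small pools
the mean over all C(n, k) subset medians is computed directly and the
Monte-Carlo estimate must agree within 3 Monte-Carlo standard errors
(the {1,2,3,4,5}-choose-3 instance has exact expectation 3.0).

z-scaling (for cross-term comparability in summaries) uses the sample SD
(n − 1); constant vectors are an error, flagged and excluded.

## Models

**Treatment LMM.** `estimate ~ treatment + (1|species)`, REML, control
reference, fit with statsmodels MixedLM. The optimizer is tried in the order
cg, bfgs, powell, nm and the first truly converged fit is used (validated
against lme4 on fixtures; bfgs sometimes stalls at a non-optimum while
flagging non-convergence). ICC = σ²_sp/(σ²_sp + σ²_res); a species variance
below 1e-8·σ²_res is reported as a singular fit with ICC 0, flagged rather
than dropped. Marginal R² is var(Xβ̂)/(var(Xβ̂) + σ²_sp + σ²_res) with
var(·) the sample variance of the fixed-effect fitted values.

Degrees of freedom: t statistics use the residual convention
df = n_obs − n_species − (levels − 1), which gives 166 for 188 libraries, 20
species and 3 levels, and correspondingly fewer for orthogroups spanning
fewer species. This is an assumption (the exact df machinery used with lme4
in the original analysis is unstated); `df_mode: normal` switches to the z
approximation. A Satterthwaite option is not provided because no installed
library computes it for this model class.

The response is the raw bootstrapped median TPM — not logged, not z-scaled;
t statistics are invariant to affine response rescaling (tested), so scaling
would change nothing inferential.

**Biome LM.** One-way OLS of species-level FC on biome; multiple R² and
overall F-test p. Degenerate cases are defined rather than left NaN: a
constant response gives R² = 0, p = 1; exact between-biome separation with
zero within-biome variance gives R² = 1, p → 0. Biomes with a single species
are included but flagged.

**Acclimation LM.** Simple regression of the per-species trait delta on the
species' gene-set FC, pairing heat traits with the hot-vs-control contrast
and cold traits with cold-vs-control. Reports slope t, p, adjusted R², the
minimum cross-species member count ("min n") and the FC median/min/max
across species. Ranking is by adjusted R² within trait, ties broken by set
id; a Benjamini–Hochberg column is available but off by default — with 20
species the emphasis is on effect sizes, not corrected p values.

## Thermal traits

Tcrit is the breakpoint between the slow- and fast-rise phases of basal
fluorescence F0: the continuous two-segment model
f0 = β0 + β1·T + β2·(T − ψ)₊ is fit by least squares at every ψ on a 0.1 °C
grid over the central 80% of the (peak-truncated) temperature range, and
Tcrit is the RSS-minimising ψ. Exhaustive grid search was chosen over
iterative segmented regression for determinism and freedom from
starting-value sensitivity; halving the grid step can never raise the
optimal RSS (tested). A boundary argmin or an RSS profile that a breakpoint
does not improve over a straight line raises "no breakpoint detected"; a
fast-phase slope not exceeding the slow phase is a warning flag. Traces are
truncated at the smoothed-F0 peak before fitting so post-peak decay cannot
distort the rise phase. Cooling ramps are analysed on the negated
temperature axis and the breakpoint negated back.

Tmax is the temperature at the global maximum of the rolling-median-smoothed
F0 (window 5 points); ties resolve to the earliest point in ramp order (the
Tcrit side), and a maximum at a ramp endpoint is flagged as possibly
truncated. This smoothed-argmax definition is an explicit stand-in for the
instrument-protocol extraction, isolated behind one function so it can be
swapped.

Acclimation deltas: Δ = treatment-arm mean − control mean per species and
trait, hot arm for heat traits and cold arm for cold traits. Positive
Δ(Tcrit_hot) is gained heat tolerance; positive Δ(Tcrit_cold) (critical
temperature moving toward 0 °C) is worsened cold performance.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: 20 species across three
biomes with the real unbalanced library design (188 libraries, including
single-library arms), per-species retained-gene counts of 10,177–13,293,
134 qualifying GO terms plus distractors engineered to fail retention, and
300 orthogroups of which 220 are present in ≥ 15 species and 78 expressed in
≥ 12 — all planted exactly.

Gene-level model (log2 scale, so a planted β is an expected log2 FC):
log2 TPM = μ_g + u_s + v_ℓ + β + ε. Defaults: baseline μ ~ N(6, 1.2²)
(lognormal TPM with heavy right tail), species intercept σ_sp = 0.5,
library effect σ_lib = 0.553, gene noise σ_gene = 0.6. The library effect is
what survives the median-over-genes summary, so the planted summary-level
ICC is σ²_sp/(σ²_sp + σ²_lib) = 0.45, the between-species differentiation
regime of the study system; gene-level noise averages out. On the raw TPM
scale the fitted ICC per realisation scatters around this value because the
planted effects are multiplicative.

Planted effects: strong and moderate heat upregulation (β_hot 1.0 / 0.6),
cold up- and downregulation (+0.5 / −0.7), biome-differential terms with
weaker heat responses in arid species and weaker cold responses in alpine
species, and two acclimation-linked terms whose effects carry per-species
jitter (SD 0.6). That jitter is deliberately wide: species-level FC
estimates carry arm-level library noise of roughly 0.5 log2 units (few
libraries per arm), and an association is only detectable when the planted
between-species spread clears that floor. Thermal acclimation deltas are
generated as linear functions of those per-species effects (slopes ±1.8/−2.0,
trait noise SD 0.8), giving moderate, realistic association strengths.

Filter-margin rescue: a gene whose realised mean TPM lands within 20% of the
threshold is rescaled (whole row × constant) away from the boundary, so the
planted retained counts are recovered *exactly* rather than almost surely.
Row scaling leaves fold changes, z-scores and t statistics untouched.

Traces: heating 20→65 °C at 30 °C/h and cooling 20→−25 °C at 15 °C/h,
logged every 5 s; two-segment rise with a peak and post-peak decay, plant
breakpoint jitter SD 0.3 °C, Gaussian F0 noise SD 0.01.

Not emulated: read-level artifacts (mapping error, assembly chimeras),
GO-term overlap structure from the real DAG, phylogenetic covariance among
species, count-based noise (TPM is modelled directly as lognormal), and
instrument-specific fluorescence baselines. Passing tests therefore
demonstrate correctness of the statistical machinery under the declared
generative model, not robustness to real-data pathologies upstream of TPM.

## Problem sizes and numerical choices

The default design-scale run (acceptance script, analysis drivers) uses the
full 20-species / 188-library / 134-term configuration with 1,000 resamples,
completing in about two minutes on one CPU. Replicate-based checks use 100
recovery replicates and 400–500 null replicates at the same 188-library
design, simulated at the response level (the level at which the mixed model
operates). The test suite uses a reduced 6-species bundle with orthogroup
quorums 5/4 and 100–200 resamples.

Tie-breaks and degenerate inputs are pinned throughout: half-up rounding for
subset sizes; medians of even subsets as midpoints; ranking ties by set id;
constant inputs are exact pass-throughs for the bootstrap and errors for
z-scaling; single-species mixed models are refused (ICC undefined) rather
than silently degrading to OLS.
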