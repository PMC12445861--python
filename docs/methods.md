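# Methods

This note documents the models, conventions and numerical choices behind
mycomix, and what the synthetic-data tests do and do not establish about
real field data.

## Isotope model and mixing analysis

A sample's isotope composition is expressed in per mil against an
international standard, δ = (R_sample/R_standard − 1) × 1000, with R the
¹³C/¹²C or ¹⁵N/¹⁴N ratio (VPDB and atmospheric N₂ standards respectively).
All downstream quantities are differences of δ values, so instrument
calibration is out of scope.

**Enrichment factors.** ε = δ_S − δ_REF, where δ_REF is the arithmetic mean
over the autotrophic reference plants of the *same plot*. This plot-wise
normalisation is the design's control for microsite effects (light regime,
soil, moisture): any additive plot-level shift cancels exactly. Reference
plants receive ε records too; within a plot their ε values average to zero
by construction, which the test suite uses as a pipeline invariant. Plots
with fewer than three references produce a warning (the field protocol asks
for at least three); a plot containing targets but no references is a hard
error, since no baseline exists.

**Full-mycoheterotroph baseline.** ε¹³C_FMH is the mean ε¹³C of a
caller-chosen baseline group assumed to obtain all of its carbon from
fungi — conventionally albino (chlorophyll-free) individuals; obligately
mycoheterotrophic protocorms are a legitimate alternative. Each baseline
individual is first normalised within its own plot, so pooling across plots
and sites is valid, and applying a baseline measured at one site to targets
at another is supported (and is the realistic use case when albinos occur at
only one site).

**Two-source mixing model.** %Cdf_i = ε¹³C_i / ε¹³C_FMH × 100 per
individual; groups report the mean and the sample SD (n−1) across
individuals, not an SD propagated from group-level summaries — this matches
the per-individual construction of ε and behaves correctly for n = 1 (SD
omitted). Values outside [0, 100] are *kept and flagged* rather than clamped
by default: with realistic noise an individual near either endpoint will
routinely cross it, and a group mean like 92 ± 11 % necessarily implies
individuals above 100. A `clamp` flag truncates to [0, 100] when a bounded
estimate is required. The model is applied to carbon only; ¹⁵N enrichment
has no accepted two-source interpretation and is reported as an enrichment.

**Reporting precision.** Per-mil and percent summaries print to one
decimal; all CSV outputs keep full precision.

## Mixed-model group comparison

δ values (or, optionally, enrichment factors) are modelled as
y = μ_group + b_plot + e with b_plot ~ N(0, σ²_plot), e ~ N(0, σ²_res),
fitted by REML via statsmodels `MixedLM` with a cell-means parameterisation
(no intercept; one coefficient per group, which is that group's adjusted
mean). Variance components are bounded at zero and boundary estimates are
legitimate: with σ̂²_plot = 0 the fixed effects coincide with OLS group
means (verified to 1e-6 in the tests). Degenerate inputs are handled
explicitly: a single plot falls back to OLS with zero plot variance, a
constant response returns exact zeros, and singular fits warn and fall back
rather than raising.

**Tukey–Kramer contrasts.** All pairwise contrasts use the fitted
fixed-effect covariance; the single-step family-wise adjusted p-value is
P(Q_{k,ν} ≥ √2·|t|) with Q the studentized range, k the number of groups,
and ν the containment degrees of freedom ν = n − k − (p − 1) (residual df
after group and plot-block df; ν = n − k with a single plot). This is the
studentized-range variant, exact for equal group sizes and conservative in
the Kramer sense under imbalance; with two groups it reduces to the
ordinary two-sided t-test. Exact Kenward–Roger df are out of scope; the
containment rule calibrates well in the design sizes of interest — the
suite measures a family-wise error of ≈0.05 (±0.02 band, 1000 replicates)
under a 5-group null with plot effects.

**t-tests.** Two-sample comparisons (chlorophyll content, Fv/Fm) default to
the pooled-variance Student's test, with Welch's form behind a flag, and a
summary-statistics entry point for re-analysing published mean ± SD (n)
values. Zero-variance degeneracies resolve by convention: equal constant
samples give (t = 0, p = 1); distinct constant samples give p = 0.

## Metabarcoding post-processing

**Filtering.** Singleton OTUs (total count exactly 1 across all samples)
are removed first, then OTUs whose trophic guild is outside the whitelist.
The whitelist is a user input — which guilds count as "known orchid
mycorrhizal partners" is a literature judgement the package does not
hard-code; the default retains orchid-mycorrhizal, ectomycorrhizal and
saprotrophic OTUs and excludes only guild `other`.

**Relative abundance** is computed on the *filtered* table; per-group
percentages pool raw counts over the group's samples before dividing
(matching how per-phenotype read counts are reported), sum to exactly 100
before rounding, and are printed with half-up rounding to two decimals.
Units with zero total reads are excluded with a warning.

**Sequence identity.** Clustering tools differ in their identity
definition, so the package fixes one and tests it: identity =
matches / alignment length over a global end-to-end alignment (end gaps
count) that maximises matches and, among such alignments, minimises
alignment length. This is computed exactly with a Needleman–Wunsch scoring
trick (match B−1, mismatch −1, gap −1 with B = len(a)+len(b)+1, so the
optimal score encodes both the match count and the alignment length), and
is validated against an exhaustive dynamic-programming oracle. Threshold
comparison is ≥.

**Greedy clustering** processes reads in decreasing abundance (ties broken
lexicographically by read id, making the result independent of input
order); a read joins the first centroid, in creation order, meeting the
threshold, else founds a new centroid. The most abundant read of a cluster
is therefore its representative. This is intended for small read sets and
validation work, not as a replacement for production clusterers on
millions of reads (it is O(reads × centroids) alignments).

## Synthetic data

The generator emulates the assumed field design: sites of 2 × 2 m plots
(default 4 plots × 3 references per site), Gaussian plot effects *shared by
references and targets of the same plot* — exactly the structure that makes
plot-wise normalisation effective — and Gaussian residual noise on the ‰
scale. Targets are assigned to their site's plots round-robin, one per
group per plot in the default design. Truth records (true %Cdf per group,
plot effects) are returned alongside the samples and never enter the
analysis path.

Defaults are the study conditions the package targets: references at
−34.4 ± 0.6 ‰ δ¹³C and −4.5 ± 0.5 ‰ δ¹⁵N, true ε¹³C_FMH = 8.4 ‰, plot SD
1.0 ‰, residual SD 0.6 ‰, and groups at true %Cdf 0 / 53 / 65 / 92 plus a
100 % albino baseline group, with per-group true ¹⁵N enrichments of
0 / 7.2 / 5.6 / 8.6 / 6.3 ‰. The ¹⁵N plot and residual SDs (0.5 and 0.3 ‰)
are chosen at the scale of the reported group SDs for nitrogen. OTU counts
are Dirichlet-multinomial per sample (default 3 samples/group,
8 000–12 000 reads each) with per-group weight vectors that make one or a
few OTUs strongly dominant, mirroring real orchid-mycobiont communities;
read sets for clustering tests are sequence families with Binomial point
substitutions.

Under these defaults the pipeline recovers each group's true %Cdf to well
within 3 percentage points when averaged over 200 seeds (Monte-Carlo SE
≈ 0.3–0.4 points), and the albino baseline averages its true 8.4 ‰.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: non-Gaussian and spatially correlated
microsite variation, isotopic differences between tissues (leaf vs rhizome
vs protocorm) beyond a group label, covariance between carbon and nitrogen
enrichment, unbalanced reference counts, compositional artefacts of real
amplicon libraries (chimeras, index hopping, length variation), and any
sequence-level realism of ITS markers. Real published group values (e.g. a
92.5 ± 10.6 % fungal-carbon estimate, or an 8.4 ± 1.6 ‰ albino enrichment)
depend on unreleased per-plot raw measurements and deposited reads; the
package's claims about them are therefore structural — the estimator is
unbiased under the assumed design at matching noise scales — not numerical
reproductions.

## Problem sizes

The default test and acceptance runs use 200 generator seeds for parameter
recovery, 1000 replicates for the family-wise-error calibration (300 in the
faster unit-level check), 120 replicates for variance-component recovery,
and read sets of ≤ 30 sequences of 150 nt for clustering; these sizes give
Monte-Carlo standard errors comfortably inside the assertion bands while
keeping a full run around one to two minutes.

## Known limitations

- The mixing model is strictly two-source and linear; it does not model
  isotopic fractionation differences between fungal taxa or tissues, nor
  uncertainty in the FMH endpoint (the baseline enters as a point value).
- Contrast df use the containment rule, not Kenward–Roger; with very few
  plots the adjusted p-values can be mildly anticonservative.
- The greedy clusterer is deterministic and faithful to its stated rule but
  is not a drop-in for heuristic production clusterers, whose candidate
  ordering and identity definitions differ.
- `fit_group_lmm` assumes a single random intercept; nested or crossed
  random structures (e.g. site/plot) are not supported.
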