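# Methods

This note documents the models, conventions and numerical choices behind
`ferrotime`, and what the synthetic-data tests do and do not demonstrate.

## Experimental design being modeled

A single-channel oligonucleotide microarray time course: a reference sample
at 0 h and post-perturbation samples at 3, 12, 24, 48 and 72 h, two
replicate hybridizations per time point, transcripts represented by
replicated probes (duplicates by default), and a pool of control spots
(empty positions and unused spike-in probes) whose signal is pure
nonspecific hybridization.  All fold changes are log₂ ratios against the
0 h reference.

## Preprocessing

**Background.** Intensities are clipped from below at a positive floor
(default 1.0) so the log transform is defined.  This is a deliberately
simple background step; the package does not model scanner-specific
background distributions (e.g. normal-exponential convolutions).

**Detection filter.** A probe counts as detected if there is at least one
time point at which its signal exceeds the maximum control-spot signal on
*every* replicate array of that time point; a transcript is expressed if
any of its probes is detected (configurable to all/majority).  The filter
runs on background-corrected, pre-normalization signals: probe and control
signals share each array's scale, which makes the decision invariant to a
global rescaling of any single array.  Unexpressed transcripts are excluded
from all downstream statistics.

**Quantile normalization.** Each array's log₂ values are replaced by the
across-array mean of order statistics at their rank; within-array ties
receive the mean of the reference values their positions span.  Exact
idempotence holds for tie-free columns (after one pass every column *is*
the reference distribution); with ties the tie-averaging perturbs the
pooled reference, so a second pass moves values by a small amount — this
is inherent to any tie-averaged quantile scheme and is documented rather
than hidden.  Two practical caveats shape the synthetic defaults below:
the method assumes most probes are unchanged between arrays, and a probe
already at the top of the intensity distribution cannot gain rank, so
strong inductions starting from very high baselines are clipped.

**Summarization.** Transcript value per array = arithmetic mean of its
replicated probes' normalized log₂ values.  Relative abundance is computed
on the linear scale: mean 2^(log₂) intensity per transcript divided by the
grand mean over expressed transcripts.

## Differential expression

Per transcript, a one-way group-means fit over time points: β_t =
mean(log₂ at t) − mean(log₂ at 0 h); pooled within-time-point variance s²
with d = n_arrays − n_timepoints degrees of freedom (d = 6 for the default
design).

With two replicates per group, s² is unstable, so it is shrunk by
empirical Bayes toward a common prior.  Under a scaled inverse-χ² prior
(s₀², d₀), the marginal of log s² is a shifted log-F whose mean and
variance involve digamma/trigamma functions of the half-df; matching the
observed mean and variance of log s² gives (d₀, s₀²).  The trigamma
inversion uses a bracketed Brent root search on half-df in [1e-2, 1e6].
If the observed spread of log s² does not exceed the χ²_d sampling floor,
the prior is degenerate: d₀ = ∞ and all moderated variances equal s₀²;
in the further corner where all s² are numerically identical (variance of
log s² ≈ 0) the χ² sampling model itself cannot hold, so the
bias-correction term is skipped and s₀² is taken as the common value.
Moderated t = β_t / √(s̃²(1/n_t + 1/n₀)) on d₀ + d df (normal when
d₀ = ∞); two-sided p-values; Benjamini–Hochberg FDR across transcripts
within each time point (configurable to global pooling — the choice of
stratum is a convention, both are supported).  DE at time t requires
q_t < 0.05 and |log₂FC_t| ≥ 1; overall DE is DE at any time point.
Moderation can be disabled for ordinary t-tests.

## Enrichment

Over-representation uses the upper hypergeometric tail P(X ≥ k) with the
expressed genes as universe, tested separately for up- and downregulated
DE selections per time point; sets smaller than 5 (after intersection with
the universe) are skipped, and BH runs within each (time point, direction)
stratum.  The parametric set score is z = (mean_set − mean_all)·√n_set /
sd_all on the log₂FC of all expressed genes at a time point, with a
two-sided normal p; being a central-limit statistic it requires ≥ 10 genes
per set.  sd_all is the population (divide-by-n) standard deviation;
gene scores are fold changes, not t-statistics.

## Soft clustering

Profiles are log₂FC vectors with the 0 h reference prepended as 0 (T = 6).
Genes with profile sd < 0.25 (ddof = 1) are removed; the rest are
standardized to mean 0, sd 1, after which Euclidean distance behaves like
a correlation dissimilarity and fuzzy c-means clusters temporal *shape*.
FCM uses the standard alternating updates with fuzzifier m, tolerance 1e-6
on the maximum membership change, at most 1000 iterations, centroids
initialized from distinct data rows, best of 3 restarts by objective; an
exact-zero distance assigns hard membership.  The objective
J = Σ u^m‖x − c‖² is recorded per iteration and is non-increasing.

Parameter selection, when not fixed by the caller:

* **m**: smallest grid value (default grid 1.1…3.0) at which FCM on a
  within-row shuffled copy of the data finds no structure — maximum
  membership within 0.05 of uniform 1/c for ≥ 95 % of rows.  Shuffling
  rows destroys temporal structure while preserving marginal value
  distributions, so any structure found at a smaller m is spurious.
* **c**: scan c upward at the chosen m and watch the minimum pairwise
  centroid separation; the first c at which it falls below half its value
  at c = 2 signals a superfluous centroid, and c − 1 is returned.  The
  one-half fraction was calibrated on planted-archetype matrices: a
  superfluous centroid does not collapse onto an existing one exactly but
  settles at roughly 10–30 % of the baseline separation, so a much smaller
  fraction misses the collapse.  With this rule, planted c ∈ {2, 3, 4} is
  recovered across seeds at effect 2 / noise 0.25, and pure noise returns
  the range minimum.

Hard labels use argmax membership with a 0.5 display cutoff (below it a
gene stays unassigned).  Heatmap ordering uses scipy's complete-linkage
agglomeration on 1 − centered Pearson correlation; scipy's merge order is
deterministic, including its tie handling.

## Sense–antisense pairs

Pairs require both members to carry an overall DE flag.  Correlations are
computed over the five post-treatment time points only — the forced 0 at
0 h is excluded because it is an artifact of the reference definition, and
this convention reproduces the published per-pair coefficients from their
printed profiles.  Pearson is the default method (it matches the published
values; Spearman is available but does not).  Classes: I if r > 0.5, III
if r < −0.5, II otherwise with both boundaries inclusive to II.
Direction = sign of the median of the five log₂FC values.  The
class I vs III abundance contrast uses Δ = mean normalized intensity
(asRNA) − (mRNA) per pair and a two-sided Wilcoxon rank-sum test.

## sRNA screening

Candidate regulon members are DE sRNAs whose post-treatment profile
correlates with the marker gene at |r| ≥ 0.7 (Pearson default, same
rationale as above), split into positive and negative lists sorted by |r|.
Target windows span positions −150…+100 with +1 the first base of the
start codon (250 nt), strand-aware and clipped (with a flag) at contig
ends.  Predicted interaction energies are consumed as a table; the filter
keeps energy ≤ −10 kcal/mol (more negative = stronger) and then Spearman
r < −0.5 between sRNA and target profiles.  Spearman is used at this stage
(not Pearson) because target relationships need only be monotone.

## Cross-study meta-analysis

Per-study tables (gene, log₂FC, p) are re-called under |log₂FC| ≥ 0.5 and
p < 0.01 — looser than the single-study threshold because some published
studies report only genes passing exactly this cut.  The gene universe for
intersections is the genes measured in all studies; percentages against
other bases can be recomputed from the reported counts.  The core set
(DE everywhere) carries a concordance label from per-study directions.

## Synthetic data

The generator emulates the design above at probe level:
2^(baseline + true log₂FC + array effect + ε), ε ~ N(0, noise_sd) — the
conventional multiplicative log-normal error model.  Defaults: noise_sd
0.25 (log₂), effect size 2 (4-fold at the profile peak), 20 % responders,
duplicated probes, baselines uniform on log₂ [9, 14], control spots
N(6, 0.5) in log₂ with per-spot bases so that noise_sd = 0 makes replicate
arrays identical, planted-undetectable transcripts below a detection floor
of 128.  Four archetypes provide the temporal shapes: monotone up/down
(saturating log-time ramp) and transient up/down (peak/dip at 12 h,
relaxing afterwards).  asRNA coupling: class I copies the sense latent
profile, class III negates it, class II draws a random latent
orthogonalized against the sense profile (exactly uncorrelated at zero
noise) — classes mixed 0.4/0.3/0.3.  Marker-tracking sRNAs copy (or
negate) the marker gene's latent profile; the marker and positively
tracking sRNAs draw baselines from the lower 40 % of the baseline range
because strong inductions from top-of-distribution baselines would be
clipped by quantile normalization (see above) — which also mirrors the
biology of stress-induced transcripts that are quiet before induction.
Planted-enriched gene sets draw ~80 % of members from upregulated
responders.  One `numpy` generator seeded from `SimulationConfig.seed`
drives everything; identical configs give bit-identical outputs.

What the simulator does *not* emulate: spatial array artifacts, dye/scanner
chemistry, probe-sequence affinity biases, correlated noise between
neighboring probes, and realistic platform scale (tests run hundreds of
transcripts, not 42 000 probes).  Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that the
model captures every property of a physical array.

## Problem sizes and determinism

Tests and the acceptance script run deliberately small problems: a few
hundred transcripts per simulated dataset, 2000 transcripts × 20 seeds for
null-FDR checks, 240 profiles for clustering recovery.  These sizes give
stable Monte-Carlo estimates for the assertions made while keeping the
whole suite fast.  All randomness flows from explicit seeds (the
acceptance script derives per-stage substreams from `--seed` via
`SeedSequence`); nothing reads the wall clock.

## Known limitations

* Quantile normalization attenuates fold changes when a large fraction of
  the universe responds, and clips inductions at the top of the intensity
  range; both are properties of the method, inherited deliberately.
* The expression filter compares raw (pre-normalization) signals to
  control maxima; running it post-normalization would change marginal
  cases.
* The moment-matching moderation assumes a common prior across transcripts;
  heteroscedastic transcript families would call for trend-fitted priors,
  which are out of scope.
* Class II planted pairs are "uncorrelated by construction", which is a
  stronger statement than real uncoupled pairs satisfy; recovery numbers
  for class II are accordingly optimistic.
* The parameter-selection heuristic for (c, m) is a calibrated convention,
  not an estimator with guarantees; on data whose structure is not
  archetype-like it should be treated as a starting point.
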