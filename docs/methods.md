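# Methods

## The model

`arrayvar` analyses a two-colour spotted-microarray experiment in which
human PBMC from 5 subjects (A–E), sampled on 2 days each, were stimulated
with LPS in two parallel tubes (or left unstimulated), amplified, and
hybridised against a common pooled reference. Replication exists at five
levels — subject, day, stimulation tube, amplification run and
hybridisation — with two subjects carrying full technical replication
(repeat amplification and repeat hybridisations of one sample).

For each gene, the normalized log2 ratio on array *a* is modelled as

    M_a = beta_0 + beta_sex * female(a) + beta_LPS * stim(a)
          + u_subject + u_day + u_subject:LPS + u_day:LPS
          + u_stim + u_amp + e_a,

with independent Gaussian random effects per grouping level,
`u_k ~ N(0, sigma2_k)`. The seven variance components are: subject, day
(nested in subject), the Subject:LPS and Day:LPS interactions (per-subject
and per-day deviations of the LPS response, acting only on stimulated
arrays; all unstimulated arrays sit in a null level contributing zero),
stimulation tube, amplification run, and the residual, which is the
hybridisation-level variance plus anything else downstream of
amplification. Biological variability is the subject + day variance,
technical variability the stim + amp + residual variance; both are pooled
per gene on the variance scale before taking square roots.

## REML estimation

The restricted likelihood is coded explicitly. With
`V(theta) = sum_k theta_k Z_k Z_k' + theta_resid I`,

    -2 l_R = log|V| + log|X'V^-1X| + y'Py  (+ const),
    P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1,

and the analytic gradient `d(-2 l_R)/d theta_k = tr(P G_k) - (Py)'G_k(Py)`
is maximized by projected quasi-Newton (L-BFGS-B) over the non-negative
orthant; all solves go through Cholesky factorizations. Components whose
optimum lies on the boundary are returned as exactly zero — with only 5
subjects, a component generated at zero is estimated at zero in well over
half the genes, so its across-gene median SD is exactly 0. Components the
design cannot identify (e.g. subject variance in a single-subject design,
or any random term whose incidence is absorbed by the fixed effects or
coincides with a finer term's partition) are fixed at zero and flagged
rather than estimated. Fixed effects are the generalized-least-squares
solution at the optimum, with standard errors from `(X'V^-1X)^-1`.

Convergence: relative change in the criterion below 1e-8 and projected
gradient below 1e-6 (scaled by the per-gene data variance); 200 iterations
maximum, with best-so-far estimates and `converged=False` on failure.
Degenerate constant-response genes short-circuit to all-zero components.
The optimizer was validated against a dense grid search of the same
criterion on small designs, against closed-form ANOVA estimators on
balanced one-way layouts (where REML and method-of-moments coincide), and
during development against an independent mixed-model implementation; on
disagreeing genes the packaged optimizer attained the better restricted
likelihood.

Two constrained-REML behaviours are worth knowing. First, truncation at
zero redistributes variance: when several truly-zero components are
fitted alongside the real ones, the spurious non-negative estimates absorb
variance and the remaining components are biased down by roughly 10–20% on
this design; this is a property of the estimator (an independent
mixed-model fitter behaves identically), not of the implementation.
Second, component SDs estimated with few effective degrees of freedom
(the Subject:LPS component rests on 5 subject levels, about 4 df) have a
concave-transform bias on the SD scale; when estimates are averaged across
simulation replicates the package therefore averages variances and takes
the square root at the end.

## The DE test

The LPS differential-expression call is a per-gene Wald z-test on the LPS
fixed effect with Benjamini–Hochberg adjustment at FDR 0.05. The original
analysis does not state its test or threshold, so this is an
interpretation; counts of significant genes depend on it and are reported,
not asserted.

## The synthetic-data generator

`simulate_expression` draws data from exactly the model above, so it is
the ground truth for parameter-recovery checks. Study-condition defaults
(`study_condition_sds()`): pooled technical SD 0.16 with the residual at
its separately reported 0.10 and stimulation/amplification splitting the
remaining technical variance equally; pooled biological SD 0.06 split
equally between subject and day; both LPS-interaction components zero.
Per-gene LPS effects are spike-and-slab — 35% of genes carry an effect
drawn from N(0, 1) on the log2 scale, matching the order of magnitude of
a strong stimulus where fold changes dwarf component SDs — and gene
baselines against the common reference are N(0, 1) (no distributional
statement exists for these; the choice is flagged in the config). An
optional flag rebuilds the reference channel from day-2 samples to emulate
the common-reference artefact that makes day-2 arrays sit closer to the
reference.

`simulate_spots` expands a matrix into GPR-style two-channel spot tables
with a print-tip grid, per-spot background, an intensity-dependent
per-block dye bias, and saturation, constructed so the known distortion is
exactly invertible by the preprocessing chain; it exists to exercise
preprocessing, not to model scanner physics (no image-level simulation,
no probe-sequence effects).

What the generator does not emulate: correlated expression between genes,
heavy-tailed or gene-specific noise, spatial artefacts beyond the
per-block dye bias, and quality-flagged spots. Passing recovery tests
therefore show the estimation machinery is correct under the stated model,
not that real arrays satisfy that model.

## Preprocessing

Background correction subtracts the supplied background columns and adds
an offset of 50 to both channels, so any spot with FG − BG > −50 keeps a
finite log-ratio and low-intensity ratios are damped (the morphological
background estimator itself operates on scanner images the pipeline never
sees; background columns are consumed as given). Print-tip loess fits a
locally weighted linear regression of M on A per block (tricube weights,
span 0.4 interpreted as the fraction of fit-eligible points, one bisquare
robustness iteration by default and configurable to zero since the
original robustness setting is unstated), using only library probes with
mean A ≥ 6.5 across arrays; the fitted trend is subtracted from every
probe in the block, including low-A probes. Blocks with fewer than 10
eligible probes fall back to median-centering with a warning. After
normalization, control probes are removed and the 33% of library probes
with the lowest mean A-values are filtered; the retained count uses
round-half-even and ties on A break by probe id, so the cut is
deterministic. Note that loess cannot distinguish a per-block average of
gene baselines from dye bias — per-block baseline structure is absorbed
into the trend — so round-trip recovery of simulated truth is exact only
up to a common per-block shift; between-array contrasts, which the mixed
model consumes, are unaffected.

## Summaries

Replicate correlations are Pearson correlations across genes between a
subject's index hybridisation (day 1, tube 1, amp 1, hyb 1, stimulated)
and its repeat at each level; the comparator subject for the outermost
level is a parameter (the original choice was random and unknowable).
Component distributions use Tukey box statistics (1.5 x IQR whiskers).
Proportion of variance per component uses across-gene mean variances so
the proportions sum to one exactly (mean vs median is unstated in the
source; mean is the choice that makes the shares exact). Gene ranking by a
component sorts its SD descending with gene-id tie-breaks. The sex-vs-LPS
comparison flags outliers by robust z-score (median/MAD, threshold 4).
The effect-vs-variability comparison reports the ratio of the median
|LPS effect| among significant genes to the largest component median SD,
flagged not-applicable when either side degenerates.

## Problem sizes and numerical choices

Recovery runs use 5000 genes on the 36-array design (about 3 minutes on
one CPU; one gene fits in ~7 ms); the single-gene Subject:LPS recovery
averages 20 seeded replicates of a 1000-gene run on the variance scale.
These sizes put Monte-Carlo error on across-gene medians near 0.001 —
an order of magnitude below the ±0.02 recovery bands. Variances below
1e-8 x the data variance are snapped to exactly zero; a diagonal jitter
of ~1e-10 keeps V positive-definite at all-zero parameter vectors.

## Known limitations

- Per-gene fits are independent; no moderation or information sharing
  across genes, so component estimates are noisy at 5 subjects / 2 days.
- The exact replicate layout of the original 36 arrays is not fully
  recoverable from its description; the default layout reproduces 36
  arrays but the per-sample replicate counts are configurable.
- No dye-swap support (sample fixed on Cy5), no between-array scale
  normalization, no spot-quality weighting — none of these steps exist in
  the emulated protocol.
- The Day:LPS artefact analysis (reference composed of day-2 RNA) is
  reproduced qualitatively by a generator flag, not estimated from data.
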