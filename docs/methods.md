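# Methods

`surfhet` analyzes semiquantitative immunohistochemistry (IHC) data from
multi-site tumor tissue microarrays (TMAs), of the kind produced by rapid
autopsy programs in metastatic castration-resistant prostate cancer (CRPC):
many metastatic sites per patient, one formalin-fixed tumor block per site,
and one to a few TMA cores per block. This note documents the statistical
models, the defaults and why they were chosen, and what the synthetic data
generator does and does not emulate.

## H-score and positivity

Each core is scored as the percentage of tumor cells at staining intensity
0 (none), 1 (faint) and 2 (prominent). The H-score is the intensity-weighted
sum `H = 0·p0 + 1·p1 + 2·p2`, bounded by 0–200 on this two-intensity scale.
Precomputed H-score columns bypass the formula but pass the same [0, 200]
validation, since scoring sheets often carry only the final score.

A single global positivity threshold (default 20, **inclusive**: H = 20 is
positive) is applied to every marker. One threshold for all markers keeps
positivity comparable across targets; it is a config value, not a constant.

## Molecular subtyping

Tumors are classified on two marker axes — androgen-receptor signaling
(AR, NKX3.1) and neuroendocrine differentiation (SYP, INSM1) — into the
four-quadrant scheme AR+/NE− (adenocarcinoma), AR−/NE+ (NEPC), AR+/NE+
(amphicrine), AR−/NE− (double negative). An axis is positive when the
aggregated score of its markers reaches the threshold. Defaults: `max`
aggregation within an axis and across a block's cores, at the same ≥20
cut-off used everywhere else. `max` is the standard TMA convention (a block
is positive if any of its sampled tissue is); `mean`/`median` are config
alternatives. Classification is at the block level by default because the
block is the unit of tissue; externally provided pathologist labels
(`subtype_label` column) take precedence over derived calls so that cohorts
scored by eye can be reproduced exactly. An axis with both markers missing
is an indeterminate-subtype error rather than a silent guess.

## Co-expression and patient classes

Co-expression tables are 2×2 contingency tables of joint binarized status
for a marker pair, computed over cores by default (block-level aggregation
available), excluding units missing either marker. Percentages use decimal
half-up rounding, integers by default with a one-decimal option — the
conventions under which such tables are reported.

Patients are classified per marker over their metastatic sites
(cores → site by `max`): *non-expressor* if every site is below threshold,
*uniform-high* if every site is at or above it, *heterogeneous* otherwise.
Patients with no measured unit for a marker are excluded from the
denominator and reported, so per-marker denominators are explicit rather
than silently shrinking.

## Heterogeneity index

For a marker and scope, the index is the probability that two samples drawn
at random without replacement from the same group are discordant in
binarized status. Groups are tumor blocks (intra-tumoral) or patients with
the pair restricted to different blocks (inter-tumoral). For one group with
`n` samples and `k` positives, concordance is the finite-population
identity `[C(k,2) + C(n−k,2)] / C(n,2)`; the package computes the index two
ways:

* **exact** — exhaustive enumeration of all eligible pairs, either pooled
  (pair weighting, every eligible pair equally likely — the default,
  matching a uniform draw of pairs) or averaging groups equally (group
  weighting, reported in output when used);
* **bootstrap** — each replicate draws `n_pairs` pairs uniformly with
  replacement from the pool (default 1000) and takes the discordant
  fraction; the point estimate is the replicate mean, with bias-corrected
  and accelerated (BCa) 95% limits.

BCa uses the standard constructions: bias constant `z0 = Φ⁻¹(#{θ* < θ̂}/B)`
(ties counted half, proportion clipped to keep z0 finite) and acceleration
`a = Σd³ / (6(Σd²)^1.5)` from leave-one-out jackknife deviations `d`. The
jackknife/resampling unit is the pair by default, with a patient-level
cluster option to respect within-patient correlation; the pair default is a
simplification and is recorded in every output row. An all-identical
replicate distribution yields a flagged point-mass interval, not an error.

When the pool is small, `n_pairs=None` resamples pool-size draws (the
classical bootstrap); this is what the interval-coverage simulations use,
because drawing a fixed large number of pairs from a small pool measures
only Monte-Carlo noise rather than sampling variability. All sampling flows
through one seeded NumPy generator and the seed is recorded in every
estimate.

## Association models

**Site contrasts.** Mean H-score differences between anatomic sites are
estimated by a linear mixed model, `H ~ site` with a patient random
intercept, fit by REML (statsmodels MixedLM) with Wald 95% CIs and
two-sided p-values and no small-sample df correction. A random-effect
variance estimated at the zero boundary is legitimate, flagged
(`singular_fit`), and collapses the fit to ordinary least squares. Sites
represented by a single sample are flagged `wide_ci` rather than dropped.
The reference site defaults to vertebral bone, the most common metastatic
compartment; changing the reference relabels contrasts but leaves fitted
cell means invariant.

**Genomic odds ratios.** Binarized expression is regressed on a per-patient
0/1 alteration flag with a patient random intercept. The marginal
likelihood is maximized with 25-node Gauss–Hermite quadrature over the
random effect; Wald SEs come from the numeric Hessian at the MLE. With
singleton clusters the variance is unidentifiable and the fit reduces — by
construction, not approximation — to ordinary logistic regression, so the
odds ratio then equals the classical 2×2 value. Complete separation (a zero
cell in the collapsed 2×2) is detected and returned as a flagged unbounded
OR rather than a spurious finite estimate. Protein mode collapses a patient
to positive if any measured site is positive (`all` and sample-level modes
available); transcript mode dichotomizes FPKM at ≥1 by default, a common
expressed/not-expressed convention, configurable because no single standard
exists. Raw two-sided p-values are reported without multiplicity
adjustment; a Benjamini–Hochberg column can be requested downstream but
significance flags never enter estimation.

## Synthetic cohort generator

The generator emulates the structure the estimators assume, with every
stochastic choice driven by one seeded generator:

* 52 patients; sites per patient truncated-Poisson with mean 372/52; one
  block per site; cores per block on {1..4} with probabilities
  (0.40, 0.30, 0.18, 0.12), giving ≈753 cores in expectation;
* a per-patient dominant subtype (adenocarcinoma 0.60, NEPC 0.15,
  amphicrine 0.08, double-negative 0.17); 20% of patients mix a second
  subtype, and within those patients each site switches to the secondary
  subtype with probability 0.35 — subtype mixing is a patient-level
  property, not an iid per-site coin, because metastases share clonal
  origin;
* per (subtype, marker) H-scores from a three-part mixture: point mass at 0,
  point mass at 200, and a scaled-Beta interior whose parameters are solved
  numerically so the cell's marginal median equals its anchor (e.g. TROP2
  median 200 in adenocarcinoma and 0 in NEPC, DLL3 90 and CEACAM5 60 in
  NEPC, PSMA 120 in adenocarcinoma and 12 in double-negative). Anchors are
  the medians such cohorts report; dispersions are free parameters with
  documented defaults;
* a per-patient, per-marker Normal(0, 4²) shift on the zero-inflation
  logit, which makes a patient's blocks rise or fall together (most
  patients uniformly positive or uniformly negative, a minority mixed);
* within-block correlation via a block-level latent value with
  Normal(0, 12) core-level noise, so discordant cores arise mainly in
  blocks near the threshold;
* additive anatomic-site shifts (TROP2 −17 in liver, −40 in lung; DLL3 +11
  and +14; CEACAM5 +19 in prostate bed) applied to expressing blocks;
* per-patient genomic alterations with subtype-dependent prevalence (e.g.
  AR amplification enriched in AR-positive disease, RB1 loss in NEPC) and
  known log-odds effects on marker positivity (e.g. +log 4 of AR
  amplification on PSMA).

Every cohort comes with a `CohortTruth`: realized per-sample statuses, true
block subtypes and the generating effect sizes. `truth_heterogeneity`
recomputes discordance from the truth by deliberately naive enumeration, an
independent code path used as the oracle for the estimator.

**What the generator does not emulate.** Scores are exchangeable given
block and subtype — there is no spatial structure within blocks, no
pre-analytical artifacts (bone decalcification), no missing-marker
patterns, and the inter-tumoral heterogeneity of the defaults (≈13–24%
across the four surface targets) runs somewhat above what tightly clustered
real cohorts show (≈7–17%), because residual patient-level correlation
beyond the single logit shift is not modeled. Passing tests therefore
demonstrate estimator correctness under a plausible clustered
data-generating process, not fidelity of any particular real cohort.

Two focused simulators back the parameter-recovery studies:
`simulate_site_cohort` (balanced sites, known −20 liver shift, patient SD
10, residual SD 30) and `simulate_genomic_cohort` (100 patients × 3
samples, alteration prevalence 0.3, log-odds log 4, patient SD 1).

## Numerical and reproducibility choices

* Decimal half-up percentage rounding; ties at .5 always round up.
* BCa z0 proportion clipped to [0.5/B, 1−0.5/B]; degenerate replicate sets
  flagged, never raised.
* Beta-median solver: Brent's method on the interior mean at fixed
  concentration κ=3, tolerance 1e-10.
* GH quadrature: 25 nodes; log-sum-exp over nodes for stability; L-BFGS-B
  with σ bounded in [0, 10]; σ < 1e-4 treated as the boundary and replaced
  by the exact ordinary-logistic fit.
* Group keys factorize in first-appearance order, never via `hash()`, so
  results are identical across processes.
* Problem sizes in the test suite and acceptance script (500 coverage
  pools, 200 recovery simulations per model in tests; 200 and 50 in the
  script) were chosen to give stable Monte-Carlo checks at interactive
  runtimes.

## Known limitations

* Wald inference throughout; no Satterthwaite/Kenward–Roger correction for
  the mixed model, no profile-likelihood CIs for the logistic model, so
  very small cohorts will have optimistic intervals.
* The pair-level BCa default understates uncertainty when pairs share
  samples; use `resample_unit="patient"` for conservative intervals on real
  clustered cohorts.
* The heterogeneity index is binary-status-based; continuous-score
  alternatives (e.g. intraclass correlation on raw H-scores) are out of
  scope, with `PairPool` as the extension point.
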