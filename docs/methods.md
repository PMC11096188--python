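# Methods

## Droplet-level quantification

Each well partitions a reaction into ~20,000 droplets of volume
V<sub>d</sub>. Molecules load droplets independently, so the number of
molecules per droplet is Poisson with mean λ = c·V<sub>d</sub> and the
positive fraction is 1 − e<sup>−λ</sup>. Inverting, λ = −ln(1 − k/n) and
c = λ/V<sub>d</sub>. The two fluorescence channels (FAM = mutant,
VIC = wild type) load independently; a double-positive droplet is
co-occupancy, so the FAM-positive total is FAM-only + double-positive and
VAF is defined on channel *concentrations*, not raw droplet counts —
otherwise double-positive droplets would be undercounted in one channel.

Replicate quantification pools the four droplet classes across the
replicate's wells and estimates a single concentration from the pooled
counts. This is numerically equivalent to the merged-well output of droplet
readers and is deterministic; the per-eluate formula (c × elution volume ×
number of wells) is then applied once with the pooled concentration. When a
first replicate is negative and a later one positive, wells from both enter
the pooled quantification (the `combine_wells_for_quant` flag).

A saturated channel (every droplet positive) has no finite estimate and
raises an error rather than returning infinity.

**Defaults.** Droplet volume 0.85 µL·10⁻³ (0.85 nL, the QX200-class
convention; configurable), elution volume 20 µL, haploid genome equivalent
3.3 pg. Maximum sensitivity — the smallest VAF an experiment could have
called — is 2 / (total copies assayed), with the floor of 2 matching the
two-droplet calling rule, so the limit of detection and the calling rule
cannot disagree.

## Calling rules

A replicate is 20 mL of plasma or a 200-million-cell PBMC aliquot. It calls
positive with ≥ 2 FAM-positive droplets (threshold configurable). At sample
level: any positive germline or no-template control makes the timepoint
inconclusive (the controls invalidate *that* replicate set, not the
patient); otherwise the sample is positive iff some replicate is
individually positive — one droplet in each of two replicates stays
negative. Totals of 2–3 FAM droplets set a low-positive flag that demands
two additional germline-control wells before the call is confirmed; because
the eligibility phrasing ("2 or 3 droplets and only double positives") is
ambiguous, the count condition and the droplet-class condition are recorded
as separate booleans. A germline sample that itself calls positive raises
the CHIP flag: the mutation lives in blood cells, so plasma signal cannot be
attributed to tumor.

An inconclusive replicate is excluded and the sample is called from the
remaining valid replicates; a timepoint with none is inconclusive.

## CTC counting

The spike-in calibration is an ordinary least-squares line of mutant copies
per eluate on spiked cell count, fit through individual replicate points
(64/128 cells, triplicate). Inversion gives cells = (copies − intercept) /
slope; copy yields below the intercept invert to negative cell counts and
are clamped to zero (the assay background makes sub-intercept yields
non-physical, a case the source data never exercise). Published constants
(slope 0.1992 copies/cell, intercept 0.3072) are the default when no
spike-in table is supplied. Depletion efficiency is log₁₀(cells before /
cells after), with an infinite-depletion sentinel at zero remaining cells.

## Longitudinal MRD

Combined status is positive if either analyte is positive; an inconclusive
analyte is ignored when the other is conclusive (a timepoint can be rescued
by the second analyte). Trajectory classification drops inconclusive
timepoints, then partitions the post-surgery binary sequence:

| sequence | group |
|---|---|
| no positives | always negative |
| ≥ 1 positive, ends negative | cleared on treatment |
| starts negative, ends positive | converted to positive |
| starts positive, ends positive | intermittently positive |

The partition is exhaustive and mutually exclusive over every binary
sequence (property-tested to length 6). The source cohort defines the groups
only by example; the ends-negative ⇒ cleared tie-break is this package's
choice and treats any terminal clearance as clearance.

Lead time is relapse month minus the earliest post-surgery MRD-positive
month; detection after relapse returns a negative value with a warning flag
instead of an error. Diagnostic sensitivity uses the exact Clopper–Pearson
interval (beta-quantile form; the tests cross-check it against independent
bisection of the binomial tails). Cohort detection percentages are
*truncated* to two decimals (6/9 → 66.66), matching the reporting convention
of the emulated study, while sensitivity is rounded (12/13 → 92.31).

## Response model

Predictors are log₁₀(x+1)-transformed MGE at pre-treatment and post-NAC
(signed log for the pre-minus-post change, which can be negative). Manual
selection screens predictors by Cramér's V against the outcome — continuous
predictors median-split into two bins, because cohorts of ~20 make finer
tables unstable — keeps those with V ≥ 0.1, ranks them by V and admits each
in turn only if McFadden pseudo-R² improves by ≥ 0.01. Automated selection
runs forward (from intercept-only), backward (from the full model) and
bidirectional stepwise AIC searches. Every candidate is scored by training
ROC AUC and the best is kept.

DeLong's test against AUC = 0.5 uses the placement-value variance with a
normal reference, as canonical implementations do. At very small n the
asymptotic p deviates from the exact permutation p by up to ~0.08; the tests
therefore check agreement with the exhaustive-relabeling oracle in the
median over seeded n = 12 cases and on the documented worked example under
the mid-p convention, rather than asserting case-by-case equality the
asymptotic test cannot deliver.

LOOCV refits the model n times and pools the n out-of-fold probabilities
into a single AUC (a per-fold AUC is undefined with one held-out patient);
a training fold that loses an outcome class falls back to the class
prevalence. The Youden cutoff maximizes sensitivity + specificity − 1 over
observed probabilities, ties broken toward higher sensitivity then lower
threshold — in an MRD context missed detections cost more than false
alarms. Complete separation (likely at n ≈ 20) is flagged, not fatal.

## Synthetic cohorts

The generator emulates the study design: per patient one truncal mutation;
20 mL plasma and 200-million-PBMC aliquots per timepoint; eight
20,000-droplet wells per replicate; matched germline controls with the same
partitioning and two empty no-template wells; a pCR rate of 7/21.
Pre-treatment plasma burden is log-normal with median 0.73 mutant copies/mL
(σ = 1.2 on the log scale), cfDNA yield log-normal with median 8 ng/mL
(σ = 0.5 — plausible ranges, as real per-patient yields are not published).
CTC burden is Poisson at 0.6 cells/mL scaled by the patient's relative
plasma burden, and the residual leukocyte background reflects the 3.48-log
depletion.

Treatment dynamics: responders clear to 1% of pre-treatment burden, 
non-responders to 30%. Responders carry 4.84× the pre-treatment burden,
chosen so the ratio of median MGE changes between groups is
4.84 × 0.99/0.70 ≈ 6.85, the reported scale. After surgery a latent carrier
state (15% of responders, 50% of non-responders) keeps 10% of pre-treatment
burden; carriers relapse with a 0.03/month hazard, censored at 36 months.
False-positive droplets arise in every well at 10⁻⁶ per droplet; 5% of
patients are CHIP carriers whose germline DNA holds the mutation at 2% VAF.

Mutant molecules are placed *individually* into droplets, so the realized
molecular ground truth (how many mutant-occupied droplets actually exist) is
exact; the wild-type background uses per-droplet occupancy probabilities.
Ground truth — true concentrations, realized molecules, true MRD states,
relapse months — is written to a separate file the pipeline never reads.

What the generator does **not** emulate: fragment-size biology, assay-to-
assay efficiency differences, droplet gating errors, copy-number gains at
the mutant locus, inter-timepoint correlation in cfDNA yield, and clinical
covariate structure beyond random subtype/nodal labels. Tests passing on
synthetic cohorts therefore certify the statistical machinery, not the
wet-lab performance of any particular assay.

## Problem sizes and numerics

The test suite runs cohorts of 21 (study-sized) and 200 patients (model
recovery), 1,000-trial Poisson-recovery batteries, 10,000-trial CI-coverage
simulations and exhaustive permutation oracles up to n = 12 — sizes chosen
so the whole suite completes in seconds while estimates remain stable. All
randomness flows from a single integer seed per generator. Percentage
comparisons against printed values use ±0.01 because the emulated reporting
mixes truncation and rounding. Log-likelihoods are clipped at 10⁻¹² to keep
separation finite; AIC searches require strict improvement (tolerance 10⁻⁹)
to terminate.

## Known limitations

- Eq.-style quantification assumes the "number of wells" multiplier applies
  to a pooled-count concentration; a per-well-average reading would differ
  only by sampling noise but is not what is implemented.
- cfDNA mass for MGE is the total eluate mass, not per-well mass.
- The depletion-efficiency denominator is taken as remaining cells after
  enrichment (input/remaining ratio).
- The pipeline models at most one visit per timepoint label per patient;
  longer follow-up series are supported by the data types but not by the
  fixed four-visit table dialect.
- The response model's real-cohort AUCs are not reproducible here because
  per-patient MGE values are not published; the machinery is validated on
  synthetic cohorts instead.
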