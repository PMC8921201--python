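# Methods

## Data model and pre-processing

The atomic record is a timed button-press report of one of four perceptual
states (H, V, PM, SI); a trial is an ordered, contiguous stream of such
reports with its design labels (participant, group, paradigm, contrast
condition, counterbalancing arrangement, trial index). Times are seconds,
trial-relative, starting at 0. H and V jointly form the *exclusive* class.

Cleaning applies three rules in a fixed order:

1. **Last-response drop.** Trials end when a button is released after the
   minimum trial duration, so the final report's duration is truncated by
   design and uninterpretable; it is always removed first. Ordering matters:
   dropping it first guarantees it can never survive by merging into an
   earlier same-state report.
2. **Short-response filter.** Reports with duration ≤ 0.180 s are removed
   (inclusive comparison on the stored float): they are faster than plausible
   reaction times and treated as motor noise. Their time is discarded, not
   re-attributed — a filtered report is unreliable evidence about *any*
   state.
3. **Same-state merging.** Runs of consecutive identical states created by
   the filter are merged into one phase whose duration is the sum of the
   merged reports.

The result may be empty (e.g. a single-report trial); empty trials are valid,
flagged, and excluded from every aggregate. Pre-processing is idempotent, and
total clean time never exceeds total raw time. Unreported gaps in input data
are tolerated in lenient mode (warned, excluded from denominators, never
merged across); strict mode rejects gaps/overlaps beyond 1 ms.

## Basic statistics and aggregation

Per trial: per-state relative proportions of reported time (summing to 100%),
per-state mean phase durations (a state absent from a trial contributes *no*
duration sample rather than a zero), class aggregates for
exclusive/piecemeal/superimposed, and flip counts — *full flips* are direct
H↔V changes, *half flips* every other adjacent change, so full + half equals
the number of phase transitions exactly.

Aggregation is hierarchical: trial values are averaged within participant
first (flips are summed), then participants are averaged with equal weight
regardless of usable trial count. The trial-pooled alternative is also
computed and labelled, since the two differ whenever trial counts are
unbalanced; participant weighting is the default everywhere. A per-condition
mode retains the condition key for contrast-condition breakdowns.

Group inference uses the pooled-variance (Student) two-tailed independent
t-test with df = n₁ + n₂ − 2 — the classical t(df) form — rather than Welch;
zero pooled variance yields a flagged degenerate result. Trait correlations
(AQ or EQ against a rivalry measure per participant) are ordinary least
squares with a one-sample t-test of the slope against 0 (df = n − 2) and a
symmetric 95% CI from the t quantile. No multiple-testing correction is
applied anywhere; all p-values are reported raw and labelled as such.

## Phase-distribution fits

Exclusive phase durations are normalized by dividing each duration by the
mean of its cell — subject × condition within group × paradigm, H and V
pooled before normalization — giving dimensionless samples with unit mean per
cell, then pooled across subjects. (An alternative per-subject normalization
pooled over conditions is available behind a flag; the cell-wise version is
the default.) Single-phase cells contribute x = 1 and are flagged.

Gamma parameters are estimated by maximum likelihood with location fixed at
0. Goodness of fit is the coefficient of determination between the fitted
density and a density-normalized histogram with fixed bin width 0.2 over
[0, 4]; fixing the binning makes R² reproducible, and on real (non-ideal)
data it behaves like the familiar histogram-overlay R². The peak is the mode
(α − 1)β for α > 1, with its amplitude reported on the event-scaled curve
N·f(x) so that group curves reflect how many percepts occurred; for α ≤ 1 the
density is monotone and the peak is flagged at the left evaluation bound
rather than raised as an error. The AUC uses the trapezoid rule on 100 evenly
spaced evaluation points over x ∈ [0.18, 4] (the off-by-one between 99 and
100 intervals changes the value by < 1e-4); both the unit-density AUC and the
event-scaled AUC are reported. A lognormal fit with identical machinery
serves as the comparison family.

## Markov transition modelling

Clean sequences are fully observed, so the Markov transition MLE is the
row-normalised matrix of adjacent-pair counts; no latent-state estimation is
needed or used. The diagonal is structurally zero (merging removes
self-transitions). Rows with zero departures are *undefined* — carried as
NaN, never imputed as zero, because a zero would fabricate certainty about
unobserved behaviour. Each ordered transition also carries an
actual-to-posterior weight: the mean duration of phases of the actual state
that were immediately followed by the posterior state; the final phase of a
trial has no posterior and contributes nothing.

Averaging across trials, participants and conditions is hierarchical and
unweighted over defined entries only; averaged probability rows are
re-normalised to sum to 1 over their defined cells. Non-randomness of each
state's destinations is tested with a Pearson chi-square of the three
destination counts against equal thirds (df = 2), computed on counts summed
over trials and participants within group × paradigm, because the test
requires counts, not averaged probabilities. Group differences per source
state use KL(autism ‖ control) on the group-averaged rows with an ε = 1e-12
floor on the reference cells (logged when triggered); the symmetric
Jensen–Shannon divergence is exported alongside since the KL direction is a
convention. Chain graphs (nodes attributed with state mean durations, edges
with probability and weight, chi-square annotations) serialise to GraphML and
DOT.

## Weighted matrices, ratio tables, bootstrap comparison

Weighted transition matrices divide each probability by its
actual-to-posterior mean duration (units s⁻¹); undefined cells propagate and
non-positive weights are flagged invalid. Ratio tables divide the autism
group's weighted matrix cell-wise by the control group's within each
paradigm: 12 candidate off-diagonal cells, asymmetric by construction,
undefined cells excluded pairwise.

The IOG-vs-CBR table difference is tested against a bootstrap null: 12 base
values evenly spaced on [0, 1] *inclusive of both endpoints* — the only
reading with 12 values, both endpoints, and mean exactly 0.5 — resampled with
replacement 10,000 times, recording each replicate's mean. The realised null
mean is 0.5 and its SD ≈ sd(base)/√12 ≈ 0.091. No convention pins down "the
difference between two tables", so three statistics are computed side by
side: mean |IOG − CBR| over jointly defined cells (primary), mean signed
difference, and max |difference|. The primary statistic is z-scored against
the null and tested two-tailed at α = 0.05, with a flag for whether it falls
inside the central 95% of the realised null. The bootstrap seed is recorded
in the output.

## Synthetic cohorts

The generator produces response streams with exactly the structure the
analysis assumes — it is a testing instrument, not a cognitive model:

* **Semi-Markov core.** Initial state uniform over the four states (trial
  onset percept is otherwise unconstrained); dwell times gamma with per-state
  shape and scale; next state from a zero-diagonal row-stochastic matrix.
  Phases accumulate until cumulative time crosses the minimum trial duration
  (default 60 s); the crossing phase is emitted at its full sampled length,
  mirroring trials that end at button release, and pre-processing later
  removes it.
* **Motor noise.** Spurious reports with duration uniform on (0, 0.18] s are
  inserted at a homogeneous Poisson rate per minute, splitting a
  duration-weighted host phase in place (total time conserved). Split points
  keep both host fragments above the cutoff, so the count of sub-180 ms
  reports stays exactly Poisson at the configured rate and the filter/merge
  rules are exercised precisely.
* **Heterogeneity.** A per-participant lognormal multiplier on dwell means
  (unit mean, configurable sd, default 0.3); AQ, EQ, and age from normal
  distributions truncated to the instrument ranges ([0, 50], [0, 80]).
* **Determinism.** One integer seed; per-participant substreams spawned from
  it, so cohorts are bit-identical across runs.

The study-scale configuration uses 17 autism + 18 control participants, both
paradigms, three contrast conditions (labels only — contrast-dependent
dynamics are not modelled), 8 trials per condition of ≥ 60 s. Group dwell
means per state and paradigm are set to the groups' reported mean durations
(autism CBR exclusive 6.7 s, piecemeal 2.8 s, superimposed 1.4 s; control
4.2 / 1.7 / 1.0 s; autism IOG 4.3 / 10.7 / 1.6 s; control 2.9 / 6.4 /
1.1 s), dwell shape 2.5 (a typical dominance-duration skew), and AQ/EQ
distributions at the demographic table means. Default transition matrices
encode exclusive percepts dissolving mostly via piecemeal, with the autism
matrices slightly biased toward mixed states; the noise rate defaults to
2/min.

What the generator does **not** emulate: serial correlation between
successive dwells, contrast-dependent dynamics, learning/adaptation across
trials, report latency (state changes and reports are simultaneous), or
eye-of-origin substructure within piecemeal. Dwells are exactly gamma, so
goodness-of-fit values on synthetic data (R² ≈ 0.99) are upper bounds that
say nothing about how well real data fit; passing tests validate the
*machinery*, not the distributional claims about real observers.

### Known estimation biases under the stopping rule

Stopping a trial at the phase that crosses 60 s and then discarding that
(length-biased) final phase leaves the remaining phases conditioned to fit
below the threshold: pooled mean durations sit a few percent (~4–5% at these
settings) below the generating means. Similarly, pooling transitions across
many stopped trials slightly over-represents destinations with short dwells
(trials that draw them fit more transitions). Both effects shrink with trial
length and are inherent to any fixed-minimum-duration design, not artifacts
of the implementation; recovery tests account for them by using sufficient
data and tolerances derived from simulation, and the transition-frequency
check samples one long sequence where the selection effect vanishes.

## Numerical choices and degenerate inputs

* Matrices are 4×4 in fixed state order (H, V, PM, SI); undefined = NaN
  everywhere; CSV exports leave undefined cells empty.
* Stochasticity checked to 1e-9; proportions sum to 100 ± 1e-6%.
* KL ε-floor 1e-12; 0·log 0 = 0.
* Chi-square with zero departures, empty clean trials, constant-x trait fits,
  and zero-variance t-tests all return flagged results instead of raising.
* Gamma/lognormal fits require ≥ 10 strictly positive samples.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at: 200 trials × 60 s for transition-matrix and
gamma-shape recovery; 500 trials for dwell-mean recovery; ≥ 10,000 sampled
transitions for frequency checks; 1,000 replicates for type-I-error and
estimator-equivalence checks; 20 seeded replicates of 4 + 4-participant
cohorts for the directional group comparison; and one full study-scale cohort
(35 participants × 2 paradigms × 3 conditions × 8 trials) for the end-to-end
acceptance run. These sizes give Monte-Carlo error comfortably below the
assertion tolerances while keeping the whole suite under a minute.

## Limitations

Markov transition probabilities are memory-free by construction; the package
deliberately does not model cumulative perceptual history, higher-order or
variable-length chains. The chi-square test on pooled counts treats
transitions as exchangeable across participants. Printed-scale comparisons
with any particular empirical dataset require that dataset; synthetic cohorts
demonstrate correctness of the computations and the direction of configured
group effects only.
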