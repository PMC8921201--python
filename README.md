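# rivaldyn

Analysis of perceptual multistability dynamics from button-press response
streams — binocular rivalry and interocular grouping experiments — for visual
psychophysicists and computational neuroscientists.

When dissimilar images are shown to the two eyes, perception alternates among
four principal states: exclusively horizontal (H), exclusively vertical (V), a
piecemeal patchwork (PM), and a superimposed plaid (SI). Observers report
their percept continuously by holding one of four buttons. `rivaldyn` turns
those raw report streams into the field's standard dynamics measures and a
Markov-chain characterisation of state-to-state transitions, and ships a
semi-Markov generator of synthetic cohorts so the entire pipeline can be
exercised and validated without participant data.

## What it computes

**Pre-processing.** Per trial: the truncated final report is dropped, reports
≤ 180 ms are removed as motor noise, and runs of consecutive identical states
are merged into single phases.

**Basic statistics.** Per-state relative proportions (%) and mean phase
durations (s); *full flips* (direct H↔V changes) and *half flips* (all other
changes); hierarchical aggregation (trials → participant → group) and
pooled-variance two-tailed independent t-tests between groups; OLS trait
correlations (AQ/EQ vs. rivalry measures) with a one-sample t-test on the
slope.

**Phase distributions.** Exclusive phase durations, normalized per subject ×
condition and pooled, are fitted by maximum likelihood with the gamma density

    f(x | α, β) = x^(α−1) e^(−x/β) / (β^α Γ(α)),   x > 0,

(and a lognormal comparison fit). Reported per fit: shape α, scale β, event
count N, R² against a fixed-bin histogram, the density peak (mode
x* = (α−1)β for α > 1), and trapezoidal AUC over x ∈ [0.18, 4].

**Markov dynamics.** Per-trial transition MLEs (adjacency counts, row
normalised, structural zero diagonal), actual-to-posterior weights (mean
duration of state i immediately before changing to state j), hierarchical
averaging over defined cells, a chi-square test of each state's destination
counts against the uniform null (1/3 each), Kullback–Leibler divergence
between group transition rows, and chain-graph export (GraphML/DOT).

**Group comparison.** Weighted transition matrices (probability ÷ weight,
s⁻¹), autism/control ratio tables per paradigm, and a bootstrap z-test of the
difference between the two paradigms' tables against a null of resampled
means of 12 evenly spaced values on [0, 1].

## Worked example

```python
import numpy as np
from rivaldyn import (study_config, simulate_cohort, preprocess_trials,
                      normalize_phases, fit_gamma)
from rivaldyn.stats import (trial_summary_table, participant_summary,
                            group_comparison_table)
from rivaldyn.markov import group_paradigm_aggregates, kl_table

cfg = study_config(seed=42, n_autism=6, n_control=6, trials_per_condition=4)
trials, meta = simulate_cohort(cfg)
cleans = [c for c in preprocess_trials(trials) if not c.is_empty]
part = participant_summary(trial_summary_table(cleans))

tests = group_comparison_table(part)
row = tests[(tests.paradigm == "CBR") & (tests.measure == "mean_dur_exclusive")].iloc[0]
print(f"CBR mean exclusive duration: autism {row['mean_autism']:.1f} s "
      f"vs control {row['mean_control']:.1f} s, t({row['df']}) = {row['t']:.2f}, "
      f"p = {row['p']:.4f}")

norm = normalize_phases(cleans)
x = norm[(norm.group == "control") & (norm.paradigm == "CBR")]["x"].to_numpy()
fit = fit_gamma(x)
print(f"Gamma fit (control, CBR): shape {fit.shape:.2f}, scale {fit.scale:.2f}, "
      f"N = {fit.n_events}, R^2 = {fit.r_squared:.2f}, peak x = {fit.peak_x:.2f}")

agg = group_paradigm_aggregates(cleans)
print("P(PM -> .) autism CBR:", np.round(agg[("autism", "CBR")]["probabilities"][2], 2))
```

prints

```
CBR mean exclusive duration: autism 5.0 s vs control 4.3 s, t(10) = 0.69, p = 0.5042
Gamma fit (control, CBR): shape 2.59, scale 0.39, N = 805, R^2 = 0.99, peak x = 0.61
P(PM -> .) autism CBR: [0.38 0.35 0.   0.27]
```

The t-test compares the groups' per-participant mean exclusive durations on
the conventional binocular rivalry paradigm (df = n₁ + n₂ − 2 = 10 for this
small demonstration cohort; the simulated autism group dwells longer on
average). The gamma fit describes the 805 pooled normalized exclusive phases
of the control group — unit mean by construction, mode near 0.6 — and the PM
row of the autism transition matrix shows piecemeal resolving to either
exclusive percept roughly symmetrically, never to itself (structural zero).

The same analyses are available from the shell:

```
rivaldyn run --config config.yaml --seed 1 --out outdir
```

which writes tidy CSVs, labelled matrices, GraphML/DOT chain graphs, a
`table_comparison.json`, a collated `report.json` and a `manifest.json`
recording the config snapshot, seed and per-stage record counts.

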