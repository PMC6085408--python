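# bingedbs

Resting ventral-striatal LFP features and deep-brain-stimulation (DBS)
outcome classification in a rat binge-eating model — implemented as a
reusable, tested pipeline driven entirely by synthetic data.

DBS of the nucleus accumbens (NAc) core or shell can suppress binge-like
feeding, but outcomes vary strongly across individuals, and the animals
that respond to one target are often not the ones that respond to the
other. This package implements the analysis chain that asks whether
*resting* network activity — recorded without stimulation — carries enough
information to classify who responds where:

1. **Spectral features.** Each 4-channel resting LFP session (bilateral
   NAc core and shell) is reduced to 60 features: 24 band powers
   (6 bands × 4 channels, log10) and 36 band coherences (6 bands ×
   6 channel pairs), estimated by Welch averaging over rest intervals.
2. **Responder labels.** Binge size per session is normalized to percent
   change from the animal's baseline average; pooled baseline variation
   (SD ≈ 13 %) sets a 2-SD meaningful-change threshold (≈ 26 %). A rat is
   a responder to a target iff all three stimulation sessions beat the
   threshold; the optimal target is the responding target with the larger
   mean reduction.
3. **Classification.** L1-penalized (lasso) logistic regression under
   animal-grouped, stratified 4-fold cross-validation with 100
   repetitions, for three models: core R/NR, shell R/NR, core-vs-shell.
   Chance level comes from animal-level label permutations; observed and
   permuted accuracy distributions are compared by Mann-Whitney U,
   converted to a Cohen's d (z → r → d). Features are ranked by lasso
   survival (% of fold models with nonzero coefficient) and by univariate
   leave-one-animal-out logistic accuracy, with direction arrows.
4. **Synthetic cohorts.** A linear band-limited mixing model generates
   LFPs with *analytically known* band coherence — group differences are
   planted power-neutrally in chosen (pair, band) coherences — and a
   normal intake model generates binge tables with 13 % session-to-session
   variation and per-animal stimulation effects. The generator's closed
   forms are the test oracles for the whole chain.

See `docs/methods.md` for the model equations, defaults and limitations.

## Worked example

Run the full chain on a synthetic demo cohort (6 + 6 animals, 2 sessions
each, one planted coherence difference between the core-responsive and
shell-responsive groups):

```bash
bingedbs run-all --seed 7 --out demo_run
```

which ends by printing the rendered report (abridged):

```
Response profiles (n=12): 5 core-only, 6 shell-only, 0 both, 1 neither (11 single-target)

== Model: core ==
mean accuracy 74% (SD ± 12%) vs permuted 58% (SD ± 8%), d = 1.49
  top features by % survival (lasso):
    ↑ Cclcr hγ     74
    ↑ Psl θ        15
    ...
  stability: Cclcr hγ within/between ratio 0.11 — stable discriminative feature

== Model: core-vs-shell ==
mean accuracy 100% (SD ± 0%) vs permuted 51% (SD ± 6%), d = 2.44
  top features by % survival (lasso):
    ↑ Cclcr hγ     100
    ...
```

Reading this: the cohort's response profile is counted from the simulated
intake tables (11 of 12 animals responded to exactly one target); each
model's observed cross-validated accuracy is shown against its own
permutation null with the U-derived effect size; `Cclcr hγ` — high-gamma
coherence between left and right NAc core, the feature the generator
actually planted — tops the survival ranking with an upward arrow
(higher in the core-responsive group), and its session-to-session drift is
~10× smaller than the group separation, marking a stable discriminative
feature.

Each stage is also available separately (`simulate`, `features`,
`outcomes`, `classify`, `report`) on intermediate CSV/JSON artifacts, and
everything is importable from Python:

```python
import bingedbs as bd

spec = bd.CohortSpec(n_per_group=12,
                     planted_effects=(bd.PlantedEffect("coherence", ("cl", "cr"), "hγ", 0.4),))
cohort = bd.simulate_cohort(spec)
table = bd.features_to_frame(
    bd.extract_feature_vector(c.recording, animal_id=c.animal_id, session_id=c.session_id)
    for c in cohort)
dm = bd.make_design_matrix(table, {c.animal_id: int(c.group == "R") for c in cohort})
cv = bd.fit_lasso_repeated_cv(dm, reps=100, seed=0)
print(cv.mean, cv.survival_pct.nlargest(3))
```

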