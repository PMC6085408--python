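# Methods

`bingedbs` implements, as a tested pipeline on synthetic data, an
analysis linking resting ventral-striatal local field potentials (LFPs) to
deep-brain-stimulation (DBS) outcomes in a rat binge-eating model. This
note documents the models, the defaults and why they were chosen, and what
the synthetic generator does and does not emulate.

## Synthetic LFP model

Each session is a 4-channel time series (bilateral nucleus accumbens core
and shell: `cl, cr, sl, sr`). Within every frequency band *b*, channel *c*
receives a linear mixture of independent band-limited unit-variance
Gaussian sources plus independent broadband Gaussian noise:

    x_c(t) = Σ_b σ_s(b) · G_b[c,:] · s_b(t) + e_c(t)

Sources are produced by brick-wall (zero-phase) spectral masking of white
noise. The mask extends up to 0.5 Hz beyond each band edge — capped at
half the gap to the neighboring band — and the realization is normalized
so the variance inside the nominal band edges is exactly one. The padding
exists because a Welch frequency bin sitting exactly on a band edge
otherwise sees a half-cut source spectrum, which biases band-averaged
coherence downward by up to 0.05; with locally flat source power at the
edges the band-averaged estimate matches the closed form below.

Because the in-band spectra are flat, the expected magnitude-squared
coherence of channels *c, d* in band *b* is available in closed form from
the signal covariance `C = σ_s² G_b G_bᵀ` and the in-band noise power
`n_c = σ_e,c² · bandwidth / nyquist`:

    coh(c,d;b) = C[c,d]² / ((C[c,c] + n_c) (C[d,d] + n_d))

This analytic table rides along with every simulated recording and is the
oracle the Welch estimator is tested against.

### Cohorts and planted effects

`simulate_cohort` builds two groups of animals. Per band the source layout
is: one globally shared source (setting a baseline pairwise coherence,
default 0.15), one dedicated source per planted coherence effect shared by
exactly the named channel pair, and per-channel private sources. A planted
coherence difference (default +0.4 on one pair/band for the second group)
trades private variance for pair-shared variance, so per-channel band
power is unchanged — the effect is *power-neutral* and appears only in the
targeted coherence feature. Power effects instead scale one channel's
gains in one band (log10 units).

Per-animal mixing matrices are drawn once (multiplicative entry-wise gain
heterogeneity, SD 5 %) and re-jittered per session (SD 5 %), so planted
group differences are stable across an animal's two sessions — the
within-animal session drift of the planted feature is small against the
between-group difference, which the stability report quantifies.

Defaults: 1000 Hz sampling, 120 s per session, 2 sessions per animal,
broadband noise SD 1, per-channel in-band signal power 1. At these
settings the planted +0.4 coherence shift is roughly 15 within-group SDs
of the estimated feature, comfortably beyond the ≥3 SD regime the recovery
analysis assumes.

### What the generator does not emulate

No 1/f background, no mains interference, no stimulation or movement
artifacts, no non-stationarity within a session, no volume conduction, and
rest intervals cover the whole recording by default. Passing tests
therefore show that the *analysis chain* is correct and calibrated — not
that real accumbens recordings carry outcome information.

## Spectral features

Rest intervals (seconds, half-open) are merged, clipped, converted to
sample ranges (start rounded up, stop down) and dropped below 4 s. Welch
estimation uses 2 s Hamming windows, 50 % overlap, per-window linear
detrend; windows never span gaps between rest segments — per-segment
spectra are pooled weighted by window count. Coherence with fewer than two
windows total is refused (the estimator is identically 1 there).

A session yields `B·(C + C(C−1)/2)` features — 60 for 4 channels and the
six rodent bands Δ 1–4, θ 5–10, α 11–14, β 15–30, lγ 45–65, hγ 70–90 Hz.
Exact band edges vary across labs; these are conventional rodent choices,
fully configurable, and recorded in every output. Band power is log10 of the mean in-band density
(variance stabilization for the regressions); coherence is the untransformed
in-band mean. Names follow `P<ch> <band>` / `C<ch><ch> <band>` with pair
channels normalized to scheme order. A 60 Hz notch is off by default
(synthetic data has no mains); interval gating is the only artifact
handling.

## Binge outcomes

Session intake is expressed as percent change from the animal's average
baseline intake. The meaningful-change threshold is twice the SD of the
pooled baseline percent-change distribution; at the emulated
session-to-session CV of 13 % this is the 26 % rule. Because each
observation is centered on its own animal's *observed* baseline mean,
the pooled SD estimator uses `N − n_animals` degrees of freedom —
without this correction 3-session centering shrinks the estimate by
√(2/3). The normal fit reports an R² against a Freedman–Diaconis-binned
empirical density.

An animal is a **responder** to a target iff all three stimulation
sessions show reductions strictly beyond the threshold. Consistent
increases beyond +threshold — which do occur with shell stimulation in
this paradigm — are flagged as paradoxical but never count as response.
The **optimal target** is the responding target with
the larger mean reduction; exact ties (impossible in continuous data)
break toward core with a logged warning; animals responding to neither
target are excluded from target classification.

The intake generator draws baseline sessions i.i.d. normal around a
per-animal mean (between-animal CV 0.2, emulating known animal-to-animal
binge-size variation) with session SD = 13 % of that mean; stimulation
sessions shift the mean by a per-animal, per-target percent effect; draws
below zero clip to zero with a logged count. When exact responder calls
are needed (e.g. regenerating published response-profile counts through
the intake chain), the responder effect is set to −80 %: with session
noise of ~13.5 % including baseline-mean estimation error, the per-session
miss probability is ~3·10⁻⁵, making the resulting counts effectively
deterministic at any seed. The default demo effect is a milder −60 %.

## Outcome classification

The design matrix has one row per animal-session (both sessions of an
animal, same label). The classifier is L1-penalized logistic regression
under stratified 4-fold cross-validation repeated 100 times. Folds are
**animal-grouped**: all sessions of an animal share a fold, because
session-level folds would let a test session's twin appear in training.
Within each training fold, features are standardized from training rows
only, and the penalty is chosen by an inner animal-grouped 4-fold CV over
a 7-point logarithmic grid (C = 10⁻²…10¹) at minimum held-out deviance,
ties toward the stronger penalty. Held-out accuracy is pooled over the
k folds of a repetition at a 0.5 probability cutoff. Feature **% survival**
is the percentage of fitted fold models (reps × k) in which the feature
keeps a nonzero coefficient; constant features are centered to zero and can
never be selected.

Chance performance comes from animal-level label permutations (marginals
preserved; all sessions move with their animal) with the entire repeated
CV rerun per permutation — 10 permutations by default, as a coarse null;
≥100 is recommended when runtime allows. Observed and pooled permuted
accuracy distributions are compared with a Mann-Whitney U test (midranks,
tie-corrected normal σ) and the statistic converted to Cohen's d via

    z = (U − n₁n₂/2)/σ_U,  r = z/√(n₁+n₂),  d = 2r/√(1−r²)

with d > 0 when the observed distribution stochastically dominates. The
conversion route is a documented choice (the effect-size literature has
several); it is exercised against brute-force rank computation for all
sample sizes up to 6.

Per-feature information content uses single-feature logistic fits under
exhaustive leave-one-animal-out CV. Fits carry a very light ridge
(C = 10⁶) so separated training splits remain well-defined; accuracy is
the mean over splits, and the direction arrow is the sign of the class-1
minus class-0 feature mean. Rankings (top-5 by univariate accuracy and by
lasso survival) break ties by the other metric, then by name.

## Pipeline

`run_pipeline` chains simulate → features → outcomes → classify → report
into a run directory, with a resolved-config YAML, per-stage artifacts
(recordings CSV+JSON sidecar, feature CSV, intake CSV, labels JSON,
report JSON/TXT) and stage-named error reporting. Reruns with the same
config are file-identical. Three model types are fitted: core responder
vs non-responder, shell responder vs non-responder, and optimal-target
core vs shell.

## Numerical and scale choices

- Liblinear solver, tol 10⁻⁴, deterministic under fixed seeds; all
  stochastic steps take explicit seeds and derive per-repetition streams.
- The analytic-coherence agreement check compares the estimate averaged
  over 8 independent 60 s recordings against the closed form at ±0.05. A
  single 60 s recording cannot support a per-value 0.05 bound in the
  narrowest band: the 1–4 Hz band offers ~360 degrees of freedom in 60 s,
  an estimator-SD floor of ~0.04 at coherence 0.25, so the averaged
  estimate is what meaningfully tests estimator correctness.
- Calibration and recovery analyses run at: null calibration 6+6 animals ×
  2 sessions × 120 s, 100 repetitions, 10 permutations; planted-effect
  recovery 12+12 animals × 2 sessions × 60 s, 40 repetitions,
  4 permutations, 10 replicate cohorts. These sizes keep the full chain
  (simulation through permutation nulls) at desk scale.

## Known limitations

- The linear mixing model has flat in-band spectra and zero-phase
  coupling; real LFP coherence varies within bands and carries phase lags.
- With ~12 animals per class, repeated-CV accuracy distributions are
  coarse (steps of 1/24); Cohen's d between observed and permuted
  distributions is the designed summary, not a calibrated p-value.
- The univariate logistic accuracies are in-sample with respect to feature
  *selection* (every feature is scored); they rank features and should not
  be read as honest generalization estimates.
- The 10-permutation default mirrors a coarse null; effect sizes beyond ~3
  saturate (complete separation of observed and permuted accuracies).
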