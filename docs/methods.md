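# Methods

## The problem and the estimand

Two discs differ in diameter by 0.5 mm (40.0 vs 40.5 mm) — below most
observers' just-noticeable difference. Each trial yields a dichotomous
perceptual judgement (is the front object larger or smaller than the back
one?) and a continuous visuomotor measure, the maximum grip aperture (MGA)
of the grasp directed at the front object. Comparing "the hand" with "the
observer" requires a common scale. The package's central statistic, the
optimal cut-off proportion (OC%), maps the continuous measure onto the
dichotomous one: classify every MGA strictly above a threshold as "big
object", at or below it as "small object", choose the threshold that
maximises the proportion correct, and report that proportion.

Properties that matter for interpretation:

- **Completeness of the candidate grid.** Accuracy as a function of the
  threshold is piecewise constant, changing only at observed values, so the
  midpoints between consecutive distinct pooled values plus the two
  degenerate extremes (everything-small / everything-big) exhaust all
  achievable accuracies. The implementation searches exactly this finite
  grid; a test proves equality with exhaustive search over every
  pooled-value interval.
- **Tie-break.** Among equally good thresholds the smallest is returned.
  The reported proportion is tie-invariant; only the serialised `cutoff_mm`
  depends on the convention. Degenerate extremes serialise as pooled
  min − 1 / max + 1.
- **Fixed direction.** The rule is "above → big" for everyone. A
  participant whose apertures scale inversely with size floors at
  max(n_small, n_big)/n rather than being rescued by flipping labels — the
  question is whether the aperture carries size information in the
  direction grasping implies, not whether any labelling performs well.
- **In-sample optimism.** The threshold is optimised on the trials it
  classifies, so OC% is biased upward; it deliberately favours the motor
  measure. For two equal-variance Gaussian classes `delta` apart with SD
  `sigma` and balanced trials, the ideal threshold achieves
  `Phi(delta/(2*sigma))`; measured in-sample OC% exceeds this by ≈ +0.052
  at 48 trials per class and ≈ +0.058 at 36 (Monte-Carlo, ~flat in `delta`
  over the relevant range). `crossvalidated_cutoff` (leave-one-out)
  removes the optimism and lands below the ideal value; the two estimates
  bracket it.

OC% is computed per participant, pooling trials across experimental blocks
within a vision condition (a single OC% per participant per condition); a
`per_block` mode computes block-wise cut-offs and averages the proportions,
since block-wise fitting is a defensible alternative reading and the two
differ systematically (more fitted thresholds → more optimism).

## Inference

The ANOVA operates on per-participant cell means of MGA (size ×
judgement-correctness × block, or × vision), never trial-level data, so
unequal trial counts per cell are irrelevant once cells are non-empty.
Participants with an empty cell — typically someone who never misjudged a
size in some block, which happens generically at ~0.69 accuracy and 16
trials per size/block — are excluded from the ANOVA but kept in the OC%
analysis; both sets are tracked explicitly.

The fully-within decomposition projects the subjects × cells matrix onto
orthonormal Kronecker contrasts (Helmert for factors in the effect, the
normalised unit vector for collapsed factors). With contrast scores `Z`
(subjects × df): `SS_effect = n·‖mean(Z)‖²`, `SS_error = Σ‖Z_i − mean(Z)‖²`,
each effect tested against its own effect-by-subject interaction,
`η_p² = SS_effect/(SS_effect+SS_error)`. This reproduces classical sums of
squares exactly on balanced designs (verified against statsmodels'
`AnovaRM` to 1e-8, and against the paired-t identity `F = t²` to 1e-10 for
single-df effects). For effects involving a factor with more than two
levels, Greenhouse–Geisser epsilon is estimated from the covariance of the
contrast scores (`ε = tr(S)²/(df·tr(S²))`, clipped to [1/df, 1]) and both
uncorrected and corrected p are reported — whether the original analyses
corrected the 3-level block factor is unknowable from the published text,
so both readings are emitted. Follow-ups are Bonferroni-corrected paired
t-tests (`p_adj = min(1, p·family)`), with per-condition t-based 95% CIs;
normality of paired differences is checked with Shapiro–Wilk (scipy's
implementation; constant input raises rather than pretending a W value).

## Generative model

One latent estimate links perception and action. Participant *i* forms
noisy internal sizes for both objects, `ŝ = s + ε`, `ε ~ N(0, σ_p,i)`
independently per object; the verbal response compares the two estimates,
giving accuracy `Phi(0.5/(σ_p√2))`. The aperture blends the perceived and
true front size with weight `w`:

    MGA = a_i + k·(w·ŝ_front + (1−w)·s_front − s̄) + N(0, σ_m,i)

with `s̄ = 40.25` mm so `a_i` is the participant's mean MGA. `w > 0`
concentrates the aperture size effect in correct-judgement trials (the
size-by-report interaction regime); `w = 0` yields a pure size main effect
independent of the report. Conditional on true size,
`σ_total² = k²w²σ_p² + σ_m²`, so the ideal dichotomisation accuracy is
`Phi(k·0.5/(2σ_total))`. Baselines are normal across participants
(SD 5 mm), noise SDs lognormal (log-SD 0.25 for σ_p, 0.15 for σ_m) — the
heterogeneity that gives per-participant OC% and verbal accuracy realistic
spread and makes empty ANOVA cells occur at realistic rates. Sizes and
distractor positions are counterbalanced within blocks; identical config
and seed give byte-identical output.

### Calibrated presets

| preset | n | trials | verbal acc. | k (mm/mm) | w | mean MGA |
|--------|----|--------|-------------|-----------|-----|----------|
| E1 | 29 | 96 (3 blocks) | 0.690 | 1.8 | 0.5 | 83.0 mm |
| E2 | 26 | 96 (3 blocks) | 0.667 | 1.6 | 0.0 | 70.5 mm |
| E3 | 30 | 144 (3 closed + 3 open blocks) | 0.700 | 1.7 | 0.5 | 81.6 mm |

`σ_p` is solved (quadrature + root-finding) so the *population-mean* verbal
accuracy under the lognormal spread equals the target; `σ_m` is solved so
the expected *measured* in-sample OC% equals the target 0.58/0.59/0.58 —
i.e. ideal accuracy = target − frozen optimism (0.528/0.538/0.522). The
slopes reproduce the observed 0.8–0.9 mm aperture difference for the 0.5 mm
size step. The implied motor noise (σ_total ≈ 4–6.5 mm) is the model's
way of saying what the OC% data say: the aperture is a noisy readout of
size. The open-loop condition adds +5 mm aperture and scales σ_m by 1.4
(typical effects of removing visual feedback during the reach; the
magnitudes are modelling choices, as no summary of them is printed).

What the generator does **not** emulate: Weber-law scaling of aperture
variability, block-order or learning effects (block is a pure label, since
no block effect was found), trial-to-trial sequential dependence,
approach-angle or digit-placement strategy, and any perception–action noise
*correlation* beyond the shared estimate (real coupling strength is only
constrainable from deposited raw data). Passing calibrated-simulation tests
therefore shows the analysis machinery behaves correctly under a model with
the published moments — not that the model is the true data-generating
process.

### Kinematic traces

Synthetic reaches place two markers (thumb, index) symmetrically about a
random hand position; the aperture opens from a 20 mm pinch to the
programmed peak at 65% of an 0.8 s movement and closes onto the object,
with half-cosine segments (zero-slope joins ⇒ the analytic maximum equals
the programmed MGA exactly). Extraction: optional linear interpolation of
dropout gaps ≤ 3 samples, 4th-order zero-lag Butterworth low-pass at 10 Hz
on marker coordinates (bypassable), Euclidean distance, reach window from
start-button release to the first settling of the aperture within 2 mm of
its final-contact value for 100 ms (capped at the last sample), maximum
over the window, ≥ 3 usable samples required. The segmentation and filter
rules are declared conventions — the source studies do not state theirs —
and every constant is configurable. Recovery of the programmed peak is
< 0.1 mm at both 50 and 100 Hz.

## Fallacy grid

`fallacy_simulation` strips the situation to its core: two Gaussian classes
`delta/sigma` apart, n trials per participant, paired mean-difference test
across participants versus mean in-sample OC% and leave-one-out accuracy.
A replication falls in the *fallacy region* when the mean difference is
significant yet mean OC% < 0.6. At the calibrated effect size
(`delta/sigma ≈ 0.19`) the majority of replications land there: a
textbook-significant effect coexisting with near-chance classification is
the generic outcome, not a quirk.

## Numerical and scale choices

- Test-suite problem sizes: 10,000 instances for the cut-off/brute-force
  equivalence, 2,000 null simulations for ANOVA type-I calibration, 500
  replications (4 participants each) for parameter recovery, 200
  replications of the 30-participant two-class design for the dissociation
  check — sizes at which Monte-Carlo error is well inside the asserted
  tolerances.
- Parameter-recovery CIs: t-based OLS intervals for the slope (exact under
  the model); Wilson intervals on verbal accuracy, monotonically
  transformed to σ_p (`σ_p = 0.5/(√2·Φ⁻¹(acc))`, with accuracy bounds ≤ 0.5
  or ≥ 1 mapping to infinite/zero endpoints).
- `paired_t` zero-variance conventions: all-zero differences → t = 0,
  p = 1; zero variance with non-zero mean → signed infinite t, p = 0,
  logged.
- Missing MGA is a data feature, not an error: such trials stay valid for
  verbal accuracy and are excluded from MGA-based analyses.
- Reported OC% summary SDs are across participants. (A published
  closed-loop OC% SD of 0.42 alongside open-loop 0.042 is almost certainly
  a typo for 0.042; the package reports what it computes and takes no
  position in its outputs.)

## Known limitations

- OC% inherits the granularity of small samples: with 36–48 trials per
  class its per-participant distribution is discrete; population-level
  comparisons (paired t across participants) are the intended use.
- The ANOVA path requires complete cells by design; datasets where most
  participants lack incorrect-judgement trials (very easy discriminations)
  will legitimately shrink the eligible sample — that is the published
  exclusion rule, not a defect.
- Replication against deposited raw data depends on unstated analysis
  details (OC% pooling, sphericity handling, trial-validity criteria); the
  pipeline exposes each as a config variant rather than guessing one.
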