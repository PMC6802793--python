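# gripdisc

Does the hand "know" object size better than the observer does? A classic
argument for distinct vision-for-action and vision-for-perception systems
runs: present two discs differing by only 0.5 mm (40.0 vs 40.5 mm); verbal
judgements of which is bigger hover near chance, yet the maximum grip
aperture (MGA) of grasps directed at them differs *significantly* between
the two sizes — so the motor system must have access to finer size
information. The catch is that this compares a dichotomous measure
(proportion of correct judgements) with a mean difference in a continuous
one. Scots are on average ~2 cm shorter than Englishmen, yet guessing
nationality from height alone fails constantly: a significant mean
difference does not imply good classification.

`gripdisc` implements the analysis that puts both measures on the same
footing, for researchers in motor control and psychophysics:

- **OC% (optimal cut-off proportion)** — dichotomise each participant's
  MGAs at the accuracy-maximising threshold (aperture above the cut-off →
  "big object") and report the proportion correct. Because the threshold is
  optimised on the data it classifies, OC% is biased *upward* — it favours
  the motor measure — and a leave-one-out variant quantifies that optimism.
  For two equal-variance Gaussian classes `delta` apart with SD `sigma`,
  the ideal threshold achieves `Phi(delta / (2*sigma))`.
- **Fully-within repeated-measures ANOVA** on per-participant MGA cell
  means over object size × judgement correctness × block (or × vision
  condition), with partial eta squared, Greenhouse–Geisser reporting and
  Bonferroni-corrected pairwise follow-ups.
- **A generative perception→action model** in which one noisy internal
  size estimate drives both the verbal response and (with weight `w`) the
  grip aperture: `MGA = a_i + k·(w·ŝ + (1−w)·s − s̄) + ε_m`. It synthesises
  complete experiments — trial tables and two-marker kinematic traces —
  with calibrated presets, plus a grid simulator for the
  significant-mean-difference-vs-chance-classification fallacy.
- **Kinematics**: grip aperture from thumb/index 3D marker trajectories
  (Euclidean distance, zero-lag low-pass filtering, dropout interpolation)
  and MGA extraction over the reach.

## Worked example

```python
import gripdisc as gd

cfg = gd.calibrate_to_paper("E1", seed=11)       # 29 participants, 96 trials
records = gd.generate_experiment(cfg)
report = gd.run_experiment_analysis(records, "E1")

print(report.occ_summary[["condition", "verbal_mean", "occ_mean"]])
print(report.paired_tests[["condition", "t", "df", "p"]])
row = report.anova.set_index("effect").loc["size x verbal"]
print(f"size x verbal: F({row['df_effect']:.0f},{row['df_error']:.0f}) = "
      f"{row['F']:.2f}, p = {row['p']:.4f}, eta_p^2 = {row['partial_eta_sq']:.2f}")
```

prints

```
  condition  verbal_mean  occ_mean
0       all     0.686063  0.581897
  condition         t  df             p
0       all  7.825395  28  1.593846e-08
size x verbal: F(1,28) = 10.03, p = 0.0037, eta_p^2 = 0.26
```

Verbal judgements are right ~69% of the time, while classifying the target
size from the grip aperture — even with the threshold chosen *after the
fact* to maximise accuracy — succeeds only ~58% of the time; the paired
t-test shows the perceptual measure is reliably the better classifier. At
the same time the ANOVA finds a strong size-by-judgement interaction: the
aperture tracks the object's size mainly on trials where the observer also
judged it correctly. A significant aperture effect and near-chance motor
classification coexist in the same dataset.

The same analyses run from the shell:

```
grip-disc simulate --design e2 --seed 4 --out sim/
grip-disc occ --trials sim/trials.csv --out occ.csv
grip-disc anova --trials sim/trials.csv --design e2 --out anova.csv
grip-disc run --config run.yaml
grip-disc fallacy --out grid.csv
```

Real data enter as tidy CSV trial tables (schema in
`gripdisc.trial_data.COLUMNS`, with a column-remapping config for foreign
headers) or as plain-text marker trajectories via
`grip-disc extract-mga`.

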