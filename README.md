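# foragebold

Simulation and analysis tooling for dissociating two reward signals in a
cued foraging task: the **reward prediction error** generated when an
informative cue changes the expectation of upcoming reward, and the **mean
reward rate** sustained while reward is being harvested.  The package is
aimed at model-based fMRI methodologists who want a fully synthetic,
end-to-end testbed — task timing, a reinforcement-learning simulator,
haemodynamic design matrices, phantom BOLD cohorts, GLM estimation and
permutation-corrected group inference — in which every planted effect is
known exactly.

## The task and the model

Each run holds 12 trials: a 2 s coloured cue announcing the reward level of
the trial (1 or 20 cents per hit), a 3 s interval, a 14.5 s *foraging patch*
in which lateralised targets appear (bounded-exponential spacing on
300–1800 ms with mean 1220 ms, or regular 1250 ms spacing), and a 10 s
pause — 354 s in total.  Reward levels alternate at random (informative
cues) or strictly regularly (fully predictable cues).

The model is undiscounted tabular TD(0).  With states s_t, rewards r_t and
state values V(s_t) = E[r_t + r_{t+1} + …], each visited state is nudged by
a fraction α of the one-step prediction error

    δ(s_t) = V(s_{t+1}) − V(s_t) + r_t .

After learning, δ spikes at informative cues (positive for high-reward,
negative for low-reward trials) and hovers around zero inside the patch,
where the *consistency condition* r_t = V(s_t) − V(s_{t+1}) holds: the
reward stream is carried by the differential valuation of successive
states, not by changes in expectation.  The same identity holds for
state–action values under the optimal policy,
r_t = Q(s_t,a_t) − Q(s_{t+1},a_{t+1}).  BOLD-level consequences follow by
convolving δ and r impulse trains with a canonical double-gamma
haemodynamic response: cue contrasts (high vs. low) detect prediction-error
differences, patch contrasts detect reward-rate differences.

The synthetic cohort generator plants exactly this logic in a voxel
phantom: a cue effect in a "VS" (ventral striatum) box and a patch effect
in a "VTA_SN" (midbrain) box, with AR(1) temporal noise, Gaussian spatial
smoothing and between-subject amplitude variability.  Analysis mirrors the
standard pipeline: voxelwise GLM with pooled AR(1) prewhitening, per-subject
contrasts, random-effects second level, and max-statistic permutation
correction (peak and cluster level, sign-flip or group-relabelling null),
whole-volume or within ROI boxes such as the ventral-striatum box
(x −12…+12, y 0…+12, z −12…+6 mm; 5184 mm³).

## Worked example

```sh
$ foragebold schedule --experiment 1 --seed 7 --out events.tsv
wrote events.tsv: 12 trials, 354.0 s, 139 targets

$ foragebold tdsim --experiment 1 --seed 7 --out trace.tsv
wrote trace.tsv: 12400 steps, trained 10000 trials (converged=False); patch mean delta 0.0109
```

The schedule is the expected 6-minute run; the trained model's prediction
error averages 0.01 cents across foraging steps — the consistency condition
at work (the `converged` flag refers to the stochastic-chain update norm,
which cannot reach the deterministic tolerance; patch-state values are at
their fixed point).  An end-to-end scenario on the Experiment-1 preset
(35 subjects, TR 2.46 s, 8 mm smoothing, 500 resamples):

```python
>>> from foragebold import pipeline
>>> rep = pipeline.run_scenario(pipeline.experiment_preset(1, n_perm=500, seed=7, run_td=False))
>>> rep.detected
{'cue_high_gt_low': True, 'patch_high_gt_low': True}
>>> print(rep.tables["patch_high_gt_low"].to_string(index=False))
 cluster     x     y     z   k  p_cluster         t   p_peak
       2  16.5 -13.5 -10.5 691   0.001996 13.540303 0.001996
       3  -7.5   1.5   7.5   4   0.536926  4.014450 0.465070
       1 -25.5  13.5 -25.5   3   0.654691  4.011240 0.471058
       4   4.5 -19.5  19.5   3   0.654691  3.820067 0.636727
```

The planted midbrain patch effect comes back as a large cluster (peak t =
13.5, corrected p = 0.002, the floor for 500 resamples); the remaining rows
are sub-threshold noise clusters.  Columns mirror the conventional cluster
table: peak coordinates (mm), extent k (voxels), cluster- and peak-level
corrected permutation p-values.

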