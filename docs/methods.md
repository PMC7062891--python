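# Methods

## Task model

A run is a fixed sequence of trials, each cue (2 s) → interval (3 s) →
foraging patch (14.5 s) → pause (10 s); 12 trials give 354 s.  Rewards are
1 or 20 cents per hit.  Two generators of trial-level structure are
configurable: reward-level alternation (`random_balanced`, a seeded
permutation with equal counts, or `regular`, strict alternation starting
low by default) and target spacing (`irregular` or `regular`).

Irregular inter-target intervals follow an exponential density truncated to
[300, 1800] ms.  Only the bounds and the mean (1220 ms) are fixed by the
design, so the rate is calibrated by scalar root-finding on the closed-form
truncated mean.  Because 1220 ms lies *above* the midpoint of the support,
the calibrated rate is negative (an increasing density); the sampler uses
the analytic inverse CDF, which is valid for either sign.  Targets are
packed into each patch starting one interval after patch onset until the
next onset would pass the patch end; the final partial interval is simply
censored at the boundary.  Sides are independent fair coin flips.  With a
patch shorter than the minimal interval the schedule warns and leaves the
patch empty rather than failing.

## TD(0) simulator

The trial is approximated by a finite chain: pre-cue context, cue,
interval, one 250 ms slot per model step of the patch (a *target* episode
carrying the trial's reward if a target lands on the slot — onsets are
rounded to the nearest slot — otherwise a *non-target* episode), pause, and
a terminal state pinned to zero, as the undiscounted episodic setting
requires.  The 250 ms grain keeps at least one empty slot between targets
at the 300 ms minimum spacing.

Learning is tabular TD(0) with γ = 1: V(s) ← V(s) + α·δ, α defaulting to
0.1.  Values start at zero.  Training stops when the largest update in a
trial falls below 1e-8 or after 10,000 trials.  On chains with stochastic
transitions (random cue order, random target placement) the update norm
cannot reach that tolerance — the convergence flag is then false by
construction — but every state whose downstream chain is deterministic
(all patch states after the cue) converges geometrically to its exact
fixed point, which is why the regular-target variant reaches machine-zero
prediction errors inside the patch.

Trace records store each transition with the reward of the departed state
(r_t belongs to s_t), both state values and δ, so the defining identity is
re-derivable row by row.  Phase attribution offers both endpoints: the
entered state locates cue- and target-locked responses (δ at the moment the
cue appears is the transition *into* the cue state), the departed state
locates delivered rewards.

Predictable alternation is modelled by letting the pre-cue context state
encode the upcoming trial type — the minimal state extension under which
the strictly alternating cue is fully predicted; with a shared context
state (random alternation) the cue transition carries the prediction-error
spike.  Q-values are learned on-policy under the fixed optimal policy
(click at every target); the package checks the reward-difference identity
r_t = Q(s_t,a_t) − Q(s_{t+1},a_{t+1}) after convergence and the equality of
greedy Q with V.

Model curves place δ impulses at transition times and reward impulses at
delivery times on a 0.1 s grid, average across recorded trials per
condition (200 recording trials by default) and convolve with the canonical
haemodynamic kernel, so the curves show what a slow haemodynamic readout
would carry.  With full hits and regular targets the high/low ratio of
time-averaged reward curves is exactly the reward ratio (20).

## Design matrices

The canonical response is the standard double-gamma: peak gamma with 6 s
delay and 1 s dispersion, undershoot with 16 s delay at ratio 6, 32 s
kernel.  The kernel is scaled to unit peak so coefficients read in signal
units.  Regressors are built on a 16-fold oversampled grid and decimated at
scan times.  Blocks (cue, patch, per reward level) are unit-height boxcars;
target events are unit sticks.  Note that convolved task regressors are not
non-negative: the undershoot produces dips bounded by 1/6 of the peak.

Parametric modulators scale event sticks by a covariate, mean-centred per
condition: trial number at the cues; within-patch time to powers 1..4 at
the targets, convolved and then sequentially orthogonalised against the
condition's main event regressor and all lower degrees (orthogonalisation
after convolution, ascending degree; projection is applied twice so
residual dot products sit at the rounding floor).  A constant modulator is
rejected with a rank warning.  The quartile model adds first- and
last-quartile event regressors enabling a last-minus-first contrast.  An
optional discrete-cosine basis (cutoff 128 s) models slow drift; it is off
by default so that noiseless identities stay exact.

## Synthetic BOLD

The phantom is a 20×24×18 grid of 3 mm voxels, RAS, centred on the origin
so voxel centres carry MNI-like coordinates.  Two disjoint 4×4×4 boxes
stand in for the ventral striatum (inside the VS ROI box) and the VTA/SN
midbrain locus; geometry is schematic, not anatomical.  Subject data are
baseline (100, so amplitudes read as percent signal) plus
amplitude-weighted design columns in each region plus stationary AR(1)
Gaussian noise (marginal sd 1%, φ = 0.2 by default; the generator is the
exact process the estimator assumes) and optional sinusoidal drift.
Cohort amplitudes are group mean plus Gaussian between-subject deviations
(sd 0.15% in the presets); a master seed is split per subject via
SeedSequence spawning, so cohorts are reproducible and extensible.
Spatial smoothing is separable Gaussian with mass-renormalised borders
(flat volumes stay flat), FWHM 8 mm in the Experiment-1 preset and 6 mm in
the high-resolution presets.

Default effect sizes (cue: 0.75 vs 0.25% in VS when the cue is
informative, equal 0.5% otherwise; patch: 0.5 vs 0.0% in VTA/SN) were
chosen so that the 17-subject preset detects the patch effect at corrected
p < 0.05 in at least 80% of cohorts — the generator's calibration target;
real effect sizes and noise levels in vivo are unknown, so what passing
tests show is the *internal* consistency and calibration of the chain, not
field realism.  The generator also omits motion, physiological noise and
anatomy.

## Estimation and inference

First level: per-voxel OLS, a single AR(1) coefficient pooled over voxels
from the lag-1 autocorrelation of the OLS residuals, one Cochrane–Orcutt
whitening pass of data and design, re-estimation.  A voxelwise φ would be
noisier at these series lengths; the pooled choice also keeps (X'X)⁻¹
shared.  Degrees of freedom are n_scans − rank(X) with no correction for
the AR estimate (second-order at 125–144 scans).  With φ = 0 the fit equals
OLS exactly.  Zero-variance voxels carry NaN t-values and a flag instead of
infinities.  Second level is summary statistics: one-sample t across
subject contrast maps (dof n−1) or pooled two-sample t between cohorts
(dof n₁+n₂−2).  Fitted trial time courses combine cue, patch main effect
and the polynomial expansion on a 0.1 s grid; the 90% band is mean ±
1.645 between-subject standard errors, point-wise.

Permutation correction uses the max statistic: per resample, the largest t
in the search volume and the largest supra-threshold cluster
(cluster-defining one-sided p 0.001 whole-volume, 0.01 within ROI;
18-connectivity by default, 6 and 26 selectable).  One-sample nulls use
sign flips of subject maps (exchangeable under symmetric errors — the
natural scheme when "permuting the regressor" is undefined for a constant
column); two-sample nulls relabel group membership.  p = (1 + #{null ≥
observed}) / (1 + n_perm), bounded below by 1/(n_perm+1); when 2ⁿ (or the
label-combination count) fits in the budget the null is enumerated and p is
exact.  Tests are one-sided; ties count against the observed value.  The
ventral-striatum ROI is the analytic box above; the "midbrain" ROI is a
surrogate box (x ±14, y −34…−6, z −24…0 mm) covering the VTA/SN phantom
region, with no claim of equivalence to a hand-drawn anatomical mask.

## Scenario presets and problem sizes

Presets encode the three experiment variants: n = 35 / 17 / 20 subjects,
TR 2.46 / 2.85 / 2.85 s (144 / 125 / 125 scans), smoothing 8 / 6 / 6 mm,
random / regular / random alternation, irregular / irregular / regular
targets; 6000 resamples by default.  The trial count is configurable and
defaults to 12.  A master seed derives every stage's stream, so identical
configurations give identical cluster tables.  The test suite runs the
presets at 200–500 resamples and checks calibration on batches of 10–500
simulated cohorts (type-I error on 500 null cohorts of 17 smoothed noise
maps; recovery bias on 25 cohorts; detection power on 10), sizes chosen to
keep each property estimate's Monte-Carlo error well inside its acceptance
band.

## Known limitations

Single-voxel-grain box phantoms and a global AR(1) coefficient are
idealisations; no slice timing, motion or registration is modelled; the
midbrain ROI is schematic; cluster inference assumes a shared
cluster-defining threshold across permutations; the Experiment-2
"predictable cue" construction (type-encoding context state) is one minimal
realisation of predictability, not the only possible one.
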