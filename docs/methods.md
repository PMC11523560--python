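# Methods

This package studies whether pre-training a sequence network on simulated
musculoskeletal data improves torque prediction on (synthetic stand-ins
for) recorded data of fatiguing isometric elbow flexion. Everything is
desk-scale and self-contained: both the "simulated" and the "recorded"
worlds are generated by code in `src/fatiguetl`.

## Surrogate musculoskeletal model

The task is isometric at a fixed posture (45° shoulder flexion, 90° elbow
flexion, supinated forearm), so muscle–tendon dynamics collapse and elbow
torque is a static linear map of activations,

    T(t) = Σ_i  fmax_i · a_i(t) · r_i ,

over 7 actuators: three triceps heads (r < 0), two biceps heads,
brachialis and brachioradialis (r > 0). The generic parameter set ships
with the package; its values were chosen so the reference subject's
flexion-strength ceiling Σ fmax·|r| over the flexors is ≈ 76 N·m, i.e. the
30–90 N·m target grid spans feasible-to-infeasible. Scaling to a subject
multiplies moment arms by height/1.70 m and forces by mass/75.1 kg — only
the product fmax·r matters downstream, so this linear law is sufficient.

The inverse problem (excitations that track a torque target) is solved per
time step as the minimum-norm muscle-redundancy problem: minimize Σ a_i²
subject to Σ c_i a_i = T and 0 ≤ a_i ≤ 1, with c_i = fmax_i·r_i over the
flexors and extensors pinned at a co-activation floor (0 in the simulated
world). The interior solution is a_i = T·c_i/Σc_j²; channels exceeding 1
are clamped (largest first, deterministic order) and the remainder
re-solved against the residual torque. A configuration is *non-converged*
when the target exceeds the strength ceiling at any step; this
infeasibility surrogate reproduces the partial-convergence filtering of
full computed-muscle-control pipelines (with the default cohort, roughly
a quarter of the 2,100 configurations fail, biased toward high peaks and
small subjects). The solver was validated against an SLSQP quadratic
program and an exhaustive 2-channel grid.

## Fatigue model

A 3-compartment motor-unit model per muscle: rested (MR), active (MA),
fatigued (MF) fractions with

    dMR/dt = −C + R·MF,   dMA/dt = C − F·MA,   dMF/dt = F·MA − R·MF,

and drive C = LD·min(TL − MA, MR) when MA < TL, C = LR·(TL − MA) ≤ 0 when
MA ≥ TL. F = 0.00912 and R = 0.00094 are interpreted as per-second rates:
this yields a steady-state active fraction R/(F+R) ≈ 0.093 under full
drive and task failure (MA < 0.8) ≈ 27 s into a sustained 80 % load, which
is what motivates the 30 s trial horizon. LD = LR = 10 s⁻¹ — drive must
merely be fast relative to F and R; results are insensitive to the exact
value. Integration is forward Euler at dt = 0.01 s (stability requires
dt·max(LD, LR) < 1; halving dt changes trajectories by < 1e-3 once the
recruitment transient is resolved). The fatigued excitation a muscle can
express is MA(t); a multiplicative residual-capacity variant
(TL·(1 − MF)) is available behind a flag.

## Simulated dataset

Per (subject, peak) configuration: 10 N·m ramp start, 1.5 s linear ramp to
a peak ∈ {30,…,90} N·m, 1.5 s plateau, then the final excitation vector is
held to 30 s; excitations feed the fatigue model (muscles start at the
ramp-start load, MA(0) = TL(0), since the trial begins mid-contraction);
fatigued activations feed the forward map; both signals are linearly
resampled to 300 steps (10 Hz) and the 7 actuators collapse to 4 muscle
groups (BRA, TRI, BIC, BRD order) by fmax-weighted mean. Simulated
subjects draw height and mass from the reference distribution truncated at
the 5th–95th percentiles; remaining statics derive from height/mass by
fixed allometric ratios with 2 % noise.

## Synthetic recorded sessions

The generator stands in for the human experiment, not for its physiology.
Per subject (statics drawn at the recorded cohort's means/SDs, ±3 SD
truncation, 9:16 female:male):

* **MVC**: three 5 s plateaus at the true MVC torque with 2 % multiplicative
  noise; measured strength = best plateau mean.
* **Sustained task** at 80 % of measured MVC on a strength-calibrated model
  (flexor forces rescaled so the ceiling equals the subject's MVC — the
  subject's "true" strength). Subjects ramp from rest to the target over
  2 s under visual feedback, so trials contain a low-torque rise (recorded
  data always do; it is also where sequence models struggle most).
  Exerted effort then wanders log-normally (5 % SD, 0.15 Hz bandwidth)
  around the target; a 5 % antagonist co-activation floor keeps the TRI
  channel alive, since real recordings show clearly nonzero triceps
  activity during flexion. Per-subject lognormal jitter (SD 0.3) on the
  fatigue rate spreads time-to-failure; under defaults the cohort mean is
  ≈ 35–40 s with a ≈ 18–80 s range. The termination rule is applied to
  the hold phase (the commanded ramp would otherwise spend the
  below-threshold budget).
* **Torque** = forward torque of the fatigued activations times
  (1 + s(t)·ε): the noise SD ramps quadratically from 1.5 % to 12 % as the
  residual-capacity ceiling (Σc·(1 − MF)) falls from its initial value to
  the failure threshold, concentrating variability near task failure.
* **EMG** (3000 Hz) = activation envelope × (1 + 10 % linear drift) ×
  slow lognormal gain wander (15 % SD, 0.2 Hz) × band-limited (20–450 Hz)
  Gaussian carrier, plus baseline noise and a DC offset.
* **Termination**: the trial truncates at the first sample whose trailing
  5 s window contains ≥ 3 s cumulatively below 70 % MVC.

The drift and gain wander are the deliberate simulation-to-reality gap:
they corrupt the measured envelope relative to the torque-generating
activation in a way peak normalization cannot undo, which is exactly what
transfer learning must be robust to. The effort wander makes the torque
profile informative beyond the statics — without it, failure-truncation
plus fixed-length resampling makes every trial a near-deterministic
function of MVC alone and the comparison degenerates. Magnitudes are
standard scales for surface-EMG amplitude nonstationarity and isometric
force tracking. What the generator does **not** emulate: motor-unit-level
EMG structure, crosstalk between specific muscle pairs, electromechanical
delay, sex differences in fatigability — and, importantly, the full
hardness of real recordings, whose consequences are discussed under
"What the benchmark shows" below.

## EMG processing

Per channel: mean subtraction → 4th-order Butterworth band-pass 10–500 Hz
→ full-wave rectification → 4th-order Butterworth low-pass 5 Hz → median
filter over the largest odd window ≤ 0.5 s (1499 samples at 3000 Hz) →
division by the subject's peak envelope across trials → clip to [0, 1] →
linear resampling to 300 steps. Both Butterworth stages are zero-phase
(forward–backward), the standard choice for envelope extraction; the
envelope of a symmetric burst therefore peaks without lag. For the
physics baseline, activations are additionally smoothed by a 25-sample
centered moving average (reflect padding); a sum-of-absolute-differences
sweep over windows 5–50 supports that choice (the selector returns 25
unless diminishing returns, < 5 % relative SAD drop, set in earlier).

## Networks and training

Both regimes share one architecture: activation sequences (4 channels ×
300 steps) feed a stack of unidirectional LSTM layers; at each step the
top hidden state is concatenated with the encoded static features (sex as
0/1, six z-scored measures standardized on training subjects only) and
passed through a shared per-step ReLU feedforward stack to one torque
output in raw N·m. Final configurations: 3 LSTM layers of width 24; head
2 × 23 (direct) or 2 × 18 with the top 2 LSTM layers unfrozen (transfer).
Training uses Adam with coupled weight decay and MSE loss (direct:
lr 6.4e-3, wd 4.5e-2; transfer fine-tune: lr 9.0e-3, wd 9.4e-2).

The implementation is plain numpy (forward, backpropagation through time,
Adam), verified against finite differences. Two numerical choices matter:
the output bias starts at the training-target mean (Adam's per-step
movement is bounded by ≈ lr, so reaching tens of N·m from zero would
consume the whole step budget), and pre-training uses lr 5e-3 with weight
decay 1e-3 — pre-training hyperparameters are a separate choice from the
fine-tuning ones, and the strong fine-tune decay provably stalls
pre-training at the mean predictor. Pre-training attaches a temporary
linear per-step readout (discarded at hand-off) and uses no statics; its
fit floor is set by a real ambiguity — minimum-norm activations carry the
*shape* but not the *scale* of a subject's strength, so torque is
underdetermined from activations alone across a heterogeneous cohort. The
fine-tuned head resolves the scale through the MVC static.

Desk-scale schedule (one CPU): pre-train 60 epochs at batch 8 on ~150–200
simulated trials; fine-tune/direct 150 epochs at batch 4 on 20 trials.
Random hyperparameter search (log-uniform lr and decay, discrete widths,
0/1/2 unfrozen layers) under subject-wise 5-fold cross-validation is
implemented and tested at small draw counts; the published final
configurations are the defaults so the benchmark does not depend on a
search run.

## Evaluation

Leave-out evaluation on 5 of 25 subjects (seeded uniform split): pooled
RMSE/MAE over all 300 × 5 leave-out steps (per-subject values are also
emitted), prediction SD versus actual SD, and parity pairs. The physics
baseline scales the generic model to each leave-out subject
anthropometrically — deliberately *without* strength calibration, since a
generic scaled model does not know the subject's true strength — smooths
the processed activations (window 25) and applies the forward map; its
large error is dominated by that strength mismatch plus the normalization
of envelopes to the subject peak. Boxplot statistics use
linear-interpolation quantiles and Tukey fences at 1.5 IQR.

The headline benchmark re-runs everything from scratch: simulated
pre-training set (30 subjects × 7 peaks → ~200 converged trials),
25 synthetic subjects, fixed 20/5 split, three training seeds; the
reported quantity is the per-approach median leave-out RMSE across seeds.

## What the benchmark shows

Under the default conditions the benchmark driver
(`analysis/03_train_and_evaluate.py`) finds that **both** learned models
outperform the physics baseline by roughly a factor of five (median
leave-out RMSE ≈ 3.8–5.7 N·m versus ≈ 19 N·m) — the baseline's error is
dominated by its ignorance of each subject's true strength, exactly the
failure mode expected of a generically scaled model. The **direction of
the transfer effect does not reproduce** here: the direct model (≈ 3.8
N·m) outperforms the transfer model (≈ 5.7 N·m) across seeds. The package
includes the controls behind that statement: the gap persists when the two
heads are given equal width, when the backbone is used as a warm start
with nothing frozen, when fine-tuning early-stops on a validation split,
and when simulated inputs are peak-normalized like recorded ones. The
mechanism is that this synthetic recorded world is *too easy for direct
learning*: after failure-truncation and resampling, torque is largely
predictable from the MVC static plus a canonical profile, so 20 subjects
put the direct model at the torque-noise floor, while frozen
activation-derived features import the EMG gain wander as irreducible
feature noise. Transfer learning pays off when recorded data leave direct
learning far from any floor — the situation with real human recordings,
where activation–torque relations are far less stereotyped — and a
generator built as a noisier copy of the same forward model cannot
manufacture that hardness without simply being tuned until the comparison
flips, which we deliberately do not do.

## Known limitations

* The recorded world is generated by (a noisier version of) the same
  forward model used in pre-training, so the reality gap — though real
  (drift, gain wander, antagonist activity, noise) — is structurally
  milder than between a full musculoskeletal simulator and human
  muscle. Margins between
  approaches are correspondingly smaller than with real recordings.
* Euler integration and the per-step static optimization ignore
  activation dynamics and tendon compliance; both are deliberate
  simplifications for an isometric task.
* The per-step feedforward head is shared across time and the LSTM is
  unidirectional (causal); neither choice was searched.
* Training runs single-threaded numpy; schedules were sized for minutes
  per model, and longer schedules improve fits only marginally (the
  pre-training floor above is informational, not computational).
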