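# Methods

## Problem and model

The package decodes continuous forearm kinematics from multi-array surface
EMG. The input is a 500 ms window of 32-channel EMG envelope sampled at
120 Hz (a 60 × 32 matrix); the output is a 3-vector of joint angles in
signed degrees: wrist flexion/extension (WF/WE), forearm
pronation/supination (P/S) and hand grip/open (HG/HO). Flexion, pronation
and grip are positive; extension, supination and open are negative.

The decoder is a two-layer channel-wise CNN. Six 60 × 1 temporal filters
("force-pattern" filters), shared across channels and applied with stride 1
and no padding, collapse the time axis to one value per channel; tanh gives
a 6 × 32 feature map with **no channel mixing**. The map is flattened
feature-map-major into a 192-vector and read out linearly:

    angle_i = W_i · fm + b_i ,   i ∈ {WF/WE, P/S, HG/HO}

Total parameters: 6·60 + 6 + 3·192 + 3 = 945. The model is small enough
that forward, analytic backprop and Adam are implemented directly in NumPy;
gradient correctness is verified against central finite differences for
every parameter in the test suite. One bias per filter is included
(disable with `use_conv_bias=False`); initialization is scaled-uniform
fan-in, seed-controlled.

## Preprocessing

Raw EMG (500 Hz) → envelope (120 Hz), in this order:

1. **Rectify** — elementwise absolute value.
2. **Envelope (IEMG) filter** — causal second-order low-pass realized as a
   difference of exponentials, h(t) = A(e^(−a t) − e^(−b t)), the classic
   quasi-tension filter of Koike & Kawato (1995). Defaults A = 6.44,
   a = 10.80 s⁻¹, b = 16.52 s⁻¹ are configuration, not a claim about any
   particular dataset; the filter attenuates power above 10 Hz by well over
   20 dB relative to DC. Filtering is causal only (no zero-phase), since
   the intended end use is real-time control.
3. **Normalize** — per-channel min–max to [0, 1] over the *whole training
   session*. The (min, max) stats are stored; a new-day session evaluated
   with the old model reuses the old stats (so out-of-range values are
   visible and deliberately **not clipped**), while recalibration recomputes
   stats on the new session. A constant channel maps to 0 with a warning.
4. **Resample** — polyphase 6:25 rational resampling 500 → 120 Hz
   (`scipy.signal.resample_poly`), trimmed to round(n·120/500) samples.
   Tiny negative ringing on an otherwise nonnegative envelope is clipped to
   0 so nonnegativity survives the pipeline.

## Dataset construction

Envelope and angle streams are truncated to their common length (a
mismatch > 1 s raises). Windows are 60 samples with a 12-sample stride
(500 ms / 100 ms, i.e. 400 ms overlap) and never cross trial boundaries;
the target is the per-joint arithmetic mean of the 60 in-window angle
samples. Cross-validation folds are built at trial level: the *initial*
design randomly partitions 10 trials into 5 pairs with a recorded seed;
the *second* (recalibration) design maps each of 5 trials to its own
group. No window ever appears in more than one test fold.

## Training and evaluation

Minibatch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on elementwise-mean MSE
over the three outputs; learning rate 0.001; 15 epochs for a full session
and 5 for recalibration; batch size 64 (unreported in the source protocol,
config-exposed); seeded shuffling. Each CV fold re-initializes from a seed
lineage (`init_seed + fold`) so folds are independent. Performance is the
Pearson correlation coefficient per joint between predicted and measured
window-target series on the concatenated held-out fold (a per-trial
averaging flag was considered and rejected as the folds are short), then
averaged over the five folds (CC₅). CC of a constant series is undefined
and returned as NaN with a warning rather than silently zeroed.

## Transfer / recalibration

*Direct testing* evaluates a trained model on a new session with no
updates. *Fine-tuning* freezes the convolutional layer (bit-equality is
asserted) and retrains only W and b for 5 epochs, warm-started from the
trained weights — the force-pattern filters encode temporal activation
shape, which transfers across days, while the linear readout re-learns the
changed channel-to-joint mapping. New-day stats are recomputed before
fine-tuning; direct testing keeps the old stats (the deployed model cannot
know the new range).

## Geometry maps

Each FC row splits into six consecutive 32-long blocks aligned with
channels. The per-channel map is their **gain-aligned superposition**: each
block is multiplied by the sign of its filter's effective gain (the sum of
its 60 taps — the feature's response to a uniform rise of a channel's
envelope) and then summed. A plain sum was evaluated first and rejected:
trained filter gains carry essentially random signs that approximately
cancel (their sum is near zero in practice), and the FC layer compensates
each negative-gain filter with sign-flipped weights, so the plain sum
cancels exactly the learned structure it is meant to display. The aligned
sum reads every block in input space, so red (positive) always means "an
envelope rise here pushes the joint toward WF/P/HG". Plain sum, mean and
abs-sum remain available via the `mode` argument. Maps are normalized
per joint by their own absolute maximum to [−1, 1] and arranged on the two
4 × 4 sleeve faces (flexor rows ch5–8/13–16/21–24/29–32, extensor rows
ch1–4/9–12/17–20/25–28; columns left→right by increasing channel number) —
a rendering convention recorded here, with a diverging blue-white-red
colormap centered at 0.

## Synthetic data generator

No public recordings exist for this task, so the generator emulates the
study structure end to end:

* **Paradigm** — each trial starts at the neutral central position (CP)
  and performs WF, WE, WF, WE, P, S, P, S, HG, HO, HG, HO; every excursion
  is a raised-cosine CP → peak → CP pulse (C¹-smooth, so the envelope
  filter does not ring) with rest at CP between motions. Defaults: 2 s
  excursions, 1 s rests, peaks ±60° (WF/WE), ±80° (P/S), ±45° (HG/HO);
  amplitudes and durations are unreported in the source protocol, so these
  are free choices of plausible range-of-motion values, fixed once. A
  small smoothed jitter (0.2° SD) emulates tracker noise.
* **Activations** — each of the six motions gets a nonnegative activation:
  its joint's excursion in its direction, rectified and normalized by the
  trial peak; zero at CP.
* **EMG** — per channel, unit-variance Gaussian noise band-passed to
  20–200 Hz (the bulk of the surface-EMG spectrum under the 250 Hz
  Nyquist) amplitude-modulated by `mixing_matrix · activation +
  noise_floor` (floor 0.05). The mixing matrix plants each motion on a
  disjoint 4-channel patch of the anatomically correct sleeve face
  (flexors drive WF/P/HG, extensors WE/S/HO) with gain 1, plus grid
  neighbors at gain 0.3 — so the channel sets a decoder should weight are
  known ground truth.
* **Day shift** — per-channel lognormal gain changes, a whole-column
  rotation of the sleeve (electrode slip), and extra carrier noise scaled
  on the floor. Angles are unchanged. The identity shift is a bitwise
  no-op.

Per-trial seeds are `seed + trial_index`. What the generator does *not*
model: motor-unit physiology, volume conduction/crosstalk between
channels, force or fatigue dynamics, nonstationary noise within a session.
Passing tests therefore demonstrate that the pipeline recovers structure
the generator plants under realistic rates, scales and day-shift
mechanisms — not performance on human recordings.

## Problem sizes and acceptance checks

The packaged study uses a 10-trial session (37 s per trial, 366 windows
per trial, 3660 windows) for the initial experiment and a day-shifted
5-trial session for recalibration; the model-comparison and
permutation-control runs use a shortened paradigm (one excursion per
motion pair, 5 trials, 605 windows) with the 32-dim per-channel-mean
baseline features — the baselines' input representation is unreported in
the source protocol, and this choice keeps all five models on equal
footing per channel. `scripts/acceptance.py --seed N --out results.json`
recomputes all headline numbers from scratch at these sizes.

On this clean, low-noise synthetic data the classical baselines (LR, SVR,
KNN) match or exceed the CNN — the planted mixture is exactly linear in
the envelope, so this comparison checks protocol plumbing (shared folds,
shared CC, honest nulls), not the real-data superiority claim, which only
human recordings could test. The permutation control (labels shuffled
across windows) drives every model to |CC| < 0.2.

## Numerical choices and edge cases

* Resampled length is trimmed to round(n·fs_out/fs_in); `resample_poly`
  alone returns the ceiling.
* Envelope nonnegativity is enforced by clipping post-resampling ringing
  at 0; normalized signals may exceed [0, 1] only when scaled with
  another session's stats.
* CC on a constant series → NaN + warning; paired t-test on identical
  vectors → (t = 0, p = 1); nonzero constant differences raise a
  degenerate-data error; BH-FDR validates p ∈ [0, 1] and preserves input
  order.
* Training raises on non-finite loss with the offending epoch/batch.
* Checkpoints are NPZ with a JSON hyperparameter header; round trips are
  bit-exact.

## Known limitations

Real sEMG violates the generator's linear-mixture assumption (crosstalk,
impedance drift within a session, deep-muscle sources for P/S and HG/HO),
so absolute CC values here are optimistic. The 500 ms window is an offline
choice; real-time control would need 50–400 ms windows. The geometry map
is a linear sensitivity readout of a shallow model, not an anatomical
claim.
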