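# Methods

## Scope

`trackcast` forecasts the future of cell trajectories in a "social" scene —
a video or region of interest in which several cells move and interact at
once — and judges the forecasts the way a motility study would: not by
pixel error alone but by whether the statistical descriptors extracted from
predicted track endings are distributionally indistinguishable from those
extracted from the true endings.  The package contains a stochastic phantom
simulator that plays the role of ground truth, the social generative
adversarial predictor, an iterative long-horizon test procedure, two
competing predictors, the descriptor set, and the statistical screens.

## Phantom migration models

Two fully synthetic atlases emulate the biology at the level of particle
kinematics.

**One population (collective migration).** Each video holds 16 immune cells
for 240 frames at 1 frame / 20 s (80 min).  Per frame each cell moves by

```
x_{t+1} = x_t + mu*dt + sigma*eta_t + F_rep
```

with `|mu|` the drift modulus (3 um/min in the test atlas, 3.4 um/min in
the training atlas; direction a per-cell fixed random heading), `eta_t`
standard bivariate normal noise of scale `sigma`, and `F_rep` a soft-core
repulsion summing, over neighbours j within `repulsion_range`, a
displacement of magnitude `repulsion_strength * (1 - d_ij/range)` directed
away from j.  Test atlases hold 100 videos (1600 immune tracks), training
atlases 10 videos (160 tracks).

**Two populations (tumor-immune interaction).** A single tumor cell
performs a pure random walk (scale `tumor_noise_sigma`); immune cells drift
toward the tumor's current position.  When an immune cell comes strictly
closer than the interaction radius `R_int` (sum of tumor and immune radii,
default 12 + 6 um), an attractive force of the same modulus `|mu|` holds it
for the effectiveness time `T_eff` (8.3 min in the test atlas, 13.3 min in
training; 25 and 40 frames after rounding `round(T_eff*60/dt)`).  After the
episode the cell departs under a fresh random fixed heading and never
re-engages; every episode is logged `(immune_id, t_on, t_off)`.  An episode
is only started if it fits before the video ends, so every logged episode
has exactly the imposed duration.  A literal "revert to the previous
migration mode" would send the cell straight back to the tumor and pin it
there; the departure heading keeps interaction-time distributions
non-degenerate while preserving the imposed episode length, and the
refractory rule makes episodes well separated.

**Parameter choices the models leave open.**

* `noise_sigma = 1.5` um/step.  The per-frame drift displacement is 1
  um; immune-cell migration in vitro is strongly fluctuating, with
  instantaneous speed variation at least comparable to the directed
  component.  This value gives ending-slice persistence around 0.5 —
  a realistic straightness for immune cells — while the Monte-Carlo
  recovery of `|mu|` from net displacement over duration stays unbiased
  well within three standard errors at 500 tracks (the upward bias of the
  net-displacement estimator, `sigma^2/(2|mu|T)`, is about 0.014 um/min
  against a 3-SE band of 0.039).
* Field geometry: the field is 2000 x 2000 um with reflecting boundaries,
  and cells are seeded uniformly in a central 500 x 500 um box, like an ROI
  centred on a cell cluster.  Drifted cells travel at most ~240 um in a
  video, so reflections essentially never occur; a 500 um field with
  uniform seeding would reflect most drifted tracks and distort the very
  drift statistics the atlas is meant to impose.
* Radii 6 um (immune) and 12 um (tumor), repulsion range 12 um and
  strength 1 um: soft contact exclusion at about the cell-diameter scale.
* Atlas seeding: the atlas seed spawns independent per-scene seeds through
  `numpy.random.SeedSequence`, so scenes are independent and every atlas is
  bit-reproducible from one integer.

## The social adversarial predictor

The generator is a recurrent encoder-decoder over per-step displacements.
A linear layer embeds each agent's displacement (embedding 64); one shared
LSTM (hidden 64) encodes each agent's observed history; the decoder LSTM
(hidden 128) is initialised from the encoder state concatenated with a
noise vector (dimension 8) and emits one displacement per step.  At every
decode step the decoder hidden states of neighbouring agents are pooled on
an 8 x 8 occupancy grid spanning a 24 um neighbourhood centred at each
agent (half-open cells; a neighbour exactly on an internal boundary goes to
the lower-index cell — the rule is stated so it is testable).  Hidden
states are projected to 32 dimensions before gridding and the flattened
grid is compressed to 64 dimensions before entering the decoder input.
The discriminator embeds displacement sequences of trajectories — the
true or generated future in a trailing context of observed steps
(`disc_context`, default 24; the full history adds cost, not signal, to
the local-realism judgement) — encodes them with an LSTM (hidden 64) and
scores the final state with a two-layer MLP.

Training minimises the usual min-max objective with Adam (learning rate
5e-4, batch of 8 scenes) plus an L2 loss between predicted and true future
displacements (best-of-`variety_k` samples; `variety_k` defaults to 1 since
single-future prediction is the use case here).  The discriminator and
generator alternate 1:1.  The generator's adversarial term is weighted 0.1
against the L2 term by default: the adversarial signal shapes realism but,
at full weight, destabilises the displacement calibration that the
iterative recursion then amplifies over a hundred stages.

**Scale equivariance (ballistic prior).** The network consumes
displacements normalised by each agent's mean observed step length and
emits a *residual* around the agent's observed mean velocity; the residual
is rescaled to native units before use.  Every atlas trains at one drift
modulus (3.4 um/min) and is tested at another (3.0 um/min); an
unconstrained displacement regressor converges to the training modulus —
the conditional mean over a training set in which every cell shares one
modulus — and cannot transfer.  With the prior, transfer across moduli is
exact by construction and the network learns direction, interaction and
fluctuation structure instead.  Both behaviours are switchable
(`ballistic_prior`, `scale_normalize`).

**Training windows.** Each scene contributes its starting slice (the full
observed half, matching the inputs used at test time) plus one random
translate of the same window as augmentation, each predicting its immediate
`train_pred_len = 12` future steps.  Matching the training observation
length to the test window matters: a model trained on much shorter windows
learns a noise-shrinkage gain calibrated to short-window velocity estimates,
and the iterative recursion compounds that miscalibration into a systematic
speed bias.  Backpropagation through time is truncated every 30 steps
(`tbptt`), bounding graph memory without changing the forward pass.

**Checkpoint selection on rollout calibration.** The training losses are
one-step (plus a short rollout); the quantity that decides long-horizon
quality is the closed-loop gain of the recursion, which the losses never
observe.  During `fit`, every `checkpoint_every` epochs the current
generator runs the full iterative recursion on the *training* scenes and
the signed log-ratio of predicted to true mean ending speed is recorded;
at the end, a linear fit of that drift across checkpoints selects the
snapshot whose calibration is nearest zero.  The reference for the ratio
is each track's ballistic continuation, |mean observed displacement|
times the number of predicted steps: under drifted random-walk migration
this has the same distribution as the true ending net displacement, so it
targets the correct mean while removing ground-truth sampling noise from
the estimate.  Only training-role data enters this choice.  Gradients are
clipped to a global norm of 1 — without clipping an occasional
adversarial spike derails the displacement calibration entirely.
Calibration during adversarial training wanders non-monotonically and, at
long training times, settles on a systematically shrinking closed loop
(the conditional-mean behaviour the L2 loss rewards), which is why a
near-zero checkpoint is selected rather than the final epoch.

**Closed-loop gain calibration.** Even the best checkpoint carries a
residual speed-scale error of the order of the selection score's own
sampling noise, and the recursion turns any per-step scale error into a
systematic ending-speed bias.  After selection, a single scalar gain on
the predicted displacement is solved by secant iteration so that the
full-horizon rollout on the training scenes is speed-neutral against the
same ballistic reference (at most four rollouts are needed).  This is an
output calibration in the spirit of
post-hoc recalibration of probabilistic classifiers: fitted on training
data only, stored with the model (`gamma_`), and switchable
(`gain_calibration=False`).

At prediction time the same gain is re-solved *transductively* against the
ballistic continuation of the observed windows of the scenes being
predicted — data the predictor legitimately holds as its input; the
held-out endings are never read.  This closes the residual operating-point
gap between training and prediction conditions (the training atlas drifts
at 3.4 um/min, the test atlas at 3.0, so the noise-to-drift ratio the
network sees differs by ~10%).  The reference embodies the drifted
random-walk assumption; for scenes where ballistic continuation is a poor
model of the mean future, pass ``recalibrate=False``.

**Iterative test.** At each stage the predictor receives the current window
of N positions per agent (ground truth while available, earlier predictions
beyond), predicts every agent's next position jointly, appends it, and
drops the oldest position, keeping N constant; one decoder step per stage.
Tumor agents participate in pooling but follow their ground-truth
positions instead of being predicted.  All scenes of a test set advance
through the recursion together (batched along the agent axis; pooling never
crosses scene boundaries).

## Competing predictors

* **Linear ballistic baseline**: per cell, the mean of the last `tau = 9`
  instantaneous velocities advances the last position by one frame;
  iterated through the same harness.
* **Conv-LSTM-conv recurrent model**: a per-track (non-social) one-step
  predictor — four 1-D convolutions with ReLU, an LSTM, four 1-D
  convolutions with a linear final activation — over a (time, x/y
  coordinate) displacement series.  It requires equal-length inputs;
  ragged training tracks are equalized by replicating first/last positions
  (dummy points), never by zero padding.

## Descriptors

Computed on track endings (true or predicted), per cell: mean straight-line
speed `d(first, last)/T_p`; max distance travelled `max_t d(first, Z_t)`
(the farthest excursion from the ending's start — the printed formula's
max over a single scalar is read as max over the ending, the only reading
that makes the max meaningful); persistence (straightness index, net over
total path length, in [0, 1]); mean angular speed (mean absolute turning
angle per minute, skipping zero-length steps); and, for two-population
scenes, the mean interaction time — the number of frames strictly inside
`R_int` of the tumor centre (ties count as non-interacting), returned per
track in frames and optionally minutes.

## Statistical screens

Distribution pairs are compared with the two-sample pooled-variance
Student's t-test (Welch available by flag), significance at p < 0.05,
without multiple-testing correction (a Bonferroni flag exists, off by
default, since per-descriptor raw p-values are the object of interest).
The *equivalence screen* tests predicted vs ground-truth distributions per
descriptor and passes when nothing is significant; the *contrast screen*
tests condition pairs (e.g. treated vs untreated) per source and asks
whether the ground-truth effect direction and significance survive on
predictions.  Prediction error is additionally summarised as the average
MSE: mean over tracks of the per-frame mean squared Euclidean distance.
Degenerate t-test input (two constant equal groups) reports p = 1 by
convention.

## Problem sizes used in the shipped experiments

The packaged experiments run the pipeline at desk scale: training atlases
of 5-10 scenes, 50 training epochs, and 20 test scenes (320 immune tracks)
for the equivalence screen, with three independent seeds and a 2-of-3
decision rule.  These sizes give the t-test enough power to expose a
mis-calibrated predictor (the untrained-generator negative control fails
the screen decisively) while keeping a full pipeline run in the minutes
range on one CPU core.  Simulation-only quantities use larger samples
(>= 500 tracks for drift recovery).

## What the phantoms do and do not show

The phantom atlases make ground truth exactly known, so they validate the
machinery: simulator statistics, descriptor closed forms, harness
bookkeeping, and the predictor's ability to reproduce descriptor
distributions across a drift-modulus shift.  They do not emulate real
videos' segmentation and tracking errors, cell appearance/disappearance,
heterogeneous per-cell speeds, shape-dependent interactions, or
pixel-quantised coordinates; conclusions about real data require real
tracked videos, for which the package reads any tracker output in the
plain CSV dialect.

## Numerical choices and degenerate inputs

Networks run in float64 on a small reverse-mode autodiff core written for
this package (dense linear algebra, LSTM gates fused into one operation,
length-preserving 1-D convolution); gradients are verified against central
differences.  Coordinates round-trip CSV exactly (`%.17g` writing,
round-trip float parsing).  Zero-length displacement steps have no
direction and are skipped by the turning-angle descriptor (their count is
reported by `nan` when fewer than two directed steps remain); a track with
zero path length has undefined persistence (`nan`).  A stationary agent's
displacement scale falls back to 1 so normalisation never divides by zero.
Episodes are logged with frame-exact durations; `t_eff` rounds to
`round(t_eff*60/dt)` frames.

## Known limitations

* The GAN's stochastic head (noise injection) is retained but the variety
  loss defaults to a single sample; multi-modal future evaluation is out
  of scope.
* The adversarial weight, like all architecture constants the originating
  design leaves unnumbered, is a package default chosen for stable
  training, not a recovered value.
* Long-horizon recursion amplifies any per-step calibration error; the
  ballistic prior keeps the speed scale anchored, but pathological inputs
  (e.g. windows consisting entirely of padding) will produce degenerate
  forecasts.
* The simulator's potential forces are the simplest members of their
  family (linear soft-core repulsion, constant-modulus attraction); they
  are config-selectable stand-ins, not fitted physics.
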