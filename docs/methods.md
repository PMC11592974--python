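# Methods

## The screening model

`facepheno` implements a binary ASD/TD screen over per-frame facial-behavior
streams. A session is a K x L grid of frames (K = 6 stimulus-aligned slices,
L = 200 frames per slice after equal-interval downsampling); every frame
carries six basic-expression intensities in [0, 1], a 7-class expression
probability distribution (6 basic + neutral) with its argmax label, and three
head-pose Euler angles (pitch, roll, yaw) in [-pi/2, pi/2] radians.

The classifier composes three feature stages:

1. **Coarse stage.** Per slice k: mean of the per-frame maximum intensity
   (Ibar_k), count of happy-labelled frames (Cbar_k), and the per-axis pose
   range (Pbar_k). Thresholds T1 = 0.3, T2 = 10 frames, T3 = pi/3 rad turn
   these into binary indicators — intensity activated (Ibar_k >= T1), happy
   expression displayed (Cbar_k >= T2), attention maintained
   (max-axis range < T3). All comparisons use >= at the boundary. The 3K
   indicators concatenate block-wise, [intensity | happy | attention], into
   the 18-dimensional coarse vector Oc. The underlying behavioral rationale:
   reduced expression intensity, reduced socially congruent (happy)
   expression, and attention deviation (proxied by large head rotation) are
   the coarse markers of ASD in stimulus-viewing protocols.
2. **Fine stage.** Per slice, an L x 11 matrix [happiness intensity | 7-class
   probabilities | pitch, roll, yaw] is encoded by one of two structurally
   identical LSTMs, selected by the slice's coarse happy indicator. Routing
   means each LSTM models temporal dynamics *within* slices whose coarse
   summaries agree, which is exactly where coarse features stop
   discriminating. The final hidden state passes through a slice-specific
   linear projection to e = 1 scalar; the K scalars form the fine vector Of.
3. **Fusion stage.** O = [Oc | Of] (24 channels) enters a
   squeeze-and-excitation block without global pooling (each entry is
   already one channel): A = sigmoid(W2 relu(W1 O + b1) + b2), with the
   hidden width C / r (r = 4, hidden 6). The reweighted O' = O * A feeds a
   single affine layer + softmax binary classifier.

### Training and evaluation

Training is two-phase. Phase 1 fits each route's LSTM + projections with a
small auxiliary logistic head on the projected scalar (binary cross-entropy
against the session's group label); the head is discarded afterwards.
Phase 2 freezes the encoders and trains the SE block + classifier with
cross-entropy (a flag allows joint fine-tuning, off by default). Both phases
use the adaptive-moment (Adam) optimizer. The default `TrainConfig`
(learning rate 1e-5, batch size 2, 200 epochs) follows the reference
protocol; the simulation-property tests and the acceptance script pass
explicit faster schedules (Adam 1e-3 to 3e-3, batch 8 sessions, 5-150
epochs, slices of 50-100 frames for the Monte-Carlo suites) — these are the
package's own desk-scale problem sizes and are stated wherever used.

Evaluation is stratified three-fold cross-validation over subjects
(an 81-subject cohort splits 27/27/27), reporting mean accuracy in percent
to two decimals. The four-arm ablation (coarse-only, fine-only,
concatenated, concatenated + attention) shares fold splits across arms, and
the per-fold phase-1 encoders are shared by arms 2-4, which are identically
specified.

No deep-learning framework is used: the LSTM (with backprop through time
and stacked-layer input gradients), the SE block, the softmax classifier
and Adam are implemented directly in NumPy. The backward passes are pinned
by central-difference numeric-gradient tests at tolerance 1e-6.

## Significance screening

Each of the 18 binary coarse features is tested for a group difference with
a textbook one-way ANOVA (SS_between / SS_within decomposition, F with
(g-1, n-g) degrees of freedom, upper-tail p). The ANOVA runs on the 0/1
data directly, with no continuity correction. Reports follow the
slice-major variable order (V1 = head pose slice 1, V2 = expression
category slice 1, V3 = expression intensity slice 1, ...), which differs
from the coarse vector's block order; the bijection is emitted with every
report. Printed p-values use three decimals with "0.000" meaning
p < 0.0005; full precision is stored. A Bonferroni-adjusted column is
included as an optional extra and is not part of the reference analysis.
Features with zero within-group variance are reported "not testable"
rather than failing the report.

## Synthetic cohorts

The study data behind this kind of screen are private (identifiable
children's faces), so the generator emulates the statistical structure the
pipeline consumes, not faces or video:

* **Attention drift**: a Poisson number of disjoint half-sine yaw
  excursions per slice (amplitude `drift_span`, default 1.25 rad > T3), on
  top of a small smooth wander. P(attention maintained) = exp(-drift_rate).
* **Intensity activation**: the happiness channel ramps within each slice
  between per-slice `intensity_base` and `intensity_peak` envelopes, plus a
  per-slice N(0, `intensity_jitter_sd`) subject-level offset that provides
  between-subject variance. The default TD envelope rises across slices
  (cumulative arousal over increasingly effective stimulus clips); the
  default ASD envelope is flat and low.
* **Happy occurrence**: a Poisson number of disjoint happy bouts of fixed
  length (default 15 frames > T2, so one bout usually trips the indicator);
  E[happy frames] = rate x length.
* **Ambiguity**: category probabilities are a tempered softmax over latent
  scores (neutral baseline, happiness during bouts, margin 2 against score
  noise of SD 0.3, so the argmax label is exact); `ambiguity_temp` flattens
  the distribution without moving the argmax.
* **Dynamics**: `smooth_ramp` keeps the generated trajectories;
  `erratic_jitter` applies a random within-slice permutation of frames.
  Since every coarse statistic is order-free, permutation leaves the joint
  distribution of all 18 coarse features *exactly* unchanged while
  destroying temporal structure. `coarse_null_profiles()` exploits this to
  build cohorts separable only by the fine stage.

Default effect sizes were set once so that the default cohort is learnable
but not trivially separable — coarse-only CV accuracy sits in the 70-85%
band (measured 76.8% over five cohort seeds at n = 81). The Poisson rates,
envelopes and temperatures are configuration, not estimates from any
clinical data, and no claim of clinical realism is made: real streams
contain upstream-model estimation error, autocorrelated noise, posture
habits, and expression co-occurrence structure the generator does not
model. Passing tests therefore demonstrate correctness and sensitivity of
the *pipeline*, not expected field performance.

## Numerical and design choices

* Downsampling uses first-of-bin indices floor(j M / L): deterministic,
  order-preserving, duplicate-free for M >= L.
* Argmax ties in the category distribution break by the fixed alphabetical
  order (anger, disgust, fear, happiness, neutral, sadness, surprise).
* The attention rule thresholds the per-axis *range* by default; the
  alternative per-frame absolute-angle reading is available as
  `CoarseThresholds(attention_rule="instant")`.
* The slice summary is the LSTM's final hidden state (not a pooled mean);
  hidden size defaults to 32, one layer. Each (route, slice) pair owns its
  projection.
* SE layers include zero-initialized biases; weights use uniform fan-in
  initialization from a recorded seed. Attention weights are continuous in
  (0, 1) in the forward pass; reports binarize the cohort-averaged weights
  at 0.5. No sparsity penalty pushes weights to exact 0/1.
* The classifier is a single affine layer to 2 logits + softmax.
* Empty slices, non-binary happy labels, out-of-range angles and
  malformed CSVs raise typed errors with row context; the generator clips
  pose to [-pi/2, pi/2] while the reader rejects violations.
* Seed fan-out (cohort -> session, master -> stage, seed -> fold) uses
  NumPy seed sequences; everything downstream of a seed is bit-reproducible.

## Known limitations

* With e = 1 the fine stage compresses each slice to one scalar; subtle
  multi-modal dynamics may need e > 1 (supported, but the 4-column
  attention report layout requires e = 1).
* Phase-1 auxiliary supervision is a design choice where only the routing
  is prescribed; gradients through a per-route head are the simplest
  label-consistent option.
* Stochastic properties (complementarity, attention noise-suppression,
  type-I calibration) are Monte-Carlo statements at stated cohort sizes
  and seeds; per-feature type-I rates over 500 replicates carry a +/- 0.01
  standard error by construction.
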