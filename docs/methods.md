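# Methods

## Scope and model

`actisleep` implements a minute-epoch actigraphy analysis in four stages:
rule-based sleep scoring, awake→sleep dataset construction, a six-model
prediction suite, and confusion-matrix/ROC evaluation, plus a synthetic
cohort generator that supplies ground truth for all of them. Only the
vertical accelerometer axis is used — on the wrist it is the axis most
indicative of physical activity — and all series are assumed contiguous at
one count per minute (gaps are validation errors, trailing partial minutes
are dropped, sub-minute epochs are summed into minutes).

## Sleep scoring

A minute is a **candidate row** when its count is at or below
`movement_threshold`. The state machine scans maximal candidate/movement
runs:

* a candidate run of at least `onset_run_min` (15) minutes opens a sleep
  period at its first minute;
* inside a period, movement runs shorter than `close_movement_min` (30)
  minutes are wake bouts within sleep; a movement run of at least 30 minutes
  closes the period at the end of the last candidate run of length ≥
  `awakening_run_min` (15);
* the end of the recording closes an open period at its last candidate
  minute; such periods are marked `truncated` (last night of a week's wear).

WASO sums wake bouts strictly longer than 5 minutes; 5-minute bouts count as
sleep. Bedtime is inferred as the start of the maximal run of minutes at or
below `sedentary_threshold` immediately preceding onset, never crossing the
previous period's awakening; its length is the latency. Sleep efficiency is
(duration − WASO)/(latency + duration); SE ≥ 0.85 (inclusive) labels the
period good. Intervals are half-open `[start, end)` and 0-based throughout,
which keeps every run-length and duration computation a plain difference.

### Thresholds

Defaults: `movement_threshold = 10` counts/min, `sedentary_threshold = 100`
counts/min, both configurable. The two concepts must be separated for
latency to be observable: if sedentary minutes also qualified as sleep
candidates, any pre-bed sedentary run adjacent to sleep would be absorbed
into the onset run (sleep wins ties) and latency would be identically zero,
leaving the SE denominator without its latency term. Ten counts/min is a
micro-movement scale (sleep retains small twitches); one hundred counts/min
admits quiet wakefulness such as reading. When a candidate run qualifies
both as latency tail and sleep, sleep wins — onset is the earliest
qualifying minute.

### Nonwear

A wearer asleep still produces micro-movements, so runs of *exact-zero*
counts of at least `nonwear_zero_run_min` (90) minutes indicate device
removal. Two modes: `paper_naive` detects and flags these intervals but
still scores them as sleep — a pure zero-block trivially achieves SE = 1 —
and `exclude`, the practical default for real data, in which flagged periods
are omitted from dataset construction. The mode is recorded in every output
row.

## Dataset construction

Each sleep period's label is paired with the activity between the previous
awakening (or series start) and this period's bedtime. Instances shorter
than 60 awake minutes are dropped (logged). The stratified split assigns
each instance (not subject) randomly at 70/15/15 while maintaining class
balance, mirroring an instance-level partition; subject-level splitting is
available via the instances' `subject_id` for leakage-safe practice.
Fixed-input models consume the most recent `fixed_length` minutes
(left-padded with zeros when shorter) — the pre-sleep tail is the plausibly
informative part. Time-batching merges non-overlapping windows of 15
minutes (configurable) into per-step vectors for the TB-LSTM, zero-padding
the final partial window.

## Models and training

All six classifiers end in a single sigmoid unit whose output is the
confidence of good-quality sleep (decision threshold 0.5). Hidden units are
rectified linear except inside LSTM cells, which use the standard memory
block (sigmoid gates, tanh cell/output nonlinearity, forget bias 1).
Per-architecture optima (mini-batch, dropout, hidden size) are built in:
LR 5/0.5/–, MLP 20/0.1/15, CNN 5/0.0/25 filters (length 5, pooling 4),
RNN 5/0.1/75, LSTM 5/0.5/100, TB-LSTM 5/0.5/100. LR has no hidden layer, so
its dropout ratio applies to the input vector. The CNN is the minimal
topology consistent with its stated sizes: one convolution layer, ReLU,
non-overlapping max-pooling, flatten, sigmoid output.

Training minimizes binary cross-entropy with RMSprop (ρ = 0.9, ε = 1e-8) for
at most 50 epochs. The learning rate is a free parameter, default 0.001.
After every epoch the model is evaluated on the validation set; training
stops at the first epoch whose validation accuracy is *below* the previous
epoch's, restoring the previous epoch's parameters (equal accuracy
continues). Because accepted epochs are non-decreasing in validation
accuracy, the returned parameters always come from a best-so-far epoch.
Everything — init, shuffling, dropout masks — draws from one seeded
generator, so identical seeds give bit-identical fits.

Numerical choices that mattered in practice:

* **Input standardization.** Counts are standardized by the training set's
  global mean and standard deviation (applied after padding, so padding
  equals a zero-count minute). Raw counts are all-positive and large;
  without centering, RMSprop at lr 1e-3 cannot move the output bias to the
  separating hyperplane within 50 epochs.
* **Gradient clipping.** Gradients are clipped to global norm 5. Without it
  the ReLU Elman RNN occasionally diverges on minute-resolution sequences
  (hundreds of back-propagation-through-time steps).
* **Recurrent init.** The Elman recurrent matrix starts at identity (plus
  tiny noise); with ReLU units, fan-in random init makes gradients vanish
  within tens of steps. Other weights use fan-scaled Gaussian init.
* Sequences are consumed variable-length with left-padding and masks; masked
  steps carry hidden (and cell) state through unchanged, and backward passes
  route gradients around them.

## Evaluation

Metrics are computed as exact rationals from integer confusion-matrix cells
and reported at 4 decimal places (round-half-even); a metric with a zero
denominator is `None`, never 0. The positive class is good sleep. The ROC
curve sweeps all distinct thresholds and AUC is the trapezoidal area, which
equals the rank statistic (ties ½) — the suite asserts agreement to 1e-12
against a pairwise oracle. `implied_confusion` inverts printed
sensitivity/specificity over a known test composition into the unique
integer matrix consistent with them (printed precision preserved by passing
strings), which is how published rounded metric rows are reconstructed and
verified cell by cell.

## Synthetic cohort generator

The generator emulates what the scorer and the models need from real wrist
actigraphy, one subject-day (1440 min, recordings start at noon so each
night lies inside one day) at a time:

* **Daytime** counts from a zero-inflated gamma–Poisson: with probability
  0.25 an idle minute uniform in (10, 100], otherwise a negative-binomial
  draw with mean 600 and dispersion 1.5 (floored above the candidate
  threshold). These values are documented choices resembling wrist counts,
  not fits to any dataset.
* **Night structure**: bedtime 560–680 min after day start, a sedentary run
  of 5–40 min (the planted latency; values in (10, 100]), a sleep block of
  360–540 min, then active wake. The minute before bed and the minute after
  awakening are forced above the sedentary threshold so inferred bedtime and
  awakening are unambiguous.
* **Class targets**: each night is good with probability 0.5; a target SE is
  drawn uniformly from [0.85, 0.98] (good) or [0.55, 0.85) (poor) and
  realized by planting WASO = duration − SE·TIB as wake bouts of 6–28
  minutes (each strictly above the WASO cut, safely below the 30-minute
  close), separated by ≥15 sleep minutes so onset/awakening detection is
  exact. Realized SE is kept at least 0.005 away from the 0.85 cut so noise
  cannot flip a label. Infeasible targets (e.g. SE 0.999 with a long forced
  latency) raise a generation error. Occasional ≤5-minute bouts are planted
  that by definition contribute nothing to WASO.
* **Sleep noise**: each sleep minute is nonzero with probability 0.3
  (magnitude 1 + Poisson(2), capped at the candidate threshold); 10% of
  those are larger one-minute twitches above the threshold, kept ≥15 minutes
  away from the block boundaries so they read as brief awakenings, not as
  shifted onset/awakening. Setting the rate to 0 gives the noise-free mode
  in which scoring recovers every planted quantity exactly.
* **Coupling**: with strength *c*, the upcoming night's class shifts three
  daytime channels — mean activity (±10%·c), idle-minute probability
  (∓15%·c), and evening (last 2 h before bed) activity (∓12%·c). At c = 0
  the class-conditional daytime distributions are identical; at c = 2 the
  signal is strong and learnable by all architectures.
* **Nonwear**: with probability 0.05 per day, a 100–180 min exact-zero block
  is inserted into the daytime.

What the generator does *not* emulate: circadian phase drift, naps, age or
cultural effects, inter-subject habitual differences, device artifacts other
than zero-run nonwear. Passing tests therefore demonstrate correctness of
the scoring rules and learnability of a planted signal — not performance on
any real cohort.

## Validation design and problem sizes

The acceptance checks run at sizes chosen for a desktop CPU: oracle
equivalence on 1000 random run-structured series of length ≤ 200;
parameter-recovery on a 200-night cohort (noise-free: onset/awakening exact
and SE within ±0.01; default noise: SE within ±0.02 on ≥95% of nights);
learning sanity on 300-instance cohorts averaged over 5 seeds, with inputs
truncated to the most recent 480 awake minutes and epochs reduced
(feedforward 12, RNN 6, LSTM 4, TB-LSTM 10) — early stopping usually halts
sooner. Under those conditions CNN and TB-LSTM reach seed-averaged held-out
AUC ≥ 0.85 on the strong-coupling cohort and every architecture stays within
[0.40, 0.60] on label-shuffled data.

## Known limitations

* With patience-1 early stopping and a small validation set, recurrent
  models can stop after 2–3 epochs; the plain LSTM plateaus below the
  (ceiling-saturated) linear baseline on the strongly coupled synthetic
  task. The suite therefore holds deep models to a decisive absolute AUC
  bound rather than an LR-relative one.
* The naive nonwear mode knowingly mislabels device removal as perfect
  sleep; it exists to reproduce that behavior faithfully, not to recommend
  it.
* The scorer assumes minute epochs and a single subject per recording;
  timezone arithmetic, AGD/GT3X binary parsing and raw 30 Hz resampling are
  out of scope.
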