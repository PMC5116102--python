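# actisleep

Actigraphy sleep scoring and sleep-quality prediction from awake-time
activity, in pure scientific Python.

Wrist-worn accelerometers ("actigraphy" devices, and most consumer activity
trackers) record movement as non-negative *activity counts* per epoch. From a
week of such data, sleep researchers derive each night's **sleep efficiency**

```
SE = total sleep time / total time in bed
   = (duration − WASO) / (latency + duration)
```

where *duration* is the sleep period (onset → awakening), *WASO* (wake after
sleep onset) is the summed length of within-sleep wake bouts lasting longer
than 5 minutes, and *latency* is the sedentary time between bedtime and sleep
onset. Nights with SE ≥ 85% are labeled **good**-quality sleep, below 85%
**poor**.

`actisleep` is aimed at sleep and mobile-health researchers who need this
pipeline end to end:

1. **Scoring** — a rule-based state machine over minute-epoch vertical-axis
   counts: *candidate rows* are minutes with (almost) no movement; sleep
   onset is the first minute of 15 continuous candidate minutes; awakening is
   the last minute of the last ≥15-minute candidate run before 30 continuous
   minutes of movement; bedtime is inferred as the start of the sedentary run
   adjacent to onset. Exact-zero runs are flagged as device nonwear, with a
   naive mode (nonwear scored as perfect sleep) and an exclude mode.
2. **Dataset construction** — each continuous awake period's activity vector
   `X = (x_1, …, x_T)` becomes one instance labeled by the *following*
   night's good/poor label, then a stratified 70/15/15
   train/validation/test split.
3. **Prediction** — six classifiers behind one sklearn-style estimator,
   trained with RMSprop on cross-entropy, dropout, and early stopping on
   validation accuracy: logistic regression (LR), a multilayer perceptron
   (MLP, 15 hidden units), a 1-d convolutional network (CNN, 25 filters of
   length 5, max-pooling 4), a simple Elman RNN (75 units), an LSTM (100
   units), and a time-batched LSTM (TB-LSTM) that merges 15-minute windows
   into each recurrent step.
4. **Evaluation** — exact-rational confusion-matrix metrics (accuracy,
   precision, recall/sensitivity, specificity, F1), ROC curves and
   trapezoidal AUC, plus reconstruction of integer confusion matrices from
   published rounded sensitivity/specificity pairs.
5. **Simulation** — since cohorts of this kind are rarely public, a
   synthetic-cohort generator produces multi-day minute-epoch recordings with
   fully known ground truth (planted bedtime, latency, wake bouts, SE, label,
   nonwear blocks) and a tunable coupling between daytime activity and the
   upcoming night's quality, making both the scorer and the models testable.

## Worked example

```python
import numpy as np
from actisleep import (SimConfig, generate_cohort, score_recording,
                       segment_awake_pairs, stratified_split,
                       SleepQualityClassifier, evaluate_predictions)
from actisleep.scoring import periods_to_frame

sim = SimConfig(n_subjects=12, days_per_subject=7, seed=42,
                coupling_strength=2.0, p_nonwear=0.0)
series_list, truth = generate_cohort(sim)

periods = score_recording(series_list[0])
print(periods_to_frame(periods, series_list[0]).head(3))
```

```
            bedtime               onset           awakening  latency_min  waso_min  efficiency label
2026-01-05T23:03:00 2026-01-05T23:11:00 2026-01-06T06:29:00            8       135      0.6794  poor
2026-01-06T22:00:00 2026-01-06T22:38:00 2026-01-07T07:04:00           38        84      0.7757  poor
2026-01-07T21:35:00 2026-01-07T21:46:00 2026-01-08T03:46:00           11       133      0.6119  poor
```

The first night: the subject went to bed at 23:03, fell asleep 8 minutes
later, accumulated 135 minutes of >5-minute wake bouts before the 06:29
awakening, for SE = (438 − 135)/(8 + 438) ≈ 0.679 — a poor night.

Training a CNN on the awake-time activity preceding each night (the most
recent 8 hours feed the model):

```python
instances = []
for s in series_list:
    instances.extend(segment_awake_pairs(score_recording(s), s))
split = stratified_split(instances, seed=0)          # 84 instances, 70/15/15
X = [i.awake_activity[-480:] for i in instances]
y = np.array([i.label for i in instances])

model = SleepQualityClassifier("cnn", fixed_length=480, random_state=0,
                               max_epochs=12)
model.fit([X[i] for i in split.train], y[split.train],
          validation_data=([X[i] for i in split.validation],
                           y[split.validation]))
conf = model.predict_proba([X[i] for i in split.test])[:, 1]
print(evaluate_predictions(y[split.test], conf).rounded())
```

```
{'accuracy': 1.0, 'precision': 1.0, 'recall_sensitivity': 1.0,
 'specificity': 1.0, 'f1': 1.0, 'auc': 1.0}
```

At coupling strength 2.0 the planted daytime signal (activity volume,
fragmentation and evening activity all shifted with the upcoming night's
class) is strong enough for the CNN to classify the 12 held-out nights
perfectly; at coupling 0 the same pipeline hovers at AUC ≈ 0.5.

The same flow is available from the shell:

```bash
actisleep run-all --seed 7 --out runs/demo          # simulate → … → evaluate
actisleep simulate --seed 7 --out runs/sim
actisleep score --sim-dir runs/sim --out runs --seed 7
```

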