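# herdsense

Classify dairy-cow behaviour — feeding, moving, resting, ruminating and
standing still — from a single flank-mounted tri-axial accelerometer
sampled at 5 Hz, using an 8-layer 1D convolutional neural network.

Continuous behaviour monitoring is the basis of precision-livestock
health surveillance: changes in time spent feeding, resting or
ruminating are early signs of lameness, respiratory disease and
management problems. A sensor on the left paralumbar fossa measures the
gravity vector projected onto its axes (X vertical, Y parallel to the
ground, Z orthogonal to the flank when the cow stands), so posture
re-orients the signal and behaviours add characteristic dynamics: an
approximately 1 Hz chewing oscillation while ruminating or feeding, and
movement bursts while walking.

## Method

The pipeline, stage by stage:

1. **Trace I/O** — labelled CSV traces (timestamp, aX, aY, aZ,
   behaviour) are read, samples with an `unclear` label are excluded,
   and the stream is segmented into label-contiguous, gap-free runs.
2. **Feature engineering** — each sample becomes 15 variables: the raw
   X/Y/Z values and, per axis, the trailing 15-sample rolling average
   and sample standard deviation, the percentage change
   100·(xₜ − xₜ₋₁)/xₜ₋₁, and its binary sign indicator (0 if negative,
   else 1).
3. **Windowing** — overlapping windows of 40 time-steps (8 s) with
   stride 13 form observation units: (40, 15) tensors, each labelled
   with its run's single behaviour. Units are split 80/20 into
   train/test and z-scored with training-set statistics only.
4. **Model** — a sequential stack: Conv1D(128, k=3) → Conv1D(64, k=3) →
   Conv1D(32, k=3) (all valid padding, stride 1, ReLU) → Dropout(0.3) →
   MaxPool(2) → Flatten → Dense(100, ReLU) → Dense(5, softmax);
   91,709 trainable parameters. Trained with Adam on categorical
   cross-entropy, batch size 32. The network is implemented on the
   package's own NumPy backend (im2col convolutions, analytic
   backpropagation, Adam), and an independent analytic audit of the
   layer arithmetic must agree with the instantiated weight arrays
   before any training runs.
5. **Evaluation** — confusion matrix (rows actual, columns predicted)
   and per-class precision TP/(TP+FP), recall TP/(TP+FN),
   F1 = 2pr/(p+r), with overall accuracy and macro/support-weighted
   averages.

Because farm recordings of this kind are rarely shareable, the package
includes a seeded generative simulator (`herdsense.synth`) producing
labelled 5 Hz traces with behaviour-dependent orientations,
oscillations, bursts and realistic class imbalance, so the entire
pipeline is runnable and testable end to end with no external data.

## Worked example

```python
from herdsense import pipeline

cfg = pipeline.RunConfig(seed=1, difficulty="realistic")   # 4 simulated cows, 55 min each
report = pipeline.run_pipeline(cfg, "out/demo")
```

The run log shows the bookkeeping of every stage:

```
simulated 4 cow(s), difficulty=realistic, 55 min each
samples read: 65995, excluded as unclear: 2208
label-contiguous runs: 237 (0 too short to featurize)
observation units (40x15, stride 13): 4045
split: train=3236 test=809 (fraction 0.8, seed 1); updates/epoch=102
trained 30 epochs, batch 32; 91709 parameters
test accuracy 0.9654, macro F1 0.9621
```

and `out/demo/eval_report.txt` holds the held-out metric table:

```
Behaviour        Precision    Recall        F1     Units
--------------------------------------------------------
feeding               0.99      0.97      0.98       158
moving                0.89      0.97      0.93       168
resting               0.99      1.00      0.99       253
ruminating            1.00      0.97      0.98       101
standing_still        0.97      0.88      0.92       129
--------------------------------------------------------
Accuracy                                  0.97       809
Macro avg             0.97      0.96      0.96       809
Weighted avg          0.97      0.97      0.97       809
```

Resting — the behaviour with the most distinctive (lying) orientation
and the most data — is classified best, while the three standing-family
behaviours account for most confusions; 809 is the number of held-out
observation units. The same objects are scriptable stage by stage
(`simulate`, `featurize`, `window`, `train`, `evaluate`, `run`,
`audit`) through the `herdsense` command; `herdsense audit` prints the
layer-by-layer output shapes and parameter counts:

```
          layer      type output_shape  params
       conv1d_1    conv1d    (38, 128)    5888
       conv1d_2    conv1d     (36, 64)   24640
       conv1d_3    conv1d     (34, 32)    6176
      dropout_1   dropout     (34, 32)       0
max_pooling1d_1 maxpool1d     (17, 32)       0
      flatten_1   flatten       (544,)       0
        dense_1     dense       (100,)   54500
        dense_2     dense         (5,)     505
Total trainable parameters: 91,709
```

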