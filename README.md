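# ripplekit

Detection and interpretation of hippocampal **sharp-wave ripples (SWRs)**
from multichannel local field potentials (LFP).

SWRs are brief CA1 events — a slow sharp-wave deflection across the
somatodendritic axis plus a 100–250 Hz ripple burst maximal at the stratum
pyramidale — that accompany memory replay. `ripplekit` is for
electrophysiologists who need to detect them automatically, offline or in a
causal streaming setting, and to understand *what* a learned detector
responds to.

The toolkit provides:

* **`ripplekit.synthetic`** — a seeded generator of annotated 8-channel
  laminar sessions (1/f background, theta epochs, depth-profiled SWRs,
  broadband artifacts), so every stage is testable without external data.
* **`ripplekit.io`** — LFP file formats (int16 + JSON sidecar, HDF5),
  downsampling to 1250 Hz, z-scoring, slicing into 57.6 s chunks (72,000
  samples) and soft labels: each 32 ms (or 12.8 ms) window is labelled with
  the fraction of it covered by an annotated event.
* **`ripplekit.cnn`** — the fully-convolutional detector: seven blocks of
  Conv1D → BatchNorm → LeakyReLU(0.1) and a per-step sigmoid unit. Kernel
  size equals stride (5,1,2,1,2,1,2 for CNN32; 2,1,2,1,2,1,2 for CNN12;
  4,2,8,4,16,8,32 kernels), so an L-sample input yields ⌊L/40⌋ or ⌊L/16⌋
  probabilities p(SWR) at 32 / 12.8 ms resolution. Trained with Adam on
  binary cross-entropy

      H = −(1/N) Σᵢ [ yᵢ log p(yᵢ) + (1−yᵢ) log(1−p(yᵢ)) ]

  with soft labels yᵢ ∈ [0,1] and L2 (5e-4) on conv kernels. Events are
  extracted with a dual threshold: a run of windows above the onset
  threshold containing at least one window above the confirm threshold.
* **`ripplekit.spectral`** — the Butterworth baseline: 100–300 Hz
  second-order zero-phase band-pass, rectified/smoothed envelope, dual
  thresholds in SD units with a 15 ms merge rule, a 60-combination grid
  search, and a causal online variant with an artifact veto channel.
* **`ripplekit.evaluate`** — event-level scoring: two intervals match when
  IoU = |∩|/|∪| ≥ 0.1 (greedy one-to-one matching); precision, recall,
  F1 = 2PR/(P+R), threshold-robustness curves, time-to-peak, and
  inter-annotator agreement.
* **`ripplekit.features`** — per-event spectral features on 100 ms windows:
  ripple-envelope peak, preferred frequency after subtracting a fitted
  exponential decay, <100 Hz power fraction, and spectral entropy
  −Σ p_f log₂ p_f.
* **`ripplekit.interpret`** — gradient-ascent kernel saliency maps,
  concatenated kernel-activation feature maps, sliding template matching,
  and 2-D UMAP embeddings of feature maps.
* **`ripplekit.probe`** — simulated 8-channel penetrations swept along a
  dense probe (advance by 4 sites) and current-source density
  (second spatial derivative) maps.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import numpy as np
import ripplekit as rk

# 1. a synthetic training session (default study conditions, ~0.2 events/s)
params = rk.GeneratorParams(duration_s=2304.0, fs_raw=1250.0, seed=11)
session = rk.generate_session(params)
print(len(session.ground_truth))          # 416 annotated SWR events

# 2. training tensors: X (chunks, 72000, 8), Y (chunks, 1800, 1)
ds = rk.prepare_dataset(session.recording, session.ground_truth)
print(ds.X.shape, ds.Y.shape)             # (40, 72000, 8) (40, 1800, 1)

# 3. train CNN32 and detect on a held-out session
model = rk.build_model(rk.ArchitectureConfig.cnn32(), seed=0)
model, history = rk.train(model, ds, rk.TrainingConfig(epochs=200, seed=0))
held = rk.generate_session(rk.GeneratorParams(duration_s=600.0,
                                              fs_raw=1250.0, seed=99))
rec = rk.zscore(held.recording)
trace = rk.predict(model, rec)            # one probability per 32 ms window
det = rk.extract_events(trace, thr_onset=0.5, thr_confirm=0.7)

# 4. event-level scoring against the ground truth
m = rk.metrics(rk.match(det.events, held.ground_truth,
                        duration_s=rec.duration_s))
print(f"P={m.precision:.2f} R={m.recall:.2f} F1={m.f1:.2f}")
# P=1.00 R=0.78 F1=0.87
```

The trace assigns one SWR probability to every non-overlapping 32 ms
window; `extract_events` turns it into intervals, and the F1 line says that
at the (0.5, 0.7) thresholds every detection is a planted event and 78 %
of planted events are found. Sweeping the candidate threshold grid
(`rk.sweep_thresholds`) raises the best-threshold F1 to ≈ 0.99 on this
session.

The filter baseline on the same session:

```python
env = rk.envelope(rk.bandpass(rec.data[:, 2]))     # pyramidal channel
(t1, t2), table = rk.grid_search(env, held.ground_truth,
                                 duration_s=rec.duration_s)
print(t2, round(table.f1.max(), 3))       # 5.0 (SD units), 0.904
```

A command-line interface mirrors the library
(`ripplekit generate / prepare / train / detect / evaluate / features /
saliency / embed / sweep`); run `ripplekit --help`.

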