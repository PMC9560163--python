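# Methods

## Problem and approach

Hippocampal sharp-wave ripples (SWRs) are brief CA1 events combining a slow
sharp-wave deflection across the somatodendritic axis with a fast
(100–250 Hz) ripple oscillation maximal at the stratum pyramidale (SP).
`ripplekit` detects them in 8-channel laminar LFP with two methods that share
one evaluation pipeline:

1. a fully-convolutional 1-D network (CNN32 / CNN12) that maps the raw
   z-scored multichannel signal to one SWR probability per non-overlapping
   window, and
2. a spectral baseline: band-pass filtering, envelope extraction and
   dual SD-unit thresholds.

Everything is testable without external recordings through a seeded
synthetic laminar-LFP generator.

## The network

Seven blocks of Conv1D → BatchNorm → LeakyReLU(α = 0.1), then a per-time-step
dense unit with a sigmoid. Kernel size equals stride in every conv layer
(no pooling), so the network is fully convolutional and behaves identically
offline and in streaming use: an input of L samples yields ⌊L/S⌋
probabilities, with S = 5·1·2·1·2·1·2 = 40 samples (32 ms at 1250 Hz) for
CNN32 and 2·1·2·1·2·1·2 = 16 samples (12.8 ms) for CNN12. Kernel counts are
4, 2, 8, 4, 16, 8, 32. Training minimizes binary cross-entropy against soft
labels (the fraction of each window occupied by an annotated event, used
as-is without binarization) with Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7),
batches of 16 chunks, and an L2 penalty of 5e-4 on conv kernels; chunks are
split 70/30 into train/development sets by a seeded shuffle.

The network is small (~2.5 k parameters), and because stride equals kernel
size each convolution reduces to a block reshape followed by a matrix
product. The model is therefore implemented directly in NumPy with
hand-written forward/backward passes (BatchNorm uses momentum 0.99 and
ε 1e-3, running statistics at inference), which keeps training exactly
reproducible from a seed, runs in well under a second per epoch per ten
chunks on one core, and exposes the input gradients the saliency analysis
needs. BCE clips probabilities at ε = 1e-7.

Numerical/degenerate choices: probability traces index half-open windows
`[i·w, (i+1)·w)`; a dual-threshold event is a maximal run of windows at or
above the onset threshold containing at least one window at or above the
confirm threshold (the degenerate case onset = confirm reduces to simple
thresholding); detection time is the run start so anticipation is
measurable; CNN events are not gap-merged (merging belongs to the filter
pipeline only). The streaming simulation (CNN12) hops half a window
(6.4 ms), z-scores with statistics from a calibration prefix (default 60 s)
and emits each probability at the end of its window, making the trace
strictly causal.

## Data preparation

LFP is downsampled to 1250 Hz by zero-phase 8th-order Butterworth low-pass
at 0.4·target rate followed by integer decimation (the source rate must be
an integer multiple), then z-scored per channel over the whole session —
session scope mirrors the single calibration epoch of online use, and
z-scoring twice is a no-op. Sessions are sliced into 57.6 s chunks (72,000
samples; 1800 32 ms or 4500 12.8 ms windows exactly); the trailing
remainder is dropped and logged. Chunks with no events are retained by
default for unbiased evaluation (`drop_empty` restores discarding). Events
straddling a chunk border contribute their overlap to each side; labels are
clipped at 1 (reachable only with overlapping annotations). Channel
selection keeps all SP-labelled channels first and fills the remainder by a
seeded uniform draw, output ordered by depth.

## The spectral baseline

Offline: zero-phase second-order Butterworth band-pass 100–300 Hz;
envelope = rectification with a fixed gain, fourth-order Savitzky-Golay
smoothing (11-sample frame, 8.8 ms — an SG frame must be odd), then two
moving averages of 2.3 and 6.7 ms, rectified again. Thresholds are in SD
units of the envelope, applied to the centered envelope
((env − mean)/SD ≥ k): the rectified envelope's mean typically exceeds
1–2.5 × its SD, so thresholding the raw envelope at the low multipliers of
the candidate grid would select one session-long run; centering keeps every
grid value meaningful while preserving scale invariance (any constant gain
cancels). A candidate run is bounded by the first threshold and must reach
the second; events closer than 15 ms are merged after the second-threshold
filter (merging candidates first would let two sub-threshold bumps pass
jointly). The grid search evaluates 4 first-threshold × 15 second-threshold
= 60 combinations and returns the F1-argmax (ties → higher thr2, then
higher thr1). The online variant thresholds the causally filtered signal
with a calibration-prefix SD and discards events co-occurring on a veto
channel.

## Evaluation

Event-level IoU matching with the ≥ 0.1 criterion: greedy in descending
IoU, one-to-one (each prediction and truth event used at most once; TP is
per matched truth event, so a truth event hit by several predictions counts
once and the extras are FPs). This greedy rule is deterministic and is
oracle-checked against an exhaustive optimal assignment in the tests. True
negatives are counted at window resolution — the only resolution at which
"nothing happened here" is enumerable. P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); 0/0 returns 0 with an explicit flag. Time-to-peak is
detection onset minus ripple-envelope peak time (negative = anticipation).
Threshold sweeps emit a normalized-threshold axis (θ/θ*) for robustness
curves; the CNN candidate grid is 15 onset × 8 confirm values, pairs with
onset above confirm being skipped as ill-formed.

## Event features

All features use a 100 ms (125-sample) window around the event center on
the pyramidal channel. The PSD estimator is a plain periodogram (no taper):
the window is too short for averaging estimators and the 10 Hz bin grid is
the natural resolution. Preferred frequency: periodogram of the 70–400 Hz
band-passed window, minus a least-squares fit of a single-term exponential
a·e^{bf} (log-linear initialization, nonlinear refinement) to correct the
1/f decay; if the fit fails or leaves no positive residual the raw argmax
is returned with a flag. The <100 Hz contribution uses the uncorrected
full-band spectrum. Spectral entropy is −Σ p_f log₂ p_f of the
sum-normalized spectrum with 0·log 0 = 0. Ripple peaks use a third-order
70–400 Hz Butterworth, SG smoothing and 3 + 6.5 ms moving averages.

## Interpretability

Saliency maps maximize the mean kernel activation (the raw conv output,
i.e. the kernel activation proper; for the output unit, the pre-sigmoid
logit, which is monotone in the probability) over an 8×S input patch by
SGD gradient ascent with lr 0.1 and momentum 0.1, initialized from
N(0, 0.01), stopping when the mean squared input change drops below 1e-9 or
after 2000 iterations. Normalizing the activation by its number of output
time steps makes the objective window-length invariant. The network is
piecewise linear, so individual SGD steps can cross activation kinks and
dip; the optimizer therefore tracks and returns the best input seen, making
the recorded (accepted-step) activation history monotone by construction.
A vanishing gradient returns a flagged non-converged map.

Feature maps concatenate every conv block's activations in fixed
(block, kernel, time) order — post-ReLU by default, with a flag for raw conv
outputs — plus, behind a flag that defaults on, the dense outputs. The
vector length is validated at runtime against the architecture formula
Σ_blocks ⌊L/ cumulative stride⌋ · n_filters (+ dense terms); this formula is
authoritative, and no fixed length constant is asserted anywhere. Template
matching is the unnormalized sliding cross-correlation (sum of elementwise
products per lag) of a saliency patch against a z-scored 8×125 event window
centered on the LFP trough nearest (±10 ms) the ripple-envelope maximum.
Embeddings use UMAP with default neighborhood parameters (n_neighbors 15,
min_dist 0.1) and a fixed seed for reproducible figures; the embedding
algorithm is consumed from `umap-learn`, not re-derived.

## Laminar-probe utilities

Simulated penetrations take n = 8 depth-consecutive sites and advance by
4, ordered by depth with ties broken by lateral position so checkerboard
columns alternate naturally; the group-count arithmetic
⌊(N−n)/step⌋+1 is exposed rather than any probe-specific constant.
Current-source density is the plain second spatial difference
(V_{i−1} − 2V_i + V_{i+1})/Δz² on uniformly spaced channels (edge channels
dropped), with conductivity treated as an isotropic constant, so values are
in arbitrary units; optional 3-point spatial smoothing is display-only.

## Synthetic sessions

The generator emulates an 8-channel, 20 µm-pitch laminar probe. Background
is unit-SD 1/f^β noise per channel (β = 1, a representative broadband LFP
slope) with optional theta epochs — a 6–10 Hz oscillation of 1.5 SD in
alternating block structure (10 s blocks, default fraction 0.5) — so events
occur in both oscillatory states. Events arrive as a Poisson process
(0.2 Hz) thinned to a 250 ms refractory gap. Each event is a sharp wave
(asymmetric half-Gaussian lobes, rise dur/3 and fall dur/2, linear polarity
profile crossing zero one channel below the SP channel: positive above,
negative below) plus a ripple: a sinusoid at a truncated-normal frequency
(150 ± 20 Hz on [100, 250]) under a Gaussian envelope (σ = dur/4, duration
60 ± 20 ms on [30, 120] ms), maximal at the SP channel and decaying
exponentially with channel distance (length constant 1.2 channels).
Amplitudes default to 4 SD (sharp wave) and 3 SD (ripple) — a few SD over
background, typical of clearly visible events and chosen once for
detectability since real amplitude distributions vary widely across
preparations. Broadband artifacts (8 SD, 50 ms, Hann-tapered white noise,
0.05 Hz) are added identically on all channels and thinned so no event
overlaps an artifact. Annotated start/end are the 10% crossings of the
ripple envelope, mirroring the convention of marking the first and last
visible ripple. One RNG stream is consumed in a fixed order (background →
theta → events → artifacts), so sessions are bit-reproducible from the
seed.

What the generator does *not* emulate: spike transients and unit firing,
replay content, realistic CSD geometry beyond a linear dipole, non-Poisson
event clustering, electrode drift and movement artifacts restricted to
subsets of channels. Passing tests therefore demonstrate correct method
implementation and recoverability of planted structure, not performance on
real recordings.

## Problem sizes and defaults used in tests and the acceptance script

Sessions are generated directly at 1250 Hz (the generator supports 30 kHz;
the downsampling path is exercised separately on short 30 kHz segments).
Training uses a 2304 s session (40 chunks of 57.6 s, ≥ 300 events at the
default 0.2 Hz rate) for 200 epochs with the standard hyper-parameters; the
held-out session is 600 s, and feature/baseline tests use a 240 s session.
These sizes make the planted structure statistically recoverable while the
whole pipeline remains single-core friendly.

## Known limitations

* BatchNorm statistics are batch-global (per feature over batch × time), so
  streaming probabilities can differ slightly from offline ones when the
  calibration prefix is not representative.
* The exponential spectral correction uses a single-term exponential; an
  offset term can fit broad spectra better but is less stable on 34-bin
  windows.
* The greedy IoU matcher is not guaranteed optimal (it is in ≥ 95 % of
  random trials against the exhaustive oracle and is deterministic, which
  the grid searches require).
* The saliency optimizer uses a fixed learning rate; for kernels with
  nearly linear response the MSE stopping rule may never trigger and the
  iteration cap applies instead. First-layer kernels reach their preferred
  pattern well within the cap; the output unit's ascent can still be
  mid-climb at the cap on some trained models, in which case patches from
  different initializations agree less — a flagged, under-converged case
  rather than an error.
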