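# Methods

## Signal model and preprocessing

**ECG → heart rate.** QRS detection follows the Pan–Tompkins chain:
band-pass 5–15 Hz (2nd-order Butterworth, applied forward–backward so the
filter is zero-phase and R indices stay on the raw time axis), five-point
derivative, squaring, and 150 ms moving-window integration. Decision logic
uses running signal/noise levels updated with coefficient 0.125, a
threshold at noise + 0.25·(signal − noise), a search-back pass at half
threshold when more than 1.66× the running RR average elapses without a
beat, rejection of candidates within 360 ms of the previous beat whose
maximal band-passed slope is below half of that beat's slope (T waves), and
a 200 ms refractory period. Accepted candidates are refined to the local
extremum of the band-passed signal.

Beat timing gives inter-beat intervals in samples; the mean IBI
μ = (1/n) Σ (RRᵢ₊₁ − RRᵢ) converts to heart rate as HR = 60·FS/μ. The
per-second series splits the record into floor(window) one-second
segments; a peak belongs to segment k if its index lies in
[k·fs, (k+1)·fs), and the first peak after the segment is included so the
interval bracketing the boundary is attributed to the earlier segment.
When a segment has fewer than two usable beats — the situation in which
the mean-IBI formula is undefined, e.g. at rates below 60 BPM — its value
is the mean of the nearest preceding and following computed values; a
boundary gap takes the single nearest value. A record in which no segment
yields a value raises an explicit error rather than producing silent
zeros.

**Video.** Face crops are square expansions of the highest-confidence
detector box resized to 448×448. No landmark alignment is applied: head
movement is itself a behavioural pain cue, and de-rotating the face would
suppress it. The detector is an interface (boxes + confidences); the
bundled passthrough detector serves pre-cropped or synthetic input, and a
per-frame miss reuses the last successful box. Each crop yields four
disjoint 224×224 quadrants (TL, TR, BL, BR, half-open pixel ranges — the
quadrants reassemble the crop exactly) plus a bicubic 224×224 resize of
the whole crop.

## Architecture choices

Attention is the standard scaled dot-product softmax(QKᵀ/√d_k)V; all
blocks are pre-norm residual with GELU feed-forward networks. The
Transformer-in-Transformer encoder shares one set of weights across the
five images of a frame (separate towers would multiply the parameter count
several-fold) and uses learned 1-D position tables at both granularities,
shared across tiles, with a class-token readout through a final d×d linear
layer. Pixels are scaled to [−1, 1] with fixed constants.

The heart-rate encoder and the temporal classifier are perceiver-style:
a small learned latent array queries the input tokens through
cross-attention, making attention cost linear in the input length. Both
use Fourier position features — the normalised coordinate plus sin/cos
pairs at 32 frequencies log-spaced up to the Nyquist frequency of the
token axis. The heart-rate readout flattens the 4×512 latent array to
2048 without an extra projection. The bicubic expansion arranges the
2048-vector on a 32×64 grid, resamples with the Keys cubic kernel
(a = −0.5, half-pixel centres, edge replication — cross-checked against
Pillow's BICUBIC in the grid interior), flattens row-major and truncates
to the exact target length; it reproduces constants exactly and is the
identity at equal sizes.

The temporal tokenisation slices the embedding into 100-wide tokens,
matching the per-frame width of the video embedding so attention positions
align with session time; inputs that do not divide evenly are zero-padded
and the padding reported. Each token stream is scale-normalised per sample
(division by its own max absolute value) so predictions are independent of
batch composition. Latents are mean-pooled before the linear head
(parameter-free readout).

**Free hyperparameters.** The printed parameter budgets constrain widths
the architecture description leaves open. Fixed once: spatial inner width
24 with feed-forward widths 96 (inner) and 600 (outer) → 2 566 064
parameters; heart-rate feed-forward width 3232 → 4 404 384; temporal
32 latents and feed-forward width 1300 → 1 629 266 (binary head); AugmNet
widths 13 800→36→170→36→13 800 → 1 019 882. Totals: 9 619 596 (training),
8 599 714 (inference, AugmNet excluded). FLOP figures are analytic matmul
counts (2·m·n·k) for one forward pass at the default shapes and are
reported for orientation, not gated.

**AugmNet objective.** The augmenter is trained end-to-end by the
downstream classification loss alone; its narrow mixing layers (36 wide)
force information loss, which is the corruption mechanism. No separate
reconstruction or adversarial loss is attached.

**Multi-task loss.** The homoscedastic-uncertainty combination is
implemented as Σᵢ e^{−wᵢ}·Lᵢ + wᵢ with learned wᵢ. The sign in the
exponent matters: with e^{+w}L + w the objective is unbounded below in w,
so the standard bounded form is used. Its stationary point for constant L
is w* = ln L, giving per-task contribution 1 + ln L — both verified
analytically in the tests.

**Training.** AdamW with decoupled weight decay 0.1, base learning rate
1e-4, linear warmup (50 epochs) then cosine decay, batch size 32. The
spatial and heart-rate encoders act as frozen feature extractors
(seeded random initialisation or a supplied checkpoint) and the temporal
module — optionally jointly with AugmNet — is trained on the resulting
embeddings. Training the encoders through pixel-level backpropagation, or
pretraining them on external face/emotion/ECG corpora, is out of scope
here. Evaluation is leave-one-subject-out: one fold per subject, fold
confusion matrices summed before computing accuracy and macro
precision/recall/F1 (pooling is invariant to fold size).

## Synthetic data: what it does and does not emulate

The generator reproduces the protocol's structure exactly: per subject,
20 baseline (NP) sessions and 20 per pain level in a subject-seeded random
order (8 700 sessions at the defaults); 448×448 frame sequences at
round(window·fps) frames; ECG of round(window·fs) samples with R peaks
placed at round(60·fs/BPM) spacing, so every downstream quantity has exact
ground truth. Label effects are injected as (i) a facial-stroke
deformation proportional to pain level that ramps toward the session end,
mimicking the late manifestation of pain in a stimulation window, and
(ii) a heart-rate offset of `bpm_per_level` BPM per level over a subject
baseline drawn from N(72, 7²). Defaults (3 BPM and 3 px per level,
ECG noise 0.05 of R amplitude) make classes separable but overlapping
across subjects. The faces are geometric surrogates: tests exercised on
them demonstrate the pipeline's mechanics, determinism and capacity, not
recognition of real facial expressions; likewise the ECG wavelet train
lacks arrhythmias, electrode artefacts and morphology variation, so
detector performance on it is an upper bound.

## Numerical conventions and degenerate inputs

All arithmetic is float64. Indices are 0-based; intervals stay in samples
until the final conversion to BPM. A flat or peak-free record returns an
empty peak series with a warning flag rather than raising; fewer than two
peaks raises an insufficient-beats error; windows shorter than 2 s are
rejected because the fill rule needs neighbours. Attention-map
normalisation maps a constant score field to an all-zero map instead of
dividing by zero. Autodiff gradients are verified against central finite
differences at 1e-4 relative tolerance.

## Problem sizes used in tests

Forward/training tests run reduced architectures (spatial depth 1 with
d = 16, temporal width 32) and short synthetic sessions (2 s at 2 fps /
256 Hz); the full-size defaults are exercised where instantiation or a
single forward pass suffices (parameter accounting, embedding dimensions).
The end-to-end check trains binary LOSO on 5 subjects × 40 binary
sessions (200 fused test predictions) with a strong injected effect
(6 BPM and 6 px per level) and requires the pooled accuracy to beat chance
at p < 0.01 by a one-sided binomial test — a functioning-pipeline floor,
not a reproduction of the study's accuracy figures, which would require
the real corpus and encoder pretraining.

## Known limitations

* Face detection ships only with the passthrough interface binding; a
  production detector must be plugged in by the caller.
* Video input is PNG frame directories; container formats need an
  external frame extractor.
* ECG I/O is two-column CSV.
* The frozen-encoder training strategy means video-modality accuracy on
  real data would understate what end-to-end-trained or pretrained
  encoders could achieve.
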