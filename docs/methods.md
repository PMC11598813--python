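# Methods

## Problem and scope

The package implements a 1-bit ({0,1}) convolutional classifier for
single-lead ECG beats under the AAMI five-class convention (N, S, V, F, Q),
plus the three transformations that make such a network implementable with
AND gates, popcounts and comparators only: merged convolution–pooling,
blockwise incremental inference, and batch-norm folding. It does not do
R-peak detection or signal denoising (annotations are taken as given), and
it does not emit RTL or estimate power — the latency and storage reports
count model cycles and stored values, never wall-clock time or joules.

## Network and training

Weights and activations are binarized with `b(x) = 1 if x > 0 else 0`, so
multiplication is logical AND. The first convolution (3 channels, 3×3,
stride 1) is followed directly by the zero-threshold binarization and a 2×2
OR-max-pool: there is deliberately *no* batch norm after the first layer,
because a zero activation threshold is the hypothesis under which the
merged convolution–pooling algebra is exact. Batch norm appears after the
depthwise-separable layer and both fully connected layers. The depthwise
popcounts (integers 0–9) are not binarized; channel mixing happens in the
pointwise step before BN and binarization.

Training uses the standard latent-weight straight-through-estimator recipe,
implemented directly in NumPy (manual backprop): latent real weights are
clipped to [−1, 1] and binarized at >0 in every forward pass; activation
binarizations pass gradients inside a window around the threshold (|x̂| ≤ 1
after BN; popcount ≤ 2 for the BN-free first layer); OR-max-pool routes
gradients equally to all maximal entries. Optimization is Adam with a
cosine learning-rate decay from 1e-3 to 1e-4, cross-entropy loss, batch
size 128, early stopping on validation loss with patience 10, all seeded.
Batch statistics train the BN layers; exponential running statistics
(momentum 0.9) serve inference and folding. The softmax exists only on the
training/reference path — deployed classification is the argmax of the
FC2-BN outputs, with ties broken toward the lowest class index
(N < S < V < F < Q).

## Merged convolution–pooling (MCP)

For binary windows w and kernels k with threshold 0,
`b(popcount(w AND k)) = OR(w AND k)`, and OR-pooling shifted outputs equals
a single pass with the OR of correspondingly shifted kernels. The merged
kernel has side `K_R = K_O + S_O(P−1)` and stride `S_R = S_O·S_P`; with the
default 3×3/stride-1 kernel and 2×2/stride-2 pool that is 4×4/stride-2.
Zero bits cannot affect an OR-reduction and are pruned. The equivalence is
verified exhaustively (all 2^16 4×4 images × 50 kernels) and at scale
(10,000 random 32×32 images); it is claimed *only* for threshold 0, and
`build_mcpk` rejects any attempt to merge after a folded (nonzero)
threshold. The baseline operation count against which the merged count is
quoted prices a 2×2 pool window at 2 operations
(`30²·3·9 + 15²·3·2 = 25,650` vs `15²·3·16 = 10,800` merged); that pooling
convention is a counting choice, stated here once.

## Blockwise incremental inference

The input image is cut into `M_D² = 169` overlapping blocks of side
`K_R + S_R(K_D−1) = 8`, origin stepping by `S_R = 2`. Each block passes
through MCP (3×3×3 bits), depthwise (1×1×3 popcounts), pointwise plus
integer threshold (1×1×18 bits), and multiplies the 18 FC1 weight rows that
its position owns (flatten order: row-major over (i, j), channel fastest).
Because integer accumulation is order-independent, the accumulated FC1
pre-activations equal the layerwise ones exactly — the engines are
interchangeable and tested bit-for-bit. Latency is modeled in the
one-operation-per-cycle convention: layerwise `L = M_C² + 2M_D² + K_P·M_D²
= 3605`; blockwise `LB = (K_D²+1+1+K_P)·M_D² = 4901`; with the feature
stages pipelined behind FC1, `K_P·M_D² = 3042`. The pipeline is modeled
analytically (the formula fully determines the number), not by an event
simulator; published hardware adds ~45 control cycles on top of the 3042,
which this model deliberately does not claim. The geometry formula
`M_C = (M − K_R)/S_R + 1` generalizes the 2×-downsampling special case
`(M − K_R + P)/2` and errors on non-tiling configurations.

## Batch-norm folding and the integer twin

For integer pre-activations s and γ > 0,
`γ(s−μ)/√(σ²+ε) + β > 0 ⇔ s > ⌊μ − β·√(σ²+ε)/γ⌋` — flooring is exact, not
an approximation, so the folded comparator classifies identically to the
floating-point reference. For γ < 0 the comparison flips
(`s ≤ ⌈t⌉−1`) and the channel is flagged; γ = 0 is a non-invertible fold
and an error. The FC2 BN, which feeds the final comparison rather than a
binarization, becomes a per-class lookup table over the attainable FC2
popcounts (0…32).

The LUT is kept at two precisions. Classification uses full float64
entries, computed with the same expression as the reference BN, which makes
integer/float argmax agreement exact by construction — matching the
invariant that folding must not change any classification. A 13-bit signed
fixed-point view with 6 fractional bits mirrors the hardware registers; a
2^-6 quantization step can in principle flip a near-tie between two
classes, so `fold_model` additionally checks every cross-class pair of
entries and reports whether the quantized table preserves all orderings
(`quantization_order_safe`) — when it does, the hardware-width twin is
certified to classify identically too. Strict mode also checks the declared
register widths (4-bit depthwise, 12-bit FC1 accumulators, 5-bit FC2 sums)
and raises on overflow. Whether LUT outputs are compared before or after a
shared monotone rescaling is immaterial to the argmax and left unspecified.

A note on the folding arithmetic: with BN parameters printed to four
decimals (μ=0.8035, β=−2.0248, σ=0.9242, γ=0.7093, ε=1e-4) the bound
evaluates to 3.4419; dropping the negligible ε gives 3.4418. Both floor
to 3; the package always keeps ε inside the square root.

## Synthetic data: what it emulates and what it does not

The generator exists so that every stage is testable without downloads. A
beat is five Gaussian bumps (P, Q, R, S, T) on 300 samples at 360 Hz with
the R peak pinned to index 100, ±10% seeded jitter on amplitudes and
widths, and white noise at 20 dB SNR. Class identities: N is the nominal
morphology; V widens the QRS, drops the P wave and inverts T; F averages N
and V; Q draws a fresh random morphology per beat; S shares N's morphology
and is marked by a preceding RR interval at 60% of the nominal 0.8 s —
deliberately, because the S class is the one whose detectability rests on
the RR feature rather than shape. Records concatenate beats with ±10%
RR jitter and annotate peaks and labels.

This is a separability fixture, not a physiological simulator: it has no
baseline wander, electrode artifacts, inter-patient morphology drift,
rhythm context beyond one RR interval, or realistic class imbalance
dynamics. Passing the end-to-end criterion (>60% five-class accuracy on
held-out synthetic beats, chance 20%) therefore shows that the *pipeline*
learns and that every deployment transformation preserves its decisions —
it says nothing about accuracy on real ambulatory recordings, which depends
on data the tests do not use. The default end-to-end scale — 2,000 beats,
70/9/21 patient-specific split, z-score augmentation to the majority-class
count, 25 training epochs — is the package's chosen desk-scale study
condition; a typical seeded run reaches ~84% held-out accuracy through the
folded blockwise integer path.

## Preprocessing choices

Rasterization is not standardized by common practice, so the package
declares one: the beat is scaled to a 300×128 canvas (minimum amplitude at
the bottom row, row 0 on top), consecutive samples are joined by vertical
1-px runs so the trace is connected, and the canvas reduces to 32×32 by
block-max — a block containing any trace pixel maps to 1, preserving thin
traces that averaging would erase. The RR feature is rr_prev normalized by
the record's median RR and quantized to 4 unsigned bits (code 8 = nominal);
four bits is the width consistent with an FC1 input of 3042 image features
plus the RR code. A record's first beat takes the median RR rather than
being dropped. Z-score augmentation perturbs μ′ within μ±0.1σ and σ′ within
[0.9, 1.1]σ — small enough to preserve class identity — and is never
applied to validation or test partitions. Splits are 70% train, then 30/70
of the remainder to validation/test, drawn per record (patient-specific) or
over whole records (patient-wise).

## Numerical and interface choices

- All randomness flows through seeded `numpy.random.Generator`s; identical
  seeds give bit-identical records, splits, and trained weights.
- Weight bundles are JSON with base64 bit-packed masks and decimal BN
  parameters; round-trips are bit-exact.
- Zero-denominator metrics are reported as NaN with a warning, never 0;
  display rounding is two decimals, round-half-even. Raw ratios are always
  available next to the percentages.
- The FC2 input is the 32 FC1 bits only; the RR code enters at FC1.
- Records are exchanged as plain-text CSV (samples and annotations) with a
  JSON header, readable and writable by the package itself.

## Known limitations

- The STE trainer is a compact reference, not a performance-tuned one; it
  targets the desk-scale study conditions above, and very large runs would
  benefit from a GPU framework.
- The latency model counts the published micro-steps only; control overhead
  and memory ports are out of scope.
- The 13-bit fixed-point LUT is certified per-model by the order-safety
  check rather than guaranteed a priori; models whose FC2-BN outputs
  nearly tie at some popcount may classify differently at hardware width
  (the check reports exactly this).
- Real-data (WFDB) ingestion is limited to what the CSV interchange
  expresses: sample stream, annotated R-peak indices, labels, sampling
  rate.
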