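# Methods

This note records the model, the numerical conventions, the design
choices made where the design was genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Entropy core

ASPE is permutation entropy with amplitude weighting: each delay-embedded
vector contributes to its ordinal-pattern frequency in proportion to its
coefficient of variation (CV), and the Shannon entropy of the weighted
distribution is normalized by log₂(m!). Conventions:

- **Embedding.** `m` ≥ 2 (≤ 10 so m! is exact in float64), delay `τ` ≥ 1;
  N = T − (m−1)τ vectors. Series shorter than (m−1)τ + 1 are rejected
  with the required minimum named.
- **Ordinal ties** break toward the earlier original index (stable
  argsort) — the dominant convention in the ordinal-pattern literature,
  and deterministic.
- **CV denominator.** The CV is undefined for zero-mean vectors, which
  are common in zero-mean EEG. The weight is std(Y)/max(|mean(Y)|, ε)
  with ε = 1e−12 × the signal's amplitude range (or 1 for a constant
  signal). Weights are therefore finite and nonnegative; within the
  well-posed regime the plain CV is returned unchanged.
- **Standard deviation** uses the sample (n−1) denominator by default,
  matching the numerical environment most published entropy work uses;
  a config switch (`sample_std=False`) selects n.
- **Degenerate total weight.** A constant signal gives all-zero weights;
  the distribution falls back to unweighted pattern frequencies, which
  puts probability 1 on the single tie-broken pattern and yields entropy
  exactly 0 (a constant signal has zero complexity).
- 0·log 0 ≡ 0; probabilities are normalized by the binned weight sum so
  a single-pattern series scores exactly 0 (no summation-order residue).

ASPE is exactly invariant under positive rescaling (patterns and CVs are
scale-free); bit-exactness of that invariance holds for power-of-two
factors, and to ~1e−14 otherwise (rounding of the scaled samples).

## Multiscale families

- **RCMASPE(s)**, s = 1…S_max (default 10): the s phase-shifted
  coarse-grained subsequences (window mean, width s) have their m!-bin
  weighted pattern distributions averaged element-wise; the entropy of
  the average is reported. Averaging distributions before the entropy
  stabilizes large-scale estimates where each subsequence is short.
  Trailing samples that do not fill a window are dropped per
  subsequence, following the window-index algebra literally. Scale 1
  reduces exactly to ASPE.
- **TSMASPE(k)**, k = 1…K_max (default 10): the mean ASPE of the k
  interleaved decimated subsequences. Lag 1 reduces exactly to ASPE.
- A scale or lag whose shortest subsequence is below the embedding
  minimum raises a descriptive error. Constant subsequences inside a
  scale use the entropy-core fallback rather than aborting the scale.

## Wavelet sub-band entropies

`haspe_dwt` performs an L-level multilevel DWT (db4 by default),
reconstructs each of the L+1 bands by inverting with all other
coefficient sets zeroed, truncates every reconstruction to the input
length, and scores each band with ASPE, ordered [A_L, D_L, …, D₁].

- **Boundary extension** is symmetric (half-point), the common default
  in the numerical environments this kind of analysis is usually run in;
  it is exposed in `WaveletConfig`.
- **Perfect reconstruction** (the bands sum to the input within 1e−8
  relative) holds by linearity and is asserted in the tests.
- **Round-off-degenerate bands.** The detail bands of a constant signal
  are pure float round-off (~1e−15 relative). A band whose amplitude
  range is ≤ 1e−10 × the input range is scored 0 instead of the entropy
  of rounding noise. The threshold scales with the signal, preserving
  rescaling invariance.
- **Boundary kinks.** For a smooth monotone trend the detail bands are
  *not* numerically degenerate: the symmetric extension introduces
  genuine kink energy at the edges, so a ramp has zero entropy in the
  multiscale/time-shift features and in the approximation band, but not
  necessarily in the detail bands. This is a property of every standard
  extension mode, not an implementation artifact.

## Feature assembly and standardization

`extract_mde` groups [ASPE, RCMASPE(1..10)] (d_m=11), the L+1 band
entropies (d_h=5 at L=4), and TSMASPE(1..10) (d_t=10). All raw entries
lie in [0,1]. Because the classifier's gating nonlinearities
(tanh(x⊙w), exp(−γ·Var)) are scale-sensitive, features are z-scored per
column with statistics fit on the training fold only (switchable off);
scales are floored at 1e−12 and columns that were constant in training
map to exactly 0. The feature CSV (`m_0..m_10, h_0..h_L, t_1..t_10,
label`) round-trips float64 losslessly (17-significant-digit writing,
round-trip parsing).

## Classifier

Pathway gates: G_h = tanh(x_h ⊙ W_h_att), x_h' = x_h ⊙ G_h;
g_t = exp(−γ·Var(x_t)) with Var using n−1 (switchable), x_t' = g_t·x_t;
x_m' = x_m ⊙ W_m_att. Each gated vector feeds tanh(x'W + b) of width 16;
the concatenation feeds one tanh fusion layer of width 32 and a linear
layer to K logits; softmax (max-subtracted) gives posteriors.

Open design points resolved here:

- The final fusion network is realized as **one** hidden tanh layer of
  width 32 — exactly one fusion width is specified, depth otherwise
  open; this is the shallowest faithful reading.
- γ > 0 is enforced by softplus reparameterization so the quasi-Newton
  search stays unconstrained; the multiscale mask is unconstrained.
- **Initialization:** attention vectors and mask start at all-ones
  (neutral, pass-through gates so early optimization sees undistorted
  features), γ starts at 1, fusion/output weights ~ U(−a, a) with
  a = 1/√fan-in, biases 0. The RNG seed is the only randomness; training
  is bit-deterministic given the seed.
- **Optimizer:** full-batch L-BFGS-B (a limited-memory BFGS-family
  quasi-Newton method) on the cross-entropy, max 50 iterations, max 10⁶
  function evaluations. No mini-batching — the objective is full-batch
  by construction.
- **Loss:** mean cross-entropy with natural log. The training objective
  uses the numerically stable log-softmax form; the standalone
  `cross_entropy` operation floors probabilities at 1e−15. The analytic
  gradient backpropagates through every block, including the softplus
  chain for γ and the per-sample variance inside the stability gate; it
  is verified against central finite differences (h=1e−6, 1e−5 relative)
  across random architectures in the tests.

Models serialize to versioned JSON (arrays, config echo, seed);
load→save round trips are byte-stable.

## Evaluation protocol

Folds are stratified with contiguous within-class blocks in dataset
order (fold f takes block f of every class; remainders go to earlier
folds), matching the sequential protocol used with balanced benchmark
segment sets; a seeded shuffled mode permutes within class first. Five
metrics — accuracy, precision, recall, specificity, F1 — are computed
from confusion-matrix counts as percentages; for K > 2 classes,
one-vs-rest per-class values plus macro averages are reported (a
standard, documented convention; several aggregations circulate in the
literature and are not mutually derivable). Zero-denominator metrics
return 0 with an explanatory flag. Cross-validation fits the
standardizer and the classifier on training indices only (no leakage),
derives per-fold training seeds from the master seed, and reports
per-fold metrics, mean ± sd, and the summed confusion matrix.

## Synthetic test bed

The generator emulates the stylized contrast that the method exploits,
not physiological EEG:

- **background**: zero-mean 1/f^α colored noise, α = 1 (the standard
  stylized resting-EEG spectrum), unit variance, via spectral shaping;
- **ictal-like**: background plus a sustained 3 Hz spike-wave train
  (a ~60 ms-FWHM spike followed by a dominant slow half-wave, 10%
  cycle-amplitude jitter) with RMS twice the background RMS;
- **interictal-like** (three-class preset): background plus sparse
  isolated biphasic transients (0.5 events/s, 4 background-SD peaks).

Defaults are 23.6 s segments at 173.61 Hz (4097 samples), 100 segments
per class. Per-signal seeds derive from one master seed and are recorded
in a manifest; regeneration from the manifest is bit-identical.

What passing tests show: the pipeline separates ordered-rhythmic from
disordered-broadband dynamics end to end, the implementation's
arithmetic matches independent brute-force oracles, and every stage is
seed-reproducible. What they do not show: performance on real EEG, with
its artifacts, inter-patient variability, non-stationarity and mixed
acquisition conditions — the synthetic classes are far more separable
than clinical data, so the near-perfect synthetic CV accuracy is a
correctness check, not a performance claim.

## Problem sizes and limitations

The shipped test suite and the acceptance script use the default
dataset size (200 segments × 4097 samples; feature extraction ~50 s,
training seconds) — chosen as the canonical balanced two-class segment
count for this segment length. Known limitations: single-channel
analysis only; no artifact removal or preprocessing; the sequential
fold protocol does not enforce patient-wise separation (by design, to
mirror common benchmark practice); EDF support covers standard 16-bit
headers via mne, and the bundled EDF writer is a minimal fixture
generator, not a clinical exporter.
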