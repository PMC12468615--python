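# eegentropy

Entropy-based feature extraction and structure-aware classification for
EEG seizure detection.

Seizure onset shows up in the EEG as a transition from complex,
desynchronized broadband activity to lower-dimensional, rhythmic,
high-amplitude patterns (spikes, sharp waves, spike-and-wave complexes).
`eegentropy` quantifies this transition with a family of ordinal-pattern
entropies and classifies the result with a small gated neural network
whose architecture mirrors the structure of the feature set. It is aimed
at researchers working with single-channel EEG segment benchmarks
(ASCII segment files at 173.61 Hz, EDF recordings at 256 Hz) and at
anyone who needs a reproducible, fully seeded entropy-classification
pipeline that can be exercised end to end on synthetic data.

## The measures

**Amplitude-sensitive permutation entropy (ASPE).** For a series
*X = {x₁,…,x_T}*, delay embedding with dimension *m* and delay *τ*
yields vectors *Yᵢ = (xᵢ, xᵢ₊τ, …, xᵢ₊₍ₘ₋₁₎τ)*, *i = 1…T−(m−1)τ*. Each
vector is assigned its ordinal pattern π (the argsort of its entries,
ties to the earlier index) and an amplitude weight equal to its
coefficient of variation *wᵢ = std(Yᵢ)/|mean(Yᵢ)|* (denominator floored
for zero-mean vectors). Pattern probabilities are weighted relative
frequencies *p(π) = Σ_{type(Yᵢ)=π} wᵢ / Σ wᵢ*, and

ASPE = −Σ p(π) log₂ p(π) / log₂(m!) ∈ [0, 1].

Monotone series score exactly 0; iid noise approaches 1. High-amplitude
fluctuating epochs dominate the distribution, which makes the measure
sensitive to epileptic transients.

**Three multi-domain extensions** build the grouped MDE feature set:

- **RCMASPE** (refined composite multiscale): at each scale *s* ≤ S_max
  the series is coarse-grained into *s* phase-shifted subsequences of
  window averages; their pattern distributions are averaged *before*
  taking the entropy.
- **HASPE-DWT** (hierarchical): an *L*-level db4 discrete wavelet
  decomposition; each sub-band (A_L, D_L, …, D₁) is reconstructed back
  to the time domain and scored with ASPE.
- **TSMASPE** (time-shift multiscale): for each lag *k* ≤ K_max, the
  ASPE values of the *k* interleaved decimated subsequences are
  averaged.

Defaults: m=3, τ=1, S_max=10, K_max=10, L=4 (or 5 for 256 Hz data),
giving pathway dimensions d_m=11, d_h=5, d_t=10.

## The classifier

The dynamic-synapse classifier keeps the three blocks separate. Each
pathway applies a multiplicative gate before a tanh compression layer
(width 16): the hierarchical pathway an input-dependent attention gate
G_h = tanh(x_h ⊙ W_h), the time-invariant pathway a scalar stability
gain g_t = exp(−γ·Var(x_t)) with learnable γ > 0, and the multiscale
pathway a learned static mask. The three codes are concatenated, fused
by one tanh layer (width 32) and mapped linearly to softmax posteriors.
All parameters are trained jointly by full-batch quasi-Newton (L-BFGS)
minimization of the cross-entropy with an analytic gradient, capped at
50 iterations. Evaluation follows a sequential stratified k-fold
protocol with the five standard metrics (accuracy, precision, recall,
specificity, F1) reported per fold and aggregated.

## Worked example

```python
import numpy as np
from eegentropy import (SyntheticConfig, generate_dataset, FeatureConfig,
                        extract_batch, cross_validate, aspe)

dataset = generate_dataset(SyntheticConfig.two_class(n_per_class=20, seed=7))
bg = [aspe(s) for s, l in zip(dataset.signals, dataset.labels) if l == 0]
ic = [aspe(s) for s, l in zip(dataset.signals, dataset.labels) if l == 1]
print(f"mean ASPE, background: {np.mean(bg):.3f}")
print(f"mean ASPE, ictal-like: {np.mean(ic):.3f}")

features = extract_batch(dataset.signals, FeatureConfig())
report = cross_validate(features, dataset.labels, n_folds=5, seed=7)
print(f"5-fold CV accuracy: {report.mean['accuracy']:.1f}% +/- {report.std['accuracy']:.1f}%")
print(f"aggregate confusion matrix:\n{report.aggregate_cm}")
```

prints

```
mean ASPE, background: 0.912
mean ASPE, ictal-like: 0.888
5-fold CV accuracy: 100.0% +/- 0.0%
aggregate confusion matrix:
[[20  0]
 [ 0 20]]
```

The sustained ~3 Hz spike-wave rhythm lowers ordinal complexity relative
to 1/f background noise (0.888 vs 0.912 at the native scale; the
multiscale and sub-band features widen the gap), and the two synthetic
classes are fully separable under 5-fold cross-validation.

The same pipeline is available from the shell:

```bash
eegentropy simulate --out data --classes 2 --n 100 --seed 42
eegentropy extract  --data data --out features.csv
eegentropy cv       --features features.csv --folds 10 --seed 42 --out report.json
```

Reports are bit-identical across reruns with the same seed.

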