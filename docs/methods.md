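# Methods

`sersmix` recognises binary and ternary mixtures of three pesticides —
paraquat (A), thiram (B) and tricyclazole (C) — from their surface-enhanced
Raman (SERS) spectra, using a model that is trained **only on pure-compound
spectra**. This note documents the model, the synthetic data that stands in
for instrument data, the numerical choices, and the limits of what the tests
show.

## 1. Recognition model

### Preprocessing

A raw spectrum (wavenumber in cm⁻¹, intensity in arbitrary units) is mapped
to the model input `x ∈ [0,1]^L`, `L = 2048`, by four steps applied in
order:

1. **Crop + resample** — restrict to the fingerprint region 500–1800 cm⁻¹
   and linearly interpolate onto 2048 uniform points.
2. **Savitzky–Golay smoothing** — window 5, polynomial order 2, with
   polynomial-fit edge handling (no padding artifacts, which min–max
   normalisation would otherwise amplify).
3. **Iterative polynomial baseline removal** (modified polyfit): repeatedly
   fit a degree-5 Chebyshev polynomial and clip the working spectrum to lie
   at or below the fit, so peaks progressively drop out of the baseline
   estimate; stop at relative change < 1e-6 or 100 iterations. Negative
   residuals are floored at zero (intensities are physical). The polynomial
   degree and iteration control are exposed in `PreprocConfig`; degree 5
   tracks a broad fluorescence hump without eating 10–20 cm⁻¹ bands.
4. **Min–max normalisation + power transform** — `((y−min)/(max−min))^1.5`;
   the exponent sharpens peak-to-valley contrast.

The converged baseline fit leaves a small compensation lobe (≈2% of the
height of a narrow peak riding on a polynomial drift); this is inherent to
the clip-above-fit family, not an iteration-count artifact.

### Encoder and dual branches

A 1-D residual convolutional encoder `F` maps `x` to an embedding
`f ∈ R^d`: stem convolution → residual stages → global average pooling →
linear projection. Two heads read the same embedding:

* **Classification branch** (pure-substance discrimination): large-margin
  cosine logits. At training time `logit_k = s_cls·(cos(f,w_k) − m·1[k=y])`
  with margin `m = 0.35` and scale `s_cls = 16`; at inference the margin is
  dropped.
* **Evidence branch** (per-component presence): `u_k = s_evi·cos(f,v_k)`
  with `s_evi = 16`, converted to probabilities `p_k = σ(u_k)`. A plain
  affine head is available behind `ModelConfig.evidence_head = "linear"`;
  the cosine parameterisation is the default because the evidence scale
  constant presupposes a bounded pre-scale score.

Two architecture choices matter and were established empirically (each
fails measurably without it):

* **Wavenumber coordinate channel** (`coord_channel`, default on). Raman
  bands of different compounds are near-identical Lorentzians that differ
  mainly in *absolute position*, but a translation-equivariant convolution
  stack followed by global average pooling is position-invariant: it cannot
  represent "band at 1380" versus "band at 1403". A second input channel
  carrying the normalised wavenumber coordinate lets channels act as
  position-specific band detectors while staying in the conv-residual-GAP
  family. Without it, thiram and tricyclazole bands 20–40 cm⁻¹ apart are
  confounded and mixture evidence is unreliable.
* **Default encoder size.** The full profile uses stem (kernel 7, stride 2,
  32 ch), four residual stages (32, 64, 128, 256) with stride 2 between
  stages, `d = 128`. The reduced profile (`ModelConfig.small()`, used by the
  tests and the acceptance script) uses channels (8, 16, 32, 32) and
  `d = 64`; it reaches the same pure-spectrum accuracy on the synthetic
  task at a fraction of the CPU cost.

The network core (convolutions, batch norm, pooling, heads, AdamW, cosine
learning-rate schedule, 1-D Grad-CAM) is implemented in NumPy inside
`sersmix.nnet`; every backward pass is verified against finite differences
in the test suite.

### Training objective

Only pure spectra reach the optimiser (a hard guard raises on any mixture
category). The loss is

    L = L_cls + λ_evi·L_evi + λ_reg·L_reg,   λ_evi = 1.0, λ_reg = 0.01

with `L_cls` softmax cross-entropy on the margin-adjusted cosine logits,
`L_evi` binary cross-entropy of `p` against the one-hot component indicator,
and `L_reg = mean_k max(0, |u_k| − c)²` with clip `c = 6` — the clip both
stabilises the evidence magnitudes and pulls the non-target evidence levels
of different components toward a common floor, which is what makes the
*ordering* of weak evidence meaningful on mixtures.

Optimisation: AdamW, lr 1e-3 cosine-annealed to 1e-5, weight decay 1e-4,
batch size 32, class-balanced batches; 3000 steps in the full profile,
1200 in the reduced profile.

**Pure-spectrum augmentation.** Two input transformations are applied to
training batches (pure spectra only; no mixtures are ever synthesised for
training):

* *Amplitude scaling* (always on, factor U(0.1, 1)): inside a mixture, a
  component's band pattern appears scaled down by the dominant component's
  maximum — down to ≈0.1 for the weakest partner of a ternary mixture under
  the default enhancement disparity. Scaling pure spectra teaches the
  evidence branch to respond monotonically to band amplitude instead of
  keying on full-strength patterns only.
* *Window erasing* (probability 0.8, 1–2 windows of 50–150 points set to
  zero): on pure-only data, "presence of own bands" and "absence of the
  other compounds' bands" are perfectly confounded cues, and the
  discriminative optimum may key on absence. Erasing random regions of
  pure-A spectra penalises any B/C evidence that fires on A-band absence,
  breaking the tie toward presence-keyed detectors.

Without these two regularisers the evidence branch ranks an absent
component above a present-but-weak one on roughly a quarter of synthetic
binary mixtures; with them, stage-1 pair ranking is essentially always
correct (see §4).

### Checkpoint selection

Tracking starts after 500 steps. A checkpoint is *eligible* if its
pure-spectrum validation accuracy is ≥ 0.95; among eligible checkpoints the
one with the highest seven-category validation accuracy wins, ties going to
the latest (most annealed) step. The seven-category selection metric scores
pure categories with the classification branch and mixture categories with
the full two-stage mixture inference. (Scoring everything through a single
unified candidate list was tried first and is still available, but it is
degenerate as a *selection* metric: a singleton's set-likelihood dominates
whenever a weak component's probability is below ½, so every checkpoint
scores identically on mixture validation samples and the mixture-aware
selection protocol loses its purpose.)

### Two-stage inference

Stage 1 ranks candidate sets by the set likelihood
`Score(S) = Σ_{k∈S} log p_k + Σ_{k∉S} log(1−p_k)` (probabilities clamped to
[1e-7, 1−1e-7]). In `pairs_only` mode (mixture recognition) the candidates
are {AB, AC, BC}; `unified` mode adds the singletons. Note that for pair
candidates the score differences telescope to evidence differences
(`Score(AB) − Score(AC) = logit(p_B) − logit(p_C)`), so stage 1 needs only
the correct *ordering* of evidence, not calibrated probabilities. Exact
ties resolve to the lexicographically smallest candidate. The ternary
category never competes in stage 1.

Stage 2 reconstructs the spectrum by nonnegative least squares on the
class-mean prototype spectra under the winning binary hypothesis and under
the full ternary hypothesis (`e_tri ≤ e_bin` always, by support nesting;
asserted at run time). With squared-L2 residuals, the relative residual
gain `g = (e_bin − e_tri)/e_bin` (defined as 0 when `e_bin = 0`) and the
missing-component weight share `ρ = β_missing/Σβ` (0 when `Σβ = 0`) trigger
the ternary upgrade iff `g ≥ 0.040` and `ρ ≥ 0.080`. The residual metric is
configurable (`squared_l2` default, `l2` available) because `g` is not
invariant to that choice.

## 2. Synthetic data generator

The generator emulates the statistical structure of the experimental
dataset, which is not publicly deposited:

* **Band positions** follow the compounds' characteristic SERS band assignments: paraquat 840, 1029,
  1190, 1298, 1646, 1766 cm⁻¹; thiram 560, 932, 1380, 1512 cm⁻¹;
  tricyclazole 596, 988, 1000, 1090, 1193, 1303, 1403, 1420, 1589 cm⁻¹.
  Reference bands (840 / 1380 / 1589 cm⁻¹) are fixed at relative amplitude
  1; the other relative amplitudes are not specified by the band assignments and are drawn once per
  configuration from U(0.3, 1), with Lorentzian FWHMs from U(8, 16) cm⁻¹
  (typical SERS linewidths). Lorentzian line shapes are the default
  (Raman lines are near-Lorentzian); Gaussian is available for tests.
* **Replicate variability**: per-band amplitude jitter with RSD 0.08
  (matching the ~8% reference-band replicate RSD typical of this assay) and band
  position jitter U(−2, 2) cm⁻¹.
* **Enhancement disparity**: per-component signal factors A:B:C = 3:1.5:1,
  emulating the strongly dominant paraquat SERS response.
* **Non-linear mixing**: a mixture is a weighted sum of jittered component
  profiles, but a weaker component's bands are attenuated globally
  (competitive adsorption) by `1 − 0.5·μ·dom` and additionally by
  `1 − μ·dom` where a band lies within one FWHM of a stronger component's
  band; `μ` is `masking_strength` (default 0.6) and
  `dom = (r−1)/r ∈ [0,1)` maps the effective intensity ratio `r ≥ 1`.
  `μ = 0` recovers exact linear superposition. Mixing weights are nominally
  equal (1:1 volumes) with ±20% variability.
* **Baseline and noise**: order-2 polynomial drift plus one broad Gaussian
  fluorescence hump (amplitude 0.2–0.6 of the signal maximum, centre
  800–1400 cm⁻¹, FWHM 300–600 cm⁻¹), plus additive Gaussian noise at 1% of
  the signal maximum.
* **Axis**: raw spectra span 400–1900 cm⁻¹ at 1 cm⁻¹ so the 500–1800 crop
  and 2048-point resample are both exercised non-trivially.
* **Split protocol**: training contains only pure spectra (157 A, 215 B,
  220 C); validation and test cover all seven categories (A, B, C, AB, AC,
  BC, ABC) with 50 and 53 spectra per category respectively. Requesting a
  mixture category in the training split raises.

All randomness derives from one seed through named, independent streams
(library amplitudes / per-component jitter / environment / mixing weights),
so datasets are bit-reproducible and a zero-weight component does not
perturb the other components' draws.

**What the generator does not model**: concentration–response curves,
physical electromagnetic/chemical enhancement, instrument line-shape
functions, cosmic-ray spikes, wavelength miscalibration, or correlated
(non-white) noise. Within-class diversity is consequently lower than in
real replicate data; passing tests demonstrate that the implementation of
the recognition framework is correct under the stated statistical
conditions, not that the method attains any particular accuracy on real
instrument data.

## 3. Numerical choices

* Probability clamp ε = 1e-7 in the set likelihood (log-domain stability).
* NNLS via the Lawson–Hanson active-set solver; the grid-search oracle in
  the tests agrees within grid resolution.
* Residual metric squared-L2 by default (config field, see above).
* `g := 0` when `e_bin = 0`; `ρ := 0` when the ternary fit is all-zero.
* Stage-1 tie-break: lexicographically smallest candidate; checkpoint
  tie-break: latest step.
* Batch-norm running statistics are frozen at inference; evaluation-mode
  forward passes are bit-reproducible for fixed weights.
* Grad-CAM: gradients of the margin-free target-class cosine score at the
  final convolutional stage; channel weights are length-averaged gradients;
  the map is ReLU-ed, linearly upsampled to L and max-normalised (an
  all-zero map is returned with a warning rather than an error).

## 4. Measured behaviour at the reduced profile

Numbers below are produced by the test suite and
`scripts/acceptance.py` (seeds 1–3, reduced profile):

* pure-spectrum test accuracy 1.0 on every seed (eligibility floor 0.95);
* mixture recognition accuracy 0.95 / 0.99 / 0.99 on the 53×4 mixture test
  set; residual errors are almost exclusively ABC↔AB confusions, i.e. cases
  where the faint tricyclazole share of a ternary mixture sits near the
  missing-component threshold ρ = 0.080;
* classification and evidence losses end below their first-eval values;
  the clip regulariser rises when evidence magnitudes first exceed the
  clip and declines as the constraint takes hold.

## 5. Known limitations

* K = 3 components; the decision logic upgrades exactly one missing
  component (binary → ternary), mirroring the study design. The code keeps
  K general in the heads and losses but not in the refinement rule.
* Concentration quantification is out of scope; β weights are fit
  diagnostics, not concentration estimates.
* The evidence branch's mixture behaviour rests on generalisation from
  augmented pure spectra; no mixture ever contributes a gradient. On data
  whose mixing deviates far more strongly from additivity than the masking
  model does, stage-1 ordering can fail, and the refinement stage cannot
  repair a wrong pair.
* t-SNE visualisation of embeddings is deliberately not part of the tested
  core (stochastic, no assertable property); embeddings can be exported and
  fed to any standard implementation.
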