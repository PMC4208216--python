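# Methods

This note documents the models implemented in `wcesum`, the parameters that
matter, the numerical choices made where the design was genuinely open, what
the synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Colour descriptor

Frames are converted from 8-bit sRGB (D65 white point assumed — the dominant
convention when only "CIELAB" is named) and described by per-channel
histograms: 16 uniform bins over L ∈ [0, 100] and 4 bins over each of
a, b ∈ [−128, 127]. The full canonical ranges are used for the bin edges so
the descriptor is reproducible without per-video calibration. Each channel's
counts are divided by that channel's *maximum* count — not its sum — and the
three blocks are concatenated into a 24-vector. Max-normalization is kept
deliberately: the divergence below is applied to the descriptor exactly as
defined, and its properties (symmetry, non-negativity, zero iff equal) do
not require a probability vector. An all-zero channel (possible only for
masked/empty input) is left as zeros rather than dividing by zero.

## Redundancy model

Per frame transition `t → t+1` two cues are computed:

- **Jeffrey divergence** `D_J` between the descriptors, with the
  `0·log 0 = 0` convention and natural logarithms. `D_J` is symmetric,
  non-negative and zero only for identical descriptors; it is known to be
  stable under noise and bin-size choices, which is why it is preferred over
  simpler histogram distances here.
- **Boolean-series correlation** `BC`. The change map of a transition is,
  per Lab channel, the indicator of `curr ≥ prev` at each pixel (ties count
  as "no decrease"). `BC` compares the change maps of two *consecutive*
  transitions by XOR: `BC = Σ_c (1 − XOR-fraction_c) ∈ [0, 3]`, with 3
  meaning the change structure repeated exactly. The first transition of a
  run has no predecessor map; its `BC` is defined as 3, i.e. the structural
  term is uninformative there and the divergence term decides alone.

Both cue streams are smoothed by a weighted history sum evaluated at the
current transition `p`: with full history, `(1/q) Σ_{i=0..q} v_{p−i}/(i+1)`.
During the warm-up (`p < q`) the sum runs over the available lags and is
divided by `max(1, number of lagged terms)`, so a lone first value passes
through unchanged and early transitions are not inflated. The history length
defaults to `q = 4`, about two seconds of context at the capsule's 2 frames/s.

**Fusion polarity.** `BC` is a similarity while the fused quantity is a
distance. In the default *coherent* mode the per-transition value
`1 − BC/3` is accumulated and the net distance is `d = δ + ρ` with both
terms dissimilarities; a run of identical frames then has `d = 0` at every
history depth, which is the property the elimination rule relies on. The
conversion happens *before* accumulation on purpose: with the `1/q`
prefactor the accumulation operator does not preserve constants
(`accum(1) ≠ 1`), so converting after accumulation would leave a constant
offset and identical frames would no longer fuse to zero at full history. A
*literal* mode that adds the accumulated similarity-valued `ρ` unchanged is
retained for comparison; under it even static video scores a large `d` and
the threshold rule degenerates, which is why coherent is the default.

**Elimination rule.** Frame `t+1` is redundant iff `d ≤ τ` (ties count as
redundant; the rule is written with ≤). The first frame is always kept, and
kept frames are grouped into maximal contiguous segments — the non-redundant
"short video segments" whose volume enters the offloading model as `V_S`.
Two anchoring policies exist: `consecutive` (default; each frame compared
with its predecessor, exactly as the transition quantities are defined) and
`last_kept` (compared with the most recent survivor, which catches slow
drift that consecutive comparison lets pass). The threshold

```
τ = exp(−(BW² + B²)) · U
```

is strictly decreasing in normalized bandwidth BW and battery B, linear in
the user preference U, and tends to 1 as resources vanish with U = 1. It is
computed once per run from the supplied resource context; the context is an
input, not something the library measures.

## Multi-fractal texture features

The informative/non-informative contrast is an edge-structure contrast:
clear mucosa is rough at every scale, while bubbles, turbid fluid and
defocus produce smooth images. The descriptor:

1. **Measure.** `|∇²(G_σ * F)|` on the L channel — Gaussian smoothing
   (σ_gauss = 1.0 px) followed by the 5-point discrete Laplacian
   `[[0,1,0],[1,−4,1],[0,1,0]]`, in magnitude, with reflect padding. The
   smoothing and second derivative are applied as separate steps rather than
   one fused LoG kernel, matching the `G` then `∇²` composition. The second
   derivative is direction-free, which is what makes the descriptor
   orientation-robust.
2. **Local density exponent.** For each pixel, the measure mass μ(B(x, r))
   is summed over square (2r+1)×(2r+1) windows (a square stands in for the
   closed disk: exact integer geometry and separable sums) at radii
   r ∈ {1..5}, and α(x) is the least-squares slope of log μ against
   log(2r+1). On a raster the defining r → 0 limit is unattainable, so the
   slope over growing windows is the standard estimator. A locally uniform
   measure gives α = 2; curve-like measure gives α ≈ 1; pixels whose
   window mass is zero at any radius get a NaN sentinel and belong to no
   level set. The per-pixel regression R² is kept for audit.
3. **Spectrum.** α values are binned into 8 equal-width level sets over the
   canonical range [0.5, 3.5] (out-of-range values clamp into the end
   bins), and each level set's box-counting dimension is estimated from
   N(σ) — the number of occupied σ×σ grid cells — over σ ∈ {2,4,8,16,32},
   as the slope of log N versus log(1/σ), clipped to the planar range
   [0, 2]. Empty level sets score 0.

None of the spectrum parameters is canonical; the defaults above were chosen
once for 256×256 frames (box sizes divide the frame evenly, radii small
relative to texture scale) and every trained model records them in its
header. For square inputs whose side the box sizes divide, the spectrum is
*exactly* invariant under 90°/180°/270° rotation (boxes permute), and
translation by a multiple of the smallest box size changes entries only
through boundary boxes.

## Ensemble classifier

Heterogeneous capsule content argues for an ensemble over a single SVM. The
dataset is split into K = 5 class-stratified folds (stratification
guarantees both classes in every training split); member k trains on all
folds but k. Per member, a small logarithmic grid over C ∈ {0.1, 1, 10, 100}
(and kernel width γ ∈ {scale, 0.01, 0.1, 1} for rbf/sigmoid) is scored by
accuracy on the held-out fold k — a transparent, deterministic replacement
for gradient-based kernel-parameter optimization. Features are standardized
by training-split statistics inside each member's pipeline.

Members emit probabilities via an explicit Platt step: a logistic regression
fitted to the SVM margins on the member's own training split. Calibration is
what makes the aggregation rules commensurable: `sum` is the arithmetic
mean, `median` the middle order statistic (mean of the two middles for even
K; default, as it is the most outlier-tolerant), and `product` the geometric
combination renormalized against the complementary class,
`p = Πp_k / (Πp_k + Π(1−p_k))`. Note the product rule is *not* an averaging
rule: it sharpens unanimous scores away from 0.5 (three members at 0.25
combine to ≈ 0.036); 0.5 is its only interior fixed point. The final label
is informative iff the aggregated probability is ≥ 0.5 — the tie goes to
informative, favouring recall of diagnostically useful frames. Models
serialize with a versioned header recording kernel, K, seed, per-member
hyperparameters and the feature configuration.

## Offloading cost models

Time and smartphone-energy costs for the three execution strategies follow
the linear compute + transmission form given in the README, with units fixed
and validated at the interface: volumes in bits, bandwidth in bits/s, powers
in W, times in s, energies in J, and `V_K ≤ V_S ≤ V_F` enforced. Two
behaviours deserve note:

- As printed, the adaptive strategy's energy uses the *full local summary*
  compute time `T_FL`, although adaptively only redundancy removal runs
  locally. Under that form `E_adaptive ≥ E_local` identically (the compute
  terms cancel and `V_K ≤ V_S`), so the adaptive strategy can never win the
  energy comparison — strong evidence the term is a transcription slip. The
  default mode implements the formula as printed for fidelity; a `corrected`
  mode substitutes a separate redundancy-only time `T_RL`, under which the
  expected adaptive win (smaller upload than full offloading, cheaper
  compute than local) is reproduced. Both modes are tested.
- The energy ledger utility sums per-component cells (component × strategy ×
  tier) into smartphone subtotals and grand totals, and checks computed
  grand totals against externally printed ones, *flagging* disagreements
  beyond 0.5 J instead of adopting the printed number. The bundled benchmark
  ledger exercises this: one strategy's printed grand total exceeds its own
  component sum by 140 J, and the package reports the computed sum with the
  mismatch flagged.

## Evaluation metrics

Selected and truth keyframe lists are matched greedily: each selected index
claims the nearest unclaimed truth index within `window` frames (default 0,
i.e. exact matching — the strictest reading when no tolerance is specified).
Matched pairs are TP, unmatched selections FP, unmatched truth FN; recall,
precision and the F-measure follow, with empty-denominator metrics defined
as 0 (with a warning) so empty summaries evaluate rather than crash. Note
F is the harmonic mean, so `min(R,P) ≤ F` does *not* hold in general; the
valid bound `F ≤ (R+P)/2` is what the tests assert. Table averaging is the
arithmetic mean per metric across videos.

## Synthetic data generator

The generator emulates the statistical contrasts the pipeline exploits —
inter-frame similarity structure, colour-histogram separation between
scenes, and edge-density differences between informative and
non-informative content — not endoscopic appearance. Design choices, all
fixed once at design time by measuring candidate constructs:

- **Scenes** are band-limited noise textures (two spatial scales) with
  darker vessel-like random-walk curves, in a warm red/pink palette.
  Because the 24-bin descriptor is global, two textures at the same
  lightness are histogram-indistinguishable (divergence ≈ 0.01); successive
  scene/episode appearances therefore alternate between two lightness rungs
  (112 and 152 of 255), which puts every adjacent-block divergence in a
  comparable moderate band (≈ 1.4–1.8).
- **Near-duplicate runs** apply a constant-velocity sub-pixel translation
  (bilinear, wrap-around, total ≤ `jitter_px`; wrap keeps the base frame's
  colour statistics intact), a slow illumination swing that rises for the
  first half of the dwell and returns to baseline (peak 12%), and mild
  sensor noise (σ = 0.4 DN). The swing and translation dominate the noise,
  so consecutive change maps share their sign structure — the property the
  Boolean-correlation cue measures on real near-duplicates. Each block's
  swing starts in the direction of the lightness change that entered the
  block, emulating a camera gain that keeps adapting briefly after a scene
  change before correcting; a swing that returned to baseline was chosen
  over an unbounded monotone drift because the latter moves a block's
  endpoint brightness by the full drift amplitude and makes boundary
  divergences erratic.
- **Non-informative episodes** come in three kinds: bubble fields
  (overlapping discs with bright rims and flat interiors over a gently
  varying wash), turbid washes (low-frequency yellow-green field under
  strong blur; hue ratios chosen so its divergence from mucosa lands in the
  same band as the other kinds), and defocus (Gaussian blur, σ = 6.5, of a
  fresh mucosa texture). Episodes are emitted as short near-duplicate runs
  in the gaps between scene blocks, sized so the requested fraction of all
  frames is non-informative.
- All randomness flows from a single seeded generator; a fixed seed
  reproduces the frames bit for bit.

With the default spec (5 scenes × 10 copies, 30% non-informative, 256×256,
2 fps) the fused-distance bands separate: within-run transitions stay below
≈ 0.63 and scene entries above ≈ 0.73 across the seeds tested. The
pipeline's default resource context (BW = 0.3, B = 0.45, U = 0.9, hence
τ ≈ 0.672) was chosen as a mid-range operating point inside that band.

**What passing on this generator does and does not show.** It shows the
machinery is self-consistent: descriptors separate blocks the way they were
planted, the threshold rule recovers planted segmentation, and the spectrum
separates sharp from smooth content well enough for the ensemble to label it
almost perfectly. It does not show clinical performance. Real capsule video
has specular highlights, peristaltic deformation (not rigid translation),
gradual scene *transitions* rather than cuts, colour drift within one organ,
and non-informative frames that blend into informative ones; none of these
is emulated, and the clean separation of the synthetic distance bands should
be read as a best case.

## Numerical choices and degenerate inputs

- Divergence terms with a zero numerator contribute 0; negative histogram
  entries and length mismatches are rejected.
- `remove_redundant` requires τ ∈ (0, 1], matching the threshold model's
  range; the kept/dropped sets partition the input and the first frame is
  always kept.
- Box counts pad the frame with empty cells when a box size does not divide
  the side; dimensions are clipped to [0, 2].
- The density fit excludes any pixel with zero window mass at any radius
  (NaN sentinel) rather than propagating −∞ through the regression.
- K-fold splitting requires n ≥ K; single-class training data is rejected
  before any member is fitted.
- Aggregation rejects scores outside [0, 1]; the product rule returns 0.5
  in the measure-zero case where both class products vanish simultaneously.

## Known limitations

- Video-file decoding is not built in; frames are ingested as PNG/JPEG
  sequences (natural filename sort). Decode videos externally first.
- The threshold is fixed per run. Re-deriving τ per frame from a streaming
  resource context is a straightforward extension but is not implemented.
- Published benchmark accuracies for the classifier on clinical data are
  context, not a reproduction target: they depend on a private dataset, so
  only ordering and consistency properties are asserted here.
- The α range [0.5, 3.5] and bin count were fixed for 256×256 inputs;
  materially different frame sizes warrant revisiting the radii and box
  sizes together with it.
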