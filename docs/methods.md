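# Methods

## Model

The tracker is a kernelized discriminative correlation filter. The target
region of the first frame, padded by a factor of 2, is cropped, resized to
a fixed model window (its larger side capped at 96 feature cells of 4 px)
and converted into a stack of feature maps. For each feature source the
filter is the ridge-regression solution over all cyclic shifts of the
template, expressed through dual coefficients in the Fourier domain:
`α̂ = ŷ/(k̂ˣˣ + λ)` with a Gaussian kernel (`σ_k = 0.5`, KCF convention)
and a Gaussian regression target whose bandwidth is
`0.1·sqrt(w·h)/cell` in cells. Detection evaluates
`R_z = F⁻¹(k̂ˣᶻ ⊙ α̂)` per source on the search window of the new frame;
FFTs use the exact grid size so the cyclic algebra is exact. The peak cell
is refined to sub-cell precision by a separable quadratic fit to its 3×3
neighbourhood (clamped to ±0.5 cell); cell displacements are mapped back
to frame pixels through the window-to-model resize factor. Template and
coefficients are updated by linear interpolation with learning rate
`η = 0.01`; `λ = 1e−4`. The single regularizer plays the role of both the
primal and kernel-space penalties.

## Features and fusion

Per frame five maps are extracted from the (resized) search window:

* `hog` — 31-channel Felzenszwalb-style HOG, cell 4 (18 contrast-sensitive
  + 9 contrast-insensitive orientation channels + 4 texture-energy
  channels, four-neighbourhood block normalisation truncated at 0.2). This
  variant is implemented in-package; it is the descriptor conventionally
  used by correlation-filter trackers and no installed library provides
  it.
* `conv_shallow`, `conv_mid`, `conv_deep`, `conv3_3` — convolutional
  levels at strides 4/8/16/4 with 256/512/512/256 channels from a
  pluggable backbone. The built-in backbone projects 7×7 local windows of
  an intensity+gradient representation onto a fixed seeded Gaussian random
  basis followed by a ReLU. The input is low-pass filtered per level
  (σ = 1.0/1.5/3.0 px) so coarser levels acquire the shift tolerance that
  real deep layers owe to their wide receptive fields. Random projections
  approximately preserve patch geometry, so the maps discriminate texture;
  they carry no semantics, which matters for what the tests can and cannot
  show (below).

All maps are bilinearly resampled to the HOG grid, spatially zero-meaned
per channel (without this, the non-negative conv maps correlate through
the cosine-window envelope and the response locks at zero shift), rescaled
to unit per-element energy so heterogeneous sources contribute comparable
kernel magnitudes, and multiplied by a Hann window.

Fusion is at the response level: each source trains its own filter and a
branch's response is the weighted sum of member responses — the only
dimensionally consistent reading of a weighted sum over tensors with
different channel counts (weighted channel concatenation is available as
`fusion_mode="concat"`). Branch A combines the three conv levels; branch B
replaces the shallow level with HOG. Default member weights are
(1.0, 0.3, 0.1) for (sharp member, mid, deep): with the random-projection
backbone the coarse levels localise poorly, and weighting them highest
simply anchors the fused peak at zero displacement (measured as total
tracking loss on the constant-velocity fixture). Sharp-member-dominant
weighting gives ~0.6 px mean error there. With a semantically trained
backbone a deeper-weighted profile may be preferable; the weights are
config-exposed per branch.

## Reliability gate

Each branch response is scored by `Fmax` and
`APCE = (Fmax − Fmin)²/mean((F − Fmin)²)` (0 for a constant map, which
carries no localisation evidence; APCE is invariant under affine
rescaling of the response). A branch is trusted iff
`Fmax > α₁·ref_Fmax` and `APCE > α₂·ref_APCE` with `α₁ = α₂ = 0.8`; the
frame is untrusted iff no branch passes (`gate_policy="no_branch"`; the
strict all-branches variant is available). Among trusted branches the one
with the larger APCE wins, ties broken by `Fmax`.

The reference levels are, by default, the median of the per-frame
best-branch scores over the last 20 non-collapsed frames plus the current
frame's branches (`mean_mode="temporal"`); with an empty history this
reduces exactly to the cross-branch mean of the current frame
(`mean_mode="frame"` forces that behaviour always). Design notes:

* *Warm-up.* Match quality decays from the fresh model's near-self-match
  toward a steady level over the first frames; the first 10 frames are
  trusted while their scores fill the pool, and frame 1 (the inflated
  self-match) stays out of the pool but calibrates the collapse floor.
* *Median, best branch only.* The median is robust to the residual
  post-initialisation decay, and pooling only the best branch prevents a
  chronically weak branch from dragging the reference down and silently
  disarming the gate.
* *Every structured frame enters the pool.* The pool follows gradual
  appearance decay (per-frame deformation, noise) instead of deadlocking
  on a level the scene no longer supports; its 20-frame inertia still
  flags an abrupt collapse for the duration of a typical occlusion.
* *Collapse floor.* A frame whose best APCE falls below 10% of the
  first frame's self-match APCE counts as a response collapse. Collapse
  frames are kept out of the pool and routed to re-tracking; gate failures
  above the floor are "marginal" — the tracker follows the best peak but
  does not learn from the frame. After 20 consecutive frames without
  learning the pool is cleared and the tracker re-bootstraps, since a
  permanent appearance change would otherwise deadlock a
  reliable-frames-only reference.

## Re-tracking

Reliable frames push their feature stack into a ring buffer (capacity 20).
On a collapse frame the update feature is composed per source as
`E = ω₇·χ_time + ω₈·χ_current` with the current conv3-3 map adding `ω₉`
extra weight on its source block; weights (0.4, 0.4, 0.2) are normalised
and zero-weight members dropped, so (1,0,0) reproduces the buffered stack
exactly. `χ_time` is the buffered stack with the highest APCE
(quality-ranked; recency-ranked available). A temporary filter trained on
`E` (embedded centrally into a 1.5× grid — windowed features vanish at
their borders, so zero-padding is smooth) re-detects in a window enlarged
1.5× and anchored at the last reliable position. The temporary filter
partially self-matches the current stack by construction and would always
look confident, so the re-tracked *position* is instead scored by the
persistent model against the same frame's reference levels; only on a
pass does the persistent model interpolate. On failure the position is
accepted (a box must be emitted every frame) but learning stays frozen, so
occluder appearance never contaminates the template. The temporary filter
is discarded after the frame.

## Scale

A 3-point pyramid evaluates the translation filter at size factors
{1/1.02, 1, 1.02}; non-unity peaks are penalised by 0.97 and the argmax
wins. Numerical care proved decisive: all three probes are sampled from
one shared crop by central zoom (independent crops at window sizes a few
pixels apart carry resampling artefacts larger than the scale signal), and
a common 1 px low-pass removes the systematic advantage of the zoomed-in
probe (which suppresses per-frame pixel noise). Because a 2% probe changes
the response by roughly its noise level, the per-frame verdict is treated
as a vote and a step is applied only when 3 of the last 5 votes agree; on
frames where learning is frozen the probes must additionally pass the
`Fmax` confidence check, so an occluded target cannot random-walk the
size. The box is clamped to [0.2, 5] × the initial size.

**Known limitation.** This estimator is deliberately conservative: a
static target keeps its size in ≥95% of frames, but a sustained ramp of
2%/frame is adapted to only partially (position tracking remains correct;
the box lags the true size). Matching fast ramps would need a dedicated
scale filter (DSST-style, a natural extension) or less scale-robust
features.

## Synthetic sequences

The generator renders band-limited noise backgrounds and an elliptical
target with its own seeded texture, under events covering the challenge
taxonomy: a textured occluder sliding across the target (full coverage at
peak), anisotropic scale ramps, illumination gain ramps, look-alike
distractors sharing the target's texture (the background-clutter regime
typical of camouflaged animals), affine texture deformation/rotation,
motion jitter and out-of-view excursions. Ground truth is the rendered box
itself — zero annotation noise — and per-frame event labels (occluded
fraction, full-occlusion flag, gain, out-of-view) are written alongside.
Everything derives from one seed; PNG output is lossless, so regeneration
is byte-identical. A static virtual camera cannot produce the
viewpoint-change or camera-motion attributes; the canonical suite covers
the other twelve.

What passing tests on these fixtures does *not* show: robustness to
semantic appearance change (a real animal turning its head), to
photometric effects beyond global gain, or to backgrounds with structured
(non-stationary) statistics. The backbone carries no semantics, so
conclusions about the relative value of "deep" features do not transfer to
a trained network.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
sequences of 45–80 frames at 240×320 px with targets of roughly 20–40 px —
small enough to regenerate and track from scratch in a couple of minutes,
large enough that the search window, feature grids and event dynamics are
non-degenerate.

## Numerical choices

* FFTs at the exact grid size; wrap-around indexing for shifts; float64
  throughout (the spatial-vs-Fourier agreement of the engine is asserted
  to 1e−8).
* Bilinear resampling uses pixel-centre alignment with edge clamping:
  constants are preserved exactly and values never overshoot the source
  range.
* Evaluation comparisons are strict (`<` for precision, `>` for success);
  the success grid includes both endpoints, so a perfect tracker scores
  AUC 50/51 ≈ 0.98 (overlap 1.0 is not > 1.0 at the last grid point).
* A constant response map has APCE 0 by convention; an underflowing
  denominator is treated the same way.
* Degenerate boxes (non-positive sides, non-finite coordinates) are
  rejected at construction; annotation files are 1-based inclusive on
  disk and 0-based half-open in memory.

## Ablation switches

`disable_update` removes the reliability-gated learning entirely (every
frame updates, no re-tracking); `disable_fusion_selection` tracks with
branch B alone. On the hard fixture subset (full occlusion, clutter,
combined) the full method's mean overlap exceeds both ablations, with the
caveat that the margin over the single-branch ablation is small: with a
random-projection backbone the purely convolutional branch only rarely
carries information that HOG does not, and on some texture seeds its APCE
can win the selection while localising slightly worse. The benefit of
adaptive fusion selection is expected to grow with a semantically trained
backbone.
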