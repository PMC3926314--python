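# Methods

## The detection model

`statedge` classifies every pixel of an RGB micrograph into *edge* versus
*non-edge* by thresholding a texture-derived edge-strength map per color
channel and OR-fusing the three binary decisions. The underlying
assumptions are:

* a cell boundary manifests as an abrupt change in the *local second-order
  statistics* of at least one primitive color channel, even when the raw
  gradient is noisy or weak;
* edge polarity is irrelevant (a dark-to-light transition is as much a
  boundary as the reverse);
* the edge/non-edge decision per channel is a two-class problem on a
  one-dimensional strength distribution, for which Otsu's between-class
  variance criterion selects the split without user tuning.

No post-processing (thinning, linking, gap filling) is applied: the
detection band around a true boundary is therefore a few pixels wide, and
downstream metrics must be read with that in mind (see "Limitations").

### Windowed co-occurrence features

For a `t×t` window, the co-occurrence matrix at distance `d` and
orientation θ counts ordered gray-level pairs; the table is indexed
`0..Nc` with `Nc` the window maximum, so its size follows the local
dynamic range. Orientations sweep 180° — offsets `(0,d)`, `(−d,d)`,
`(−d,0)`, `(−d,−d)` — and the diagonal directions count both opposite
offsets by definition. By default the axial directions (0°, 90°) also add
the transposed pairs (`symmetric=True`), which makes all four tables
orientation-symmetric and yields exact invariance of four-direction
averages under quarter-turn rotations; the asymmetric literal reading
remains available.

Features are evaluated on the *normalized* matrix `p(i,j)` rather than on
raw counts. Raw-count evaluation (available via `glcm_feature(..., raw=True)`)
makes energy and homogeneity scale with window area; normalization gives
bounded, window-size-invariant values — `direc`, `ener`, `odm` ∈ (0, 1],
`dm ≥ 0` — which is what the thresholding stage needs. The diagonal
moment uses `|i−j|` under the square root: matrices are symmetric, so
`i<j` cells are unavoidable and the absolute value is the only reading
that keeps the feature real.

### Attribute image

Each pixel receives the four-direction average of one feature computed on
the window centered there. Borders are reflect-padded (edge-inclusive
mirror), so the attribute image covers all `M×N` pixels; the same padding
convention is used by the 3×3 edge operators for consistency. Windows
containing a single gray level are legal and produce the analytic limits
(`ener = odm = direc = 1`, `dm = var = 0`).

Two engines exist. The reference engine recomputes the feature window by
window from the co-occurrence definitions. The default engine encodes
every in-window pixel pair as an integer `first·256 + second` and
evaluates features from per-window code multisets using sliding-window
views; energy and the diagonal moment, which need per-cell counts,
recover them by sorting each window's codes and measuring run lengths
(Σ r² over runs is the energy numerator). The two engines agree to
≤ 1e-9 on all features (tested), and the vectorized path processes a
256×256×3 image in about a second on one CPU core.

### Edge strengths and LMES

The eight 3×3 compass patterns have zero coefficient sum (constant inputs
give zero response) and are reflection-complete up to sign. The local
maximum edge strength takes the maximum of *absolute* responses; a signed
maximum would treat the two polarities of the same boundary differently.
LMES is linear under positive scaling of the attribute image and
invariant to constant offsets.

### Threshold selection

The real-valued LMES map is rescaled so its maximum falls in bin
`L = 255` (floor binning; bin `b` covers `[b·vmax/L, (b+1)·vmax/L)`).
Otsu's criterion is evaluated at every candidate split with both classes
non-empty. Two numerical choices matter:

* **Exact tie-breaking.** `σ_B²(t)` is exactly constant across runs of
  empty bins, and floating-point summation order can reorder such
  plateaus. Candidates are therefore compared as exact rationals
  (`σ_B² ∝ (S₁c₂ − S₂c₁)²/(c₁c₂)` with integer cumulative counts and
  index sums), and the smallest maximizing `t` wins — deterministic and
  sensitivity-favoring (more edge pixels).
* **Decision threshold.** `T` is the raw value of the lower edge of bin
  `t*+1`, so `LMES ≥ T` selects exactly the pixels binned above `t*`.

A histogram with a single occupied bin (constant LMES, e.g. a
constant-color channel) is *degenerate*: the channel declares zero edge
pixels, logs a warning, and fusion proceeds with the remaining channels.

### Defaults

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| feature   | `ener`  | —    | bounded, parameter-free uniformity measure; `var` kept as an extension |
| t         | 5       | px   | smallest window with stable 4-direction statistics at d = 1 that keeps boundaries sharp |
| d         | 1       | px   | adjacent-pair statistics, the common choice |
| symmetric | true    | —    | orientation-consistent tables, exact rotation invariance |
| border    | reflect | —    | full-size outputs without inventing gray levels |
| L         | 255     | bins | 8-bit convention; ample resolution for 3×3 operator outputs |
| levels    | none    | —    | matrix size follows the window maximum; global quantization only as a speed option |

## Evaluation statistics

`Sen(%)` counts label agreement over *both* classes. `P_C` and `P_f`
condition on the reference classes `R₁` (cells/edge) and `R₂`
(background): `P_C = N₁C/N₁r`, `P_f = N₁f/N₂r`. Because a 1-pixel
reference boundary punishes 1-pixel localization offsets under exact
matching, both accept a Euclidean tolerance radius: an `R₁` pixel counts
as detected if a predicted pixel lies within the radius, and a predicted
pixel counts as false only if it is farther than the radius from every
`R₁` pixel. Tolerance 0 reduces exactly to pixelwise recall and
false-positive rate; tolerance 2 px is used in the reproduction script.
These definitions keep the invariants `N₁C ≤ N₁r`, `N₁f ≤ N₂r`, and
`Sen(pred) + Sen(¬pred) = 100`.

## Synthetic test material

The generator produces what the evaluation needs — exact, closed,
1-pixel ground truth — not photorealistic histology:

* **Two-region images**: a circle (or rectangle) of one color on a
  uniform background. Default palette mimics immunohistochemistry
  staining: foreground (150, 40, 60), background (230, 210, 220), i.e.
  per-channel contrasts of 80/170/160 gray levels.
* **Cell-like images**: non-overlapping ellipses with smooth radial
  falloff from full foreground color at the center to the halfway color
  at the rim (so the rim retains half the nominal contrast), ≥ 2 px
  apart, placed by seeded rejection sampling.
* **Salt-and-pepper noise** of density `D`: each pixel position is
  corrupted independently with probability `D`, becoming pure black or
  white (jointly across channels by default, matching the visual
  character of impulse noise on color images; per-channel mode behind a
  flag). Ground-truth masks are never touched by the noise.

What this material does *not* emulate: stain variability, uneven
illumination, texture inside cells, touching/overlapping cells, blur.
Passing tests on it demonstrate the pipeline's mechanics and its behavior
under impulse noise — not clinical performance.

## Known limitations

* **Equality-blindness of `ener`/`direc`/`odm` under impulse noise.**
  These features depend only on which pixel pairs are *equal*, not on how
  different unequal pairs are. A single impulse in a 5×5 window lowers
  `ener` by ≈ 0.19 while a genuine two-region boundary lowers it by
  ≈ 0.5–0.6 — only a ~3× separation. At noise density D = 0.02 on a
  256×256 image, impulse responses blanket roughly 60 % of pixels with
  nonzero LMES, and the between-class-variance split then groups that
  mass with the boundary class (scikit-image's independent Otsu makes
  the same choice on the same data). Measured on the seeded noisy circle
  at defaults: Sen ≈ 59 %, P_C = 1.00, P_f ≈ 0.39. Larger windows
  attenuate impulses (t = 9 reaches P_f ≈ 0.03) but widen the un-thinned
  detection band so pixelwise Sen saturates near 95 %. On noise-free or
  lightly corrupted material the defaults recover boundaries cleanly
  (Sen ≈ 97 %, P_f ≈ 0.01). Denoising before detection (e.g. a median
  filter) is the practical remedy but is deliberately outside this
  pipeline, which applies no pre- or post-processing.
* **Band width.** Without thinning, every boundary is detected as a band
  roughly `t/2 + 2` pixels wide; pixel-exact agreement metrics penalize
  this even for perfect localization. Use the tolerance-based `P_C`/`P_f`
  for localization quality.
* **Problem sizes.** The test suite and the reproduction script run on
  256×256 images (the conventional size for this method's test imagery),
  which one CPU core handles in seconds; the vectorized engine scales
  linearly in pixel count and window area.
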