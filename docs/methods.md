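# Methods

`nestcam` quantifies two things from calibrated photographs of ground nests —
how well eggs and nest materials blend into their surroundings, and how much
experimental nest material the birds kept — and one thing from thermocouple
logs: how fast model eggs heat on different nest materials. This note
describes the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical decisions that
were genuinely open.

## Camouflage from texture clustering

### Pipeline

Each photograph arrives as a linear RGB raster with an ROI mask (egg, nest,
internal buffer ring, external/microhabitat; code 0 marks excluded pixels).
Processing per image:

1. **Margin exclusion.** Pixels within `margin_fraction · min(H, W)` of any
   edge are excluded (default 0.02), because lens distortion and vignetting
   make the outermost pixels unreliable. The operation is idempotent and
   conserves total pixel counts.
2. **Gray-standard Lab conversion.** Linear values are divided by the
   measured value of an 18%-reflectance gray card in the frame and multiplied
   by 0.18, putting the image in absolute reflectance units; the result is
   exactly invariant to global exposure. Reflectances are then mapped to CIE
   L\*a\*b\* under a D65 white point. The gray-card adaptation is the only
   camera calibration performed; RAW decoding, lens correction and spectral
   calibration are out of scope (a `raw_reader` hook accepts externally
   decoded linear rasters).
3. **Filter bank.** Every channel (L\*, a\*, b\*) is convolved with a bank of
   14 spatial filters per scale at four scales, 56 filters in total: per
   scale, five odd-symmetric and five even-symmetric oriented
   Gaussian-derivative kernels (orientations evenly spaced over [0°, 180°);
   the orientation label is the derivative-axis angle) plus two Gaussians and
   two Laplacian-of-Gaussian kernels at σ/2 and σ. This yields 168 features
   per pixel. Even-symmetric kernels are the second derivative of a 3:1
   elongated Gaussian across its short axis; odd-symmetric kernels are their
   Hilbert pair, computed in closed form with the Dawson function. Kernel
   window is `2⌈2σ⌉+1` (support > 4σ at bounded cost). Zero-mean families are
   L1-normalized so response magnitudes are comparable across scales; plain
   Gaussians sum to 1. Convolution is spatial with mirror (reflect) padding;
   internally it runs over FFT, which is exactly equivalent because the pad
   covers the kernel half-width (verified against a direct-summation oracle).
4. **Texture clustering.** All analyzed pixels of *one* image are clustered
   with K-means (k-means++ init, 10 restarts, tolerance 1e-4, fixed seed);
   labels are 1..k. Signatures are only ever compared within the image they
   came from, so no cross-image feature standardization is needed (a
   `standardize` flag exists, default off). If an image holds fewer distinct
   feature vectors than requested clusters — distinctness judged after
   quantizing at 1e-9 of the feature range, so FFT round-off on a constant
   image does not masquerade as texture — the count is reduced with a
   warning.
5. **Signatures and χ² score.** A region's clustering signature is the
   relative presence (%) of each cluster among its pixels. Two signatures are
   compared with the χ² histogram distance d(g, h) = ½ Σᵢ (gᵢ−hᵢ)²/(gᵢ+hᵢ),
   skipping empty bins. On %-normalized signatures the value lies in
   [0, 100]; it is symmetric and zero iff the signatures are equal, but the
   triangle inequality can fail, so it is a score, not a metric. The ½
   factor is the convention of the histogram-comparison literature; a
   no-½ variant is a flag. Scores are reported for Egg–Nest, Egg–External
   and Nest–External; the internal buffer ring is clustered but never
   scored.

### Choosing the cluster count

`select_n_clusters` runs the pipeline over a scene set for each candidate
count and averages, per scene, the Pearson correlation between the egg and
external signatures (a rank-based variant is a flag). More clusters
decorrelate egg from ground until the curve saturates; the function returns
the smallest candidate after which the decrease falls below a tolerance
(default 0.02) together with the whole curve. The default operating count is
14 clusters over candidates {6, 8, 10, 12, 14, 16, 20}.

### Disruptive score

The egg outline (one-pixel inner border of each egg instance) is dilated
with a cross-shaped structuring element of radius `round(1% of the mean egg
major-axis length)`, at least 1 px; the dilation is intersected with the
texture-frontier image (4-connected label changes, drawn one pixel thick on
the lower-label side) and thinned back to unit width. A border pixel counts
as detected when a thinned pixel lies within the dilation radius (+0.5 px so
a diagonal neighbour at radius 1 counts); the score is the percentage of
border pixels detected, pooled over all eggs, with per-egg values reported.
Lower is better camouflage. The score is exactly invariant to translation
and 90° rotation. Intersection connectivity is 8-connected (via the
Euclidean distance criterion); 4-vs-8 connectivity of the original procedure
is not documented anywhere we could follow, so the symmetric Euclidean rule
was chosen.

### Filter scales and image resolution

The default scales σ = {16, 24, 32, 48} px suit field photographs in which
an egg spans several hundred pixels. The synthetic scenes used in tests are
256 px across with eggs of 30–200 px, so analyses of synthetic scenes use
proportionately smaller scales (typically {4, 8, 12, 16}); scale sets are a
config entry, not a constant. Images must comfortably exceed the largest
kernel half-width or the convolution refuses to run.

## Nest-material coverage

A digital grid of `square_mm` × `square_mm` squares (default 2 mm) is
anchored at the nest bounding-box corner. A square belongs to the nest when
at least 50% of its area lies inside the nest mask (the tie goes to
inclusion); it is *dominated* when material pixels exceed 50% of its in-nest
area (the tie goes to not dominated, since the protocol says "covered
> 50%"). Coverage is the percentage of dominated squares. Grid anchoring at
the bounding box makes the result exactly invariant to translating both
masks by whole squares. Material masks are inputs; segmenting material from
pixels is out of scope.

## Newtonian heating fits

Under constant irradiance, an egg whose internal heat redistribution is fast
relative to surface exchange follows T(t) = T_f + (T_i − T_f)·e^(−t/Tc).
Equivalently y = a·e^(bx) with y = T − T_f, a = T_i − T_f (negative for
heating), b = −1/Tc. Tc is the characteristic heating time: at t = Tc the
egg has completed 1 − e⁻¹ ≈ 63.2% of its total change (exact by the model's
algebra, and `characteristic_fraction` returns it).

**Fitting.** T_f is estimated as the mean of the last five records — the
same convention used for final temperatures in the field protocol — rather
than the single last record, which would inject its full measurement noise
as a constant offset into every residual (empirically this one choice
dominates the Tc error budget: median relative error drops from ~2.7% to
~1.2% at 0.2 °C noise). After a first two-parameter fit of (a, b) on
y = T − T_f, the tail mean is corrected once by the model's own predicted
unfinished change a·mean(e^(b·t_tail)) and the fit repeated, so a noiseless
exponential is reproduced to machine precision. The model stays strictly
two-parameter; T_f is never a free least-squares parameter. Initial guesses
are deterministic (a₀ from the first record, b₀ from a log-linear regression
over the first half of the series), so fits are reproducible. Series that
are too short (<10 samples), too flat (range ≤ 0.5 °C), or that cool or
diverge (a > 0 or b ≥ 0) are rejected with explicit errors.

**Field protocol.** Materials heated in sunlight do not all follow the model
(convection-dominated twigs in particular), so no Tc is estimated there:
series are cropped to 1111 s and summarized by the mean of the last five
records. The Spearman correlation between material reflectance (from the
gray-standard normalization) and final temperature uses average ranks for
ties and an exact full-permutation two-sided p-value for n ≤ 8 materials
(720 orderings at n = 6); beyond that the asymptotic p is returned.

## Synthetic data

`synthetic_data` renders what the analyses assume, not what a camera sees:

- **Scenes.** Concentric geometry (elliptical eggs ⊂ nest disk ⊂ internal
  ring ⊂ microhabitat) with per-region lightness, chromaticity, pebble grain
  and contrast. Texture is low-pass-filtered seeded Gaussian noise
  thresholded at its median into two-tone patches (equal areas, so the
  region mean converges to the target lightness) plus a mild within-patch
  gradient. Default lightness values are the field means of unmanipulated
  nests (egg 25.31, nest 32.28, microhabitat 28.42); default grains are
  egg 2 px < nest 5 px < microhabitat 8 px, contrast 3 L\* units — chosen as
  a plausible pebble-to-substrate progression. A gray-standard patch of
  known linear value sits in the frame corner (excluded from analysis) and
  tracks any exposure gain. Every generated parameter, realized per-region
  statistic and egg length is stored as ground truth. Per-ingredient RNG
  streams mean that adding material to a scene changes nothing else;
  the same seed reproduces byte-identical output.
- **Treatments.** `make_treatment_scenes` builds the original/treated/
  week-after triple (O/T/W) sharing geometry and base textures, with the
  experimental material covering the whole nest cup (T) or a retained
  fraction, default 15%, as thresholded patches (W). The W material mask
  doubles as the coverage module's input.
- **Heating curves.** Exact exponentials with Gaussian noise; the lab
  defaults (T_i 25 °C, T_f 45 °C, Tc 300 s, 15 s sampling for 60 min → 241
  records, sd 0.2 °C) match the laboratory protocol's regime.

What the generators do **not** emulate: photographic noise, shadows,
illumination gradients, chromatic texture independent of lightness,
non-elliptical eggs, maculation (egg spotting), or radiative/convective
physics in the curves. Passing tests therefore demonstrate that the
algorithms recover known structure under the assumed statistical model — not
that the scores are accurate on real photographs, where ROI quality and
calibration dominate.

## Numerical and design notes

- Margin semantics: the excluded width is `int(margin_fraction · min(H, W))`
  (floor), so a 0.02 margin on a 100-px side removes exactly 2 px.
- Masks: label rasters are primary; polygon JSON is rasterized on pixel
  centers with even-odd fill, 0-based row/col coordinates.
- Egg length on a raster is the major-axis length of the best-fit ellipse of
  each egg instance (scikit-image regionprops convention).
- Lab conversion uses the standard linear-sRGB↔XYZ matrices (D65); L\* is
  clipped to [0, 100] after clipping linear values at 1, and more than 1% of
  pixels clipping triggers an overexposure warning.
- K-means determinism is per (data, seed); across library versions the exact
  labels may differ on genuinely ambiguous pixels, which is why recovery
  tests assert agreement percentages, not exact label maps.
- Boundary/tie-breaks: texture frontiers are drawn on the lower-label side;
  coverage ties are resolved as stated above; χ² terms with empty bins are
  skipped.
- Degenerate inputs: empty regions, masks without eggs, zero-length borders,
  constant images, cooling/flat series and infeasible geometry all raise (or
  warn and reduce, where the contract says so) rather than returning
  numbers.

## Problem sizes used in the checks

The self-contained verification (`scripts/acceptance.py` and the test suite)
uses 256×256 scenes for segmentation/disruptive checks, 192×192 scenes for
the eight-point lightness-gap sweep, and 100 seeded heating curves of 241
records — sizes at which every statistic it reports is stable across seeds.
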