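# Methods

## Measurement model

A camera looks straight down at a crop canopy from a mast a few metres up.
Pixels are classified leaf/background; the binary mask is tiled into sample
squares of side W; square i has gap probability P_i. Under the Boolean
(Poisson) canopy model with leaf projection function G(θ), the gap
probability of an infinitesimal beam at view zenith θ is
P = exp(−G(θ) L / cos θ), so −cos θ · ln P / G(θ) inverts LAI. Averaging
this inversion over finite squares (finite-length averaging) keeps the
estimate robust to large-scale heterogeneity and yields the clumping index

    Ω = m ln(mean P_i) / Σ ln P_i,

the ratio of the "one big square" inversion to the averaged one. By
Jensen's inequality Ω ∈ (0, 1] whenever all P_i ∈ (0, 1); equality holds
for equal gaps.

Two pathologies motivate the second estimator. When a square is fully
covered, ln 0 diverges; when W is comparable to the leaf size, the
within-square gap distribution is strongly non-lognormal and the classical
estimator biases high. The improved estimator replaces −ln P with an
empirical response f(P, D) parameterised by W/D, where D (the equivalent
leaf length) is the square root of the mean single-leaf area. f is bounded
(f(0) = A₄, f(1) = 0), continuous, and for W/D ∈ [2, 10] monotone
non-increasing over any practical sampling of (0, 1); the coefficient table
is fixed — this package never re-fits it. At W/D = 3 (the recommended
setting) f tracks −ln P closely in mid-range gaps and deviates exactly
where the small-square bias lives (f(e⁻²) ≈ 1.98 against −ln = 2.00,
f(0.5) ≈ 0.685 against 0.693).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| W (square side) | 3 D | sample square side; 10 D effectively removes the finite-size bias of the classical method, 3 D is the recommended operating point of the improved formula |
| D (equivalent leaf length) | 0.09 m | √(mean single-leaf area); sets the W/D ratio the coefficients depend on |
| G(θ) | spherical (0.5) | leaf projection function; horizontal (cos θ) matches the flat-leaf simulator |
| log base in A_i | natural | the coefficient expression's logarithm; base-10 selectable. Natural log is the default because at W/D = 3 it makes f(P) track −ln P, which base-10 does not |
| zero-gap policy | substitute | closed squares get P = 1/(2 W_px²) (half a pixel of gap) in the classical method and are counted in `zero_gap_squares`; a strict-error mode exists. The improved formula needs no policy |
| W/D validity | [1, 20] | outside this the improved estimate carries a warning note, not an error |
| thresholds | method 1: (80, 160, 18, 240, t5 ∈ {−1, 40}); method 2: (5, 5, −1, 80, −1) | hue bounds in degrees, everything else on the 8-bit channel scale, rescaled linearly for deeper images; all inequalities strict, so boundary pixels are background |
| ROI | ≤ 30° view zenith | largest centred rectangle inside the zenith disc; ≈ 2.3 m ground side for a 120° lens at 3 m |

Classification design choices: hue is measured in degrees [0, 360) — the
default window (80, 160) brackets green at 120°, which would be meaningless
on a 0–255 hue scale; the saturation floor t3 = 18 is interpreted on the
0–255 scale (S·255 > t3) for consistency with the channel thresholds. The
dark-soil branch (R < t5 and B < t5) is a per-run soil-moisture config
choice, not an automatic detection. Method selection by growth stage
(sparse → evening true-colour image with method 1; dense → noon
false-colour image with method 2) is a lookup with fallback, and image
quality screening is a boolean accept flag in the manifest — both were
manual steps in the original deployment.

The false-colour band-mixing matrix of the camera is not public; the
default conversion is the permutation that swaps the green- and
blue-carrying channels, and any non-zero user matrix is accepted (band
mixing has no need to be invertible; the all-ones matrix, for instance, is
a legitimate luminance collapse).

## The simulator and what it does (not) show

`simulate` drops flat lens-shaped leaves (two circular arcs through the
tips, widest at midspan; aspect ratio 6, corn-like) on a torus-wrapped
square plot. Leaf count is ⌈target · area / D²⌉, so the true LAI is exact
and within one leaf of the target; placement is uniform (Boolean model) or
Gaussian around uniform plant centres (clustered; 4 plants/m², scatter
σ = 1.5 D). The torus wrap avoids edge-density bias. Overlap is allowed:
LAI counts total leaf area, which is precisely the quantity gap inversion
must recover. Because leaves are flat and horizontal, G(0) = 1 and the
nadir gap law is P = exp(−LAI) exactly — the closed form every estimator
test is checked against.

What the simulator does **not** emulate: leaf inclination and its
projection effects, mutual shading and illumination gradients, perspective
(it renders an orthographic nadir view), weeds, soil-moisture variation,
specular sky reflection. Passing tests therefore demonstrate the
correctness of the inversion mathematics and the classification rules on
their own assumptions, not field accuracy — field accuracy is what the
bundled campaign tables measure.

Default study conditions for estimator checks: 6 m plots at 300 px/m,
D = 0.09 m, LAI ∈ {0.5, 1, 2}, five seeds. These sizes keep a full
recovery run in seconds while leaving ≥ 36 squares even at W = 10 D;
tolerances are 5 % (classical, W = 10 D), 15 % (improved, W = 3 D — kept
generous because the coefficient table was calibrated on a leaf-shape
family whose exact geometry is not public, and our lens outline only
approximates it), and a sign test for the small-square overestimation.
Rendering defaults are leaf (0, 200, 0) and soil (110, 70, 45): the soil
green is kept below method 2's highlight threshold (G > 80), as in the
darkened false-colour acquisitions that rule is designed for.

## Validation statistics

Estimates are regressed on destructive truth (OLS with intercept). Both
RMSE conventions are reported — √(mean squared signed error) and the
regression residual √(SSE/(n−2)) — because the campaign's printed RMSE is
not labelled with a convention; on the bundled 19 records they are 0.2532
and 0.2646 for the photographic system. The printed slope (0.944) is not
recoverable from the printed records under any standard OLS convention
(the fit gives 0.974); the package therefore reports the computed slope and
documents the qualitative claim it supports: the photographic system's
slope is close to 1 and closer to 1 than the canopy analyzer's (0.774).
Signed errors follow the bundled table's convention (estimate = truth +
error, "+" meaning overestimation); relative errors divide by truth and
are flagged unstable when truth < 0.2.

## Numerical notes and edge cases

- Gap-grid tiling anchors at the top-left and discards partial edge
  squares; leaf-pixel conservation (Σ(1−P_i)W² = leaf count over the tiled
  region) is asserted exactly in tests.
- f(P) endpoints are evaluated by their algebraic limits, not the raw
  expression (0^0 hazards). The P→0 limit converges like P^(1/A₁), i.e.
  slowly; numerical continuity checks probe at 10⁻³⁰.
- If every square is fully gap, Ω is defined as 1 (the 0/0 limit of a
  bare canopy); P_i = 1 squares contribute ln 1 = 0 and stay in the mean.
- The ROI clip adds a half-pixel slack before an exact corner check, so an
  image whose corners sit exactly on the zenith limit is retained whole.
- View zenith mapping normalises the half-diagonal to half the field of
  view, for both the equidistant (default, typical of a 120° lens) and
  rectilinear projections.
- 10-bit camera data is carried in 16-bit containers at stored scale;
  thresholds are specified on the 8-bit scale and rescaled by
  (2^depth−1)/255 at comparison time.

## Known limitations

- Off-nadir operation is untested: the per-square θ path exists but all
  bundled and simulated inputs are nadir (θ = 0).
- No weed/crop discrimination; in the field this inflates LAI, which the
  campaign data show.
- The improved formula's coefficients apply to fusiform leaves sampled
  with squares; other leaf shapes or transect sampling would need a
  different table.
- Only per-pixel colour rules are provided — no learned segmentation, no
  shadow model.
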