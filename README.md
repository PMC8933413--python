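# canopylai

Leaf area index (LAI) and clumping index from nadir canopy photographs.

Fixed downward-looking cameras over crop plots (corn in the motivating
deployment) take photographs several times a day. Each photograph is
clipped to its near-nadir region, every pixel is classified as leaf or soil
background with simple colour thresholds, and the resulting binary mask is
tiled into sample squares whose gap fractions are inverted to LAI. The
package is aimed at people running such ground stations — and at anyone who
needs a well-tested reference implementation of finite-length gap averaging
with its small-square correction.

## The estimators

Tile the leaf mask into m squares of side W; square i has gap probability
P_i (fraction of soil pixels). With view zenith θ and leaf projection
function G(θ) (0.5 for a spherical leaf angle distribution, cos θ for
horizontal leaves):

**Classical finite-length averaging**

    L = -cos(θ) / (m G(θ)) · Σᵢ ln P_i(θ)
    Ω =  m ln( mean_i P_i ) / Σᵢ ln P_i          (clumping index)

Averaging log-gaps over finite squares yields LAI and the clumping index Ω
simultaneously (Ω = 1 for a random canopy, < 1 for a clumped one). It has
two known pathologies: a fully covered square (P_i = 0) makes the sum
diverge, and squares not much larger than a leaf bias L upward.

**Improved small-square formula** — replaces -ln P by an empirical function
of P and the equivalent leaf length D = √(mean single-leaf area):

    L = (1/m) Σᵢ cos(θᵢ)/G(θᵢ) · f(P_i, D)
    f(P, D) = (1-P) P^(1/A₁) + (1 - P^(1/A₂)) (1-P)^(1/A₃) / (1/A₄ + A₅ P^(A₆))
    A_i = a_i1 + a_i2 (W/D) + a_i3 ln(W/D)

with a fixed 6×3 coefficient table calibrated on simulated fusiform-leaf
scenes. f(1) = 0 and f(0) = A₄, so closed squares contribute a finite cap,
and the small-square bias is largely removed. The recommended square side
is W ≈ 3D.

The package also ships the destructive ground-truth computation
(leaf length × width sums scaled by a shape factor and plant density),
validation statistics (OLS slope, two RMSE conventions, error extrema)
against bundled field-campaign tables, 3×3 satellite LAI window means, and
a Boolean-model canopy simulator whose scenes have exactly known LAI — the
oracle behind all estimator tests.

## Worked example

```python
from canopylai import (
    SceneSpec, Appearance, simulate_scene, render_rgb, classify_image,
    ThresholdSet, gap_grid, lai_classical, lai_improved,
    ImprovedCoefficients, LeafAngleModel,
)

spec = SceneSpec(target_lai=1.5, extent=6.0, resolution=300.0, D=0.09, seed=42)
scene = simulate_scene(spec)
img, truth = render_rgb(scene, Appearance(glint_fraction=0.02, noise_sd=3.0, seed=42))
mask = classify_image(img, ThresholdSet.method2_defaults())

lad = LeafAngleModel("horizontal")            # simulator leaves are flat
grid = gap_grid(mask, W_px=81)                # W = 3 D at 300 px/m
coeff = ImprovedCoefficients(W=81.0, D=27.0)
classical = lai_classical(grid, lad)
improved = lai_improved(grid, coeff, lad)

print(f"true LAI           {scene.true_lai:.4f}  ({scene.n_leaves} leaves)")
print(f"FVC                {classical.fvc:.4f}")
print(f"classical (W=3D)   L = {classical.L:.4f}   omega = {classical.omega:.4f}")
print(f"improved  (W=3D)   L = {improved.L:.4f}   omega = {improved.omega:.4f}")
```

prints

```
true LAI           1.5001  (6667 leaves)
FVC                0.7754
classical (W=3D)   L = 1.5805   omega = 0.9449
improved  (W=3D)   L = 1.5638   omega = 0.9449
```

A 6 m plot carrying 6667 randomly placed 9-cm leaves (true LAI 1.5001) is
rendered, classified, and inverted: 77.5 % of the ground is covered, the
classical estimator at the small square side W = 3D overestimates (1.58),
and the improved formula pulls the estimate back toward the truth (1.56).
The clumping index near 0.94 reflects the mild apparent clumping that
finite squares see even in a Poisson canopy.

The same steps are available from the shell:

```bash
canopylai simulate --lai 1.5 --seed 42 --out-rgb scene.png --out-truth truth.json
canopylai classify --method 2 --in scene.png --out mask.png
canopylai lai --mask mask.png --w-px 81 --d-px 27 --lad horizontal --out results.csv
canopylai fixtures --table 5 --out campaign.csv
```

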