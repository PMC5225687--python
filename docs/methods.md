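# Methods

`thermofac` segments the hot *thermal core* and the surrounding *thermal
edge* of an abnormal region in a breast thermogram with a two-stage
parametric active contour (snake) whose growth is supervised by a Mamdani
fuzzy controller. This note documents the model, the numerical choices, the
defaults and their rationale, and what the synthetic phantoms do and do not
establish about clinical data.

## Input model

A thermogram is a 2-D temperature field in °C (`ThermalImage`). When only
an RGB rendering is available, the BT.601 luma of the channels serves as a
documented grayscale proxy; it preserves the ordering of hot and cold but
not radiometric units. Coordinates are `(row, col)`, 0-based, pixel centers
at integers; sub-pixel snake positions are sampled bilinearly. Physical
distances are pixel distances times `pixel_pitch_mm` (user input, default
1.0, i.e. distances reported in pixels) because thermal cameras rarely
publish their pixel-to-millimetre calibration.

## Stage 1 — thermal core

**NASTA feature.** The short-term autocorrelation of a signal at center
`t` and lag `k` is `R_t(k) = Σ_l w(l) f(t+l) w(l+k) f(t+l+k)` over a
rectangular window of odd length `L` (windows are clipped at the border —
no out-of-image temperatures are invented). Summing over all integer lags
in `[-L//2, L//2]` gives the accumulative STA; the 2-D extension weights
each pixel by a temperature coefficient `p` before the lag products. The
per-pixel accumulation over all lag pairs, min-max normalized to
`[0, 255]`, is the NASTA map. Choices:

* `p(T) = T / max(T)` (default): monotone emphasis of hot pixels and
  scale-free. `unit` and `softmax` strategies are available; the exact
  functional form is not recoverable from prior art, so it is isolated
  behind `temperature_weights`.
* Normalization is per-image min-max. A constant image (or constant
  accumulation) is information-free and maps to all zeros; without this
  rule, border clipping alone would paint spurious structure onto a
  featureless image.
* Default `L = 5`. The window trades feature locality against smoothing:
  the NASTA transition ramp across a temperature step spans roughly `±L/2`
  pixels, and `L = 5` keeps that ramp narrow enough for the pressure snake
  to localize boundaries of cores as small as 8 px while still averaging
  noise. (`L = 7` widens the ramp and degrades small-core localization.)

**Pressure snake.** The contour seeds as a small circle inside the hottest
zone (Canny edges of the normalized image place the seed at the centroid of
the closed component containing the temperature maximum; a 5-px circle at
the maximum is the fallback — the component only *places* the seed, the
seed stays small so it starts strictly inside the plateau). Each point
feels the internal force `α S'' − β S''''` plus the NASTA balloon force
`q · G(NASTA(S)) · n̂` along the outward normal, where the gate

```
G(v) = clamp(1 − |v − μ| / (k σ), −1, 1)
```

compares the local feature value with statistics `(μ, σ)` of the pixels
inside the current contour: the snake inflates where the image looks like
its interior and deflates where it does not, coming to rest on the core
boundary. Interior statistics are refreshed at the consultation cadence.
The interior spread uses the scaled median absolute deviation (1.4826·MAD)
rather than the standard deviation: the minority of near-boundary pixels
whose feature values are already transitional would otherwise widen the
gate band and let small cores leak into the first layer. A sigma floor
(`sigma_floor = 0.02` of the map's dynamic range) keeps the gate usable
over perfectly uniform interiors. `k = 1.25` and `q = 0.5` place the
equilibrium within ~1 px of the true boundary across core radii 8–20 px on
phantoms.

## Stage 2 — thermal edge

The converged core contour, dilated outward by `edge_dilate = 4` px (past
the texture transition band of the core boundary itself), seeds a second
snake with four forces:

* the same internal terms (weights restarted at 1, then fuzzy-tuned);
* an edge-energy force `γ ∇(|∇(G_σ * I)|²)` (Gaussian smoothing
  `sigma_g = 3` px, `γ = 45`) — gradient ascent on smoothed edge magnitude;
* a texture pressure force: the same gate applied to the Beltrami texture
  descriptor `T(x, y) = exp(−det(g)/σ)`, where `g = I₂ + JᵀJ` is the metric
  tensor of the position-plus-window embedding and `J` the window's spatial
  Jacobian (central differences, reflected borders). `det(g) ≥ 1` with
  equality on locally constant images, so `T` is bounded in
  `(0, e^{−1/σ}]`, monotone in texture energy, and invariant to constant
  offsets. The descriptor's closed form is a declared design choice,
  isolated behind `texture_descriptor` so it can be swapped.
* a spring force `−λ (V_i − S_i)` toward the corresponding anchor point on
  the core result (`λ = 0.005`), stabilizing against runaway growth.

Mechanics on a layered region: interior texture statistics mix flat and
transition-band values, so mild texture dips at interior layer boundaries
keep a positive gate (`sigma_floor_T = 0.35` enforces this) and the snake
grows through them; the outer boundary carries both the strongest
temperature step (deep texture crater, `G = −1`) and the strongest edge
attraction, so the snake is pulled onto it and pinned. `γ` is sized so the
edge force overcomes the crater's deflation near the crest (offset
`∝ q_T/γ`), while the 25-fold weaker inner-ring attraction never traps the
contour; `q_T = 0.3` sets growth speed and stop overshoot. The result must
enclose the core contour (checked against a slightly shrunk anchor so the
stiff-spring limit is not flagged); otherwise a contour-inversion error is
raised.

## Time stepping

External (image) forces are applied explicitly with `ρ = 1`. The internal
tension/rigidity terms are integrated *semi-implicitly*:

```
(I + ρ (α K2 + β K4 + λ)) S^{n+1} = S^n + ρ F_ext + ρ λ S_anchor
```

because the explicit update is unstable for order-one weights — the cyclic
fourth-difference operator `K4` has eigenvalues up to 16, an amplification
factor of 15 per explicit step. On a cyclic uniformly indexed contour both
difference operators are circulant, so the implicit solve is an exact
division in Fourier space; folding the (diagonal) spring term in keeps the
step unconditionally stable for any `α, β, λ ≥ 0`, including the
stiff-spring limit. Arc-length resampling every `reparam_every = 5`
iterations keeps the discretization uniform and enforces counter-clockwise
orientation, fixing the outward-normal sign.

**Termination**, in priority order: (1) the fuzzy controller orders a stop;
(2) energy balance — either the maximum per-iteration displacement falls
below `tol = 0.05` px, or the enclosed area is stable to 0.5 % across two
consecutive 10-iteration windows (a balloon snake at equilibrium jitters
against the opposing force instead of freezing, so a pure displacement
criterion would never fire); (3) `max_iter = 2000`, returned flagged
non-converged. A contour whose area falls below 4 px² raises a
degenerate-contour error.

## Fuzzy controller

Every `fuzzy_every = 5` iterations the controller computes three crisp
inputs: the mean temperature of the annulus swept since the previous
consultation (empty annulus → 1-px band along the contour), the relative
area growth rate (shoelace polygon areas; sub-pixel-consistent stand-in for
pixel counting, difference < 1 px per boundary vertex), and the largest
Lyapunov exponent of the contour's radius series (too-regular series are
treated as firmly non-chaotic). Membership functions are triangles/
trapezoids; temperature labels are relative to the image's robust
(1st/99th-percentile) range — *low* saturates below baseline + 25 % of the
range, *high* above + 60 % — because absolute clinical breakpoints are not
available; growth labels are *uniform* (≤ 0.05), *moderate*, *excessive*
(≥ 0.30); behavior labels are *non-chaotic* (≤ −0.05), *weakly chaotic*,
*chaotic* (> 0.10). All breakpoints are configuration; the defaults were
calibrated on phantoms.

Inference is Mamdani min–max over a user-replaceable plain-text rulebase of
25 rules (two wildcard-merged) on the 3×3×3 antecedent grid: hot layers are
abnormal — the more so under excessive growth or chaotic behavior — and
cool layers with orderly growth are Normal. Centroid defuzzification over
four output memberships on `[0, 1]` yields `μ_out`, which becomes both
snake weights (`α = β = μ_out`); the class dominating the landscape at the
centroid is the verdict, and class Normal orders the stop (the contour has
left the abnormal thermal layers). If no rule fires, the declared fallback
is class Suspicious with unchanged weights and no stop. Under this
rulebase, inference is monotone: raising the *high*-temperature degree
never moves the verdict toward a less abnormal class.

## Lyapunov test

The boundary's radius series (centroid-to-vertex distances in traversal
order) is standardized, delay-embedded (`M = 3`), and all vector pairs with
temporal separation > M and separation `0 < d₀ < r = 1` (one standard
deviation) are collected; `L` is the mean of `ln(d_n/d₀)/n` over the pairs.
Two estimator safeguards:

* **Horizon `n_step = 2`.** Close pairs of a strongly chaotic series
  saturate at the attractor diameter within a few steps; longer horizons
  systematically shrink the estimate (on the logistic map the horizon-5
  estimate falls to half the true ln 2, the horizon-2 estimate to ~0.56).
* **1 % separation inflation.** Conditioning on `d₀ < r` selects initially
  small separations, which regress toward the typical chord length and
  bias the log-ratio slightly positive even for periodic series. Each
  `d₀` is therefore inflated by 1 %: a pair must diverge by more than 1 %
  over the horizon before it counts as evidence of chaos. The margin is
  invisible against a genuine positive exponent but keeps periodic and
  deterministic series non-positive.

Verdicts: `L < 0` deterministic, `0 ≤ L ≤ 0.1` weakly chaotic, `L > 0.1`
chaotic (threshold shared with the fuzzy behavior labels). Constant series
and series with fewer than `min_pairs = 10` qualifying pairs raise an
insufficient-recurrence error, which the controller maps to non-chaotic.

## Evaluation metrics

`d(a, M)` is the minimum distance from a point to the contour's polygonal
*segments* (robust to unequal sampling densities; a vertex-only variant
exists behind a flag). MD averages and HD maximises these distances,
symmetrized over both directions because one-sided variants are ambiguous
about direction. Both are translation/rotation invariant and scale linearly;
millimetre outputs are pixel values × pitch. Sensitivity, specificity and
accuracy come from explicit confusion-matrix counts; a zero denominator
raises an error naming the statistic.

## Synthetic phantoms

`make_phantom` renders a compact core plateau at `t_base + ΔT` surrounded
by `n_layers` concentric annuli whose temperature drops by `δ` per layer,
over a cooler baseline, with seeded Gaussian noise and an optional radial
boundary perturbation (sinusoidal, or chaotic via a logistic-map orbit so
the boundary radius series is genuinely chaotic). The same relative
perturbation profile multiplies every boundary radius, preserving nesting;
pixels are classified against the perturbed per-angle radii, so the
≥64-vertex ground-truth contours match the rendered image exactly.

Defaults — baseline 32 °C, ΔT 4 °C, δ 0.5 °C per layer, layer width 6 px,
noise SD 0.2 °C — are stand-ins for typical breast-thermogram contrast on a
~0.1 °C-sensitive camera; the clinical source ranges are not published.
What phantom results do **not** show: real thermograms have non-circular
lesions, vascular structure, body-contour background, and camera fixed-
pattern noise; the phantoms establish correctness of the machinery
(feature definitions, force balance, stopping logic, metrics), not clinical
accuracy. Problem sizes used throughout testing — 128×128 images, 20
phantom geometries with core radii 8–20 px and 2–4 layers, series length
2000 for the Lyapunov references — were chosen to exercise every code path
at desk scale.

## Known limitations

* The texture descriptor saturates (underflows to 0) where `det(g)` is
  very large; only the gate's sign matters there, so this is harmless, but
  `T` should not be used as a quantitative texture measure at strong edges.
* The edge stage assumes the outer boundary carries the strongest
  temperature step in the region swept; a lesion whose interior steps are
  stronger than its rim would pin the contour early.
* The controller's temperature labels adapt to the image range, so a
  thermogram with no abnormal region at all makes *high* relative to a
  benign maximum; the tool segments the hottest structure it finds and
  reports distances — deciding whether that structure is pathological
  requires the clinical context around the tool.
* Spring correspondence between the edge contour and its anchor is by
  index after joint arc-length resampling; for strongly non-convex cores
  the correspondence can shear, which weakens (but does not destabilize)
  the spring.
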