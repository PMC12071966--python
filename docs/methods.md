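# Methods

`exoenrich` implements the quantitative core of a medium-exchange
optimization workflow for in-situ exosome enrichment in a shallow
microfluidic bioreactor (µBR): a two-factor response-surface experiment over
the exchange interval and exchanged volume, constrained optimization of the
fitted surfaces, a fed-batch mass-balance model of product accumulation,
geometric estimators for the chamber and the tumor interstitium, and a
morphometric spreading statistic.

## Experimental design (`design`)

The design is a rotatable central composite design (CCD) in two factors:
medium-exchange interval A (center 10 h, axial half-range 5 h) and exchanged
volume B (center 275 µL, axial half-range 125 µL). With four factorial runs
the rotatable axial distance is α = 4^(1/4) = √2, so factorial points sit at
coded ±1 (actual center ± halfrange/√2: 6.46/13.54 h, 186.6/363.4 µL), axial
points at coded ±√2 (the range extremes 5/15 h, 150/400 µL), plus five
center replicates — 13 runs in standard order.

Coded and actual units are linked by `actual = center + x · halfrange/α`.
All regression happens in coded units, so the common practice of printing
display-rounded actual levels (186 µL for 186.6) cannot perturb any
coefficient. When a design is read from CSV, recovered coded levels are
snapped to the canonical set {−√2, −1, 0, 1, √2} within 0.05 coded units;
this tolerance absorbs exactly that display rounding (≈0.007 coded units in
the bundled table) while still rejecting non-CCD layouts.

## Surface fitting (`rsm`)

Each response is modeled as a polynomial in the coded factors,

    Y = b0 + b1·X1 + b2·X2 + b12·X1X2 + b11·X1² + b22·X2²,

estimated by ordinary least squares (statsmodels OLS behind the module
surface). Default model forms: exosome content uses the full second-order
polynomial; cell density and glucose use first-order forms. These are the
unique forms whose 13 fitted values agree with the bundled design's
predictive columns at printing precision — e.g. the first-order glucose fit
gives 75.79 mg/dL at run 1 and 67.86 at the center, which a full quadratic
would not. No automatic term selection is applied; a backward-elimination
helper (drop the largest-p term while p > 0.05) exists but is never invoked
implicitly, preferring reproducibility over automation.

ANOVA splits the corrected total sum of squares into model and residual,
and the residual into lack of fit and pure error, the latter estimated from
the center replicates only. F ratios are reported without significance
thresholding. Range-ratio summaries (max/min of a response) are computed
from the *experimental* columns, not fitted surfaces.

## Constrained optimization (`optimize`)

The reproduction path is the hard-constrained problem: maximize predicted
exosome content over the actual-unit box [5, 15] h × [150, 400] µL subject
to predicted glucose ≥ 40 mg/dL. The box — not the coded-radius-√2 circle —
is the feasible region; the optimum lies outside the coded circle, which is
only consistent with box bounds. The solver evaluates a dense 501×501 grid
(vectorized polynomial evaluation), then polishes the best feasible grid
point with SLSQP on the continuous problem; the polished point is accepted
only when feasible and at least as good, so the grid argmax is always a
fallback and the procedure is deterministic (grid ties break toward smaller
volume, then smaller time). On the bundled design this yields 150 µL (volume
bound active), 12.06 h (glucose floor active), predicted exosome
189.4×10³/µL.

A Derringer–Suich desirability composite (per-response scores in [0, 1],
combined by geometric mean) is provided for heat-map parity with commercial
DOE software; since the original desirability weights are not known, the
hard-constrained formulation — which is fully determined by the stated
objective, floor and box — is primary. Cell density is reported at the
optimum but not constrained by default; a floor can be added in the spec.

## Fed-batch accumulation (`fedbatch`)

The chamber plus its two feed reservoirs are treated as one well-mixed
volume `V_tot` (default 500 µL; the physical reservoir volumes are a device
property, so this is a configuration parameter — exchanged volumes of
150–400 µL against a 9 µL chamber necessarily address a larger connected
volume). Between exchanges, exosome concentration follows
dC/dt = qN/V_tot − k_deg·C (closed form; linear ramp at k_deg = 0) and
glucose falls linearly at uN/V_tot (converted to mg/dL·h⁻¹), floored at
zero with the crossing flagged as starvation. An exchange instantaneously
replaces the fraction f = min(1, V_ex/V_tot) with fresh medium under ideal
mixing: C⁺ = (1−f)C⁻ and G⁺ = (1−f)G⁻ + f·G_f.

The pre-exchange exosome level converges to the periodic steady state
C* = qNτ/(V_tot·f) (k_deg = 0), so partial exchange concentrates product by
1/f relative to full exchange at the same interval — the quantitative
content of the semi-fed-batch argument; f ≤ 0.25 gives the ≥4-fold
enrichment regime. Cell number is held constant within a simulation
(proliferation is not coupled), matching the fixed-cell-load framing of the
theoretical comparison the model serves.

Defaults: N = 4×10⁵ cells, G_f = 100 mg/dL (low-glucose medium), q = 50
exosomes·cell⁻¹·h⁻¹ (literature-typical order for tumor lines), u = 1.8×10⁻⁸
mg·cell⁻¹·h⁻¹ — chosen once so that the optimized schedule (150 µL every
12 h) holds the steady-state glucose minimum just above the 40 mg/dL floor
(≈42.8 mg/dL), consistent with discharge glucose of about 40 mg/dL under
that schedule. Because none of q, u, or V_tot is independently measured,
fed-batch claims are validated as closed-form identities and monotonicity
or existence properties, never as point targets.

## Geometry (`geometry`)

Chamber volume and area use exact cylinder formulas (15 mm × 50 µm gives
8.84 µL and 1.77 cm²). The interstitial fraction of a packed tumor layer
models cells as cylinders on a planar lattice: areal packing density
ρ·(d/(d+gap))² with ρ = π/4 (square) or π/(2√3) (hexagonal), scaled by the
height occupancy of the layer. The TME-confinement estimator redistributes
the mass measured in an assay volume into the interstitial fraction of a
tumor volume (mass conservation is exact by construction). All inputs are
parameters; the module deliberately hard-codes no published interstitial
fraction or spiked-concentration value, because the published derivation of
those numbers is not reproducible from its stated inputs (a measured
20 ng/mL with a 29% fraction cannot simultaneously give ≈3×10⁵ ng/mL and a
"100,000×" enrichment; 306,513/20 ≈ 15,300).

## Morphometrics (`morphometrics`)

The tortuosity index is the ratio of mean minimum-enclosing-circle areas of
cell outlines between a later and a reference time point — group means, not
matched pairs. "A circle tangent to the cell body" is read as the minimum
enclosing circle: for a round day-1 cell this is its circumscribed circle,
for a spread cell the smallest circle covering all appendages; it is the
only reading consistent with both morphologies. The circle is computed with
Welzl's move-to-front algorithm over a fixed-seed permutation (deterministic,
expected linear time, exact for the 2- or 3-point support set; collinear
support degenerates to the widest diameter circle). The index is invariant
to rigid motions and scales as k² under uniform k-fold spreading.

## Synthetic data (`synthetic`)

The CCD generator evaluates known coded-unit coefficients at the 13 design
points and adds i.i.d. Gaussian noise, homoscedastic per response. Default
truth is the set of surfaces fitted to the bundled design (re-derived at
call time); default noise SDs are the center-replicate sample SDs
(cell 75.8 /mm², exosome 3.05×10³/µL, glucose 7.03 mg/dL) — the only
replication information available. The outline generator produces polygonal
ellipses (semi-axes r·elongation × r) with random rotation, translation and
optional radial vertex jitter. All generators are pure functions of their
seed.

What the generators do not emulate: run-order or drift effects,
heteroscedastic or non-Gaussian measurement error, factor-setting error, and
any coupling between responses. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated error model, not
robustness of the original experiment.

A consequence worth stating: with glucose noise at the replicate-anchored
7.03 mg/dL, the refitted optimum's interval coordinate (the glucose-floor
crossing at the volume bound) has a sampling SD of ≈0.77 h by the delta
method (≈0.74 h empirically over 500 seeds, mean 12.08 h, i.e. unbiased).
About 83% of refits land within ±1 h of 12.06 h, and the volume coordinate
returns to the 150 µL bound in >99% of refits. The interval coordinate is
thus the noise-limited part of the optimum under this error model.

## Numerical choices

- OLS is solved by statsmodels; tests cross-check against explicit normal
  equations. Rank deficiency raises an error naming the collinear terms.
- Constraint satisfaction tolerance 1e-6 response units; binding constraints
  reported at |slack| < 1e-3.
- Surface evaluation outside coded radius √2 is permitted but warned as
  extrapolation (the constrained optimum itself lies at radius 1.53).
- Simulations use closed forms between exchange events — no ODE stepping —
  so steady-state identities hold to round-off.
- Problem sizes in the test suite: 2001² grid for the one-shot optimizer
  oracle, 1000 random instances for the enclosing-circle oracle and the
  coefficient-recovery study, 500 seeds for end-to-end optimum recovery at
  a 201² grid.

## Known limitations

- Exchange is ideal instantaneous mixing; plug-flow washout, spatial
  gradients, oxygen/pH dynamics and growth coupling are out of scope.
- The desirability path reproduces heat-map shape, not the unknown original
  weighting.
- Prediction uncertainty of the optimum (confidence region on the
  stationary/boundary point) is not computed.
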