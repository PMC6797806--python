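# Methods

## Model

`osteoadapt` simulates load-adaptive remodeling of trabecular bone in a 2D
(mesial–distal) section of the anterior mandible carrying one or three
teeth. The model couples three ingredients:

1. **Linear elasticity.** Plane-stress, isotropic, linear-elastic 4-node
   bilinear quadrilaterals with full 2×2 Gauss quadrature, assembled into a
   sparse symmetric system and solved by direct sparse LU factorization.
   Units are mm–N–MPa, so a strain energy density of 1 MPa is numerically
   1 J/cm³ and the stimulus below needs no conversion factor. Each tooth's
   load (100 N vertical + 10 N lateral toward the mesial side, per tooth)
   is split in equal shares over a small node set at the crown tip — a
   3-grid-column cap — because a single-node point load would create a
   mesh-dependent stress singularity in the stimulus field. The bottom
   edge is fully fixed; the lateral edges are either constrained to
   vertical motion ("constrained", the default) or left free.

2. **Modulus–density law.** Non-trabecular tissues (enamel 79,600 MPa /
   ν 0.3, dentin 18,600 / 0.31, pulp 150 / 0.49, cementum 13,700 / 0.3,
   PDL 200 / 0.45, gingiva 200 / 0.45, cortical 13,700 / 0.3) keep fixed
   constants. Trabecular elements get E = C·ρ³ with C = 3790 MPa·cm⁹/g³
   and ρ the apparent density in g/cm³. The trabecular Poisson ratio is
   not density-dependent; 0.3 (the cortical value) is used, standard in
   bone FE and consistent with the isotropic-linear simplification.

3. **Remodeling rule.** The stimulus is strain energy density per unit
   bone mass, S = U/ρ (J/g). Per iteration, each trabecular element's
   density changes by

       Δρ = 0                              if (1−δ)S₀ ≤ S ≤ (1+δ)S₀
       Δρ = (S − (1+δ)S₀)·BΔt  (growth)    clipped to +0.05·ρ
       Δρ = (S − (1−δ)S₀)·BΔt  (loss)      clipped to −0.05·ρ

   with defaults S₀ = 0.008 J/g, half-width δ = 15%, BΔt = 2 g²/(J·cm³),
   and a 5% saturation cap. The saturation thresholds S_l and S_u are
   defined *implicitly* as the stimuli where the linear branches reach the
   cap — the unique continuous completion of the five-branch rule; a
   discontinuous jump to the saturated branches would need numeric S_l/S_u
   values that are nowhere defined. Density is clamped to
   [0.1, 2.2] g/cm³ (the upper clamp being the apparent density of
   cortical bone). Updates are simultaneous (Jacobi-style) over all
   elements. Cortical bone is not remodeled; its properties stay fixed.

The loop iterates solve → stimulus → update until the mean trabecular
density changes by less than 0.03% (relative) over two consecutive
iterations, or for at most 80 iterations.

## Synthetic geometry

No anatomy accompanies the study this model emulates, so the section is
generated parametrically: a 48 × 30 mm rectangle with three evenly spaced
stylized teeth (elliptical crowns — enamel shell over dentin over a pulp
chamber — above a gingival line; trapezoidal tapered roots — dentin core
with a pulp canal, wrapped by cementum and PDL layers — embedded in bone),
a 2 mm cortical plate across the bottom, a 2 mm gingival band at the
alveolar crest, and trabecular fill elsewhere. Default tooth dimensions
(crown 14 mm tall / 11 mm wide, root 11 mm long tapering 55% from a
6.8 mm width, apices 3 mm above the cortical plate, ~4 mm of bone beyond
the outer teeth) are in the range of natural anterior human teeth and were
chosen so that at the default 0.2 mm element size the mesh has ≈29,000
elements with ≈10,400 of them trabecular — the target proportions of the
emulated models. Two geometric features matter mechanically: the apices
must clear the cortical plate (otherwise tooth loads shunt directly into
the fixed plate and bypass the basal trabecular bone), and the outer teeth
need bone margins (otherwise edge boundary effects contaminate the
peri-root region).

Meshing is rasterized: a structured axis-aligned quad grid covers the
domain, each cell is labeled by classifying its centroid, and cells
outside the anatomy are dropped. This guarantees positive Jacobians and
deterministic region labels with no mesh-generator dependency; the cost is
staircase tissue boundaries and sub-element layers (PDL 0.4 mm, cementum
0.25 mm) rasterizing to the nearest label, acceptable because region areas
still converge under refinement and the remodeled region is the bulk fill.

## Calibration of the stimulus scale

A 2D section model has an out-of-plane thickness that the physical problem
does not define; with fixed tooth forces, the entire stimulus field scales
as 1/t² and the converged density field follows it. The package therefore
treats thickness as the one calibrated parameter: the default, 0.175 mm,
is set so that the default run (constrained edges, uniform 0.8 g/cm³
start) on the reference mesh reproduces the expected behavior of the
emulated models — most trabecular elements start above the equilibrium
zone, mean density rises rapidly in the early iterations, and the mean at
the 80th iteration is ≈1.67 g/cm³. With a naive thickness of 1 mm the
stimulus is ~30× too weak and the simulation resorbs instead of
densifying. All *trend* results (which parameter moves the converged state
in which direction) are insensitive to this calibration; all *absolute*
densities inherit it and should be read as calibrated, not predicted.

## Parametric studies

Five one-at-a-time sweeps, all other parameters at defaults:
boundary-condition mode {constrained, free}; uniform initial density
0.2–2.0 g/cm³ step 0.2; i.i.d. uniform random perturbations (±0.5%, 1%,
2%, 5%) of the 0.8 g/cm³ start; reference stimulus 0.002–0.014 J/g step
0.002; equilibrium half-width 5–45% step 10%. The perturbation
distribution is uniform and element-wise independent (a choice; nothing
constrains it otherwise).

Sweep runs always execute the full 80-iteration budget rather than
stopping at the 0.03% criterion, because sweep values are compared at a
common iteration count and because the mean-change criterion can fire
spuriously early when growth and loss transiently balance (observed, e.g.,
three iterations into a run started at 1.6 g/cm³). The iteration at which
the criterion is first met is recorded in each trajectory and in the sweep
summary (`converged_at`).

Summary metrics: final mean trabecular density; "lowest/highest density
area" fractions, defined as ρ ≤ 0.3 and ρ ≥ 2.0 g/cm³ (near-clamp bands
standing in for the blue/red regions of a color map; both configurable);
field similarity 1 − mean|Δρ|/(ρ_max−ρ_min) over a mask. Two standard
masks: the *peri-root band* (trabecular elements within 1.5 mm of a
PDL/cementum surface — a tight band hugging the roots; a wide band would
cover most of the trabecular area and be unselective) and the *bottom
half* of the trabecular band by centroid height.

## Numerical choices and diagnostics

- Direct sparse LU on the constrained system; the solver verifies that
  reaction forces balance applied loads to 1e-8 relative and that the
  solution is finite. The work–energy identity ∑U·V = ½fᵀu holds to
  solver precision and is tested.
- Full 2×2 integration everywhere. The nearly incompressible soft tissues
  (pulp ν 0.49; PDL/gingiva 0.45) may lock mildly; they are thin, not
  remodeled, and act as load spreaders, so this is accepted.
- U per element is the volume-weighted Gauss-point average of ½σ:ε
  (for these bilinear quads, equivalent to the element mean).
- Checkerboard index: mean absolute density difference across
  edge-adjacent trabecular element pairs, normalized by the field range
  (0 = uniform or smooth, 1 = perfect min/max alternation). Default runs
  score ≈0.06; the regression guard is 0.2. The equilibrium zone and the
  5% saturation cap are what keep the field smooth — removing both is the
  classical recipe for checkerboard divergence.
- Fixed-point structure: an element is stationary exactly when its S lies
  in the zone; because the discrete iteration approaches a zone edge
  geometrically (contraction ratio ≈0.9 for the single-bar problem), a
  run that approaches equilibrium from outside halts on the 0.03%
  criterion slightly *outside* the zone (≈0.3% in density for the bar).
  Verification runs that must reach the edge use a tighter tolerance.
- Degenerate inputs: densities at or below zero are rejected (the clamps
  make them impossible in-loop); inverted elements abort assembly naming
  the element; empty load node sets abort meshing.

## Reference problem sizes

Tests and the parametric drivers run on a reduced mesh (0.6 mm elements:
3,146 elements, 1,160 trabecular, ~6,600 dof), where one 80-iteration run
takes a few seconds and the full five-study suite a few minutes on one
CPU. The full-resolution mesh (0.2 mm: 28,254 elements) is used for mesh
verification and is the default for production runs via the CLI. Trend
results quoted in the README are from the reduced reference configuration.

## What the synthetic setup does and does not show

The geometry is stylized (ellipse/trapezoid primitives, equal teeth,
straight gingival line) and the load case is a static proxy for chewing.
Passing trend tests show that the *algorithmic* claims — direction and
relative sensitivity of each parameter's effect, stability without
checkerboarding, near-independence from initial conditions — are
reproduced by an independent implementation on an independent geometry.
They do not show agreement with any specific patient anatomy, nor do
absolute densities carry meaning beyond the thickness calibration above.
Known limitations: no PDL nonlinearity or contact; no cortical
remodeling; no muscle forces or 3D effects; loading history reduced to a
single static case.
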