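# Methods

## The model

The early fly blastoderm is modelled in cross-section as an elastic rod — a
chain of `N+1` particles joined by springs — confined inside a rigid
semi-elliptical shell of semi-major axis `L` (the model length unit) and
aspect ratio `beta = 0.4` (eccentricity `e = sqrt(1 - beta²)`). The total
energy per unit length is the discretized stretching + bending functional

    W*_T = ½ K_s Σ (Δr_i/Δr_o − 1)² Δr_o  +  ½ K_b Σ (κ_i − κ_{o,i})² Δr_o

with both sums over the particles/springs that have full neighbour support
away from the two pinned particles at each end, `Δr_i` the current length of
spring *i*, `Δr_o = L0/N` the common rest length derived from the full
semi-ellipse arc `L0`, and `κ_i` the discrete signed curvature at particle
*i*. The single control parameter is the dimensionless bending rigidity
`K_b* = K_b/(K_s L²)`; `K_s = 1` throughout.

**Discrete curvature.** `κ_i = 2 sin(θ_i/2) / l̄_i`, where `θ_i` is the
signed turning angle between the two incident segments and `l̄_i` their mean
length. This is exact (`1/R`) for equally spaced points on a circle and has
a cheap analytic gradient. Sign convention: curvature that follows the
convex shell is positive; an invagination toward the interior is negative.

**Dynamics.** Overdamped explicit-Euler relaxation,

    r_i ← r_i − dt·(L/(K_s τ))·∂W*/∂r_i + ζ_i,

with `τ = 1`, `dt = 1e-5·τK_s/L` and `ζ_i` i.i.d. Gaussian displacement
noise of standard deviation `1e-5·L` per component per step, applied before
confinement. Any proposal outside the shell is repositioned at the
intersection of the proposal segment with the ellipse (the root in [0, 1] of
a quadratic; a proposal from a point already on the boundary returns the
previous point). The first and last two particles never move. The inner
loop is numba-compiled; noise is drawn in chunks from a seeded NumPy
generator, so trajectories are bit-reproducible for a given seed.

## Morphogenetic programs

* **Germ-band extension** enters only through initialization: the tissue is
  laid at equal arc spacing on `[u', π]` with `u' = arccos(1 − 2g)`, while
  rest lengths come from the full `[0, π]` arc, leaving a uniform
  compression `Δr(0)/Δr_o = arc(u',π)/arc(0,π)` for `g > 0`.
* **Mitotic domains** insert a particle at the midpoint of every spring
  inside the configured regions; daughter springs keep `Δr_o`, so the
  region's preferred length doubles. Default layout: two regions of arc
  length `0.5L` each — a head region (centre 0.80 embryo length, clear of
  the furrow) and a posterior region (0.35). The region-extent convention (0.5L *per region* vs *in total*)
  matters: with only 0.5L of total insertion, mitotic domains cannot drive
  any ectopic folding at bending rigidities ≥ 0.4e-4 within feasible run
  lengths, which would leave the mitotic-domain-only condition inert across
  the canonical rigidity range; we therefore adopt per-region.
* **Cephalic furrow**: particles within arc distance `width/2` (default
  `width = 0.05L`, the initiator-cell span) of the centre (default 0.65
  embryo length) receive a negative preferred curvature. The quoted furrow
  strengths `κ_cf ∈ [0.1, 2]` are interpreted *per joint*:
  `κ_{o,i} = −κ_cf/Δr_o`, i.e. a preferred turning angle of `κ_cf` radians
  at each joint. Read instead as a continuum curvature in `1/L`, the same
  numbers are geometrically incapable of invagination (a region of width
  `w` at curvature `κ ≤ 2/L` dimples by only ~`κw²/8 ≈ 1e-3·L` plus a
  stretch-limited pull-in; measured depth ≈ 0.005L, independent of `κ_cf`).
  The per-joint reading produces the intended behaviour: a robust single
  furrow-site fold at the reference rigidity, with robustness onset between
  0.3 and 0.5 on the default strength grid.

Events are scheduled by iteration; `t_MD = 1` corresponds to 1e5 steps.

## Observables

A **fold** is a maximal contiguous cluster of particles whose distance to
the elliptical boundary (Newton/bisection closest-point solve, ~1e-12·L)
exceeds `0.035L`, the model's canonical detection threshold; a fold's
position is the
axis position of its deepest particle, on a 0 (posterior) → 1 (anterior)
embryo-length scale. Folds inside the programmed furrow region are labelled
"cephalic furrow", all others "ectopic". `calibrate_threshold` re-measures
the threshold as the maximum stress-free excursion. **With the default
noise and timestep this calibration yields ≈0.006L at 20×1e5 steps (N=200),
not 0.035L**; the excursion grows only sub-diffusively with duration
(≈0.009L after 1e6 steps), so the canonical threshold cannot be recovered
at desk scale from the stated noise parameters. We keep 0.035L for
detection — it is part of the model definition — and report the measured
calibration honestly. Consequently fold detection here has essentially no noise floor
false positives.

Energy traces record `W_s`, `W_b`, `W_T` (raw and normalized by the initial
total energy); stochastic replicates are aligned at the smoothed bending-
energy peak (moving window, default 50 recorded points, ties to earliest)
before averaging, because fold formation converts stretching into bending
energy at an unpredictable iteration but the fold count rarely changes
after the peak.

## Experiment campaigns and their regimes

Replicate `r` of any condition uses seed `base_seed + r`, so conditions are
compared at matched seeds. Default grids: `K_b* ∈ {0.2, …, 2.0}·1e-4`,
`g ∈ {0, …, 0.4}`, furrow strengths `{0.1, 0.3, 0.5, 1.0, 2.0}`; default
run length 3e5 steps (long enough to cover a `t_MD = 1` delay plus two
time units of post-insertion relaxation).

Because buckling here is noise-activated escape, fold counts depend on run
length; the regimes used by the acceptance suite were chosen for where each
phenomenon is measurable at desk scale, not for the numbers they produce:

* Phase diagrams and the reference-rigidity criterion: N=150, n=10
  replicates, 3e5 steps. The germ band at maximum extension stops folding
  at `K_b* ≈ 1.0–1.4e-4`; mitotic domains alone stop at ≈0.6–0.8e-4; the
  joint criterion (both mean fold counts < 1) lands at ≈0.8e-4.
* Furrow robustness sweep: `K_b* = 1e-4`, g=0, mitotic domains simultaneous
  (the furrow needs a compression source to absorb; without one no swept
  strength exceeds the fold threshold), 10 replicates, 2e5 steps.
* Buffering contrast (furrow vs no furrow): `K_b* = 0.2e-4`, where MD-only
  ectopic folding is reliable within 3e5 steps. The furrow organizes the
  would-be fold at the head–trunk site into the programmed invagination;
  total fold count with a furrow (ectopic-only) is lower than without.
* Delayed-timing condition: reference rigidity 1e-4; the furrow forms
  within the first 1e5 steps and the delayed mitotic domains produce no
  head-region ectopic folds.

## Synthetic-data generators (kinematics)

The strain-rate magnitude `E = |½∇·v + ½(∂x v_y + ∂y v_x)|` is computed by
central differences (one-sided at edges). The generator emits linear
velocity fields `v = (D/2·x + (S−Ω)/2·y, (S+Ω)/2·x + D/2·y)` plus i.i.d.
Gaussian noise, with ground truth `E = |D/2 + S/2|`; rotation Ω is invisible
to E by construction. Outlines are sinusoids with tortuosity (arc/chord)
computed by dense quadrature; kymographs are linear `d(t) = d₀ + v·t` plus
noise, fit by OLS over a 30 s window. What these emulate: smooth gridded
PIV displacement fields, already-extracted outline polylines and binarized
kymograph traces. What they do not: image noise structure, PIV correlation
artefacts, segmentation errors, curvature of real embryonic axes — so a
green round-trip test establishes correctness of the estimators, not
robustness to imaging pathology.

## Numerical choices and degenerate inputs

* Elliptic arcs: adaptive quadrature (1e-12 tolerances); equal-arc particle
  placement by inverse interpolation of a 2000-node cumulative table.
* Closest-point distance: bracketed Newton in the first quadrant (the
  bracket `f(0)·f(π/2) ≤ 0` is guaranteed); centre point returns the
  semi-minor distance.
* Curvature at an exactly folded-back joint (`θ = ±π`) is regularized by
  clamping the squared normalizer at 1e-300; with `dt = 1e-5` such states
  are never reached in practice.
* A projection from a point exactly on the boundary returns the previous
  point (the intersection is degenerate); tangential sliding remains
  possible on later steps.
* Ties in the bending-energy peak break to the earliest iteration.

## Known limitations

* Three reference constants are sensitive to implementation details the
  continuum description does not fix (particle count, run length, the
  discrete-curvature convention, the mitotic-domain layout): the 0.035L
  threshold, the rigidity up to which mitotic domains alone fold, and the
  furrow-strength units. Our resolutions are documented above; where a
  residual discrepancy remains (the threshold calibration) it is reported,
  not patched.
* No self-contact or excluded-volume forces: at very soft rigidity deep
  folds can cross themselves, and a strong furrow (`κ_cf = 2`) can split
  into two adjacent detected clusters.
* Fold onset times are resolved only to `record_every` steps, and onset
  matching across frames is positional (±0.05 embryo length), which is
  adequate because folds do not migrate along the axis.
* The delayed-timing protection (the wild-type-like schedule) emerges here
  only at the reference rigidity; in very soft tissue (0.2e-4) insertion
  mass overwhelms the furrow's absorption capacity and timing confers no
  protection.
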