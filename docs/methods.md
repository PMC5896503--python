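# Methods

This note records the models, numerical choices and calibrations behind
`coccotopo`, and what the synthetic populations do and do not show.

## Topological model

A complete coccosphere is treated as a 3-connected cubic planar graph:
faces are coccoliths, edges are pairwise shield overlaps, vertices are
the junctions where three overlaps meet.  Face sizes are restricted to
4–6 (a 3-edged coccolith would force inter-coccolith angles below 90°
and coccoliths longer than the cell; more than six neighbours is
excluded by the generation itself at small sizes).  Euler's formula
then fixes `2F₄ + F₅ = 12` with `F₆` free, and the mean edge number per
face is `n̄ = 6 − 12/F`.

**Existence checking.**  Admissible face compositions are only
*necessary*; whether a polyhedron exists with a given face-size
multiset is decided by exhaustive generation.  Every 3-connected cubic
planar graph arises from K₄ by repeatedly subdividing two distinct
edges of one face and joining the two new vertices, so the generator
grows a per-face-count catalogue level by level, deduplicating with a
canonical planar code (breadth-first vertex labelling from a root
directed edge, minimised over all roots and both orientations, so
mirror images are identified).  Face sizes of intermediates are *not*
pruned — a large face can later be split — which keeps the construction
exhaustive; the per-level counts reproduce the classical counts of
simplicial 3-polytopes (1, 1, 2, 5, 14, 50, 233, 1249, 7595 for 4–12
faces).  The default tractable bound is 12 faces (20 vertices; the
12-face level takes a few minutes on one core); larger compositions are
reported as "not tested", never silently absent.  3-connectivity is
checked by exhaustive two-vertex removal — simplicity over speed at
these sizes.

## Coverage model

- Mean cell surface: per-cell averaging of `π·d²` equals the moment
  identity `π·(μ² + σ²)`; both estimators are provided, and the identity
  explains why the population figure slightly exceeds `π·μ²`.
- Coccolith surface: the *minor* spherical cap with base diameter equal
  to the mean of DSL and DSW on the cell's own sphere.  (The major cap
  would exceed a hemisphere, contradicting the single-layer geometry.)
- Effective coverage per coccolith: cap area × `r(n̄)`, with
  `r(n) = (n/2π)·sin(2π/n)` the maximum-inscribed-polygon area fraction
  of an ellipse; real-valued `n` is accepted because the identity is
  applied at population means.
- Count estimate: damped fixed-point iteration (damping 0.5, relative
  tolerance 1e-10, start `A_sphere/A_cap`, iterates floored at 4 so
  `6 − 12/N > 3`), cross-checked against bisection to 1e-8 relative.
- Regression direction: sphere area on count, so the slope has units
  μm² per coccolith, directly comparable with the effective coverage
  area.  The published "fraction of variation explained" figure derived
  from the slope is *not* reproduced: its derivation is not
  reconstructible from the printed quantities, so only the fit's own R²
  is reported.
- Division bookkeeping: equal-volume division of one sphere into `k`
  daughters multiplies total surface by `k^(1/3)`; respiration and
  dark-calcification offsets are user-supplied fractions defaulting to
  0 (no published values).

## Interlocking simulator

All simulation is planar.  The overlap edges around a central coccolith
form a polygon inscribed in its outer ellipse; vertices sit at equally
spaced parameter angles (the maximum-inscribed-polygon family, phase
optimisable), and each bordering coccolith is placed with its polygon
chord as a chord of its own outline, mirror-symmetric about the chord's
perpendicular bisector, axes parallel to the chord.  Adjacent borders
share a polygon vertex.

The feasibility criterion is explicit and configurable, because no
quantitative criterion is published:

1. **Central clearance** (mandatory): every polygon chord must clear
   the central coccolith's central area.  Clearance is a support-
   function test: a line at distance `p` from an ellipse's centre
   clears it iff `p ≥ √(a²cos²θ + b²sin²θ)` in the normal direction θ.
   For a circular outline this yields the closed-form triangle
   threshold OSW/DSL = 1/4, used as an exact oracle.
2. **Border clearance**: the mutual overlap chord of each adjacent
   border pair (computed by locating the boundary intersections of the
   two outlines with a 360-point scan plus Brent refinement) must clear
   both borders' central areas.
3. **Tightness**: that same overlap chord must penetrate each border's
   shield annulus by at least a threshold fraction of the shield
   width, else the configuration is "loose".

A geometric fact drives the design: an ellipse through two fixed
vertices becomes *flatter* as it grows, so the central↔border pair
geometry gets shallower for larger neighbours, and it is the
border↔border engagement that deepens with neighbour size.  This
reproduces the observed failure directions — undersized neighbours
disengage (loose), oversized neighbours' mutual overlaps cut into
central areas (transect) — and bounds the neighbour count: three
borders force chords through the central area at observed shield
ratios, eight force border–border transection.

**Calibration.**  The strict module default for tightness (0.9 of the
shield width, encoding "interlocked very closely") makes the idealised
mirror-symmetric placement read "loose" for most configurations; scans
and the neighbour-count Monte-Carlo therefore take the threshold as an
explicit parameter, with the Monte-Carlo defaulting to 0.2 (engagement
over at least a fifth of the shield width), chosen once as the weakest
threshold that still separates disengaged from engaged neighbours.
Published calibration points (the 0.37 triangle threshold for much
larger neighbours, the 0.75–0.8 seven-neighbour size band) are treated
as diagnostics: the simulator brackets the seven-neighbour band with
the correct failure modes but locates it more widely than printed,
since the printed band's criterion is not recoverable.  One scan result
is opposite to naive expectation and is asserted as computed: with the
polygon phase free, the minimal shield width for a three-neighbour
interlock *increases* with DSW/DSL — shrinking the outline by a fixed
OSW makes an eccentric central area relatively flatter and easier to
avoid, so the circle is the worst case.

## Morphometric probabilities

Gaussian tails use scipy's complementary-error-function routines, so
nine-sigma events (OSW/DSL ≥ 0.37 under N(0.19, 0.02), ≈1.1e-19) retain
relative accuracy.  The bordering-size band probability is reported
under three readings — central size fixed at the mean (closed form
`q(μ)^k`), one random shared central (`∫φ·q^k` by adaptive quadrature,
Monte-Carlo Rao-Blackwellised over the central draw), and independent
size ratios (`P(lo ≤ X/Y ≤ hi)^k` by quadrature over the denominator) —
because the published figure does not pin one down; the three span
roughly 1e-11 to 1e-7 at the published band, with the independent-ratio
reading within a factor of three of the printed value.

## Synthetic populations

DSW and OSW are generated as truncated-normal *ratios* of a truncated-
normal DSL, which matches the published absolute and ratio statistics
simultaneously; truncation uses the printed hard ranges.  Coccolith
counts close the loop with the coverage model: the true count is the
fixed point for the cell's own diameter plus N(0, 1.5) noise before
rounding (the noise scale is the one free knob, set so the count SD
lands near the observed 3.6), floored at 6; the reported count hides
22% of interlocked coccoliths and doubles the visible half.  One master
seed spawns independent substreams per table.

What the generator does *not* emulate: malformed or incomplete
coccoliths, treatment-group structure (the source populations were
pooled), any within-cell correlation between coccolith size and cell
size, and measurement error.  Passing tests therefore demonstrate the
internal consistency of the analysis chain on an idealised population,
not robustness to those real-data features.

## Numerical conventions

Lengths μm, areas μm², angles radians; ellipse frames are
centre/major-axis aligned.  Sample SDs use the n−1 denominator;
percentiles are linear-interpolation quantiles; normality testing is a
D'Agostino–Pearson diagnostic that gates nothing.  The spherical-cap
height uses the cancellation-free form `r²/(R + √(R² − r²))`.  Problem
sizes in the test suite (10⁵ coccoliths, 10⁴ coccospheres, 150-trial
Monte-Carlo, exhaustive polyhedra to 12 faces) were chosen to make
sampling error negligible relative to the asserted tolerances while
keeping the suite comfortably fast on one core.
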