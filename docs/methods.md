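# Methods

This note documents the models implemented in vmatflux, the choices made
where the underlying methods leave freedom, and what the synthetic study
conditions do and do not establish.

## Fluence model

The MLC is modeled as a 2-D in-air primary fluence φ(x, y) on the isocenter
plane: a 512×512 grid at 1 mm with element centers on integer mm and the
central axis on the center of element (256, 256). Rays are parallel —
fluence lives only at the isocenter level, so no source divergence or
in-patient ray tracing enters the fluence step. Columns run along leaf
travel, rows along leaf width, in the collimator frame; collimator rotation
is applied to the finished map (exact index permutations for multiples of
90°, bilinear resampling otherwise, conserving total fluence to ≲0.5% for
smooth maps).

Per sample point the fluence is 1 in the open field and otherwise the
transmission of the governing structure, most attenuating first: the jaw
value (default 0) outside the jaw rectangle; `t_leaf` under the
full-thickness mid part of a leaf; and inside the tongue-and-groove strip —
total width `tg_width` = 0.8 mm, centered on each interior leaf boundary —
`t_tg` when exactly one adjoining pair covers the point (single tongue or
groove over the neighbor's opening), `t_interleaf` when both do (the
interlocked stack), 1 when neither does. The strip transmission is bilinear
in the two pairs' covered fractions so all four corner cases are met exactly
and the transition across the leaf-end penumbra is smooth; monotonicity
(opening a leaf never lowers fluence anywhere) holds provided
`t_tg > t_interleaf`, which the defaults satisfy.

Orientation convention: the tongue is on the +y side of every leaf, the
groove on the −y side. The choice is arbitrary (the physical strip is the
overlap of one leaf's tongue with the neighbor's groove and is symmetric in
this model); it fixes only which pair "owns" a strip sub-zone in
`zone_profile`.

Transmission defaults are typical published Varian values — `t_leaf` 0.015,
`t_interleaf` 0.020, `t_tg` 0.08 — and are constructor parameters, as every
clinic commissions its own. The rounded leaf end is a logistic sigmoid of
the signed tip distance, scaled from `t_leaf` to 1, with an effective
dosimetric-gap half-width of 1 mm (`LeafEndCurve.width`); the product of the
two tip sigmoids of a pair also produces the residual abutted-pair leak. A
measured transmission table can replace the sigmoid by subclassing the
curve; the parameterization, not the exact shape, is what the tests rely on.

### Volume averaging

With 5/10 mm leaves every boundary (hence every 0.8 mm TG strip) sits on an
element center and single center-point sampling is exact — volume averaging
provably changes nothing (asserted element-wise in the tests). With 2.5 mm
leaves, half of the central boundaries fall on half-integer mm; the strip
then straddles two elements and center sampling misses it completely. The
correction divides each element into two 0.5 mm sub-rows (sample points at
±0.25 mm), averages the two samples, and therefore equals a box-downsampled
0.5 mm rasterization exactly, since the sample points coincide — this
equality over random apertures is the module's core correctness check. The
half-open/half-tongue element value is then (1 + t_tg)/2.

## Arc discretization

Weights: wᵢ = ½(MUᵢ − MUᵢ₋₁) + ½(MUᵢ₊₁ − MUᵢ) for interior CPs, zero at the
ends. The telescoping identity Σwᵢ = ½(MU_N₋₁ + MU_N₋₂ − MU₁ − MU₀) is
asserted on random monotone sequences.

Three-aperture beams interpolate full machine states (both banks *and*
jaws): the flanking apertures are ⅔xᵢ + ⅓xᵢ₋₁ and ⅔xᵢ + ⅓xᵢ₊₁. The
published description states the "before" coefficient twice; the "after"
aperture is implemented with the i+1 neighbor, which is what "interpolated
at two-thirds' degree before and after each beam" requires (erratum noted).
Beam tripling inserts CPs at ⅓ and ⅔ of each interval with everything —
gantry (unwrapped through 0°), leaves, jaws, cumulative MU — linearly
interpolated, then reweights the expanded sequence with the same wᵢ formula.

**Weight bookkeeping caveat.** The zero-endpoint convention discards half of
the first and last MU interval, and discards *less* of it after tripling
(edge intervals shrink threefold): the 5-CP arc retains Σw = 0.9 of its MU
as 5 beams but 0.9667 as 13. Raw 3apers/3xbeams doses therefore differ by a
~7% scale factor that has nothing to do with aperture sampling — a static
plan shows the same offset. All mode comparisons here are made per unit
retained MU (dose / Σw); on that scale the three-aperture and tripled-beam
calculations agree at the isocenter to ~0.04% on the 5-CP arc while the
single-aperture mode is off by ~6%. For clinical-length arcs (≥ 100 CPs)
the retained-MU difference is negligible and the caveat disappears.

The exact mathematical content of the equivalence is linearity: the
convolution correction is linear in φ, so the dose of the Eq.-average
fluence equals the weight-split sum of per-aperture doses at the same gantry
angle to FFT roundoff (asserted ≤ 1e−10 relative over the well-conditioned
in-field region). The remaining 3apers-vs-3xbeams difference is the genuine
discretization residual: the tripled plan weights an inserted aperture by
its local MU interval, the three-aperture beam by the centered difference of
its parent CP, and these coincide only where cumulative MU is locally
linear in arc position.

## Dose engine

D(x, y, d) = D₀ · conv(φ, K_d)/conv(U, K_d), convolutions by FFT on the full
grid. Where the open-field convolution falls below 10⁻⁶ of its maximum (far
outside the jaws) the ratio falls back to the raw fluence value — a
D₀-scaled transmission — and the element is flagged in the provenance,
never a division blow-up. Kernels are tabulated at discrete depths; the
correction ratio is computed at the bracketing depths and interpolated
linearly, since the underlying relation holds per depth.

Geometry is parallel-beam: gantry 0° points straight down, rotation about
the couch axis; a coronal measurement plane is projected into each beam's
transverse frame and sampled bilinearly. The phantom is a laterally
unbounded slab stack, so the equivalent depth of a flat plane under one
beam is a single ray-traced number (density-weighted path length from the
entry surface). The canonical setup is film-between-slabs: 5 cm buildup +
5 cm backscatter of water, plane through the isocenter.

All beams of a discretization are evaluated, zero-weight endpoints included:
the evaluation count (N vs 3N−2) is the structural cost model of the two
schemes and is part of the provenance, so the "same number of beams" claim
is testable without wall clocks.

## Toy commissioning data

No measured beam data are used anywhere; absolute clinical doses are out of
scope. The deterministic toy set: TMR(d, s) = exp(−μ(s)(d − d_max)) with
d_max = 1.5 cm and μ(s) = 0.038 cm⁻¹ · (1 − 0.003(s − 10)) (a realistic 6 MV
falloff with a mild field-size dependence; no buildup region is modeled
since all study depths exceed d_max); unit output and off-axis factors; a
two-Gaussian pencil-beam kernel — 90% core with σ = 1.0 mm + 0.1 mm/cm of
depth, 10% scatter with σ = 8 mm + 0.4 mm/cm — tabulated at depths 1.5, 5,
10, 20, 30, 40 cm on a ±80 mm support and normalized to unit sum. These
values were fixed once as plausible for a 6 MV beam; every dose assertion in
the tests is relative (ratios, mode differences, identities), not absolute.

## Synthetic study data

`five_cp_arc` realizes the printed constraints of the validation arc:
gantry 357/358/0/2/3°, cumulative MU 0/0.1/0.5/0.9/1, collimator 90°, only
pairs 30–31 moving, leading/trailing travel 8/4 cm, kick-off and ending CPs
duplicating their inner neighbors. The exact aperture coordinates are not
published; the fixture uses the symmetric left-to-right sweep
(−4,−2) → (−2,2) → (0,6) cm for the moving pairs, with pairs 21–40 statically
open at (−3,3) so the region around the isocenter — including the reference
point 1 cm to its left — sees a constant aperture. Tests depend only on the
printed constraints, not on the free coordinates.

`random_arc` random-walks the centers of ten central leaf pairs with fixed
opening widths, step SD chosen so the expected absolute movement equals the
requested `motion_scale`; out-of-range steps are applied with flipped sign
(magnitude-preserving) and only clipped, with a warning, in the rare case
neither direction fits. Realized mean movement converges to the request
(within 10% at 200 CPs is asserted).

What these fixtures do **not** emulate: measured beam data (head scatter,
flattening-filter profiles, divergence), film/chamber response, patient
anatomy, delivery-time effects (dose-rate modulation, leaf-position errors).
Passing tests therefore establish the internal consistency and the
discretization/sampling behavior of the algorithms — the mechanism of the
accuracy improvements — not absolute clinical dosimetry.

## Gamma and difference metrics

Gamma is exhaustive within 3× the distance criterion at 0.1×DTA steps
(test dose bilinearly interpolated), visited in order of increasing shift
with early exit once the distance term alone exceeds every remaining
candidate — equivalent to the full scan, which an independent brute-force
oracle confirms on 32×32 crops. Local normalization (the stricter clinical
convention) is the default; elements below 10% of the ROI reference maximum
are excluded. The dose-difference summary normalizes the mean to the ROI
mean reference dose and reports the >4% high-difference area under both
normalizations (ROI-mean and local), since both conventions are in use.
Leaf-motion SD uses the population estimator (divide by n); the >2 cm
percentage counts strictly greater movements.

## Numerical and degenerate-input policy

Plan validation is total and locates the first offending control point;
nothing is silently repaired. Gantry sequences are unwrapped so arcs
crossing 0° interpolate correctly and are re-wrapped to [0, 360). Rays
missing the phantom or running parallel to the slabs yield zero depth with
a warning rather than an error, matching the flagged-fallback philosophy of
the dose engine. Fluence values are clamped nowhere — the model produces
[0, 1] by construction, and a property test asserts it.

## Known limitations

* No 3-D leaf-tip curvature ray tracing, jaw scatter, head scatter, or MLC
  calibration offsets; transmission magnitudes are configuration, not
  measurement.
* Parallel (non-divergent) beams; slab phantoms only; coronal planes only.
* One arc per plan; no couch or isocenter shifts.
* The ~100-aperture accumulation alternative at 5° spacing is discussed in
  the literature but intentionally not implemented.
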