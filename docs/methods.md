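# Methods

## The model family

`foveamap` implements analytic retino-cortical projections for the early
visual areas V1, V2 and V3 of the primate brain. A visual hemifield
location is written as a complex number `z = E·exp(iθ)` with eccentricity
`E` in degrees and polar angle `θ` in radians (0 on the horizontal
meridian, positive for the upper field). The map variants are

| variant            | map                                   | character |
|--------------------|---------------------------------------|-----------|
| `monopole`         | `w = k·log(z + a)`                    | conformal; foveal taper only |
| `dipole`           | `w = k·log((z + a)/(z + b))`          | conformal; tapers at fovea and periphery |
| `sheared_monopole` | monopole of `E·exp(i·θ̂(θ,E))`        | meridionally isotropic |
| `sheared_dipole`   | dipole of `E·exp(i·θ̂(θ,E))`          | meridionally isotropic |

`w` is a planar cortical position in mm (right hemifield → left
hemisphere, x growing fovea → periphery). The sheared variants are the
family known in the retinotopy literature as the double-sech model; see
"The shear function" below for how this implementation derives the shear.

The V1–V2–V3 complex is built in two stages. First the hemifield is
reflected into an intermediate "pacman" space: V1 keeps its angles
(compression `alpha1`, default 1), V2v/V2d are appended by mirroring each
quadrant about the vertical-meridian border with compression `alpha2`
(default 0.5), and V3v/V3d by mirroring once more with `alpha3` (default
0.4), so that the V2/V3 border carries the horizontal meridian and the
pacman rim is again a vertical-meridian image. Second, the pacman is
pushed through one of the maps above. Because each area's wedge shares
its border rays with its neighbours, cortical border images coincide
exactly and the confluence is seamless.

## The shear function

The defining requirement of the sheared family is that areal cortical
magnification `M_a` at fixed eccentricity must not vary with polar angle
(the observed polar-angle invariance of magnification in V1). For a map
`w = f(ẑ)`, `ẑ = E·exp(iθ̂)`, with `f` complex-analytic, the areal
density per unit visual area is `|f'(ẑ)|²·∂θ̂/∂θ`, so constancy in `θ`
is the ordinary differential equation

    dθ̂/dθ = |f'(E)|² / |f'(E·exp(iθ̂))|²,   θ̂(0) = 0.

Rather than transcribing a fixed algebraic approximation, this package
solves the equation exactly:

* monopole (`f' = 1/(z+a)`): closed form
  `tan(θ̂/2) = tan(c·θ/2)/c` with `c = |E−a|/(E+a)`;
* dipole (`f' ∝ 1/((z+a)(z+b))`): the quadrature
  `θ(θ̂) = ∫₀^θ̂ |f'(E·e^{iu})|² du / |f'(E)|²` is a sum of two
  Poisson-kernel integrals with closed antiderivatives (a separate
  branch handles the degenerate eccentricity `E = √(ab)` where the two
  kernels become proportional), inverted by a vectorized Newton
  iteration (tolerance 1e-12, initialized at the monopole solution).

The shear introduces no free parameters, is odd in `θ`, vanishes on the
horizontal meridian (so sheared and conformal maps agree there
pointwise), and is strongest at the vertical meridian near `E ≈ a` and
`E ≈ b`. Residual meridional anisotropy of the sheared dipole is at
numerical-precision level (~1e-8), well inside the 5% band used by the
tests. A genuine limitation: any angle-dependent shear is discontinuous
across the ray `θ = ±π` (the "seam", placed in the pacman mouth); only
the banded model's folded V1 fovea ever approaches it.

Direct consequences, all verified by the test suite:

* conformal variants are locally isotropic everywhere (`M_p/M_e = 1`),
  but their areal magnification balloons with polar angle near `E ≈ a`
  (up to ≥ 7× for foveal V3 in the wedge composition);
* the sheared wedge has constant meridional anisotropy per area — 1 in
  V1 and `alpha3 = 0.4` in V3 — at the price of local anisotropy
  `1/alpha` per area (2.5 in V3 for the log-polar wedge, which keeps
  conformality instead);
* V3:V1 integrated surface is `alpha3/alpha1 = 0.4` over any
  eccentricity band under the sheared wedge.

## Banding (the foveal confluence)

Empirically V2 and V3 do not converge to a point at the fovea but form
bands around the tip of V1. The model reproduces this by displacing the
pacman along Cartesian x before the log stage: every point moves toward
the mouth by `s(θ′)`, with

    s(θ′) = lam                            for |θ′| ≤ π/2  (the V1 half-plane)
    s(θ′) = lam · (1 + (|θ′| − π/2))       beyond,

re-expressed in polar coordinates afterwards. V1 translates rigidly, so
its foveal point remains a point (at pacman `(−lam, 0)`); for V2/V3 the
graded magnitude tears the shared apex into a line whose cortical image
is a curve of positive length — the foveal bands. The displaced frame
needs no clamping: radii are non-negative by construction, and for
`lam < a` the folded V1 region (eccentricities ≲ `lam` that cross
`x = 0`) stays clear of the log pole; folded points are flagged in all
gridded outputs. Setting `lam = 0` recovers the plain wedge exactly.

The exact grading of `s` beyond `π/2` is a modelling choice; this
implementation grades linearly at `lam` per radian. The slope trades off
two foveal effects — the areal boost of V2/V3 (the shift stage has
Jacobian `E + s'(θ′)·sinθ′` per pacman area, so graded regions gain
surface as `E → 0`) against the distance of the bands from the magnified
pole. The value 1.0/rad was chosen, once, as the best compromise: it
yields foveal V2 magnification above V1 below ~0.1°, V3 local anisotropy
crossing 1 around 0.25° (against 2.5 without banding), and thin bands.
Two stronger statements are *not* achievable under any monotone
x-displacement grading and are therefore not asserted: V3 magnification
exceeding V1 all the way up to 0.5°, and local isotropy persisting to
arbitrarily small eccentricity (the tangential magnification of a
point-to-line map necessarily diverges as `E → 0`).

## Estimators

All three field estimators mimic the empirical procedure of projecting
small visual-field squares (half-side `delta = 1%` of local
eccentricity, one side orthogonal to eccentricity, the other orthogonal
to the polar direction):

* **local anisotropy** — ratio of projected side lengths, reported as
  `M_p/M_e` (iso-polar over iso-eccentricity). The opposite convention
  appears in parts of the literature; this orientation makes the
  log-polar wedge score `1/alpha3 = 2.5` in V3.
* **meridional anisotropy** — projected square surface divided by the
  surface of the square at the same eccentricity on V1's horizontal
  meridian.
* **areal magnification `M(E)`** — square root of (projected surface of
  a thin iso-eccentricity band / its visual surface), in mm/deg. The
  closed form `k·|1/(E+a) − 1/(E+b)|` is recovered on the horizontal
  meridian within finite-difference error.

Projected surfaces are computed by splitting each quadrilateral into two
triangles (shoelace formula), robust to the strong foveal shear. The
default grid uses 64 log-spaced eccentricities in [0.05°, 24°] and 181
polar samples distributed over the pacman arc in proportion to each
area's angular share; this resolves the ballooning region around
`E ≈ a = 1.05°` without singular squares. Evaluations within 1e-6 deg of
a log pole return NaN and are excluded from aggregates rather than
raising mid-grid.

A further numerical note: the pure inverse-eccentricity law `M = k/E`
is only the asymptotic regime `a ≪ E ≪ b` of the dipole. At the
canonical parameters the dipole's magnification stays 17–23% below
`k/E` throughout 5–15° (`M·E/k = E(b−a)/((E+a)(E+b)) ≤ 0.83` there), so
the law is asserted against the monopole at `E ≥ 15°` in the unit suite;
the dipole comparison at 5–15° within 10% is retained as a deliberately
failing end-to-end check because that bound is not attainable from the
formula.

## Parameter fitting

`RetinotopyFit` (positions) and `MagnificationCurveFit` (curves) follow
the statsmodels shape: model object from data, `fit()` → results object
with estimates, Gauss–Newton standard errors and `summary()`. Fittable
parameters and bounds: `k ∈ [5, 50]` mm, `a ∈ (0, 5]`°, `b ∈ [40, 180]`°,
`lam ∈ [0, 2]`°. By default only `k` is free — the canonical structural
values fit most subjects — and freeing more parameters is explicit.
Optimization is bounded least squares (trust-region reflective) from a
deterministic multi-start grid: the initial guess plus three
one-at-a-time sweeps per free parameter across its bounds; starts are
ranked by objective value and the best few polished. Samples are sorted
canonically before fitting, making results exactly independent of input
order. Position residuals are in mm; curve residuals are in `log M`,
since magnification spans orders of magnitude and relative error is the
physically meaningful scale. Under-determined problems (fewer than one
sample, or three curve points, per free parameter) return a flagged
result instead of a silent fit.

## Synthetic retinotopy

The generator emulates sparse retinotopic mapping data: per area,
eccentricities drawn log-uniformly on [0.2°, 12°] (matching the roughly
log-uniform coverage of eccentricity designs), polar angles uniform over
the area's quadrant, projected through a ground-truth model, plus
isotropic Gaussian position noise (default 1 mm, the scale of fMRI
flat-map localization error). It does not emulate systematic
distortions of real data — flattening distortion, pRF-size-dependent
position bias, hemodynamic spatial correlation, or subject motion — so
parameter-recovery results bound estimator behaviour under idealized
noise only. Recovery studies in the tests use 100 samples per area and
20 noise seeds; at that size the median recovery error of `k`, `a` and
`lam` stays within 10%.

## Known limitations

* Strictly planar: no cortical folding or intrinsic curvature.
* Areas beyond V3, and hemisphere stitching across the vertical
  meridian, are out of scope.
* The banded V1 fovea (E ≲ lam) folds through the confluence point and
  crosses the shear seam; magnification estimates there carry the fold's
  tear and are flagged.
* The grading of the banding shift is this package's own calibrated
  choice (see above); alternative gradings that also satisfy the pinned
  boundary behaviour would change foveal V2/V3 detail.
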