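# Methods

## Forward model

Expected TOF coincidences per LOR and TOF bin t:

    ybar_t = n · exp(−χμ) · H_t λ + s_t

λ is the activity image, μ the 511 keV linear attenuation image (cm⁻¹),
H_t the TOF emission operator, χ the transmission (line-integral)
operator, n multiplicative normalization factors and s_t the additive
expectation (scatter plus randoms; randoms carry no timing information and
are spread evenly over TOF bins). Data are Poisson. Summing over t gives
the non-TOF model used for attenuation estimation.

**Projector.** Both H and χ come from one Siddon ray engine that computes
exact chord lengths of each LOR through square pixels. The discrete
operators are stored as sparse triplets grouped by projection angle, so
ordered-subsets updates address an angle subset directly and the
backprojector is the exact transpose — adjointness holds to float64
round-off, which the test suite asserts at 1e−10. LORs are parameterized
parallel-beam style by radial offset (bin width = activity voxel size) and
angle; crystal-pair geometry informs only the default bin counts. The
reduced-3D variant stacks independent direct-plane slices
(max ring difference 0); oblique LORs are out of scope.

**TOF kernel.** Timing resolution Δt maps to a spatial kernel of FWHM
c·Δt/2 along the LOR (4.50 cm at the default 300 ps). Per-chord TOF
weights are Gaussian bin integrals evaluated at the chord midpoint,
truncated at 3σ and renormalized to sum exactly to one — hence
Σ_t H_t = H holds elementwise to machine precision, and the MLEM
sensitivity image can be computed with a single non-TOF backprojection.
The outermost bins absorb overflow beyond the binned range before
truncation. Defaults: 13 bins × 3 cm, covering the 38.4 cm image
field-of-view; both are configuration parameters, chosen as a realistic
sinogram TOF mashing for a 300 ps scanner (the bin width corresponds to
200 ps).

## Reconstruction updates

**Activity (TOF OSEM).** Multiplicative update with attenuation factors
(and normalization) folded into a; subsets partition angles in
bit-reversed interleaved order. One subset configured as a single subset
reproduces MLEM bit-for-bit, and full (non-subset) iterations
monotonically increase the Poisson log-likelihood. The sensitivity
denominator is floored at 1e−12 of its maximum; voxels below the floor
inside the mask are left unchanged with a warning. Initial estimate: 1
inside the support mask, 0 outside.

**Attenuation (XMLTR / MLTR).** Additive updates from non-TOF data with
the activity projection p = n·Hλ̂ recomputed from the current activity at
every global iteration (never cached across scaling updates). The XMLTR
denominator term χᵀ[b(1 − ys/ȳ²)·χ1] uses χ1 = forward projection of the
all-ones image restricted to the reconstruction support. With s = 0 the
MLTR denominator is written as b·(b/ȳ)·χ1 so the two updates coincide
exactly in floating point. After each update μ̂ is clamped nonnegative and
pinned to zero outside the support. The update's numerator and denominator
equal the gradient and the negated Hessian row-sum of the transmission
log-likelihood; the suite verifies both against central finite differences
of the likelihood on an 8×8 / 10-LOR instance at 1e−4 relative. Voxels
with non-positive curvature (possible transiently with large s) skip the
update with a warning. A damping factor (default 1.0) is exposed for
stability experiments.

## Scale ambiguity and its resolution

TOF data determine (λ, μ) only up to the family (Cλ, μ + log C·μ_unit)
with χμ_unit = 1 on detectable LORs. For a 2D disk support of radius R the
unit medium has the closed form 1/(π√(R²−r²)), singular at the boundary —
VOIs must therefore avoid the support rim.

**Detectable-LOR set Ω.** An LOR is detectable when its chord through the
object support exceeds 1% of the support diameter (the longest chord).
The threshold excludes grazing LORs, along which attenuation recovery is
intrinsically unstable (fewer than two activity-bearing points).

**Unit-medium fit.** Synthetic transmission projections (e⁻¹ on Ω, 1
elsewhere) are fitted with five XMLTR iterations and 28 subsets, with
blank-scan projection p = 1 and s = 0, restricted to the object support.
The residual max|χμ_unit − 1| over interior LORs (chord > 5 cm) is stored
on the result and reported by the CLI — it is dominated by near-tangent
LORs and is never silently ignored. The azimuthally averaged radial
profile of the fitted medium matches the closed form to a few percent for
r ≤ 0.8R; voxel-wise comparison is dominated by angular discretization
noise of the subsetted fit and is not the operative check.

Importantly, Ω and the unit-medium fit use the *object* support, not the
margin-dilated reconstruction support (next paragraph). LORs that
intersect only the margin carry no activity, so attenuation placed there
by the scaling update could never be corrected by emission data; deriving
Ω from the object support keeps the unit medium inside the region the
data constrain. This was measured to be the difference between whole-image
bias stalling at ~13% and converging to ~0.1% on noiseless data.

**Support masks.** Attenuation is reconstructed on the object support
dilated by a 1 cm margin (tolerance against support misestimation); the
activity mask uses the same dilated support. The uniform-water initial
attenuation fills the object support only.

**Scaling step.** log C = (wᵀμ_true − wᵀμ̂)/(wᵀμ_unit) with uniform VOI
weights; both images are updated each global iteration (λ̂ scaled, μ̂
shifted along μ_unit and clamped nonnegative). The default VOI for the
packaged phantom is a 12 cm disk of known water attenuation at (5, −5) cm;
two alternates (6 cm at the center, 8 cm at (−4, 10)) are used to verify
that the VOI choice moves the final activity scale by well under 1%.
The per-iteration (C, log C) trace is recorded; if |log C| exceeds 0.01
and grows for three consecutive iterations the run aborts with a
divergence error (the 0.01 floor keeps noise-level jitter of a converged
trace from triggering the detector).

## The simulator

`default_phantom()` reproduces the evaluation object: a 35 cm water
cylinder (0.096 cm⁻¹), a lung-like cylinder (water/3, 8 cm diameter at
(−8, 0)), an air cylinder (5 cm at (6, 8)), and hot lesions of 22 mm at
contrasts 1.5 and 6 and 37 mm at contrast 3. Lesion positions — (−2, 7),
(10, 4), (0, −10) cm — are a fixed package choice placing all three in
water background away from the attenuation inserts and the lesion-free
evaluation VOI at (2, 1). Voxels take the value of the region containing
their center (no sub-voxel anti-aliasing). Expected trues are rescaled so
their total equals the requested count (default 5×10⁶ for the 2D desk
configuration — reconstruction is scale-equivariant in λ, so a count
target substitutes for absolute activity × time), then independent Poisson
counts are drawn per (LOR, TOF bin) from a seeded generator. The simulator
expectation *is* the forward model, so noiseless runs probe pure
algorithmic convergence.

What the simulator does not emulate: scatter and randoms physics (an
optional smooth synthetic "stub" sinogram exercises the s-dependent terms;
real scatter estimation is an external input), detector normalization
structure (an optional uniform-cylinder emulation produces near-unity
factors), crystal geometry, dead time, decay, and 3D oblique sampling.
Passing tests therefore demonstrate the estimator's correctness and the
scaling mechanism under ideal Poisson statistics, not robustness to the
data imperfections of a physical scanner.

## Default configuration and problem sizes

Scanner: 84.2 cm ring, 19.2 cm FOV radius, 193 radial bins × 96 angles,
300 ps timing. Grids: 2 mm activity (192²), 4 mm attenuation (96²) — the
factor-2 ratio is linked by an adjoint-consistent block-mean/injection
resampling pair. Joint reconstruction: 10 global iterations; per global
iteration one activity iteration with 8 angular subsets and one XMLTR
iteration with 8 subsets (28 for the unit-medium fit and for
scaling-convergence studies, matching the transmission settings used in
the convergence experiments); initial attenuation "uniform water in the
object support" by default, "zero" (no attenuation correction at the first
activity update) as the studied alternative. These sizes keep a full joint
reconstruction around a minute on one CPU.

## Numerical behavior and known limitations

- **Noiseless data:** whole-image activity bias after 10 global iterations
  is ~0.1% from water initialization; |log C| falls below 0.01 within 10
  iterations from both initializations (with 28 attenuation subsets), and
  the lesion-site attenuation crosstalk decays monotonically.
- **Poisson data at desk scale:** a single 2D replicate at 5×10⁶ trues
  carries a noise-seeded, weakly-restored low-frequency attenuation mode
  that leaves a seed-dependent whole-image activity bias of roughly ±2.5%
  after 10 iterations (the VOI constraint pins only the component of the
  gauge mode visible inside the VOI). A 3D acquisition with two orders of
  magnitude more counts and LORs averages this mode far below 1%; the 2D
  desk configuration does not, and no parameter here is tuned to hide
  that.
- **VOI attenuation errors** propagate exponentially into the activity
  scale (a ±1% VOI error moves the activity by ∓≈4–5%), while the mean
  attenuation error stays smaller — activity is the more sensitive output,
  and accurate VOI attenuation is the method's key external input.
- Rays lying exactly along pixel edges are assigned by floor tie-break;
  they are measure-zero and excluded from oracle comparisons.
- The exact unit medium does not exist for general discrete geometries;
  the fit residual quantifies the approximation and the scaling becomes
  insensitive to it as log C → 0.
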