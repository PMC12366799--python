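# Methods

## Problem and model

Transcranial focused ultrasound (tFUS) delivers acoustic energy through
the intact skull to a millimetre-scale brain target. The skull's sound
speed (~2850 m/s) is nearly twice that of soft tissue/water (~1482 m/s)
and varies with local bone thickness and incidence angle, so the
wavefronts from the individual elements of a phased array arrive at the
target with element-dependent phase errors. The resulting interference
shifts and smears the focus, predominantly along the array axis.

This package implements a full-wave *phase-reversal* correction for a
random spherical-cap phased array driving continuous-wave (CW)
ultrasound:

1. fire each element alone in a free field (water only) and record the
   pressure at the intended target;
2. reintroduce the skull and repeat;
3. for element *i*, take the difference of the *last detected peak*
   positions of the two records (in time steps),
   `dt_i = lastpeak(skull) − lastpeak(free)`, and convert it to a phase
   `dphi_i = 2π f0 · dt_i · δt`;
4. add `dphi_i` to element *i*'s source phase and drive all elements
   together.

Because the drive is a single frequency, only the phase modulo 2π
matters; steady-state CW records define the last-peak difference modulo
one acoustic period, which is exactly the quantity the correction needs.
Records that contain no qualifying peak (height ≥ 50 % of the record's
maximum inside the final 25 % of the record — both configurable) mark the
element *unreliable*: it keeps firing with zero correction, matching the
all-elements-active definition of the corrected condition.

## Wave model and solver

Linear lossy acoustics in a heterogeneous fluid (no shear — bone is
modelled as a fluid, consistent with a single skull sound speed), solved
with a k-space pseudospectral time-domain scheme:

* first-order coupled equations for particle velocity and acoustic
  density, staggered in space and time;
* spectral derivatives with the k-space correction factor
  `sinc(c_ref·k·δt/2)`, `c_ref = c_water`; the scheme is exact for
  homogeneous water at any time step (verified to 1e-10 per 100 steps);
* the acoustic density is split per axis so the absorbing boundary layer
  can damp each axis separately (split-field formulation, polynomial
  ramp of exponent 4, `pml_alpha = 2`); measured plane-pulse reflection
  is below 1e-4 at a 20-voxel layer;
* time step locked to the period: `δt = 1/(round(PPW/CFL)·f0)`, so a
  period is an integer number of steps (100 at PPW 2 / CFL 0.02) and
  step-count delays convert to phase exactly;
* absorption is narrowband: the attenuation coefficient (Np/m/MHz,
  linear in frequency) is evaluated once at f0 and applied as a
  per-voxel exponential decay `exp(−α·c·δt)` on all field components per
  step, which reproduces Beer–Lambert decay `exp(−α·x)` for travelling
  waves (verified within 2 %). This deliberately replaces the power-law
  fractional-Laplacian operator of general-purpose solvers: with a CW
  source only one frequency is present.
* additive pressure sources are injected into the split density with the
  plane-wave-equivalent scaling `2·c·δt/dx`. The absolute pressure scale
  therefore depends on this convention; every correction result
  (positions, overlaps, ratios) is invariant to it, and energy metrics
  should be compared only within one convention.

Material constants: skull c = 2850 m/s, ρ = 1732 kg/m³,
α = 85 Np/m/MHz; water c = 1482 m/s, ρ = 1000 kg/m³,
α = 3.48e-4 Np/m/MHz; f0 = 700 kHz; per-element source amplitude 1 MPa.

### Sampling regime

At the full-scale spacing dx = 1.07 mm, water at 700 kHz is sampled at
1.98 points per wavelength — *at* the two-point sampling limit for
axis-aligned propagation (oblique propagation, which dominates for a
focused cap, is representable). Validation tests that need clean
quasi-1D plane-wave propagation therefore run at dx = 1.0 mm (PPW 2.1)
or at lower drive frequencies (350/250 kHz) where the same mechanisms
are measured away from the band edge; the absorption and boundary models
are frequency-independent once α is fixed.

### Known resolution limitation: staircased bone interfaces

The skull is a binary mask, so its surfaces are voxel staircases. At ~2
points per wavelength with a pressure reflection coefficient of 0.54,
the one-voxel transition (sharpened further by the staggered-density
averaging) acts as a fraction-of-a-wavelength matching layer: the
full-wave transmission phase through a flat slab differs from the
straight-ray time of flight by about 1 rad at PPW 2.1, decreasing to
about 0.6 rad at PPW 4.2, with Fabry–Pérot slab resonances contributing
up to a further 0.3 rad at unfavourable thicknesses (exact three-layer
solution). The correction is unaffected — it measures and cancels
whatever phase the wave model actually produces, interfaces included —
but element-wise comparisons between ray and full-wave delays carry this
offset, and the tests bound it rather than assert ray equality.

## Grids and profiles

The inner grid is wrapped in an absorbing layer sized automatically: for
each axis, layer thickness 10–40 voxels per side is searched and the
choice minimizes the largest prime factor of the expanded size (ties to
the smaller size), keeping FFTs fast; 86×140×140 expands to 128×162×162.

Three bundled profiles (`tfus.profiles`):

| profile | inner grid | dx (mm) | steps/period | t_end | array |
|---|---|---|---|---|---|
| paper | 86×140×140 | 1.0714 | 100 (CFL 0.02) | 50 µs | 128 el, 64 mm aperture, 35 mm focus, 4 mm discs |
| desk  | 64×95×95   | 1.0    | 40 (CFL 0.05)  | 40 µs | same array |
| mini  | 36×37×37   | 1.0    | 20 (CFL 0.1)   | 30 µs | 16 el, 24 mm aperture, 17 mm focus, 3.5 mm discs |

The desk profile keeps dx at 1.0 mm rather than coarsening further:
spacings above ~1.06 mm put 700 kHz water propagation below the two-point
sampling limit. Odd lateral dimensions put the array axis exactly on a
voxel column, so the free-field lateral peak offset is exactly 0 at grid
resolution. The mini profile's CFL (0.1) stays well inside the
heterogeneous-medium stability bound (instability was confirmed at an
effective water CFL of 0.2 with bone present). Single-element
delay-estimation runs use a shorter horizon than full-array runs (20 µs
vs 30 µs at mini scale): the target record is steady well before the
full field has converged everywhere. Both horizons are profile fields.

Solver arithmetic defaults to float32 (validated against float64 to
seven significant digits on focal fields); precision-sensitive
validation tests pass float64 explicitly.

## Array model

Element centres are drawn by seeded rejection sampling uniformly on the
spherical cap (uniform in cos θ and azimuth, candidates closer than one
element diameter to an accepted centre rejected), giving a reproducible
random layout; the physical transducer's element chart is proprietary,
and measured coordinates can be imported from CSV instead. Every centre
is equidistant from the geometric focus, so zero-phase drive focuses
there by construction, and `geometric_steering_phases` provides
equal-time-of-flight phases for off-focus targets.

Discs are rasterized as one-voxel-thick oriented slabs with
super-sampled occupancy weights (8×8×8 sub-points per voxel; 4×4×4
aliases badly for discs oriented near 45° to the grid). The weight sum
times dx² reproduces the disc area within 5 % for all 128 elements of
the full-scale array.

## Evaluation metrics

The focus is the −6 dB region: voxels with amplitude ≥ 0.5 × the peak
within the evaluation region (half maximum; the literal −6 dB amplitude
factor is 0.5012, a 0.24 % difference absorbed into the definition).
In skull-present runs the evaluation region is the *intracranial*
compartment — the 6-connected water component containing the target,
with the flood fill restricted to beyond the skull's axial entry plane
so it cannot leak around an open cap's rim — making normalization
relative to peak intracranial pressure. Metrics: axial mean position
`X_focus` (midpoint of the focal axial extent; the centroid is offered
as an alternative), peak position `X_peak`, lateral centroids relative
to the array axis, per-axis diameters `(max−min+1)·dx` (a single-voxel
focus has diameter dx), focal volume, overlap volume with the target
ROI, overlap rate (% of ROI volume), `p_rms = p_peak/√2` at the focal
peak voxel, energy density `p_rms²/(ρc²)` with water constants, and
`E_target = E_density × V_overlap` in SI joules (µJ scale for these
pressures and volumes). Peak ties break to the smallest axial index,
then lexicographically.

## Ray baseline

A deliberately minimal geometric comparator: straight element→target
segments sampled at dx/4, bone path length from the in-bone sample
fraction, delay `2π f0 · l_bone (1/c_bone − 1/c_water)` (no Snell
refraction, no internal reflections), and an activation criterion that
switches an element off when its incidence angle at the bone entry
(normal from a smoothed mask gradient) exceeds 30° — near the
water→bone longitudinal critical angle asin(1482/2850) ≈ 31.3°,
configurable. Conditions: `NoCorr` (zero phases), `kPR` (full-wave
delays, all elements), `KE` (full-wave delays, ray activation), `KE+Ph`
(ray delays, ray activation), `Ray` (ray delays, all elements).

## Synthetic phantoms and cohorts

Each cohort member is a calvaria-like cap: a large-radius spherical
shell whose near cap lies between the array and the target (full-scale
defaults: radius 70–90 mm, thickness 4–8 mm, axial crossing 18–26 mm,
tilt ±10° implemented as a lateral shell-centre offset), with an
ellipsoidal target ROI (9–14 mm axes, centred within 3 voxels of the
geometric focus). Mini-scale ranges shrink the geometry proportionally
(radius 28–40 mm, thickness 3–5 mm, ROI axes 4–7 mm) while keeping the
cap gently curved relative to the target depth — a tightly curved shell
close to the focus acts as a concave mirror and buries the focal
physics in cavity reverberation, which is not the regime of a skull cap
over a cortical target. Phantom parameters and ROI offsets are drawn
from a single seeded RNG stream, so a cohort is one integer seed.

What the phantoms emulate: a 3–8 mm curved bone layer with varying
thickness along each element's path, oblique incidence, and an
imperfectly centred target. What they do not emulate: trabecular/cortical
bone heterogeneity (the mask is binary by design), skull-base geometry,
soft tissue, shear conversion, and subject-to-subject anatomical
variability beyond these few parameters. Passing cohort tests therefore
demonstrates the correction mechanism under controlled aberration, not
clinical-scale effect sizes; cohort summaries assert directions
(medians, counts), never magnitudes from any full-scale study.

## Statistics

Cohort tables report mean ± sd per condition, paired two-tailed t-tests
between conditions (no multiple-testing correction, by design of the
comparison), percent change against the reference condition with
improvement-positive sign conventions (reduction for position/extent
metrics, increase for overlap/energy/pressure), and per-phantom
improved/worsened/unchanged counts with |Δ| < dx/2 treated as unchanged
for mm-scale metrics (the tie rule is configurable; volume and energy
metrics use exact comparison).

## Problem sizes used in the shipped checks

The test suite runs quasi-1D strips (≤ 200×4×4), small 3D grids
(≤ 88×90×90), the mini profile, and an 8-phantom mini cohort
(16 free-field + 128 transcranial single-element runs + 16 full-array
runs); the whole suite completes in roughly a quarter hour on one core.
The acceptance script's free-field run uses the desk profile
(128×125×125 expanded, 1120 steps, a few minutes on one core). The
paper-scale profile (3500 steps on 128×162×162, 100 steps/period) is
available but not exercised by default.

## Degenerate inputs and tie-breaks

Flat or all-negative records flag an element unreliable rather than
raising; an all-zero activation mask yields an identically zero field;
empty ROIs and empty evaluation regions raise; peak ties and plateau
peaks resolve deterministically (smallest axial index / last plateau
sample); boundary layers of zero voxels turn the solver periodic (used
as a negative control in tests). Array generation fails with a clear
message when the requested element count cannot be packed on the cap.
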