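# Methods

`spiralfoil` models the downstream separation region of a spiral
inertial-microfluidic chip for circulating-tumor-cell (CTC) enrichment: a
4-loop Archimedean spiral (300 µm wide, 100 µm deep, 150 µm loop spacing)
pre-focuses 17 µm CTC-like and 10 µm WBC-like particles onto two streaks,
and a cambered NACA9730 hydrofoil (300 µm chord, 30° attack angle) placed
ahead of a half-elliptic separation wall widens the gap between the streaks
so that the large particles can be collected from a narrow (75 µm) outlet
passage.  The package simulates that region in 2D, scores separations with
a chromatography-style resolution statistic, and computes the count-based
enrichment statistics of one- and two-cycle processing.

## Upstream focusing model

The spiral itself is not simulated; its effect enters through the measured
equilibrium positions of the two particle classes.  The force model that
rationalizes those positions is the standard pair

    F_L = 2 ρ U_avg² a⁴ c_L / D_H²      (net inertial lift)
    F_D = 3 π µ U_D a                   (Dean-vortex drag)

with F_L/F_D ∝ a³, so particle size selects the focusing streak.  The lift
coefficient c_L defaults to 0.5 (a mid-range literature value; nothing in
the pipeline is sensitive to it) and the mean Dean velocity uses the
power-law convention U_D = 1.8·10⁻⁴ De^1.63 m/s, both pluggable.  The
wall shear stress is reported with the wide-slot formula τ = 6µQ/(wh²),
which gives 40 Pa (400 dyn/cm²) at the 1.2 mL/min operating point.

## Canonical inlet streams

Cross-channel fluorescence profiles are modelled as two Gaussians over a
constant baseline.  The canonical configuration places the 17 µm peak at
100 µm and the 10 µm peak at 160 µm from the *reference wall* (the wall
nearest the large-particle streak), each with a full width at half maximum
(FWHM) of 15.8 µm.  The FWHM value is obtained by inverting the resolution
statistic

    R = 1.18 · s_p / (w_CTC + w_WBC)

at the upstream value R_u = 2.24 with s_p = 60 µm, assuming equal widths;
"width at half the height" is read as FWHM (= 2√(2 ln 2)·σ for a
Gaussian), the convention under which the 1.18 prefactor is standard.
Distributions are discretized into 50 seeding bins over ±3σ with
Gaussian-density weights.

## Flow solve

The downstream region is a 800 × 300 µm rectangle meshed at 3 µm
(configurable; keep ≤ 5 µm).  Steady incompressible Navier–Stokes is
solved by pseudo-transient fractional stepping on a staggered (MAC) grid:
MUSCL (van Leer-limited) conservative advection, explicit diffusion, and
an exact discrete pressure projection each step, with the hydrofoil and
separation wall entering as an immersed staircase mask.  Inertia is
essential, not optional: the channel Reynolds number is ≈100 on the
hydraulic diameter, and the routing of flow between the outlet passages
depends on the momentum of the jet leaving the hydrofoil.  Boundary
conditions are a prescribed parabolic inflow carrying Q/depth (the 100 µm
depth enters only through this normalization), no-slip walls, and a common
zero reference pressure over both outlet passages, so the CTC/waste flow
split is an emergent quantity, reported and logged for every run.  The
solve stops when the relative field change per 200-step window falls below
2·10⁻³ (hard failure above 5·10⁻²); the projection makes the flux through
every cross-section match the inlet flux to solver precision.

Geometric placements the device description leaves qualitative were fixed
by inspecting solved fields: the foil leading edge at (250, 62) µm puts
the under-foil flux share at ≈0.40, i.e. the dividing streamline between
the 17 µm band (top ≈0.35 of the flux) and the 10 µm band (bottom ≈0.45),
so the large-particle stream dives under the foil toward the reference
wall while the small-particle stream passes over; the wall nose at
x = 640 µm sits at the tail of the wake vortex, where the under-foil jet
is still compact.  These are package defaults, not tuned constants: all
specs are user-constructible.

## Particle transport

Particles are tracked as Stokes-drag spheres: ẋ = v, v̇ = (u(x) − v)/τ_p
with τ_p = ρ_p a²/18µ (ρ_p = 1050 kg/m³), integrated by classical RK4 at
a ≤1 µm spatial step.  Lift and Dean forces are *not* applied here — they
act upstream, in the spiral — but translational inertia matters at the
separation-wall nose, where the 17 µm Stokes number is ≈0.4: large
particles cannot follow the sharply curving streamlines around the blunt
tip.  Within one radius of the channel walls or the hydrofoil a particle
is pushed back onto the standoff surface and slides.  At the wall tip a
dissection rule applies: a particle whose approach position (at the
measurement station, one wall-minor-diameter upstream of the tip) falls
within one radius of the wall band is routed to the side of the wall
centerline its centre faces, with exactly centred hits going to waste —
the conservative choice for recovery claims.  This encodes the ballistic
character of the final tip-length of approach; resolving those impacts
directly would need a grid much finer than the staircase boundary layer.

In the no-hydrofoil *reference* configuration the wall is treated as a
downstream collector: it defines the outlet partition and the dissection
rule but is left out of the flow solve.  A 2D solve with truncated
equal-pressure outlets and the wall immersed drags the dividing streamline
about 10 µm toward the narrow passage over the whole domain — an artifact
of the missing outlet-channel network — whereas the physical reference
behaviour is an undisturbed stream arriving at the wall.  With the foil
present the wall stays in the solve, because the jet–wall interaction is
the separation mechanism itself.

Outcomes are weight sums over the discretized bins (fractions per class
sum to 1 exactly); downstream distributions are weighted histograms of
station crossings (2 µm bins, parabolic peak refinement, FWHM measured on
the histogram with a one-bin floor), and the downstream resolution R_d is
evaluated on them.

## Synthetic data

Generators reproduce the statistical structure the analysis assumes, with
binomial counting noise throughout (the simplest model consistent with
independent per-cell capture — real counts may be overdispersed):

- intensity profiles: two Gaussians (peaks 100/160 µm, FWHM 15.8 µm) plus
  baseline 0.05 and additive N(0, 0.02) noise on 256 samples;
- spiking series: 15 levels geometrically spaced over 50–3500 cells,
  recovered ~ Binomial(n, 0.771) in cycle 1, rethinned by 0.849 in cycle 2
  (so cumulative capture is 0.655);
- two-cycle WBC carryover 0.369 then 0.317 (cumulative depletion 0.883),
  with the second-cycle rates derived so both printed cycle values hold;
- Trypan-blue viability: inlet viability 0.816, losses as independent
  thinning of viable and dead pools.

Every generator is bit-reproducible per seed; fixtures serialize with a
manifest recording the seed and all parameters.  Passing the
parameter-recovery tests shows the estimators are consistent under this
noise model at these sample sizes; it does not validate the binomial
assumption against real counting noise, nor the 2D flow model against the
full 3D device.

## Enrichment statistics

Recovery, purity, per-cycle depletion and recovery (both cycles referenced
to the original inlet), viable/total cell loss, and the through-origin
linear-fit recovery estimator (zero spike recovers zero cells; R² on the
no-intercept model).  The enrichment factor is 100/(100 − depletion); at
88.3% depletion this gives 8.5×, reported as such (the order-of-magnitude
"~10×" phrasing is a rounding).  Volume bookkeeping applies the exact 2:3
outlet split, conserving volume exactly.

## Numerical choices and degenerate inputs

- Two-Gaussian fits initialize from the two largest local maxima of a
  5-point-smoothed trace with the profile minimum as baseline; genuinely
  single-peaked profiles return a degenerate pair with a warning rather
  than failing.
- Discretization bins clipped by the fluid region are renormalized with a
  warning; an all-clipped distribution is an error.
- Seeding positions clamp to one radius off the walls; bins inside a solid
  are dropped and the class reweighted.
- A run with more than 5% stuck particle weight raises a quality error.
- The NACA thickness polynomial uses the closed-trailing-edge coefficient
  (−0.1036) so the surface polygon is simple.

## Known limitations

- The flow model is 2D and depth-averaged; Dean vortices in the spiral,
  the blunt depth-averaged velocity profile of the real 3:1 duct, and
  vertical focusing are outside its scope.  The simulated flow split into
  the outlet passages reflects the truncated domain, not the chip's outlet
  channel network (which the hardware tunes to a 2:3 volume ratio).
- First-order staircase walls limit boundary-layer fidelity near the foil
  and wall tip; the tip-shadow dissection rule compensates at the wall tip
  specifically.
- Wet-lab performance numbers (bead purities, measured depletion/recovery/
  viability) are not predictable from first principles here; they enter as
  worked examples of the formulas and as synthetic-generator defaults.
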