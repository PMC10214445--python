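# Methods

`vesiwrap` studies how a lipid vesicle wraps a dumbbell-shaped colloid —
the passive, adhesion-driven first stage of endocytosis for an
anisotropic particle. Four components cooperate: a coarse-grained
membrane + colloid simulator, a trajectory-observable and
state-classification layer, a flicker-spectroscopy tension estimator,
and an analytical engulfment theory. This note records the models, the
defaults and why they were chosen, and what the synthetic data do and do
not establish.

## Coarse-grained membrane simulation

The membrane is a one-particle-thick fluid surface: each bead carries an
orientation vector and pairs interact through

- a repulsive branch `u_R(r) = eps[(r_min/r)^4 - 2 (r_min/r)^2] +
  eps (1 - Phi)` for `r < r_min`, and
- an attractive branch `u_A(r) = -eps cos^{2 zeta}((pi/2)(r -
  r_min)/(r_cut - r_min)) Phi` for `r_min <= r < r_cut`, with the
  alignment weight `Phi = 1 + mu[(n_i x r̂)·(n_j x r̂) + sin(theta0)
  (n_j - n_i)·r̂ - sin^2(theta0) - 1]`.

Misaligned orientations are penalized through `Phi`, which gives the
self-assembled sheet its bending rigidity (set mainly by `mu`) while the
wide attractive well (`zeta`) keeps it fluid and self-healing. Defaults:
`eps = 1`, `mu = 3`, `zeta = 4`, `theta0 = 0`, `r_min = 2^{1/6}`,
`r_cut = 2.6` (bead diameters), `kBT = 0.23 eps` — a standard fluid-phase
working point for this model family. All are exposed in the config.

Unit system: bead diameter `sigma_b` (length), `eps` (energy),
`tau0 = sigma_b sqrt(m/eps)`, `m = 1` (time). Integration uses a
BAOAB-style Langevin scheme (`dt = 0.01 tau0`, unit frictions) for bead
translations, rotational Langevin about the two in-plane axes for bead
orientations, and a quaternion rigid-body Langevin integrator for the
dumbbell (two tangent spheres; exact prolate inertia tensor; Euler
gyroscopic term retained). With the thermostat off the scheme reduces to
velocity Verlet; measured energy drift is ~1e-5 eps per bead per 1e4
steps at `dt = 0.002`. Neighbourhoods come from a cell-list-built Verlet
pair list (skin 0.4) rebuilt on a displacement trigger. A single seeded
generator drives all noise, so identical configurations reproduce
trajectories bitwise on the same platform.

**Vesicle construction.** Beads are spiral-placed on a sphere and evened
out by a sphere-constrained inverse-square repulsion descent. The
default radius gives each bead the *calibrated* equilibrium area
0.88 sigma_b^2 — denser than hexagonal packing at `r_min` because the
long attractive tail compresses the sheet; the value is the thermal
plateau radius of free vesicles at the default working point. Building
at the naive hexagonal radius is supported and also valid (the vesicle
then relaxes by a few percent during equilibration).

**Tension control.** Interior (and optionally exterior) solute particles
interact with everything by volume exclusion only (WCA; solute diameter
0.5 sigma_b). A concentration imbalance exerts an ideal-gas pressure
difference `dP = kBT (c_in - c_out)` balanced by the Laplace tension
`sigma = dP R / 2`. Counts are chosen from the target tension with
volumes and areas measured at the effective wall (one solute-membrane
exclusion length inside the bead-centre sphere); the measured pressure
agrees with the ideal-gas value up to the expected positive second-virial
correction (~10% at the densities used). The high-tension condition used
in the wrapping ensembles is `sigma = 0.2 eps/sigma_b^2`, chosen as
comfortably above the arrest threshold for second-lobe wrapping at the
default adhesion; floppy vesicles carry no solutes.

**Adhesion.** The dumbbell attracts membrane beads through a well in the
distance to the *nearest* lobe surface (no double counting at the neck):
quartic repulsion below the contact distance `d0 = 0.5 sigma_b`
(linearized below `0.4 d0` so overlaps give a strong but finite force),
cosine-squared attraction of depth `eps_ad` vanishing smoothly at
`r_cut_ad = 1.5 sigma_b`. The default `eps_ad = 1.5 eps` is the strong
but non-tearing working point: the effective adhesion energy per area,
`W = eps_ad / (area per bead) ≈ 1.7 eps/sigma_b^2`, clearly exceeds the
bending threshold `2 kappa / a^2` for the default lobe radius `a = 3`,
while staying below the bead cohesion energy (~2.7 eps) above which the
adhesive load extracts beads from the sheet and the membrane tears — a
failure mode the model genuinely exhibits at strong binding.

**Rupture and evaporation.** The fluid sheet occasionally evaporates
single beads, especially when stretched; the self-healing membrane
tolerates this. A run is flagged ruptured only on evidence of a tear:
clustered under-coordinated beads (a hole rim) persisting for more than
100 steps, or evaporation exceeding 2% of the beads. Checks run at the
snapshot cadence.

**Scale.** Default wrapping experiments use 1500 beads (vesicle radius
~10.3 sigma_b) and lobe radius 3 sigma_b, i.e. a vesicle ~1.7 dumbbell
long-axes across — a deliberately compressed version of the experimental
size ratio (a ~1 um dumbbell in a 5–15 um vesicle) that keeps an
ensemble of runs at desk scale. Full engulfment completes in
400–1600 tau0. Consequences of the compressed ratio: wrapping consumes
~17% of the vesicle area (so tension feedback during wrapping is
stronger than in experiment) and insertion depths saturate nearer
~0.3 d_s than the experimental ~0.7 d_s. End-state identities,
their tension dependence, and the waist bottleneck are the quantities
this scale supports; absolute depths and times are not compared to
experiment.

## Wrapping observables and state taxonomy

Observables are measured against the *undistorted* vesicle sphere
(centre = bead centroid; radius = median bead distance, robust to the
wrapped pocket): the tilt `theta` of the long axis against the radial
direction, folded to [0, 90] degrees (fore–aft symmetry); the insertion
depth `d = R - |com - centre|`, positive inward; the height `z` used by
the tracking-band filter `-0.8 R < z < 0.8 R`. Per-lobe wrapped
fractions sample 500 quasi-uniform mesh points per lobe (excluding the
neck-occluded cap) and count points within the adhesion range of a
membrane bead; lobes are relabelled per frame so `f1 >= f2`.

Frames map to a nine-state taxonomy (A1/A2/A3 attachment, B single-lobe
wrapping, C shallow double contact, D half-wrapped terminal, E1/E2
asymmetric/symmetric double wrapping, F fully wrapped) through a total
decision table with thresholds 0.05 / 0.20 / 0.45 / 0.90 on the wrapped
fractions and 30 degrees for the perpendicular attachment band. The
taxonomy is pictorial in origin; the cut points are package choices,
configurable, and far coarser than the mesh resolution (~0.02). A lobe
counts as "in contact" only when at least three beads touch it, which
keeps stray evaporated beads from flipping contact flags. Transition
times are measured between debounced state runs (default window 5
frames) from entry to entry.

## Flicker spectroscopy

For a quasi-spherical vesicle the equatorial contour modes `c_n` of the
relative radial displacement obey, in the quasi-circular static
approximation,

    <|c_n|^2> = (kBT / 2 kappa) / ((n^2 - 1)(n^2 + sigma R^2 / kappa)).

Estimation is maximum likelihood with per-frame powers exponentially
distributed about the model mean; the per-mode time-averaged powers are
sufficient statistics. Default fit range n = 3..20 (low modes are
drift-prone, high modes noise-dominated); options: a white noise-floor
parameter, a multiplicative exposure-correction hook, and holding either
parameter fixed (used to calibrate `kappa` on a tensionless reference
and then fit `sigma` alone). Finite-exposure and projection corrections
of the full experimental method are out of scope.

On *simulated* vesicles the contour is extracted by least-squares
projection of the beads in an equatorial band (half-width 1.5 sigma_b)
onto harmonics; bead granularity acts as a noise floor. The
quasi-circular formula applied to a sliced 3D vesicle is known to bias
the absolute parameter values, and desk-scale runs yield few independent
samples of the slow low-n modes, so the simulation-side check is
directional: solute-imposed tension must suppress the low modes and
raise the fitted `sigma` at fixed calibrated `kappa` — which it does.
Absolute agreement between flicker tension and the Laplace estimate is
not asserted at this scale.

## Analytical engulfment theory

The dumbbell is two tangent spheres of radius `a` with the neck smoothed
by a meridional circular fillet of radius `rho_n`; the contact line
advances axisymmetrically along the meridian arc `s`. The landscape is

    E(s) = -W A_w(s) + sigma A_w(s) (1 - cos psi(s))/2 + ∫ 2 kappa H^2 dA,

with `A_w` the wrapped area (piecewise analytic), `psi` the normal tilt
angle at the front, and the bending integral analytic on the spherical
caps and quadrature-evaluated on the fillet. Kinetics are overdamped:
`v(s) = max(0, -dE/ds) / (alpha eta_eff L(s))` with contact-line
circumference `L = 2 pi r(s)` floored at `2 pi (0.05 a)`; wrap time
`T = ∫ ds / v` by adaptive quadrature over the resolved arc (polar caps
below the drag floor excluded — without the exclusion the floored-drag
integral diverges logarithmically at the poles). A non-positive drive
anywhere reports a stall with its location instead of a time.

Two neck conventions serve two questions:

- `rho_n = 2a/3` (*catenoid neck*) makes the waist mean curvature
  exactly zero — the membrane bridges the junction as a near-minimal
  surface. This is the kinetic default: wrapping completes below a stall
  tension, `T(sigma)` rises nonlinearly toward it, and lab-scale
  parameters (`d_s = 0.98 um`, `kappa = 20 kBT`, `W ~ 0.76 uJ/m^2`,
  `eta_eff ~ 0.8 Pa s`, `alpha = 1`) give wrap times of tens of seconds
  over the nN/m tension range — the experimentally observed scale.
- `rho_n = 0.15 a` (*conformal neck*) represents a membrane forced to
  follow the junction tightly, as a perfectly symmetric crossing would
  require. Its fillet bending cost creates the waist barrier: the
  steepest energy cost per wrapped area and all stall locations sit in
  the neck region, which is why half-wrapped dumbbells are long-lived.

The barrier converts to a fluctuation amplitude by equating it to the
energy of one effective membrane mode of wavevector `q = pi/a` over the
waist annulus: `DeltaE = (sigma q^2 + kappa q^4) A h*^2 / 2`. This
deliberately order-of-magnitude estimator gives `h* ~ 100–185 nm` across
the lab-scale parameter ranges — far beyond thermal membrane roughness,
so symmetric waist crossing is effectively forbidden.

Fitting `(W, eta_eff)` to wrap-time data is least squares on `log T`
(times span decades near stall); stalled data points are excluded and
counted, stalled model evaluations are softened through a tiny floored
drive so the optimizer is steered back to completing parameter sets;
confidence intervals come from the Jacobian. Self-consistency recovery
is exact to <1e-4; with 5% multiplicative noise, 8 tensions, the median
recovery error is ~0.2% for `W` and ~4% for `eta_eff`.

## Synthetic data

- Contour series: per-frame complex-Gaussian mode amplitudes drawn from
  the model spectrum, inverse-transformed, plus optional white tracking
  noise. They test the estimator against its own model; they do not
  contain drift, projection, or exposure artefacts of real microscopy.
- Pathway templates: monotone-cubic interpolants through the narrated
  milestones of the four observed pathway classes (parallel or
  perpendicular start, full or half final state), with tracking-scale
  noise (3 deg rms on theta, 0.03 um rms on d). They exercise the
  observable and classifier layer; they are not mechanistic simulations.
- Wrap-time datasets: theory times with multiplicative lognormal noise
  (default cv = 0.05) on a tension grid below the stall threshold.

All generators are deterministic given (parameters, seed).

## Numerical and design notes

- Problem sizes: acceptance-grade runs use 2000-frame contour series,
  20-seed fit ensembles, and wrapping ensembles of two to three runs per
  tension arm at 1500 beads; these sizes keep the whole pipeline at desk
  scale while leaving the assertions' margins wide.
- The WCA interactions floor their force evaluation at 0.65 sigma of
  separation (placement prevents real overlaps; the floor only guards
  pathological starts).
- Classifier totality: fraction combinations the pictorial taxonomy does
  not name (e.g. deep single-lobe wrapping with second contact) are
  assigned to the nearest named state (E1 in that example); an
  independent re-implementation of the table is used as a test oracle.
- Known limitations: no hydrodynamics (Langevin friction only), no
  explicit ligand/receptor discreteness, compressed vesicle-to-colloid
  size ratio, quasi-circular (not full spherical-harmonic) flicker
  reduction, and an engulfment theory whose neck treatment is a declared
  geometric convention rather than a derived membrane shape.
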