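# Methods

`actophase` studies how directed motility changes the phase behaviour of
associating polymers, and provides the measurement pipeline used on tracked
fluorescent condensates.  This note records the models, the parameter
choices and their rationale, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Active-polymer model

Polymers are flexible bead-spring chains in reduced units: bead diameter
σ = 1, bead mass m = 1, thermal energy k_BT = 1, time τ = σ√(m/k_BT).

* **Nonbonded pairs** (within and between chains, excluding bonded
  neighbours) interact through a 12-6 Lennard-Jones potential
  U(r) = 4ε[(σ/r)¹² − (σ/r)⁶] with ε = 0.40 k_BT, truncated at 2.5 σ.  The
  truncation is plain by default; a cut-and-shifted variant
  (`lj_shift=True`) is available and is what the energy-conservation test
  uses, because the unshifted cutoff makes the total energy discontinuous
  when pairs cross it.
* **Bonds** are finitely extensible (FENE),
  U(r) = −½ K R₀² ln(1 − (r/R₀)²), with K = 100 ε/σ² and R₀ = 1.5 σ, plus
  the standard WCA repulsion (the purely repulsive LJ core, cutoff 2^{1/6} σ,
  same ε) carried by the bond itself.  The WCA term is part of the bond
  because the nonbonded LJ excludes bonded pairs and a bare FENE bond has
  its minimum at r = 0: without the core the bonds collapse to ≈ 0.5 σ and
  the dense phase compresses to an unphysical ≈ 1.6 beads/σ³.  With it the
  equilibrium bond length is ≈ 0.91 σ and the dense phase sits near
  0.55–0.65 beads/σ³.  The quoted spring constant "100ϵσ²" is read as
  100 ε/σ² (the printed unit is a typo; only this reading is dimensionally
  a spring constant).
* **Activity**: a constant force F_act (in k_BT/σ) along +z acts on the
  *head* bead — the first bead — of every active chain.  In mixtures, a
  fraction `f_passive` of chains receives no active force; the passive
  chains are the last ⌊f_passive·n⌋ chain ids, fixed for the whole run and
  independent of the seed so labels are reproducible across dialects.
* **R₀, cutoff, boundaries**: R₀ and the LJ cutoff are not part of the
  stated protocol; 1.5 σ and 2.5 σ are the standard Kremer–Grest choices.
  Boundaries are periodic in all three dimensions with the minimum-image
  convention (box spans x, y ∈ [−L/2, L/2)).

## Integrator and thermostat

The Langevin equation is integrated with the BAOAB splitting of
velocity-Verlet at dt = 0.01 τ: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update (v ← c₁v + c₂ξ with c₁ = e^{−γdt},
c₂ = √(k_BT(1−c₁²)), ξ ~ N(0,1) per component), half-drift, half-kick.
Friction is γ = m/damping with damping = 0.50 τ, i.e. underdamped dynamics.
One force evaluation per step.  With γ = 0 the O-step is the identity and
the scheme reduces to plain velocity-Verlet, which is how the
energy-conservation check isolates the integrator error.  The BAOAB form
was chosen over the impulse-style Langevin kick because its free-particle
velocity distribution is exact at any dt; the free-bead kinetic temperature
test (1.00 ± 0.02 k_BT) passes with no dt correction.

Nonbonded forces run off a Verlet pair list built by cell binning with a
0.45 σ skin, rebuilt whenever any bead has moved more than half the skin
since the last build; the cell path requires at least three cells per axis
and falls back to an O(N²) build in smaller boxes.  The pair-list forces
are asserted identical (1e-10) to an all-pairs reference on small systems.

## Protocol

The headline protocol is 650 chains × 25 beads in a 64 × 64 × 100 σ box:
random-walk placement, a soft force-capped push (staged LJ force caps with
a per-bead speed clamp) to remove overlaps, then a weak harmonic bias
(0.05 ε/σ² per bead toward the box centre) for 2×10⁵ steps to collect a
single droplet, then 5×10⁷ production steps with the active force on,
snapshots every 2×10⁴ steps (= 200 τ = τ′, the snapshot time unit) and the
last half used for analysis.  Initialization fails loudly if the largest
cluster holds ≤ 90% of chains when the bias comes off.

Desk-scale work uses `SimulationParameters.scaled()`: 100 chains × 25 beads
in 32 × 32 × 50 σ (same density), bias 2×10⁴ steps, production 4×10⁵ steps
(snapshots every 2×10³).  The production length was chosen from
equilibration diagnostics: the dilute-phase density of the passive system
stops drifting after roughly 10⁵ steps at this size, so the default
analyses the last 2×10⁵.

The acceptance analyses use a replica design chosen for desk-scale
throughput: one biased droplet initialization is shared by all runs (the
bias phase carries no active force, so the starting configuration is
force-independent), and three dynamical replicas per force value differ
only in their thermostat noise stream.  Because the same three noise
streams are reused across force values, comparisons in F are paired
(common random numbers), which removes the initialization component of the
replica variance.  Production is 3.4×10⁴ steps per run with the last half
analyzed (mixtures: 4.5×10⁴); medians over replicas are reported.  Single
runs of a 2 500-bead droplet have appreciable spread in ρ_sat — at these
sizes the dilute phase holds tens of beads.

## Coexistence analytics

Clustering links beads within 1.5 σ (first LJ coordination shell) using a
periodic k-d tree and connected components; a chain belongs to a cluster
when the majority of its beads do.  The cluster centre of mass uses the
circular mean per coordinate, which is exact on the torus up to a small
curvature bias (≪ bin width).

The isotropic profile bins beads in spherical shells (0.5 σ) around the
per-snapshot cluster COM and divides by shell volume; shells beyond the
inscribed sphere are clipped to the box by a fixed-seed Monte-Carlo volume
estimate, so profiles remain deterministic.  Directional profiles use one
pencil estimator for both directions so their widths are directly
comparable: *parallel* = beads in the pencil |x − x_c| ≤ 1 σ and
|y − y_c| ≤ 1 σ binned by |z − z_c|; *perpendicular* = the average of the
analogous pencils along x and along y.  A single-coordinate slab was
rejected because dilute-phase beads at every transverse position would
contaminate each bin, and an annulus-based perpendicular profile was
rejected after calibration on force-free droplets showed it reports
systematically wider interfaces than the pencil (the two estimators must
agree for a spherical droplet, and only the pencil/pencil pairing does).
The convention that in-plane distances are the *perpendicular* direction
follows the geometry of a z-directed force.

Two ρ_sat estimators are provided.  The profile estimator (the outer
plateau of the radial profile, above) is the classic method and works well
for large, near-spherical condensates.  At desk scale a driven condensate
elongates along the force, and its z-tail leaks into the outer shells of a
spherical profile, biasing the profile ρ_sat upward by up to an order of
magnitude; `dilute_gas_density` therefore measures ρ_sat directly as the
density of dilute-phase chains — chains in clusters of at most 2 (free
chains and dimers; larger satellite clusters are condensed material, not
gas) — over the box volume minus the condensate volume.  The scaled
acceptance analyses use this estimator; both are reported by
`analyze_coexistence`.

Coexistence densities: the profile is smoothed with a 3-bin moving
average; the interface is the contiguous band around the steepest descent
where |dρ/dr| exceeds 10% of its maximum.  ρ_den is the volume-weighted
mean over all bins inside the band, ρ_sat over all bins outside it
(volume weighting = Σcounts/Σvolume, the correct estimator for a plateau
with strongly unequal bin volumes).  A profile with no derivative signal,
or with plateau contrast below 2×, is flagged single-phase rather than
raising.  The interfacial width is the radial extent of the band, floored
by the bin resolution (a step sharper than a bin reports ≲ 2 bins with
3-bin smoothing).  Errors on widths come from the leave-one-out bootstrap:
10³ trials, each deleting one uniformly chosen profile point and
recomputing the width on the remaining uneven grid; trials that destroy
the two-phase structure are skipped and counted.

Per-phase velocities are chain-COM displacements between consecutive
snapshots (minimum-image per bead) divided by the elapsed time, grouped by
dense/dilute membership at the earlier snapshot, in σ/τ′ with τ′ = 200 τ.
Partition fractions of mixtures are reported under both normalizations
(per all chains and per label class) since both are in common use.

## Track motility

Local MSD exponents use sliding windows of 12 points; within a window the
MSD is averaged over all origin pairs for lags 1..⌊window/3⌋ (the
short-lag regime), and α is the least-squares slope of log MSD vs log τ.
Stationary windows (zero MSD) yield NaN, flagged not thrown.  A window is
*active* when α > 1; the window-level active fraction is the primary
statistic, and a per-track label (median defined α > 1) is provided as a
convenience.  Turning angles are the angles between consecutive
displacement vectors in [0°, 180°]; zero-length displacements give NaN.

KL divergence between area histograms adds a pseudocount (default 10⁻⁶)
to every bin of both histograms, renormalizes, and sums P ln(P/Q) in nats
(bits via flag); with pseudocount 0 an empty prior bin under support of P
returns +inf with no exception.  The divergence is direction-explicit:
callers choose prior and posterior, and the pipeline reports both
directions, since either convention appears in practice.

## Condensate sizing

For each spot: a ±5 px window about the centre pixel (spots whose window
would cross the frame edge are excluded, not padded); global threshold at
33% of the window maximum (≥ comparison); 8-connected component labeling
with the component nearest the centre pixel selected (minimum pixel
distance; ties to the lower label; centroid distance via flag); ellipse
axes from the normalized second central moments of the pixel set with the
+1/12 per-pixel variance correction (each pixel a unit square — the
MATLAB-regionprops convention, which makes an n-pixel row have exactly the
continuous uniform variance n²/12); area A = π(major/2)(minor/2), with
μm² = px² × pixel_size².  Rows whose timestamps are off the nominal frame
grid are excluded with reason "timestamp".  Exclusions plus measurements
always account for every input spot.

## Synthetic data

* **Track cohorts**: active tracks move at a constant speed along a fixed
  random heading (optional angular diffusion) plus 2D diffusion; passive
  tracks are pure Brownian motion; both get i.i.d. Gaussian localization
  noise.  Defaults: 0.15 s frame interval (the MSD analysis time step),
  100-point tracks, D = 0.05 μm²/s, v = 2 μm/s, localization noise
  0.075 μm.  The noise default is a typical centroid-localization error
  for dim, fast-moving spots and matters scientifically: it is what pushes
  the short-lag exponent of genuinely passive tracks clearly below 1
  (observed passive pools are dominated by α ≤ 1), so the α > 1 classifier
  separates the classes.  Noise-free cohorts (used by the exponent
  calibration tests) have Brownian mean α ≈ 1, and a threshold at exactly
  1 would split them 50/50 — a property of the statistic, not a bug.  The
  area model is constant or affine in instantaneous speed, clipped
  positive.
* **Images**: spots are anisotropic Gaussians on a constant background
  with optional Gaussian noise.  The rendered Gaussian widths are chosen
  so that the 33%-of-peak isophote has exactly the stated axes
  (axis = 2σ_g√(2 ln(1/0.33)) ≈ 2.98 σ_g); the ground-truth area is then
  directly comparable to what thresholding at 33% measures, since a
  thresholded Gaussian region is the filled ellipse of those axes and the
  moment ellipse of a filled ellipse equals its boundary ellipse.
  Overlapping spots are allowed but flagged.
* **Slab/cluster configurations**: beads placed uniformly at ρ_den inside
  a stated sphere or ellipsoid and at ρ_sat outside, chain ids in blocks
  of 25.  These are placement-only fixtures for the profile analytics;
  they carry no bonded structure.

What the generators do *not* emulate: photobleaching, motion blur, spot
detection/linking errors (tracks are given, as from TrackMate), drift,
3D motion projected to 2D, and actin-network geometry (active headings
are straight lines, not filament paths).  Passing tests therefore show
that the *measurement pipeline* is correct and calibrated on data with
the assumed statistical structure, not that the upstream tracking of real
microscopy data is error-free.

## Numerical choices and edge cases

* Determinism: every stochastic component takes a seed; simulations are
  bit-reproducible for a given seed and parameter set (chunk seeds derive
  from a SeedSequence).  The bootstrap, generators and pipeline report are
  likewise seeded.
* Initialization robustness: the overlap-removing push caps pair forces
  (staged caps 20 → 200 → 2000 k_BT/σ) under a per-bead speed clamp of
  2 σ/τ; FENE forces are never capped, so bonds cannot overstretch during
  the push.
* Degenerate inputs: empty slabs give all-zero profiles with a warning;
  single-phase profiles give flagged results from density extraction but
  raise for width requests; stationary tracks give NaN exponents; dark or
  edge spots give excluded AreaRecords with reasons.
* The tanh-profile recovery of ρ_sat is limited by tail contamination of
  the outer plateau; with volume weighting and a domain a few widths past
  the interface it is within a few percent.

## Known limitations

* Desk-scale runs (100 chains, 4×10⁵ steps) resolve the monotone ρ_sat(F)
  trend and interface anisotropy but carry seed-to-seed spread; the
  full-scale protocol (650 chains, 5×10⁷ steps) is available through the
  same API (`SimulationParameters()` defaults, `--scale full`) and takes
  hours per force value on one core.
* ρ_sat at strong forcing approaches the counting floor of the scaled box
  (a handful of beads in the dilute region); medians over seeds are
  reported for this reason.
* The windowed-MSD classifier's track-level labels depend on track length
  and localization noise as described above; the window-level fraction is
  the stable statistic.
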