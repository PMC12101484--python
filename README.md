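# actophase

Directed motility as a driver of biomolecular condensation: coarse-grained
simulations of active polymers, coexistence analytics, and the
track-motility / condensate-size statistics used on fluorescently tracked
condensates.

Many cytoplasmic condensates are not passive droplets — motor proteins drag
them along cytoskeletal filaments at micrometres per second.  `actophase`
asks what that directed driving does to the phase behaviour of the
condensate-forming polymers, and packages the measurements used to answer
the same question in cells:

* **`actophase.sim`** — Langevin dynamics of bead-spring polymers (FENE
  bonds with the standard WCA core, 12-6 Lennard-Jones cohesion with
  ε = 0.40 k\_BT) in which a constant force F\_act along +z acts on the
  *head* bead of every active chain.  Reduced units (σ = m = k\_BT = 1),
  BAOAB velocity-Verlet with damping 0.50 τ, dt = 0.01 τ, periodic box,
  numba inner loops with a skinned Verlet pair list.
* **`actophase.phase`** — largest-cluster identification, radial and
  force-resolved (parallel/perpendicular) density profiles, the coexisting
  densities ρ\_den and ρ\_sat from profile plateaus, interfacial widths with
  leave-one-out bootstrap errors, per-phase velocities in σ/τ′ (τ′ = 200 τ),
  and active/passive partitioning of mixtures.
* **`actophase.motility`** — windowed local-MSD exponents α (12-point
  windows; α > 1 = active transport, α ≤ 1 = passive), instantaneous
  speeds and turning angles, joint speed–angle densities, speed-conditioned
  condensate-area histograms and their Kullback–Leibler divergence.
* **`actophase.geometry`** — per-spot condensate areas from fluorescence
  frames: ±5 px window, 33 %-of-max threshold, nearest connected component,
  moment-ellipse fit, A = π(major/2)(minor/2).
* **`actophase.synth`** — generators for condensate-track cohorts
  (ballistic/Brownian mixtures with localization noise), frames of
  elliptical Gaussian spots with known ground truth, and two-phase bead
  configurations — every analysis is testable with no external data.
* **`actophase.io` / CLI** — TrackMate-style CSV tables, extended-XYZ and
  columnar trajectory dumps, flat key=value configs; `actophase simulate |
  phase-analyze | tracks-analyze | area | synth | pipeline`.

The physics the simulation component addresses: directed driving enhances
the driving force for condensation — at full scale the dilute-phase
(saturation) density ρ\_sat falls roughly log-linearly with F\_act while
the dense-phase density barely moves — and it breaks the condensate's
spherical symmetry, elongating it along the force.  Desk-scale runs
reproduce the coexistence, the drift, the elongation and the expulsion of
passive chains from a driven condensate; docs/methods.md discusses which
finite-size effects remain at 100 chains.

## Worked example

```python
from actophase import SimulationParameters, run_simulation
from actophase.phase import analyze_coexistence

params = SimulationParameters.scaled(f_act=2.0, total_steps=100_000, seed=1)
dump = run_simulation(params)              # 100 chains x 25 beads, ~4 min
res = analyze_coexistence(dump, n_bootstrap=200, rng=1)
print(res.rho_den, res.gas_density, res.two_phase)
```

This is `examples/01_active_polymer_simulation.py`, which prints (seed 1):

```
rho_den            : 0.569 beads/sigma^3
rho_sat (profile)  : 0.0038 beads/sigma^3
rho_sat (gas)      : 0.00146 beads/sigma^3
two-phase          : True
dense-phase speed  : 12.85 sigma/tau'
```

The driven system holds a condensate (ρ ≈ 0.57) in coexistence with a
sparse gas three hundred times more dilute, drifting along the force at
≈ 13 σ/τ′.  The same analysis over a sweep of F\_act
(see `examples/02_force_sweep_saturation.py`) probes how ρ\_sat responds to
the force.  On the measurement side:

```python
from actophase.motility import classify_active, local_msd_exponents
from actophase.synth import TrackCohortSpec, make_tracks

tracks, labels = make_tracks(TrackCohortSpec(n_tracks=200,
                                             active_fraction=0.30, seed=42))
cls = classify_active([local_msd_exponents(t) for t in tracks])
print(cls.track_active_fraction)   # ~0.30: recovers the generated fraction
```

The `examples/` directory holds one short narrative script per capability
(simulation, force sweep, track classification, KL pipeline, image sizing);
each prints the numbers it computes and a line on what they mean.

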