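"""Langevin dynamics of active bead-spring polymers.

Flexible chains of Lennard-Jones beads joined by FENE bonds (each bond
carrying the standard WCA short-range repulsion; the nonbonded LJ excludes
bonded pairs) evolve under an
underdamped Langevin thermostat (BAOAB splitting of velocity-Verlet).  A
constant force ``f_act`` along +z acts on the *head* bead (first bead) of
every active chain, modelling motor-driven transport of condensate-forming
polymers; passive chains receive no active force.  All quantities are in
reduced units: bead diameter sigma = 1, bead mass m = 1, thermal energy
kBT = 1, time tau = sigma * sqrt(m/kBT) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

from . import _kernels
from .errors import (
    BondOverstretchError,
    InitializationFailureError,
    IntegrationBlowUpError,
    SingularOverlapError,
)

__all__ = [
    "SimulationParameters",
    "SystemState",
    "TrajectoryDump",
    "fene_energy",
    "fene_force",
    "lj_energy",
    "total_forces",
    "langevin_step",
    "initialize_condensed",
    "run_simulation",
]


@dataclass(frozen=True)
class SimulationParameters:
    """Physical and protocol parameters of an active-polymer run.

    Defaults reproduce the headline protocol: 650 chains of 25 beads in a
    64 x 64 x 100 box at epsilon = 0.40 kBT, dt = 0.01 tau, damping 0.50 tau,
    2e5 biased-initialization steps, 5e7 production steps with snapshots every
    2e4 steps and the last half used for analysis.  ``scaled()`` gives a
    desk-scale twin (100 chains, 32 x 32 x 50 box) with the same physics.
    """

    n_chains: int = 650
    beads_per_chain: int = 25
    box: tuple[float, float, float] = (64.0, 64.0, 100.0)
    epsilon: float = 0.40          # LJ well depth, kBT
    sigma: float = 1.0
    fene_K: float = 100.0          # spring constant, epsilon/sigma^2
    fene_R0: float = 1.5           # maximum bond extension, sigma
    lj_cutoff: float = 2.5
    lj_shift: bool = False         # truncate-and-shift the LJ energy
    dt: float = 0.01               # tau
    damping: float = 0.50          # tau; friction gamma = m/damping
    f_act: float = 0.0             # active force on head beads, kBT/sigma
    f_passive: float = 0.0         # fraction of chains left passive
    bias_steps: int = 200_000
    total_steps: int = 50_000_000
    dump_every: int = 20_000
    analysis_start: int = -1       # -1 -> total_steps // 2
    bias_k: float = 0.05           # bias spring constant, epsilon/sigma^2
    seed: int = 0

    def __post_init__(self):
        if min(self.box) <= 0 or self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("lengths and energies must be positive")
        if not (0.0 <= self.f_passive <= 1.0):
            raise ValueError("f_passive must lie in [0, 1]")
        if self.f_act < 0:
            raise ValueError("f_act must be >= 0")
        if not (0 < self.dt < self.damping):
            raise ValueError("require 0 < dt < damping")
        if self.fene_R0 <= self.sigma:
            raise ValueError("fene_R0 must exceed sigma")
        if self.total_steps > 0 and not (0 <= self.analysis_start_resolved < max(self.total_steps, 1)):
            raise ValueError("analysis_start must lie in [0, total_steps)")

    @property
    def analysis_start_resolved(self) -> int:
        return self.total_steps // 2 if self.analysis_start < 0 else self.analysis_start

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.beads_per_chain

    @property
    def gamma(self) -> float:
        return 1.0 / self.damping

    @property
    def n_active(self) -> int:
        return self.n_chains - self.n_passive

    @property
    def n_passive(self) -> int:
        return int(round(self.f_passive * self.n_chains))

    @classmethod
    def scaled(cls, **overrides) -> "SimulationParameters":
        """Desk-scale twin: 100 chains x 25 beads in a 32 x 32 x 50 box."""
        base = dict(
            n_chains=100,
            box=(32.0, 32.0, 50.0),
            bias_steps=20_000,
            total_steps=400_000,
            dump_every=2_000,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        d = dict(d)
        if "box" in d:
            d["box"] = tuple(float(x) for x in d["box"])
        return cls(**d)

    def replace(self, **kw) -> "SimulationParameters":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Instantaneous configuration of the bead-spring system."""

    positions: np.ndarray        # (N, 3) in sigma, wrapped into the box
    velocities: np.ndarray       # (N, 3) in sigma/tau
    chain_id: np.ndarray         # (N,) int
    head: np.ndarray             # (N,) bool, first bead of each chain
    active_chain: np.ndarray     # (n_chains,) bool
    step: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return self.active_chain.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.chain_id.copy(),
            self.head.copy(), self.active_chain.copy(), self.step,
        )

    def active_bead_force(self, f_act: float) -> np.ndarray:
        """Per-bead z-force: f_act on head beads of active chains, else 0."""
        fz = np.zeros(self.n_beads)
        fz[self.head & self.active_chain[self.chain_id]] = f_act
        return fz


@dataclass
class TrajectoryDump:
    """Ordered snapshots of a run plus the parameters that produced them."""

    params: SimulationParameters
    steps: list[int] = field(default_factory=list)
    snapshots: list[SystemState] = field(default_factory=list)

    def append(self, state: SystemState) -> None:
        if self.steps and state.step <= self.steps[-1]:
            raise ValueError("snapshot steps must be strictly increasing")
        self.steps.append(state.step)
        self.snapshots.append(state.copy())

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[SystemState]:
        return iter(self.snapshots)

    def analysis_snapshots(self) -> list[SystemState]:
        """Snapshots at or after analysis_start (default: last half)."""
        start = self.params.analysis_start_resolved
        return [s for s in self.snapshots if s.step >= start]


# ---------------------------------------------------------------------------
# potentials


def fene_energy(r: float, params: SimulationParameters) -> float:
    """FENE bond energy U(r) = -1/2 K R0^2 ln(1 - (r/R0)^2) in kBT.

    K is quoted in epsilon/sigma^2, so the kBT-unit spring constant is
    fene_K * epsilon.  Diverges as r -> R0; r >= R0 is an overstretch error.
    """
    r = float(r)
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= params.fene_R0:
        raise BondOverstretchError(f"bond length {r} >= R0 = {params.fene_R0}")
    keff = params.fene_K * params.epsilon
    return -0.5 * keff * params.fene_R0 ** 2 * math.log(1.0 - (r / params.fene_R0) ** 2)


def fene_force(r: float, params: SimulationParameters) -> float:
    """Magnitude of the restoring FENE force at extension r (kBT/sigma)."""
    if r >= params.fene_R0:
        raise BondOverstretchError(f"bond length {r} >= R0 = {params.fene_R0}")
    keff = params.fene_K * params.epsilon
    return keff * r / (1.0 - (r / params.fene_R0) ** 2)


def lj_energy(r: float, params: SimulationParameters) -> float:
    """Truncated 12-6 Lennard-Jones energy 4 eps [(s/r)^12 - (s/r)^6] in kBT."""
    r = float(r)
    if r <= 0:
        raise SingularOverlapError("LJ energy undefined at r = 0")
    if r >= params.lj_cutoff:
        return 0.0
    sr6 = (params.sigma / r) ** 6
    e = 4.0 * params.epsilon * (sr6 * sr6 - sr6)
    if params.lj_shift:
        src6 = (params.sigma / params.lj_cutoff) ** 6
        e -= 4.0 * params.epsilon * (src6 * src6 - src6)
    return e


# ---------------------------------------------------------------------------
# engine plumbing


class _Engine:
    """Preallocated buffers + kernel dispatch for one parameter set."""

    def __init__(self, params: SimulationParameters):
        self.params = params
        self.box = np.asarray(params.box, dtype=np.float64)
        rcell = params.lj_cutoff + _kernels.SKIN  # cells must hold the skinned list radius
        self.ncell = np.maximum((self.box // rcell).astype(np.int64), 1)
        ntot = int(np.prod(self.ncell))
        self.cell_head = np.empty(ntot, dtype=np.int64)

    def buffers(self, n: int):
        return self.cell_head, np.empty(n, dtype=np.int64), np.empty((n, 3))


def _check_finite(state: SystemState, step: int) -> None:
    if not (np.isfinite(state.positions).all() and np.isfinite(state.velocities).all()):
        raise IntegrationBlowUpError(f"non-finite coordinates at step {step}")


def _raise_status(status: int, step: int) -> None:
    if status == _kernels.STATUS_OVERSTRETCH:
        raise BondOverstretchError(f"FENE bond reached R0 near step {step}")
    if status == _kernels.STATUS_OVERLAP:
        raise SingularOverlapError(f"nonbonded overlap near step {step}")
    if status == _kernels.STATUS_LIST_OVERFLOW:
        raise RuntimeError(f"pair-list overflow near step {step}")


def total_forces(state: SystemState, params: SimulationParameters,
                 bias_k: float = 0.0, all_pairs: bool = False) -> np.ndarray:
    """Per-bead forces: FENE + truncated LJ (minimum image) + active z-force.

    ``bias_k`` > 0 adds the initialization spring toward the box center; the
    production default is 0.  ``all_pairs`` forces the O(N^2) reference path
    (the cell-list result must match it to 1e-10).
    """
    eng = _Engine(params)
    fz = state.active_bead_force(params.f_act)
    F = np.empty((state.n_beads, 3))
    keff = params.fene_K * params.epsilon
    args = (state.positions, state.chain_id.astype(np.int64), fz, eng.box,
            params.epsilon, params.lj_cutoff ** 2, keff, params.fene_R0 ** 2,
            bias_k * params.epsilon, 0.0, F)
    if all_pairs or np.any(eng.ncell < 3):
        status = _kernels._forces_allpairs(*args)
    else:
        head, nxt, _ = eng.buffers(state.n_beads)
        cap = max(state.n_beads * 120, 4096)
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        npairs = _kernels._build_pairs(
            state.positions, state.chain_id.astype(np.int64), eng.box,
            params.lj_cutoff ** 2, eng.ncell, head, nxt, pi, pj)
        if npairs < 0:
            raise RuntimeError("pair-list overflow in force evaluation")
        scratch = [np.empty(cap) for _ in range(4)]
        status = _kernels._forces_pairs(*args, pi, pj, npairs, *scratch)
    _raise_status(status, state.step)
    return F


def langevin_step(state: SystemState, params: SimulationParameters,
                  seed: int, n_steps: int = 1, bias_k: float = 0.0,
                  fcap: float = 0.0, vcap: float = 0.0,
                  gamma: float | None = None, kT: float = 1.0) -> float:
    """Advance the state in place by ``n_steps`` BAOAB Langevin steps.

    gamma defaults to m/damping; gamma = 0 with kT arbitrary gives plain
    velocity-Verlet (deterministic, energy conserving).  Returns the
    per-step mean of sum_i |v_i|^2, from which the kinetic temperature is
    v2_mean / (3 N).
    """
    eng = _Engine(params)
    fz = state.active_bead_force(params.f_act)
    head, nxt, F = eng.buffers(state.n_beads)
    keff = params.fene_K * params.epsilon
    g = params.gamma if gamma is None else gamma
    status, v2_mean = _kernels.run_chunk(
        state.positions, state.velocities, state.chain_id.astype(np.int64), fz,
        eng.box, n_steps, params.dt, g, kT, params.epsilon,
        params.lj_cutoff ** 2, keff, params.fene_R0 ** 2,
        bias_k * params.epsilon, fcap, vcap, seed % (2 ** 31),
        eng.ncell, head, nxt, F)
    state.step += n_steps
    _raise_status(status, state.step)
    _check_finite(state, state.step)
    return v2_mean


def total_energy(state: SystemState, params: SimulationParameters) -> float:
    """All-pairs KE + LJ + FENE energy (small systems; conservation checks)."""
    keff = params.fene_K * params.epsilon
    return float(_kernels.total_energy(
        state.positions, state.velocities, state.chain_id.astype(np.int64),
        np.asarray(params.box), params.epsilon, params.lj_cutoff ** 2,
        keff, params.fene_R0 ** 2, params.lj_shift))


# ---------------------------------------------------------------------------
# initialization and production runs


def _random_walk_chains(params: SimulationParameters, rng: np.random.Generator) -> SystemState:
    """Chains laid down as random walks with bond length ~ 0.97 sigma."""
    n, bpc = params.n_chains, params.beads_per_chain
    box = np.asarray(params.box)
    pos = np.empty((n * bpc, 3))
    bond = 0.97 * params.sigma
    for c in range(n):
        start = (rng.random(3) - 0.5) * box
        pos[c * bpc] = start
        for b in range(1, bpc):
            v = rng.normal(size=3)
            v *= bond / np.linalg.norm(v)
            pos[c * bpc + b] = pos[c * bpc + b - 1] + v
    pos -= box * np.round(pos / box)
    vel = rng.normal(scale=1.0, size=(n * bpc, 3))
    chain_id = np.repeat(np.arange(n), bpc)
    head = np.zeros(n * bpc, dtype=bool)
    head[::bpc] = True
    active = np.ones(n, dtype=bool)
    if params.n_passive:
        # last n_passive chain ids are passive -> first chains stay active,
        # labels fixed for the whole run and independent of the seed
        active[n - params.n_passive:] = False
    return SystemState(pos, vel, chain_id, head, active, step=0)


def initialize_condensed(params: SimulationParameters,
                         rng: np.random.Generator | None = None,
                         cluster_check: bool = True) -> SystemState:
    """Build a single dense cluster by biased relaxation.

    Chains start as random walks anywhere in the box; a short force-capped
    push removes overlaps, then a weak harmonic spring (bias_k, in
    epsilon/sigma^2) pulls every bead toward the box center for
    ``bias_steps``.  The bias is then removed.  Fails if the largest cluster
    afterwards holds <= 90% of the chains.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    state = _random_walk_chains(params, rng)
    seeds = np.random.SeedSequence(int(rng.integers(2 ** 31))).generate_state(8)
    # no active force until the bias comes off
    p0 = params.replace(f_act=0.0)
    # staged overlap-removing push: progressively relax the LJ force cap
    # under a displacement limit (vcap * dt per step), bias already on
    stage_len = max(1000, params.bias_steps // 20)
    used = 0
    for i, fcap in enumerate((20.0, 200.0, 2000.0)):
        langevin_step(state, p0, int(seeds[i]) % 2 ** 31, stage_len,
                      bias_k=params.bias_k, fcap=fcap, vcap=2.0)
        used += stage_len
    langevin_step(state, p0, int(seeds[3]) % 2 ** 31,
                  max(params.bias_steps - used, stage_len),
                  bias_k=params.bias_k)
    state.step = 0
    if cluster_check and params.n_chains > 1:
        from .phase import largest_cluster
        cluster = largest_cluster(state, box=params.box)
        frac = len(cluster.chain_ids) / params.n_chains
        if frac <= 0.9:
            raise InitializationFailureError(
                f"largest cluster holds {frac:.0%} of chains after bias")
    return state


def run_simulation(params: SimulationParameters,
                   initial_state: SystemState | None = None,
                   progress: bool = False,
                   cluster_check: bool = True) -> TrajectoryDump:
    """Biased initialization followed by ``total_steps`` of production.

    Snapshots (including the initial state at step 0) are recorded every
    ``dump_every`` steps.  Deterministic for a given seed.  On an integrator
    error the dump collected so far is attached to the raised exception as
    ``exc.partial_dump``.
    """
    ss = np.random.SeedSequence(params.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    state = initial_state.copy() if initial_state is not None \
        else initialize_condensed(params, init_rng, cluster_check=cluster_check)
    dump = TrajectoryDump(params=params)
    dump.append(state)
    n_chunks = params.total_steps // params.dump_every
    rem = params.total_steps % params.dump_every
    chunk_seeds = ss.generate_state(n_chunks + 2, dtype=np.uint32)
    try:
        for c in range(n_chunks):
            langevin_step(state, params, int(chunk_seeds[c]) % 2 ** 31,
                          params.dump_every)
            dump.append(state)
            if progress:
                print(f"  step {state.step}/{params.total_steps}", flush=True)
        if rem:
            langevin_step(state, params, int(chunk_seeds[-1]) % 2 ** 31, rem)
            dump.append(state)
    except (BondOverstretchError, SingularOverlapError, IntegrationBlowUpError) as exc:
        exc.partial_dump = dump
        raise
    return dump
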