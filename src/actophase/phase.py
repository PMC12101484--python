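"""Coexisting-phase analytics for active-polymer trajectories.

Identifies the largest condensed cluster, builds radial and directional
density profiles around its center of mass, and extracts the coexistence
densities (rho_den, rho_sat), interfacial widths parallel/perpendicular to
the applied force, per-phase velocities and active/passive partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import SinglePhaseError
from .sim import SystemState, TrajectoryDump

__all__ = [
    "ClusterResult",
    "DensityProfile",
    "CoexistenceDensities",
    "BootstrapWidth",
    "PhaseVelocities",
    "PartitionFractions",
    "CoexistenceResult",
    "chain_cluster_sizes",
    "largest_cluster",
    "radial_density_profile",
    "directional_profiles",
    "coexistence_densities",
    "interfacial_width",
    "bootstrap_width",
    "phase_velocities",
    "partition_fractions",
    "dilute_gas_density",
    "analyze_coexistence",
]

TAU_PRIME = 200.0  # snapshot time unit tau' = 200 tau


@dataclass
class ClusterResult:
    chain_ids: np.ndarray     # chains assigned to the largest cluster
    bead_indices: np.ndarray  # beads belonging to those chains
    com: np.ndarray           # (3,) center of mass, minimum-image unwrapped
    n_components: int


@dataclass
class DensityProfile:
    """Binned density versus distance from the cluster center.

    direction is "isotropic" (spherical shells), "perpendicular" (in-plane
    radius within the z = z_c slab) or "parallel" (|z - z_c| within the
    x/y pencil).  rho is in beads/sigma^3, averaged over n_snapshots.
    """

    direction: str
    r: np.ndarray
    rho: np.ndarray
    counts: np.ndarray
    bin_width: float
    n_snapshots: int = 1
    volumes: np.ndarray | None = None  # per-snapshot bin volumes, sigma^3

    def __post_init__(self):
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.rho < -1e-12):
            raise ValueError("densities must be non-negative")


@dataclass
class CoexistenceDensities:
    rho_den: float
    rho_sat: float
    two_phase: bool
    inner_bins: np.ndarray = field(default_factory=lambda: np.array([], int))
    outer_bins: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class BootstrapWidth:
    mean: float
    sd: float
    n_ok: int
    n_skipped: int


@dataclass
class PhaseVelocities:
    dense: float   # mean chain-COM speed, sigma/tau'
    dilute: float


@dataclass
class PartitionFractions:
    """Dense-phase occupancy under both normalizations.

    *_over_total divides by all chains in the system; *_over_class divides
    by the number of chains of that label.  Passive entries are NaN when the
    system has no passive chains.
    """

    active_over_total: float
    active_over_class: float
    passive_over_total: float
    passive_over_class: float


@dataclass
class CoexistenceResult:
    f_act: float
    rho_den: float
    rho_sat: float
    two_phase: bool
    width_parallel: float
    width_parallel_sd: float
    width_perpendicular: float
    width_perpendicular_sd: float
    velocity_dense: float
    velocity_dilute: float
    gas_density: float = float("nan")  # off-cluster bead density, beads/sigma^3
    partition: PartitionFractions | None = None


# ---------------------------------------------------------------------------
# clustering


def _periodic_pairs(pos: np.ndarray, box: np.ndarray, cutoff: float):
    shifted = np.mod(pos + box / 2.0, box)
    # guard against round-up to exactly L
    shifted[shifted >= box] -= 1e-12
    tree = cKDTree(shifted, boxsize=box)
    return tree.query_pairs(cutoff, output_type="ndarray")


def _circular_com(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Center of mass on the torus via the circular mean of each coordinate."""
    theta = 2.0 * np.pi * pos / box
    mean = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return mean / (2.0 * np.pi) * box


def chain_cluster_sizes(state: SystemState, cutoff: float = 1.5,
                        box: tuple[float, float, float] | None = None
                        ) -> np.ndarray:
    """Size (in chains) of the cluster each chain belongs to.

    Chains are linked when any bead pair between them lies within cutoff.
    """
    b = np.asarray(box if box is not None else _guess_box(state), dtype=float)
    pairs = _periodic_pairs(state.positions, b, cutoff)
    n_chains = state.n_chains
    parent = np.arange(n_chains)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    cp = state.chain_id[pairs]
    cp = np.unique(np.sort(cp[cp[:, 0] != cp[:, 1]], axis=1), axis=0) \
        if len(cp) else cp
    for i, j in cp:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(c) for c in range(n_chains)])
    counts = np.bincount(roots, minlength=n_chains)
    return counts[roots]


def largest_cluster(state: SystemState, cutoff: float = 1.5,
                    box: tuple[float, float, float] | None = None) -> ClusterResult:
    """Largest connected cluster of beads under a distance-cutoff linkage.

    Beads are linked when their minimum-image distance is <= cutoff; chains
    are assigned to the component that holds the majority of their beads.
    The COM is computed with periodic (circular-mean) unwrapping.
    """
    if state.n_beads == 0:
        raise ValueError("empty state")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    b = np.asarray(box if box is not None else _guess_box(state), dtype=float)
    pairs = _periodic_pairs(state.positions, b, cutoff)
    n = state.n_beads
    if len(pairs):
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    # component with most beads
    sizes = np.bincount(labels)
    big = int(np.argmax(sizes))
    # chain majority vote
    chain_ids = np.unique(state.chain_id)
    in_cluster = []
    for c in chain_ids:
        lab = labels[state.chain_id == c]
        if np.count_nonzero(lab == big) * 2 > len(lab):
            in_cluster.append(c)
    if not in_cluster:
        # fall back to the chain owning the largest share of the big component
        share = [(np.count_nonzero(labels[state.chain_id == c] == big), c)
                 for c in chain_ids]
        in_cluster = [max(share)[1]]
    in_cluster = np.asarray(in_cluster)
    beads = np.flatnonzero(np.isin(state.chain_id, in_cluster))
    com = _circular_com(state.positions[beads], b)
    return ClusterResult(in_cluster, beads, com, n_comp)


def _guess_box(state: SystemState) -> np.ndarray:
    span = np.abs(state.positions).max(axis=0)
    return 2.0 * np.maximum(span * 1.001, 1.0)


# ---------------------------------------------------------------------------
# density profiles


def _minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _shell_volumes(edges: np.ndarray, box: np.ndarray,
                   mc_samples: int = 200_000) -> np.ndarray:
    """Volumes of spherical shells clipped to the periodic box.

    Shells inside the inscribed sphere are exact; beyond it the occupied
    fraction is estimated by a fixed-seed Monte-Carlo of the box volume,
    so profiles remain deterministic.
    """
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    r_ins = float(np.min(box)) / 2.0
    if edges[-1] <= r_ins + 1e-12:
        return vol
    rng = np.random.default_rng(123456789)
    pts = (rng.random((mc_samples, 3)) - 0.5) * box
    r = np.linalg.norm(pts, axis=1)
    counts, _ = np.histogram(r, bins=edges)
    frac_in_box = counts / mc_samples  # fraction of box volume in each shell
    box_vol = float(np.prod(box))
    clipped = np.where(edges[1:] <= r_ins, vol, frac_in_box * box_vol)
    return np.maximum(clipped, 1e-12)


def radial_density_profile(state: SystemState, center: np.ndarray,
                           bin_width: float = 0.5,
                           box: tuple[float, float, float] | None = None,
                           r_max: float | None = None) -> DensityProfile:
    """Isotropic density profile: bead counts in spherical shells / volume."""
    b = np.asarray(box if box is not None else _guess_box(state), dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width > np.min(b) / 2:
        raise ValueError("bin_width exceeds the smallest box half-length")
    rmax = float(np.min(b)) / 2.0 if r_max is None else float(r_max)
    d = _minimum_image(state.positions - np.asarray(center), b)
    r = np.linalg.norm(d, axis=1)
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    counts, _ = np.histogram(r, bins=edges)
    vols = _shell_volumes(edges, b)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile("isotropic", centers, counts / vols,
                          counts.astype(float), bin_width, volumes=vols)


def directional_profiles(state: SystemState, center: np.ndarray,
                         slab_half_thickness: float = 1.0,
                         bin_width: float = 0.5,
                         box: tuple[float, float, float] | None = None,
                         ) -> tuple[DensityProfile, DensityProfile]:
    """Profiles perpendicular and parallel to the +z active force.

    Both directions use the same pencil estimator so their widths are
    directly comparable: parallel = beads in the pencil |x - x_c| <= s and
    |y - y_c| <= s binned by |z - z_c|; perpendicular = the average of the
    analogous pencils along x and along y.  Each bin is normalized by the
    pencil cross-section (2s)^2 times the bin width, counting both signs.
    """
    if slab_half_thickness <= 0:
        raise ValueError("slab_half_thickness must be positive")
    b = np.asarray(box if box is not None else _guess_box(state), dtype=float)
    s = slab_half_thickness
    d = _minimum_image(state.positions - np.asarray(center), b)

    def _pencil_counts(axis, edges):
        others = [k for k in range(3) if k != axis]
        sel = (np.abs(d[:, others[0]]) <= s) & (np.abs(d[:, others[1]]) <= s)
        counts, _ = np.histogram(np.abs(d[sel, axis]), bins=edges)
        return counts

    # perpendicular: pencils along x and along y, averaged
    rmax_perp = min(b[0], b[1]) / 2.0
    edges = np.arange(0.0, rmax_perp + bin_width, bin_width)
    counts_p = _pencil_counts(0, edges) + _pencil_counts(1, edges)
    vols = 2.0 * (2.0 * s) ** 2 * np.diff(edges) * 2.0  # two pencils, +/- sides
    centers = 0.5 * (edges[:-1] + edges[1:])
    perp = DensityProfile("perpendicular", centers, counts_p / vols,
                          counts_p.astype(float), bin_width, volumes=vols)
    if counts_p.sum() == 0:
        warnings.warn("empty pencil selection for perpendicular profile")

    # parallel: pencil along z
    rmax_par = b[2] / 2.0
    edges_z = np.arange(0.0, rmax_par + bin_width, bin_width)
    counts_z = _pencil_counts(2, edges_z)
    vols_z = (2.0 * s) ** 2 * np.diff(edges_z) * 2.0
    centers_z = 0.5 * (edges_z[:-1] + edges_z[1:])
    par = DensityProfile("parallel", centers_z, counts_z / vols_z,
                         counts_z.astype(float), bin_width, volumes=vols_z)
    if counts_z.sum() == 0:
        warnings.warn("empty pencil selection for parallel profile")
    return perp, par


def average_profiles(profiles: list[DensityProfile]) -> DensityProfile:
    """Snapshot-average profiles sharing bin centers (rho averaged, counts summed)."""
    if not profiles:
        raise ValueError("no profiles to average")
    r = profiles[0].r
    for p in profiles[1:]:
        if len(p.r) != len(r) or not np.allclose(p.r, r):
            raise ValueError("profiles have mismatched bins")
    rho = np.mean([p.rho for p in profiles], axis=0)
    counts = np.sum([p.counts for p in profiles], axis=0)
    return DensityProfile(profiles[0].direction, r, rho, counts,
                          profiles[0].bin_width, n_snapshots=len(profiles),
                          volumes=profiles[0].volumes)


# ---------------------------------------------------------------------------
# coexistence densities and interfacial widths


def _smooth(y: np.ndarray, k: int = 3) -> np.ndarray:
    if k <= 1 or len(y) < k:
        return y.astype(float)
    pad = k // 2
    ypad = np.concatenate([y[pad:0:-1], y, y[-2:-2 - pad:-1]])
    kernel = np.ones(k) / k
    return np.convolve(ypad, kernel, mode="valid")


def _smooth_profile(profile: DensityProfile, k: int) -> np.ndarray:
    """Moving-average density; volume-weighted when bin volumes are known.

    Volume weighting (window counts / window volume) suppresses the large
    Poisson noise of the small inner shells, which would otherwise dominate
    the profile derivative.
    """
    if profile.volumes is None or k <= 1:
        return _smooth(profile.rho, k)
    c = _smooth(profile.counts, k)   # mean counts over the window
    v = _smooth(profile.volumes, k)
    return c / np.maximum(v * profile.n_snapshots, 1e-12)


def _interface_band(profile: DensityProfile, smooth_bins: int,
                    deriv_frac: float) -> tuple[int, int] | None:
    """Contiguous descending band around the interface, or None.

    The interface is located at the most *significantly* negative smoothed
    derivative (a t-statistic against the Poisson error of each window,
    when bin volumes are known) — plain steepest descent otherwise — and
    extended over the contiguous region where the density keeps falling
    faster than deriv_frac of the peak slope.  The significance weighting
    keeps the tiny, noisy innermost shells from masquerading as interfaces.
    """
    rho_s = _smooth_profile(profile, smooth_bins)
    d = np.gradient(rho_s, profile.r)
    if profile.volumes is not None:
        cw = _smooth(profile.counts, smooth_bins) * smooth_bins
        vw = _smooth(profile.volumes, smooth_bins) * smooth_bins
        sigma_rho = np.sqrt(np.maximum(cw, 1.0)) / np.maximum(
            vw * profile.n_snapshots, 1e-12)
        dr = np.gradient(profile.r)
        sigma_d = np.sqrt(2.0) * sigma_rho / (2.0 * dr)
        t = d / np.maximum(sigma_d, 1e-30)
        ipeak = int(np.argmin(t))
        if t[ipeak] >= -2.0:
            return None
    else:
        # exact (volume-less) profiles: any descent is significant
        ipeak = int(np.argmin(d))
        if d[ipeak] >= 0.0:
            return None
    thr = deriv_frac * abs(d[ipeak])
    if thr <= 0:
        return None
    lo = ipeak
    while lo > 0 and d[lo - 1] < -thr:
        lo -= 1
    hi = ipeak
    while hi < len(d) - 1 and d[hi + 1] < -thr:
        hi += 1
    return lo, hi


def _region_mean(profile: DensityProfile, idx: np.ndarray) -> float:
    """Mean density over a bin region, volume-weighted when volumes are known."""
    if len(idx) == 0:
        return float("nan")
    if profile.volumes is not None:
        vol = profile.volumes[idx].sum() * profile.n_snapshots
        return float(profile.counts[idx].sum() / vol)
    return float(profile.rho[idx].mean())


def coexistence_densities(profile: DensityProfile, smooth_bins: int = 3,
                          deriv_frac: float = 0.10,
                          min_ratio: float = 2.0) -> CoexistenceDensities:
    """Dense- and dilute-phase densities from the profile plateaus.

    The smoothed profile's derivative localizes the interface: the
    contiguous band around the steepest descent where |d rho/dr| exceeds
    deriv_frac of its maximum.  The dense plateau is everything inside the
    band, the dilute plateau everything outside; each density is the
    volume-weighted mean over its plateau.  A profile without contrast
    (flat, or plateau ratio below min_ratio) is flagged single-phase —
    never an exception.
    """
    if len(profile.r) < 10:
        raise ValueError("profile needs at least 10 bins")
    band = _interface_band(profile, smooth_bins, deriv_frac)
    n = len(profile.r)
    if band is None:
        idx = np.arange(n)
        m = _region_mean(profile, idx)
        return CoexistenceDensities(m, m, False, idx, idx)
    lo, hi = band
    inner = np.arange(0, lo)
    outer = np.arange(hi + 1, n)
    if len(inner) == 0 or len(outer) == 0:
        idx = np.arange(n)
        m = _region_mean(profile, idx)
        return CoexistenceDensities(m, m, False, inner, outer)
    rho_den = _region_mean(profile, inner)
    rho_sat = _region_mean(profile, outer)
    if not (rho_den > min_ratio * max(rho_sat, 0.0) and rho_den > rho_sat):
        idx = np.arange(n)
        m = _region_mean(profile, idx)
        return CoexistenceDensities(m, m, False, inner, outer)
    return CoexistenceDensities(rho_den, rho_sat, True, inner, outer)


def interfacial_width(profile: DensityProfile, smooth_bins: int = 3,
                      deriv_frac: float = 0.10) -> float:
    """Width of the interfacial region of a two-phase profile.

    The interface is the contiguous band of bins around the steepest point
    where |d rho/dr| (after smoothing) exceeds deriv_frac of its maximum;
    the width is the radial extent of that band.  Raises SinglePhaseError
    when no two-phase structure is present.
    """
    co = coexistence_densities(profile, smooth_bins, deriv_frac)
    if not co.two_phase:
        raise SinglePhaseError("interfacial width undefined for a single-phase profile")
    lo, hi = _interface_band(profile, smooth_bins, deriv_frac)
    return float(profile.r[hi] - profile.r[lo])


def bootstrap_width(profile: DensityProfile, n_trials: int = 1000,
                    rng: np.random.Generator | int | None = None,
                    smooth_bins: int = 3, deriv_frac: float = 0.10,
                    ) -> BootstrapWidth:
    """Leave-one-out bootstrap of the interfacial width.

    Each trial deletes one uniformly chosen profile point and recomputes the
    width on the remaining (unevenly spaced) bins; trials whose deletion
    destroys the two-phase structure are skipped but counted.
    """
    rng = np.random.default_rng(rng)
    widths = []
    n_skipped = 0
    n = len(profile.r)
    for _ in range(n_trials):
        k = int(rng.integers(n))
        keep = np.ones(n, dtype=bool)
        keep[k] = False
        sub = DensityProfile(profile.direction, profile.r[keep],
                             profile.rho[keep], profile.counts[keep],
                             profile.bin_width, profile.n_snapshots,
                             None if profile.volumes is None
                             else profile.volumes[keep])
        try:
            widths.append(interfacial_width(sub, smooth_bins, deriv_frac))
        except (SinglePhaseError, ValueError):
            n_skipped += 1
    if not widths:
        raise SinglePhaseError("all bootstrap trials failed to find an interface")
    w = np.asarray(widths)
    return BootstrapWidth(float(w.mean()), float(w.std(ddof=1)) if len(w) > 1 else 0.0,
                          len(w), n_skipped)


# ---------------------------------------------------------------------------
# per-phase velocities and partitioning


def _chain_coms_displacement(a: SystemState, b: SystemState, box: np.ndarray
                             ) -> np.ndarray:
    """Per-chain COM displacement b - a with minimum-image bead unwrapping."""
    d = _minimum_image(b.positions - a.positions, box)
    chains = np.unique(a.chain_id)
    out = np.empty((len(chains), 3))
    for i, c in enumerate(chains):
        out[i] = d[a.chain_id == c].mean(axis=0)
    return out


def phase_velocities(dump: TrajectoryDump, cluster_cutoff: float = 1.5,
                     analysis_only: bool = True) -> PhaseVelocities:
    """Mean chain-COM speed in the dense vs dilute phase, in sigma/tau'.

    Speeds are COM displacements between consecutive snapshots divided by
    the elapsed time; chains are labeled dense when they belong to the
    largest cluster at the earlier snapshot.  tau' = 200 tau.
    """
    snaps = dump.analysis_snapshots() if analysis_only else list(dump.snapshots)
    if len(snaps) < 2:
        raise ValueError("need at least two snapshots")
    box = np.asarray(dump.params.box, dtype=float)
    dt = dump.params.dt
    dense_speeds, dilute_speeds = [], []
    for a, b in zip(snaps[:-1], snaps[1:]):
        elapsed = (b.step - a.step) * dt
        disp = _chain_coms_displacement(a, b, box)
        speed = np.linalg.norm(disp, axis=1) / elapsed * TAU_PRIME
        cluster = largest_cluster(a, cluster_cutoff, tuple(box))
        chains = np.unique(a.chain_id)
        dense_mask = np.isin(chains, cluster.chain_ids)
        if dense_mask.any():
            dense_speeds.append(speed[dense_mask].mean())
        if (~dense_mask).any():
            dilute_speeds.append(speed[~dense_mask].mean())
    dense = float(np.mean(dense_speeds)) if dense_speeds else float("nan")
    dilute = float(np.mean(dilute_speeds)) if dilute_speeds else float("nan")
    return PhaseVelocities(dense, dilute)


def dilute_gas_density(state: SystemState, cluster: ClusterResult,
                       box: tuple[float, float, float],
                       cutoff: float = 1.5, max_oligomer: int = 2) -> float:
    """Bead density of the dilute phase outside the largest cluster.

    Dilute-phase material is defined as chains in clusters of at most
    ``max_oligomer`` chains (free chains and small oligomers); larger
    satellite clusters are condensed material, not gas.  The largest
    cluster's volume (from the 95th-percentile bead radius about its COM)
    is excluded from the gas volume.  A direct, profile-free estimator of
    rho_sat that stays unbiased when the condensate is aspherical.
    """
    b = np.asarray(box, dtype=float)
    sizes = chain_cluster_sizes(state, cutoff, box)
    dilute_chains = np.flatnonzero(sizes <= max_oligomer)
    n_gas = int(np.isin(state.chain_id, dilute_chains).sum())
    d = _minimum_image(state.positions[cluster.bead_indices] - cluster.com, b)
    r95 = float(np.quantile(np.linalg.norm(d, axis=1), 0.95))
    v_cluster = 4.0 / 3.0 * np.pi * r95 ** 3
    return n_gas / max(float(np.prod(b)) - v_cluster, 1.0)


def partition_fractions(state: SystemState, cluster: ClusterResult) -> PartitionFractions:
    """Dense-phase occupancy of active and passive chains, both normalizations."""
    active = state.active_chain
    n_total = len(active)
    n_active = int(active.sum())
    n_passive = n_total - n_active
    in_dense = np.zeros(n_total, dtype=bool)
    in_dense[cluster.chain_ids] = True
    a_dense = int((in_dense & active).sum())
    p_dense = int((in_dense & ~active).sum())
    return PartitionFractions(
        active_over_total=a_dense / n_total,
        active_over_class=a_dense / n_active if n_active else float("nan"),
        passive_over_total=p_dense / n_total,
        passive_over_class=p_dense / n_passive if n_passive else float("nan"),
    )


# ---------------------------------------------------------------------------
# end-to-end trajectory analysis


def analyze_coexistence(dump: TrajectoryDump, cluster_cutoff: float = 1.5,
                        bin_width: float = 0.5, slab_half_thickness: float = 1.0,
                        n_bootstrap: int = 1000,
                        rng: np.random.Generator | int | None = None,
                        r_max: float | None = None) -> CoexistenceResult:
    """Full coexistence analysis of a trajectory's analysis window.

    Snapshot-averaged isotropic and directional profiles are built around
    the per-snapshot largest-cluster COM; coexistence densities, widths
    (with leave-one-out bootstrap errors), per-phase velocities and — for
    mixtures — partition fractions are extracted.
    """
    rng = np.random.default_rng(rng)
    snaps = dump.analysis_snapshots()
    if not snaps:
        raise ValueError("no snapshots in the analysis window")
    box = tuple(dump.params.box)
    iso, perp, par = [], [], []
    partitions, gas = [], []
    has_passive = not dump.snapshots[0].active_chain.all()
    if r_max is None:
        # reach into the long axis (shells beyond the inscribed sphere are
        # clipped to the box) so the dilute plateau has room to show
        r_max = float(max(box)) / 2.0
    for s in snaps:
        cl = largest_cluster(s, cluster_cutoff, box)
        gas.append(dilute_gas_density(s, cl, box, cluster_cutoff))
        iso.append(radial_density_profile(s, cl.com, bin_width, box,
                                          r_max=r_max))
        pe, pa = directional_profiles(s, cl.com, slab_half_thickness, bin_width, box)
        perp.append(pe)
        par.append(pa)
        if has_passive:
            partitions.append(partition_fractions(s, cl))
    iso_avg = average_profiles(iso)
    perp_avg = average_profiles(perp)
    par_avg = average_profiles(par)
    co = coexistence_densities(iso_avg)

    def _boot(profile):
        try:
            return bootstrap_width(profile, n_bootstrap, rng)
        except SinglePhaseError:
            return BootstrapWidth(float("nan"), float("nan"), 0, n_bootstrap)

    bw_par = _boot(par_avg)
    bw_perp = _boot(perp_avg)
    vel = phase_velocities(dump, cluster_cutoff) if len(snaps) >= 2 \
        else PhaseVelocities(float("nan"), float("nan"))
    part = None
    if partitions:
        part = PartitionFractions(
            float(np.mean([p.active_over_total for p in partitions])),
            float(np.mean([p.active_over_class for p in partitions])),
            float(np.mean([p.passive_over_total for p in partitions])),
            float(np.mean([p.passive_over_class for p in partitions])),
        )
    return CoexistenceResult(
        f_act=dump.params.f_act,
        rho_den=co.rho_den, rho_sat=co.rho_sat, two_phase=co.two_phase,
        width_parallel=bw_par.mean, width_parallel_sd=bw_par.sd,
        width_perpendicular=bw_perp.mean, width_perpendicular_sd=bw_perp.sd,
        velocity_dense=vel.dense, velocity_dilute=vel.dilute,
        gas_density=float(np.mean(gas)),
        partition=part,
    )
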