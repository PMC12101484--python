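"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all pure functions of (spec, seed):

* condensate track cohorts — mixtures of ballistic (persistent-heading,
  superdiffusive) and Brownian 2D motion at a stated frame interval, with
  localization noise and an optional area-vs-speed model;
* fluorescence frames containing elliptical Gaussian spots of known axes on
  a noisy background;
* bead configurations with a dense spherical or ellipsoidal cluster
  coexisting with a dilute gas, for the phase analytics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .motility import MSD_FRAME_INTERVAL, Track
from .sim import SystemState

__all__ = [
    "TrackCohortSpec",
    "SpotSpec",
    "ImageSpec",
    "make_tracks",
    "make_images",
    "make_slab_configuration",
]


@dataclass(frozen=True)
class TrackCohortSpec:
    """Parameters of a synthetic condensate-track cohort.

    Active tracks move with a fixed random heading at ``ballistic_speed``
    plus diffusion; passive tracks are purely Brownian.  Localization noise
    is i.i.d. Gaussian per coordinate.  The area model is "constant"
    (areas ~ N(area_base, area_sd)) or "speed" (area_base +
    area_slope * instantaneous speed + noise), clipped positive.
    """

    n_tracks: int = 100
    track_length: int = 100
    frame_interval: float = MSD_FRAME_INTERVAL      # s
    active_fraction: float = 0.3
    ballistic_speed: float = 2.0                    # um/s
    diffusion: float = 0.05                         # um^2/s
    noise_sd: float = 0.075                         # um, localization error
    heading_diffusion: float = 0.0                  # rad^2/s, optional wobble
    area_model: str = "constant"
    area_base: float = 0.5                          # um^2
    area_slope: float = 0.0                         # um^2 per um/s
    area_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ValueError("active_fraction must lie in [0, 1]")
        if min(self.frame_interval, self.track_length) <= 0:
            raise ValueError("scales must be positive")
        if self.area_model not in ("constant", "speed"):
            raise ValueError("area_model must be 'constant' or 'speed'")


def make_tracks(spec: TrackCohortSpec,
                rng: np.random.Generator | int | None = None,
                ) -> tuple[list[Track], dict[int, bool]]:
    """Generate a track cohort and its ground-truth active labels."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n_active = int(round(spec.active_fraction * spec.n_tracks))
    dt = spec.frame_interval
    sig_diff = math.sqrt(2.0 * spec.diffusion * dt)
    tracks, labels = [], {}
    for tid in range(spec.n_tracks):
        active = tid < n_active
        labels[tid] = active
        steps = rng.normal(scale=sig_diff, size=(spec.track_length - 1, 2))
        if active:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            if spec.heading_diffusion > 0:
                dth = rng.normal(scale=math.sqrt(spec.heading_diffusion * dt),
                                 size=spec.track_length - 1)
                headings = theta + np.concatenate([[0.0], np.cumsum(dth[:-1])])
            else:
                headings = np.full(spec.track_length - 1, theta)
            steps += spec.ballistic_speed * dt * \
                np.column_stack([np.cos(headings), np.sin(headings)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(scale=spec.noise_sd, size=pos.shape) \
            if spec.noise_sd > 0 else pos
        frames = np.arange(spec.track_length)
        # per-frame areas; frame i carries the speed of the step leaving it
        speed = np.linalg.norm(steps, axis=1) / dt
        speed = np.append(speed, speed[-1])
        if spec.area_model == "speed":
            areas = spec.area_base + spec.area_slope * speed
        else:
            areas = np.full(spec.track_length, spec.area_base)
        areas = np.clip(areas + rng.normal(scale=spec.area_sd,
                                           size=spec.track_length), 1e-3, None)
        tracks.append(Track(tid, frames, pos[:, 0], pos[:, 1],
                            areas=areas, frame_interval=dt))
    return tracks, labels


# ---------------------------------------------------------------------------
# synthetic fluorescence frames


@dataclass(frozen=True)
class SpotSpec:
    """One elliptical Gaussian spot: axes are those of its 33% isophote."""

    frame: int
    row: float
    col: float
    major_px: float
    minor_px: float
    orientation_deg: float = 0.0
    peak: float = 1000.0


@dataclass(frozen=True)
class ImageSpec:
    frame_shape: tuple[int, int] = (64, 64)
    n_frames: int = 1
    spots: tuple[SpotSpec, ...] = ()
    background: float = 0.0
    noise_sd: float = 0.0
    threshold_frac: float = 0.33     # isophote defining the spot axes
    pixel_size: float = 0.1          # um/px
    seed: int = 0

    def __post_init__(self):
        for s in self.spots:
            if not (0 <= s.row < self.frame_shape[0]
                    and 0 <= s.col < self.frame_shape[1]):
                raise ValueError(f"spot at ({s.row}, {s.col}) outside frame")
            if s.peak <= self.background:
                raise ValueError("spot peak must exceed the background")


def _gaussian_sigmas(spot: SpotSpec, frac: float) -> tuple[float, float]:
    # axis = full width of the frac-of-max isophote = 2 sigma sqrt(2 ln(1/frac))
    scale = 2.0 * math.sqrt(2.0 * math.log(1.0 / frac))
    return spot.major_px / scale, spot.minor_px / scale


def make_images(spec: ImageSpec,
                rng: np.random.Generator | int | None = None,
                ) -> tuple[np.ndarray, list[dict]]:
    """Render frames of Gaussian spots; return (stack, ground-truth records).

    The rendered Gaussian widths are chosen so that the threshold_frac
    isophote of each spot has exactly the stated axes, making the ground
    truth directly comparable to the thresholding measurement.  Each record
    carries the spot geometry, its true area pi (major/2)(minor/2), and an
    ``overlaps`` flag when another spot in the same frame comes closer than
    the sum of the semi-major axes.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    stack = np.full((spec.n_frames, *spec.frame_shape), float(spec.background))
    rr, cc = np.mgrid[0:spec.frame_shape[0], 0:spec.frame_shape[1]]
    truth = []
    for i, s in enumerate(spec.spots):
        sa, sb = _gaussian_sigmas(s, spec.threshold_frac)
        th = math.radians(s.orientation_deg)
        u = (rr - s.row) * math.cos(th) + (cc - s.col) * math.sin(th)
        w = -(rr - s.row) * math.sin(th) + (cc - s.col) * math.cos(th)
        stack[s.frame] += (s.peak - spec.background) * \
            np.exp(-0.5 * (u / sa) ** 2 - 0.5 * (w / sb) ** 2)
        overlaps = any(
            j != i and o.frame == s.frame
            and math.hypot(o.row - s.row, o.col - s.col)
            < (o.major_px + s.major_px) / 2.0
            for j, o in enumerate(spec.spots))
        truth.append({
            "frame": s.frame, "row": s.row, "col": s.col,
            "major_px": s.major_px, "minor_px": s.minor_px,
            "orientation_deg": s.orientation_deg,
            "area_px2": math.pi * (s.major_px / 2.0) * (s.minor_px / 2.0),
            "area_um2": math.pi * (s.major_px / 2.0) * (s.minor_px / 2.0)
            * spec.pixel_size ** 2,
            "overlaps": overlaps,
        })
    if spec.noise_sd > 0:
        stack += rng.normal(scale=spec.noise_sd, size=stack.shape)
    return stack, truth


# ---------------------------------------------------------------------------
# slab/cluster bead configurations


def make_slab_configuration(rho_den: float, rho_sat: float,
                            radius: float | tuple[float, float, float],
                            box: tuple[float, float, float],
                            beads_per_chain: int = 25,
                            rng: np.random.Generator | int | None = None,
                            ) -> SystemState:
    """Bead gas at rho_sat coexisting with a dense ellipsoidal cluster.

    Beads are placed uniformly at rho_den inside the sphere/ellipsoid of the
    given radius (or semi-axes) centered in the box and at rho_sat outside.
    Chain ids are assigned in contiguous blocks of ``beads_per_chain``; the
    beads are placement-only fixtures for the phase analytics, not bonded
    chains.
    """
    if not (rho_den > rho_sat >= 0):
        raise ValueError("require rho_den > rho_sat >= 0")
    if rho_den > 1.2:
        raise ValueError("rho_den exceeds close packing for unit beads")
    rng = np.random.default_rng(rng)
    box_arr = np.asarray(box, dtype=float)
    axes = np.asarray(radius if np.ndim(radius) else [radius] * 3, dtype=float)
    if np.any(axes * 2 > box_arr):
        raise ValueError("cluster does not fit in the box")
    v_cluster = 4.0 / 3.0 * math.pi * float(np.prod(axes))
    v_box = float(np.prod(box_arr))
    n_dense = int(round(rho_den * v_cluster))
    n_dilute = int(round(rho_sat * (v_box - v_cluster)))

    dense = np.empty((n_dense, 3))
    k = 0
    while k < n_dense:
        cand = (rng.random((max(n_dense, 64), 3)) * 2.0 - 1.0)
        cand = cand[np.sum(cand ** 2, axis=1) <= 1.0] * axes
        take = min(len(cand), n_dense - k)
        dense[k:k + take] = cand[:take]
        k += take

    dilute = np.empty((n_dilute, 3))
    k = 0
    while k < n_dilute:
        cand = (rng.random((max(2 * n_dilute, 64), 3)) - 0.5) * box_arr
        cand = cand[np.sum((cand / axes) ** 2, axis=1) > 1.0]
        take = min(len(cand), n_dilute - k)
        dilute[k:k + take] = cand[:take]
        k += take

    pos = np.vstack([dense, dilute])
    n = len(pos)
    n_chains = max(1, math.ceil(n / beads_per_chain))
    chain_id = np.repeat(np.arange(n_chains), beads_per_chain)[:n]
    head = np.zeros(n, dtype=bool)
    head[np.searchsorted(chain_id, np.arange(n_chains))] = True
    return SystemState(pos, np.zeros_like(pos), chain_id, head,
                       np.ones(n_chains, dtype=bool), step=0)
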