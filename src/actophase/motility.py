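"""Condensate-track motility statistics.

Implements the windowed local-MSD analysis used to separate active
(superdiffusive, alpha > 1) from passive (diffusive, alpha <= 1) condensate
motion, instantaneous speed/turning-angle statistics, speed-conditioned
condensate-area distributions and the Kullback-Leibler divergence between
area histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Track",
    "LocalMotionProfile",
    "ActiveClassification",
    "local_msd_exponents",
    "classify_active",
    "speeds_and_angles",
    "joint_density",
    "area_distributions_by_speed",
    "kl_divergence",
]

DEFAULT_FRAME_INTERVAL = 1.0 / 2.3  # s, imaging at 2.3 frames/s
MSD_FRAME_INTERVAL = 0.15           # s, time-step size of the local-MSD analysis


@dataclass
class Track:
    """A 2D condensate trajectory (positions in micrometers, times in seconds)."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    times: np.ndarray | None = None
    areas: np.ndarray | None = None  # per-frame condensate area, um^2
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.times is None:
            self.times = self.frames * self.frame_interval
        else:
            self.times = np.asarray(self.times, dtype=float)
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class LocalMotionProfile:
    """Windowed MSD exponents and per-step kinematics of one track.

    alpha[i] is the log-log slope of the within-window MSD for the window
    starting at point i; NaN marks windows with zero MSD (stationary).
    """

    track_id: int
    window: int
    window_times: np.ndarray   # window-center times, s
    alpha: np.ndarray
    speeds: np.ndarray         # um/s, one per step
    angles: np.ndarray         # deg in [0, 180], one per interior point (NaN if undefined)
    lags: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def defined_alpha(self) -> np.ndarray:
        return self.alpha[np.isfinite(self.alpha)]


@dataclass
class ActiveClassification:
    window_active_fraction: float   # fraction of defined windows with alpha > threshold
    track_active_fraction: float    # fraction of tracks whose median alpha > threshold
    track_labels: dict[int, bool]
    n_windows: int
    n_tracks: int


def _window_msd(pos: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """MSD(lag) averaged over all origin pairs inside one window."""
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        out[k] = np.mean(np.sum(d * d, axis=1))
    return out


def local_msd_exponents(track: Track, window: int = 12,
                        max_lag: int | None = None) -> LocalMotionProfile:
    """Sliding-window MSD exponents (local alpha) along a track.

    For each window of ``window`` consecutive points the MSD is computed for
    lags 1..max_lag (default window // 3, short-lag regime) by averaging
    over all origins inside the window; alpha is the least-squares slope of
    log MSD versus log lag-time.  Windows with zero MSD yield NaN.
    """
    if len(track) < window:
        raise ValueError(
            f"track {track.track_id} has {len(track)} points; "
            f"local MSD needs at least window = {window}")
    if window < 4:
        raise ValueError("window must be at least 4 points")
    max_lag = max(window // 3, 2) if max_lag is None else int(max_lag)
    lags = np.arange(1, max_lag + 1)
    dt = float(np.median(np.diff(track.times)))
    pos = track.positions
    n_windows = len(track) - window + 1
    alpha = np.full(n_windows, np.nan)
    centers = np.empty(n_windows)
    log_tau = np.log(lags * dt)
    for i in range(n_windows):
        msd = _window_msd(pos[i:i + window], lags)
        centers[i] = 0.5 * (track.times[i] + track.times[i + window - 1])
        if np.any(msd <= 0):
            continue
        slope = np.polyfit(log_tau, np.log(msd), 1)[0]
        alpha[i] = slope
    speeds, angles = speeds_and_angles(track)
    return LocalMotionProfile(track.track_id, window, centers, alpha,
                              speeds, angles, lags)


def classify_active(profiles: list[LocalMotionProfile],
                    threshold: float = 1.0) -> ActiveClassification:
    """Active/passive classification from local MSD exponents.

    A window is active when its alpha exceeds the threshold (default 1, the
    diffusive exponent); the window-level active fraction over all defined
    windows is the primary statistic.  As a convenience, each track is also
    labeled active when the median of its defined alphas exceeds the
    threshold.
    """
    all_alpha = np.concatenate([p.alpha for p in profiles]) if profiles else np.array([])
    defined = all_alpha[np.isfinite(all_alpha)]
    if defined.size == 0:
        raise ValueError("no defined MSD exponents in any window")
    window_frac = float(np.mean(defined > threshold))
    labels: dict[int, bool] = {}
    for p in profiles:
        da = p.defined_alpha
        labels[p.track_id] = bool(np.median(da) > threshold) if da.size else False
    counted = [p for p in profiles if p.defined_alpha.size]
    track_frac = float(np.mean([labels[p.track_id] for p in counted])) if counted else 0.0
    return ActiveClassification(window_frac, track_frac, labels,
                                int(defined.size), len(profiles))


def speeds_and_angles(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous speeds (um/s) and turning angles (deg) of a track.

    speed_i = |r_{i+1} - r_i| / dt_i; angle_i is the angle between
    consecutive displacement vectors, in [0, 180] degrees, NaN where a
    displacement has zero length.
    """
    pos = track.positions
    disp = np.diff(pos, axis=0)
    dts = np.diff(track.times)
    norms = np.linalg.norm(disp, axis=1)
    speeds = norms / dts
    if len(disp) < 2:
        return speeds, np.array([])
    a, b = disp[:-1], disp[1:]
    na, nb = norms[:-1], norms[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(a * b, axis=1) / (na * nb)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[(na == 0) | (nb == 0)] = np.nan
    return speeds, angles


def joint_density(speeds: np.ndarray, angles: np.ndarray,
                  speed_bins: int | np.ndarray = 20,
                  angle_bins: int | np.ndarray = 18,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized joint histogram of (speed, angle) pairs; sums to 1."""
    speeds = np.asarray(speeds, dtype=float)
    angles = np.asarray(angles, dtype=float)
    ok = np.isfinite(speeds) & np.isfinite(angles)
    if not ok.any():
        raise ValueError("no defined (speed, angle) pairs")
    H, se, ae = np.histogram2d(speeds[ok], angles[ok],
                               bins=[speed_bins, angle_bins])
    return H / H.sum(), se, ae


def area_distributions_by_speed(tracks: list[Track],
                                speed_edges: np.ndarray | None = None,
                                n_area_bins: int = 30,
                                area_edges: np.ndarray | None = None,
                                ) -> dict:
    """Normalized condensate-area histograms conditioned on spot speed.

    Each spot (except the last of every track) is assigned to a speed
    interval by its instantaneous speed; all intervals share one set of
    area-bin edges.  By default the speed edges are the quartiles of the
    pooled speed distribution.  Empty intervals are flagged and carry no
    histogram.
    """
    pool_speed, pool_area = [], []
    for t in tracks:
        if t.areas is None:
            raise ValueError(f"track {t.track_id} carries no per-frame areas")
        s, _ = speeds_and_angles(t)
        pool_speed.append(s)
        pool_area.append(t.areas[:-1])
    speeds = np.concatenate(pool_speed)
    areas = np.concatenate(pool_area)
    ok = np.isfinite(speeds) & np.isfinite(areas)
    speeds, areas = speeds[ok], areas[ok]
    if speed_edges is None:
        speed_edges = np.quantile(speeds, [0.0, 0.25, 0.5, 0.75, 1.0])
    speed_edges = np.asarray(speed_edges, dtype=float)
    if area_edges is None:
        area_edges = np.linspace(areas.min(), areas.max(), n_area_bins + 1)
    out = {"speed_edges": speed_edges, "area_edges": np.asarray(area_edges),
           "histograms": [], "empty": [], "n_spots": []}
    for lo, hi in zip(speed_edges[:-1], speed_edges[1:]):
        sel = (speeds >= lo) & ((speeds < hi) | (hi == speed_edges[-1]) & (speeds <= hi))
        n = int(sel.sum())
        out["n_spots"].append(n)
        if n == 0:
            out["histograms"].append(None)
            out["empty"].append(True)
            continue
        h, _ = np.histogram(areas[sel], bins=area_edges)
        out["histograms"].append(h / h.sum())
        out["empty"].append(False)
    return out


def kl_divergence(p: np.ndarray, q: np.ndarray, pseudocount: float = 1e-6,
                  bits: bool = False) -> float:
    """Kullback-Leibler divergence D(P || Q) between two histograms.

    Both histograms (on identical bin edges) receive ``pseudocount`` in
    every bin and are renormalized before the sum P_i log(P_i / Q_i) is
    taken (natural log by default).  With pseudocount 0, bins where P > 0
    but Q = 0 make the divergence infinite; that value is returned rather
    than raised.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share bin edges (equal shapes)")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = p + pseudocount
    q = q + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(mask & (q == 0)):
        return float("inf")
    d = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    return d / np.log(2.0) if bits else d
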