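"""Synthetic fixtures with known ground truth for every pipeline.

Three generators emulate the raw material the analyses consume:

* :func:`gen_flared_end` — an MT end whose protofilaments run straight
  inside the lattice cylinder and then peel away as circular arcs of
  prescribed radius (per-joint curvature = step / radius), optionally with
  a linear curvature gradient toward the tip, out-of-plane pitch, and
  i.i.d. Gaussian point noise.  Points are placed every 2-4 nm along the
  bending part, matching the manual tracing convention.
* :func:`gen_spot_field` — an image of diffraction-limited spots whose
  peak amplitude is the sum of N i.i.d. lognormal single-fluorophore
  intensities, rendered with a Gaussian PSF over a constant background,
  with Poisson shot noise and Gaussian read noise.
* :func:`gen_event_series` — per-MT event histories with alternating
  growth/pause sojourns and catastrophes drawn as a Poisson process over
  the growth+pause clock, followed by brief shrinkage.

All generators are deterministic given a seed and echo their ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kymo_dynamics import Calibration, DynamicEvent, EndHistory, KymoSegment
from .pf_geometry import MT_RADIUS_14PF_NM, MTEndRecord, PFTrace
from .spot_photometry import ImageFrame

__all__ = [
    "FlareGroundTruth",
    "SpotFieldGroundTruth",
    "EventGroundTruth",
    "gen_flared_end",
    "gen_flared_ends",
    "gen_spot_field",
    "gen_event_series",
    "gen_frap_series",
]


@dataclass
class FlareGroundTruth:
    """Hidden parameters of a generated flared MT end.

    curvature (deg/nm) implied by *radius* is (1/radius)*(180/pi); a
    radius of 25 nm gives 2.292 deg/nm.  *curvature_gradient* (deg/nm per
    nm, applied along the arc so curvature rises toward the tip) is zero
    for constant-curvature arcs.
    """

    radius: float = 25.0              # nm, arc radius of the flare
    flare_arc_length: float = 40.0    # nm
    out_of_plane_pitch: float = 0.0   # nm of axial deviation per full turn
    noise_sigma: float = 1.0          # nm, i.i.d. per coordinate
    n_pf: int = 14
    mt_radius: float = MT_RADIUS_14PF_NM
    curvature_gradient: float = 0.0   # deg/nm per nm toward the tip
    point_spacing: tuple[float, float] = (2.0, 4.0)  # nm, manual-style
    seed: int = 0
    origin_index: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SpotFieldGroundTruth:
    """Hidden parameters of a generated single-molecule spot field."""

    molecules_per_spot: np.ndarray    # int, >= 1, one per spot
    mu: float = 5.0                   # lognormal log-mean of 1-fluorophore peak
    sigma_log: float = 0.3
    psf_sigma: float = 1.5            # px
    background: float = 100.0         # counts
    read_noise: float = 2.0           # counts, Gaussian sigma (0 = off)
    poisson: bool = True
    seed: int = 0
    centers: np.ndarray | None = None  # (n, 2) row/col; random if None
    crowded: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.molecules_per_spot = np.asarray(self.molecules_per_spot, dtype=int)
        if np.any(self.molecules_per_spot < 1):
            raise ValueError("molecules_per_spot must be >= 1")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


@dataclass
class EventGroundTruth:
    """Hidden parameters of generated dynamic-instability histories."""

    growth_rate_mean: float = 1.0     # um/min
    growth_rate_sd: float = 0.2
    catastrophe_rate: float = 0.2     # per min of growth+pause time
    pause_entry_rate: float = 0.0     # pauses per min of growth
    pause_duration_mean: float = 0.5  # min (paper regime: 0.28-0.72 min)
    shrink_rate: float = -12.0        # um/min
    shrink_duration_mean: float = 0.1  # min
    observation_span: float = 10.0    # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observation_span <= 0 or self.pause_duration_mean <= 0:
            raise ValueError("durations and span must be positive")


# ---------------------------------------------------------------------------
# flared PF ends


def _rotation_from_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to *direction* (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _flare_arc(truth: FlareGroundTruth, arc_positions: np.ndarray) -> np.ndarray:
    """Points of the flare arc in a local frame.

    Local frame: the PF leaves the cylinder along +z from the origin; it
    bends outward in the +x direction with per-arc-length curvature
    1/radius (plus an optional linear gradient toward the tip); the
    out-of-plane pitch tilts the bending plane helically in y.
    """
    L = truth.flare_arc_length
    kappa0 = 1.0 / truth.radius  # rad / nm
    grad = np.radians(truth.curvature_gradient)  # rad/nm per nm
    # heading angle theta(l) = integral of curvature; curvature rises
    # linearly toward the tip when grad > 0
    kappa = kappa0 + grad * (arc_positions - L)
    kappa = np.clip(kappa, 0.0, None)
    theta = np.concatenate([[0.0], np.cumsum(
        0.5 * (kappa[1:] + kappa[:-1]) * np.diff(arc_positions))])
    # integrate the planar curve (z along the MT axis, x radially outward)
    dz = np.cos(theta)
    dx = np.sin(theta)
    z = np.concatenate([[0.0], np.cumsum(0.5 * (dz[1:] + dz[:-1]) * np.diff(arc_positions))])
    x = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * np.diff(arc_positions))])
    y = np.zeros_like(x)
    if truth.out_of_plane_pitch != 0.0:
        # tilt out of the bending plane proportionally to arc length
        y = truth.out_of_plane_pitch * arc_positions / max(L, 1e-9)
    return np.column_stack([x, y, z])


def gen_flared_end(truth: FlareGroundTruth, grid_id: str = "g0",
                   mt_id: str = "mt0") -> MTEndRecord:
    """Generate one MT end with flared PFs and attached ground truth.

    Each PF starts with a wall point 8 nm behind the end, an origin point
    on the cylinder at the end (``origin_index`` = 1), then arc points
    spaced 2-4 nm along the flare bending radially outward.  Gaussian
    point noise is added to every coordinate.  A zero or sub-spacing
    ``flare_arc_length`` deliberately produces zero-length flares.
    """
    rng = np.random.default_rng(truth.seed)
    traces: list[PFTrace] = []
    for p in range(truth.n_pf):
        phi = 2.0 * np.pi * p / truth.n_pf
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        wall = truth.mt_radius * radial + np.array([0.0, 0.0, -8.0])
        origin = truth.mt_radius * radial
        pts = [wall, origin]
        L = truth.flare_arc_length
        lo, hi = truth.point_spacing
        if L >= lo:
            # manual-style spacing: increments drawn uniformly in [lo, hi]
            arc = [0.0]
            while arc[-1] < L:
                arc.append(arc[-1] + rng.uniform(lo, hi))
            arc[-1] = L
            arc_positions = np.asarray(arc)
            local = _flare_arc(truth, arc_positions)
            # local x -> radially outward, local y -> tangent, local z -> +axis
            M = np.column_stack([radial, tangent, np.array([0.0, 0.0, 1.0])])
            flare = origin + local @ M.T
            pts.extend(flare[1:])  # arc position 0 is the origin itself
        arr = np.asarray(pts)
        if truth.noise_sigma > 0:
            arr = arr + rng.normal(0.0, truth.noise_sigma, size=arr.shape)
        traces.append(PFTrace(grid_id=grid_id, mt_id=mt_id, pf_id=f"pf{p}",
                              points=arr, origin_index=truth.origin_index))
    rec = MTEndRecord(grid_id=grid_id, mt_id=mt_id, polarity="plus",
                      cap_state="none", n_pf=truth.n_pf, traces=traces)
    return rec


def gen_flared_ends(truth: FlareGroundTruth, n_ends: int,
                    grid_id: str = "g0") -> list[MTEndRecord]:
    """Generate *n_ends* independent ends from per-end sub-seeds."""
    rng = np.random.default_rng(truth.seed)
    ends = []
    for i in range(n_ends):
        sub = FlareGroundTruth(**{**truth.__dict__,
                                  "seed": int(rng.integers(0, 2**31 - 1))})
        ends.append(gen_flared_end(sub, grid_id=grid_id, mt_id=f"mt{i}"))
    return ends


# ---------------------------------------------------------------------------
# spot fields


def gen_spot_field(truth: SpotFieldGroundTruth, shape: tuple[int, int] = (256, 256),
                   margin: int = 8, min_separation: float = 8.0) -> ImageFrame:
    """Render a synthetic single-molecule frame with attached truth.

    Spot peak amplitude = sum of N i.i.d. lognormal(mu, sigma_log)
    single-fluorophore draws; the PSF is an isotropic Gaussian; noise is
    Poisson on (background + signal) plus Gaussian read noise.  Centres
    closer than 1 px trigger a ``crowded`` warning flag.
    """
    rng = np.random.default_rng(truth.seed)
    n_spots = len(truth.molecules_per_spot)
    H, W = shape
    if truth.centers is None:
        centers = []
        attempts = 0
        while len(centers) < n_spots and attempts < 100000:
            cand = rng.uniform([margin, margin], [H - margin, W - margin])
            if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
                centers.append(cand)
            attempts += 1
        if len(centers) < n_spots:
            raise ValueError("could not place spots with the requested separation")
        centers = np.asarray(centers)
    else:
        centers = np.asarray(truth.centers, dtype=float)
        if len(centers) != n_spots:
            raise ValueError("centers and molecules_per_spot differ in length")
        if np.any(centers < 0) or np.any(centers >= [H, W]):
            raise ValueError("centers outside the frame")
    truth.centers = centers
    if n_spots > 1:
        from scipy.spatial.distance import pdist
        if pdist(centers).min() < 1.0:
            truth.crowded = True
            warnings.warn("spot centres closer than 1 px", stacklevel=2)

    img = np.full(shape, float(truth.background))
    yy, xx = np.mgrid[0:H, 0:W]
    amplitudes = np.empty(n_spots)
    for i, (c, n_mol) in enumerate(zip(centers, truth.molecules_per_spot)):
        amp = float(np.sum(rng.lognormal(truth.mu, truth.sigma_log, size=int(n_mol))))
        amplitudes[i] = amp
        r2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
        img += amp * np.exp(-r2 / (2.0 * truth.psf_sigma**2))
    if truth.poisson:
        img = rng.poisson(img).astype(float)
    if truth.read_noise > 0:
        img = img + rng.normal(0.0, truth.read_noise, size=img.shape)
    img = np.clip(img, 0.0, None)
    frame = ImageFrame(pixels=img)
    frame.true_amplitudes = amplitudes  # truth echo for recovery tests
    return frame


# ---------------------------------------------------------------------------
# dynamic events


def gen_event_series(truth: EventGroundTruth, n_mts: int) -> list[EndHistory]:
    """Simulate per-MT event histories under the stated regime.

    The growth+pause clock alternates growth sojourns (exponential with
    mean 1/pause_entry_rate before a pause, when pauses are enabled) and
    pauses (exponential, mean *pause_duration_mean*).  Catastrophes occur
    as a Poisson process of rate *catastrophe_rate* over that clock; each
    catastrophe appends a brief shrinkage event and growth resumes.  The
    history is truncated at *observation_span* minutes.
    """
    rng = np.random.default_rng(truth.seed)
    histories = []
    for m in range(n_mts):
        t = 0.0
        events: list[DynamicEvent] = []
        span = truth.observation_span
        while t < span - 1e-9:
            # time to next catastrophe on the growth+pause clock
            t_cat = (rng.exponential(1.0 / truth.catastrophe_rate)
                     if truth.catastrophe_rate > 0 else np.inf)
            produced = 0.0
            state = "growth"
            while produced < t_cat and t + produced < span - 1e-9:
                if state == "growth":
                    sojourn = (rng.exponential(1.0 / truth.pause_entry_rate)
                               if truth.pause_entry_rate > 0 else np.inf)
                else:
                    sojourn = rng.exponential(truth.pause_duration_mean)
                end = min(produced + sojourn, t_cat, span - t)
                dur = end - produced
                if dur > 1e-9:
                    if state == "growth":
                        rate = max(float(rng.normal(truth.growth_rate_mean,
                                                    truth.growth_rate_sd)), 0.06)
                        events.append(DynamicEvent("growth", rate, dur))
                    else:
                        events.append(DynamicEvent("pause", 0.0, dur))
                produced = end
                if produced >= t_cat or t + produced >= span - 1e-9:
                    break
                state = "pause" if state == "growth" else "growth"
            t += produced
            if produced >= t_cat and t < span - 1e-9:
                # catastrophe: brief shrinkage, then regrowth
                dur = min(rng.exponential(truth.shrink_duration_mean), span - t)
                if dur > 1e-9:
                    events.append(DynamicEvent("shrinkage", truth.shrink_rate, dur))
                    t += dur
            else:
                break
        histories.append(EndHistory(mt_id=f"mt{m}", events=events,
                                    observation_span=span))
    return histories


def histories_to_segments(histories: list[EndHistory],
                          calib: Calibration) -> list[KymoSegment]:
    """Quantise event histories into kymograph segments (px, frames)."""
    segments = []
    for h in histories:
        for ev in h.events:
            dt_frames = max(round(ev.duration * 60.0 / calib.frame_interval), 1)
            duration_s = dt_frames * calib.frame_interval
            dx_px = ev.rate / 60.0 * duration_s / calib.pixel_size
            segments.append(KymoSegment(mt_id=h.mt_id, dx=dx_px, dt=dt_frames,
                                        tip_marker_present=ev.tip_marker_present))
    return segments


def gen_frap_series(n_series: int = 30, plateau: float = 0.6, tau_s: float = 30.0,
                    bleach_depth: float = 1.0, noise_sigma: float = 0.02,
                    dt_s: float = 2.0, pre_s: float = 20.0, post_s: float = 120.0,
                    seed: int = 0):
    """Simulate single-exponential FRAP traces (raw, un-normalised).

    Post-bleach signal: (1 - bleach_depth) + plateau * (1 - exp(-t/tau)),
    relative to a pre-bleach level of 1, with Gaussian noise.  Returns
    (times, list of raw traces, bleach_index).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, pre_s + post_s, dt_s)
    bleach_index = int(pre_s / dt_s)
    traces = []
    for _ in range(n_series):
        ideal = np.ones_like(times)
        post_t = times[bleach_index:] - times[bleach_index]
        ideal[bleach_index:] = (1.0 - bleach_depth) + plateau * (1.0 - np.exp(-post_t / tau_s))
        traces.append(ideal + rng.normal(0.0, noise_sigma, size=ideal.shape))
    return times, traces, bleach_index
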