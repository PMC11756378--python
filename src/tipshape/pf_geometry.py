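"""Protofilament (PF) shape quantification at microtubule (MT) ends.

Growing and shrinking MT ends terminate in curved PFs that peel ("flare")
away from the MT cylinder.  Manually traced 3D contours of terminal PFs —
one ordered point sequence per PF, with the convention that the first point
sits on the MT wall and the point at ``origin_index`` is the last point
still inside the MT cylinder — are turned into per-PF and per-end summary
statistics:

* flare length: arc length from the flare origin to the PF terminus (nm);
* curvature: the turn angle between consecutive segment pairs of the
  uniformly resampled, LOESS-smoothed trace, expressed in degrees per nm;
* terminal curvature: curvature averaged over the joints nearest the
  distal tip;
* tip-aligned mean curvature profiles with a linear fit;
* Pearson correlation between per-end mean curvature and mean PF length;
* fractions of MT ends carrying a luminal capping density.

All coordinates are in nanometres, right-handed.  Curvature is handled
fully in 3D: traces are not projected onto a plane, so PFs that deviate
from a single plane are measured correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "PFTrace",
    "ResampledTrace",
    "CurvatureProfile",
    "MTEndRecord",
    "PerEndStats",
    "TipAlignedProfile",
    "CorrelationResult",
    "LatticeConstants",
    "resample_uniform",
    "loess_smooth",
    "curvature_profile",
    "flare_origin",
    "pf_flare_length",
    "terminal_curvature",
    "per_end_stats",
    "tip_aligned_profile",
    "curvature_length_correlation",
    "cap_statistics",
    "per_grid_cap_summary",
    "pooled_fraction",
    "coiled_coil_axial_length",
]

Polarity = Literal["plus", "minus"]
CapState = Literal["none", "partial", "full", "attached"]

#: Axial rise of the tubulin dimer along a PF (nm).
DIMER_RISE_NM = 8.0
#: Axial rise per residue of a two-stranded alpha-helical coiled coil (nm).
CC_RISE_PER_RESIDUE_NM = 0.15
#: Default arc-length resampling step (nm): the coarse end of the manual
#: 2-4 nm point spacing, so the 10-point LOESS window spans enough arc to
#: keep point noise from inflating unsigned joint angles.
DEFAULT_STEP_NM = 4.0
#: Nominal outer-wall radius proxy for a 14-PF MT lattice (nm).
MT_RADIUS_14PF_NM = 12.5


@dataclass(frozen=True)
class LatticeConstants:
    """Fixed geometric constants of the MT lattice and coiled coils."""

    dimer_rise: float = DIMER_RISE_NM
    mt_radius: float = MT_RADIUS_14PF_NM
    cc_rise_per_residue: float = CC_RISE_PER_RESIDUE_NM

    def __post_init__(self) -> None:
        if min(self.dimer_rise, self.mt_radius, self.cc_rise_per_residue) <= 0:
            raise ValueError("lattice constants must be positive")


def _as_points(points: Sequence) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be an (n, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass
class PFTrace:
    """One manually traced protofilament at an MT end.

    ``points[0]`` lies on the MT wall; ``points[origin_index]`` is the last
    point still inside the MT cylinder (the flare origin); subsequent
    points follow the bending part of the PF, placed every 2-4 nm.
    """

    grid_id: str
    mt_id: str
    pf_id: str
    points: np.ndarray
    origin_index: int = 1

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        n = len(self.points)
        if n < 2:
            raise ValueError("a PF trace needs at least 2 points")
        if not (0 <= self.origin_index < n):
            raise ValueError(f"origin_index {self.origin_index} out of range for {n} points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("consecutive trace points must be distinct")

    @property
    def flare_points(self) -> np.ndarray:
        """Points from the flare origin to the PF terminus."""
        return self.points[self.origin_index:]


@dataclass
class ResampledTrace:
    """A flare trace resampled at uniform arc-length spacing."""

    points: np.ndarray
    step: float
    source: PFTrace | None = None
    degenerate: bool = False  # flare had < 2 points; zero-length output

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class CurvatureProfile:
    """Per-joint turn angles along a smoothed PF flare.

    ``joint_angles[i]`` is the 3D angle (degrees, in [0, 180]) between the
    segments flanking interior point ``i + 1``; ``arc_positions[i]`` is that
    point's arc distance from the flare origin (nm).
    """

    joint_angles: np.ndarray
    arc_positions: np.ndarray
    step: float
    empty: bool = False

    def __post_init__(self) -> None:
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)

    @property
    def angles_per_nm(self) -> np.ndarray:
        """Turn angle divided by the resampling step (degrees / nm)."""
        return self.joint_angles / self.step

    @property
    def angles_per_dimer(self) -> np.ndarray:
        """Turn angle per 8-nm tubulin dimer (degrees / dimer)."""
        return self.angles_per_nm * DIMER_RISE_NM

    def __len__(self) -> int:
        return len(self.joint_angles)


@dataclass
class MTEndRecord:
    """One MT end: polarity, cap classification and its PF traces."""

    grid_id: str
    mt_id: str
    polarity: Polarity
    cap_state: CapState = "none"
    n_pf: int = 14
    traces: list[PFTrace] = field(default_factory=list)

    _POLARITIES = ("plus", "minus")
    _CAP_STATES = ("none", "partial", "full", "attached")

    def __post_init__(self) -> None:
        if self.polarity not in self._POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.cap_state not in self._CAP_STATES:
            raise ValueError(f"unknown cap_state {self.cap_state!r}")

    @property
    def capped(self) -> bool:
        return self.cap_state != "none"


@dataclass
class PerEndStats:
    """Per-end means over PFs with nonzero flare length."""

    grid_id: str
    mt_id: str
    mean_length: float
    mean_curvature: float
    mean_terminal_curvature: float
    n_pf_nonzero: int
    n_pf_total: int

    @property
    def defined(self) -> bool:
        return self.n_pf_nonzero > 0 and np.isfinite(self.mean_curvature)


@dataclass
class TipAlignedProfile:
    """Mean +/- SEM curvature vs distance from the distal PF tip."""

    offsets: np.ndarray          # non-positive, 0 at the tip-most joint
    mean_curvature: np.ndarray   # degrees / nm
    sem_curvature: np.ndarray
    n_per_offset: np.ndarray
    fit_slope: float
    fit_intercept: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# resampling and smoothing


def _cumulative_arclen(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_uniform(trace: PFTrace | np.ndarray, step: float = DEFAULT_STEP_NM) -> ResampledTrace:
    """Resample the flare of *trace* at uniform arc-length spacing.

    The polyline from the flare origin to the terminus is parameterised by
    cumulative arc length and linearly interpolated every *step* nm.  The
    origin and terminus are preserved exactly; the final interval may be
    shorter than *step*.  A flare with fewer than 2 points yields a
    zero-length, flagged result (never raises).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if isinstance(trace, PFTrace):
        pts = trace.flare_points
        source = trace
    else:
        pts = _as_points(trace)
        source = None
    if len(pts) < 2:
        return ResampledTrace(points=pts.reshape(-1, 3), step=step, source=source,
                              degenerate=True)
    t = _cumulative_arclen(pts)
    total = t[-1]
    positions = np.arange(0.0, total, step)
    if total - positions[-1] > 1e-9:
        positions = np.concatenate([positions, [total]])
    else:
        positions[-1] = total
    out = np.column_stack([np.interp(positions, t, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return ResampledTrace(points=out, step=step, source=source)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_smooth(trace: ResampledTrace, window_points: int = 10, degree: int = 2) -> ResampledTrace:
    """Locally weighted polynomial smoothing of a resampled trace.

    Each coordinate is regressed on arc length with a locally weighted
    polynomial of the given degree over the *window_points* nearest samples
    (tricube weights, bandwidth = distance to the farthest point in the
    window).  Uniform resampling makes arc length equal index x step, so
    that nominal grid is the regression abscissa (the sub-step final
    interval is treated as a full step).  Traces shorter than the window
    are fitted with a single global polynomial of the same degree.  The
    number of points never changes, and coordinates polynomial of degree
    <= *degree* in arc length are reproduced exactly.
    """
    if window_points < degree + 2:
        raise ValueError("window_points must be at least degree + 2")
    pts = trace.points
    n = len(pts)
    if n <= degree + 1:
        # too few points to constrain the polynomial beyond interpolation
        return ResampledTrace(points=pts.copy(), step=trace.step, source=trace.source,
                              degenerate=trace.degenerate)
    t = trace.step * np.arange(n, dtype=float)
    out = np.empty_like(pts)
    if n <= window_points:
        # global polynomial fit per coordinate
        tc = t - t.mean()
        for k in range(3):
            coef = np.polynomial.polynomial.polyfit(tc, pts[:, k], degree)
            out[:, k] = np.polynomial.polynomial.polyval(tc, coef)
        return ResampledTrace(points=out, step=trace.step, source=trace.source)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argpartition(d, window_points - 1)[:window_points]
        h = d[idx].max()
        if h <= 0:  # pragma: no cover - distinct points guarantee h > 0
            out[i] = pts[i]
            continue
        w = _tricube(d[idx] / h)
        # guard: keep enough support if ties put several points at the bandwidth
        if np.count_nonzero(w) < degree + 1:
            w = w + 1e-12
        tc = t[idx] - t[i]
        sw = np.sqrt(w)
        # weighted least squares, evaluated at the window centre (tc = 0)
        V = np.vander(tc, degree + 1, increasing=True)
        A = V * sw[:, None]
        for k in range(3):
            coef, *_ = np.linalg.lstsq(A, pts[idx, k] * sw, rcond=None)
            out[i, k] = coef[0]
    return ResampledTrace(points=out, step=trace.step, source=trace.source)


# ---------------------------------------------------------------------------
# curvature


def curvature_profile(trace: ResampledTrace) -> CurvatureProfile:
    """Turn angles between consecutive segment pairs of a smoothed trace.

    The angle at interior point *i* is the 3D angle between segments
    (i-1 -> i) and (i -> i+1), computed with atan2 of the cross/dot
    products for numerical stability near 0 and 180 degrees.  Traces with
    fewer than 3 points give an empty, flagged profile.
    """
    pts = trace.points
    if len(pts) < 3:
        return CurvatureProfile(joint_angles=np.empty(0), arc_positions=np.empty(0),
                                step=trace.step, empty=True)
    v = np.diff(pts, axis=0)
    a, b = v[:-1], v[1:]
    cross = np.linalg.norm(np.cross(a, b), axis=1)
    dot = np.einsum("ij,ij->i", a, b)
    angles = np.degrees(np.arctan2(cross, dot))
    t = _cumulative_arclen(pts)
    return CurvatureProfile(joint_angles=angles, arc_positions=t[1:-1], step=trace.step)


def pf_flare_length(trace: PFTrace | ResampledTrace) -> float:
    """Arc length (nm) of the polyline from the flare origin to the terminus."""
    pts = trace.flare_points if isinstance(trace, PFTrace) else trace.points
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def terminal_curvature(profile: CurvatureProfile, n_terminal_joints: int = 3) -> float:
    """Mean curvature (deg/nm) over the joints nearest the distal tip.

    Returns NaN for an empty profile so the value is excluded from
    aggregation.
    """
    if profile.empty or len(profile) == 0:
        return float("nan")
    k = min(n_terminal_joints, len(profile))
    return float(profile.angles_per_nm[-k:].mean())


def flare_origin(points: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray,
                 mt_radius: float = MT_RADIUS_14PF_NM, delta: float = 1.5) -> int:
    """Locate the flare origin of a raw trace automatically.

    Returns the index of the last point whose radial distance from the MT
    axis is within ``mt_radius + delta`` and after which every point
    exceeds that threshold.  If no point ever leaves the cylinder the last
    index is returned (zero-length flare); if even the first point is
    outside, index 0 is returned.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    d = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(d)
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValueError("degenerate axis direction")
    d = d / norm
    rel = pts - np.asarray(axis_point, dtype=float)
    radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
    inside = radial <= mt_radius + delta
    if inside.all():
        return len(pts) - 1
    if not inside.any():
        return 0
    return int(np.max(np.nonzero(inside)[0]))


# ---------------------------------------------------------------------------
# per-end aggregation


def _pf_pipeline(trace: PFTrace, step: float, window: int,
                 n_terminal_joints: int = 3) -> tuple[float, float, float]:
    """Resample -> smooth -> curvature for one PF.

    Returns (flare length nm, mean curvature deg/nm, terminal curvature
    deg/nm); the curvatures are NaN when undefined (< 3 flare points).
    """
    rs = resample_uniform(trace, step)
    if rs.degenerate or rs.n_points < 2:
        return 0.0, float("nan"), float("nan")
    sm = loess_smooth(rs, window_points=window)
    length = pf_flare_length(sm)
    prof = curvature_profile(sm)
    if prof.empty:
        return length, float("nan"), float("nan")
    return length, float(prof.angles_per_nm.mean()), terminal_curvature(prof, n_terminal_joints)


def per_end_stats(end: MTEndRecord, step: float = DEFAULT_STEP_NM, window: int = 10,
                  n_terminal_joints: int = 3) -> PerEndStats:
    """Per-MT-end means of flare length and curvature.

    Each PF runs through the resample -> LOESS -> curvature pipeline.
    Means are taken over PFs with nonzero flare length only; untraced
    (blunt) PFs of the lattice count toward ``n_pf_total`` but not the
    means.  PFs too short for curvature still contribute to the length
    mean.
    """
    lengths, curvatures, terminals = [], [], []
    for tr in end.traces:
        length, curv, term = _pf_pipeline(tr, step, window, n_terminal_joints)
        if length > 0:
            lengths.append(length)
            if np.isfinite(curv):
                curvatures.append(curv)
                terminals.append(term)
    n_total = max(end.n_pf, len(end.traces))
    nz = len(lengths)
    return PerEndStats(
        grid_id=end.grid_id,
        mt_id=end.mt_id,
        mean_length=float(np.mean(lengths)) if nz else float("nan"),
        mean_curvature=float(np.mean(curvatures)) if curvatures else float("nan"),
        mean_terminal_curvature=float(np.mean(terminals)) if terminals else float("nan"),
        n_pf_nonzero=nz,
        n_pf_total=n_total,
    )


def tip_aligned_profile(profiles: Iterable[CurvatureProfile]) -> TipAlignedProfile:
    """Average curvature profiles aligned at their distal tips.

    Joints are indexed from the tip (offset 0 = tip-most joint, then
    -step, -2*step, ...).  Mean, SEM and count are reported per offset;
    SEM is NaN where fewer than 2 profiles contribute.  An ordinary
    least-squares line of mean curvature vs offset is fitted over offsets
    with data.
    """
    profs = [p for p in profiles if not p.empty and len(p) > 0]
    if not profs:
        raise ValueError("need at least one non-empty profile")
    step = profs[0].step
    if any(abs(p.step - step) > 1e-9 for p in profs):
        raise ValueError("profiles have mixed resampling steps")
    max_len = max(len(p) for p in profs)
    stacks: list[list[float]] = [[] for _ in range(max_len)]
    for p in profs:
        rev = p.angles_per_nm[::-1]  # tip-most joint first
        for j, val in enumerate(rev):
            stacks[j].append(float(val))
    offsets = -step * np.arange(max_len)
    mean = np.array([np.mean(s) for s in stacks])
    sem = np.array([np.std(s, ddof=1) / math.sqrt(len(s)) if len(s) >= 2 else np.nan
                    for s in stacks])
    n = np.array([len(s) for s in stacks])
    if max_len >= 2:
        fit = _stats.linregress(offsets, mean)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = 0.0, float(mean[0])
    return TipAlignedProfile(offsets=offsets, mean_curvature=mean, sem_curvature=sem,
                             n_per_offset=n, fit_slope=slope, fit_intercept=intercept)


def curvature_length_correlation(stats: Iterable[PerEndStats]) -> CorrelationResult:
    """Pearson correlation between per-end mean curvature and mean length."""
    pairs = [(s.mean_curvature, s.mean_length) for s in stats if s.defined]
    if len(pairs) < 3:
        raise ValueError("need at least 3 ends with defined means")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = _stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(pairs))


# ---------------------------------------------------------------------------
# cap statistics


def pooled_fraction(n_hits: int, n_total: int) -> float:
    """Pooled percentage n_hits / n_total * 100 (NaN for an empty stratum)."""
    if n_total == 0:
        return float("nan")
    return 100.0 * n_hits / n_total


def cap_statistics(ends: Iterable[MTEndRecord],
                   mode: Literal["pooled", "per_grid"] = "per_grid") -> pd.DataFrame:
    """Fraction of MT ends carrying a capping density, by polarity.

    ``pooled`` divides summed counts per polarity; ``per_grid`` returns one
    fraction per (grid, polarity) stratum (summarise across grids with
    :func:`per_grid_cap_summary`).  Fractions are percentages.
    """
    rows = [{"grid_id": e.grid_id, "polarity": e.polarity, "capped": e.capped}
            for e in ends]
    if not rows:
        raise ValueError("no MT ends given")
    df = pd.DataFrame(rows)
    keys = ["polarity"] if mode == "pooled" else ["grid_id", "polarity"]
    if mode not in ("pooled", "per_grid"):
        raise ValueError(f"unknown mode {mode!r}")
    out = (df.groupby(keys, as_index=False)
             .agg(n_total=("capped", "size"), n_capped=("capped", "sum")))
    out["fraction_pct"] = 100.0 * out["n_capped"] / out["n_total"]
    return out


def per_grid_cap_summary(per_grid_table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of per-grid cap fractions, per polarity."""
    return (per_grid_table.groupby("polarity", as_index=False)
            .agg(mean_pct=("fraction_pct", "mean"),
                 sd_pct=("fraction_pct", "std"),
                 n_grids=("fraction_pct", "size")))


def coiled_coil_axial_length(n_residues: int,
                             rise_per_residue: float = CC_RISE_PER_RESIDUE_NM) -> float:
    """Axial length (nm) of a two-stranded alpha-helical coiled coil.

    The canonical coiled coil rises ~0.15 nm per residue, so ~80 residues
    span ~12 nm — the scale used to interpret solution-scattering maximum
    dimensions of coiled-coil fragments.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    if rise_per_residue <= 0:
        raise ValueError("rise_per_residue must be positive")
    return n_residues * rise_per_residue
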