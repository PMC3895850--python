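"""Mid-wall point tracking and circumferential stretch.

The measurement chain: 100 points are seeded equidistantly along the
diastolic mid-wall delineation; each point is carried to its systolic
position by the decoded displacement field (the encoding runs from maximal
expansion to the diastolic readout, so the expanded position is the
diastolic position *minus* the displacement); the systolic point cloud is
regularized with a 5-piece periodic least-squares cubic spline; stretch is
the ratio of distances between adjacent points along the expanded and
resting splines, the systolic distance taken in 3-D (through-plane motion
included) and the diastolic distance in the imaging plane.

Both states are smoothed with the same spline basis and stretch compares
corresponding spline-projected points, so the basis approximation error
(which is common to numerator and denominator) cancels in the ratio; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import (
    AnalysisError,
    DegenerateInputError,
    ParameterError,
    TrackingError,
)
from .geometry import (
    QUADRANT_LABELS,
    ClosedCurve,
    circumferential_angle,
    quadrant_of,
)
from .phase import DisplacementField

TWO_PI = 2.0 * np.pi


@dataclass
class TrackedPoints:
    """Corresponding diastolic (z = 0 plane) and systolic 3-D points, mm."""

    diastolic: np.ndarray  # (n, 3), z = 0
    systolic: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        if self.diastolic.shape != self.systolic.shape:
            raise ParameterError("diastolic/systolic point counts differ")

    @property
    def n(self) -> int:
        return self.diastolic.shape[0]


@dataclass
class StretchProfile:
    """Per-segment circumferential stretch around the wall.

    ``ratios[i]`` is the stretch of the segment between points i and i+1
    (periodic), ``angles[i]`` its diastolic mid-angle in the A/R/P/L
    convention, ``quadrants[i]`` its quadrant label.
    """

    ratios: np.ndarray
    angles: np.ndarray
    quadrants: np.ndarray  # array of 'A'/'R'/'P'/'L'

    def __post_init__(self):
        if np.any(np.asarray(self.ratios) <= 0):
            raise ParameterError("stretch ratios must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.ratios)


@dataclass
class QuadrantSummary:
    """Overall and per-quadrant mean stretch with relative differences.

    ``rel_diff[q] = (S_quadrant - S_overall) / S_overall`` is the asymmetry
    statistic; stretch is reported both as a ratio and as percent.
    """

    overall: float
    per_quadrant: dict  # label -> mean stretch ratio
    rel_diff: dict  # label -> relative stretch difference

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall

    @property
    def per_quadrant_percent(self) -> dict:
        return {k: 100.0 * v for k, v in self.per_quadrant.items()}


def seed_points(mid: ClosedCurve, n: int = 100) -> np.ndarray:
    """n points at equal arc-length spacing on the mid curve, the first at
    the curve's anterior-axis crossing (theta = 0)."""
    if n < 8:
        raise ParameterError("need at least 8 seed points")
    t0 = mid.angle_parameter(0.0)
    t = np.mod(t0 + np.arange(n) / n, 1.0)
    pts = mid(t)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(n)])
    return pts


def track_points(points, field: DisplacementField,
                 window_sigma_px: float = 1.0) -> TrackedPoints:
    """Carry diastolic points to their systolic positions through the field.

    Each displacement component is sampled at the sub-pixel point location
    by a certainty-weighted local linear fit (moving least squares) over a
    5x5 footprint of valid pixels, with a Gaussian spatial window of
    ``window_sigma_px``; zero-certainty pixels are excluded.  The local
    linear model reproduces affine displacement fields exactly, so rigid
    motion incurs no sampling bias on the thin wall.  Systolic position =
    diastolic - u, the through-plane component becoming the systolic z
    coordinate.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dia = pts if pts.shape[1] == 3 else np.column_stack([pts, np.zeros(len(pts))])
    u = _interpolate_field(dia[:, :2], field, window_sigma_px)
    return TrackedPoints(diastolic=dia, systolic=dia - u)


def _interpolate_field(points_xy, field: DisplacementField,
                       sigma_px: float) -> np.ndarray:
    dx, dy = field.pixel_spacing
    ny, nx = field.valid.shape
    cert = np.where(field.valid, field.certainty, 0.0)
    out = np.empty((len(points_xy), 3))
    for idx, (x, y) in enumerate(points_xy):
        px, py = x / dx, y / dy
        ix, iy = int(np.round(px)), int(np.round(py))
        cols = np.arange(ix - 2, ix + 3)
        rows = np.arange(iy - 2, iy + 3)
        if cols[0] < 0 or rows[0] < 0 or cols[-1] >= nx or rows[-1] >= ny:
            raise TrackingError(f"point {idx} footprint leaves the image")
        cgrid, rgrid = np.meshgrid(cols, rows)
        w = cert[rgrid, cgrid] * np.exp(
            -((cgrid - px) ** 2 + (rgrid - py) ** 2) / (2.0 * sigma_px**2)
        )
        if w.sum() <= 0:
            raise TrackingError(f"point {idx} has no valid interpolation support")
        # weighted linear fit u(dx, dy) = a + b dx + c dy; value at point = a
        A = np.column_stack([
            np.ones(w.size), (cgrid.ravel() - px), (rgrid.ravel() - py),
        ])
        aw = A.T * w.ravel()
        rhs = aw @ field.u[rgrid, cgrid].reshape(-1, 3)
        sol, *_ = np.linalg.lstsq(aw @ A, rhs, rcond=None)
        out[idx] = sol[0]
    return out


# ---------------------------------------------------------------------------
# periodic least-squares B-spline


class PeriodicBSpline:
    """Uniform periodic cubic B-spline on [0, 1) with ``pieces`` knots."""

    def __init__(self, coefficients: np.ndarray, pieces: int):
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.pieces = int(pieces)
        self._basis = BSpline.basis_element(np.arange(5.0), extrapolate=False)

    def _basis_matrix(self, t) -> np.ndarray:
        t = np.mod(np.asarray(t, dtype=float), 1.0)
        p = self.pieces
        A = np.zeros((t.size, p))
        for j in range(p):
            x = np.mod(p * t - j, p)
            total = np.zeros_like(x)
            shift = 0.0
            while shift < 4.0:  # wrap basis support around the period
                v = self._basis(x + shift)
                total += np.nan_to_num(v)
                shift += p
            A[:, j] = total
        return A

    def __call__(self, t):
        t = np.atleast_1d(t)
        return self._basis_matrix(t) @ self.coefficients

    @classmethod
    def fit(cls, t, values, pieces: int) -> "PeriodicBSpline":
        self = cls(np.zeros((pieces, np.shape(values)[1])), pieces)
        A = self._basis_matrix(np.asarray(t, dtype=float))
        coef, *_ = np.linalg.lstsq(A, np.asarray(values, dtype=float), rcond=None)
        self.coefficients = coef
        return self


def fit_periodic_spline(points, pieces: int = 5) -> ClosedCurve:
    """Least-squares periodic cubic spline through ordered periodic points.

    Points are parameterized by index/n; ``pieces`` uniformly spaced knots
    (default 5) span the period and each coordinate (x, y, z) is fitted
    independently.  Returns the smoothed closed curve.
    """
    pts = np.asarray(points, dtype=float)
    if pieces < 3:
        raise ParameterError("need at least 3 spline pieces")
    if pts.shape[0] < 2 * pieces:
        raise ParameterError(
            f"need at least {2 * pieces} points to fit {pieces} pieces"
        )
    n = pts.shape[0]
    t = np.arange(n) / n
    spline = PeriodicBSpline.fit(t, pts, pieces)
    return ClosedCurve.from_function(lambda u: spline(u), control_points=pts)


# ---------------------------------------------------------------------------
# stretch


def stretch_profile(
    tracked: TrackedPoints,
    smoothed_systolic: ClosedCurve | None = None,
    smoothed_diastolic: ClosedCurve | None = None,
    pieces: int = 5,
    center=None,
) -> StretchProfile:
    """Per-segment stretch ratios from tracked points.

    Both point sets are projected onto their smoothed splines (fitted here
    with the same ``pieces`` basis when not supplied); for each periodic
    adjacent pair the stretch is the 3-D systolic chord over the in-plane
    diastolic chord.  Each segment's quadrant comes from its diastolic
    midpoint.
    """
    if smoothed_systolic is None:
        smoothed_systolic = fit_periodic_spline(tracked.systolic, pieces)
    if smoothed_diastolic is None:
        smoothed_diastolic = fit_periodic_spline(tracked.diastolic[:, :2], pieces)
    n = tracked.n
    p_sys = _project_points(tracked.systolic, smoothed_systolic)
    p_dia = _project_points(tracked.diastolic[:, : smoothed_diastolic.dim],
                            smoothed_diastolic)
    if p_dia.shape[1] == 2:
        p_dia = np.column_stack([p_dia, np.zeros(n)])

    d_sys = np.linalg.norm(np.roll(p_sys, -1, axis=0) - p_sys, axis=1)
    d_dia = np.linalg.norm(
        (np.roll(p_dia, -1, axis=0) - p_dia)[:, :2], axis=1
    )
    if np.any(d_dia <= 0):
        raise DegenerateInputError("zero-length diastolic segment")
    ratios = d_sys / d_dia

    mids = 0.5 * (np.roll(tracked.diastolic, -1, axis=0) + tracked.diastolic)[:, :2]
    if center is None:
        center = tracked.diastolic[:, :2].mean(axis=0)
    angles = circumferential_angle(mids, center)
    quadrants = np.array([quadrant_of(m, center) for m in mids])
    return StretchProfile(ratios=ratios, angles=np.atleast_1d(angles),
                          quadrants=quadrants)


def _project_points(points, curve: ClosedCurve) -> np.ndarray:
    pts = np.asarray(points, dtype=float)[:, : curve.dim]
    n = len(pts)
    out = np.empty_like(pts)
    t_hint = None
    for i, p in enumerate(pts):
        t = curve.project(p, t_hint=t_hint)
        out[i] = curve(t)
        t_hint = t + 1.0 / n
    return out


def quadrant_summary(profile: StretchProfile) -> QuadrantSummary:
    """Mean stretch overall and per quadrant, with relative differences."""
    overall = float(np.mean(profile.ratios))
    per_quadrant, rel_diff = {}, {}
    for label in QUADRANT_LABELS:
        sel = profile.quadrants == label
        if not sel.any():
            raise AnalysisError(f"quadrant '{label}' contains no segments")
        s_q = float(np.mean(profile.ratios[sel]))
        per_quadrant[label] = s_q
        rel_diff[label] = (s_q - overall) / overall
    return QuadrantSummary(overall=overall, per_quadrant=per_quadrant,
                           rel_diff=rel_diff)
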