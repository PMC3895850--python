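"""Vessel-wall geometry: closed periodic curves, wall masks, quadrants.

Coordinate conventions
----------------------
Pixels are indexed ``[row, col]``; physical coordinates are ``x = col * dx``,
``y = row * dy`` in mm, with the origin at the centre of pixel ``(0, 0)``.
All curve mathematics is done in mm.

The anatomical frame assumes a supine axial slice: image ``-y`` points to the
patient's anterior (A), image ``-x`` to the patient's right (R), ``+y``
posterior (P), ``+x`` left (L).  The circumferential angle ``theta`` is zero
on the A axis and increases toward R (clockwise in image coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from shapely.geometry import LineString

from .errors import DegenerateInputError, GeometryError, ParameterError

TWO_PI = 2.0 * np.pi

#: quadrant labels in circumferential order starting at the anterior axis
QUADRANT_LABELS = ("A", "R", "P", "L")


def circumferential_angle(points, center) -> np.ndarray:
    """Angle of ``points`` about ``center`` in the A/R/P/L convention.

    theta = 0 on the anterior axis (image -y), pi/2 on the patient-right
    axis (image -x), i.e. increasing clockwise in image coordinates.
    Result in [0, 2*pi).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(center, dtype=float)
    d = p[..., :2] - c[:2]
    theta = np.arctan2(-d[..., 0], -d[..., 1]) % TWO_PI
    return theta if theta.size > 1 else theta.reshape(())


def unit_vector_at_angle(theta) -> np.ndarray:
    """Inverse of :func:`circumferential_angle`: unit vector for angle(s)."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([-np.sin(theta), -np.cos(theta)], axis=-1)


def quadrant_of(point, center) -> str:
    """Quadrant label (A, R, P or L) of ``point`` about ``center``.

    Quadrants are the 90-degree sectors centred on the anatomical axes.
    A point exactly on a 45-degree boundary belongs to the sector that
    follows in the A -> R -> P -> L direction (so theta = 45 deg is R).
    """
    p = np.asarray(point, dtype=float)[:2]
    c = np.asarray(center, dtype=float)[:2]
    if np.allclose(p, c):
        raise ParameterError("quadrant_of: point coincides with center")
    theta = circumferential_angle(p, c)
    idx = int(((theta + np.pi / 4.0) % TWO_PI) // (np.pi / 2.0)) % 4
    return QUADRANT_LABELS[idx]


class ClosedCurve:
    """Closed C1 periodic curve parameterized by normalized arc length.

    ``curve(t)`` with ``t`` in [0, 1) traverses the curve once; equal steps
    in ``t`` correspond to equal arc length (to ~1e-6 relative).  The curve
    keeps its exact underlying parametric function and only tabulates the
    arc-length reparameterization, so evaluated points lie on the true
    curve to machine precision.  Curves may live in 2-D or 3-D.
    """

    _N_DENSE = 8192  # samples used for arc-length tabulation

    def __init__(self, fun, length: float, s_table, t_table, control_points=None):
        self._fun = fun
        self.length = float(length)
        self._s_table = s_table  # normalized arc length at t_table entries
        self._t_table = t_table
        self.control_points = control_points
        self.dim = np.atleast_2d(fun(np.array([0.0]))).shape[-1]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_control_points(cls, control_points) -> "ClosedCurve":
        """Periodic cubic interpolating spline through ordered control points."""
        pts = np.asarray(control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] not in (2, 3):
            raise ParameterError(
                "closed curve needs >= 4 control points of dimension 2 or 3"
            )
        if np.any(np.all(np.isclose(np.diff(pts, axis=0), 0.0), axis=1)):
            raise ParameterError("duplicated consecutive control points")
        closed = np.vstack([pts, pts[:1]])
        chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
        if t[-1] == 0.0:
            raise ParameterError("control points are all coincident")
        t /= t[-1]
        spline = CubicSpline(t, closed, axis=0, bc_type="periodic")
        return cls.from_function(lambda u: spline(np.mod(u, 1.0)), pts)

    @classmethod
    def from_function(cls, fun, control_points=None) -> "ClosedCurve":
        """Build from any 1-periodic parametric function ``fun(t) -> (n, d)``."""
        t = np.linspace(0.0, 1.0, cls._N_DENSE, endpoint=False)
        p = np.asarray(fun(t), dtype=float)
        seg = np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        length = s[-1]
        if length <= 0:
            raise ParameterError("curve has zero length")
        s_table = s / length
        t_table = np.concatenate([t, [1.0]])
        return cls(fun, length, s_table, t_table, control_points)

    # -- evaluation --------------------------------------------------------

    def _t_of(self, u):
        return np.interp(np.mod(u, 1.0), self._s_table, self._t_table)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.asarray(self._fun(np.atleast_1d(self._t_of(t))), dtype=float)
        return out[0] if t.ndim == 0 else out

    def derivative(self, t, h: float = 1e-6):
        """dC/dt (mm per unit parameter); |dC/dt| ~ length everywhere."""
        t = np.asarray(t, dtype=float)
        return (self(t + h) - self(t - h)) / (2.0 * h)

    def polygon(self, n: int = 512) -> np.ndarray:
        """n-point polygonization at equal arc spacing (no repeated endpoint)."""
        return self(np.linspace(0.0, 1.0, n, endpoint=False))

    @property
    def centroid(self) -> np.ndarray:
        return self.polygon(1024).mean(axis=0)

    def is_simple(self, n: int = 512) -> bool:
        """Non-self-intersection check on an n-point polygonization (2-D)."""
        poly = self.polygon(n)[:, :2]
        ring = np.vstack([poly, poly[:1]])
        return bool(LineString(ring).is_simple)

    def project(self, point, t_hint: float | None = None) -> float:
        """Parameter of the nearest curve point to ``point``.

        With ``t_hint`` the search is restricted to a local window around the
        hint, otherwise a global coarse search seeds the refinement.
        """
        p = np.asarray(point, dtype=float)

        def dist2(t):
            return float(np.sum((self(t) - p) ** 2))

        if t_hint is None:
            tt = np.linspace(0.0, 1.0, 2048, endpoint=False)
            d = np.sum((self(tt) - p) ** 2, axis=1)
            t0 = tt[int(np.argmin(d))]
            half = 1.0 / 2048
        else:
            t0 = float(t_hint)
            half = 0.05
        res = minimize_scalar(
            dist2, bounds=(t0 - half, t0 + half), method="bounded",
            options={"xatol": 1e-12},
        )
        t = float(res.x)
        # Newton refinement of the foot point: solve (C(t) - p) . C'(t) = 0
        h = 1e-6
        for _ in range(3):
            c0 = self(t)
            d1 = (self(t + h) - self(t - h)) / (2 * h)
            d2 = (self(t + h) - 2 * c0 + self(t - h)) / h**2
            g = float(np.dot(c0 - p, d1))
            gp = float(np.dot(d1, d1) + np.dot(c0 - p, d2))
            if gp <= 0:
                break
            step = g / gp
            t -= step
            if abs(step) < 1e-14:
                break
        if dist2(t) > res.fun:
            t = float(res.x)
        return float(np.mod(t, 1.0))

    def angle_parameter(self, theta: float, center=None) -> float:
        """Parameter t where the curve crosses circumferential angle ``theta``.

        For star-shaped curves about ``center`` (default: centroid) the
        crossing is unique.
        """
        c = self.centroid[:2] if center is None else np.asarray(center, float)[:2]
        tt = np.linspace(0.0, 1.0, 4096, endpoint=False)
        ang = circumferential_angle(self(tt)[:, :2], c)
        diff = np.mod(ang - theta + np.pi, TWO_PI) - np.pi
        # locate a sign change of the wrapped angular offset
        idx = int(np.argmin(np.abs(diff)))
        lo, hi = tt[idx] - 1.0 / 4096, tt[idx] + 1.0 / 4096

        def f(t):
            a = circumferential_angle(self(t)[:2], c)
            return float(np.mod(a - theta + np.pi, TWO_PI) - np.pi)

        flo, fhi = f(lo), f(hi)
        if flo == 0.0:
            return float(np.mod(lo, 1.0))
        if flo * fhi > 0:  # fall back to the dense minimizer
            return float(tt[idx])
        for _ in range(60):  # bisection
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            if fm == 0.0:
                break
            if flo * fm < 0:
                hi = mid
            else:
                lo, flo = mid, fm
        return float(np.mod(0.5 * (lo + hi), 1.0))


def fit_closed_curve(control_points) -> ClosedCurve:
    """Periodic interpolating spline through control points, arc-length
    parameterized; raises :class:`GeometryError` if the result self-intersects.
    """
    curve = ClosedCurve.from_control_points(control_points)
    if curve.dim == 2 and not curve.is_simple():
        raise GeometryError("fitted closed curve self-intersects")
    return curve


def mid_curve_between(inner: ClosedCurve, outer: ClosedCurve, n: int = 256) -> ClosedCurve:
    """Mid-wall curve as the angular midpoint of inner and outer contours.

    Both contours are sampled at matched circumferential angles about the
    shared centroid; assumes the wall is star-shaped about that centre, which
    holds for cross-sections of the ascending aorta.
    """
    c = 0.5 * (inner.centroid[:2] + outer.centroid[:2])
    thetas = np.linspace(0.0, TWO_PI, n, endpoint=False)
    pts = np.empty((n, 2))
    for i, th in enumerate(thetas):
        pi = inner(inner.angle_parameter(th, c))[:2]
        po = outer(outer.angle_parameter(th, c))[:2]
        pts[i] = 0.5 * (pi + po)
    return ClosedCurve.from_control_points(pts)


@dataclass
class WallDelineation:
    """Inner/outer/mid wall contours plus the included-pixel mask."""

    inner: ClosedCurve
    outer: ClosedCurve
    mid: ClosedCurve
    mask: np.ndarray | None = None

    def __post_init__(self):
        inner_poly = self.inner.polygon(512)[:, :2]
        outer_path = MplPath(self.outer.polygon(512)[:, :2])
        if not outer_path.contains_points(inner_poly).all():
            raise GeometryError("inner contour is not strictly inside outer contour")

    @property
    def center(self) -> np.ndarray:
        """Centroid of the mid-wall contour (mm)."""
        return self.mid.centroid[:2]


def pixel_centers(shape, pixel_spacing):
    """(x, y) mm coordinates of pixel centers for an image of ``shape``."""
    ny, nx = shape
    dx, dy = pixel_spacing
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    return np.meshgrid(x, y)


def annulus_pixels(inner: ClosedCurve, outer: ClosedCurve, shape, pixel_spacing):
    """Boolean image of pixels whose centers lie between the two contours."""
    gx, gy = pixel_centers(shape, pixel_spacing)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_outer = MplPath(outer.polygon(512)[:, :2]).contains_points(pts)
    in_inner = MplPath(inner.polygon(512)[:, :2]).contains_points(pts)
    return (in_outer & ~in_inner).reshape(shape)


def build_wall_mask(
    inner: ClosedCurve,
    outer: ClosedCurve,
    magnitude: np.ndarray,
    pixel_spacing,
    exclusion_fraction: float = 0.3,
) -> np.ndarray:
    """Wall-pixel mask with low-magnitude exclusion.

    Pixels between the contours are kept when their magnitude is at least
    ``exclusion_fraction`` times the median magnitude of all between-contour
    pixels; low-magnitude pixels carry unreliable phase and are dropped.
    """
    if not 0.0 <= exclusion_fraction < 1.0:
        raise ParameterError("exclusion_fraction must be in [0, 1)")
    geo = annulus_pixels(inner, outer, magnitude.shape, pixel_spacing)
    if not geo.any():
        raise DegenerateInputError("no pixel centers lie between the contours")
    threshold = exclusion_fraction * np.median(magnitude[geo])
    mask = geo & (magnitude >= threshold)
    if not mask.any():
        raise DegenerateInputError("all wall pixels excluded by the magnitude rule")
    return mask
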