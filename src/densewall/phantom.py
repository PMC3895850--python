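"""Synthetic DENSE acquisitions of a deforming annulus with known stretch.

No aortic DENSE data is publicly deposited, so recovery tests run against
this phantom: an annular "wall" (black-blood lumen, low background) on a
coarse pixel grid, deformed by a circumferential stretch pattern

    s(theta) = s0 + sum_k a_k cos(k theta + phi_k)

composed with a rigid in-plane rotation and a constant through-plane shift.
The forward map scales the mid-wall radius by ``s(theta)`` while preserving
wall thickness (pure circumferential stretch), which gives a closed-form
ground-truth stretch profile while reproducing the expand-and-rotate
phenomenology seen in vivo.

Phase images follow the DENSE contract ``phi = 2*pi*k_e*(u . e)`` (wrapped),
where ``u`` carries tissue from the encoded expanded state to the resting
readout state.  Noise is complex Gaussian, added to the real and imaginary
channels before magnitude/phase extraction, reproducing the
magnitude-dependent phase noise that motivates certainty weighting.  Pixel
magnitude is the analytically computed area fraction of the annulus covering
the pixel, so partial-volume edge pixels exercise the low-magnitude
exclusion rule realistically.

Angles use the anatomical convention of :mod:`densewall.geometry`
(theta = 0 anterior, increasing toward patient right).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .geometry import (
    ClosedCurve,
    WallDelineation,
    build_wall_mask,
    circumferential_angle,
    fit_closed_curve,
    pixel_centers,
    unit_vector_at_angle,
)
from .io import DenseAcquisition
from .phase import wrap_phase

TWO_PI = 2.0 * np.pi

#: balanced four-point encoding directions (vertices of a regular tetrahedron
#: on the unit sphere); the first acquisition serves as the reference
TETRAHEDRAL_DIRECTIONS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class StretchPattern:
    """Circumferential stretch s(theta) = s0 + sum a_k cos(k theta + phi_k)."""

    s0: float = 1.0
    harmonics: tuple = ()  # ((a_1, phi_1), (a_2, phi_2), ...)

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        s = np.full_like(theta, self.s0, dtype=float)
        for k, (a_k, phi_k) in enumerate(self.harmonics, start=1):
            s = s + a_k * np.cos(k * theta + phi_k)
        return s

    def derivative(self, theta):
        theta = np.asarray(theta, dtype=float)
        ds = np.zeros_like(theta, dtype=float)
        for k, (a_k, phi_k) in enumerate(self.harmonics, start=1):
            ds = ds - k * a_k * np.sin(k * theta + phi_k)
        return ds


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic acquisition.

    Geometry defaults emulate the published acquisitions: 2.3 mm pixels,
    8 mm slice, a 2.5 mm wall (aortic walls are of the order of 2-3 mm)
    around a 15 mm mid-wall radius, and an encoding frequency of
    0.08 cycles/mm from the reported 0.08-0.11 range.  ``snr`` is the ratio
    of wall magnitude to the per-channel complex noise standard deviation
    (``inf`` disables noise).
    """

    grid_size: int = 64
    pixel_spacing: float = 2.3  # mm
    center: tuple | None = None  # (x, y) mm; None = grid centre
    mid_radius: float = 15.0  # mm
    wall_thickness: float = 2.5  # mm
    stretch_pattern: StretchPattern = field(default_factory=lambda: StretchPattern(1.06))
    rotation: float = 0.0  # rad, counter-clockwise in (x, y)
    translation: tuple = (0.0, 0.0)  # mm, rigid in-plane shift between states
    through_plane_shift: float = 0.0  # mm
    wall_magnitude: float = 1.0
    lumen_magnitude: float = 0.05
    snr: float = np.inf
    k_e: float = 0.08  # cycles/mm
    seed: int = 0
    encoding_directions: tuple | None = None  # None = balanced tetrahedral set

    def validate(self):
        if self.grid_size < 8 or self.pixel_spacing <= 0:
            raise ParameterError("grid_size >= 8 and pixel_spacing > 0 required")
        if self.wall_thickness <= 0:
            raise ParameterError("wall_thickness must be positive")
        if self.mid_radius <= self.wall_thickness / 2:
            raise ParameterError("annulus self-intersects: mid_radius <= thickness/2")
        theta = np.linspace(0, TWO_PI, 4096, endpoint=False)
        if np.min(self.stretch_pattern(theta)) <= 0:
            raise ParameterError("stretch pattern s(theta) must stay positive")
        if not self.lumen_magnitude < self.wall_magnitude:
            raise ParameterError("black-blood contract: lumen_magnitude < wall_magnitude")
        if not self.snr > 0:
            raise ParameterError("snr must be positive (inf allowed)")
        if self.k_e <= 0:
            raise ParameterError("k_e must be positive")

    @property
    def center_mm(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        half = (self.grid_size - 1) / 2.0 * self.pixel_spacing
        return np.array([half, half])

    @property
    def directions(self) -> np.ndarray:
        if self.encoding_directions is None:
            return TETRAHEDRAL_DIRECTIONS.copy()
        return np.asarray(self.encoding_directions, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stretch_pattern"] = {
            "s0": self.stretch_pattern.s0,
            "harmonics": [list(h) for h in self.stretch_pattern.harmonics],
        }
        d["snr"] = "inf" if np.isinf(self.snr) else self.snr
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if isinstance(d.get("stretch_pattern"), dict):
            sp = d["stretch_pattern"]
            d["stretch_pattern"] = StretchPattern(
                s0=float(sp.get("s0", 1.0)),
                harmonics=tuple(tuple(h) for h in sp.get("harmonics", ())),
            )
        if isinstance(d.get("snr"), str):
            d["snr"] = np.inf
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        if d.get("translation") is not None:
            d["translation"] = tuple(d["translation"])
        if d.get("encoding_directions") is not None:
            d["encoding_directions"] = tuple(
                tuple(row) for row in d["encoding_directions"]
            )
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic truth accompanying a phantom acquisition."""

    displacement: np.ndarray  # (ny, nx, 3) mm at pixel centers
    spec: PhantomSpec
    contours: dict  # {('inner'|'outer'|'mid', 'rest'|'deformed'): ClosedCurve}

    def stretch_of_theta(self, thetas):
        """True circumferential mid-wall stretch at the given angles."""
        return analytic_stretch_profile(self.spec, thetas)


# ---------------------------------------------------------------------------
# exact circle/pixel overlap (partial-volume rendering)


def _circle_area_integral(x, r):
    """Antiderivative of sqrt(r^2 - x^2)."""
    x = np.clip(x, -r, r)
    return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0)) + r * r * np.arcsin(x / r))


def circle_rectangle_area(cx, cy, r, x0, y0, x1, y1) -> float:
    """Exact area of the intersection of a disk and an axis-aligned rectangle.

    Piecewise-analytic integration of the clipped chord height; breakpoints
    are placed where the circle crosses the rectangle's horizontal edges so
    the integrand branch is constant on each sub-interval.
    """
    a, b = x0 - cx, x1 - cx
    yl, yh = y0 - cy, y1 - cy
    lo, hi = max(a, -r), min(b, r)
    if lo >= hi or yl >= r or yh <= -r:
        return 0.0
    brk = {lo, hi}
    for y_edge in (yl, yh):
        if abs(y_edge) < r:
            xc = np.sqrt(r * r - y_edge * y_edge)
            for x_edge in (-xc, xc):
                if lo < x_edge < hi:
                    brk.add(float(x_edge))
    xs = sorted(brk)
    area = 0.0
    for p, q in zip(xs[:-1], xs[1:]):
        m = 0.5 * (p + q)
        g = np.sqrt(max(r * r - m * m, 0.0))
        top = min(yh, g)
        bot = max(yl, -g)
        if top <= bot:
            continue
        if g < yh:  # top follows the circle
            upper = _circle_area_integral(q, r) - _circle_area_integral(p, r)
        else:
            upper = yh * (q - p)
        if -g > yl:  # bottom follows the circle
            lower = -(_circle_area_integral(q, r) - _circle_area_integral(p, r))
        else:
            lower = yl * (q - p)
        area += upper - lower
    return float(area)


def disk_coverage(center, radius, shape, pixel_spacing) -> np.ndarray:
    """Per-pixel area fraction covered by a disk; exact on boundary pixels."""
    gx, gy = pixel_centers(shape, (pixel_spacing, pixel_spacing))
    h = pixel_spacing / 2.0
    cx, cy = center
    d = np.hypot(gx - cx, gy - cy)
    diag = np.sqrt(2.0) * h
    frac = np.zeros(shape)
    frac[d <= radius - diag] = 1.0
    boundary = (d < radius + diag) & (d > radius - diag)
    px_area = pixel_spacing ** 2
    for i, j in zip(*np.nonzero(boundary)):
        x, y = gx[i, j], gy[i, j]
        frac[i, j] = (
            circle_rectangle_area(cx, cy, radius, x - h, y - h, x + h, y + h)
            / px_area
        )
    return frac


# ---------------------------------------------------------------------------
# deformation model


def _rotation_matrix(alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s], [s, c]])


def deform_points(spec: PhantomSpec, points_xy) -> np.ndarray:
    """Forward map: resting in-plane points -> deformed 3-D positions (mm)."""
    p = np.atleast_2d(np.asarray(points_xy, dtype=float))
    c = spec.center_mm
    d = p - c
    r = np.linalg.norm(d, axis=1)
    theta = circumferential_angle(p, c)
    s = spec.stretch_pattern(theta)
    r_new = s * spec.mid_radius + (r - spec.mid_radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        ray = np.where(r[:, None] > 1e-12, d / np.maximum(r, 1e-12)[:, None], 0.0)
    xy = (
        (r_new[:, None] * ray) @ _rotation_matrix(spec.rotation).T
        + c
        + np.asarray(spec.translation, dtype=float)
    )
    out = np.column_stack([xy, np.full(len(p), spec.through_plane_shift)])
    return out


def true_displacement(spec: PhantomSpec, points_xy) -> np.ndarray:
    """DENSE displacement u = resting position - deformed position (3-D)."""
    p = np.atleast_2d(np.asarray(points_xy, dtype=float))
    deformed = deform_points(spec, p)
    rest = np.column_stack([p, np.zeros(len(p))])
    return rest - deformed


def _material_circle(spec: PhantomSpec, rho: float, deformed: bool) -> ClosedCurve:
    """Curve traced by the material circle of resting radius ``rho``."""
    c = spec.center_mm

    def rest_fun(t):
        theta = TWO_PI * np.asarray(t)
        return c + rho * unit_vector_at_angle(theta)

    if not deformed:
        return ClosedCurve.from_function(rest_fun)

    rot = _rotation_matrix(spec.rotation)

    def def_fun(t):
        theta = TWO_PI * np.asarray(t)
        r_new = spec.stretch_pattern(theta) * spec.mid_radius + (rho - spec.mid_radius)
        return (
            (r_new[:, None] * unit_vector_at_angle(theta)) @ rot.T
            + c
            + np.asarray(spec.translation, dtype=float)
        )

    return ClosedCurve.from_function(def_fun)


def analytic_stretch_profile(spec: PhantomSpec, thetas, tol: float = 1e-8):
    """True circumferential stretch of the mid-wall at the given angles.

    Ratio of deformed to resting arc-length density |dC_sys/dtheta| /
    |dC_dia/dtheta|, by central differences with step halving until the
    result changes by less than ``tol``.
    """
    spec.validate()
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    c = spec.center_mm
    rot = _rotation_matrix(spec.rotation)

    def sys_point(theta):
        r = spec.stretch_pattern(theta) * spec.mid_radius
        return (
            (r[..., None] * unit_vector_at_angle(theta)) @ rot.T
            + c
            + np.asarray(spec.translation, dtype=float)
        )

    def dia_point(theta):
        return c + spec.mid_radius * unit_vector_at_angle(theta)

    def density(fun, theta, h):
        return np.linalg.norm(
            (fun(theta + h) - fun(theta - h)) / (2 * h), axis=-1
        )

    h = 1e-4
    prev = density(sys_point, thetas, h) / density(dia_point, thetas, h)
    for _ in range(8):
        h /= 2.0
        cur = density(sys_point, thetas, h) / density(dia_point, thetas, h)
        if np.max(np.abs(cur - prev)) < tol:
            return cur if cur.size > 1 else float(cur[0])
        prev = cur
    return prev if prev.size > 1 else float(prev[0])


# ---------------------------------------------------------------------------
# acquisition synthesis


def make_phantom(
    spec: PhantomSpec, exclusion_fraction: float = 0.3
) -> tuple[DenseAcquisition, GroundTruth, WallDelineation]:
    """Synthesize one DENSE acquisition of the deforming annulus.

    Returns the acquisition (magnitude + wrapped per-encoding phases), the
    analytic ground truth, and the resting-state wall delineation (contours
    fitted through points on the true circles, mask with the given
    low-magnitude exclusion fraction).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    n = spec.grid_size
    shape = (n, n)
    c = spec.center_mm
    r_in = spec.mid_radius - spec.wall_thickness / 2.0
    r_out = spec.mid_radius + spec.wall_thickness / 2.0

    frac_out = disk_coverage(c, r_out, shape, spec.pixel_spacing)
    frac_in = disk_coverage(c, r_in, shape, spec.pixel_spacing)
    mag_true = spec.wall_magnitude * (frac_out - frac_in) + spec.lumen_magnitude * frac_in

    gx, gy = pixel_centers(shape, (spec.pixel_spacing, spec.pixel_spacing))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    u = true_displacement(spec, pts).reshape(n, n, 3)

    dirs = spec.directions
    phases_true = wrap_phase(
        TWO_PI * spec.k_e * np.tensordot(dirs, np.moveaxis(u, -1, 0), axes=(1, 0))
    )

    if np.isinf(spec.snr):
        magnitude = mag_true
        phases = phases_true
    else:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.wall_magnitude / spec.snr
        z = mag_true[None] * np.exp(1j * phases_true)
        z = z + sigma * (
            rng.standard_normal(z.shape) + 1j * rng.standard_normal(z.shape)
        )
        magnitude = np.abs(z).mean(axis=0)
        phases = wrap_phase(np.angle(z))

    acq = DenseAcquisition(
        magnitude=magnitude,
        phases=phases,
        encoding_directions=dirs,
        k_e=spec.k_e,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_thickness=8.0,
    )

    contours = {}
    for role, rho in (("inner", r_in), ("outer", r_out), ("mid", spec.mid_radius)):
        for state, deformed in (("rest", False), ("deformed", True)):
            contours[(role, state)] = _material_circle(spec, rho, deformed)
    truth = GroundTruth(displacement=u, spec=spec, contours=contours)

    def circle_points(rho, m=24):
        theta = np.linspace(0.0, TWO_PI, m, endpoint=False)
        return c + rho * unit_vector_at_angle(theta)

    inner = fit_closed_curve(circle_points(r_in))
    outer = fit_closed_curve(circle_points(r_out))
    mid = fit_closed_curve(circle_points(spec.mid_radius))
    mask = build_wall_mask(
        inner, outer, magnitude, (spec.pixel_spacing, spec.pixel_spacing),
        exclusion_fraction,
    )
    delin = WallDelineation(inner=inner, outer=outer, mid=mid, mask=mask)
    return acq, truth, delin


def make_cine_series(spec: PhantomSpec, n_frames: int, seed=None,
                     jitter_mm: float = 0.0, n_vertices: int = 120):
    """Synthetic cine lumen-contour series between rest and full deformation.

    Frame ``f`` interpolates the lumen contour with the half-cycle
    raised-cosine weight ``w = (1 - cos(pi f/(n-1)))/2`` so the first frame
    is exactly the resting lumen (minimum area) and the last exactly the
    fully deformed lumen (maximum area) for any ``n_frames >= 2``.  The
    deformed lumen is the resting lumen scaled by ``s(theta)`` (and rotated),
    emulating the cross-section the cine modality sees.  Optional Gaussian
    vertex jitter (mm) is controlled by ``seed``.
    """
    from .stats import AreaSeries

    spec.validate()
    if n_frames < 2:
        raise ParameterError("a cine series needs at least 2 frames")
    rho = spec.mid_radius - spec.wall_thickness / 2.0
    c = spec.center_mm
    theta = np.linspace(0.0, TWO_PI, n_vertices, endpoint=False)
    ray = unit_vector_at_angle(theta)
    s = spec.stretch_pattern(theta)
    rng = np.random.default_rng(seed) if jitter_mm > 0 else None
    contours = []
    for f in range(n_frames):
        w = 0.5 * (1.0 - np.cos(np.pi * f / (n_frames - 1)))
        r_f = rho * ((1.0 - w) + w * s)
        rot = _rotation_matrix(w * spec.rotation)
        poly = (
            (r_f[:, None] * ray) @ rot.T
            + c
            + w * np.asarray(spec.translation, dtype=float)
        )
        if rng is not None:
            poly = poly + rng.normal(scale=jitter_mm, size=poly.shape)
        contours.append(poly)
    return AreaSeries(contours=contours)


# ---------------------------------------------------------------------------
# ground-truth sidecar i/o


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "displacement.npy", truth.displacement)
    (path / "spec.json").write_text(
        json.dumps(truth.spec.to_dict(), indent=1, sort_keys=True)
    )
    return path


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    spec = PhantomSpec.from_dict(json.loads((path / "spec.json").read_text()))
    displacement = np.load(path / "displacement.npy")
    r_in = spec.mid_radius - spec.wall_thickness / 2.0
    r_out = spec.mid_radius + spec.wall_thickness / 2.0
    contours = {
        (role, state): _material_circle(spec, rho, state == "deformed")
        for role, rho in (("inner", r_in), ("outer", r_out), ("mid", spec.mid_radius))
        for state in ("rest", "deformed")
    }
    return GroundTruth(displacement=displacement, spec=spec, contours=contours)
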