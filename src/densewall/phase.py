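"""Phase processing: certainty-weighted smoothing, unwrapping, decoding.

The DENSE signal stores tissue displacement in its phase,
``phi = 2*pi*k_e*(u . e)`` for encoding direction ``e`` and encoding
frequency ``k_e`` (cycles/mm), so the measured phase is known only modulo
2*pi and its noise grows as signal magnitude falls.  The stage therefore

1. smooths each wrapped phase image by normalized convolution on the
   unit-complex representation, weighting pixels by a certainty derived
   from the signal magnitude (Gaussian applicability, default sigma of one
   pixel);
2. unwraps the reference-subtracted phases with a least-squares (Poisson)
   solver on the full rectangular grid, with gradients that cross
   non-wall pixels removed;
3. decodes per-pixel 3-D displacement from the net encoding directions by
   linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import gaussian_filter

from .errors import (
    DegenerateInputError,
    EncodingConfigurationError,
    ParameterError,
)
from .io import DenseAcquisition

TWO_PI = 2.0 * np.pi

#: relative floor on the normalized-convolution denominator below which an
#: output pixel is flagged invalid instead of being divided by near-zero
DENOMINATOR_FLOOR = 1e-3


def wrap_phase(phi):
    """Wrap angles to the principal interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), TWO_PI)


def certainty_from_magnitude(magnitude, mask=None, exponent: float = 1.0):
    """Per-pixel certainty ``magnitude**exponent``, zeroed outside ``mask``.

    Larger signal magnitude means more reliable phase, so magnitude is the
    natural certainty.  The exponent is configurable; 1 (linear) is the
    default.
    """
    c = np.asarray(magnitude, dtype=float) ** exponent
    if mask is not None:
        c = np.where(mask, c, 0.0)
    if np.any(c < 0):
        raise ParameterError("certainty must be non-negative")
    return c


@dataclass
class DisplacementField:
    """Per-pixel 3-component displacement (mm) with validity and certainty.

    ``u[..., :2]`` is the in-plane displacement along image x and y,
    ``u[..., 2]`` the through-plane component.  ``u`` carries tissue from
    the encoded (expanded) state to the readout (resting) state, so the
    expanded position of a resting point p is ``p - u(p)``.
    Invalid pixels are flagged, never silently zero.
    """

    u: np.ndarray  # (ny, nx, 3) mm
    valid: np.ndarray  # (ny, nx) bool
    certainty: np.ndarray  # (ny, nx) >= 0
    pixel_spacing: tuple = (1.0, 1.0)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.certainty = np.asarray(self.certainty, dtype=float)
        if self.u.ndim != 3 or self.u.shape[-1] != 3:
            raise ParameterError("displacement array must be (ny, nx, 3)")
        if not np.all(np.isfinite(self.u[self.valid])):
            raise ParameterError("non-finite displacement on valid pixels")


def normalized_average(phase, certainty, sigma_px: float = 1.0):
    """Certainty-weighted Gaussian smoothing of a wrapped phase image.

    Normalized convolution on the unit-complex representation,
    ``arg(G_sigma * (c e^{i phi}) / G_sigma * c)``, so phase wraps are
    respected and zero-certainty pixels borrow values from reliable
    neighbours.  Returns ``(smoothed_phase, valid)`` where ``valid`` flags
    pixels whose denominator exceeded a small floor.
    """
    phase = np.asarray(phase, dtype=float)
    c = np.asarray(certainty, dtype=float)
    if sigma_px <= 0:
        raise ParameterError("sigma_px must be positive")
    if phase.shape != c.shape:
        raise ParameterError("phase and certainty shapes differ")
    if not np.any(c > 0):
        raise DegenerateInputError("certainty is zero everywhere")
    num_re = gaussian_filter(c * np.cos(phase), sigma_px, mode="constant")
    num_im = gaussian_filter(c * np.sin(phase), sigma_px, mode="constant")
    den = gaussian_filter(c, sigma_px, mode="constant")
    valid = den > DENOMINATOR_FLOOR * den.max()
    out = np.zeros_like(phase)
    out[valid] = np.arctan2(num_im[valid], num_re[valid])
    return wrap_phase(out), valid


def _solve_poisson_neumann(rho):
    """Solve  laplacian(phi) = rho  with Neumann conditions via DCT-II."""
    ny, nx = rho.shape
    wy = 2.0 * (np.cos(np.pi * np.arange(ny) / ny) - 1.0)
    wx = 2.0 * (np.cos(np.pi * np.arange(nx) / nx) - 1.0)
    denom = wy[:, None] + wx[None, :]
    denom[0, 0] = 1.0
    rho_hat = dctn(rho, type=2, norm="ortho")
    phi_hat = rho_hat / denom
    phi_hat[0, 0] = 0.0
    return idctn(phi_hat, type=2, norm="ortho")


def _weighted_median(values, weights):
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return float(np.median(values))
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def _weighted_divergence(gx, gy, shape):
    rho = np.zeros(shape)
    rho[:, :-1] += gx
    rho[:, 1:] -= gx
    rho[:-1, :] += gy
    rho[1:, :] -= gy
    return rho


def unwrap_poisson(phase, mask=None, certainty=None, tol: float = 1e-9,
                   max_iter: int = 300):
    """Weighted least-squares phase unwrapping on a rectangular grid.

    Wrapped first differences are computed in x and y; each difference is
    weighted by the smaller certainty of its two pixels (zero when either
    pixel is outside ``mask``, which confines information flow to the wall).
    The weighted normal equations — a discrete Poisson problem with Neumann
    boundary conditions — are solved by conjugate gradients preconditioned
    with the unweighted cosine-transform Poisson solver; with uniform
    weights the first iteration is already exact.  The continuous solution
    is then snapped to congruence with the input (each output pixel equals
    the wrapped input plus the nearest integer multiple of 2*pi) and the
    additive constant is fixed so the certainty-weighted median offset over
    the mask becomes the nearest multiple of 2*pi.

    Returns values over the full grid; only masked pixels are meaningful to
    downstream consumers.
    """
    phase = np.asarray(phase, dtype=float)
    mask = np.ones(phase.shape, bool) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("unwrap_poisson: empty mask")
    w = np.ones(phase.shape) if certainty is None else np.asarray(certainty, float)
    w = np.where(mask, w, 0.0)
    wmax = w.max()
    if wmax <= 0:
        raise DegenerateInputError("unwrap_poisson: certainty is zero on the mask")
    w = w / wmax
    wx = np.minimum(w[:, 1:], w[:, :-1])
    wy = np.minimum(w[1:, :], w[:-1, :])

    gx = wrap_phase(np.diff(phase, axis=1))
    gy = wrap_phase(np.diff(phase, axis=0))
    b = _weighted_divergence(wx * gx, wy * gy, phase.shape)

    def apply_q(u):
        return _weighted_divergence(
            wx * np.diff(u, axis=1), wy * np.diff(u, axis=0), u.shape
        )

    # preconditioned conjugate gradients on the weighted normal equations
    u = np.zeros_like(phase)
    r = b.copy()
    b_norm = np.linalg.norm(b)
    if b_norm > 0:
        rz_prev, p = 0.0, None
        for _ in range(max_iter):
            z = _solve_poisson_neumann(r)
            rz = float(np.sum(r * z))
            p = z if p is None else z + (rz / rz_prev) * p
            qp = apply_q(p)
            denom = float(np.sum(p * qp))
            if denom == 0.0:
                break
            alpha = rz / denom
            u += alpha * p
            r -= alpha * qp
            rz_prev = rz
            if np.linalg.norm(r) <= tol * b_norm:
                break

    # centre the solution on its weighted-median offset (the additive
    # constant is arbitrary), then snap to congruence: keep the measured
    # wrapped values, using the least-squares solution only to choose the
    # per-pixel 2*pi branch
    m0 = _weighted_median((u - phase)[mask], w[mask])
    out = phase + TWO_PI * np.round((u - m0 - phase) / TWO_PI)
    m1 = _weighted_median((out - phase)[mask], w[mask])
    out = out - TWO_PI * np.round(m1 / TWO_PI)
    return out


def _net_system(acq: DenseAcquisition):
    ref = acq.reference_index
    others = [i for i in range(acq.n_encodings) if i != ref]
    net_dirs = acq.encoding_directions[others] - acq.encoding_directions[ref]
    return ref, others, net_dirs


def solve_encoding_system(net_phases, net_directions, k_e, require_3d: bool = True):
    """Least-squares decode of displacement from net (reference-subtracted)
    phases: solves ``(2 pi k_e) D u = phi`` per pixel.

    With ``require_3d`` (default) the net direction set must span 3-D;
    otherwise the minimum-norm solution in the spanned subspace is returned.
    """
    D = np.asarray(net_directions, dtype=float)
    phi = np.asarray(net_phases, dtype=float)
    if phi.shape[0] != D.shape[0]:
        raise ParameterError("one net phase image per net direction required")
    _, S, Vh = np.linalg.svd(D)
    rank = int(np.sum(S > 1e-10 * max(S[0], 1e-300)))
    if require_3d and rank < 3:
        null_dirs = Vh[rank:]
        raise EncodingConfigurationError(
            "encoding directions do not span 3-D displacement; "
            f"unsensed direction(s): {np.round(null_dirs, 6).tolist()}"
        )
    pinv = np.linalg.pinv(D) / (TWO_PI * float(k_e))
    u = np.tensordot(pinv, phi, axes=(1, 0))  # (3, ny, nx)
    return np.moveaxis(u, 0, -1)


def decode_displacement(
    acq: DenseAcquisition,
    phases=None,
    mask=None,
    certainty=None,
    require_3d: bool = True,
) -> DisplacementField:
    """Decode per-pixel displacement from processed per-acquisition phases.

    ``phases`` (default: the stored wrapped phases) are the smoothed and —
    where wraps occur — unwrapped phase images, one per acquisition.  The
    reference acquisition's phase is subtracted before the per-pixel linear
    solve, so the phantom's zero reference phase is not assumed.
    """
    phases = acq.phases if phases is None else np.asarray(phases, dtype=float)
    ref, others, net_dirs = _net_system(acq)
    net_phases = phases[others] - phases[ref]
    u = solve_encoding_system(net_phases, net_dirs, acq.k_e, require_3d=require_3d)
    if certainty is None:
        certainty = certainty_from_magnitude(acq.magnitude, mask)
    valid = np.ones(acq.magnitude.shape, bool) if mask is None else np.asarray(mask, bool)
    return DisplacementField(
        u=u, valid=valid, certainty=np.where(valid, certainty, 0.0),
        pixel_spacing=acq.pixel_spacing,
    )


def process_acquisition(
    acq: DenseAcquisition,
    mask,
    sigma_px: float = 1.0,
    certainty_exponent: float = 1.0,
) -> DisplacementField:
    """Full phase stage: smooth -> reference-subtract -> unwrap -> decode.

    Each acquisition's wrapped phase is smoothed by normalized averaging,
    net phases are formed against the reference acquisition (as wrapped
    differences), each net phase is unwrapped with the masked Poisson
    solver, and the displacement is decoded per pixel.
    """
    certainty = certainty_from_magnitude(acq.magnitude, mask, certainty_exponent)
    smoothed = np.empty_like(acq.phases)
    valid = np.asarray(mask, bool).copy()
    for i in range(acq.n_encodings):
        smoothed[i], ok = normalized_average(acq.phases[i], certainty, sigma_px)
        valid &= ok
    ref, others, net_dirs = _net_system(acq)
    net = wrap_phase(smoothed[others] - smoothed[ref])
    unwrapped = np.stack(
        [unwrap_poisson(p, mask=valid, certainty=certainty) for p in net]
    )
    u = solve_encoding_system(unwrapped, net_dirs, acq.k_e)
    return DisplacementField(
        u=u, valid=valid, certainty=np.where(valid, certainty, 0.0),
        pixel_spacing=acq.pixel_spacing,
    )
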