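"""On-disk containers shared by all pipeline stages.

An acquisition lives in one directory per slice::

    acq/
      magnitude.npy   float image, arbitrary signal units
      phases.npy      (n_enc, ny, nx) wrapped phases in (-pi, pi]
      meta.json       k_e, pixel_spacing, slice_thickness, encoding_directions

Contours are plain text, one point per line, with a header line per record::

    # contour role=inner frame=0 closed=1
    12.3  4.56

The `.npy`/JSON layout keeps every byte deterministic for a given input,
which the pipeline manifest relies on.  A DICOM import adapter is provided
for scanner data; it requires an explicit phase rescale because stored phase
scaling is vendor-specific.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

_META_KEYS = ("k_e", "pixel_spacing", "slice_thickness", "encoding_directions")


@dataclass
class DenseAcquisition:
    """One displacement-encoded slice: magnitude plus per-encoding phase images.

    Parameters
    ----------
    magnitude : (ny, nx) array, signal units
    phases : (n_enc, ny, nx) array of wrapped phases in (-pi, pi]
    encoding_directions : (n_enc, 3) array
        Unit displacement-sensitivity direction per acquisition; an all-zero
        row marks an explicit reference acquisition.
    k_e : float, cycles/mm
        Displacement-encoding frequency: phase = 2*pi*k_e*(u . direction).
    pixel_spacing : (dx, dy) mm
    slice_thickness : float, mm
    """

    magnitude: np.ndarray
    phases: np.ndarray
    encoding_directions: np.ndarray
    k_e: float
    pixel_spacing: tuple
    slice_thickness: float

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        self.encoding_directions = np.asarray(self.encoding_directions, dtype=float)
        self.pixel_spacing = tuple(float(v) for v in self.pixel_spacing)
        self.k_e = float(self.k_e)
        self.slice_thickness = float(self.slice_thickness)
        self.validate()

    def validate(self):
        if self.magnitude.ndim != 2:
            raise ValidationError("magnitude must be a 2-D image")
        if self.phases.ndim != 3 or self.phases.shape[1:] != self.magnitude.shape:
            raise ValidationError("phase images must share the magnitude shape")
        if self.encoding_directions.shape != (self.phases.shape[0], 3):
            raise ValidationError(
                "need one 3-vector encoding direction per phase image"
            )
        if np.any(self.phases > np.pi) or np.any(self.phases <= -np.pi):
            bad = float(
                self.phases[(self.phases > np.pi) | (self.phases <= -np.pi)].flat[0]
            )
            raise ValidationError(
                f"phase value {bad:g} outside the wrapped range (-pi, pi]"
            )
        if not self.k_e > 0:
            raise ValidationError("k_e must be positive")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel_spacing must be positive")

    @property
    def n_encodings(self) -> int:
        return self.phases.shape[0]

    @property
    def reference_index(self) -> int:
        """Index of the reference acquisition: the all-zero direction row if
        exactly one exists, otherwise acquisition 0 (balanced sets)."""
        zero = np.where(~self.encoding_directions.any(axis=1))[0]
        return int(zero[0]) if zero.size == 1 else 0


def write_acquisition(acq: DenseAcquisition, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "magnitude.npy", acq.magnitude)
    np.save(path / "phases.npy", acq.phases)
    meta = {
        "k_e": acq.k_e,
        "pixel_spacing": list(acq.pixel_spacing),
        "slice_thickness": acq.slice_thickness,
        "encoding_directions": acq.encoding_directions.tolist(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_acquisition(path) -> DenseAcquisition:
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"missing meta.json in {path}") from exc
    for key in _META_KEYS:
        if key not in meta:
            raise FormatError(f"acquisition metadata lacks required key '{key}'")
    try:
        magnitude = np.load(path / "magnitude.npy")
        phases = np.load(path / "phases.npy")
    except FileNotFoundError as exc:
        raise FormatError(f"missing array file in {path}: {exc}") from exc
    return DenseAcquisition(
        magnitude=magnitude,
        phases=phases,
        encoding_directions=np.asarray(meta["encoding_directions"], dtype=float),
        k_e=meta["k_e"],
        pixel_spacing=tuple(meta["pixel_spacing"]),
        slice_thickness=meta["slice_thickness"],
    )


# ---------------------------------------------------------------------------
# contour files

ROLES = ("inner", "outer", "mid", "lumen")


@dataclass
class ContourRecord:
    """Ordered control points of one delineated contour."""

    points: np.ndarray  # (n, 2) mm
    role: str = "mid"
    frame: int = 0
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.role not in ROLES:
            raise ValidationError(f"contour role must be one of {ROLES}")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("contour points must be (n, 2)")
        if self.closed and self.points.shape[0] < 4:
            raise ValidationError("a closed contour needs at least 4 points")
        if np.any(np.all(np.isclose(np.diff(self.points, axis=0), 0), axis=1)):
            raise ValidationError("duplicated consecutive contour points")


def write_contours(records, path) -> Path:
    path = Path(path)
    lines = []
    for rec in records:
        lines.append(
            f"# contour role={rec.role} frame={rec.frame} closed={int(rec.closed)}"
        )
        for x, y in rec.points:
            lines.append(f"{x:.17g} {y:.17g}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def read_contours(path) -> list:
    path = Path(path)
    records, header, pts = [], None, []

    def flush():
        if header is not None:
            records.append(ContourRecord(points=np.array(pts, dtype=float), **header))

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            flush()
            fields = dict(
                tok.split("=", 1) for tok in line.lstrip("# ").split()[1:]
            )
            if "role" not in fields:
                raise FormatError("contour header lacks 'role'")
            header = {
                "role": fields["role"],
                "frame": int(fields.get("frame", 0)),
                "closed": bool(int(fields.get("closed", 1))),
            }
            pts = []
        else:
            if header is None:
                raise FormatError("contour point before any '# contour' header")
            vals = line.split()
            if len(vals) != 2:
                raise FormatError(f"expected 'x y' per line, got: {line!r}")
            pts.append([float(vals[0]), float(vals[1])])
    flush()
    if not records:
        raise FormatError(f"no contour records found in {path}")
    return records


# ---------------------------------------------------------------------------
# displacement-field container (arrays produced by the phase pipeline)


def write_displacement(field, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "u.npy", field.u)
    np.save(path / "certainty.npy", field.certainty)
    np.save(path / "valid.npy", field.valid)
    meta = {"pixel_spacing": list(field.pixel_spacing)}
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_displacement(path):
    from .phase import DisplacementField  # local import avoids a cycle

    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
        u = np.load(path / "u.npy")
        certainty = np.load(path / "certainty.npy")
        valid = np.load(path / "valid.npy")
    except FileNotFoundError as exc:
        raise FormatError(f"incomplete displacement container in {path}: {exc}")
    if "pixel_spacing" not in meta:
        raise FormatError("displacement metadata lacks required key 'pixel_spacing'")
    return DisplacementField(
        u=u, certainty=certainty, valid=valid,
        pixel_spacing=tuple(meta["pixel_spacing"]),
    )


# ---------------------------------------------------------------------------
# optional DICOM import


def import_dicom_acquisition(
    magnitude_file,
    phase_files,
    encoding_directions,
    k_e: float,
    phase_slope: float,
    phase_intercept: float,
) -> DenseAcquisition:
    """Build a :class:`DenseAcquisition` from a DICOM magnitude/phase series.

    ``phase_slope``/``phase_intercept`` map stored pixel values to radians in
    (-pi, pi]; they must be supplied explicitly because phase scaling is
    scanner-specific.  Only pixel data, PixelSpacing and SliceThickness are
    consumed; vendor private tags are ignored.
    """
    import pydicom

    mag_ds = pydicom.dcmread(str(magnitude_file))
    magnitude = mag_ds.pixel_array.astype(float)
    spacing = [float(v) for v in mag_ds.PixelSpacing]  # (row, col) mm
    thickness = float(getattr(mag_ds, "SliceThickness", 0.0))
    phases = []
    for f in phase_files:
        ds = pydicom.dcmread(str(f))
        phases.append(ds.pixel_array.astype(float) * phase_slope + phase_intercept)
    return DenseAcquisition(
        magnitude=magnitude,
        phases=np.stack(phases),
        encoding_directions=np.asarray(encoding_directions, dtype=float),
        k_e=k_e,
        pixel_spacing=(spacing[1], spacing[0]),
        slice_thickness=thickness,
    )
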