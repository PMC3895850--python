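"""End-to-end orchestration: simulate -> process -> stretch -> report.

A run is driven by a single plain-text (YAML) configuration and writes a
run directory with per-stage outputs plus ``manifest.json`` recording the
configuration hash, seed, package version and a checksum per output file.
All stage outputs are byte-deterministic for a given configuration, so
re-running an identical configuration reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, StageError
from .geometry import WallDelineation, build_wall_mask, fit_closed_curve
from .io import (
    ContourRecord,
    read_acquisition,
    read_contours,
    write_acquisition,
    write_contours,
    write_displacement,
)
from .phantom import PhantomSpec, make_cine_series, make_phantom, write_ground_truth
from .phase import process_acquisition
from .stats import relative_area_change
from .tracking import fit_periodic_spline, quadrant_summary, seed_points, stretch_profile, track_points

log = logging.getLogger("densewall")

_PROCESSING_DEFAULTS = {"sigma_px": 1.0, "exclusion_fraction": 0.3,
                        "certainty_exponent": 1.0}
_TRACKING_DEFAULTS = {"n_points": 100, "pieces": 5}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``phantom`` (a :class:`PhantomSpec` parameter mapping) or
    ``inputs`` (paths to an acquisition directory and a contour file) must
    be present.  Any stochastic stage (finite phantom SNR, cine jitter)
    requires an explicit ``seed``; there is no silent default.
    """

    phantom: dict | None = None
    inputs: dict | None = None
    processing: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    cine: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        if (self.phantom is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'phantom' or 'inputs' must be configured"
            )
        self.processing = {**_PROCESSING_DEFAULTS, **(self.processing or {})}
        self.tracking = {**_TRACKING_DEFAULTS, **(self.tracking or {})}
        stochastic = False
        if self.phantom is not None:
            snr = self.phantom.get("snr", PhantomSpec.snr)
            stochastic |= np.isfinite(float(snr)) if not isinstance(snr, str) else False
        if self.cine and float(self.cine.get("jitter_mm", 0.0)) > 0:
            stochastic = True
        if stochastic and self.seed is None:
            raise ConfigurationError(
                "a stochastic stage is configured (finite snr or cine jitter) "
                "but no seed was given"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def canonical(self) -> str:
        payload = {
            "phantom": self.phantom,
            "inputs": self.inputs,
            "processing": self.processing,
            "tracking": self.tracking,
            "cine": self.cine,
            "seed": self.seed,
        }
        return json.dumps(payload, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()

    def phantom_spec(self) -> PhantomSpec:
        d = dict(self.phantom or {})
        if self.seed is not None:
            d.setdefault("seed", int(self.seed))
        return PhantomSpec.from_dict(d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_tree(root: Path) -> dict:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            out[str(p.relative_to(root))] = _checksum(p)
    return out


def _delineation_from_contours(records, magnitude, pixel_spacing, exclusion_fraction):
    by_role = {}
    for rec in records:
        by_role.setdefault(rec.role, rec)
    for role in ("inner", "outer"):
        if role not in by_role:
            raise ConfigurationError(f"contour file lacks a '{role}' contour")
    inner = fit_closed_curve(by_role["inner"].points)
    outer = fit_closed_curve(by_role["outer"].points)
    if "mid" in by_role:
        mid = fit_closed_curve(by_role["mid"].points)
    else:
        from .geometry import mid_curve_between

        mid = mid_curve_between(inner, outer)
    mask = build_wall_mask(inner, outer, magnitude, pixel_spacing, exclusion_fraction)
    return WallDelineation(inner=inner, outer=outer, mid=mid, mask=mask)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest dictionary.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained and the manifest marks the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    log.info("run %s (seed=%s)", config.config_hash[:12], config.seed)

    def finish_stage(name):
        manifest["stages"][name] = "ok"

    def fail(name, exc):
        manifest["stages"][name] = f"failed: {exc}"
        manifest["checksums"] = _checksum_tree(out)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise StageError(name, str(exc)) from exc

    # -- simulate / load ---------------------------------------------------
    stage = "simulate"
    try:
        excl = config.processing["exclusion_fraction"]
        if config.phantom is not None:
            spec = config.phantom_spec()
            acq, truth, delin = make_phantom(spec, exclusion_fraction=excl)
            write_acquisition(acq, out / "acquisition")
            write_ground_truth(truth, out / "ground_truth")
            write_contours(
                [
                    ContourRecord(points=c.control_points, role=role)
                    for role, c in (
                        ("inner", delin.inner),
                        ("outer", delin.outer),
                        ("mid", delin.mid),
                    )
                ],
                out / "contours.txt",
            )
        else:
            acq = read_acquisition(config.inputs["acquisition"])
            records = read_contours(config.inputs["contours"])
            delin = _delineation_from_contours(
                records, acq.magnitude, acq.pixel_spacing, excl
            )
            truth = None
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # -- phase processing --------------------------------------------------
    stage = "process"
    try:
        fld = process_acquisition(
            acq,
            delin.mask,
            sigma_px=config.processing["sigma_px"],
            certainty_exponent=config.processing["certainty_exponent"],
        )
        write_displacement(fld, out / "displacement")
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    # -- tracking and stretch ----------------------------------------------
    stage = "stretch"
    try:
        n_points = int(config.tracking["n_points"])
        pieces = int(config.tracking["pieces"])
        seeds = seed_points(delin.mid, n_points)
        tracked = track_points(seeds, fld)
        profile = stretch_profile(tracked, pieces=pieces, center=delin.center)
        summary = quadrant_summary(profile)
        _write_stretch_tables(out, profile, summary)
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    # -- report -------------------------------------------------------------
    stage = "report"
    try:
        report = {
            "overall_stretch_ratio": summary.overall,
            "overall_stretch_percent": summary.overall_percent,
            "quadrant_stretch_ratio": summary.per_quadrant,
            "relative_stretch_difference": summary.rel_diff,
        }
        if config.phantom is not None and config.cine:
            series = make_cine_series(
                config.phantom_spec(),
                n_frames=int(config.cine.get("n_frames", 20)),
                seed=config.seed,
                jitter_mm=float(config.cine.get("jitter_mm", 0.0)),
            )
            report["relative_area_change"] = relative_area_change(series)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    manifest["checksums"] = _checksum_tree(out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_stretch_tables(out: Path, profile, summary):
    lines = ["segment\tangle_deg\tquadrant\tstretch_ratio\tstretch_percent"]
    for i, (lam, ang, q) in enumerate(
        zip(profile.ratios, profile.angles, profile.quadrants)
    ):
        lines.append(
            f"{i}\t{np.degrees(ang):.6f}\t{q}\t{lam:.9f}\t{100 * lam:.7f}"
        )
    (out / "stretch.tsv").write_text("\n".join(lines) + "\n")

    lines = ["quadrant\tstretch_ratio\tstretch_percent\trel_diff"]
    lines.append(
        f"overall\t{summary.overall:.9f}\t{summary.overall_percent:.7f}\t0"
    )
    for q in "ARPL":
        lines.append(
            f"{q}\t{summary.per_quadrant[q]:.9f}\t"
            f"{100 * summary.per_quadrant[q]:.7f}\t{summary.rel_diff[q]:.9f}"
        )
    (out / "summary.tsv").write_text("\n".join(lines) + "\n")
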