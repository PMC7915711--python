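"""Configuration, pipeline orchestration and seeded fixtures.

The pipeline chains the toolkit end to end: lens design -> Monte Carlo
fluence -> PA acquisition -> beamforming -> rendering.  A run is described
by a JSON-compatible :class:`RunConfig`; every stochastic stage takes an
explicit integer seed, and a manifest records the config hash, seeds and a
content hash of every numeric artifact so a run is reproducible
byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from truspa import io
from truspa.array_geometry import build_convex_array, synthesize_pulse
from truspa.beamforming import das_beamform, envelope_logcompress, scan_convert
from truspa.lens_optics import LensDesign, trace_elevation, trace_lateral
from truspa.pa_simulation import (
    AcquisitionConfig,
    PointTargetPhantom,
    intestine_transmission,
    make_wire_phantom,
    simulate_pa_rf,
)
from truspa.photon_transport import (
    MEDIUM_PRESETS,
    GridSpec,
    Medium,
    SourceSpec,
    simulate_fluence,
)

__all__ = ["RunConfig", "run_pipeline", "fixtures", "PipelineError"]

logger = logging.getLogger("truspa.workbench")

_FIXTURE_NAMES = ("wires66", "single_target", "milk3", "intestine_slab")


class PipelineError(RuntimeError):
    """Raised when a stage is missing an upstream artifact."""


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (JSON-compatible)."""

    lens: dict = field(default_factory=dict)
    array: dict = field(default_factory=dict)
    pulse: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=lambda: {"kind": "wires"})
    medium: str | dict = "milk3"
    illumination: str = "lens"          # uniform | lens | bare
    fluence: dict = field(default_factory=lambda: {"n_photons": 20000})
    acquisition: dict = field(default_factory=dict)
    beamform: dict = field(
        default_factory=lambda: {"dynamic_range_db": 35.0, "aperture_size": 64}
    )
    seeds: dict = field(default_factory=lambda: {"fluence": 0, "noise": 0})
    stages: dict = field(
        default_factory=lambda: {
            "design": True, "fluence": True, "simulate": True,
            "beamform": True, "render": True,
        }
    )
    output_dir: str = "truspa_run"

    def __post_init__(self):
        if self.illumination not in ("uniform", "lens", "bare"):
            raise ValueError(
                f"illumination must be uniform|lens|bare, got {self.illumination!r}"
            )
        for key, val in self.seeds.items():
            if not isinstance(val, int):
                raise ValueError(f"seed {key!r} must be an explicit integer")
        self.resolve_medium()  # fail fast on unknown presets

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of "
                f"{sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_json(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def resolve_medium(self) -> Medium:
        if isinstance(self.medium, str):
            if self.medium not in MEDIUM_PRESETS:
                raise ValueError(
                    f"unknown medium preset {self.medium!r}; valid: "
                    f"{sorted(MEDIUM_PRESETS)}"
                )
            return MEDIUM_PRESETS[self.medium]
        return Medium(**self.medium)

    def resolve_phantom(self) -> PointTargetPhantom:
        spec = dict(self.phantom)
        kind = spec.pop("kind", "wires")
        if kind == "wires":
            return make_wire_phantom(**spec)
        if kind == "single":
            pos = spec.pop("position_mm", [0.0, 25.0])
            return PointTargetPhantom(np.array([pos]), np.array([1.0]), **spec)
        if kind == "file":
            return io.read_phantom_tsv(spec["path"])
        raise ValueError(f"unknown phantom kind {kind!r}")


def _array_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": dict(config.seeds),
        "versions": _versions(),
        "artifacts": {},
        "stage_seconds": {},
    }

    def record(name: str, path: Path, *arrays) -> None:
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _array_hash(*arrays)
        }

    lens = LensDesign(**config.lens)
    array = build_convex_array(**config.array)
    acq = AcquisitionConfig(
        noise_seed=config.seeds.get("noise", 0), **config.acquisition
    )
    pulse = synthesize_pulse(
        sampling_rate_mhz=acq.sampling_rate_mhz, **config.pulse
    )

    lateral = elevation = None
    if stages.get("design", True):
        t0 = time.perf_counter()
        lateral = trace_lateral(lens)
        elevation = trace_elevation(lens)
        report = {
            "fov_full_angle_deg": lateral.fov_full_angle_deg,
            "tir_count": lateral.tir_count,
            "deviation_angle_deg": elevation.deviation_angle_deg,
            "crossing_depth_mm": elevation.crossing_depth_mm,
        }
        path = out / "lens_report.json"
        io.dump_json(path, report)
        record("lens_report", path, lateral.exit_rays.directions)
        manifest["stage_seconds"]["design"] = time.perf_counter() - t0
        logger.info("design: FOV %.1f deg, crossing %.1f mm",
                    report["fov_full_angle_deg"], report["crossing_depth_mm"])

    fluence_grid = None
    if stages.get("fluence", True):
        t0 = time.perf_counter()
        medium = config.resolve_medium()
        fl = dict(config.fluence)
        n_photons = fl.pop("n_photons", 20000)
        grid_spec = GridSpec(**fl.pop("grid", {}))
        if config.illumination == "lens":
            if lateral is None:
                raise PipelineError(
                    "fluence stage with lens illumination requires the design "
                    "stage (enable stages.design)"
                )
            source = SourceSpec(kind="lens", lateral_trace=lateral,
                                elevation=elevation, na=lens.source_na)
        else:
            source = SourceSpec(kind="bare")
        fluence_grid, _ = simulate_fluence(
            source, medium, grid_spec, n_photons=n_photons,
            seed=config.seeds.get("fluence", 0),
        )
        path = out / "fluence.h5"
        io.write_fluence_grid(path, fluence_grid)
        record("fluence", path, fluence_grid.deposited_weight)
        manifest["stage_seconds"]["fluence"] = time.perf_counter() - t0

    rf = None
    if stages.get("simulate", True):
        t0 = time.perf_counter()
        phantom = config.resolve_phantom()
        if config.illumination == "uniform":
            illum = None
        else:
            if fluence_grid is None:
                raise PipelineError(
                    f"simulate stage with {config.illumination!r} illumination "
                    "requires the fluence stage (enable stages.fluence)"
                )
            illum = fluence_grid
        rf = simulate_pa_rf(phantom, array, pulse, illumination=illum, config=acq)
        path = out / "pa_rf.h5"
        io.write_rf_frame(path, rf)
        record("pa_rf", path, rf.data)
        manifest["stage_seconds"]["simulate"] = time.perf_counter() - t0

    scanlines = None
    if stages.get("beamform", True):
        if rf is None:
            raise PipelineError(
                "beamform stage requires the simulate stage (enable "
                "stages.simulate)"
            )
        t0 = time.perf_counter()
        bf = dict(config.beamform)
        dr_db = bf.pop("dynamic_range_db", 35.0)
        pixel = bf.pop("pixel_spacing_mm", 0.2)
        scanlines = das_beamform(rf, array, **bf)
        compressed = envelope_logcompress(scanlines, dr_db)
        path = out / "pa_scanlines.h5"
        io.write_scanlines(path, compressed)
        record("pa_scanlines", path, compressed.data)
        manifest["stage_seconds"]["beamform"] = time.perf_counter() - t0
        if stages.get("render", True):
            t0 = time.perf_counter()
            image = scan_convert(compressed, array, pixel_spacing_mm=pixel)
            h5path = out / "pa_image.h5"
            io.write_bmode_h5(h5path, image)
            png = out / "pa_image.png"
            io.write_png(png, image)
            record("pa_image", h5path, image.data)
            manifest["stage_seconds"]["render"] = time.perf_counter() - t0
    elif stages.get("render", True) and stages.get("beamform", True) is False:
        raise PipelineError(
            "render stage requires the beamform stage (enable stages.beamform)"
        )

    path = out / "manifest.json"
    io.dump_json(path, manifest)
    return manifest


def _versions() -> dict:
    import scipy

    import truspa

    return {"truspa": truspa.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__}


def fixtures(name: str, seed: int = 0, output_dir: str = ".") -> list[Path]:
    """Write a named deterministic fixture; returns the paths written."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "wires66":
        phantom = make_wire_phantom()
        path = out / "wires66_phantom.tsv"
        io.write_phantom_tsv(path, phantom)
        return [path]
    if name == "single_target":
        phantom = PointTargetPhantom(np.array([[0.0, 25.0]]), np.array([1.0]))
        path = out / "single_target_phantom.tsv"
        io.write_phantom_tsv(path, phantom)
        return [path]
    if name == "milk3":
        medium = MEDIUM_PRESETS["milk3"]
        path = out / "milk3_medium.json"
        io.dump_json(path, dataclasses.asdict(medium))
        return [path]
    if name == "intestine_slab":
        grid = np.arange(650.0, 976.0, 25.0)
        table = {
            "wavelength_nm": grid.tolist(),
            "transmission": [intestine_transmission(w) for w in grid],
            "thickness_mm": 3.0,
        }
        path = out / "intestine_slab.json"
        io.dump_json(path, table)
        return [path]
    raise ValueError(
        f"unknown fixture {name!r}; valid names: {', '.join(_FIXTURE_NAMES)}"
    )
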