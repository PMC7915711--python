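"""File I/O: HDF5 gridded containers, delimited text tables, PNG rasters."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from truspa.array_geometry import ConvexArray
from truspa.beamforming import BModeImage, ScanlineSet
from truspa.lens_optics import BeamProfile, RayBundle
from truspa.pa_simulation import PointTargetPhantom, RFFrame
from truspa.photon_transport import FluenceGrid, GridSpec

__all__ = [
    "write_fluence_grid", "read_fluence_grid",
    "write_rf_frame", "read_rf_frame",
    "write_scanlines", "write_bmode_h5",
    "write_png", "write_overlay_png",
    "write_profile_csv", "write_phantom_tsv", "read_phantom_tsv",
    "write_array_tsv", "write_rays_csv",
    "load_json", "dump_json",
]


def write_fluence_grid(path, grid: FluenceGrid) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("deposited_weight", data=grid.deposited_weight)
        f.create_dataset("interaction_counts", data=grid.interaction_counts)
        for name, ax in zip(("x_edges_mm", "y_edges_mm", "z_edges_mm"), grid.axes):
            f.create_dataset(name, data=ax)
        f.attrs["voxel_size_mm"] = grid.spec.voxel_size_mm
        f.attrs["photons_launched"] = grid.photons_launched
        f.attrs["seed"] = -1 if grid.seed is None else grid.seed
        for k in ("transmitted_weight", "reflected_weight", "side_weight",
                  "roulette_net", "truncated_weight"):
            f.attrs[k] = getattr(grid, k)


def read_fluence_grid(path) -> FluenceGrid:
    with h5py.File(path, "r") as f:
        xe = f["x_edges_mm"][:]
        ye = f["y_edges_mm"][:]
        ze = f["z_edges_mm"][:]
        spec = GridSpec(
            x_extent=(float(xe[0]), float(xe[-1])),
            y_extent=(float(ye[0]), float(ye[-1])),
            z_extent=(float(ze[0]), float(ze[-1])),
            voxel_size_mm=float(f.attrs["voxel_size_mm"]),
        )
        seed = int(f.attrs["seed"])
        grid = FluenceGrid(
            spec=spec,
            deposited_weight=f["deposited_weight"][:],
            interaction_counts=f["interaction_counts"][:],
            photons_launched=int(f.attrs["photons_launched"]),
            seed=None if seed < 0 else seed,
            transmitted_weight=float(f.attrs["transmitted_weight"]),
            reflected_weight=float(f.attrs["reflected_weight"]),
            side_weight=float(f.attrs["side_weight"]),
            roulette_net=float(f.attrs["roulette_net"]),
            truncated_weight=float(f.attrs["truncated_weight"]),
        )
    return grid


def write_rf_frame(path, frame: RFFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=frame.data)
        f.attrs["mode"] = frame.mode
        f.attrs["sampling_rate_mhz"] = frame.sampling_rate_mhz
        f.attrs["sound_speed_m_s"] = frame.sound_speed_m_s
        f.attrs["t0_us"] = frame.t0_us
        if frame.active_start is not None:
            f.create_dataset("active_start", data=frame.active_start)
            f.create_dataset("active_count", data=frame.active_count)
        if frame.noise_seed is not None:
            f.attrs["noise_seed"] = frame.noise_seed


def read_rf_frame(path) -> RFFrame:
    with h5py.File(path, "r") as f:
        kwargs = dict(
            mode=str(f.attrs["mode"]),
            data=f["data"][:],
            sampling_rate_mhz=float(f.attrs["sampling_rate_mhz"]),
            sound_speed_m_s=float(f.attrs["sound_speed_m_s"]),
            t0_us=float(f.attrs["t0_us"]),
        )
        if "active_start" in f:
            kwargs["active_start"] = f["active_start"][:]
            kwargs["active_count"] = f["active_count"][:]
        if "noise_seed" in f.attrs:
            kwargs["noise_seed"] = int(f.attrs["noise_seed"])
    return RFFrame(**kwargs)


def write_scanlines(path, scanlines: ScanlineSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=scanlines.data)
        f.create_dataset("beam_angles_deg", data=scanlines.beam_angles_deg)
        f.create_dataset("ranges_mm", data=scanlines.ranges_mm)
        f.attrs["aperture_size"] = scanlines.aperture_size
        f.attrs["normalized"] = scanlines.normalized
        if scanlines.dynamic_range_db is not None:
            f.attrs["dynamic_range_db"] = scanlines.dynamic_range_db


def write_bmode_h5(path, image: BModeImage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=image.data)
        f.create_dataset("mask", data=image.mask)
        f.attrs["pixel_spacing_mm"] = image.pixel_spacing_mm
        f.attrs["x0_mm"] = image.x0_mm
        f.attrs["z0_mm"] = image.z0_mm
        if image.dynamic_range_db is not None:
            f.attrs["dynamic_range_db"] = image.dynamic_range_db


def write_png(path, image: BModeImage) -> None:
    """8-bit grayscale PNG of a scan-converted image."""
    gray = np.round(np.clip(image.data, 0.0, 1.0) * 255).astype(np.uint8)
    iio.imwrite(Path(path), gray)


def write_overlay_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8))


def write_profile_csv(path, profile: BeamProfile) -> None:
    arr = np.column_stack([profile.positions_mm, profile.intensity])
    header = f"depth_mm={profile.depth_mm}\nposition_mm,intensity"
    np.savetxt(path, arr, delimiter=",", header=header)


def write_phantom_tsv(path, phantom: PointTargetPhantom) -> None:
    arr = np.column_stack([phantom.positions_mm, phantom.strengths])
    np.savetxt(
        path, arr, delimiter="\t",
        header=f"wire_diameter_mm={phantom.wire_diameter_mm}\nx_mm\tz_mm\tstrength",
    )


def read_phantom_tsv(path) -> PointTargetPhantom:
    with open(path) as f:
        first = f.readline()
    diam = 0.1
    if first.startswith("#") and "wire_diameter_mm=" in first:
        diam = float(first.split("=", 1)[1])
    arr = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    return PointTargetPhantom(arr[:, :2], arr[:, 2], wire_diameter_mm=diam)


def write_array_tsv(path, array: ConvexArray) -> None:
    idx = np.arange(array.n_elements)
    arr = np.column_stack([
        idx, array.element_positions, array.element_angles_deg,
    ])
    np.savetxt(path, arr, delimiter="\t",
               header="element\tx_mm\tz_mm\tnormal_angle_deg")


def write_rays_csv(path, rays: RayBundle) -> None:
    arr = np.column_stack([rays.origins, rays.directions, rays.weights])
    np.savetxt(path, arr, delimiter=",",
               header="x_mm,z_mm,dx,dz,weight")


def load_json(path) -> dict:
    with open(path) as f:
        return json.load(f)


def dump_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")
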