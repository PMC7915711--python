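"""Sector image reconstruction for convex arrays.

Walking-aperture delay-and-sum (DAS): scanlines are co-located with the 128
element positions and steered radially; a fixed-size active sub-aperture
(default 64 channels) slides with the scanline and is clipped at the array
edges, so the outermost scanline of a 128-element array is formed from 32
channels and the centre scanline from 64.  PA data are beamformed with
one-way delays, pulse-echo US with two-way delays.  An optional
coherence-factor weight (|sum|^2 / (N sum |s|^2)) is provided as an
explicitly labelled stand-in for adaptive beamforming; it is not a
reproduction of any published adaptive algorithm.

Envelope detection uses the analytic-signal magnitude along range;
log compression maps ``dynamic_range_db`` onto [0, 1].  Scan conversion
inverts the convex-sector geometry (range measured from the element arc)
with bilinear interpolation onto a Cartesian grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from truspa.array_geometry import ConvexArray

__all__ = [
    "ScanlineSet",
    "BModeImage",
    "active_channels",
    "das_beamform",
    "coherence_factor",
    "envelope_logcompress",
    "scan_convert",
    "overlay",
    "sector_to_xy",
    "xy_to_sector",
]


@dataclass
class ScanlineSet:
    """Beamformed amplitude on a (beam angle, range) grid."""

    beam_angles_deg: np.ndarray   # (n_scanlines,)
    ranges_mm: np.ndarray         # (n_ranges,) from the element arc
    data: np.ndarray              # (n_scanlines, n_ranges)
    aperture_size: int = 64
    normalized: bool = False
    dynamic_range_db: float | None = None
    clipped_lookups: int = 0      # focal points beyond the recorded window

    def __post_init__(self):
        self.beam_angles_deg = np.asarray(self.beam_angles_deg, dtype=float)
        self.ranges_mm = np.asarray(self.ranges_mm, dtype=float)
        if np.any(self.ranges_mm < 0):
            raise ValueError("range axis must be non-negative")
        dr = np.diff(self.ranges_mm)
        if len(dr) and not np.allclose(dr, dr[0], rtol=1e-9):
            raise ValueError("range axis must be uniform")


@dataclass
class BModeImage:
    """Scan-converted raster: normalised intensity on a Cartesian grid."""

    data: np.ndarray              # (nz, nx) in [0, 1]
    mask: np.ndarray              # True inside the sector
    pixel_spacing_mm: float
    x0_mm: float                  # x of column 0
    z0_mm: float                  # z of row 0
    dynamic_range_db: float | None = None

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nz, nx = self.data.shape
        return (self.x0_mm, self.x0_mm + (nx - 1) * self.pixel_spacing_mm,
                self.z0_mm, self.z0_mm + (nz - 1) * self.pixel_spacing_mm)


def active_channels(scanline_index: int, n_elements: int,
                    aperture_size: int) -> tuple[int, tuple[int, int]]:
    """Walking-aperture channel window for one scanline.

    A symmetric window of ``aperture_size`` centred on the scanline's
    element, clipped to the physical array.  Returns ``(count, (lo, hi))``
    with ``hi`` exclusive.
    """
    if not 0 <= scanline_index < n_elements:
        raise ValueError("scanline_index out of range")
    if aperture_size % 2 != 0 or aperture_size <= 0:
        raise ValueError("aperture_size must be even and positive")
    lo = max(scanline_index - aperture_size // 2, 0)
    hi = min(scanline_index + aperture_size // 2, n_elements)
    return hi - lo, (lo, hi)


def sector_to_xy(angles_deg, ranges_mm, array: ConvexArray):
    """Cartesian (x, z) of sector nodes; range measured from the element arc."""
    th = np.radians(np.asarray(angles_deg, dtype=float))
    r = np.asarray(ranges_mm, dtype=float)
    rho = array.radius_mm + r
    x = rho * np.sin(th)
    z = rho * np.cos(th) - array.radius_mm
    return x, z


def xy_to_sector(x, z, array: ConvexArray):
    """Inverse of :func:`sector_to_xy`."""
    zc = np.asarray(z, dtype=float) + array.radius_mm
    xv = np.asarray(x, dtype=float)
    rho = np.hypot(xv, zc)
    theta = np.degrees(np.arctan2(xv, zc))
    return theta, rho - array.radius_mm


def _sample_linear(channels: np.ndarray, sample_pos: np.ndarray) -> np.ndarray:
    """Fractional-sample lookup along the last axis (out of window -> 0)."""
    n = channels.shape[-1]
    i0 = np.floor(sample_pos).astype(np.int64)
    frac = sample_pos - i0
    valid = (i0 >= 0) & (i0 < n - 1)
    i0c = np.clip(i0, 0, n - 2)
    ch_idx = np.broadcast_to(
        np.arange(channels.shape[0])[:, None], sample_pos.shape
    )
    v = channels[ch_idx, i0c] * (1.0 - frac) + channels[ch_idx, i0c + 1] * frac
    return np.where(valid, v, 0.0), valid


def das_beamform(
    rf,
    array: ConvexArray,
    ranges_mm: np.ndarray | None = None,
    range_step_mm: float | None = None,
    max_range_mm: float = 60.0,
    aperture_size: int = 64,
    weighting: str = "none",
    delay_law: str | None = None,
) -> ScanlineSet:
    """Walking-aperture delay-and-sum of an RF frame.

    ``rf`` is an :class:`truspa.pa_simulation.RFFrame` (pa: one-way delays
    across the full array; us: two-way delays across the frame's stored
    active channels).  ``weighting`` is ``"none"`` or ``"cf"`` (coherence
    factor).  ``delay_law`` overrides the delay model ("pa" one-way /
    "us" two-way) independently of the data layout -- useful only for
    demonstrating the mislocation caused by a mismatched law.
    """
    if weighting not in ("none", "cf"):
        raise ValueError("weighting must be 'none' or 'cf'")
    if rf.mode not in ("pa", "us"):
        raise ValueError("unknown rf mode")
    delay_law = delay_law or rf.mode
    if delay_law not in ("pa", "us"):
        raise ValueError("delay_law must be 'pa' or 'us'")
    c = rf.sound_speed_m_s * 1e-3  # mm/us
    dt = 1.0 / rf.sampling_rate_mhz
    if ranges_mm is None:
        dr = range_step_mm if range_step_mm is not None else c * dt
        ranges_mm = np.arange(0.0, max_range_mm, dr)
    ranges_mm = np.asarray(ranges_mm, dtype=float)
    n_el = array.n_elements
    if rf.mode == "pa" and rf.data.shape[0] != n_el:
        raise ValueError("rf channel count must match the array")
    angles = array.element_angles_deg
    out = np.zeros((n_el, len(ranges_mm)))
    clipped = 0
    beam_dirs = array.element_normals
    for s in range(n_el):
        count, (lo, hi) = active_channels(s, n_el, aperture_size)
        focal = (
            array.element_positions[s][None, :]
            + ranges_mm[:, None] * beam_dirs[s][None, :]
        )                                                    # (n_r, 2)
        if rf.mode == "pa":
            channels = np.asarray(rf.data[lo:hi], dtype=float)
            d_rx = np.linalg.norm(
                array.element_positions[lo:hi][:, None, :] - focal[None, :, :],
                axis=2,
            )                                                 # (count, n_r)
        else:
            a_lo = int(rf.active_start[s])
            a_n = int(rf.active_count[s])
            channels = np.asarray(rf.data[s, :a_n], dtype=float)
            d_rx = np.linalg.norm(
                array.element_positions[a_lo:a_lo + a_n][:, None, :]
                - focal[None, :, :],
                axis=2,
            )
        if delay_law == "pa":
            tau = d_rx / c
        else:
            tau = (ranges_mm[None, :] + d_rx) / c
        samples, valid = _sample_linear(channels, (tau - rf.t0_us) / dt)
        clipped += int((~valid).sum())
        summed = samples.sum(axis=0)
        if weighting == "cf":
            summed = summed * coherence_factor(samples)
        out[s] = summed
    return ScanlineSet(
        beam_angles_deg=angles,
        ranges_mm=ranges_mm,
        data=out,
        aperture_size=aperture_size,
        clipped_lookups=clipped,
    )


def coherence_factor(channel_samples: np.ndarray) -> np.ndarray:
    """|sum|^2 / (N sum |s|^2) across the channel axis (axis 0).

    Equals 1 for perfectly coherent channels and has expectation ~1/N for
    zero-mean incoherent channels.  Stand-in for adaptive weighting.
    """
    n = channel_samples.shape[0]
    num = np.abs(channel_samples.sum(axis=0)) ** 2
    den = n * (np.abs(channel_samples) ** 2).sum(axis=0)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def envelope_logcompress(scanlines: ScanlineSet,
                         dynamic_range_db: float = 35.0) -> ScanlineSet:
    """Analytic-signal envelope + log compression onto [0, 1].

    pixel = max(0, 1 + 20 log10(env / max) / DR); an all-zero input maps to
    all zeros.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    data = scanlines.data
    env = np.abs(hilbert(data, axis=1)) if data.shape[1] > 1 else np.abs(data)
    peak = env.max()
    if peak <= 0:
        comp = np.zeros_like(env)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(env / peak)
        comp = np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)
    return ScanlineSet(
        beam_angles_deg=scanlines.beam_angles_deg.copy(),
        ranges_mm=scanlines.ranges_mm.copy(),
        data=comp,
        aperture_size=scanlines.aperture_size,
        normalized=True,
        dynamic_range_db=dynamic_range_db,
        clipped_lookups=scanlines.clipped_lookups,
    )


def scan_convert(
    scanlines: ScanlineSet,
    array: ConvexArray,
    pixel_spacing_mm: float = 0.2,
) -> BModeImage:
    """Bilinear interpolation of (angle, range) samples onto Cartesian pixels.

    Pixels outside the sector are flagged in the image mask and set to 0.
    """
    if not scanlines.normalized:
        raise ValueError("scan_convert expects normalized (log-compressed) scanlines")
    th = scanlines.beam_angles_deg
    r = scanlines.ranges_mm
    r_max = r[-1]
    # sector bounding box
    corner_th = np.array([th[0], th[-1]])
    xs, zs = sector_to_xy(
        np.concatenate([corner_th, corner_th, [0.0]]),
        np.concatenate([[0.0, 0.0], [r_max, r_max], [r_max]]),
        array,
    )
    x0, x1 = xs.min(), xs.max()
    z0, z1 = min(zs.min(), 0.0), zs.max()
    nx = int(math.ceil((x1 - x0) / pixel_spacing_mm)) + 1
    nz = int(math.ceil((z1 - z0) / pixel_spacing_mm)) + 1
    gx = x0 + pixel_spacing_mm * np.arange(nx)
    gz = z0 + pixel_spacing_mm * np.arange(nz)
    xx, zz = np.meshgrid(gx, gz)
    theta_p, r_p = xy_to_sector(xx, zz, array)
    dth = th[1] - th[0] if len(th) > 1 else 1.0
    dr = r[1] - r[0] if len(r) > 1 else 1.0
    fi_th = (theta_p - th[0]) / dth
    fi_r = (r_p - r[0]) / dr
    inside = (
        (theta_p >= th[0]) & (theta_p <= th[-1]) & (r_p >= r[0]) & (r_p <= r_max)
    )
    img = map_coordinates(
        scanlines.data, [fi_th.ravel(), fi_r.ravel()], order=1, mode="constant",
        cval=0.0,
    ).reshape(xx.shape)
    img = np.where(inside, np.clip(img, 0.0, 1.0), 0.0)
    return BModeImage(
        data=img,
        mask=inside,
        pixel_spacing_mm=pixel_spacing_mm,
        x0_mm=float(x0),
        z0_mm=float(z0),
        dynamic_range_db=scanlines.dynamic_range_db,
    )


def overlay(us_image: BModeImage, pa_image: BModeImage,
            threshold: float = 0.0) -> np.ndarray:
    """Paint PA pixels above ``threshold`` over the US grayscale.

    Returns an (nz, nx, 3) RGB array in [0, 1]; PA is rendered in a
    red-amber ramp.
    """
    if us_image.data.shape != pa_image.data.shape:
        raise ValueError("US and PA images must share a pixel grid")
    rgb = np.repeat(us_image.data[:, :, None], 3, axis=2)
    hot = pa_image.mask & (pa_image.data > threshold)
    pa = pa_image.data
    rgb[hot, 0] = pa[hot]
    rgb[hot, 1] = 0.45 * pa[hot]
    rgb[hot, 2] = 0.0
    return rgb
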