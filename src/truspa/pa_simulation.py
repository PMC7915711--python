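"""Synthetic PA / US acquisition on point-target phantoms.

The radial wire phantom mirrors the probe's characterisation setup: 100 um
tungsten wires on a polar grid about the probe face centre (-75..75 degrees
in 15 degree steps, 5..55 mm radius in 10 mm steps; 66 wires).  At 6.75 MHz
the acoustic wavelength (~228 um) exceeds the wire diameter, so wires are
modelled as 2-D point absorbers.

Photoacoustic (one-way) channel data: for element e and target t the
arrival is |p_t - x_e| / c and the amplitude is strength x illumination
weight x 1/r spherical spreading.  Pulse-echo US (two-way) data are
simulated per walking-aperture scanline with the transmit reference at the
scanline's element.  Fractional delays use linear interpolation.

:func:`intestine_transmission` provides the wavelength-dependent fraction
of laser energy penetrating a ~3 mm intestinal wall: a piecewise-linear
preset anchored so the value at 780 nm is 0.263 and the mean over the
650:25:975 nm grid is 0.219 (the two anchor constraints); the spectral shape
between anchors is a synthetic stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from truspa.array_geometry import ConvexArray, PulseModel
from truspa.beamforming import active_channels

__all__ = [
    "PointTargetPhantom",
    "RFFrame",
    "AcquisitionConfig",
    "make_wire_phantom",
    "simulate_pa_rf",
    "simulate_us_rf",
    "intestine_transmission",
]


@dataclass(frozen=True)
class PointTargetPhantom:
    """Point absorbers/scatterers in the imaging plane."""

    positions_mm: np.ndarray   # (N, 2)
    strengths: np.ndarray      # (N,)
    wire_diameter_mm: float = 0.1

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        s = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if pos.shape[0] != s.shape[0] or (pos.size and pos.shape[1] != 2):
            raise ValueError("positions (N,2) and strengths (N,) required")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if pos.size and np.any(s <= 0):
            raise ValueError("strengths must be positive")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "strengths", s)

    def __len__(self) -> int:
        return len(self.strengths)


@dataclass
class RFFrame:
    """Per-channel time series from a simulated acquisition.

    pa mode: ``data`` is (n_elements, n_samples).  us mode: ``data`` is
    (n_scanlines, aperture, n_samples) holding only the walking-aperture
    channels, with ``active_start[s]`` the first active element index of
    scanline ``s`` (padding channels are zero).
    """

    mode: str
    data: np.ndarray
    sampling_rate_mhz: float
    sound_speed_m_s: float = 1540.0
    t0_us: float = 0.0
    active_start: np.ndarray | None = None
    active_count: np.ndarray | None = None
    noise_seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("pa", "us"):
            raise ValueError("mode must be 'pa' or 'us'")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RF samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def times_us(self) -> np.ndarray:
        return self.t0_us + np.arange(self.n_samples) / self.sampling_rate_mhz


@dataclass(frozen=True)
class AcquisitionConfig:
    """Shared acquisition settings (mm / us / MHz at the boundary)."""

    sampling_rate_mhz: float = 40.0
    sound_speed_m_s: float = 1540.0
    max_depth_mm: float = 60.0
    aperture_size: int = 64
    noise_snr_db: float | None = None
    noise_seed: int = 0
    attenuation_db_cm_mhz: float = 0.0
    strength_scale: float = 1.0

    @property
    def c_mm_us(self) -> float:
        return self.sound_speed_m_s * 1e-3


def make_wire_phantom(
    angle_start_deg: float = -75.0,
    angle_stop_deg: float = 75.0,
    angle_step_deg: float = 15.0,
    radius_start_mm: float = 5.0,
    radius_stop_mm: float = 55.0,
    radius_step_mm: float = 10.0,
) -> PointTargetPhantom:
    """Radial wire grid about the probe face centre (inclusive endpoints).

    Angle 0 lies along the probe axis (+z); target position is
    (r sin(theta), r cos(theta)).
    """
    if angle_step_deg <= 0 or radius_step_mm <= 0:
        raise ValueError("steps must be positive")
    if angle_stop_deg < angle_start_deg or radius_stop_mm < radius_start_mm:
        raise ValueError("stops must be >= starts")
    n_ang = int(round((angle_stop_deg - angle_start_deg) / angle_step_deg)) + 1
    n_rad = int(round((radius_stop_mm - radius_start_mm) / radius_step_mm)) + 1
    angles = np.radians(angle_start_deg + angle_step_deg * np.arange(n_ang))
    radii = radius_start_mm + radius_step_mm * np.arange(n_rad)
    rr, aa = np.meshgrid(radii, angles)
    pos = np.stack([rr.ravel() * np.sin(aa.ravel()), rr.ravel() * np.cos(aa.ravel())], 1)
    return PointTargetPhantom(pos, np.ones(len(pos)))


def _illumination_weights(illumination, positions: np.ndarray) -> np.ndarray:
    """Relative illumination weight at each in-plane target position.

    ``illumination`` is None / "uniform", a callable (x, z) -> weight, or a
    fluence grid (weights bilinearly interpolated from the imaging-plane
    fluence, normalised to unit maximum).
    """
    if illumination is None or (
        isinstance(illumination, str) and illumination == "uniform"
    ):
        return np.ones(len(positions))
    if callable(illumination):
        return np.asarray(
            [float(illumination(x, z)) for x, z in positions], dtype=float
        )
    grid = illumination  # duck-typed FluenceGrid
    xs, ys, zs = grid.axes
    xc = 0.5 * (xs[:-1] + xs[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])
    ny = grid.deposited_weight.shape[1]
    mid = grid.deposited_weight[:, max(ny // 2 - 1, 0): ny // 2 + 1, :].mean(axis=1)
    peak = mid.max()
    if peak <= 0:
        raise ValueError("illumination grid holds no deposited energy")
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (xc, zc), mid / peak, bounds_error=False, fill_value=0.0
    )
    return np.clip(interp(positions), 0.0, None)


def _check_in_front(phantom: PointTargetPhantom, array: ConvexArray) -> None:
    c = array.center_of_curvature
    rel = phantom.positions_mm - c
    r = np.linalg.norm(rel, axis=1)
    ang = np.degrees(np.arctan2(rel[:, 0], rel[:, 1]))
    if np.any(r <= array.radius_mm) or np.any(np.abs(ang) >= 90.0):
        raise ValueError("all targets must lie in front of the array")


def _deposit(rf_row: np.ndarray, pulse: PulseModel, tau_us: np.ndarray,
             amps: np.ndarray, dt_us: float) -> None:
    """Add the pulse at fractional delays tau (linear interpolation)."""
    n_samples = rf_row.shape[-1]
    wave = pulse.waveform
    start = (tau_us + pulse.times_us[0]) / dt_us
    base = np.floor(start).astype(np.int64)
    frac = start - base
    k = np.arange(len(wave))
    idx = base[:, None] + k[None, :]                     # (M, L)
    vals0 = amps[:, None] * wave[None, :] * (1.0 - frac[:, None])
    vals1 = amps[:, None] * wave[None, :] * frac[:, None]
    for offset, vals in ((0, vals0), (1, vals1)):
        ii = idx + offset
        ok = (ii >= 0) & (ii < n_samples)
        if rf_row.ndim == 1:
            np.add.at(rf_row, ii[ok], vals[ok])
        else:
            rows = np.broadcast_to(np.arange(rf_row.shape[0])[:, None], ii.shape)
            np.add.at(rf_row, (rows[ok], ii[ok]), vals[ok])


def _attenuate(amps, dist_mm, config: AcquisitionConfig, fc_mhz: float):
    if config.attenuation_db_cm_mhz <= 0:
        return amps
    db = config.attenuation_db_cm_mhz * fc_mhz * (dist_mm / 10.0)
    return amps * 10.0 ** (-db / 20.0)


def simulate_pa_rf(
    phantom: PointTargetPhantom,
    array: ConvexArray,
    pulse: PulseModel,
    illumination=None,
    config: AcquisitionConfig = AcquisitionConfig(),
) -> RFFrame:
    """One-way photoacoustic channel data for every array element."""
    _check_in_front(phantom, array)
    if abs(pulse.sampling_rate_mhz - config.sampling_rate_mhz) > 1e-9:
        raise ValueError("pulse sampling rate must match the acquisition rate")
    dt = 1.0 / config.sampling_rate_mhz
    t_max = (config.max_depth_mm + array.radius_mm) / config.c_mm_us + pulse.duration_us
    n_samples = int(math.ceil(t_max / dt))
    rf = np.zeros((array.n_elements, n_samples))
    weights = _illumination_weights(illumination, phantom.positions_mm)
    for p_t, strength, w in zip(phantom.positions_mm, phantom.strengths, weights):
        amp_scale = strength * w * config.strength_scale
        if amp_scale == 0.0:
            continue
        d = np.linalg.norm(array.element_positions - p_t, axis=1)
        tau = d / config.c_mm_us
        amps = _attenuate(amp_scale / d, d, config, pulse.center_frequency_mhz)
        _deposit(rf, pulse, tau, amps, dt)
    if config.noise_snr_db is not None:
        rng = np.random.default_rng(config.noise_seed)
        peak = np.abs(rf).max()
        sigma = peak * 10.0 ** (-config.noise_snr_db / 20.0) if peak > 0 else 1.0
        rf = rf + rng.normal(0.0, sigma, rf.shape)
    return RFFrame(
        mode="pa",
        data=rf.astype(np.float32),
        sampling_rate_mhz=config.sampling_rate_mhz,
        sound_speed_m_s=config.sound_speed_m_s,
        noise_seed=config.noise_seed if config.noise_snr_db is not None else None,
    )


def simulate_us_rf(
    phantom: PointTargetPhantom,
    array: ConvexArray,
    pulse: PulseModel,
    config: AcquisitionConfig = AcquisitionConfig(),
    n_background: int = 0,
    background_seed: int = 0,
    background_strength: float = 0.02,
) -> RFFrame:
    """Two-way pulse-echo channel data, one walking-aperture transmit per
    scanline (scanlines co-located with the elements).

    Optional diffuse background scatterers add a speckle-like floor.
    """
    _check_in_front(phantom, array)
    if abs(pulse.sampling_rate_mhz - config.sampling_rate_mhz) > 1e-9:
        raise ValueError("pulse sampling rate must match the acquisition rate")
    positions = phantom.positions_mm
    strengths = phantom.strengths * config.strength_scale
    if n_background > 0:
        rng = np.random.default_rng(background_seed)
        r = np.sqrt(rng.random(n_background)) * config.max_depth_mm
        th = np.radians((rng.random(n_background) - 0.5) * array.angular_span_deg)
        bg = np.stack([r * np.sin(th), r * np.cos(th)], axis=1)
        positions = np.vstack([positions, bg]) if len(positions) else bg
        strengths = np.concatenate(
            [strengths, background_strength * rng.random(n_background)]
        )
    dt = 1.0 / config.sampling_rate_mhz
    t_max = (
        2.0 * (config.max_depth_mm + array.radius_mm) / config.c_mm_us
        + pulse.duration_us
    )
    n_samples = int(math.ceil(t_max / dt))
    ap = config.aperture_size
    rf = np.zeros((array.n_elements, ap, n_samples), dtype=np.float32)
    starts = np.empty(array.n_elements, dtype=np.int64)
    counts = np.empty(array.n_elements, dtype=np.int64)
    for s in range(array.n_elements):
        count, (lo, hi) = active_channels(s, array.n_elements, ap)
        starts[s], counts[s] = lo, count
        if len(positions) == 0:
            continue
        x_tx = array.element_positions[s]
        d_tx = np.linalg.norm(positions - x_tx, axis=1)       # (T,)
        d_rx = np.linalg.norm(
            array.element_positions[lo:hi][None, :, :] - positions[:, None, :], axis=2
        )                                                      # (T, count)
        tau = (d_tx[:, None] + d_rx) / config.c_mm_us
        amps = strengths[:, None] / (d_tx[:, None] * d_rx)
        amps = _attenuate(
            amps, d_tx[:, None] + d_rx, config, pulse.center_frequency_mhz
        )
        # deposit per channel: flatten (T, count) onto channel rows
        row = np.zeros((count, n_samples))
        chan = np.broadcast_to(np.arange(count)[None, :], tau.shape)
        _deposit_multi(row, pulse, tau.ravel(), amps.ravel(), chan.ravel(), dt)
        rf[s, :count, :] = row
    if config.noise_snr_db is not None:
        rng = np.random.default_rng(config.noise_seed + 1)
        peak = np.abs(rf).max()
        sigma = peak * 10.0 ** (-config.noise_snr_db / 20.0) if peak > 0 else 1.0
        rf = (rf + rng.normal(0.0, sigma, rf.shape)).astype(np.float32)
    return RFFrame(
        mode="us",
        data=rf,
        sampling_rate_mhz=config.sampling_rate_mhz,
        sound_speed_m_s=config.sound_speed_m_s,
        active_start=starts,
        active_count=counts,
        noise_seed=config.noise_seed if config.noise_snr_db is not None else None,
    )


def _deposit_multi(rows: np.ndarray, pulse: PulseModel, tau_us: np.ndarray,
                   amps: np.ndarray, chan: np.ndarray, dt_us: float) -> None:
    """Deposit pulses into per-channel rows given a channel index per event."""
    n_samples = rows.shape[-1]
    wave = pulse.waveform
    start = (tau_us + pulse.times_us[0]) / dt_us
    base = np.floor(start).astype(np.int64)
    frac = start - base
    k = np.arange(len(wave))
    idx = base[:, None] + k[None, :]
    ch = np.broadcast_to(chan[:, None], idx.shape)
    for offset, fr in ((0, 1.0 - frac), (1, frac)):
        vals = amps[:, None] * wave[None, :] * fr[:, None]
        ii = idx + offset
        ok = (ii >= 0) & (ii < n_samples)
        np.add.at(rows, (ch[ok], ii[ok]), vals[ok])


# ---------------------------------------------------------------------------
# intestinal-wall transmission preset

# synthetic spectral shape: NIR-window rise to 780 nm, slow decline, water
# absorption dip toward 975 nm.  Affinely calibrated below so that
# T(780) = 0.263 and the 650:25:975 grid mean is 0.219 exactly.
_SHAPE_NM = np.array([650.0, 700.0, 750.0, 780.0, 800.0, 850.0, 900.0, 925.0,
                      950.0, 975.0])
_SHAPE_REL = np.array([0.55, 0.75, 0.92, 1.00, 0.98, 0.92, 0.85, 0.80,
                       0.70, 0.60])

_PEAK_NM, _PEAK_T = 780.0, 0.263
_GRID_MEAN_T = 0.219


def _calibrate_transmission() -> tuple[float, float]:
    grid = np.arange(650.0, 976.0, 25.0)
    shape_on_grid = np.interp(grid, _SHAPE_NM, _SHAPE_REL)
    mean_shape = shape_on_grid.mean()
    b = (_PEAK_T - _GRID_MEAN_T) / (1.0 - mean_shape)
    a = _PEAK_T - b
    return a, b


_TRANS_A, _TRANS_B = _calibrate_transmission()


def intestine_transmission(wavelength_nm: float) -> float:
    """Fraction of laser energy penetrating the intestinal-wall preset.

    Piecewise linear in wavelength over 650-975 nm; peak 0.263 at 780 nm,
    grid-mean 0.219 by construction.
    """
    wl = float(wavelength_nm)
    if not 650.0 <= wl <= 975.0:
        raise ValueError("wavelength must be within 650-975 nm")
    return float(_TRANS_A + _TRANS_B * np.interp(wl, _SHAPE_NM, _SHAPE_REL))
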