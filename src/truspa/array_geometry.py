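"""Convex ultrasound array geometry and band-limited acquisition pulse.

The endocavity probe carries a 128-element convex array with a 134.5 degree
angular span over an 11.4 mm arc footprint (measured centre frequency
6.75 MHz, -6 dB fractional bandwidth 66%).  Element centres are equally
spaced in angle on a circular arc whose apex sits at the coordinate origin,
with +z the depth axis; normals point radially outward.

The acquisition pulse is modelled as a Gaussian-enveloped cosine whose
amplitude spectrum has a -6 dB full width of ``fractional_bandwidth x
center_frequency``; :func:`characterize_pulse` recovers both parameters
from a sampled waveform by interpolating the -6 dB band edges of its
zero-padded amplitude spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvexArray",
    "PulseModel",
    "build_convex_array",
    "synthesize_pulse",
    "characterize_pulse",
]

# exact -6 dB amplitude ratio and the matching Gaussian full-width factor
_MINUS6DB = 10.0 ** (-6.0 / 20.0)
_GAUSS_6DB_WIDTH = 2.0 * math.sqrt(2.0 * math.log(1.0 / _MINUS6DB))


@dataclass(frozen=True)
class ConvexArray:
    """Convex-array geometry in the imaging (lateral-axial) plane."""

    n_elements: int
    angular_span_deg: float
    arc_width_mm: float
    elevation_mm: float
    elevational_focus_mm: float
    radius_mm: float
    element_positions: np.ndarray  # (N, 2) mm, apex of arc at the origin
    element_normals: np.ndarray    # (N, 2) unit, radially outward
    element_angles_deg: np.ndarray  # (N,) beam angles from the +z axis

    @property
    def center_of_curvature(self) -> np.ndarray:
        """Arc centre, at (0, -radius) below the apex."""
        return np.array([0.0, -self.radius_mm])

    @property
    def pitch_deg(self) -> float:
        return self.angular_span_deg / (self.n_elements - 1)


def build_convex_array(
    n_elements: int = 128,
    angular_span_deg: float = 134.5,
    arc_width_mm: float = 11.4,
    elevation_mm: float = 5.0,
    elevational_focus_mm: float = 30.0,
) -> ConvexArray:
    """Build the convex array; radius follows from arc width / span.

    The angular span is measured between the first and last element
    centres, and the footprint is treated as arc length, so
    ``radius = arc_width / span_in_radians``.
    """
    if n_elements < 2:
        raise ValueError("n_elements must be >= 2")
    if not 0 < angular_span_deg < 360:
        raise ValueError("angular_span_deg must be in (0, 360)")
    if arc_width_mm <= 0:
        raise ValueError("arc_width_mm must be positive")
    span = math.radians(angular_span_deg)
    radius = arc_width_mm / span
    theta = np.radians(
        np.linspace(-angular_span_deg / 2, angular_span_deg / 2, n_elements)
    )
    normals = np.stack([np.sin(theta), np.cos(theta)], axis=1)
    positions = radius * normals + np.array([0.0, -radius])
    return ConvexArray(
        n_elements=n_elements,
        angular_span_deg=angular_span_deg,
        arc_width_mm=arc_width_mm,
        elevation_mm=elevation_mm,
        elevational_focus_mm=elevational_focus_mm,
        radius_mm=radius,
        element_positions=positions,
        element_normals=normals,
        element_angles_deg=np.degrees(theta),
    )


@dataclass(frozen=True)
class PulseModel:
    """Sampled acquisition pulse (peak-normalised)."""

    center_frequency_mhz: float
    fractional_bandwidth: float
    sampling_rate_mhz: float
    times_us: np.ndarray
    waveform: np.ndarray

    @property
    def duration_us(self) -> float:
        return float(self.times_us[-1] - self.times_us[0])


def synthesize_pulse(
    center_frequency_mhz: float = 6.75,
    fractional_bandwidth: float = 0.66,
    sampling_rate_mhz: float = 40.0,
) -> PulseModel:
    """Gaussian-enveloped cosine with a prescribed -6 dB fractional bandwidth.

    The amplitude spectrum is Gaussian with sigma_f such that its -6 dB
    full width equals ``fractional_bandwidth * center_frequency``; by the
    Fourier pair, the time-domain envelope has sigma_t = 1 / (2 pi sigma_f).
    The waveform spans +/- 4 sigma_t and is normalised to unit peak.
    """
    if not 0 < fractional_bandwidth < 2:
        raise ValueError("fractional_bandwidth must be in (0, 2)")
    if sampling_rate_mhz < 4.0 * center_frequency_mhz:
        raise ValueError("sampling rate must be at least 4x the centre frequency")
    sigma_f = fractional_bandwidth * center_frequency_mhz / _GAUSS_6DB_WIDTH
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)  # us, since sigma_f is MHz
    dt = 1.0 / sampling_rate_mhz
    half = math.ceil(4.0 * sigma_t / dt)
    t = np.arange(-half, half + 1) * dt
    wave = np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(
        2.0 * math.pi * center_frequency_mhz * t
    )
    wave = wave / np.abs(wave).max()
    return PulseModel(
        center_frequency_mhz=center_frequency_mhz,
        fractional_bandwidth=fractional_bandwidth,
        sampling_rate_mhz=sampling_rate_mhz,
        times_us=t,
        waveform=wave,
    )


def characterize_pulse(
    waveform: np.ndarray, sampling_rate_mhz: float, pad_factor: int = 16
) -> tuple[float, float]:
    """Estimate (centre frequency MHz, -6 dB fractional bandwidth).

    Zero-pads the waveform, takes the amplitude spectrum, and linearly
    interpolates the -6 dB crossings of the band containing the spectral
    peak.  Centre frequency is the midpoint of the band edges; fractional
    bandwidth is bandwidth / centre frequency.  Scale invariant.
    """
    wave = np.asarray(waveform, dtype=float)
    if wave.size == 0 or not np.any(wave):
        raise ValueError("waveform must be non-zero")
    wave = wave / np.abs(wave).max()  # exact scale invariance
    n = int(2 ** math.ceil(math.log2(len(wave)))) * pad_factor
    spec = np.abs(np.fft.rfft(wave, n=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_mhz)
    peak_idx = int(np.argmax(spec))
    peak = spec[peak_idx]
    thresh = peak * _MINUS6DB
    below = spec < thresh
    lower = np.nonzero(below[:peak_idx])[0]
    upper = np.nonzero(below[peak_idx:])[0]
    if len(upper) == 0 or (peak_idx > 0 and len(lower) == 0 and spec[0] >= thresh):
        # a DC-adjacent band with no lower edge is fine (lower edge at f=0),
        # but the spectrum must come back down somewhere below Nyquist
        if len(upper) == 0:
            raise ValueError("spectrum never falls 6 dB below peak inside Nyquist")
    if len(lower):
        i = lower[-1]
        f_lo = np.interp(thresh, [spec[i], spec[i + 1]], [freqs[i], freqs[i + 1]])
    else:
        f_lo = freqs[0]
    j = peak_idx + upper[0]
    f_hi = np.interp(thresh, [spec[j], spec[j - 1]], [freqs[j], freqs[j - 1]])
    fc = 0.5 * (f_lo + f_hi)
    fbw = (f_hi - f_lo) / fc
    return float(fc), float(fbw)
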