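"""Design and 2-D ray tracing of the dual-geometry illumination lens.

The probe's illumination lens has two independent design planes:

* **lateral-axial plane** (the imaging plane): a two-arc diverging element
  that fans a 13 mm collimated fibre-bundle beam into a wide sector.  The
  default arrangement places the larger arc (11.5 mm, concave to the
  incoming beam) at the entry and the smaller arc (8 mm, centre downstream,
  convex to the beam inside the glass) at the exit.  Marginal rays strike
  the exit face beyond the critical angle and are clipped by total internal
  reflection; the surviving fan spans roughly 105-111 degrees.
* **elevation-axial plane**: a thin prism (planar entry, oblique exit face)
  that deflects the beam toward the imaging plane so the two side-mounted
  beams cross at the design focal depth (25 mm by default).

Angles are degrees at the API boundary and radians internally; coordinates
are (x, z) in mm with +z the depth axis and the beam initially travelling
along +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ray2D",
    "RayBundle",
    "LensDesign",
    "ArcSurface",
    "BeamProfile",
    "LateralTrace",
    "ElevationTrace",
    "refract",
    "trace_lateral",
    "trace_elevation",
    "screen_profile",
    "fwhm",
]

_UNIT_TOL = 1e-8


def _check_unit(v: np.ndarray, name: str) -> None:
    norms = np.linalg.norm(np.atleast_2d(v), axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError(f"{name} must be unit vectors (max |norm-1| = "
                         f"{np.abs(norms - 1).max():.3g})")


@dataclass(frozen=True)
class Ray2D:
    """A geometric ray in one design plane.

    origin: (x, z) in mm; direction: unit 2-vector; weight: relative
    intensity (>= 0).
    """

    origin: np.ndarray
    direction: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if origin.shape != (2,) or direction.shape != (2,):
            raise ValueError("Ray2D origin/direction must be 2-vectors")
        if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
            raise ValueError("Ray2D direction must have unit norm")
        if not self.weight >= 0:
            raise ValueError("Ray2D weight must be >= 0")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)


@dataclass
class RayBundle:
    """A vectorised collection of coplanar rays."""

    origins: np.ndarray      # (N, 2) mm
    directions: np.ndarray   # (N, 2) unit
    weights: np.ndarray      # (N,)

    def __post_init__(self):
        self.origins = np.atleast_2d(np.asarray(self.origins, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.origins.shape != self.directions.shape:
            raise ValueError("origins and directions must share shape")
        if len(self.weights) != len(self.origins):
            raise ValueError("weights length mismatch")
        _check_unit(self.directions, "directions")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def angles_deg(self) -> np.ndarray:
        """Signed direction angle from the +z axis, degrees."""
        return np.degrees(np.arctan2(self.directions[:, 0], self.directions[:, 1]))

    def select(self, mask: np.ndarray) -> "RayBundle":
        return RayBundle(self.origins[mask], self.directions[mask], self.weights[mask])

    def reversed(self) -> "RayBundle":
        return RayBundle(self.origins.copy(), -self.directions, self.weights.copy())


def refract(direction, normal, n_in: float, n_out: float):
    """Vector Snell refraction at an interface.

    Parameters are unit vectors (single (2,) vectors or (N, 2) arrays); the
    normal may point to either side of the interface -- it is re-oriented
    against the incident ray internally.  Returns ``(refracted, tir)`` where
    ``tir`` flags rays for which n_in*sin(theta_in) > n_out (total internal
    reflection); the returned direction of a TIR ray is its (unphysical)
    clamped continuation and should be discarded by the caller.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    single = d.ndim == 1
    d2 = np.atleast_2d(d)
    n2 = np.atleast_2d(n)
    if np.any(np.linalg.norm(n2, axis=-1) < _UNIT_TOL):
        raise ValueError("zero-length normal")
    _check_unit(d2, "direction")
    _check_unit(n2, "normal")
    if n2.shape[0] == 1 and d2.shape[0] > 1:
        n2 = np.broadcast_to(n2, d2.shape)
    # orient normal against the incident ray
    flip = np.einsum("ij,ij->i", d2, n2) > 0
    n2 = np.where(flip[:, None], -n2, n2)
    cos_i = -np.einsum("ij,ij->i", d2, n2)
    eta = n_in / n_out
    sin2_t = eta**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    t = eta * d2 + (eta * cos_i - cos_t)[:, None] * n2
    norm = np.linalg.norm(t, axis=-1, keepdims=True)
    t = np.divide(t, norm, out=np.zeros_like(t), where=norm > 0)
    if single:
        return t[0], bool(tir[0])
    return t, tir


@dataclass(frozen=True)
class ArcSurface:
    """A circular-arc refracting boundary in the design plane.

    ``branch`` selects which half of the circle forms the surface: +1 for
    the half downstream of the centre (points with z > centre z), -1 for
    the upstream half.
    """

    center: tuple[float, float]
    radius: float
    branch: int  # +1 or -1

    def intersect(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Forward path length to the surface (nan where missed)."""
        c = np.asarray(self.center, dtype=float)
        q = origins - c
        b = np.einsum("ij,ij->i", q, directions)
        disc = b**2 - (np.einsum("ij,ij->i", q, q) - self.radius**2)
        sq = np.sqrt(np.clip(disc, 0.0, None))
        s_out = np.full(len(origins), np.nan)
        for s in (-b - sq, -b + sq):
            p = origins + s[:, None] * directions
            on_branch = np.sign(p[:, 1] - c[1]) == self.branch
            good = (disc >= 0) & (s > 1e-9) & on_branch & np.isnan(s_out)
            s_out[good] = s[good]
        return s_out

    def normal_at(self, points: np.ndarray) -> np.ndarray:
        n = (points - np.asarray(self.center)) / self.radius
        return n


@dataclass(frozen=True)
class LensDesign:
    """Two-plane parameterisation of the illumination lens.

    Defaults are the probe's nominal design values: arc radii 8 / 11.5 mm,
    epoxy refractive index 1.519, a 13 mm x 2 mm collimated input beam,
    an 80 degree oblique exit face in elevation, and a 25 mm design focal
    depth.  ``geometry`` selects the lateral-plane surface arrangement:

    * ``"diverging"`` (default): biconcave pair, entry = outer radius
      (concave toward the beam), exit = inner radius with centre downstream.
      Reproduces the ~105 degree design fan.
    * ``"concentric"``: annular meniscus about a common centre (entry =
      inner radius).  A weak diverger (~19 degree fan) that conserves
      Bouguer's invariant n*r*sin(phi) exactly -- useful as a tracer check.
    """

    inner_radius_mm: float = 8.0
    outer_radius_mm: float = 11.5
    refractive_index: float = 1.519
    aperture_lateral_mm: float = 13.0
    aperture_elevation_mm: float = 2.0
    oblique_inclination_deg: float = 80.0
    target_focal_mm: float = 25.0
    source_na: float = 0.22
    geometry: str = "diverging"
    center_thickness_mm: float = 1.0

    def __post_init__(self):
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("require 0 < inner_radius_mm < outer_radius_mm")
        if self.aperture_lateral_mm / 2 >= self.inner_radius_mm:
            raise ValueError("half-aperture must be smaller than the inner "
                             "radius (marginal ray must strike the entry arc)")
        if self.refractive_index <= 1:
            raise ValueError("refractive_index must exceed 1")
        if not 0 < self.oblique_inclination_deg <= 90:
            raise ValueError("oblique_inclination_deg must be in (0, 90]")
        if not 0 <= self.source_na < 1:
            raise ValueError("source_na must be in [0, 1)")
        if self.geometry not in ("diverging", "concentric"):
            raise ValueError("geometry must be 'diverging' or 'concentric'")
        if self.center_thickness_mm <= 0:
            raise ValueError("center_thickness_mm must be positive")

    @classmethod
    def concentric(cls, **kwargs) -> "LensDesign":
        """The annular-meniscus variant (shared arc centre)."""
        kwargs.setdefault("geometry", "concentric")
        return cls(**kwargs)

    # -- lateral-plane surface construction -------------------------------
    def lateral_surfaces(self) -> tuple[ArcSurface, ArcSurface, float]:
        """Entry surface, exit surface and a start z upstream of both."""
        half = self.aperture_lateral_mm / 2.0
        if self.geometry == "concentric":
            entry = ArcSurface((0.0, 0.0), self.inner_radius_mm, +1)
            exit_ = ArcSurface((0.0, 0.0), self.outer_radius_mm, +1)
            return entry, exit_, 0.0
        # diverging biconcave pair; entry rim sits at z = 0
        r1, r2 = self.outer_radius_mm, self.inner_radius_mm
        zc1 = -math.sqrt(r1**2 - half**2)
        entry = ArcSurface((0.0, zc1), r1, +1)
        entry_mid = zc1 + r1
        zc2 = entry_mid + self.center_thickness_mm + r2
        exit_ = ArcSurface((0.0, zc2), r2, -1)
        return entry, exit_, -2.0


@dataclass
class LateralTrace:
    """Result of tracing the lateral-plane lens."""

    entry_rays: RayBundle
    exit_rays: RayBundle          # surviving (non-TIR) rays only
    fov_full_angle_deg: float
    tir_count: int
    tir_weight: float
    surviving_mask: np.ndarray
    glass_rays: RayBundle | None = None   # in-glass segments of survivors


@dataclass
class ElevationTrace:
    deviation_angle_deg: float
    crossing_depth_mm: float      # inf when the beam is undeviated


@dataclass
class BeamProfile:
    """A binned 1-D intensity profile on a screen at fixed depth."""

    depth_mm: float
    positions_mm: np.ndarray
    intensity: np.ndarray
    smoothing_window: int = 30

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        dp = np.diff(self.positions_mm)
        if len(dp) and (np.any(dp <= 0) or not np.allclose(dp, dp[0], rtol=1e-6)):
            raise ValueError("positions must be strictly increasing and uniform")


def trace_lateral(lens: LensDesign, n_rays: int = 1001) -> LateralTrace:
    """Trace ``n_rays`` collimated rays spanning the lateral aperture.

    Returns the surviving exit rays and the full angle between the extreme
    exit-ray directions.  TIR-flagged rays are excluded from the field of
    view and counted in ``tir_count`` / ``tir_weight``.  ``n_rays`` must be
    odd so a chief ray (aperture height 0) exists; the chief ray exits
    undeviated through the axially symmetric surfaces.
    """
    if n_rays < 3 or n_rays % 2 == 0:
        raise ValueError("n_rays must be odd and >= 3")
    n = lens.refractive_index
    half = lens.aperture_lateral_mm / 2.0
    entry, exit_, z0 = lens.lateral_surfaces()

    x = np.linspace(-half, half, n_rays)
    origins = np.stack([x, np.full(n_rays, z0)], axis=1)
    directions = np.tile([0.0, 1.0], (n_rays, 1))
    weights = np.ones(n_rays)
    entry_rays = RayBundle(origins, directions, weights)

    s1 = entry.intersect(origins, directions)
    if np.any(np.isnan(s1)):
        raise ValueError("marginal ray misses the entry arc")
    p1 = origins + s1[:, None] * directions
    d1, tir1 = refract(directions, entry.normal_at(p1), 1.0, n)

    s2 = exit_.intersect(p1, d1)
    missed = np.isnan(s2)  # rays leaving through the lens rim are lost
    p2 = p1 + np.nan_to_num(s2)[:, None] * d1
    normals = exit_.normal_at(p2)
    normals[missed] = np.array([0.0, 1.0])  # placeholder; masked out below
    d2, tir2 = refract(d1, normals, n, 1.0)

    dead = tir1 | tir2 | missed
    alive = ~dead
    if not np.any(alive):
        raise ValueError("no rays survive the lens")
    exit_rays = RayBundle(p2[alive], d2[alive], weights[alive])
    glass_rays = RayBundle(p1[alive], d1[alive], weights[alive])
    ang = exit_rays.angles_deg
    fov = float(ang.max() - ang.min())
    return LateralTrace(
        entry_rays=entry_rays,
        exit_rays=exit_rays,
        fov_full_angle_deg=fov,
        tir_count=int(dead.sum()),
        tir_weight=float(weights[dead].sum()),
        surviving_mask=alive,
        glass_rays=glass_rays,
    )


def trace_elevation(lens: LensDesign,
                    beam_center_offset_mm: float = 2.316) -> ElevationTrace:
    """Thin-prism model of the planar-oblique elevation-plane lens.

    The beam enters the planar face at normal incidence and refracts at the
    oblique exit face, whose inclination to the beam axis is
    ``oblique_inclination_deg`` (apex angle ``90 - inclination``).  The
    deviated chief ray crosses the imaging plane at
    ``offset / tan(deviation)``.
    """
    if beam_center_offset_mm <= 0:
        raise ValueError("beam_center_offset_mm must be positive")
    apex = math.radians(90.0 - lens.oblique_inclination_deg)
    n = lens.refractive_index
    arg = n * math.sin(apex)
    if arg >= 1.0:
        raise ValueError("oblique face beyond total internal reflection")
    deviation = math.asin(arg) - apex
    if deviation <= 0:
        return ElevationTrace(0.0, math.inf)
    crossing = beam_center_offset_mm / math.tan(deviation)
    return ElevationTrace(math.degrees(deviation), crossing)


def screen_profile(source, depth_mm: float, bin_width_mm: float = 0.25,
                   smoothing_window: int = 30) -> BeamProfile:
    """Bin ray weights (or deposited fluence) on a 1-D screen at ``depth_mm``.

    ``source`` is a :class:`RayBundle` of exit rays or a fluence grid (any
    object with ``deposited_weight``, ``axes`` attributes, see
    :mod:`truspa.photon_transport`).  The profile integral equals the total
    weight reaching the screen.  For a fluence grid the native lateral axis
    is used and ``bin_width_mm`` is ignored.
    """
    if hasattr(source, "deposited_weight"):
        return _grid_profile(source, depth_mm, smoothing_window)
    rays: RayBundle = source
    dz = rays.directions[:, 1]
    run = depth_mm - rays.origins[:, 1]
    forward = (dz > 1e-12) & (run > 0)
    if not np.any(forward):
        raise ValueError(f"no energy at depth {depth_mm} mm")
    t = run[forward] / dz[forward]
    hits = rays.origins[forward, 0] + t * rays.directions[forward, 0]
    w = rays.weights[forward]
    lo = math.floor(hits.min() / bin_width_mm) - 1
    hi = math.ceil(hits.max() / bin_width_mm) + 1
    edges = np.arange(lo, hi + 1) * bin_width_mm
    intensity, _ = np.histogram(hits, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return BeamProfile(depth_mm, centers, intensity, smoothing_window)


def _grid_profile(grid, depth_mm: float, smoothing_window: int) -> BeamProfile:
    xs, ys, zs = grid.axes
    if not (zs[0] <= depth_mm <= zs[-1]):
        raise ValueError(f"no energy at depth {depth_mm} mm (outside grid)")
    iz = int(np.clip(np.searchsorted(zs, depth_mm) - 1, 0, len(zs) - 2))
    slab = grid.deposited_weight[:, :, iz]
    intensity = slab.sum(axis=1)
    if intensity.sum() <= 0:
        raise ValueError(f"no energy at depth {depth_mm} mm")
    centers = 0.5 * (xs[:-1] + xs[1:])
    return BeamProfile(depth_mm, centers, intensity, smoothing_window)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average (length-30 profile smoother)."""
    window = int(max(1, min(window, len(values))))
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def fwhm(profile: BeamProfile) -> float:
    """Full width at half maximum between the *outermost* half-max crossings.

    The profile is first smoothed with the profile's moving-average window.
    Using the outermost crossings makes the width well defined for bimodal
    (split-beam) profiles.
    """
    y = moving_average(profile.intensity, profile.smoothing_window)
    x = profile.positions_mm
    peak = y.max()
    if peak <= 0:
        raise ValueError("no energy in profile")
    half = peak / 2.0
    above = y >= half
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    # linear interpolation of the outermost crossings
    if i0 > 0:
        x_lo = np.interp(half, [y[i0 - 1], y[i0]], [x[i0 - 1], x[i0]])
    else:
        x_lo = x[i0]
    if i1 < len(y) - 1:
        x_hi = np.interp(half, [y[i1 + 1], y[i1]], [x[i1 + 1], x[i1]])
    else:
        x_hi = x[i1]
    return float(x_hi - x_lo)


def bouguer_invariant(rays: RayBundle, center, n: float) -> np.ndarray:
    """n * r * sin(phi) about ``center`` for each ray (Bouguer's theorem).

    For refraction at surfaces concentric about ``center`` this quantity is
    conserved along every ray; it is an independent check of the concentric
    tracer.
    """
    c = np.asarray(center, dtype=float)
    rel = rays.origins - c
    cross = rel[:, 0] * rays.directions[:, 1] - rel[:, 1] * rays.directions[:, 0]
    return n * np.abs(cross)
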