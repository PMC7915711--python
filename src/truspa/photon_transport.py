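"""Monte Carlo photon-packet transport in homogeneous turbid media.

Weighted-packet (MCML-style) transport with exponential step sampling,
fractional absorption mu_a/mu_t per interaction, Henyey-Greenstein
scattering and Russian roulette.  Boundaries are index-matched (no Fresnel
refraction at the domain faces); a packet terminates when it leaves the
domain box, and its residual weight is tallied as transmitted (+z face),
reflected (-z face) or a side exit.  All randomness flows through an
explicit seed / numpy Generator.

Units: mm for lengths, 1/mm for optical coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from truspa import lens_optics
from truspa.lens_optics import BeamProfile, ElevationTrace, LateralTrace

__all__ = [
    "Medium",
    "PhotonPacket",
    "FluenceGrid",
    "GridSpec",
    "SourceSpec",
    "MEDIUM_PRESETS",
    "hg_sample",
    "propagate",
    "simulate_fluence",
    "slab_transmission",
]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 10.0


@dataclass(frozen=True)
class Medium:
    """Optical properties of a homogeneous turbid medium."""

    mu_a: float          # absorption, 1/mm
    mu_s: float          # scattering, 1/mm
    g: float = 0.0       # Henyey-Greenstein anisotropy, |g| < 1
    n: float = 1.33      # refractive index

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if not abs(self.g) < 1:
            raise ValueError("|g| must be < 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def reduced_mu_s(self) -> float:
        return self.mu_s * (1.0 - self.g)


#: Named presets.  "milk3" emulates the 3% milk solution used as the wire
#: phantom bath: reduced scattering 1.0/mm (g = 0.9), weak absorption.
#: These are configuration defaults, not asserted literature values.
MEDIUM_PRESETS: dict[str, Medium] = {
    "milk3": Medium(mu_a=0.002, mu_s=10.0, g=0.9, n=1.33),
    "transparent": Medium(mu_a=0.0, mu_s=0.0, g=0.0, n=1.33),
}


@dataclass(frozen=True)
class PhotonPacket:
    """A single weighted photon packet (scalar API; batches are internal)."""

    position: np.ndarray   # (3,) mm
    direction: np.ndarray  # (3,) unit
    weight: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if p.shape != (3,) or d.shape != (3,):
            raise ValueError("position/direction must be 3-vectors")
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("direction must have unit norm")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid specification: axis extents (mm) and voxel size (mm)."""

    x_extent: tuple[float, float] = (-25.0, 25.0)
    y_extent: tuple[float, float] = (-6.0, 6.0)
    z_extent: tuple[float, float] = (0.0, 40.0)
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        for lo, hi in (self.x_extent, self.y_extent, self.z_extent):
            if hi <= lo:
                raise ValueError("grid extents must be increasing")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class FluenceGrid:
    """Voxelised deposited-weight map plus exit-weight bookkeeping."""

    spec: GridSpec
    deposited_weight: np.ndarray      # (nx, ny, nz)
    interaction_counts: np.ndarray    # (nx, ny, nz) int64
    photons_launched: int
    seed: int | None
    transmitted_weight: float = 0.0
    reflected_weight: float = 0.0
    side_weight: float = 0.0
    roulette_net: float = 0.0         # killed minus boost-gained weight
    truncated_weight: float = 0.0     # packets stopped at the event cap

    @classmethod
    def empty(cls, spec: GridSpec, seed: int | None = None) -> "FluenceGrid":
        shape = tuple(
            int(round((hi - lo) / spec.voxel_size_mm))
            for lo, hi in (spec.x_extent, spec.y_extent, spec.z_extent)
        )
        return cls(spec, np.zeros(shape), np.zeros(shape, dtype=np.int64), 0, seed)

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel edge coordinates per axis."""
        s = self.spec
        return tuple(
            np.linspace(lo, hi, n + 1)
            for (lo, hi), n in zip(
                (s.x_extent, s.y_extent, s.z_extent), self.deposited_weight.shape
            )
        )

    @property
    def total_deposited(self) -> float:
        return float(self.deposited_weight.sum())

    def balance(self) -> float:
        """Launched weight minus all tallies; ~0 up to float accumulation."""
        return (
            self.photons_launched
            - self.total_deposited
            - self.transmitted_weight
            - self.reflected_weight
            - self.side_weight
            - self.roulette_net
            - self.truncated_weight
        )


def hg_sample(g: float, rng: np.random.Generator, size: int | None = None):
    """Sample deflection cosine(s) from the Henyey-Greenstein phase function.

    For g = 0 the distribution is uniform on [-1, 1]; E[cos theta] = g.
    """
    if not abs(g) < 1:
        raise ValueError("|g| must be < 1")
    u = rng.random(size)
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


def _scatter(directions: np.ndarray, g: float, rng: np.random.Generator) -> np.ndarray:
    """MCML direction update: HG polar deflection, uniform azimuth."""
    n = len(directions)
    cos_t = np.asarray(hg_sample(g, rng, n))
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * np.pi * rng.random(n)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    ux, uy, uz = directions[:, 0], directions[:, 1], directions[:, 2]
    near_pole = np.abs(uz) > 0.99999
    denom = np.sqrt(np.clip(1.0 - uz**2, 1e-30, None))
    nx = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
    ny = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
    nz = -sin_t * cos_p * denom + uz * cos_t
    # packets travelling along +/-z: rotate about the pole directly
    pz = np.sign(uz)
    nx = np.where(near_pole, sin_t * cos_p, nx)
    ny = np.where(near_pole, sin_t * sin_p, ny)
    nz = np.where(near_pole, pz * cos_t, nz)
    out = np.stack([nx, ny, nz], axis=1)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _exit_face(pos, direction, bounds):
    """Distance to the first domain face along ``direction`` and face id.

    Face ids: 0 -z (reflected), 1 +z (transmitted), 2 lateral side.
    ``bounds`` is ((x0,x1),(y0,y1),(z0,z1)); x/y bounds may be None for an
    unbounded lateral extent.
    """
    n = len(pos)
    s_min = np.full(n, np.inf)
    face = np.full(n, -1, dtype=np.int8)
    axes = []
    (xb, yb, zb) = bounds
    if xb is not None:
        axes.append((0, xb, 2, 2))
    if yb is not None:
        axes.append((1, yb, 2, 2))
    axes.append((2, zb, 0, 1))
    for axis, (lo, hi), face_lo, face_hi in axes:
        d = direction[:, axis]
        p = pos[:, axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            s_lo = (lo - p) / d
            s_hi = (hi - p) / d
        for s, f in ((s_lo, face_lo), (s_hi, face_hi)):
            valid = np.isfinite(s) & (s > 0) & (s < s_min)
            s_min[valid] = s[valid]
            face[valid] = f
    return s_min, face


def _transport(
    positions: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray,
    medium: Medium,
    rng: np.random.Generator,
    grid: FluenceGrid | None,
    z_bounds: tuple[float, float],
    lateral_bounds=None,
    roulette_threshold: float = ROULETTE_THRESHOLD,
    max_events: int = 200_000,
) -> dict:
    """Vectorised transport of a packet batch; returns tally dict."""
    if np.any(~np.isfinite(positions)):
        raise FloatingPointError("non-finite packet position (tracer bug)")
    mu_t = medium.mu_t
    albedo_loss = medium.mu_a / mu_t if mu_t > 0 else 0.0
    tally = dict(transmitted=0.0, reflected=0.0, side=0.0,
                 absorbed=0.0, roulette_net=0.0, truncated=0.0)

    if lateral_bounds is None:
        bounds = (None, None, z_bounds)
    else:
        bounds = (lateral_bounds[0], lateral_bounds[1], z_bounds)

    if grid is not None:
        spec = grid.spec
        origin = np.array([spec.x_extent[0], spec.y_extent[0], spec.z_extent[0]])
        nshape = grid.deposited_weight.shape
        flat_dep = grid.deposited_weight.reshape(-1)
        flat_cnt = grid.interaction_counts.reshape(-1)

    pos, d, w = positions.copy(), directions.copy(), weights.copy()
    for _ in range(max_events):
        if len(w) == 0:
            break
        if mu_t == 0.0:
            s_exit, face = _exit_face(pos, d, bounds)
            for f, key in ((0, "reflected"), (1, "transmitted"), (2, "side")):
                tally[key] += w[face == f].sum()
            stuck = ~np.isfinite(s_exit)
            tally["truncated"] += w[stuck].sum()
            pos = pos[:0]
            break
        step = -np.log(rng.random(len(w))) / mu_t
        s_exit, face = _exit_face(pos, d, bounds)
        exits = step >= s_exit
        if np.any(exits):
            for f, key in ((0, "reflected"), (1, "transmitted"), (2, "side")):
                tally[key] += w[exits & (face == f)].sum()
        keep = ~exits
        pos = pos[keep] + step[keep, None] * d[keep]
        d, w = d[keep], w[keep]
        if len(w) == 0:
            break
        # absorption deposit
        dw = w * albedo_loss
        if grid is not None and dw.size:
            ijk = np.floor((pos - origin) / spec.voxel_size_mm).astype(np.int64)
            inside = np.all((ijk >= 0) & (ijk < np.array(nshape)), axis=1)
            if np.any(inside):
                flat = np.ravel_multi_index(
                    (ijk[inside, 0], ijk[inside, 1], ijk[inside, 2]), nshape
                )
                np.add.at(flat_dep, flat, dw[inside])
                np.add.at(flat_cnt, flat, 1)
            # deposits outside the grid (unbounded domains) count as side loss
            tally["side"] += dw[~inside].sum()
        elif dw.size:
            tally["absorbed"] += dw.sum()  # absorbed weight without a grid tally
        w = w - dw
        # Russian roulette (zero-weight packets are always terminated)
        low = w < roulette_threshold
        if np.any(low):
            survive = (rng.random(low.sum()) < (1.0 / ROULETTE_SURVIVAL)) & (w[low] > 0)
            killed = np.zeros(len(w), dtype=bool)
            killed[np.nonzero(low)[0][~survive]] = True
            boosted = np.nonzero(low)[0][survive]
            tally["roulette_net"] += w[killed].sum()
            tally["roulette_net"] -= w[boosted].sum() * (ROULETTE_SURVIVAL - 1.0)
            w[boosted] *= ROULETTE_SURVIVAL
            keep = ~killed
            pos, d, w = pos[keep], d[keep], w[keep]
            if len(w) == 0:
                break
        if medium.mu_s > 0:
            # weighted scheme: every interaction deposits mu_a/mu_t and scatters
            d = _scatter(d, medium.g, rng)
        # mu_s == 0: direction unchanged; packet marches until it exits.
    if len(pos):
        tally["truncated"] += w.sum()
    return tally


def propagate(
    packet: PhotonPacket,
    medium: Medium,
    rng: np.random.Generator,
    grid: FluenceGrid,
    roulette_threshold: float = ROULETTE_THRESHOLD,
) -> dict:
    """Transport a single packet through ``medium``, depositing into ``grid``.

    The domain box is the grid's extents.  Returns the tally dict for the
    packet (transmitted / reflected / side / roulette_net weights).
    """
    spec = grid.spec
    tally = _transport(
        packet.position[None, :],
        packet.direction[None, :],
        np.array([packet.weight]),
        medium,
        rng,
        grid,
        z_bounds=spec.z_extent,
        lateral_bounds=(spec.x_extent, spec.y_extent),
        roulette_threshold=roulette_threshold,
    )
    grid.photons_launched += 1
    grid.transmitted_weight += tally["transmitted"]
    grid.reflected_weight += tally["reflected"]
    grid.side_weight += tally["side"]
    grid.roulette_net += tally["roulette_net"]
    grid.truncated_weight += tally["truncated"]
    return tally


# ---------------------------------------------------------------------------
# sources

@dataclass(frozen=True)
class SourceSpec:
    """Illumination source for fluence simulation.

    ``kind`` is ``"bare"`` (rectangular fibre-bundle aperture with numerical
    aperture ``na``, beams parallel to the depth axis) or ``"lens"``
    (directions resampled from a lateral lens trace, tilted in elevation by
    the planar-oblique deviation).  Two bundles at y = +/- ``y_offset_mm``
    model the probe's two-sided illumination; set ``two_sided=False`` for a
    single centred aperture.
    """

    kind: str = "bare"
    width_mm: float = 13.0
    height_mm: float = 2.0
    na: float = 0.66
    y_offset_mm: float = 2.316
    two_sided: bool = True
    lateral_trace: LateralTrace | None = None
    elevation: ElevationTrace | None = None
    lens_divergence: bool = True  # smear lens exit rays by the bundle NA

    def __post_init__(self):
        if self.kind not in ("bare", "lens"):
            raise ValueError("source kind must be 'bare' or 'lens'")
        if self.kind == "lens" and self.lateral_trace is None:
            raise ValueError("lens source requires a lateral_trace")

    def sample(self, n: int, rng: np.random.Generator):
        y_local = (rng.random(n) - 0.5) * self.height_mm
        if self.two_sided:
            side = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            y = side * self.y_offset_mm + y_local
        else:
            side = np.zeros(n)
            y = y_local
        if self.kind == "bare":
            x = (rng.random(n) - 0.5) * self.width_mm
            pos = np.stack([x, y, np.zeros(n)], axis=1)
            dirs = _cone_directions(self.na, n, rng)
            return pos, dirs, np.ones(n)
        # lens: resample traced exit rays by weight
        trace = self.lateral_trace
        w = trace.exit_rays.weights
        idx = rng.choice(len(w), size=n, p=w / w.sum())
        ox = trace.exit_rays.origins[idx, 0]
        oz = trace.exit_rays.origins[idx, 1]
        oz = oz - trace.exit_rays.origins[:, 1].max()  # exit face at z <= 0
        dlat = trace.exit_rays.directions[idx]
        dev = math.radians(self.elevation.deviation_angle_deg) if self.elevation else 0.0
        # rotate each lateral direction about the x-axis, tilting toward y=0
        tilt = -side * dev
        dx = dlat[:, 0]
        dz_plane = dlat[:, 1]
        dy = dz_plane * np.sin(tilt)
        dz = dz_plane * np.cos(tilt)
        dirs = np.stack([dx, dy, dz], axis=1)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        if self.lens_divergence and self.na > 0:
            # the design trace assumes a collimated input; the physical
            # bundle diverges at its NA, so smear each exit ray by the
            # same cone the bare source uses
            dirs = _smear_cone(dirs, self.na, rng)
        pos = np.stack([ox, y, oz], axis=1)
        return pos, dirs, np.ones(n)


def _smear_cone(dirs: np.ndarray, na: float,
                rng: np.random.Generator) -> np.ndarray:
    """Rotate each direction by a random offset within the NA cone."""
    n = len(dirs)
    local = _cone_directions(na, n, rng)
    ref = np.where(np.abs(dirs[:, 0:1]) < 0.9, [[1.0, 0.0, 0.0]],
                   [[0.0, 1.0, 0.0]])
    u = np.cross(dirs, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(dirs, u)
    out = (local[:, 0:1] * u + local[:, 1:2] * v + local[:, 2:3] * dirs)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _cone_directions(na: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Directions uniform in solid angle within the NA cone about +z."""
    if na <= 0:
        return np.tile([0.0, 0.0, 1.0], (n, 1))
    cos_max = math.cos(math.asin(min(na, 1.0 - 1e-12)))
    cos_t = 1.0 - rng.random(n) * (1.0 - cos_max)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * np.pi * rng.random(n)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def simulate_fluence(
    source: SourceSpec,
    medium: Medium,
    grid_spec: GridSpec = GridSpec(),
    n_photons: int = 100_000,
    seed: int = 0,
    profile_depths_mm: tuple[float, ...] = (),
    batch_size: int = 100_000,
) -> tuple[FluenceGrid, list[BeamProfile]]:
    """Monte Carlo fluence map for a source in a turbid medium.

    Deterministic for a fixed seed.  Optionally extracts lateral beam
    profiles at the requested depths (via
    :func:`truspa.lens_optics.screen_profile`).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    grid = FluenceGrid.empty(grid_spec, seed)
    remaining = n_photons
    while remaining > 0:
        n = min(batch_size, remaining)
        pos, dirs, w = source.sample(n, rng)
        # start just upstream of the grid and advance to the z=z0 face
        z0 = grid_spec.z_extent[0]
        dt = (z0 - pos[:, 2]) / dirs[:, 2]
        ahead = dt > 0
        pos[ahead] += dt[ahead, None] * dirs[ahead]
        in_face = (
            (pos[:, 0] >= grid_spec.x_extent[0]) & (pos[:, 0] <= grid_spec.x_extent[1])
            & (pos[:, 1] >= grid_spec.y_extent[0]) & (pos[:, 1] <= grid_spec.y_extent[1])
        )
        grid.side_weight += float(w[~in_face].sum())
        tally = _transport(
            pos[in_face], dirs[in_face], w[in_face], medium, rng, grid,
            z_bounds=grid_spec.z_extent,
            lateral_bounds=(grid_spec.x_extent, grid_spec.y_extent),
        )
        grid.transmitted_weight += tally["transmitted"]
        grid.reflected_weight += tally["reflected"]
        grid.side_weight += tally["side"]
        grid.roulette_net += tally["roulette_net"]
        grid.truncated_weight += tally["truncated"]
        remaining -= n
    grid.photons_launched = n_photons
    if grid.total_deposited == 0 and medium.mu_a > 0:
        import warnings

        warnings.warn("no photons deposited energy in the grid", stacklevel=2)
    profiles = [lens_optics.screen_profile(grid, z) for z in profile_depths_mm]
    return grid, profiles


def slab_transmission(
    medium: Medium,
    thickness_mm: float,
    n_photons: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Transmitted weight fraction through a laterally infinite slab.

    A pencil beam enters at z=0 along +z; returns ``(fraction, standard
    error)`` where the standard error is the binomial-style Monte Carlo
    estimate sqrt(f (1-f) / N).
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_photons, 3))
    dirs = np.tile([0.0, 0.0, 1.0], (n_photons, 1))
    w = np.ones(n_photons)
    tally = _transport(
        pos, dirs, w, medium, rng, grid=None,
        z_bounds=(0.0, thickness_mm), lateral_bounds=None,
    )
    frac = tally["transmitted"] / n_photons
    se = math.sqrt(max(frac * (1.0 - frac), 1e-300) / n_photons)
    return float(frac), float(se)
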