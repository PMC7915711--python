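# Methods

This note records the models behind `truspa`, the parameters that matter,
the design choices that were genuinely open, and what the synthetic-data
tests do and do not establish. Units are mm, µs, MHz and degrees at every
API boundary; radians are used internally.

## Illumination lens

### Lateral–axial plane (imaging plane)

The lens is traced as two sequential circular-arc boundaries with vector
Snell refraction; reflection losses (Fresnel and stray reflections) are
ignored, matching the collimated-ray design idealisation. The printed
design constants are: arc radii 8 and 11.5 mm, refractive index 1.519
(cast epoxy), beam width 13 mm.

**Surface arrangement.** The radii alone do not fix the lens: the axial
placement and orientation of the two arcs are free. Three candidate
arrangements were traced:

| arrangement | traced full fan |
|---|---|
| concentric annular meniscus (shared centre, entry 8 → exit 11.5) | 18.9° |
| biconcave, entry concave R = 8, exit R = 11.5 centre downstream | ~125° |
| **biconcave, entry concave R = 11.5, exit R = 8 centre downstream** | **111°** |

A concentric meniscus is bounded by Bouguer's theorem (n·r·sin φ conserved
about the shared centre), which caps the deflection of a 13 mm collimated
beam at ~19° regardless of parameters — far short of the ~105° design
target. The default is therefore the third arrangement: along the light
path the first face is concave to the incoming beam and the second face
bulges *toward* the beam inside the glass (concave–convex along the path;
8 mm is the smaller/inner radius, 11.5 mm the outer). Its wide fan is
produced by refraction near the critical angle at the exit face, and the
rays beyond it (≈30% of the aperture) are clipped by total internal
reflection; they are counted and reported, never silently dropped. The fan
of surviving rays spans 111° at 1001 rays and is stable in ray count and
in the one remaining free parameter, the centre thickness (103–111° over
0.5–2 mm; default 1.0 mm, a practical minimum for a small cast-epoxy
part). The concentric arrangement remains available
(`LensDesign.concentric()`); because Bouguer's invariant must hold exactly
there, it doubles as an independent correctness check of the tracer
(conservation to 1e-9 is enforced in the tests).

**Field-of-view definition.** FOV is the full angle between the extreme
*surviving* exit-ray directions. An intensity-threshold definition (e.g.
−6 dB fluence width) would be an alternative; the extreme-ray definition
is used because the design quantity of interest is the illuminated sector,
and it is deterministic.

### Elevation–axial plane

A thin prism with a planar entry face (normal incidence) and an oblique
exit face inclined 80° to the beam axis (apex angle 10°). The exact prism
deviation is δ = asin(n·sin A) − A = 5.294°. The chief ray from a source
offset `b` from the imaging plane crosses the plane at depth b/tan δ. The
offset is not a printed quantity; the default 2.316 mm is back-computed so
the crossing sits at the 25 mm design focal depth (plausible for a bundle
seated beside a 5 mm-tall array) and is a config field, not a constant.

### Profiles and FWHM

Screen profiles bin ray weights (or grid fluence) on a 1-D lateral axis at
a given depth; the profile integral equals the weight reaching the screen.
FWHM is measured between the *outermost* half-maximum crossings after a
centred moving average (default length 30 samples). The outermost-crossing
convention keeps the width well defined for bimodal profiles, such as the
two separated beams of a bare two-bundle source at shallow depth.

## Monte Carlo photon transport

Weighted photon packets, MCML style: step lengths s = −ln U/μt; at each
interaction a fraction μa/μt of the packet weight is deposited in the
enclosing voxel and the direction is redrawn from the Henyey–Greenstein
phase function (sampled by the standard closed-form inverse; g = 0 reduces
to an isotropic cosine). Russian roulette below weight 1e-4 with survival
factor 10. Boundaries are index-matched: a packet leaving the domain box
terminates and its weight is tallied as transmitted (+z), reflected (−z)
or a side exit, so

absorbed + transmitted + reflected + side + roulette-net = launched

holds to floating-point accumulation (enforced at 1e-9 relative). All
randomness flows through `numpy.random.default_rng(seed)`; a fixed seed
reproduces grids bit for bit.

The **"milk3" preset** (μs′ = 1.0/mm via μs = 10/mm, g = 0.9; μa =
0.002/mm; n = 1.33) is a configuration default standing in for a 3% milk
bath — a plausible reduced-scattering value, not an asserted measurement.

**Sources.** The bare source is a 13 × 2 mm rectangular aperture emitting
uniformly in solid angle within its NA cone (default NA 0.66, the bench
bundle). The lens source resamples the traced exit rays by weight. Two
bundles at y = ±2.316 mm model the probe's two-sided illumination; lens
bundles are tilted by the elevation deviation so they cross the imaging
plane at the design focus. Because the physical bundle is divergent, the
lens source by default smears each exit direction over the bundle-NA cone
(`lens_divergence=True`); setting it to `False` gives the collimated
design-mode fan.

The two modes answer different questions, and the tests use them
accordingly. In the *collimated* mode the lens delivers measurably more
imaging-plane fluence at 10–20 mm than the bare NA-0.66 source (ratio
≈1.1–1.25 in the milk preset) — the qualitative direction of the bench
comparison; the measured 5.3×/4.6× bench ratios are physical CCD
measurements in air and are not reproduced at desk scale. In the
*divergent* mode the smear removes the fan's caustic dark bands, which is
what matters for wire-ring coverage, but the plane-delivery contrast
washes out to ≈1 — strong diffusion plus a ±41° source cone erase source
directionality within a few transport mean free paths. A green directional
test therefore establishes ordering under the stated mode, not any
quantitative illumination gain.

**Cost scaling.** Conservation and Beer–Lambert acceptance checks run at
1e5 packets (ballistic: seconds). Diffusive comparisons (μs′ = 1/mm) use
2–5 × 10⁴ packets on 1 mm voxels to stay within a single-CPU test budget;
at those counts the per-voxel plane fluence carries ~10–30% noise, which
is why directional tests compare region sums or apply a 6 dB margin.

## Convex array and acquisition pulse

Element centres are equally spaced in angle over the 134.5° span, read as
the first-to-last element angle; the 11.4 mm footprint is treated as arc
length, giving radius 11.4/span = 4.856 mm (arc vs chord differs by <2% at
this curvature). The apex of the arc is the coordinate origin; +z is
depth; normals are radial. Element directivity is omitted by default so
channel-level tests are deterministic.

The pulse is a Gaussian-enveloped cosine. The −6 dB convention is applied
to the *amplitude* spectrum with the exact factor 10^(−6/20) = 0.5012 (not
the half-amplitude approximation) in both synthesis and characterisation,
so the round trip is exact by construction and recovers (fc, fbw) to ≪1%
across 2–15 MHz and 30–100% bandwidth. Characterisation zero-pads 16×,
takes the band containing the spectral peak and interpolates the crossing
frequencies linearly.

## PA / US channel-data synthesis

Wires (100 µm) are 2-D point sources: at 6.75 MHz the acoustic wavelength
is ~228 µm, so the wires are sub-resolution scatterers. PA arrivals are
one-way (|p − x_e|/c), US pulse-echo arrivals two-way with the transmit
reference at the scanline's element; amplitudes carry 1/r (PA) or
1/(r_tx·r_rx) (US) spherical spreading, an illumination weight interpolated
from the imaging-plane fluence, and optional frequency-linear attenuation
(off by default — the phantom bath is milk, not tissue). Fractional delays
use linear interpolation (a windowed-sinc variant would reduce the small
carrier-dependent amplitude ripple; tests that check amplitude laws place
targets at whole-sample delays to factor this out). Noise is white
Gaussian at a configured SNR with an explicit seed — laser-induced
interference on the bench appears only as this generic term.

## Beamforming and display

Scanlines are co-located with the 128 elements and steered radially; this
makes the walking-aperture arithmetic exact: with a 64-channel aperture
the outermost scanline keeps 32 channels and the centre one 64.
Apodization is rectangular (matching that count bookkeeping); Hann could
be added but would change none of the printed counts. The range axis
starts at the element arc (r = 0 on the transducer face). Delay-and-sum
uses the analytic one-way/two-way delays with fractional-sample lookup;
focal points outside the recorded window contribute zero and are counted.
The coherence factor |Σs|²/(N Σ|s|²) is offered as an *explicitly labelled
stand-in* for adaptive beamforming — it is not a reproduction of any
published adaptive algorithm. Envelope detection is the analytic-signal
magnitude along range; log compression maps a dynamic range DR onto [0,1]
as max(0, 1 + 20·log10(env/max)/DR) (display defaults: PA 35 dB, US 55 dB,
overlay PA 25 dB). Scan conversion inverts the convex-sector geometry
about the arc centre and interpolates bilinearly; pixels outside the
sector are masked.

## Synthetic data: what a green test establishes

The generators emulate the *geometry and bookkeeping* of the bench
experiments: the 66-wire radial phantom, two-sided illumination, walking
apertures, display compression. They do not emulate transducer element
response, laser pulse energy and shape, acoustic attenuation and
reverberation, speckle from real microstructure, or electronic
interference. Green tests therefore establish internal physical
consistency (conservation laws, closed-form limits, geometry inversion,
localisation of known targets, directional orderings) — not agreement with
any bench-measured intensity ratio.

## Numerical choices

* Unit-vector validation at 1e-6; Snell oracle agreement asserted at 1e-9.
* Arc intersection takes the nearest forward root on the declared half of
  the circle; rays missing the exit arc leave through the lens rim and are
  treated as lost, like TIR rays.
* FWHM crossings and spectral band edges are linearly interpolated.
* The intestinal transmission preset is piecewise linear over 650–975 nm;
  only its 780 nm peak (0.263) and 650:25:975-grid mean (0.219) are
  constrained — the shape between anchors (near-infrared window rise,
  water-absorption dip toward 975 nm) is a synthetic stand-in, affinely
  calibrated once at import so both constraints hold exactly.
* All stochastic APIs take explicit integer seeds; the pipeline manifest
  stores a config hash and a SHA-256 of each numeric artifact.

## Known limitations

* Geometric optics only: no diffraction, polarisation or dispersion; the
  surface prescription of the physical lens is inferred from its printed
  radii, and other prescriptions consistent with them exist.
* Single homogeneous medium (plus an optional covering-slab scaling); no
  voxel-wise heterogeneity, no Fresnel refraction at medium boundaries.
* Single-scattering acoustic model; no full-wave propagation, no
  nonlinearity, no elevation (3-D) beamforming.
* The adaptive beamformer used on the original bench system is out of
  scope; the coherence factor is a qualitative substitute.
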