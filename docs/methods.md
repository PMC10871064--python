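# Methods

`harmotrack` is a desk-scale in-silico workbench for studying how the choice
of ultrasound tracking-beam sequence affects harmonic motion imaging (HMI)
displacement maps. This note documents the models, their assumptions, the
tunable parameters, and the numerical choices, in enough detail to judge
what the simulations can and cannot say about a physical HMI system.

## System model

The simulated rig mirrors a confocal single-system HMI setup:

* **FUS transducer** — an annular spherically focused bowl (center frequency
  4.5 MHz, outer diameter 80 mm, central opening 41 mm, radius of curvature
  76 mm) that delivers an amplitude-modulated acoustic radiation force.
* **Imaging array** — a 104-element phased array (center frequency 7.8 MHz,
  pitch 11.81/104 mm, full aperture 11.81 mm, 5–12 MHz band) aligned through
  the bowl's opening, with its tracking focus co-located with the FUS focus
  at 31 mm depth.
* **Timing** — a 500-µs interleaved pulse: 70-µs FUS burst, an idle gap
  (90 µs, shortened to 40 µs when five compounding plane waves must fit),
  then the pulse-echo tracking events; tracking frame rate 2 kHz.

The speed of sound is fixed at c = 1.54 mm/µs throughout (soft tissue;
consistent with the 4λ = 0.79 mm tracking window at 7.8 MHz).

### Focal field

The bowl's continuous-wave field is computed by a Rayleigh–Sommerfeld
integral over the spherical cap, meshed into patches no larger than λ/6
(halving the patch size changes the focal peak by < 0.5%). The full-disc
limit of the integral reproduces the analytic paraxial jinc focal pattern to
better than 1% RMS, and the annular geometry's transverse −6 dB focal width
comes out at ≈ 0.40 mm with a ≈ 3.7 mm axial width — close to the 0.39 mm ×
4.3 mm hydrophone characterization of the physical transducer. The width
criterion is defined here as the **pressure −6 dB full width** (the
measurement convention for the physical spot is not uniquely determined;
the acceptance tolerance of ±15% absorbs the −3 dB/−6 dB ambiguity).

For the mechanics surrogate, a separable intensity model I(x, z) =
T(x)·A(z) is built from the exact transverse and axial Rayleigh lines
through the focus (peak-normalized). It is exact on both axes and smooth in
between; the full 2-D Rayleigh evaluation would cost minutes without
changing the surrogate's behavior.

## Phantom mechanics surrogate

A full elastodynamic FEM solve is out of scope. The workbench instead uses
a quasi-static Kelvin–Voigt surrogate whose *contract* is qualitative:

* displacement amplitude field: `u(r) = gain · [G_σ ⋆ (I/E)](r)` — the
  radiation-force drive (∝ intensity) divided by the local Young's modulus,
  smoothed by a Gaussian *shear-coupling kernel*;
* kernel width: σ = λ_s/4, where λ_s is the shear wavelength of the
  **background** medium at the AM frequency (shear modulus G = E/3, density
  1000 kg/m³). At 200 Hz in 5.3 kPa this gives σ ≈ 1.66 mm. A single global
  width keeps the zero-width limit exactly ∝ 1/E and makes the estimated
  contrast decrease monotonically as the kernel widens (both are tested);
* temporal response: the causal response of a first-order Kelvin–Voigt
  element (time constant η/E, η = 0.6 Pa·s) to the raised-cosine AM
  envelope e(t) = (1 − cos 2π f_AM t)/2, giving a steady oscillation at
  f_AM with a small viscous phase lag and zero initial displacement.

In the zero-smoothing limit the displacement contrast of the default
phantom (56-kPa, 3.6-mm sphere in a 5.3-kPa background) is exactly
1 − 5.3/56 = 0.905, the Young's-modulus ground truth. With the default
kernel, the ROI-median contrast of the surrogate field is ≈ 0.8 — matching
the value measured directly from the reference FEM in the study this
workbench emulates.

The displacement field lives on a 2-D (x, z) grid at 0.1-mm spacing in the
imaging plane and is treated as uniform over the thin (±0.5 mm) elevation
slab of scatterers; at the AM frequencies used, shear coupling spreads the
motion over ≫ 1 mm in elevation, so the in-slab decay is a few percent.
What the surrogate deliberately omits: inertia (no resonance or wave
propagation), modal coupling at the inclusion boundary, nonlinear
elasticity, and any elevation structure of the response.

`drive_gain` (µm·kPa) converts normalized intensity over stiffness into
micrometers. The default (240) produces ≈ 1 µm amplitude (≈ 2 µm
peak-to-peak) at the focus of a homogeneous 5.3-kPa background at 200 Hz —
the micron-level displacement scale HMI systems report.

### Scatterers

Speckle is represented by point scatterers at 20 per resolution cell
(axial pulse length × lateral −6 dB beamwidth² ≈ 0.104 mm³ → ≈ 192/mm³),
uniformly placed with standard-normal reflectivities. The count is
deterministic (`round(density × volume / cell)`) for reproducibility, with
a Poisson option. Scatterers move axially by trilinear interpolation of
the displacement field (bilinear in-plane, uniform over elevation);
scatterers outside the solved grid do not move.

## RF synthesis

Channel data is synthesized by delay-accurate linear superposition: each
scatterer contributes one echo per element, delayed by the transmit arrival
time plus the return path, weighted by reflectivity, the transmit beam
amplitude, a hard-baffle sinc element directivity (element width 0.95 ×
pitch) and 1/r receive spreading. Sampling is direct at 4× the imaging
center frequency (31.2 MHz); the round-trip wavelet is a 2-cycle
Gaussian-windowed cosine (no transmit apodization), tabulated at 1/64
sample and linearly interpolated inside the accumulation kernel.

Transmit models:

* **Plane waves** (steered θ): wavefront arrival (z cos θ + x sin θ)/c
  referenced through the array center; the amplitude carries the 1-D
  Fresnel near-field ripple of the finite 11.81-mm aperture (a perfectly
  uniform plane wave is unrealistically kind to plane-wave tracking).
* **Focused beams**: virtual-source timing (a spherical wave converging on
  the focus and diverging beyond it) with the lateral term faded in over
  the Rayleigh range z_R = π w₀²/λ, so the wavefront is planar through the
  focal zone — the textbook `sign(z−z_f)·|r−r_f|` form is discontinuous
  across the focal plane off axis and decorrelates edge lines. The lateral
  amplitude is an hourglass: a Gaussian mainlobe of −6 dB width λ·F#
  growing geometrically away from the focus, with 1/√width energy
  conservation **referenced to the aperture plane** (so focusing carries
  its gain relative to a plane wave) plus a wide shoulder ≈ −17 dB,
  standing in for the sidelobe skirt of a uniformly apodized aperture.
* **Elevation**: a fixed lens (aperture 4.5 mm focused at 31 mm), identical
  for every transmit mode, applied as a Gaussian-with-shoulder profile.

Band-limited Gaussian noise (white noise band-passed to 5–12 MHz) is added
at a 30-dB channel SNR. The noise floor of the acquisition electronics does
not depend on the transmit sequence, so within an experiment the SNR is
referenced to a common plane-wave event on the same scatterers: focused
transmits keep their focusing gain over the noise, plane waves see exactly
30 dB.

FUS interference tones (4.5/9/13.5 MHz) can be injected for notch-filter
testing but are **off by default** — the effect was not reproducible in a
linear scattering model.

## Beamforming

Delay-and-sum on a 3.2 mm (axial) × 1.2 mm (lateral) patch centered on the
focus: 13 lines at λ/2 ≈ 0.099 mm pitch, depth pitch c/(2·4f_s) after 4×
polyphase upsampling of the element traces, Catmull–Rom cubic interpolation
at the delay, dynamic receive aperture of width depth/2.6 clipped to the
physical aperture, uniform apodization. Compounding sums steered-plane-wave
frames coherently. Tx-Rx parallel tracking beamforms the two offset
transmits independently and assigns each line to the nearer transmit
(midline ties to the first) — a lateral analogue of multi-zone focusing.

## Displacement estimation

Per line: (1) second-order Butterworth notches (0.5-MHz −3 dB width,
zero-phase) at the FUS fundamental and harmonics; (2) 1-D normalized
cross-correlation between consecutive frames with a 4λ = 0.79 mm window and
95% overlap, lag search bounded to ± a quarter window, integer-peak ties
broken toward zero lag, and cosine interpolation of the correlation peak
(exact on pure cosines; parabolic fallback when the cosine fit is
infeasible; bit-exact matches skip refinement so integer shifts are
recovered exactly); (3) cumulative summation of interframe estimates;
(4) a 48th-order linear-phase FIR band-pass (0.75–1.25 × f_AM, unity
forward-backward gain at f_AM) applied with zero phase; (5) mean
peak-to-peak over complete AM cycles.

Numerical choices worth flagging:

* the zero-phase band-pass is applied *circularly* after removing an affine
  trend fitted jointly with the f_AM sinusoid: the tracking trains hold an
  integer number of AM cycles, and a 49-tap transient would otherwise smear
  across the short (20–60 sample) cumulative traces; on integer-cycle
  sinusoids the application is exact;
* the filtered trace is FFT-upsampled 8× before taking per-cycle extrema,
  so the P2P does not depend on where the 2-kHz frames fall in the AM cycle;
* traces shorter than the requested FIR order reduce the order (with a
  warning) rather than reject — the two-cycle in-silico protocol (20 frames)
  could not otherwise be filtered at order 48;
* zero-variance windows propagate as NaN and are excluded from every
  downstream statistic;
* the notch bank is not free: the 9-MHz notch removes real signal near the
  band center (a measurable jitter cost), and because beamforming delays
  spread injected interference tones spectrally, suppression of strong
  interference is substantial but never complete — both effects mirror the
  behavior of physical HMI acquisition chains.

On rigid 5-µm sinusoidal motion at 30-dB channel SNR the full chain
recovers the 10-µm P2P to better than 1%.

## Maps, ROIs, metrics, statistics

Raster scanning moves the confocal assembly over a grid (0.8 mm lateral ×
2.0 mm axial steps); each point's P2P patch (3.2 × 1.2 mm) overlaps its
neighbors and is blended with weights `max(0, 1 − d/d_max)` (d = pixel
distance to the raster point, d_max = patch half-diagonal), renormalized
per pixel. The stitched map is normalized axially by the mean background
displacement-vs-depth curve (a lateral interval clear of the inclusion);
depths without background coverage use a log-domain least-squares Gaussian
fit of the curve, extrapolated. Map values are then displacement *ratios*
(background ≈ 1; lower = stiffer).

ROIs follow the concentric rule: inclusion disc at 80% of the inclusion
diameter, background ring from 170% of it, ring outer diameter set by equal
area. Metrics on ROI pixel populations (median µ, standard deviation σ):
contrast C = (µ_b − µ_i)/µ_b, CNR = (µ_b − µ_i)/√(σ_b² + σ_i²), SNR = µ/σ
per region, displacement ratio DR = µ_i/µ_b = 1 − C.

Sequences are compared across speckle realizations with a tie-corrected
Friedman test (exact enumeration of within-row rank permutations for tables
up to 6 × 3; the χ² approximation otherwise, which calibrates to a 4.5–5.5%
type-I rate at α = 0.05 on 20 × 8 null tables), followed — when significant
— by two-sided Dunn tests of the highest-median sequence against each
other, Bonferroni-adjusted over the k − 1 comparisons.

### Speckle-bias profiles

The bias analysis tracks a wide line set (4 mm at λ/2 pitch) on a
homogeneous phantom excited at the focus, at 800-Hz AM so the shear-coupled
displacement profile stays narrow (FWHM ≈ 1 mm) relative to the line span,
with a reduced forcing (peak ≈ 10 µm). Estimated and true lateral profiles
of mean |interframe displacement| are compared by −6 dB full width and peak
value. With a tight transmit focus the estimated profile rides a high bias
pedestal that can stay above half maximum across the whole span; the width
is then truncated to the span (flagged), which bounds the true width from
below and preserves the orderings of interest.

## Experiment scale

The packaged experiment uses the study's in-silico protocol — two cycles of
200-Hz AM per raster point at 2 kHz, 30-dB channel noise, the default
3.6-mm/56-kPa sphere in 5.3 kPa — at desk scale: an 8 × 6 mm field of view
(10 × 3 raster points, enough to contain the ROI ring plus background
margin) and 6–10 speckle realizations, instead of the full 20-realization,
larger-FOV design. The `scale` configuration factor shrinks realizations
and FOV only; algorithm parameters (window length, F-numbers, filters)
never change with scale. A complete two-sequence, ten-realization
comparison takes roughly ten minutes on one CPU core.

## Known limitations

* The mechanics surrogate reproduces stiffness-ratio contrast and shear
  smoothing but not inertia, so AM-frequency-dependent resonance effects
  and the exact FEM displacement field are outside its contract.
* Transmit beams are analytic envelope models (Gaussian mainlobe +
  shoulder, Fresnel plane waves), not full diffraction simulations; absolute
  sidelobe structure, aberration, and reverberation clutter are absent. As
  a consequence the estimation chain is "cleaner" than a physical system:
  measured inclusion contrast stays near the surrogate's ground truth
  (≈ 0.8) instead of degrading to the ≈ 0.6 a real acquisition chain
  measures, and the CNR advantage of focused parallel tracking over
  plane-wave imaging, while consistently positive and statistically
  significant across realizations, is a few percent rather than the ≈ 12%
  a physical system shows.
* Elevation is a thin uniform slab; out-of-plane shear and slice-thickness
  averaging are not modeled.
* Respiratory/physiological motion, hardware timing jitter, and real-time
  processing constraints are out of scope.
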