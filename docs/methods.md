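# Methods

## Scope and model

`nemabench` re-creates a NEMA NU 1-2018 characterization of a benchtop
single-pinhole SPECT camera as a closed loop: an event-level Monte Carlo of
the camera head produces list-mode data, a digitizer chain converts true
interactions into observed singles, and the analysis modules compute the
NEMA reporting parameters.  The aim is statistical fidelity of the
*performance observables* (resolution, sensitivity, count-rate, uniformity,
registration, tomographic metrics), not a general-purpose transport code.

### Coordinate and geometry conventions

Detector-plane coordinates are mm with origin at the crystal centre
(x transaxial, y axial); for SPECT the rotation axis is z.  The pinhole
aperture plane sits at the collimator mid-thickness, 5 mm behind the
collimator face, so a source quoted at distance D from the face is D + 5 mm
from the aperture.  This convention reconciles the 28 mm radius of rotation
with the 23.0 mm centre-of-rotation distance used when reporting system
resolution and sensitivity.  Magnification is M = h/(D + 5) with
h = 26.75 mm measured to the crystal face; no depth-of-interaction
augmentation is applied to h in the analysis (the simulation itself does
displace interactions with depth, which is physics, not analysis).

The UFOV (84.5 mm) and CFOV (63.375 mm = 0.75 x UFOV) are centred squares,
matching the square crystal.  Pixel bins are half-open and 0-based; an
event exactly on a bin edge goes to the higher bin.

### Photon transport

Emission times follow the decaying Poisson process of the isotope
(⁹⁹ᵐTc: 140.511 keV, intensity 0.885, half-life 6.0072 h; ⁶⁷Ga: the three
principal lines 93.31/184.58/300.22 keV — minor lines ignored).  Directions
are importance-sampled toward a disk slightly larger than the aperture
(physical radius + 2.5 mm, enough to cover the knife-edge penetration
region at these energies); the solid-angle fraction is carried in event
weights, and an analog mode (isotropic directions, Bernoulli transport,
unit weights) exists as an internal cross-check — weighted and analog
totals agree within Poisson errors.  For line sources the axial emission
coordinate is additionally importance-sampled ∝ 1/r² toward the aperture,
which flattens the weight distribution when the source is millimetres from
the collimator face.

Collimator penetration uses the exact chord of each ray through the
tungsten slab minus the double-cone opening (solved analytically per
half-cone; verified against a 1 µm ray-marching oracle to ≤ 1e-6 mm), with
attenuation e^(−μ_W(E)·chord).  No fluorescence or Compton transport in
tungsten is modelled.

Crystal detection samples the interaction point from a truncated
exponential along the ray through the 3 mm CsI slab.  Photoelectric
interactions deposit the full photon energy.  A first Compton interaction
deposits the recoil-electron energy; the scattered photon is then tracked
through the remaining slab and, if photoelectrically absorbed, the two
deposits are summed (this is what the readout adder does), restoring the
event to the photopeak at the energy-weighted centroid position.  Second-
order Compton chains are ignored.  This single recovery channel contributes
roughly 8% of photopeak counts at 140 keV and is required for absolute
sensitivity fidelity.

Phantom media attenuate along exact chords (petri-dish water column,
acrylic scatter cylinder, SVS cylinder).  The scatter phantom additionally
supports forced single Klein-Nishina scatter: an isotropic first leg, an
interaction point sampled on the chord, and a forced second leg toward the
aperture weighted by the angular Klein-Nishina pdf, with the scattered
energy from the Compton relation.  Multiple scatter, detector backscatter,
and scatter in air are not modelled; this mainly affects FWTM-with-scatter
comparisons, which are therefore not treated as validation surfaces.

### Attenuation data

Mass-attenuation grids are frozen build-time constants from NIST XCOM
anchor values for tungsten, water, aluminum, acrylic, and SiO₂ glass, with
the incoherent part computed exactly from the Klein-Nishina cross-section
times Z/A.  CsI is anchored at 140.5 keV to the standard NaI 140 keV linear
attenuation with Cs/I Z-scaling, photoelectric scaled as E^−2.8 between
edges.  Coherent (Rayleigh) scattering is excluded from the working totals
(a few percent, strongly forward-peaked).  All grids sit inside
edge-free energy bands (the tungsten K edge at 69.5 keV is below the grid).
Estimated accuracy is a few percent at the simulated lines — small against
the ±10% bands used for the Monte Carlo comparisons.

### Digitizer chain and calibration

Modules apply in the readout order: adder/readout (the event generator
already merges same-photon deposits), Gaussian energy blur with
FWHM(E) = r_ref √(E_ref E) (1/√E statistical light-yield scaling,
E_ref = 140.511 keV), isotropic Gaussian position blur, pile-up merging of
arrival chains with gaps < t_min (summed energy, energy-weighted centroid,
stamped at the last arrival), paralyzable dead time (an arrival is recorded
iff no other arrival preceded it within τ; every arrival extends the dead
interval), and Bernoulli efficiency.

Defaults ship from the spline-calibration procedure
(`calibrate_parameter`: simulate the observable on a parameter grid, fit a
cubic spline, invert at the measured value):

| parameter | default | calibrated against |
|---|---|---|
| r_ref | 0.1478 | 14.7% photopeak resolution at 140.5 keV, 0.6 keV bins |
| spatial blur FWHM | 0.812 mm | 0.85 mm pencil-beam PSF FWHM |
| τ | 23.8 µs | count-rate curve (15,400 cps maximum) |
| t_min | 0 (off) | — |
| efficiency | 1.0 | — |

r_ref is slightly above 0.147 because the NEMA profile estimator (parabolic
peak, linear crossings) reads a binned Gaussian marginally narrow; the
calibration inverts the full measurement pipeline, not the formula.  The
pile-up window defaults to zero because the printed observables constrain
only the fitted dead time, which absorbs pile-up losses; t_min is an
explicit knob, and the t_min = P₁/(R_T(P₀+2P₁)) estimator is implemented
and property-tested in its small-pile-up regime of validity.  The count-rate
model uses OCR = ICR e^(−ICR·τ) — the form with a maximum (1/(eτ), i.e.
15,400 cps at τ = 23.9 µs) consistent with the decaying-source
linearization used for the fit.

### NEMA analyses

The profile methodology everywhere: peak amplitude/location from a parabola
through the maximum sample and its two neighbours (ties break toward the
profile centre), FWHM/FWTM by linear interpolation between the samples
straddling half/tenth maximum.  No slit-width or source-diameter
deconvolution is applied.  Slit-mask LSFs are extracted in 5 mm axial bands
(≤ 30 mm of slit per LSF); linearity is the SD (differential) and maximum
(absolute) deviation of fitted peaks from the per-slit straight line; the
mm-per-pixel calibration is the known 31.5 mm slit spacing over the mean
fitted spacing.  Flood uniformity smooths once with the (1,2,1;2,4,2;1,2,1)/16
kernel, renormalized where the kernel leaves the FOV; differential windows
are 5 pixels, sliding one pixel, rows and columns reported separately.
MWSR centroids are count-weighted means of pixels above 5% of peak within a
10 mm ROI — a deliberate knob that suppresses the wall-penetration
background seen with ⁶⁷Ga.  System resolution measures the line source in
both orientations and averages, then fits FWHM(D) by ordinary least
squares; sensitivity fits R(D) = c₀ + c₁e^(−c₂D) by Levenberg-Marquardt and
reports S_TOT = R/A_cal at D = 23 mm.  The 20%-loss OCR is computed from
the fitted ideal model, 0.8·ln(1.25)/τ (within 1% of the empirically
quoted value).

Tomographic metrics: point sources are analysed in 8 mm cube ROIs summed
along each axis (radial/tangential assignment from the source azimuth);
the scatter phantom volume is summed into three 3.5 mm slabs; the
average 3D (in-plane) FWHM is the mean ± SD of the five (three) table
entries.  For volume sensitivity, L is min(imaged axial extent, collimator
reconstructed axial FOV) — the cap reproduces the per-axial-centimetre
normalization for both collimator types — and the total system response is
VSAC × the collimator's reconstructed axial FOV.  The uniformity VOI covers
75% of the imaged length and 60% of the inner diameter (15.6 mm for the
26 mm cylinder); CV uses the sample SD.

### Reconstruction

The projector is ray-driven: one ray per detector pixel per aperture sample
(default 5 samples: centre plus an equal-area ring), trilinear interpolation
at fixed steps of half a voxel, camera rotation implemented as the inverse
object rotation about z.  The backprojector is the exact adjoint by
construction (verified to ≤ 1e-6 relative on random instances), so MLEM
uses a matched pair: multiplicative updates with the sensitivity image from
backprojected ones, non-negative by construction, with a monotone Poisson
log-likelihood.  FBP applies cone-beam cosine weighting (vertex at the
aperture), row-wise ramp filtering (FFT, edge-replicated padding, zero DC
gain), and voxel-driven weighted backprojection over the 270° arc with
uniform angular weights — no short-scan weighting beyond that, which is
adequate for the centred distributions used here.  No attenuation or
scatter correction is applied in reconstruction.

## Problem sizes

The shipped defaults are desk-scale choices: sensitivity uses 1.5×10⁵
weighted samples per acquisition (five distances), system resolution
3×10⁵ per orientation (five distances, two orientations), and the
tomographic study uses a 6° step over the 270° arc, a 96² detector at
0.5 mm pitch, 0.5 mm voxels on a 44×64×64 grid, nine MLEM iterations, and
3×10⁵ total counts Poisson-distributed over the views.  Every size is a
config knob; the full-protocol matrices (3° step, 208² projections,
0.25 mm voxels on 230×184×184) are supported by the same code.

## What the generator does and does not emulate

Simulated floods are statistically uniform: flood-uniformity results
quantify counting statistics plus the analysis chain, not detector
non-uniformity (no SiPM gain map is modelled, and measured-data corrections
are out of scope).  Similarly MWSR displacements are near zero by
construction — the model has no energy-dependent positioning distortion —
so the MWSR pipeline validates the analysis, not a physical misregistration
mechanism.  The slit-mask LSF comes out near 1.0 mm, wider than the
pencil-beam limiting resolution, consistent with the known observation that
the mask geometry over-reads the intrinsic resolution; the package reports
both rather than forcing agreement.  Passing tests therefore demonstrate
correctness of the measurement chain and of the transport/digitizer physics
at the observable level; they do not certify hardware effects such as
photopeak shift at extreme rates or partial light collection during
pile-up, which are deliberately unmodelled.

## Known limitations

* Single Compton scatter only, in phantom media; one recovery interaction
  in the crystal; no tungsten fluorescence, no optical photons.
* Attenuation constants carry a few-percent uncertainty from the anchor
  interpolation; sensitivity figures inherit it.
* The system-resolution figure for the 0.85 mm pinhole runs ~5-8% above
  the reference simulation value: the exact-chord knife-edge penetration
  widens the FWHM more than the reference transport model's response;
  the 1.0 mm-pinhole resolution and both sensitivities agree within ~4%.
* FBP quantitative scaling is arbitrary (resolution and linearity tests
  only); MLEM is the quantitative path.
* Event weights make time-domain digitizer losses (pile-up, dead time)
  meaningful only for analog (unit-weight) streams; the count-rate
  scenarios generate analog streams for exactly this reason.
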