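"""Scenario presets: one simulate-and-analyse pipeline per performance test.

Each ``run_<test>`` function takes a config dict and a seed and returns
``(results, tables)`` for the report layer.  The pipelines are the package's
re-creation of the bench protocols: the phantom, the acquisition, and the
analysis, at desk-scale sample counts (every knob is overridable through the
config).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DetectorGeometry, EventList, bin_events, bin_spectrum, make_energy_window
from .digitizer import DigitizerConfig, apply_chain
from .materials import DEFAULT_MATERIALS
from .nema_planar import (
    MWSRResult,
    SensitivityMeasurement,
    count_rate_fit,
    energy_resolution,
    flood_uniformity,
    intrinsic_resolution_linearity,
    mwsr,
    nema_fwhm,
    sensitivity_fit,
    system_resolution,
)
from .nema_tomo import tomo_resolution_points, volume_sensitivity, volume_uniformity_cv
from .recon import ReconConfig, SpectGeometry, fbp_ramp, mlem
from .synthetic_data import (
    ISOTOPES,
    PinholeSpec,
    SourceSpec,
    simulate_acquisition,
    simulate_decaying_source_series,
    simulate_spect_scan,
)

TC_LINE_KEV = 140.511
TC_WINDOW = make_energy_window(TC_LINE_KEV, 0.30)

SENSITIVITY_DISTANCES = (10.0, 20.0, 28.0, 50.0, 100.0)
RESOLUTION_DISTANCES = (0.4, 25.0, 50.0, 75.0, 100.0)
COR_DISTANCE = 23.0  # mm, radius of rotation minus the aperture offset


def _blur_only_config(cfg: DigitizerConfig | None = None) -> DigitizerConfig:
    base = cfg or DigitizerConfig()
    return DigitizerConfig(energy_resolution_ref=base.energy_resolution_ref,
                           reference_energy=base.reference_energy,
                           spatial_blur_fwhm=base.spatial_blur_fwhm,
                           pileup_tmin=0.0, dead_time=0.0, efficiency=1.0)


# ---------------------------------------------------------------------------
# Planar sensitivity (petri-dish disk source, Eq. 6-8 pipeline)
# ---------------------------------------------------------------------------


def planar_sensitivity_pipeline(pinhole_diameter: float = 0.85,
                                seed: int = 0,
                                a_cal: float = 210.0,
                                distances=SENSITIVITY_DISTANCES,
                                duration: float = 100.0,
                                n_samples: int = 150_000,
                                digitizer: DigitizerConfig | None = None):
    """Simulate the disk-source acquisitions and fit the sensitivity curve.

    Acquisitions run from the largest to the smallest distance (as on the
    bench, to keep rates low near the pinhole); the decay correction makes
    the fitted sensitivity independent of that schedule.
    """
    pinhole = PinholeSpec(diameter=pinhole_diameter)
    lam = ISOTOPES["Tc99m"].decay_constant
    dig = _blur_only_config(digitizer)
    measurements = []
    for i, d in enumerate(sorted(distances, reverse=True)):
        t_start = i * 1800.0
        src = SourceSpec(kind="disk", isotope="Tc99m", activity=a_cal, distance=d)
        ev = simulate_acquisition(src, pinhole=pinhole, duration=duration,
                                  seed=seed + i, n_samples=n_samples,
                                  acquisition_start=t_start)
        ev = apply_chain(ev, dig, seed=seed + 1000 + i)
        counts = ev.in_window(TC_WINDOW).total_weight
        measurements.append(SensitivityMeasurement(
            counts=counts, start_time=t_start, acq_time=duration,
            distance=d, decay_constant=lam))
    fit = sensitivity_fit(measurements, a_cal=a_cal)
    return fit


def run_sensitivity(config: dict, seed: int):
    fit = planar_sensitivity_pipeline(
        pinhole_diameter=config.get("pinhole_diameter", 0.85),
        seed=seed,
        a_cal=config.get("a_cal", 210.0),
        distances=tuple(config.get("distances", SENSITIVITY_DISTANCES)),
        n_samples=int(config.get("n_samples", 150_000)))
    results = {
        "c0_cps": fit.c0, "c1_cps": fit.c1, "c2_per_mm": fit.c2,
        "s_tot_at_cor_cps_per_mbq": float(fit.s_tot(COR_DISTANCE)),
    }
    table = pd.DataFrame({"distance_mm": fit.distances,
                          "decay_corrected_rate_cps": fit.rates,
                          "s_tot_cps_per_mbq": fit.rates / fit.a_cal})
    return results, {"sensitivity": table}


# ---------------------------------------------------------------------------
# System resolution (capillary line source, magnification-corrected fit)
# ---------------------------------------------------------------------------


def system_resolution_pipeline(pinhole_diameter: float = 0.85,
                               seed: int = 0,
                               distances=RESOLUTION_DISTANCES,
                               n_samples: int = 300_000,
                               pitch: float = 0.1,
                               segment_halfwidth: float = 15.0,
                               digitizer: DigitizerConfig | None = None):
    """LSF FWHM versus distance for the capillary line source in air.

    As in the bench protocol the line is acquired in both the axial and the
    transaxial orientation at every distance; the per-distance resolution is
    the average of the two orthogonal LSF widths.
    """
    from .nema_planar import ProfileAnalysis

    pinhole = PinholeSpec(diameter=pinhole_diameter)
    dig = _blur_only_config(digitizer)
    profiles = {}
    for i, d in enumerate(distances):
        widths = []
        for j, axis in enumerate(("y", "x")):
            src = SourceSpec(kind="line", isotope="Tc99m", activity=10.0,
                             distance=d, line_axis=axis)
            ev = simulate_acquisition(src, pinhole=pinhole, duration=100.0,
                                      seed=seed + 10 * i + 5 * j,
                                      n_samples=n_samples)
            ev = apply_chain(ev, dig, seed=seed + 2000 + 10 * i + j)
            img = bin_events(ev, TC_WINDOW, pitch=pitch)
            if axis == "y":
                rows = np.abs(img.y_centers) <= segment_halfwidth
                profile = img.counts[rows].sum(axis=0)
            else:
                cols = np.abs(img.x_centers) <= segment_halfwidth
                profile = img.counts[:, cols].sum(axis=1)
            widths.append(nema_fwhm(profile, pitch=pitch))
        profiles[d] = ProfileAnalysis(
            fwhm=0.5 * (widths[0].fwhm + widths[1].fwhm),
            fwtm=0.5 * (widths[0].fwtm + widths[1].fwtm),
            peak_position=widths[0].peak_position,
            peak_amplitude=widths[0].peak_amplitude)
    return system_resolution(profiles, cor_distance=COR_DISTANCE)


def run_system_resolution(config: dict, seed: int):
    fit = system_resolution_pipeline(
        pinhole_diameter=config.get("pinhole_diameter", 0.85),
        seed=seed,
        distances=tuple(config.get("distances", RESOLUTION_DISTANCES)),
        n_samples=int(config.get("n_samples", 300_000)))
    results = {
        "fwhm_at_cor_mm": fit.fwhm_at_cor,
        "slope_mm_per_mm": fit.slope,
        "intercept_mm": fit.intercept,
        "r_squared": fit.r_squared,
    }
    table = pd.DataFrame({"distance_mm": fit.distances,
                          "fwhm_object_mm": fit.fwhm_object,
                          "fwtm_object_mm": fit.fwtm_object})
    return results, {"system_resolution": table}


# ---------------------------------------------------------------------------
# Intrinsic tests
# ---------------------------------------------------------------------------


def simulate_slit_mask_image(n_events: int = 300_000, seed: int = 0,
                             pitch: float = 0.1,
                             slit_width: float = 0.8,
                             slit_length: float = 26.5,
                             slit_positions=(-31.5, 0.0, 31.5),
                             digitizer: DigitizerConfig | None = None,
                             warp_amplitude: float = 0.0):
    """Flood through the 3x3 parallel-slit tungsten mask (contact geometry).

    Emission is sampled directly inside the slit openings (penetration of the
    2.5 mm mask at 140 keV is ~1e-4 and is neglected); an optional sinusoidal
    warp displaces interaction positions to emulate spatial distortion.
    """
    rng = np.random.default_rng(seed)
    dig = _blur_only_config(digitizer)
    slot = rng.integers(0, 9, n_events)
    xs = np.asarray(slit_positions)[slot % 3]
    ys = np.asarray(slit_positions)[slot // 3]
    x = xs + rng.uniform(-slit_width / 2, slit_width / 2, n_events)
    y = ys + rng.uniform(-slit_length / 2, slit_length / 2, n_events)
    if warp_amplitude:
        x = x + warp_amplitude * np.sin(2 * np.pi * y / 40.0)
    t = np.sort(rng.uniform(0, 100.0, n_events))
    ev = EventList(t, x, y, np.full(n_events, TC_LINE_KEV), np.ones(n_events),
                   duration=100.0)
    ev = apply_chain(ev, dig, seed=seed + 1)
    return bin_events(ev, TC_WINDOW, pitch=pitch)


def run_intrinsic_resolution(config: dict, seed: int):
    img = simulate_slit_mask_image(n_events=int(config.get("n_events", 300_000)),
                                   seed=seed)
    res = intrinsic_resolution_linearity(img)
    results = {
        "lsf_fwhm_mm": res.fwhm_mean, "lsf_fwhm_sd_mm": res.fwhm_sd,
        "lsf_fwtm_mm": res.fwtm_mean, "lsf_fwtm_sd_mm": res.fwtm_sd,
        "differential_linearity_mm": res.differential_linearity,
        "absolute_linearity_mm": res.absolute_linearity,
        "calibration_mm_per_pixel": res.calibration_mm_per_pixel,
    }
    return results, {}


def simulate_flood_image(total_counts: float = 2e7, seed: int = 0,
                         pitch: float = 1.0, flat: bool = False,
                         digitizer: DigitizerConfig | None = None,
                         geometry: DetectorGeometry | None = None):
    """Uniform-flux flood field at 1 mm pixels (or an exact flat fixture)."""
    geometry = geometry or DetectorGeometry()
    n_pix = int(round(geometry.crystal_size / pitch))
    if flat:
        from .core import ProjectionImage

        counts = np.full((n_pix, n_pix), 100.0)
        return ProjectionImage(counts, pixel_pitch=pitch,
                               origin=(-n_pix * pitch / 2, -n_pix * pitch / 2))
    rng = np.random.default_rng(seed)
    n = rng.poisson(total_counts)
    half = geometry.crystal_size / 2.0
    x = rng.uniform(-half, half, n)
    y = rng.uniform(-half, half, n)
    t = np.sort(rng.uniform(0, 100.0, n))
    ev = EventList(t, x, y, np.full(n, TC_LINE_KEV), np.ones(n), duration=100.0)
    ev = apply_chain(ev, _blur_only_config(digitizer), seed=seed + 1)
    return bin_events(ev, TC_WINDOW, pitch=pitch)


def run_uniformity(config: dict, seed: int):
    img = simulate_flood_image(total_counts=float(config.get("total_counts", 2e7)),
                               seed=seed, flat=bool(config.get("flat", False)))
    res = flood_uniformity(img)
    results = {
        "integral_uniformity_pct": res.integral,
        "row_differential_pct": res.row_differential,
        "column_differential_pct": res.column_differential,
        "low_counts": res.low_counts,
    }
    return results, {}


def mwsr_pipeline(seed: int = 0, counts_per_position: int = 50_000,
                  digitizer: DigitizerConfig | None = None,
                  geometry: DetectorGeometry | None = None) -> MWSRResult:
    """Ga-67 pencil-beam PSFs at nine positions imaged in each photopeak window."""
    geometry = geometry or DetectorGeometry()
    rng = np.random.default_rng(seed)
    dig = _blur_only_config(digitizer)
    em = ISOTOPES["Ga67"]
    line_e = np.array([e for e, _ in em.lines])
    intens = np.array([p for _, p in em.lines])
    half_u = geometry.ufov / 2.0
    offsets = [0.0, 0.4 * half_u, -0.4 * half_u, 0.8 * half_u, -0.8 * half_u]
    positions = [(0.0, 0.0)]
    positions += [(d, 0.0) for d in offsets[1:]] + [(0.0, d) for d in offsets[1:]]
    images = {}
    for pos in positions:
        n = counts_per_position
        line = rng.choice(len(line_e), size=n, p=intens / intens.sum())
        r = 0.2 * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        x = pos[0] + r * np.cos(phi)
        y = pos[1] + r * np.sin(phi)
        t = np.sort(rng.uniform(0, 100.0, n))
        ev = EventList(t, x, y, line_e[line], np.ones(n), duration=100.0,
                       isotope="Ga67")
        ev = apply_chain(ev, dig, seed=seed + hash(pos) % 10000)
        windows = {}
        for e in line_e:
            win = make_energy_window(float(e), 0.30)
            windows[f"{e:.0f}keV"] = bin_events(ev, win, pitch=0.1)
        images[pos] = windows
    return mwsr(images)


def run_mwsr(config: dict, seed: int):
    res = mwsr_pipeline(seed=seed,
                        counts_per_position=int(config.get("counts_per_position", 50_000)))
    results = {
        "max_axial_displacement_mm": res.max_axial_displacement,
        "max_transaxial_displacement_mm": res.max_transaxial_displacement,
        "mean_euclidean_distance_mm": res.mean_euclidean_distance,
        "sd_euclidean_distance_mm": res.sd_euclidean_distance,
    }
    return results, {}


def run_count_rate(config: dict, seed: int):
    cfg = DigitizerConfig(dead_time=float(config.get("dead_time", 23.8e-6)),
                          pileup_tmin=float(config.get("pileup_tmin", 0.0)),
                          energy_resolution_ref=0.0, spatial_blur_fwhm=0.0)
    points = simulate_decaying_source_series(
        icr0=float(config.get("icr0", 1e5)), digitizer_config=cfg, seed=seed,
        acq_time=float(config.get("acq_time", 10.0)))
    fit = count_rate_fit(points, ISOTOPES["Tc99m"].decay_constant)
    results = {
        "tau_us": fit.tau * 1e6, "icr0_cps": fit.icr0,
        "max_ocr_cps": fit.max_ocr, "loss20_ocr_cps": fit.loss20_ocr,
        "n_points": fit.n_points,
    }
    table = pd.DataFrame({"time_s": [p.time for p in points],
                          "icr_cps": [p.icr for p in points],
                          "ocr_cps": [p.ocr for p in points]})
    return results, {"count_rate": table}


def energy_resolution_pipeline(seed: int = 0, total_counts: float = 4e5,
                               bin_width: float = 0.6,
                               digitizer: DigitizerConfig | None = None):
    """Photopeak spectrum at the count-rate point below 20% loss, Eq. 5.

    The photopeak is the digitizer's Gaussian energy response at the line
    energy with Poisson counting statistics, binned and analysed with the
    NEMA profile methodology.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(total_counts)
    dig = _blur_only_config(digitizer)
    t = np.sort(rng.uniform(0, 60.0, n))
    z = np.zeros(n)
    ev = EventList(t, z, z, np.full(n, TC_LINE_KEV), np.ones(n), duration=60.0)
    ev = apply_chain(ev, dig, seed=seed + 1)
    counts, edges = bin_spectrum(ev, bin_width=bin_width)
    return energy_resolution(counts, bin_width, first_bin_center=bin_width / 2.0)


def run_energy_resolution(config: dict, seed: int):
    res = energy_resolution_pipeline(seed=seed,
                                     total_counts=float(config.get("total_counts", 4e5)),
                                     bin_width=float(config.get("bin_width", 0.6)))
    return dict(res), {}


# ---------------------------------------------------------------------------
# Tomographic pipelines
# ---------------------------------------------------------------------------

POINT_SOURCE_POSITIONS = ((0.0, 0.0, 0.0), (11.25, 0.0, 5.25), (-11.25, 0.0, -5.25))


def tomo_point_source_pipeline(seed: int = 0,
                               pinhole_diameter: float = 0.85,
                               step_deg: float = 6.0,
                               detector_pixels: int = 96,
                               detector_pitch: float = 0.5,
                               voxel: float = 0.5,
                               volume_shape=(44, 64, 64),
                               iterations: int = 9,
                               total_counts: float = 300_000.0,
                               n_samples_per_view: int = 12_000,
                               algorithms=("MLEM", "FBP")):
    """Three point sources in air: SPECT scan, reconstruction, 3D resolution.

    Scaled to desk size: 0.5 mm voxels and a 6 degree step over the 270
    degree arc; projections are Poisson realizations normalized to the
    protocol's total acquired counts.
    """
    rng = np.random.default_rng(seed)
    sources = [dict(position=p, activity=0.274, axial_extent=0.4)
               for p in POINT_SOURCE_POSITIONS]
    views = simulate_spect_scan(sources, pinhole=PinholeSpec(diameter=pinhole_diameter),
                                arc=270.0, step=step_deg,
                                time_per_view=10.0,
                                n_samples_per_view=n_samples_per_view,
                                detector_pixels=detector_pixels,
                                detector_pitch=detector_pitch, seed=seed)
    stack = np.stack([v.counts for v in views])
    scale = total_counts / stack.sum()
    stack = rng.poisson(stack * scale).astype(float)
    geometry = SpectGeometry(views_deg=np.arange(0.0, 270.0, step_deg),
                             detector_pixels=detector_pixels,
                             detector_pitch=detector_pitch,
                             pinhole_diameter=pinhole_diameter)
    config = ReconConfig(iterations=iterations, voxel=voxel,
                         volume_shape=tuple(volume_shape))
    out = {}
    if "MLEM" in algorithms:
        vol = mlem(stack, geometry, config)
        out["MLEM"] = tomo_resolution_points(vol, voxel, POINT_SOURCE_POSITIONS)
    if "FBP" in algorithms:
        vol = fbp_ramp(stack, geometry, config)
        out["FBP"] = tomo_resolution_points(vol, voxel, POINT_SOURCE_POSITIONS)
    return out


def run_tomo_resolution(config: dict, seed: int):
    res = tomo_point_source_pipeline(
        seed=seed,
        step_deg=float(config.get("step_deg", 6.0)),
        iterations=int(config.get("iterations", 9)),
        algorithms=tuple(config.get("algorithms", ("MLEM", "FBP"))))
    results = {}
    for alg, r in res.items():
        results[alg] = {
            "central_transaxial_mm": r.central_transaxial,
            "central_axial_mm": r.central_axial,
            "peripheral_radial_mm": r.peripheral_radial,
            "peripheral_tangential_mm": r.peripheral_tangential,
            "peripheral_axial_mm": r.peripheral_axial,
            "average_3d_fwhm_mm": r.average_3d,
            "average_3d_fwhm_sd_mm": r.average_3d_sd,
        }
    return results, {}


def run_volume_sensitivity(config: dict, seed: int):
    """Uniform cylinder scan -> SVS, VSAC, total response, uniformity, CV."""
    conc = float(config.get("concentration_mbq_per_ml", 1.75))
    radius = float(config.get("phantom_radius", 13.0))
    length = float(config.get("phantom_length", 21.0))
    step_deg = float(config.get("step_deg", 9.0))
    time_per_view = float(config.get("time_per_view", 10.0))
    rotation_overhead = float(config.get("rotation_overhead", 2.0))
    activity = conc * np.pi * (radius / 10.0) ** 2 * (length / 10.0)  # MBq
    sources = [dict(position=(0.0, 0.0, 0.0), activity=activity,
                    axial_extent=length, radius=radius)]
    detector_pixels = int(config.get("detector_pixels", 104))
    detector_pitch = float(config.get("detector_pitch", 1.0))
    views = simulate_spect_scan(sources, arc=270.0, step=step_deg,
                                time_per_view=time_per_view,
                                n_samples_per_view=int(config.get("n_samples_per_view", 20_000)),
                                detector_pixels=detector_pixels,
                                detector_pitch=detector_pitch, seed=seed,
                                attenuation_cylinder=("water", radius, length))
    n_views = len(views)
    total_counts = float(sum(v.counts.sum() for v in views))
    elapsed = n_views * (time_per_view + rotation_overhead)
    lam = ISOTOPES["Tc99m"].decay_constant
    sens = volume_sensitivity(total_counts, elapsed, concentration_cal=conc,
                              decay_constant=lam,
                              imaged_length_cm=min(length / 10.0, 5.7))
    results = {
        "svs_cps_per_mbq_cm3": sens.svs,
        "vsac_cps_per_mbq_cm2": sens.vsac,
        "total_system_response_cps_per_mbq_cm3": sens.total_system_response,
        "axial_extent_cm": sens.axial_extent_cm,
    }
    if config.get("reconstruct", True):
        rng = np.random.default_rng(seed + 1)
        stack = rng.poisson(np.stack([v.counts for v in views])).astype(float)
        geometry = SpectGeometry(views_deg=np.arange(0.0, 270.0, step_deg),
                                 detector_pixels=detector_pixels,
                                 detector_pitch=detector_pitch)
        voxel = float(config.get("voxel", 1.0))
        rc = ReconConfig(iterations=int(config.get("iterations", 9)), voxel=voxel,
                         volume_shape=tuple(config.get("volume_shape", (32, 40, 40))))
        vol = mlem(stack, geometry, rc)
        uni = volume_uniformity_cv(vol, voxel, inner_diameter=2 * radius,
                                   imaged_length=length)
        results["integral_uniformity_pct"] = uni.integral_uniformity
        results["cv_pct"] = uni.cv
    return results, {}
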