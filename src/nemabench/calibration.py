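"""Observable simulators used to tune digitizer parameters.

The tuning procedure simulates an observable over a grid of parameter
values, fits a cubic spline, and inverts it at the measured value (see
:func:`nemabench.digitizer.calibrate_parameter`).  The shipped
DigitizerConfig defaults are the inverted values for the measured 0.85 mm
pencil-beam PSF FWHM and the 14.7% photopeak energy resolution.
"""

from __future__ import annotations

import numpy as np

from .core import EventList, bin_events, bin_spectrum, make_energy_window
from .digitizer import DigitizerConfig, apply_chain
from .nema_planar import energy_resolution, nema_fwhm

TC_LINE_KEV = 140.511


def simulate_pencil_beam_psf(spatial_blur_fwhm: float, n_events: int = 200_000,
                             seed: int = 0, beam_diameter: float = 0.4,
                             pitch: float = 0.1):
    """PSF image of the 0.4 mm pencil-beam tunnel at the detector centre."""
    rng = np.random.default_rng(seed)
    r = beam_diameter / 2.0 * np.sqrt(rng.random(n_events))
    phi = rng.uniform(0, 2 * np.pi, n_events)
    x, y = r * np.cos(phi), r * np.sin(phi)
    t = np.sort(rng.uniform(0, 100.0, n_events))
    ev = EventList(t, x, y, np.full(n_events, TC_LINE_KEV), np.ones(n_events),
                   duration=100.0)
    cfg = DigitizerConfig(energy_resolution_ref=0.0,
                          spatial_blur_fwhm=spatial_blur_fwhm,
                          pileup_tmin=0.0, dead_time=0.0)
    ev = apply_chain(ev, cfg, seed=seed + 1)
    return bin_events(ev, make_energy_window(TC_LINE_KEV, 0.30), pitch=pitch)


def pencil_beam_psf_fwhm(spatial_blur_fwhm: float, seed: int = 0) -> float:
    """Measured PSF FWHM (mm): central row profile through the peak."""
    img = simulate_pencil_beam_psf(spatial_blur_fwhm, seed=seed)
    iy, ix = np.unravel_index(np.argmax(img.counts), img.counts.shape)
    # average the three rows through the peak to tame Poisson noise
    profile = img.counts[iy - 1 : iy + 2].sum(axis=0)
    return nema_fwhm(profile, pitch=img.pixel_pitch).fwhm


def photopeak_resolution_pct(energy_resolution_ref: float, seed: int = 0,
                             total_counts: int = 400_000) -> float:
    """Measured photopeak energy resolution (%) for a blur parameter."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(total_counts)
    t = np.sort(rng.uniform(0, 60.0, n))
    z = np.zeros(n)
    ev = EventList(t, z, z, np.full(n, TC_LINE_KEV), np.ones(n), duration=60.0)
    cfg = DigitizerConfig(energy_resolution_ref=energy_resolution_ref,
                          spatial_blur_fwhm=0.0, pileup_tmin=0.0, dead_time=0.0)
    ev = apply_chain(ev, cfg, seed=seed + 1)
    counts, _ = bin_spectrum(ev, bin_width=0.6)
    return energy_resolution(counts, 0.6)["energy_resolution_pct"]
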