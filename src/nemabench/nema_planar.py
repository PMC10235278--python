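"""NEMA NU 1-2018 analyses for intrinsic and collimated planar tests.

Implements the standard's profile methodology (parabolic peak through the
maximum sample and its neighbours, linear interpolation at the half/tenth
levels), flood-field uniformity with the 3x3 smoothing kernel, multiple
window spatial registration, the decaying-source count-rate fit for the
paralyzable dead-time model, system resolution with magnification
correction, and the planar-sensitivity exponential fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .core import DetectorGeometry, ProjectionImage


class AnalysisError(RuntimeError):
    """A NEMA analysis could not be completed on the supplied data."""


# ---------------------------------------------------------------------------
# Profile methodology
# ---------------------------------------------------------------------------


@dataclass
class ProfileAnalysis:
    fwhm: float  # mm (or keV for spectra)
    fwtm: float
    peak_position: float  # same units, relative to the first sample centre
    peak_amplitude: float

    def __post_init__(self):
        if not self.fwtm >= self.fwhm > 0:
            raise ValueError("requires FWTM >= FWHM > 0")


def _crossing(profile, peak_idx, level, direction):
    """Sub-sample crossing of `level` nearest the peak, walking outward."""
    i = peak_idx
    n = len(profile)
    while 0 <= i < n and profile[i] >= level:
        i += direction
    if i < 0 or i >= n:
        raise AnalysisError("profile does not fall below the required level")
    inner = i - direction  # last sample above the level
    y0, y1 = profile[inner], profile[i]
    frac = (y0 - level) / (y0 - y1)
    return inner + direction * frac


def nema_fwhm(profile, pitch: float = 1.0) -> ProfileAnalysis:
    """FWHM/FWTM of a peaked 1D profile per the NEMA resolution methodology.

    The peak amplitude and location come from a parabola through the maximum
    sample and its two neighbours; the widths from linear interpolation
    between the samples straddling half and tenth maximum, scaled by the
    sample pitch.  Ties between equal maxima break toward the profile centre.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise AnalysisError("profile too short")
    maxima = np.flatnonzero(y == y.max())
    peak_idx = int(maxima[np.argmin(np.abs(maxima - (y.size - 1) / 2.0))])
    if 0 < peak_idx < y.size - 1:
        y0, y1, y2 = y[peak_idx - 1 : peak_idx + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            amp = y1 - 0.25 * (y0 - y2) * shift
        else:
            shift, amp = 0.0, y1
    else:
        shift, amp = 0.0, y[peak_idx]
    widths = []
    for level_frac in (0.5, 0.1):
        left = _crossing(y, peak_idx, amp * level_frac, -1)
        right = _crossing(y, peak_idx, amp * level_frac, +1)
        widths.append((right - left) * pitch)
    return ProfileAnalysis(fwhm=widths[0], fwtm=widths[1],
                           peak_position=(peak_idx + shift) * pitch,
                           peak_amplitude=float(amp))


def energy_resolution(spectrum_counts, bin_width: float,
                      first_bin_center: float = None) -> dict:
    """Photopeak FWHM / photopeak location x 100 (%), NEMA methodology."""
    pa = nema_fwhm(spectrum_counts, pitch=bin_width)
    offset = first_bin_center if first_bin_center is not None else bin_width / 2.0
    location = offset + pa.peak_position
    return {"fwhm_kev": pa.fwhm, "photopeak_kev": location,
            "energy_resolution_pct": pa.fwhm / location * 100.0}


# ---------------------------------------------------------------------------
# Intrinsic resolution / linearity from the slit-mask image
# ---------------------------------------------------------------------------


@dataclass
class IntrinsicResolutionResult:
    fwhm_mean: dict  # region -> mm
    fwhm_sd: dict
    fwtm_mean: dict
    fwtm_sd: dict
    differential_linearity: dict  # region -> mm (SD of deviations)
    absolute_linearity: dict  # region -> mm (max deviation)
    calibration_mm_per_pixel: float
    per_slit: list = field(default_factory=list)


def intrinsic_resolution_linearity(img: ProjectionImage,
                                   slit_positions=(-31.5, 0.0, 31.5),
                                   band_mm: float = 5.0,
                                   search_halfwidth: float = 10.0,
                                   geometry: DetectorGeometry | None = None
                                   ) -> IntrinsicResolutionResult:
    """Per-slit LSF resolution and spatial linearity from a slit-mask image.

    The image is cut into axial bands (<= 30 mm of slit per LSF); each band
    yields one LSF per slit.  Linearity is judged per slit against the
    best-fit straight line of fitted peak positions; the mm-per-pixel
    calibration comes from the known 31.5 mm slit spacing.
    """
    geometry = geometry or DetectorGeometry()
    pitch = img.pixel_pitch
    xc, yc = img.x_centers, img.y_centers
    half_u, half_c = geometry.ufov / 2.0, geometry.cfov / 2.0

    slit_records = {i: [] for i in range(len(slit_positions))}
    n_bands = int(np.floor(geometry.ufov / band_mm))
    y_start = -n_bands * band_mm / 2.0
    detected = set()
    for b in range(n_bands):
        ylo, yhi = y_start + b * band_mm, y_start + (b + 1) * band_mm
        rows = (yc >= ylo) & (yc < yhi)
        if not rows.any():
            continue
        profile_full = img.counts[rows].sum(axis=0)
        y_mid = 0.5 * (ylo + yhi)
        for i, x_slit in enumerate(slit_positions):
            cols = np.abs(xc - x_slit) <= search_halfwidth
            prof = profile_full[cols]
            if prof.max() <= 0:
                continue
            try:
                pa = nema_fwhm(prof, pitch=pitch)
            except AnalysisError:
                continue
            x0 = xc[cols][0] - pitch / 2.0
            peak_x = x0 + pitch / 2.0 + pa.peak_position
            detected.add(i)
            slit_records[i].append(
                dict(y=y_mid, peak_x=peak_x, fwhm=pa.fwhm, fwtm=pa.fwtm,
                     in_cfov=(abs(y_mid) < half_c and abs(x_slit) < half_c),
                     in_ufov=(abs(y_mid) < half_u and abs(x_slit) < half_u)))
    if len(detected) < 3:
        raise AnalysisError("fewer than 3 slits detected")

    regions = {"UFOV": "in_ufov", "CFOV": "in_cfov"}
    fwhm_mean, fwhm_sd, fwtm_mean, fwtm_sd = {}, {}, {}, {}
    diff_lin, abs_lin = {}, {}
    for region, key in regions.items():
        f = [r["fwhm"] for recs in slit_records.values() for r in recs if r[key]]
        t = [r["fwtm"] for recs in slit_records.values() for r in recs if r[key]]
        fwhm_mean[region], fwhm_sd[region] = float(np.mean(f)), float(np.std(f))
        fwtm_mean[region], fwtm_sd[region] = float(np.mean(t)), float(np.std(t))
        devs = []
        for recs in slit_records.values():
            sel = [r for r in recs if r[key]]
            if len(sel) < 3:
                continue
            ys = np.array([r["y"] for r in sel])
            xs = np.array([r["peak_x"] for r in sel])
            coef = np.polyfit(ys, xs, 1)
            devs.extend(xs - np.polyval(coef, ys))
        devs = np.asarray(devs)
        diff_lin[region] = float(np.std(devs)) if devs.size else 0.0
        abs_lin[region] = float(np.max(np.abs(devs))) if devs.size else 0.0

    # calibration factor: known spacing / mean fitted peak spacing in pixels
    mean_x = []
    for i in sorted(slit_records):
        xs = [r["peak_x"] for r in slit_records[i]]
        if xs:
            mean_x.append(np.mean(xs))
    spacing_mm = np.diff(sorted(mean_x))
    spacing_px = spacing_mm / pitch
    nominal = np.diff(np.asarray(slit_positions))
    calibration = float(np.mean(nominal / spacing_px)) if spacing_px.size else pitch

    return IntrinsicResolutionResult(
        fwhm_mean=fwhm_mean, fwhm_sd=fwhm_sd, fwtm_mean=fwtm_mean,
        fwtm_sd=fwtm_sd, differential_linearity=diff_lin,
        absolute_linearity=abs_lin, calibration_mm_per_pixel=calibration,
        per_slit=[slit_records[i] for i in sorted(slit_records)])


# ---------------------------------------------------------------------------
# Flood-field uniformity
# ---------------------------------------------------------------------------

_NEMA_KERNEL = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0


@dataclass
class UniformityResult:
    integral: dict  # region -> %
    row_differential: dict
    column_differential: dict
    pixel_max: dict
    pixel_min: dict
    low_counts: bool = False


def _smooth_masked(counts, mask):
    """One pass of the NEMA kernel, renormalized where the kernel leaves the FOV."""
    num = ndimage.convolve(np.where(mask, counts, 0.0), _NEMA_KERNEL, mode="constant")
    den = ndimage.convolve(mask.astype(float), _NEMA_KERNEL, mode="constant")
    out = np.zeros_like(counts)
    np.divide(num, den, out=out, where=den > 0)
    return np.where(mask, out, 0.0)


def _integral_uniformity(values):
    vmax, vmin = float(np.max(values)), float(np.min(values))
    if vmax + vmin == 0:
        return 0.0, vmax, vmin
    return (vmax - vmin) / (vmax + vmin) * 100.0, vmax, vmin


def _differential(smoothed, mask, axis, window: int = 5):
    """Worst Eq.-2 value over every `window`-pixel run fully inside the FOV."""
    worst = 0.0
    arr = smoothed if axis == 0 else smoothed.T
    msk = mask if axis == 0 else mask.T
    for line, mline in zip(arr, msk):
        idx = np.flatnonzero(mline)
        if idx.size < window:
            continue
        vals = line[idx]
        mx = np.lib.stride_tricks.sliding_window_view(vals, window).max(axis=1)
        mn = np.lib.stride_tricks.sliding_window_view(vals, window).min(axis=1)
        denom = mx + mn
        ok = denom > 0
        if ok.any():
            worst = max(worst, float(((mx[ok] - mn[ok]) / denom[ok] * 100.0).max()))
    return worst


def flood_uniformity(img: ProjectionImage,
                     geometry: DetectorGeometry | None = None) -> UniformityResult:
    """Integral and differential flood-field uniformity (UFOV and CFOV)."""
    geometry = geometry or DetectorGeometry()
    if min(geometry.cfov, geometry.ufov) / img.pixel_pitch < 5:
        raise AnalysisError("FOV smaller than the 5-pixel analysis window")
    integral, rows, cols, pmax, pmin = {}, {}, {}, {}, {}
    low = bool(img.counts.mean() < 1e2)
    for region in ("UFOV", "CFOV"):
        mask = img.mask_for(region, geometry)
        smoothed = _smooth_masked(img.counts, mask)
        iu, mx, mn = _integral_uniformity(smoothed[mask])
        integral[region], pmax[region], pmin[region] = iu, mx, mn
        rows[region] = _differential(smoothed, mask, axis=0)
        cols[region] = _differential(smoothed, mask, axis=1)
    return UniformityResult(integral=integral, row_differential=rows,
                            column_differential=cols, pixel_max=pmax,
                            pixel_min=pmin, low_counts=low)


# ---------------------------------------------------------------------------
# Multiple window spatial registration
# ---------------------------------------------------------------------------


@dataclass
class MWSRResult:
    centroids: dict  # position -> window -> (x, y) mm
    max_axial_displacement: float
    max_transaxial_displacement: float
    mean_euclidean_distance: float
    sd_euclidean_distance: float


def _psf_centroid(img: ProjectionImage, roi_mm: float = 10.0,
                  threshold_frac: float = 0.05):
    """Count-weighted centroid of pixels above threshold within a square ROI."""
    c = img.counts
    if c.max() <= 0:
        raise AnalysisError("empty PSF image")
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    xc, yc = img.x_centers, img.y_centers
    px, py = xc[ix], yc[iy]
    half = roi_mm / 2.0
    roi = np.outer(np.abs(yc - py) <= half, np.abs(xc - px) <= half)
    sel = roi & (c >= threshold_frac * c.max())
    if not sel.any():
        raise AnalysisError("empty centroid ROI")
    w = c[sel]
    ys, xs = np.nonzero(sel)
    return (float(np.sum(w * xc[xs]) / w.sum()), float(np.sum(w * yc[ys]) / w.sum()))


def mwsr(psf_images: dict) -> MWSRResult:
    """Spatial registration across energy windows.

    ``psf_images[position][window]`` are PSF ProjectionImages of the same
    pencil beam imaged through different photopeak windows.  Displacements
    are computed within each position across windows; registration accuracy
    is the Euclidean distance of each centroid to the per-position average.
    """
    centroids, dists = {}, []
    max_ax = max_tr = 0.0
    for pos, windows in psf_images.items():
        cents = {wname: _psf_centroid(im) for wname, im in windows.items()}
        centroids[pos] = cents
        pts = np.array(list(cents.values()))
        if len(pts) > 1:
            max_tr = max(max_tr, float(pts[:, 0].max() - pts[:, 0].min()))
            max_ax = max(max_ax, float(pts[:, 1].max() - pts[:, 1].min()))
        mean_c = pts.mean(axis=0)
        dists.extend(np.linalg.norm(pts - mean_c, axis=1))
    return MWSRResult(centroids=centroids, max_axial_displacement=max_ax,
                      max_transaxial_displacement=max_tr,
                      mean_euclidean_distance=float(np.mean(dists)),
                      sd_euclidean_distance=float(np.std(dists)))


# ---------------------------------------------------------------------------
# Count-rate performance (decaying source method)
# ---------------------------------------------------------------------------


@dataclass
class CountRateAnalysis:
    tau: float  # s
    icr0: float  # cps
    max_ocr: float  # cps = 1 / (e tau)
    loss20_ocr: float  # cps = 0.8 ln(1.25) / tau
    n_points: int
    slope: float
    intercept: float


def count_rate_fit(points, decay_constant: float) -> CountRateAnalysis:
    """Paralyzable dead-time fit by the decaying-source linearization.

    Ordinary least squares of (lambda t + ln OCR) on exp(-lambda t):
    slope = -ICR0 tau, intercept = ln ICR0.
    """
    t = np.array([p.time for p in points], dtype=float)
    ocr = np.array([p.ocr for p in points], dtype=float)
    good = ocr > 0
    if not good.all():
        warnings.warn("dropping non-positive OCR points from the count-rate fit")
        t, ocr = t[good], ocr[good]
    if t.size < 5:
        raise AnalysisError("count-rate fit needs at least 5 usable points")
    x = np.exp(-decay_constant * t)
    y = decay_constant * t + np.log(ocr)
    slope, intercept = np.polyfit(x, y, 1)
    icr0 = float(np.exp(intercept))
    tau = float(-slope / icr0)
    if tau <= 0:
        raise AnalysisError("fitted dead time is non-positive")
    return CountRateAnalysis(tau=tau, icr0=icr0, max_ocr=1.0 / (np.e * tau),
                             loss20_ocr=0.8 * np.log(1.25) / tau,
                             n_points=int(t.size), slope=float(slope),
                             intercept=float(intercept))


# ---------------------------------------------------------------------------
# System resolution (collimated) with magnification correction
# ---------------------------------------------------------------------------


@dataclass
class SystemResolutionFit:
    distances: np.ndarray  # mm from collimator face
    fwhm_object: np.ndarray  # mm, object space
    fwtm_object: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    fwhm_at_cor: float  # evaluated at D = 23.0 mm

    def fwhm_at(self, distance: float) -> float:
        return self.slope * distance + self.intercept


def magnification(distance: float, aperture_to_crystal: float = 26.75) -> float:
    """M = h / (D + 5): aperture-to-crystal over source-to-aperture distance."""
    if distance <= 0 and distance + 5.0 <= 0:
        raise ValueError("source distance must be positive")
    return aperture_to_crystal / (distance + 5.0)


def system_resolution(profiles: dict, cor_distance: float = 23.0,
                      aperture_to_crystal: float = 26.75) -> SystemResolutionFit:
    """Object-space resolution vs distance with a linear least-squares fit.

    ``profiles`` maps source-to-collimator distance D (mm) to the
    detector-plane ProfileAnalysis of the line-source LSF.  Detector widths
    are divided by the magnification M = h / (D + 5) to express resolution
    in the object.
    """
    ds = np.array(sorted(profiles), dtype=float)
    if np.any(ds <= 0):
        raise ValueError("source distances must be positive")
    fwhm_o = np.array([profiles[d].fwhm / magnification(d, aperture_to_crystal)
                       for d in ds])
    fwtm_o = np.array([profiles[d].fwtm / magnification(d, aperture_to_crystal)
                       for d in ds])
    slope, intercept = np.polyfit(ds, fwhm_o, 1)
    pred = np.polyval([slope, intercept], ds)
    ss_res = float(np.sum((fwhm_o - pred) ** 2))
    ss_tot = float(np.sum((fwhm_o - fwhm_o.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SystemResolutionFit(distances=ds, fwhm_object=fwhm_o,
                               fwtm_object=fwtm_o, slope=float(slope),
                               intercept=float(intercept), r_squared=r2,
                               fwhm_at_cor=float(slope * cor_distance + intercept))


# ---------------------------------------------------------------------------
# Planar sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityMeasurement:
    counts: float  # summed in-window counts C_i
    start_time: float  # T_i, s relative to the activity calibration
    acq_time: float  # T_acq,i, s
    distance: float  # D_i, mm source-to-collimator face
    decay_constant: float  # 1/s


@dataclass
class SensitivityFit:
    c0: float  # cps
    c1: float  # cps
    c2: float  # 1/mm
    a_cal: float  # MBq
    distances: np.ndarray
    rates: np.ndarray  # decay-corrected cps
    degenerate: bool = False

    def rate_at(self, distance):
        return self.c0 + self.c1 * np.exp(-self.c2 * np.asarray(distance, float))

    def s_tot(self, distance):
        """Total system sensitivity, cps/MBq."""
        return self.rate_at(distance) / self.a_cal


def decay_corrected_rate(m: SensitivityMeasurement) -> float:
    """R = lambda C e^{lambda (T - T_cal)} / (1 - e^{-lambda T_acq})."""
    if m.acq_time <= 0:
        raise ValueError("acquisition time must be positive")
    lam = m.decay_constant
    if lam * m.acq_time < 1e-12:
        return m.counts / m.acq_time
    return lam * m.counts * np.exp(lam * m.start_time) / -np.expm1(-lam * m.acq_time)


def sensitivity_fit(measurements, a_cal: float) -> SensitivityFit:
    """Levenberg-Marquardt fit of R(D) = c0 + c1 exp(-c2 D)."""
    if len(measurements) < 4:
        raise AnalysisError("sensitivity fit needs at least 4 distances")
    ds = np.array([m.distance for m in measurements], dtype=float)
    rates = np.array([decay_corrected_rate(m) for m in measurements])
    order = np.argsort(ds)
    ds, rates = ds[order], rates[order]
    span = rates.max() - rates.min()
    p0 = (max(rates.min(), 1e-6), max(span, 1e-6), 0.05)
    try:
        popt, _ = curve_fit(lambda d, c0, c1, c2: c0 + c1 * np.exp(-c2 * d),
                            ds, rates, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise AnalysisError(f"sensitivity fit did not converge: {exc}") from exc
    c0, c1, c2 = (float(v) for v in popt)
    degenerate = abs(c1) < 1e-6 * max(abs(c0), 1.0)
    if degenerate:
        warnings.warn("sensitivity fit is flat: c2 is unidentifiable")
    return SensitivityFit(c0=c0, c1=c1, c2=c2, a_cal=a_cal, distances=ds,
                          rates=rates, degenerate=degenerate)
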