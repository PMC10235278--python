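"""Tomographic NEMA analyses: reconstructed resolution, volume sensitivity
per axial centimetre, and volume uniformity/variability.

Resolution metrics follow the point-source and triple-line protocols: cubic
ROIs summed along each axis give per-axis profiles analysed with the NEMA
profile methodology; the radial/tangential split of peripheral sources is
taken from the source azimuth.  Volume sensitivity is normalized by the
axial extent of the phantom in the reconstructed image, capped at the
collimator's reconstructed axial FOV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nema_planar import AnalysisError, nema_fwhm


@dataclass
class TomoResolutionResult:
    central_transaxial: float  # mm, mean of x and y FWHM of the central source
    central_axial: float
    peripheral_radial: float  # mean over peripheral sources
    peripheral_tangential: float
    peripheral_axial: float
    average_3d: float  # mean of the five entries above
    average_3d_sd: float
    per_source: list


def _voxel_index(volume_shape, voxel, position):
    nz, ny, nx = volume_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = position
    return (z / voxel + cz, y / voxel + cy, x / voxel + cx)


def _cube_profiles(volume, voxel, position, roi_mm):
    """Sum a cubic ROI along each pair of axes -> per-axis 1D profiles."""
    nz, ny, nx = volume.shape
    fz, fy, fx = _voxel_index(volume.shape, voxel, position)
    half = int(round(roi_mm / 2.0 / voxel))
    iz, iy, ix = int(round(fz)), int(round(fy)), int(round(fx))
    if not (0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx):
        raise AnalysisError("source position outside the reconstructed volume")
    sl = tuple(slice(max(c - half, 0), min(c + half + 1, n))
               for c, n in ((iz, nz), (iy, ny), (ix, nx)))
    roi = volume[sl]
    # refine the ROI centre on the local maximum
    pk = np.unravel_index(np.argmax(roi), roi.shape)
    iz = sl[0].start + pk[0]
    iy = sl[1].start + pk[1]
    ix = sl[2].start + pk[2]
    sl = tuple(slice(max(c - half, 0), min(c + half + 1, n))
               for c, n in ((iz, nz), (iy, ny), (ix, nx)))
    roi = volume[sl]
    prof_x = roi.sum(axis=(0, 1))
    prof_y = roi.sum(axis=(0, 2))
    prof_z = roi.sum(axis=(1, 2))
    return prof_x, prof_y, prof_z


def tomo_resolution_points(volume: np.ndarray, voxel: float,
                           source_positions, roi_mm: float = 8.0
                           ) -> TomoResolutionResult:
    """Reconstructed 3D resolution from point sources in air.

    ``source_positions`` are world (x, y, z) mm: the first at the centre of
    rotation, the others peripheral (their azimuth decides the
    radial/tangential axis assignment).
    """
    per_source = []
    for pos in source_positions:
        px, py, pz = pos
        prof_x, prof_y, prof_z = _cube_profiles(volume, voxel, pos, roi_mm)
        fx = nema_fwhm(prof_x, voxel).fwhm
        fy = nema_fwhm(prof_y, voxel).fwhm
        fz = nema_fwhm(prof_z, voxel).fwhm
        r_xy = np.hypot(px, py)
        if r_xy < 1.0:
            rec = dict(kind="central", transaxial=0.5 * (fx + fy), axial=fz,
                       x=fx, y=fy, z=fz)
        else:
            # radial along the source azimuth, tangential orthogonal in-plane
            if abs(px) >= abs(py):
                radial, tangential = fx, fy
            else:
                radial, tangential = fy, fx
            rec = dict(kind="peripheral", radial=radial, tangential=tangential,
                       axial=fz, x=fx, y=fy, z=fz)
        per_source.append(rec)

    central = [r for r in per_source if r["kind"] == "central"]
    periph = [r for r in per_source if r["kind"] == "peripheral"]
    if not central or not periph:
        raise AnalysisError("need one central and at least one peripheral source")
    ct = float(np.mean([r["transaxial"] for r in central]))
    ca = float(np.mean([r["axial"] for r in central]))
    pr = float(np.mean([r["radial"] for r in periph]))
    pt = float(np.mean([r["tangential"] for r in periph]))
    pa = float(np.mean([r["axial"] for r in periph]))
    five = np.array([ct, ca, pr, pt, pa])
    return TomoResolutionResult(central_transaxial=ct, central_axial=ca,
                                peripheral_radial=pr, peripheral_tangential=pt,
                                peripheral_axial=pa,
                                average_3d=float(five.mean()),
                                average_3d_sd=float(five.std(ddof=1)),
                                per_source=per_source)


@dataclass
class TomoScatterResult:
    central: float  # mm
    radial: float
    tangential: float
    average_in_plane: float
    average_in_plane_sd: float
    per_slab: list


def tomo_resolution_scatter(volume: np.ndarray, voxel: float,
                            slab_thickness: float = 3.5,
                            line_offset: float = 10.0,
                            peripheral_angles_deg=(0.0, 270.0),
                            axial_fov: float | None = None,
                            roi_mm: float = 8.0) -> TomoScatterResult:
    """In-plane resolution with scatter from the triple-line phantom volume.

    The volume is summed axially into three ``slab_thickness`` slabs (centre
    and +-75% of the axial FOV); each slab holds one central and two
    peripheral PSFs whose in-plane profiles give the central, radial, and
    tangential FWHM.
    """
    nz = volume.shape[0]
    n_sl = max(int(round(slab_thickness / voxel)), 1)
    extent = axial_fov if axial_fov is not None else nz * voxel
    centers_mm = (-0.375 * extent, 0.0, 0.375 * extent)
    cz = (nz - 1) / 2.0

    per_slab = []
    for zc in centers_mm:
        izc = int(round(zc / voxel + cz))
        lo = max(izc - n_sl // 2, 0)
        hi = min(lo + n_sl, nz)
        if hi <= lo:
            raise AnalysisError("slab outside the reconstructed volume")
        slab = volume[lo:hi].sum(axis=0)
        half = int(round(roi_mm / 2.0 / voxel))
        rec = {}
        for name, (sx, sy) in {
            "central": (0.0, 0.0),
            "peripheral_0": _polar(line_offset, peripheral_angles_deg[0]),
            "peripheral_1": _polar(line_offset, peripheral_angles_deg[1]),
        }.items():
            fy0, fx0 = _voxel_index((1,) + slab.shape, voxel, (sx, sy, 0.0))[1:]
            iy, ix = int(round(fy0)), int(round(fx0))
            ny, nx = slab.shape
            if not (0 <= iy < ny and 0 <= ix < nx):
                raise AnalysisError(f"missing line source at {name}")
            win = slab[max(iy - half, 0):iy + half + 1, max(ix - half, 0):ix + half + 1]
            if win.max() <= 0:
                raise AnalysisError(f"missing line source at {name}")
            pk = np.unravel_index(np.argmax(win), win.shape)
            iy = max(iy - half, 0) + pk[0]
            ix = max(ix - half, 0) + pk[1]
            win = slab[max(iy - half, 0):iy + half + 1, max(ix - half, 0):ix + half + 1]
            fx = nema_fwhm(win.sum(axis=0), voxel).fwhm
            fy = nema_fwhm(win.sum(axis=1), voxel).fwhm
            if name == "central":
                rec["central"] = 0.5 * (fx + fy)
            else:
                if abs(sx) >= abs(sy):
                    rec.setdefault("radial", []).append(fx)
                    rec.setdefault("tangential", []).append(fy)
                else:
                    rec.setdefault("radial", []).append(fy)
                    rec.setdefault("tangential", []).append(fx)
        rec["radial"] = float(np.mean(rec["radial"]))
        rec["tangential"] = float(np.mean(rec["tangential"]))
        per_slab.append(rec)

    cen = float(np.mean([r["central"] for r in per_slab]))
    rad = float(np.mean([r["radial"] for r in per_slab]))
    tan = float(np.mean([r["tangential"] for r in per_slab]))
    allv = np.array([v for r in per_slab for v in (r["central"], r["radial"], r["tangential"])])
    return TomoScatterResult(central=cen, radial=rad, tangential=tan,
                             average_in_plane=float(allv.mean()),
                             average_in_plane_sd=float(allv.std(ddof=1)),
                             per_slab=per_slab)


def _polar(r, angle_deg):
    a = np.deg2rad(angle_deg)
    return (r * np.cos(a), r * np.sin(a))


# ---------------------------------------------------------------------------
# Volume sensitivity / uniformity
# ---------------------------------------------------------------------------


@dataclass
class VolumeSensitivityResult:
    average_count_rate: float  # A, cps
    concentration_mid: float  # B_c, MBq/cm^3 halfway through the acquisition
    svs: float  # cps / (MBq/cm^3)
    axial_extent_cm: float  # L used for the normalization
    vsac: float  # cps / (MBq/cm^2)
    total_system_response: float  # cps / (MBq/cm^3)


def volume_sensitivity(total_counts: float, elapsed_time: float,
                       concentration_cal: float, decay_constant: float,
                       imaged_length_cm: float,
                       axial_fov_cm: float = 5.7,
                       time_to_midpoint: float | None = None
                       ) -> VolumeSensitivityResult:
    """System volume sensitivity and its per-axial-centimetre normalization.

    ``total_counts`` over ``elapsed_time`` (including rotation overhead)
    gives the average rate A; ``concentration_cal`` (MBq/cm^3 at
    calibration) is decayed to the acquisition midpoint for B_c.  L is the
    imaged axial extent capped at the collimator's reconstructed axial FOV.
    """
    if concentration_cal <= 0:
        raise ValueError("activity concentration must be positive")
    if elapsed_time <= 0:
        raise ValueError("elapsed time must be positive")
    t_mid = time_to_midpoint if time_to_midpoint is not None else elapsed_time / 2.0
    a_rate = total_counts / elapsed_time
    b_c = concentration_cal * np.exp(-decay_constant * t_mid)
    svs = a_rate / b_c
    length = min(imaged_length_cm, axial_fov_cm)
    vsac = svs / length
    return VolumeSensitivityResult(average_count_rate=a_rate,
                                   concentration_mid=b_c, svs=svs,
                                   axial_extent_cm=length, vsac=vsac,
                                   total_system_response=vsac * axial_fov_cm)


@dataclass
class VolumeUniformityResult:
    integral_uniformity: float  # %
    cv: float  # %
    mean: float
    sd: float
    voi_voxels: int
    voi_diameter_mm: float
    voi_length_mm: float


def volume_uniformity_cv(volume: np.ndarray, voxel: float,
                         inner_diameter: float = 26.0,
                         imaged_length: float | None = None,
                         length_fraction: float = 0.75,
                         diameter_fraction: float = 0.60
                         ) -> VolumeUniformityResult:
    """Uniformity and coefficient of variation inside the cylindrical VOI.

    The VOI covers ``length_fraction`` of the phantom's imaged length and
    ``diameter_fraction`` of its inner diameter, centred on the volume's
    intensity centroid.
    """
    nz, ny, nx = volume.shape
    total = volume.sum()
    if total <= 0:
        raise AnalysisError("empty volume")
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    cz = float((volume * zz).sum() / total)
    cy = float((volume * yy).sum() / total)
    cx = float((volume * xx).sum() / total)
    length = imaged_length if imaged_length is not None else nz * voxel
    voi_len = length_fraction * length
    voi_diam = diameter_fraction * inner_diameter
    r_vox = voi_diam / 2.0 / voxel
    hz_vox = voi_len / 2.0 / voxel
    sel = (((xx - cx) ** 2 + (yy - cy) ** 2) <= r_vox**2) & \
          (np.abs(zz - cz) <= hz_vox)
    vals = volume[sel]
    if vals.size == 0:
        raise AnalysisError("empty VOI")
    vmax, vmin = float(vals.max()), float(vals.min())
    integral = (vmax - vmin) / (vmax + vmin) * 100.0 if vmax + vmin > 0 else 0.0
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    cv = sd / mu * 100.0 if mu > 0 else 0.0
    return VolumeUniformityResult(integral_uniformity=integral, cv=cv, mean=mu,
                                  sd=sd, voi_voxels=int(vals.size),
                                  voi_diameter_mm=voi_diam, voi_length_mm=voi_len)
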