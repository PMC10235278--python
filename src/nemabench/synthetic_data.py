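"""Desk-scale list-mode Monte Carlo of the pinhole camera head.

The simulator emulates the physics that matters for the performance tests:
isotropic gamma emission from decaying sources, knife-edge pinhole
collimation with exact tungsten chord lengths (septal penetration), optional
single Compton scatter in phantom media, and photoelectric absorption in the
3 mm CsI crystal with depth-of-interaction lateral displacement.  Events are
produced pre-digitizer (true interaction position and energy); the digitizer
chain turns them into observed singles.

Frames: the planar frame has the pinhole aperture plane at z = 0, the
collimator face (source side) at z = +5 mm, and the crystal front face at
z = -26.75 mm.  A source at distance D from the collimator face sits at
z = D + 5 (source-to-aperture distance D + 5 mm).

Variance reduction: directions are importance-sampled toward a disk slightly
larger than the aperture (to capture knife-edge penetration), with the solid
angle fraction carried in the event weights.  Analog mode (isotropic
directions, Bernoulli survival, unit weights) is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DetectorGeometry, EventList, ProjectionImage
from .materials import (
    DEFAULT_MATERIALS,
    MaterialTable,
    compton_scattered_energy,
    klein_nishina_total,
    sample_klein_nishina_cos_theta,
    ELECTRON_REST_KEV,
)

# ---------------------------------------------------------------------------
# Emission data (Table of Radionuclides monographs: principal gamma lines)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmissionModel:
    """Gamma lines (energy keV, intensity per decay) and half-life in s."""

    lines: tuple
    half_life: float

    def __post_init__(self):
        for _, p in self.lines:
            if not 0 < p <= 1:
                raise ValueError("line intensities must be in (0, 1]")

    @property
    def decay_constant(self) -> float:
        return np.log(2.0) / self.half_life

    @property
    def total_intensity(self) -> float:
        return float(sum(p for _, p in self.lines))


ISOTOPES = {
    "Tc99m": EmissionModel(lines=((140.511, 0.885),), half_life=6.0072 * 3600.0),
    # three principal lines; minor lines ignored
    "Ga67": EmissionModel(
        lines=((93.31, 0.3881), (184.576, 0.2141), (300.217, 0.1664)),
        half_life=3.2617 * 86400.0,
    ),
}


@dataclass
class PinholeSpec:
    """Knife-edge right-circular double-cone aperture in the tungsten slab."""

    diameter: float = 0.85  # mm
    acceptance_angle: float = 90.0  # degrees, full opening angle
    thickness: float = 10.0  # mm tungsten slab
    aperture_plane_offset: float = 5.0  # mm from collimator face (mid-thickness)

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("pinhole diameter must be positive")
        if not 0 < self.acceptance_angle < 180:
            raise ValueError("acceptance angle must be in (0, 180) degrees")

    @property
    def half_angle_tan(self) -> float:
        return float(np.tan(np.deg2rad(self.acceptance_angle / 2.0)))


@dataclass
class SourceSpec:
    """Radioactive source/phantom description.

    ``distance`` is source-to-collimator-face in mm (converted internally to
    source-to-aperture by adding the 5 mm aperture-plane offset).  Geometry
    parameters depend on ``kind``:

    * ``point``: optional ``offset=(x, y)`` mm in the source plane
    * ``line``: ``line_length`` (75), ``line_radius`` (0.2, capillary bore),
      axis along the planar y (axial) direction
    * ``pencil_beam``: ``offset=(x, y)``, ``beam_radius`` (0.2), collimator-free
    * ``disk``: ``disk_radius`` (17.5) with ``solution_volume_ml`` (2.0) of
      water (petri-dish planar sensitivity source, self-absorbing)
    * ``cylinder_shell`` / ``flood``: see the scenario presets
    """

    kind: str = "point"
    isotope: str = "Tc99m"
    activity: float = 10.0  # MBq at calibration time
    distance: float = 23.0  # mm from collimator face
    offset: tuple = (0.0, 0.0)
    line_length: float = 75.0
    line_radius: float = 0.2
    line_axis: str = "y"  # detector-plane direction of the line
    beam_radius: float = 0.2
    disk_radius: float = 17.5
    solution_volume_ml: float = 2.0

    def __post_init__(self):
        if self.activity < 0:
            raise ValueError("activity must be non-negative")
        if self.isotope not in ISOTOPES:
            raise ValueError(f"unknown isotope {self.isotope!r}")

    @property
    def emission(self) -> EmissionModel:
        return ISOTOPES[self.isotope]

    @property
    def solution_height(self) -> float:
        """Height of the petri-dish solution column in mm."""
        return self.solution_volume_ml * 1000.0 / (np.pi * self.disk_radius**2)


# ---------------------------------------------------------------------------
# Pinhole geometry: exact tungsten chord of a ray
# ---------------------------------------------------------------------------


def _quad_neg_length(A, B, C, lo, hi):
    """Length of {t in [lo, hi] : A t^2 + B t + C < 0}, vectorized."""
    seg = np.maximum(hi - lo, 0.0)
    disc = B * B - 4.0 * A * C
    sq = np.sqrt(np.maximum(disc, 0.0))
    safe_a = np.where(np.abs(A) > 1e-12, A, 1.0)
    r1 = (-B - sq) / (2.0 * safe_a)
    r2 = (-B + sq) / (2.0 * safe_a)
    rlo = np.minimum(r1, r2)
    rhi = np.maximum(r1, r2)
    inter = np.clip(np.minimum(hi, rhi) - np.maximum(lo, rlo), 0.0, None)
    between = np.where(disc > 0, inter, 0.0)
    outside = np.where(disc > 0, seg - inter, seg)
    quad = np.where(A > 0, between, outside)
    # degenerate linear case B t + C < 0
    safe_b = np.where(np.abs(B) > 1e-12, B, 1.0)
    t0 = -C / safe_b
    lin_pos = np.clip(np.minimum(hi, t0) - lo, 0.0, None)
    lin_neg = np.clip(hi - np.maximum(lo, t0), 0.0, None)
    lin_const = np.where(C < 0, seg, 0.0)
    lin = np.where(np.abs(B) > 1e-12, np.where(B > 0, lin_pos, lin_neg), lin_const)
    return np.where(np.abs(A) > 1e-12, quad, lin)


def pinhole_path_length(origin, direction, pinhole: PinholeSpec):
    """Exact chord length (mm) of a ray inside the tungsten collimator slab.

    The open region is the double cone with apex circle of ``diameter`` at
    the aperture plane (z = 0), opening toward both slab faces with
    half-angle ``acceptance_angle / 2``.  Rays through the open aperture
    return 0; rays far from the cone return the full slab chord.
    """
    o = np.atleast_2d(np.asarray(origin, dtype=float))
    u = np.atleast_2d(np.asarray(direction, dtype=float))
    scalar = np.asarray(origin).ndim == 1
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    uz = u[:, 2]
    if np.any(np.abs(uz) < 1e-12):
        raise ValueError("ray parallel to the collimator slab")
    z_face = pinhole.aperture_plane_offset
    z_back = pinhole.aperture_plane_offset - pinhole.thickness
    t_face = (z_face - o[:, 2]) / uz
    t_back = (z_back - o[:, 2]) / uz
    t_lo = np.minimum(t_face, t_back)
    t_hi = np.maximum(t_face, t_back)
    slab_chord = t_hi - t_lo

    s = pinhole.half_angle_tan
    r0 = pinhole.diameter / 2.0
    px, py, oz = o[:, 0], o[:, 1], o[:, 2]
    qx, qy = u[:, 0], u[:, 1]

    open_len = np.zeros(o.shape[0])
    for h, zl, zh in ((1.0, 0.0, z_face), (-1.0, z_back, 0.0)):
        a0 = r0 + h * s * oz
        a1 = h * s * uz
        A = qx**2 + qy**2 - a1**2
        B = 2.0 * (px * qx + py * qy - a0 * a1)
        C = px**2 + py**2 - a0**2
        tz1 = (zl - oz) / uz
        tz2 = (zh - oz) / uz
        lo = np.maximum(np.minimum(tz1, tz2), t_lo)
        hi = np.minimum(np.maximum(tz1, tz2), t_hi)
        open_len += _quad_neg_length(A, B, C, lo, hi)

    tungsten = np.clip(slab_chord - open_len, 0.0, None)
    return float(tungsten[0]) if scalar else tungsten


def transmit_through_collimator(origin, direction, energy_kev, pinhole: PinholeSpec,
                                materials: MaterialTable = DEFAULT_MATERIALS):
    """Survival weight exp(-mu_W(E) * tungsten chord) for a ray."""
    path = pinhole_path_length(origin, direction, pinhole)
    mu = materials.mu("tungsten", energy_kev)
    return np.exp(-mu * path)


def crystal_detection(entry_xy, direction, energy_kev, rng,
                      geometry: DetectorGeometry | None = None,
                      materials: MaterialTable = DEFAULT_MATERIALS):
    """Interaction of rays entering the crystal front face.

    Returns ``(p_interact, p_photo_given_interact, xy, depth_along_ray)``:
    the interaction probability ``1 - exp(-mu_tot * t / |cos theta|)``, the
    photoelectric fraction, and the interaction position laterally displaced
    from the entry point to the sampled (truncated-exponential) interaction
    depth along the ray.
    """
    geometry = geometry or DetectorGeometry()
    entry = np.atleast_2d(np.asarray(entry_xy, dtype=float))
    u = np.atleast_2d(np.asarray(direction, dtype=float))
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    cos_t = np.abs(u[:, 2])
    mu_tot = np.broadcast_to(np.atleast_1d(materials.mu("csi", energy_kev)), cos_t.shape)
    path = geometry.crystal_thickness / np.maximum(cos_t, 1e-12)
    p_int = 1.0 - np.exp(-mu_tot * path)
    pe_frac = np.broadcast_to(
        np.atleast_1d(materials.photoelectric_fraction("csi", energy_kev)), cos_t.shape
    )
    # truncated exponential depth along the ray
    xi = rng.random(cos_t.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = -np.log1p(-xi * p_int) / mu_tot
    depth = np.where(p_int > 0, depth, 0.0)
    lateral = u[:, :2] / np.maximum(cos_t, 1e-12)[:, None]
    xy = entry + lateral * depth[:, None]
    return p_int, pe_frac, xy, depth


def _rotate_about(u, cos_s, azimuth):
    """Unit vectors at angle arccos(cos_s) from u with the given azimuth."""
    u = np.atleast_2d(u)
    # orthonormal frame (a, b) perpendicular to u
    helper = np.where(np.abs(u[:, 2:3]) < 0.9,
                      np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    a = np.cross(u, helper)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(u, a)
    sin_s = np.sqrt(np.clip(1.0 - cos_s**2, 0.0, 1.0))
    return (u * cos_s[:, None]
            + a * (sin_s * np.cos(azimuth))[:, None]
            + b * (sin_s * np.sin(azimuth))[:, None])


def _compton_second_interaction(e0, u, z_depth, rng,
                                geometry: DetectorGeometry,
                                materials: MaterialTable):
    """Fate of the Compton-scattered photon inside the crystal slab.

    Returns ``(p_recover, e_scat, w, ell2)``: the probability that the
    scattered photon is photoelectrically absorbed before leaving the slab
    (making the summed deposit a photopeak event), the scattered energy, the
    scattered direction, and a sampled second-interaction path length along
    it.  The slab chord is capped laterally (a long in-plane flight is fully
    absorbed anyway at these energies).
    """
    n = len(z_depth)
    if n == 0:
        z = np.empty(0)
        return z, z, np.empty((0, 3)), z
    cos_s = sample_klein_nishina_cos_theta(e0, n, rng)
    e_sc = compton_scattered_energy(e0, cos_s)
    w = _rotate_about(u, cos_s, rng.uniform(0.0, 2.0 * np.pi, n))
    wz = w[:, 2]
    thick = geometry.crystal_thickness
    down = wz < 0
    chord = np.where(down, (thick - z_depth) / np.maximum(-wz, 1e-9),
                     z_depth / np.maximum(wz, 1e-9))
    chord = np.minimum(chord, 50.0)
    mu2 = materials.mu("csi", e_sc)
    pe2 = materials.photoelectric_fraction("csi", e_sc)
    p_int2 = 1.0 - np.exp(-mu2 * chord)
    xi = rng.random(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ell2 = np.where(p_int2 > 0, -np.log1p(-xi * p_int2) / np.maximum(mu2, 1e-12), 0.0)
    return p_int2 * pe2, e_sc, w, ell2


def on_axis_geometric_efficiency(diameter: float, source_to_aperture: float) -> float:
    """Ideal on-axis pinhole geometric efficiency d^2 / (16 D_a^2)."""
    if source_to_aperture <= 0:
        raise ValueError("source-to-aperture distance must be positive")
    return diameter**2 / (16.0 * source_to_aperture**2)


# ---------------------------------------------------------------------------
# Emission sampling helpers
# ---------------------------------------------------------------------------


def _sample_times(rng, n, lam, duration):
    """Emission times from a decaying Poisson process over [0, duration]."""
    if duration <= 0 or n == 0:
        return np.zeros(n)
    xi = rng.random(n)
    c = -np.expm1(-lam * duration)  # 1 - e^{-lam T}
    return -np.log1p(-xi * c) / lam


def _sample_disk(rng, n, radius, center=(0.0, 0.0)):
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


def _sample_positions(source: SourceSpec, n, rng):
    """Emission positions in the planar frame; returns (n, 3, ) positions and
    the importance weights of any non-uniform spatial sampling."""
    z0 = source.distance + 5.0  # aperture-plane frame
    w = np.ones(n)
    if source.kind == "point":
        pos = np.tile([source.offset[0], source.offset[1], z0], (n, 1))
    elif source.kind == "disk":
        xy = _sample_disk(rng, n, source.disk_radius)
        z = z0 + rng.random(n) * source.solution_height
        pos = np.column_stack([xy, z])
    elif source.kind == "line":
        xy = _sample_disk(rng, n, source.line_radius)
        # sample the axial line coordinate ~ 1/(b^2 + y^2): flattens the
        # solid-angle weights when the source sits close to the aperture
        half_l = source.line_length / 2.0
        theta_max = np.arctan(half_l / z0)
        theta = rng.uniform(-theta_max, theta_max, n)
        yline = z0 * np.tan(theta)
        pdf = z0 / ((z0**2 + yline**2) * 2.0 * theta_max)
        w = (1.0 / source.line_length) / pdf
        if source.line_axis == "y":
            pos = np.column_stack([xy[:, 0] + source.offset[0], yline, z0 + xy[:, 1]])
        else:
            pos = np.column_stack([yline, xy[:, 0] + source.offset[1], z0 + xy[:, 1]])
    else:
        raise ValueError(f"unsupported collimated source kind {source.kind!r}")
    return pos, w


def _directions_to_disk(rng, positions, n, target_radius, target_z=0.0):
    """Importance-sample directions toward a disk at the aperture plane.

    Returns unit directions and the per-sample solid-angle weight
    A_disk * cos(theta) / (4 pi r^2).
    """
    q = _sample_disk(rng, n, target_radius)
    target = np.column_stack([q, np.full(n, target_z)])
    d = target - positions
    r2 = np.einsum("ij,ij->i", d, d)
    r = np.sqrt(r2)
    u = d / r[:, None]
    cos_t = np.abs(u[:, 2])
    area = np.pi * target_radius**2
    w = area * cos_t / (4.0 * np.pi * r2)
    return u, w


def _source_self_attenuation(source: SourceSpec, positions, u, energy,
                             materials: MaterialTable):
    """Attenuation weight for the photon's exit path through the source medium."""
    if source.kind == "disk":
        # water column above the dish base; photons exit through the base
        z_base = source.distance + 5.0
        path = (positions[:, 2] - z_base) / np.maximum(np.abs(u[:, 2]), 1e-9)
        mu = materials.mu("water", energy)
        return np.exp(-mu * np.maximum(path, 0.0))
    return np.ones(len(positions))


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def simulate_acquisition(source: SourceSpec,
                         geometry: DetectorGeometry | None = None,
                         pinhole: PinholeSpec | None = None,
                         materials: MaterialTable = DEFAULT_MATERIALS,
                         duration: float = 100.0,
                         seed: int = 0,
                         n_samples: int = 200_000,
                         mode: str = "importance",
                         acquisition_start: float = 0.0,
                         sampling_margin: float = 2.5) -> EventList:
    """Simulate one collimated list-mode acquisition.

    Emission times follow the decaying Poisson process of the isotope,
    positions the source geometry, and directions are importance-sampled
    toward the aperture (weights carry the solid-angle fraction) unless
    ``mode="analog"`` (isotropic directions, Bernoulli transport, unit
    weights).  Events carry the true interaction position and energy;
    feed them to the digitizer chain for observed singles.
    """
    geometry = geometry or DetectorGeometry()
    pinhole = pinhole or PinholeSpec()
    rng = np.random.default_rng(seed)
    em = source.emission
    lam = em.decay_constant
    a_start = source.activity * np.exp(-lam * acquisition_start)
    n_decays = a_start * 1e6 * -np.expm1(-lam * duration) / lam
    if n_decays <= 0 or n_samples == 0:
        return EventList.empty(duration=duration, isotope=source.isotope,
                               activity_mbq=source.activity,
                               calibration_time=-acquisition_start)

    # photon line assignment
    intens = np.array([p for _, p in em.lines])
    line_e = np.array([e for e, _ in em.lines])
    photons_per_decay = intens.sum()
    line_idx = rng.choice(len(line_e), size=n_samples, p=intens / photons_per_decay)
    energy = line_e[line_idx]

    w = np.full(n_samples, n_decays * photons_per_decay / n_samples)
    pos, w_pos = _sample_positions(source, n_samples, rng)
    w = w * w_pos

    if mode == "importance":
        target_r = pinhole.diameter / 2.0 + sampling_margin
        u, w_dir = _directions_to_disk(rng, pos, n_samples, target_r)
        w = w * w_dir
    elif mode == "analog":
        cos_t = rng.uniform(-1.0, 1.0, n_samples)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_samples)
        sin_t = np.sqrt(1.0 - cos_t**2)
        u = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        going_down = u[:, 2] < -1e-6
        pos, u, energy, w = pos[going_down], u[going_down], energy[going_down], w[going_down]
    else:
        raise ValueError("mode must be 'importance' or 'analog'")

    # source self-absorption, per line energy for multi-line isotopes
    w_att = np.ones(len(w))
    for e in np.unique(energy):
        m = energy == e
        w_att[m] = _source_self_attenuation(source, pos[m], u[m], e, materials)

    # tungsten chord through the knife-edge collimator
    w_col = np.ones(len(w))
    for e in np.unique(energy):
        m = energy == e
        path = pinhole_path_length(pos[m], u[m], pinhole)
        w_col[m] = np.exp(-materials.mu("tungsten", e) * path)

    # propagate to crystal front face
    z_cry = -geometry.aperture_to_crystal
    t_cry = (z_cry - pos[:, 2]) / u[:, 2]
    entry = pos[:, :2] + u[:, :2] * t_cry[:, None]
    half = geometry.crystal_size / 2.0
    inside = (np.abs(entry[:, 0]) < half) & (np.abs(entry[:, 1]) < half) & (t_cry > 0)

    p_int = np.zeros(len(w))
    xy = entry.copy()
    depth_z = np.zeros(len(w))
    for e in np.unique(energy):
        m = inside & (energy == e)
        if not m.any():
            continue
        pi, _, pxy, dpt = crystal_detection(entry[m], u[m], e, rng, geometry, materials)
        p_int[m] = pi
        xy[m] = pxy
        depth_z[m] = dpt * np.abs(u[m, 2])

    # interaction type: photoelectric deposits the full photon energy and is
    # the photopeak channel; a single Compton interaction deposits only the
    # recoil-electron energy (scattered photon assumed to escape the 3 mm
    # crystal), pushing the event far below the photopeak window.
    pe_frac = np.ones(len(w))
    for e in np.unique(energy):
        m = inside & (energy == e)
        pe_frac[m] = materials.photoelectric_fraction("csi", e)

    deposit = energy.copy()
    is_compton = (rng.random(len(w)) >= pe_frac) & inside
    if is_compton.any():
        for e in np.unique(energy[is_compton]):
            m = is_compton & (energy == e)
            idx = np.flatnonzero(m)
            p_rec, e_sc, w2, ell2 = _compton_second_interaction(
                e, u[idx], depth_z[idx], rng, geometry, materials)
            recovered = rng.random(idx.size) < p_rec
            # recovered: adder sums both deposits -> photopeak event at the
            # energy-weighted centroid of the two interaction sites
            r_idx = idx[recovered]
            xy2 = xy[r_idx] + w2[recovered, :2] * ell2[recovered, None]
            frac = (e_sc[recovered] / e)[:, None]
            xy[r_idx] = xy[r_idx] * (1.0 - frac) + xy2 * frac
            deposit[r_idx] = e
            deposit[idx[~recovered]] = e - e_sc[~recovered]

    if mode == "analog":
        survive = (rng.random(len(w)) < w_att * w_col * p_int) & inside
        keep = survive
        w_out = w[keep]
    else:
        w_out = w * w_att * w_col * p_int
        keep = inside & (w_out > 0)
        w_out = w_out[keep]

    times = _sample_times(rng, int(keep.sum()), lam, duration)
    return EventList(times, xy[keep, 0], xy[keep, 1], deposit[keep], w_out,
                     duration=duration, isotope=source.isotope,
                     activity_mbq=source.activity,
                     calibration_time=-acquisition_start)


# ---------------------------------------------------------------------------
# Scatter phantom (triple line source in acrylic cylinder)
# ---------------------------------------------------------------------------


@dataclass
class ScatterPhantom:
    """Mouse-sized triple-line scatter cylinder, axis along planar y."""

    diameter: float = 25.4  # mm
    length: float = 60.0  # mm
    bore_offsets: tuple = ((0.0, 0.0), (10.0, 0.0), (0.0, 10.0))  # (x, z) mm from axis

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def _cylinder_exit_chord(pos, u, axis_xz, radius):
    """Distance to exit a y-axis cylinder centred at axis_xz, from inside."""
    px = pos[:, 0] - axis_xz[0]
    pz = pos[:, 2] - axis_xz[1]
    ux, uz = u[:, 0], u[:, 2]
    a = ux**2 + uz**2
    b = 2.0 * (px * ux + pz * uz)
    c = px**2 + pz**2 - radius**2
    disc = np.maximum(b * b - 4 * a * c, 0.0)
    a = np.where(a < 1e-12, 1e-12, a)
    return (-b + np.sqrt(disc)) / (2.0 * a)


def simulate_scatter_phantom(source: SourceSpec,
                             phantom: ScatterPhantom | None = None,
                             active_bore: int = 0,
                             geometry: DetectorGeometry | None = None,
                             pinhole: PinholeSpec | None = None,
                             materials: MaterialTable = DEFAULT_MATERIALS,
                             duration: float = 100.0,
                             seed: int = 0,
                             n_samples: int = 200_000,
                             scatter: bool = True,
                             scatter_fraction_of_samples: float = 0.5) -> EventList:
    """Line source inside the acrylic scatter cylinder, with single scatter.

    Primaries are attenuated along the exact chord through the cylinder
    (treated as acrylic; the thin water bores are neglected).  Scattered
    photons are generated by forced single Compton scatter: an isotropic
    first leg, an interaction point sampled on the chord, and a
    Klein-Nishina-weighted forced second leg toward the aperture with the
    scattered energy from the Compton relation.  Multiple scatter is
    ignored.
    """
    geometry = geometry or DetectorGeometry()
    pinhole = pinhole or PinholeSpec()
    phantom = phantom or ScatterPhantom()
    rng = np.random.default_rng(seed)
    em = source.emission
    lam = em.decay_constant

    bore_x, bore_dz = phantom.bore_offsets[active_bore]
    axis_xz = (0.0, source.distance + 5.0)  # cylinder axis position in (x, z)
    src_xz = (axis_xz[0] + bore_x, axis_xz[1] + bore_dz)
    if bore_x**2 + bore_dz**2 >= phantom.radius**2:
        raise ValueError("source bore lies outside the phantom")

    n_decays = source.activity * 1e6 * -np.expm1(-lam * duration) / lam
    e0 = em.lines[0][0]
    intensity = em.lines[0][1]
    mu_tot = float(materials.mu("acrylic", e0))
    mu_inc = float(materials.mu_incoherent("acrylic", e0))

    n_prim = n_samples if not scatter else int(n_samples * (1 - scatter_fraction_of_samples))
    n_scat = 0 if not scatter else n_samples - n_prim

    # --- primaries ---------------------------------------------------------
    yline = rng.uniform(-source.line_length / 2, source.line_length / 2, n_prim)
    rxy = _sample_disk(rng, n_prim, source.line_radius)
    pos = np.column_stack([src_xz[0] + rxy[:, 0], yline, src_xz[1] + rxy[:, 1]])
    target_r = pinhole.diameter / 2.0 + 2.5
    u, w_dir = _directions_to_disk(rng, pos, n_prim, target_r)
    w = n_decays * intensity / n_prim * w_dir
    chord = _cylinder_exit_chord(pos, u, axis_xz, phantom.radius)
    w = w * np.exp(-mu_tot * chord)
    ev_p = _finish_transport(pos, u, np.full(n_prim, e0), w, geometry, pinhole,
                             materials, rng)

    parts = [ev_p]

    # --- forced single scatter --------------------------------------------
    if n_scat > 0:
        yline = rng.uniform(-source.line_length / 2, source.line_length / 2, n_scat)
        rxy = _sample_disk(rng, n_scat, source.line_radius)
        pos = np.column_stack([src_xz[0] + rxy[:, 0], yline, src_xz[1] + rxy[:, 1]])
        # isotropic first leg
        cos_t = rng.uniform(-1, 1, n_scat)
        phi = rng.uniform(0, 2 * np.pi, n_scat)
        sin_t = np.sqrt(1 - cos_t**2)
        u1 = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        chord1 = _first_leg_chord(pos, u1, axis_xz, phantom)
        # interaction point uniform on the chord; weight = mu_inc * chord * attenuation
        s = rng.random(n_scat) * chord1
        x_s = pos + u1 * s[:, None]
        w = n_decays * intensity / n_scat * mu_inc * chord1 * np.exp(-mu_tot * s)
        # forced second leg toward the aperture disk
        u2, w_dir = _directions_to_disk(rng, x_s, n_scat, target_r)
        cos_sc = np.einsum("ij,ij->i", u1, u2)
        e_sc = compton_scattered_energy(e0, cos_sc)
        w = w * w_dir * 4.0 * np.pi * _kn_angular_pdf(e0, cos_sc)
        # exit attenuation at the scattered energy
        chord2 = _cylinder_exit_chord(x_s, u2, axis_xz, phantom.radius)
        mu2 = materials.mu("acrylic", e_sc)
        w = w * np.exp(-mu2 * np.maximum(chord2, 0.0))
        down = u2[:, 2] < -1e-6
        ev_s = _finish_transport(x_s[down], u2[down], e_sc[down], w[down],
                                 geometry, pinhole, materials, rng)
        parts.append(ev_s)

    xs = np.concatenate([p[1] for p in parts])
    ys = np.concatenate([p[2] for p in parts])
    es = np.concatenate([p[3] for p in parts])
    ws = np.concatenate([p[4] for p in parts])
    times = _sample_times(rng, len(xs), lam, duration)
    return EventList(times, xs, ys, es, ws, duration=duration,
                     isotope=source.isotope, activity_mbq=source.activity)


def _first_leg_chord(pos, u, axis_xz, phantom: ScatterPhantom):
    """Path length of the first leg inside the cylinder (radial + end caps)."""
    chord = _cylinder_exit_chord(pos, u, axis_xz, phantom.radius)
    # truncate at the end caps (axis along y)
    uy = u[:, 1]
    with np.errstate(divide="ignore"):
        t_cap = np.where(np.abs(uy) > 1e-12,
                         (np.sign(uy) * phantom.length / 2.0 - pos[:, 1]) / uy,
                         np.inf)
    return np.minimum(chord, np.maximum(t_cap, 0.0))


def _kn_angular_pdf(energy_kev, cos_theta):
    """Klein-Nishina scattering-angle pdf per solid angle (normalized)."""
    eps = energy_kev / ELECTRON_REST_KEV
    ratio = 1.0 / (1.0 + eps * (1.0 - cos_theta))
    r_e2 = (2.8179403262e-13) ** 2
    dsig = 0.5 * r_e2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_theta**2))
    return dsig / klein_nishina_total(energy_kev)


def _finish_transport(pos, u, energy, w, geometry, pinhole, materials, rng):
    """Collimator + crystal transport shared by primary and scatter legs."""
    if len(w) == 0:
        z = np.empty(0)
        return z, z, z, z, z
    w_col = np.ones(len(w))
    # group in coarse energy bins for the chord/attenuation evaluation
    mu_w = materials.mu("tungsten", energy)
    path = pinhole_path_length(pos, u, pinhole)
    w_col = np.exp(-mu_w * path)
    z_cry = -geometry.aperture_to_crystal
    t_cry = (z_cry - pos[:, 2]) / u[:, 2]
    entry = pos[:, :2] + u[:, :2] * t_cry[:, None]
    half = geometry.crystal_size / 2.0
    inside = (np.abs(entry[:, 0]) < half) & (np.abs(entry[:, 1]) < half) & (t_cry > 0)
    cos_t = np.abs(u[:, 2])
    mu_csi = materials.mu("csi", energy)
    p_int = 1.0 - np.exp(-mu_csi * geometry.crystal_thickness / np.maximum(cos_t, 1e-9))
    pe_frac = materials.photoelectric_fraction("csi", energy)
    xi = rng.random(len(w))
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(p_int > 0, -np.log1p(-xi * p_int) / np.maximum(mu_csi, 1e-12), 0.0)
    xy = entry + (u[:, :2] / np.maximum(cos_t, 1e-9)[:, None]) * depth[:, None]
    # photopeak channel: photoelectric first interactions plus Compton events
    # whose scattered photon is re-absorbed in the slab (adder-summed);
    # partial Compton deposits fall outside the windows of interest
    p_rec, _, _, _ = _compton_second_interaction(
        float(np.mean(energy)) if len(energy) else 140.5,
        u, depth * cos_t, rng, geometry, materials)
    pe_eff = pe_frac + (1.0 - pe_frac) * p_rec
    w_out = w * w_col * p_int * pe_eff
    keep = inside & (w_out > 0)
    z = np.zeros(int(keep.sum()))
    return z, xy[keep, 0], xy[keep, 1], energy[keep], w_out[keep]


# ---------------------------------------------------------------------------
# Decaying-source count-rate series
# ---------------------------------------------------------------------------


@dataclass
class CountRatePoint:
    time: float  # s since series start
    icr: float  # cps, true input rate
    ocr: float  # cps, observed after the digitizer


def simulate_decaying_source_series(icr0: float,
                                    digitizer_config,
                                    seed: int = 0,
                                    isotope: str = "Tc99m",
                                    interval: float = 3600.0,
                                    acq_time: float = 10.0,
                                    stop_ocr: float = 600.0,
                                    max_points: int = 120,
                                    energy_kev: float = 140.511):
    """One (time, ICR, OCR) point per interval until OCR < ``stop_ocr``.

    Each point is a short acquisition of Poisson arrivals at the decayed
    input rate, pushed through the digitizer chain (pile-up, paralyzable
    dead time, efficiency).  The last returned point is the first with
    OCR below the stop rule.
    """
    from .digitizer import apply_chain

    rng = np.random.default_rng(seed)
    lam = ISOTOPES[isotope].decay_constant
    points = []
    for k in range(max_points):
        t_k = k * interval
        icr = icr0 * np.exp(-lam * t_k)
        n_exp = icr * acq_time
        n = rng.poisson(n_exp)
        times = np.sort(rng.uniform(0.0, acq_time, n))
        z = np.zeros(n)
        ev = EventList(times, z, z, np.full(n, energy_kev), np.ones(n),
                       duration=acq_time, isotope=isotope)
        out = apply_chain(ev, digitizer_config, seed=rng.integers(1 << 31))
        ocr = len(out) / acq_time
        points.append(CountRatePoint(time=t_k, icr=float(icr), ocr=float(ocr)))
        if ocr < stop_ocr:
            break
    return points


# ---------------------------------------------------------------------------
# Rotating SPECT acquisition
# ---------------------------------------------------------------------------


def rotate_points_to_camera(points, angle_deg, radius_of_rotation=28.0):
    """Map world points (rotation axis = z) into the planar camera frame.

    The camera stays at angle 0; view ``angle_deg`` rotates the object by
    the inverse angle.  Returns planar-frame coordinates where the aperture
    plane is z = 0 and the detector looks along -z.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.deg2rad(angle_deg)
    c, s = np.cos(-a), np.sin(-a)
    xr = c * p[:, 0] - s * p[:, 1]
    yr = s * p[:, 0] + c * p[:, 1]
    zr = p[:, 2]
    return np.column_stack([-yr, zr, radius_of_rotation - xr])


def simulate_spect_scan(sources,
                        geometry: DetectorGeometry | None = None,
                        pinhole: PinholeSpec | None = None,
                        materials: MaterialTable = DEFAULT_MATERIALS,
                        arc: float = 270.0,
                        step: float = 3.0,
                        radius_of_rotation: float = 28.0,
                        time_per_view: float = 10.0,
                        n_samples_per_view: int = 20_000,
                        detector_pixels: int = 208,
                        detector_pitch: float = 0.5,
                        energy_window=None,
                        seed: int = 0,
                        digitizer_config=None,
                        attenuation_cylinder=None):
    """Rotating single-pinhole SPECT scan of point-like sources.

    ``sources`` is a list of dicts with keys ``position`` (world mm, rotation
    axis = z through the centre of rotation), ``activity`` (MBq), optional
    ``axial_extent`` (mm, short line segment along z) and ``radius``.
    Returns one ProjectionImage per view, view k at angle k * step.
    """
    from .digitizer import apply_chain
    from .core import bin_events, make_energy_window

    geometry = geometry or DetectorGeometry()
    pinhole = pinhole or PinholeSpec()
    if energy_window is None:
        energy_window = make_energy_window(140.511, 0.30)
    n_views_f = arc / step
    if abs(n_views_f - round(n_views_f)) > 1e-9:
        raise ValueError("step must divide the arc")
    n_views = int(round(n_views_f))
    rng = np.random.default_rng(seed)

    activities = np.array([s["activity"] for s in sources], dtype=float)
    p_src = activities / activities.sum()
    views = []
    for k in range(n_views):
        angle = k * step
        t_start = k * time_per_view
        ev_parts = []
        n_k = n_samples_per_view
        src_idx = rng.choice(len(sources), size=n_k, p=p_src)
        pts = np.empty((n_k, 3))
        for j, s in enumerate(sources):
            m = src_idx == j
            nm = int(m.sum())
            base = np.tile(np.asarray(s["position"], dtype=float), (nm, 1))
            ax = s.get("axial_extent", 0.0)
            rad = s.get("radius", 0.0)
            if ax > 0:
                base[:, 2] += rng.uniform(-ax / 2, ax / 2, nm)
            if rad > 0:
                base[:, :2] += _sample_disk(rng, nm, rad)
            pts[m] = base
        cam = rotate_points_to_camera(pts, angle, radius_of_rotation)
        em = ISOTOPES["Tc99m"]
        lam = em.decay_constant
        a_tot = activities.sum() * np.exp(-lam * t_start)
        n_dec = a_tot * 1e6 * -np.expm1(-lam * time_per_view) / lam
        e0, intensity = em.lines[0]
        target_r = pinhole.diameter / 2.0 + 2.5
        u, w_dir = _directions_to_disk(rng, cam, n_k, target_r)
        w = n_dec * intensity / n_k * w_dir
        if attenuation_cylinder is not None:
            med, rad_c, len_c = attenuation_cylinder
            chord = _cylinder_exit_chord(cam, u, (0.0, radius_of_rotation), rad_c)
            uy = u[:, 1]
            with np.errstate(divide="ignore"):
                t_cap = np.where(np.abs(uy) > 1e-12,
                                 (np.sign(uy) * len_c / 2.0 - cam[:, 1]) / uy,
                                 np.inf)
            chord = np.minimum(chord, np.maximum(t_cap, 0.0))
            w = w * np.exp(-materials.mu(med, e0) * np.maximum(chord, 0.0))
        path = pinhole_path_length(cam, u, pinhole)
        w = w * np.exp(-materials.mu("tungsten", e0) * path)
        z_cry = -geometry.aperture_to_crystal
        t_cry = (z_cry - cam[:, 2]) / u[:, 2]
        entry = cam[:, :2] + u[:, :2] * t_cry[:, None]
        half = geometry.crystal_size / 2.0
        inside = (np.abs(entry[:, 0]) < half) & (np.abs(entry[:, 1]) < half) & (t_cry > 0)
        p_int, pe_frac, xy, dpt = crystal_detection(entry, u, e0, rng, geometry, materials)
        p_rec, _, _, _ = _compton_second_interaction(
            float(e0), u, dpt * np.abs(u[:, 2]), rng, geometry, materials)
        w_out = w * p_int * (pe_frac + (1.0 - pe_frac) * p_rec)
        keep = inside & (w_out > 0)
        times = _sample_times(rng, int(keep.sum()), lam, time_per_view)
        ev = EventList(times, xy[keep, 0], xy[keep, 1],
                       np.full(int(keep.sum()), e0), w_out[keep],
                       duration=time_per_view)
        if digitizer_config is not None:
            ev = apply_chain(ev, digitizer_config, seed=int(rng.integers(1 << 31)))
        img = bin_events(ev, energy_window, pitch=detector_pitch,
                         extent=detector_pixels * detector_pitch)
        views.append(img)
    return views
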