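"""Shared domain types, conventions, and I/O for the camera bench.

Conventions used throughout the package:

* Detector-plane coordinates are millimetres with the origin at the crystal
  centre; ``x`` is transaxial and ``y`` axial in planar tests.  For SPECT the
  rotation axis is ``z`` (axial).
* Source-to-collimator distances ``D`` are measured to the collimator face;
  the aperture plane sits at mid-thickness, so the source-to-aperture
  distance is ``D + 5`` mm.
* Pixel bins are half-open ``[edge, edge + pitch)`` and 0-based; an event
  exactly on an edge goes to the higher bin.
* The useful and central fields of view are centred squares (the crystal is
  square), CFOV = 0.75 x UFOV linearly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DetectorGeometry:
    """Fixed head geometry (single-pinhole configuration)."""

    crystal_size: float = 102.0  # mm, square
    crystal_thickness: float = 3.0  # mm CsI
    lightguide_thickness: float = 2.0  # mm
    ufov: float = 84.5  # mm
    aperture_to_crystal: float = 26.75  # mm, aperture plane to crystal face
    collimator_thickness: float = 10.0  # mm tungsten

    def __post_init__(self):
        if not self.ufov < self.crystal_size:
            raise ValueError("UFOV must fit inside the crystal")

    @property
    def cfov(self) -> float:
        return 0.75 * self.ufov


@dataclass
class EventList:
    """List-mode container: per-event time, position, energy, weight.

    Records are kept time-sorted.  ``weight`` carries variance-reduction
    weights (1.0 for analog events).
    """

    t: np.ndarray  # s since acquisition start
    x: np.ndarray  # mm, detector plane
    y: np.ndarray  # mm
    energy: np.ndarray  # keV
    weight: np.ndarray  # unitless, > 0
    duration: float = 0.0  # s
    isotope: str = "Tc99m"
    activity_mbq: float = 0.0  # calibrated activity
    calibration_time: float = 0.0  # s, on the same clock as t

    def __post_init__(self):
        arrays = [np.asarray(a, dtype=float) for a in (self.t, self.x, self.y, self.energy, self.weight)]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise ValueError("event columns must have equal length")
        order = np.argsort(arrays[0], kind="stable")
        self.t, self.x, self.y, self.energy, self.weight = (a[order] for a in arrays)
        if n:
            if self.t[0] < 0:
                raise ValueError("event times must be >= 0")
            if np.any(self.energy <= 0) or np.any(self.weight <= 0):
                raise ValueError("energies and weights must be positive")
            if self.duration < self.t[-1]:
                self.duration = float(self.t[-1])

    def __len__(self) -> int:
        return self.t.size

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())

    def in_window(self, window) -> "EventList":
        lo, hi = window
        m = (self.energy >= lo) & (self.energy <= hi)
        return replace(self, t=self.t[m], x=self.x[m], y=self.y[m],
                       energy=self.energy[m], weight=self.weight[m])

    def to_csv(self, path):
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y,
                      "E": self.energy, "weight": self.weight}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "EventList":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(),
                   df["E"].to_numpy(), df["weight"].to_numpy(), **meta)

    @classmethod
    def empty(cls, **meta) -> "EventList":
        z = np.empty(0)
        return cls(z, z, z, z, z, **meta)


@dataclass
class ProjectionImage:
    """2D count grid with physical pixel geometry.

    ``counts[iy, ix]``; pixel (0, 0) has its lower-left corner at ``origin``.
    """

    counts: np.ndarray
    pixel_pitch: float = 0.1  # mm
    origin: tuple = (0.0, 0.0)  # mm, lower-left corner of pixel (0, 0)
    energy_window: tuple | None = None  # keV
    fov_mask: str = "none"  # UFOV | CFOV | none

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2D")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def x_centers(self) -> np.ndarray:
        nx = self.counts.shape[1]
        return self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_pitch

    @property
    def y_centers(self) -> np.ndarray:
        ny = self.counts.shape[0]
        return self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_pitch

    def mask_for(self, which: str, geometry: DetectorGeometry | None = None) -> np.ndarray:
        """Boolean pixel mask of the requested field of view."""
        geometry = geometry or DetectorGeometry()
        side = {"UFOV": geometry.ufov, "CFOV": geometry.cfov}.get(which.upper())
        if side is None:
            raise ValueError("FOV must be 'UFOV' or 'CFOV'")
        xc, yc = self.x_centers, self.y_centers
        extent_x = self.counts.shape[1] * self.pixel_pitch
        extent_y = self.counts.shape[0] * self.pixel_pitch
        if side > extent_x or side > extent_y:
            raise ValueError("FOV mask larger than image extent")
        half = side / 2.0
        mx = (xc >= -half) & (xc < half)
        my = (yc >= -half) & (yc < half)
        return np.outer(my, mx)


@dataclass
class NemaReport:
    """Structured result block with reproducibility metadata."""

    test: str
    seed: int
    config_hash: str
    results: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame

    def to_json(self) -> str:
        payload = {"test": self.test, "seed": self.seed,
                   "config_hash": self.config_hash, "results": self.results}
        return json.dumps(payload, sort_keys=True, indent=2, default=_jsonify)

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{self.test}.json").write_text(self.to_json() + "\n")
        for name, df in self.tables.items():
            df.to_csv(out / f"{self.test}_{name}.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def make_energy_window(center: float, width_fraction: float):
    """Symmetric fractional energy window ``[c(1-w/2), c(1+w/2)]`` in keV."""
    if center <= 0:
        raise ValueError("window centre must be positive")
    if not 0 <= width_fraction < 2:
        raise ValueError("width fraction must be in [0, 2)")
    half = width_fraction / 2.0
    return (center * (1 - half), center * (1 + half))


def apply_fov_mask(img: ProjectionImage, which: str,
                   geometry: DetectorGeometry | None = None) -> ProjectionImage:
    """Return a copy of the image restricted to the UFOV/CFOV square.

    Pixels whose centres fall outside the centred square are zeroed and the
    image is tagged so downstream statistics exclude them.
    """
    mask = img.mask_for(which, geometry)
    return replace(img, counts=np.where(mask, img.counts, 0.0), fov_mask=which.upper())


def bin_events(events: EventList, window, pitch: float = 0.1,
               extent: float | None = None, center=(0.0, 0.0)) -> ProjectionImage:
    """Histogram in-window events onto a square detector grid.

    Bins are half-open; an event exactly on an edge goes to the higher bin.
    The total image content equals the summed in-window weights of events
    landing inside the grid.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    extent = extent if extent is not None else DetectorGeometry().crystal_size
    n = int(round(extent / pitch))
    x0 = center[0] - n * pitch / 2.0
    y0 = center[1] - n * pitch / 2.0
    ev = events.in_window(window) if window is not None else events
    ix = np.floor((ev.x - x0) / pitch).astype(np.int64)
    iy = np.floor((ev.y - y0) / pitch).astype(np.int64)
    ok = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
    counts = np.zeros((n, n))
    np.add.at(counts, (iy[ok], ix[ok]), ev.weight[ok])
    return ProjectionImage(counts, pixel_pitch=pitch, origin=(x0, y0),
                           energy_window=tuple(window) if window is not None else None)


def bin_spectrum(events: EventList, bin_width: float = 0.6):
    """Energy histogram with the given bin width; conserves total weight.

    Returns ``(counts, edges)`` with edges starting at 0 keV so that every
    event falls in a bin.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(events) == 0:
        return np.zeros(1), np.array([0.0, bin_width])
    n_bins = int(np.floor(events.energy.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.floor(events.energy / bin_width).astype(np.int64)
    counts = np.bincount(idx, weights=events.weight, minlength=n_bins)
    return counts, edges


def save_volume_nifti(path, volume: np.ndarray, voxel: float):
    """Write a reconstructed volume (or projection stack) as NIfTI."""
    import nibabel as nib

    affine = np.diag([voxel, voxel, voxel, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def load_volume_nifti(path):
    """Read a NIfTI volume; returns (array, voxel_size_mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=float), voxel


VALID_TESTS = (
    "intrinsic_resolution", "uniformity", "mwsr", "count_rate",
    "energy_resolution", "system_resolution", "sensitivity",
    "tomo_resolution", "volume_sensitivity",
)


def run_nema_test(config: dict) -> NemaReport:
    """Run one named performance test end to end (simulate + analyse).

    ``config`` must contain ``test`` (one of :data:`VALID_TESTS`) and
    ``seed``; remaining keys override the scenario defaults.  The result is
    deterministic given (config, seed).
    """
    from . import scenarios  # local import: scenarios pull in heavy modules

    test = config.get("test")
    if test not in VALID_TESTS:
        raise ValueError(
            f"unknown test {test!r}; valid tests: {', '.join(VALID_TESTS)}"
        )
    seed = int(config.get("seed", 0))
    runner = getattr(scenarios, f"run_{test}")
    results, tables = runner(config, seed)
    report = NemaReport(test=test, seed=seed, config_hash=config_hash(config),
                        results=results, tables=tables)
    return report
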