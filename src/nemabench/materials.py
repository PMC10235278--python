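"""Photon interaction data for the simulated materials.

Mass-attenuation grids are build-time constants tabulated from the NIST XCOM
database at the relevant emission energies (90-300 keV band).  The incoherent
(Compton) component is computed from the Klein-Nishina cross-section times the
material's electron density Z/A; the photoelectric component is the tabulated
total minus the incoherent part.  Coherent (Rayleigh) scattering is excluded
from the working totals: it is a few percent in this band and strongly
forward-peaked, so treating it as non-attenuating is the standard
narrow-beam-adjacent approximation for detection modelling.

Energies are keV, mass coefficients cm^2/g, linear coefficients returned in
1/mm to match the geometry code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELECTRON_REST_KEV = 511.0
_R_E_CM = 2.8179403262e-13
_N_A = 6.02214076e23


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross-section per electron, cm^2.

    Closed form for the integrated free-electron Compton cross-section;
    binding (incoherent scattering function) corrections are negligible for
    these materials above ~60 keV.
    """
    eps = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    pref = 2.0 * np.pi * _R_E_CM**2
    a = (1 + eps) / eps**2 * (2 * (1 + eps) / (1 + 2 * eps) - np.log1p(2 * eps) / eps)
    b = np.log1p(2 * eps) / (2 * eps)
    c = (1 + 3 * eps) / (1 + 2 * eps) ** 2
    return pref * (a + b - c)


def compton_scattered_energy(energy_kev, cos_theta):
    """Energy of a Compton-scattered photon (Compton relation)."""
    e = np.asarray(energy_kev, dtype=float)
    return e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - np.asarray(cos_theta, dtype=float)))


def sample_klein_nishina_cos_theta(energy_kev, n, rng):
    """Sample n scattering-angle cosines from the Klein-Nishina distribution.

    Vectorized rejection sampling against the differential cross-section
    (photon-polar-angle form, isotropic azimuth handled by the caller).
    """
    eps = float(energy_kev) / ELECTRON_REST_KEV

    def dsigma(cos_t):
        ratio = 1.0 / (1.0 + eps * (1.0 - cos_t))  # E'/E
        return ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_t**2))

    # envelope: constant at the forward-peak value
    grid = np.linspace(-1.0, 1.0, 513)
    peak = dsigma(grid).max() * 1.0001
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.5), 64)
        cand = rng.uniform(-1.0, 1.0, m)
        keep = rng.uniform(0.0, peak, m) < dsigma(cand)
        take = cand[keep][: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


# ---------------------------------------------------------------------------
# Tabulated mass attenuation (total, coherent excluded) -- NIST XCOM anchors.
# Grids are strictly inside one absorption-edge-free band for each material
# (tungsten K edge at 69.5 keV sits below the 80 keV grid start).
# ---------------------------------------------------------------------------

_Z_OVER_A = {
    "tungsten": 0.40250,
    "csi": 0.41569,
    "water": 0.55509,
    "acrylic": 0.53937,
    "aluminum": 0.48181,
    "glass": 0.49930,
}

_DENSITY_G_CM3 = {
    "tungsten": 19.30,
    "csi": 4.51,
    "water": 0.998,
    "acrylic": 1.19,
    "aluminum": 2.699,
    "glass": 2.23,
}

# XCOM mass attenuation with coherent scattering included, cm^2/g
_XCOM_TOTAL_WITH_COH = {
    "tungsten": ([80.0, 100.0, 150.0, 200.0, 300.0], [7.810, 4.438, 1.581, 0.7844, 0.3238]),
    "water": ([60.0, 80.0, 100.0, 150.0, 200.0, 300.0], [0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186]),
    "aluminum": ([60.0, 80.0, 100.0, 150.0, 200.0, 300.0], [0.2778, 0.2018, 0.1704, 0.1378, 0.1223, 0.1042]),
    "acrylic": ([60.0, 80.0, 100.0, 150.0, 200.0, 300.0], [0.1974, 0.1771, 0.1641, 0.1451, 0.1323, 0.1147]),
    "glass": ([60.0, 80.0, 100.0, 150.0, 200.0, 300.0], [0.2508, 0.1903, 0.1644, 0.1356, 0.1215, 0.1041]),
    # CsI anchored at 140.5 keV (linear attenuation 3.00/cm without coherent,
    # equivalent to the textbook NaI(Tl) 2.22/cm anchor with Cs<->I Z-scaling),
    # photoelectric scaled as E^-2.8 between edges.
    "csi": ([60.0, 80.0, 100.0, 150.0, 200.0, 300.0], [6.126, 2.806, 1.556, 0.5715, 0.3075, 0.1546]),
}

# Estimated coherent contribution removed from the working totals, cm^2/g.
_COHERENT_FRACTION = {
    "tungsten": 0.050,
    "csi": 0.035,
    "water": 0.015,
    "aluminum": 0.020,
    "acrylic": 0.013,
    "glass": 0.020,
}


@dataclass(frozen=True)
class MaterialTable:
    """Linear attenuation lookup for the simulated materials.

    ``mu(material, E)`` and the photoelectric/incoherent split are evaluated
    by log-log interpolation on the frozen XCOM grids.  Units: 1/mm.
    """

    densities: dict = field(default_factory=lambda: dict(_DENSITY_G_CM3))

    def _grid(self, material: str):
        try:
            e, tot = _XCOM_TOTAL_WITH_COH[material]
        except KeyError:
            raise KeyError(
                f"unknown material {material!r}; known: {sorted(_XCOM_TOTAL_WITH_COH)}"
            ) from None
        e = np.asarray(e)
        tot = np.asarray(tot) * (1.0 - _COHERENT_FRACTION[material])
        return e, tot

    def mass_attenuation(self, material: str, energy_kev):
        """Total mass attenuation (coherent excluded), cm^2/g."""
        e_grid, tot = self._grid(material)
        energy = np.asarray(energy_kev, dtype=float)
        loge = np.clip(np.log(energy), np.log(e_grid[0]), np.log(e_grid[-1]))
        return np.exp(np.interp(loge, np.log(e_grid), np.log(tot)))

    def mu(self, material: str, energy_kev):
        """Linear attenuation coefficient, 1/mm."""
        rho = self.densities[material]
        return self.mass_attenuation(material, energy_kev) * rho / 10.0

    def mu_incoherent(self, material: str, energy_kev):
        """Incoherent (Compton) linear coefficient from Klein-Nishina, 1/mm."""
        sigma = klein_nishina_total(energy_kev)
        rho = self.densities[material]
        return sigma * _N_A * _Z_OVER_A[material] * rho / 10.0

    def mu_photoelectric(self, material: str, energy_kev):
        """Photoelectric linear coefficient (total minus incoherent), 1/mm."""
        diff = self.mu(material, energy_kev) - self.mu_incoherent(material, energy_kev)
        return np.maximum(diff, 0.0)

    def photoelectric_fraction(self, material: str, energy_kev):
        mu = self.mu(material, energy_kev)
        return np.where(mu > 0, self.mu_photoelectric(material, energy_kev) / mu, 0.0)


DEFAULT_MATERIALS = MaterialTable()
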