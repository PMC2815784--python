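"""Photon and electron interaction data for the materials used in the pipeline.

Mass attenuation coefficients (cm^2/g, coherent scattering included) are
embedded on a fixed energy grid for the five materials the beamline filter
stack and the water phantoms require, following the standard NIST-style
compilation, with log-log interpolation between knots.

Partial photon cross-sections for water are constructed self-consistently:

* incoherent (Compton): exact integrated Klein-Nishina cross-section per free
  electron times the electron density (binding corrections are < 1% above
  50 keV);
* coherent (Rayleigh): a power-law model anchored at 30 keV, adequate for the
  small branching fraction it represents in the 50-350 keV band;
* photoelectric: the remainder, total - incoherent - coherent, clamped at 0.

Electron collision stopping power for water is evaluated from the
Berger-Seltzer (Bethe) formula with mean excitation energy I = 75 eV; CSDA
ranges follow by numerical integration down to 1 keV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "AttenuationTable",
    "MATERIALS",
    "DENSITY_G_CM3",
    "mass_attenuation",
    "linear_attenuation",
    "water_partial_fractions",
    "klein_nishina_total_cm2",
    "klein_nishina_dcs",
    "collision_stopping_power",
    "csda_range_g_cm2",
]

ELECTRON_REST_KEV = 510.99895
AVOGADRO = 6.02214076e23
# classical electron radius, cm
R_E_CM = 2.8179403262e-13

# Energy grid (keV) shared by all embedded attenuation tables.
_E_GRID_KEV = np.array(
    [10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0,
     150.0, 200.0, 300.0, 400.0, 500.0, 600.0, 800.0, 1000.0]
)

# mu/rho with coherent, cm^2/g
_MU_RHO = {
    "H2O": np.array(
        [5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837,
         0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.09687, 0.08956,
         0.07865, 0.07072]
    ),
    "Be": np.array(
        [0.6466, 0.3070, 0.2251, 0.1792, 0.1640, 0.1554, 0.1493, 0.1401,
         0.1328, 0.1190, 0.1089, 0.09463, 0.08471, 0.07739, 0.07155,
         0.06286, 0.05652]
    ),
    "C": np.array(
        [2.078, 0.7076, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610,
         0.1514, 0.1347, 0.1229, 0.1066, 0.09546, 0.08715, 0.08058,
         0.07076, 0.06361]
    ),
    "Al": np.array(
        [26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018,
         0.1704, 0.1378, 0.1223, 0.1042, 0.09276, 0.08445, 0.07802,
         0.06841, 0.06146]
    ),
    "Cu": np.array(
        [215.9, 74.05, 33.79, 10.92, 4.862, 2.613, 1.593, 0.7630,
         0.4584, 0.2217, 0.1559, 0.1119, 0.09413, 0.08362, 0.07625,
         0.06605, 0.05901]
    ),
}

DENSITY_G_CM3 = {"H2O": 1.0, "Be": 1.848, "C": 1.70, "Al": 2.699, "Cu": 8.96}

MATERIALS = tuple(_MU_RHO)

# electrons per gram
_Z_OVER_A = {"H2O": 0.55509, "Be": 0.44384, "C": 0.49955, "Al": 0.48181,
             "Cu": 0.45636}


@dataclass(frozen=True)
class AttenuationTable:
    """Material attenuation data: energy grid, mu/rho and bulk density."""

    material: str
    energies_keV: np.ndarray
    mu_rho_cm2_g: np.ndarray
    density_g_cm3: float

    def mu_rho(self, energy_keV):
        return _loglog_interp(energy_keV, self.energies_keV, self.mu_rho_cm2_g)

    def mu(self, energy_keV):
        """Linear attenuation coefficient, 1/cm."""
        return self.mu_rho(energy_keV) * self.density_g_cm3


def table_for(material: str) -> AttenuationTable:
    if material not in _MU_RHO:
        raise KeyError(
            f"no embedded attenuation data for material {material!r}; "
            f"known materials: {', '.join(MATERIALS)}"
        )
    return AttenuationTable(
        material, _E_GRID_KEV.copy(), _MU_RHO[material].copy(),
        DENSITY_G_CM3[material],
    )


def _loglog_interp(e, knots, values):
    e = np.asarray(e, dtype=float)
    if np.any(e < knots[0]) or np.any(e > knots[-1]):
        raise ValueError(
            f"energy outside embedded table range "
            f"[{knots[0]}, {knots[-1]}] keV"
        )
    out = np.exp(np.interp(np.log(e), np.log(knots), np.log(values)))
    return out if out.ndim else float(out)


def mass_attenuation(material: str, energy_keV):
    """mu/rho (cm^2/g) with log-log interpolation between embedded knots."""
    return table_for(material).mu_rho(energy_keV)


def linear_attenuation(material: str, energy_keV):
    """mu (1/cm) at the material's nominal density."""
    return table_for(material).mu(energy_keV)


# ----------------------------------------------------------------- Compton --

def klein_nishina_total_cm2(energy_keV):
    """Integrated Klein-Nishina cross-section per free electron, cm^2."""
    a = np.asarray(energy_keV, dtype=float) / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * a
    lg = np.log(t)
    s = ((1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - lg / a)
         + lg / (2.0 * a) - (1.0 + 3.0 * a) / t**2)
    out = 2.0 * np.pi * R_E_CM**2 * s
    return out if out.ndim else float(out)


def klein_nishina_dcs(energy_keV, cos_theta):
    """Unpolarized Klein-Nishina dsigma/dOmega (cm^2/sr) at the given angle."""
    a = energy_keV / ELECTRON_REST_KEV
    ct = np.asarray(cos_theta, dtype=float)
    ratio = 1.0 / (1.0 + a * (1.0 - ct))  # E'/E
    out = 0.5 * R_E_CM**2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - ct**2))
    return out if out.ndim else float(out)


def compton_scattered_energy(energy_keV, cos_theta):
    """Scattered photon energy from the Compton relation."""
    a = energy_keV / ELECTRON_REST_KEV
    return energy_keV / (1.0 + a * (1.0 - np.asarray(cos_theta, dtype=float)))


def _incoherent_mu_rho(material, energy_keV):
    n_e = _Z_OVER_A[material] * AVOGADRO
    return n_e * klein_nishina_total_cm2(energy_keV)


# Coherent-scattering model for water: power law anchored at 30 keV where the
# coherent fraction is still appreciable; only the branching fraction matters.
_COH_ANCHOR_KEV = 30.0
_COH_ANCHOR_MU_RHO = 0.035
_COH_EXPONENT = -1.75


def _coherent_mu_rho_water(energy_keV):
    e = np.asarray(energy_keV, dtype=float)
    return _COH_ANCHOR_MU_RHO * (e / _COH_ANCHOR_KEV) ** _COH_EXPONENT


def water_partial_fractions(energy_keV):
    """Partial mu/rho for water: (photoelectric, incoherent, coherent, total).

    All in cm^2/g; total is the embedded compilation value (with coherent).
    """
    total = mass_attenuation("H2O", energy_keV)
    inc = _incoherent_mu_rho("H2O", energy_keV)
    coh = _coherent_mu_rho_water(energy_keV)
    pe = np.maximum(np.asarray(total) - inc - coh, 0.0)
    return pe, inc, coh, total


# ---------------------------------------------------------------- electrons --

_WATER_I_MEV = 75.0e-6


def collision_stopping_power(energy_keV):
    """Electron collision stopping power in water, MeV cm^2/g (Berger-Seltzer).

    Valid from ~1 keV upward; the density-effect correction is negligible
    below 1 MeV and omitted.
    """
    t_mev = np.asarray(energy_keV, dtype=float) / 1000.0
    tau = t_mev / (ELECTRON_REST_KEV / 1000.0)
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    i_ratio2 = (_WATER_I_MEV / (ELECTRON_REST_KEV / 1000.0)) ** 2
    ln_term = np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio2))
    f_tau = (1.0 - beta2
             + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0))
             / (tau + 1.0) ** 2)
    out = 0.153536 / beta2 * _Z_OVER_A["H2O"] * (ln_term + f_tau)
    return out if out.ndim else float(out)


# CSDA range table, integrated once at import on a log grid from 1 keV.
_CSDA_E_KEV = np.geomspace(1.0, 1000.0, 400)
_CSDA_G_CM2 = np.concatenate(
    [[0.0],
     cumulative_trapezoid(1.0e-3 / collision_stopping_power(_CSDA_E_KEV),
                          _CSDA_E_KEV)]
)


def csda_range_g_cm2(energy_keV):
    """CSDA range of an electron in water (g/cm^2), from 1 keV cutoff."""
    e = np.asarray(energy_keV, dtype=float)
    out = np.interp(e, _CSDA_E_KEV, _CSDA_G_CM2)
    return out if out.ndim else float(out)


def csda_range_cm(energy_keV):
    return csda_range_g_cm2(energy_keV) / DENSITY_G_CM3["H2O"]
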