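"""Monte Carlo transport of a single planar microbeam through a water cylinder.

The phantom is a water cylinder irradiated along its axis by a rectangular
("planar") microbeam entering the flat top face.  Coupled photon-electron
transport is performed analogically: free paths from the total attenuation
coefficient, interaction type from the partial cross-sections, Compton
scattering from the Klein-Nishina distribution, and secondary electrons
followed by condensed history with multiple-scattering deflections (default)
or along a CSDA-bounded straight kernel.  Doses are scored in 2-D
(transverse x depth) voxels, collapsing the beam-height axis over the central
80% of the slit height, and are normalized to the centermost in-beam entrance
voxel row (peak-dose units); absolute doses follow by multiplying with the
prescribed entrance peak dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from . import _mc, xdata
from .errors import ConfigurationError, RangeError
from .spectrum import EnergySpectrum, sample_energies

__all__ = [
    "CylinderPhantom",
    "MicrobeamSpec",
    "TransportConfig",
    "DoseGrid",
    "RAT_PHANTOM",
    "HUMAN_PHANTOM",
    "water_mu",
    "sample_interaction",
    "sample_compton",
    "transport_electron",
    "simulate_single_microbeam",
]

_ELECTRON_MODES = {"local": 0, "kernel": 1, "condensed_history": 2}


@dataclass(frozen=True)
class CylinderPhantom:
    """Water cylinder; the beam travels along the axis (depth direction)."""

    radius_cm: float
    height_cm: float
    material: str = "H2O"

    def __post_init__(self):
        if self.radius_cm <= 0 or self.height_cm <= 0:
            raise ConfigurationError("phantom radius and height must be positive")
        if self.material != "H2O":
            raise ConfigurationError("only water phantoms are supported")


#: rat head: 3 cm tall, 1.5 cm radius; human head: 16 cm tall, 8 cm radius
RAT_PHANTOM = CylinderPhantom(radius_cm=1.5, height_cm=3.0)
HUMAN_PHANTOM = CylinderPhantom(radius_cm=8.0, height_cm=16.0)


@dataclass(frozen=True)
class MicrobeamSpec:
    """Ideal top-hat rectangular microbeam (width x height)."""

    width_um: float = 50.0
    height_mm: float = 2.0

    def __post_init__(self):
        if self.width_um <= 0 or self.height_mm <= 0:
            raise ConfigurationError("beam width and height must be positive")


@dataclass(frozen=True)
class TransportConfig:
    n_histories: int = 1_000_000
    seed: int = 0
    electron_cutoff_keV: float = 1.0
    photon_cutoff_keV: float = 1.0
    electron_mode: str = "condensed_history"
    rayleigh_enabled: bool = True
    # analogue of a mixed-simulation fidelity knob: fractional energy loss per
    # electron step is 15x this value (0.01 -> 0.15)
    elastic_step_fidelity: float = 0.01
    diagnostic_mode: bool = False
    n_batches: int = 10

    def __post_init__(self):
        if self.n_histories < 1:
            raise ConfigurationError("n_histories must be >= 1")
        if self.electron_cutoff_keV < 1.0 or self.photon_cutoff_keV < 1.0:
            raise ConfigurationError("cutoff energies must be >= 1 keV")
        if self.electron_mode not in _ELECTRON_MODES:
            raise ConfigurationError(
                f"electron_mode must be one of {sorted(_ELECTRON_MODES)}"
            )
        if self.n_batches < 10:
            raise ConfigurationError("per-voxel statistics need >= 10 batches")

    @property
    def de_frac(self) -> float:
        return float(min(max(15.0 * self.elastic_step_fidelity, 0.02), 0.3))


@dataclass
class DoseGrid:
    """Voxelized dose in peak-entrance-dose units with per-voxel uncertainty.

    ``dose[ix, iz]`` is the dose in transverse bin ix (edges ``x_edges_um``,
    1 um inside the beam, geometrically widened outside) and depth bin iz
    (uniform ``z_edges_mm``), normalized so the centermost in-beam entrance
    voxel row averages 1.  ``rel_uncertainty`` is the relative standard error
    from batch statistics.
    """

    x_edges_um: np.ndarray
    z_edges_mm: np.ndarray
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    seed: int
    n_histories: int
    emitted_keV: float
    deposited_keV: float
    escaped_keV: float
    entrance_norm: float
    low_statistics: bool
    phantom: CylinderPhantom
    beam: MicrobeamSpec
    config: TransportConfig

    @property
    def x_centers_um(self) -> np.ndarray:
        return 0.5 * (self.x_edges_um[:-1] + self.x_edges_um[1:])

    @property
    def z_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.z_edges_mm[:-1] + self.z_edges_mm[1:])

    def save_hdf5(self, path, config_hash: str = "") -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("x_edges_um", data=self.x_edges_um)
            fh.create_dataset("z_edges_mm", data=self.z_edges_mm)
            fh.create_dataset("dose", data=self.dose)
            fh.create_dataset("rel_uncertainty", data=self.rel_uncertainty)
            fh.attrs["seed"] = self.seed
            fh.attrs["n_histories"] = self.n_histories
            fh.attrs["emitted_keV"] = self.emitted_keV
            fh.attrs["deposited_keV"] = self.deposited_keV
            fh.attrs["escaped_keV"] = self.escaped_keV
            fh.attrs["entrance_norm"] = self.entrance_norm
            fh.attrs["low_statistics"] = self.low_statistics
            fh.attrs["phantom_radius_cm"] = self.phantom.radius_cm
            fh.attrs["phantom_height_cm"] = self.phantom.height_cm
            fh.attrs["beam_width_um"] = self.beam.width_um
            fh.attrs["beam_height_mm"] = self.beam.height_mm
            fh.attrs["config_hash"] = config_hash

    @classmethod
    def load_hdf5(cls, path) -> "DoseGrid":
        with h5py.File(path, "r") as fh:
            return cls(
                x_edges_um=fh["x_edges_um"][...],
                z_edges_mm=fh["z_edges_mm"][...],
                dose=fh["dose"][...],
                rel_uncertainty=fh["rel_uncertainty"][...],
                seed=int(fh.attrs["seed"]),
                n_histories=int(fh.attrs["n_histories"]),
                emitted_keV=float(fh.attrs["emitted_keV"]),
                deposited_keV=float(fh.attrs["deposited_keV"]),
                escaped_keV=float(fh.attrs["escaped_keV"]),
                entrance_norm=float(fh.attrs["entrance_norm"]),
                low_statistics=bool(fh.attrs["low_statistics"]),
                phantom=CylinderPhantom(
                    float(fh.attrs["phantom_radius_cm"]),
                    float(fh.attrs["phantom_height_cm"]),
                ),
                beam=MicrobeamSpec(
                    float(fh.attrs["beam_width_um"]),
                    float(fh.attrs["beam_height_mm"]),
                ),
                config=TransportConfig(),
            )


# ------------------------------------------------------- cross-section prep --

def water_mu(energy_keV):
    """Linear attenuation coefficient of water, 1/cm (log-log interpolated)."""
    try:
        return xdata.linear_attenuation("H2O", energy_keV)
    except ValueError as exc:
        raise RangeError(str(exc)) from exc


def _water_partials_extended(energies_keV: np.ndarray):
    """Partial mu/rho down to 2 keV (photoelectric extrapolated below the
    lowest table knot as E^-3)."""
    e = np.asarray(energies_keV, dtype=float)
    inc = xdata._incoherent_mu_rho("H2O", e)
    coh = xdata._coherent_mu_rho_water(e)
    pe = np.empty_like(e)
    hi = e >= 10.0
    if np.any(hi):
        pe_hi, _, _, _ = xdata.water_partial_fractions(e[hi])
        pe[hi] = pe_hi
    if np.any(~hi):
        pe10, _, _, _ = xdata.water_partial_fractions(10.0)
        pe[~hi] = pe10 * (10.0 / e[~hi]) ** 3
    return pe, inc, coh


def _xs_tables(rayleigh_enabled: bool):
    e = np.geomspace(2.0, 1000.0, 512)
    pe, inc, coh = _water_partials_extended(e)
    if rayleigh_enabled:
        mu_rho = pe + inc + coh
    else:
        mu_rho = pe + inc
    mu = mu_rho * xdata.DENSITY_G_CM3["H2O"]
    fpe = pe / mu_rho
    finc = inc / mu_rho
    return np.log(e), np.log(mu), fpe, finc


def sample_interaction(energy_keV: float, rng: np.random.Generator,
                       rayleigh_enabled: bool = True) -> str:
    """Sample an interaction type proportional to the partial cross-sections."""
    pe, inc, coh = _water_partials_extended(np.atleast_1d(float(energy_keV)))
    pe, inc, coh = float(pe[0]), float(inc[0]), float(coh[0])
    if not rayleigh_enabled:
        coh = 0.0
    total = pe + inc + coh
    r = rng.random() * total
    if r < pe:
        return "photoelectric"
    if r < pe + inc:
        return "compton"
    return "rayleigh"


def sample_compton(energy_keV: float, rng: np.random.Generator):
    """One Klein-Nishina sample: (scattered keV, polar angle rad, electron keV).

    Rejection sampling of eps = E'/E from the standard composition of 1/eps
    and eps densities; the angle follows from the Compton relation.
    """
    a = energy_keV / xdata.ELECTRON_REST_KEV
    e0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(e0)
    a2 = 0.5 * (1.0 - e0 * e0)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = e0 * np.exp(a1 * rng.random())
        else:
            eps = np.sqrt(e0 * e0 + (1.0 - e0 * e0) * rng.random())
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            cos_theta = 1.0 - t
            e_sc = energy_keV * eps
            return e_sc, float(np.arccos(np.clip(cos_theta, -1.0, 1.0))), \
                energy_keV - e_sc


# ------------------------------------------------------------ electron step --

def transport_electron(energy_keV: float, origin, direction,
                       config: TransportConfig | None = None):
    """Deposit one electron along a straight CSDA track in infinite water.

    Returns (deposits, escaped_keV) where deposits is a list of
    (x_cm, y_cm, z_cm, dE_keV) steps; used as the diagnostic twin of the
    in-grid kernel.  Tracks are always contained (infinite medium), so the
    deposits sum to the initial energy.
    """
    config = config or TransportConfig()
    e_cut = config.electron_cutoff_keV
    de_frac = config.de_frac
    x, y, z = (float(c) for c in origin)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    deposits = []
    e = float(energy_keV)
    if e <= e_cut:
        return [(x, y, z, e)], 0.0
    while e > e_cut:
        de = e * de_frac
        if e - de < e_cut:
            de = e - e_cut * 0.999
        emid = e - 0.5 * de
        sp = xdata.collision_stopping_power(emid)
        ds = (de * 1e-3) / sp  # cm, unit density
        deposits.append((x + 0.5 * ds * u[0], y + 0.5 * ds * u[1],
                         z + 0.5 * ds * u[2], de))
        x += ds * u[0]
        y += ds * u[1]
        z += ds * u[2]
        e -= de
    deposits.append((x, y, z, e))
    return deposits, 0.0


# --------------------------------------------------------------- simulation --

def _build_x_edges(phantom: CylinderPhantom, beam: MicrobeamSpec,
                   core_margin_um: float = 150.0,
                   growth: float = 1.07) -> np.ndarray:
    """Symmetric transverse bin edges: 1 um inside and near the beam,
    geometrically widened out to the phantom radius."""
    core_half = beam.width_um / 2.0 + core_margin_um
    core = np.arange(0.0, core_half + 0.5, 1.0)
    r_um = phantom.radius_cm * 1e4
    edges = [core]
    w = 1.0
    pos = core[-1]
    outer = []
    while pos < r_um:
        w *= growth
        pos = min(pos + w, r_um)
        outer.append(pos)
    edges = np.concatenate([core, np.array(outer)])
    return np.concatenate([-edges[::-1][:-1], edges])


def simulate_single_microbeam(
    phantom: CylinderPhantom,
    beam: MicrobeamSpec,
    spectrum: EnergySpectrum,
    config: TransportConfig,
) -> DoseGrid:
    """Seeded, reproducible single-microbeam dose kernel in the phantom."""
    if beam.width_um / 1e4 / 2.0 >= phantom.radius_cm or \
            beam.height_mm / 10.0 / 2.0 >= phantom.radius_cm:
        raise ConfigurationError("beam does not fit inside the phantom cross-section")

    x_edges_um = _build_x_edges(phantom, beam)
    x_edges_cm = x_edges_um / 1e4
    dz_cm = 0.1
    nz = int(round(phantom.height_cm / dz_cm))
    z_edges_mm = np.arange(nz + 1) * dz_cm * 10.0

    xs_loge, xs_mu, xs_fpe, xs_finc = _xs_tables(config.rayleigh_enabled)
    sp_e = np.geomspace(1.0, 1000.0, 200)
    sp_loge = np.log(sp_e)
    sp_val = xdata.collision_stopping_power(sp_e)

    beam_hw = beam.width_um / 2.0 / 1e4
    beam_hh = beam.height_mm / 2.0 / 10.0
    y_half = 0.8 * beam_hh  # central 80% of the slit height

    nb = config.n_batches
    n_per = [config.n_histories // nb + (1 if i < config.n_histories % nb else 0)
             for i in range(nb)]
    nx = x_edges_um.size - 1
    dose_sum = np.zeros((nx, nz))
    dose_sq = np.zeros((nx, nz))
    emitted = deposited = escaped = 0.0
    widths_cm = np.diff(x_edges_cm)
    voxel_mass_g = widths_cm[:, None] * dz_cm * (2.0 * y_half) * 1.0

    mode = _ELECTRON_MODES[config.electron_mode]
    for b, n in enumerate(n_per):
        if n == 0:
            continue
        batch_seed = (config.seed * 1009 + 7919 * b + 12345) % (2**31 - 1)
        energies = sample_energies(spectrum, n, batch_seed)
        dose_b = np.zeros((nx, nz))
        em, dep, esc = _mc.run_photon_batch(
            energies, batch_seed,
            xs_loge, xs_mu, xs_fpe, xs_finc,
            sp_loge, sp_val,
            phantom.radius_cm, phantom.height_cm, beam_hw, beam_hh, y_half,
            x_edges_cm, dz_cm, nz,
            dose_b,
            config.electron_cutoff_keV, config.photon_cutoff_keV,
            mode, 1 if config.diagnostic_mode else 0, config.de_frac,
        )
        emitted += em
        deposited += dep
        escaped += esc
        dose_b /= voxel_mass_g * n  # keV/g per history
        dose_sum += dose_b
        dose_sq += dose_b**2

    mean = dose_sum / nb
    var = np.maximum(dose_sq / nb - mean**2, 0.0)
    se = np.sqrt(var / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, se / np.where(mean > 0, mean, 1.0), 0.0)

    centers = 0.5 * (x_edges_um[:-1] + x_edges_um[1:])
    central = np.abs(centers) <= 5.0
    norm = float(mean[central, 0].mean())
    norm_rel = float(np.sqrt((se[central, 0] ** 2).sum()) /
                     max(central.sum(), 1) / norm) if norm > 0 else np.inf
    low_stats = not np.isfinite(norm_rel) or norm_rel > 0.5 or norm <= 0

    dose = mean / norm if norm > 0 else mean
    return DoseGrid(
        x_edges_um=x_edges_um,
        z_edges_mm=z_edges_mm,
        dose=dose,
        rel_uncertainty=rel,
        seed=config.seed,
        n_histories=config.n_histories,
        emitted_keV=emitted,
        deposited_keV=deposited,
        escaped_keV=escaped,
        entrance_norm=norm,
        low_statistics=low_stats,
        phantom=phantom,
        beam=beam,
        config=config,
    )
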