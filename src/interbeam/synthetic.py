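"""Synthetic fixtures: analytic microbeam kernels and published-value tables.

The analytic kernel family — a top-hat core convolved with a Gaussian plus
two-sided exponential scatter tails —

    k(x) = 0.5 * [erf((x + w/2)/(sqrt(2) s)) - erf((x - w/2)/(sqrt(2) s))]
           + A * exp(-|x| / L)

admits closed-form values at any position and closed-form (geometric-series)
array sums, which makes it an exact oracle for the superposition, PVDR,
interlacing and planning stages without any Monte Carlo noise.  The fixture
classes carry the published planning-table and rat-dosimetry constants with
their source quotes attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .compose import ArraySpec, LateralProfile
from .errors import ConfigurationError

__all__ = [
    "AnalyticKernel",
    "make_kernel",
    "kernel_with_composite_pvdr",
    "Table1Row",
    "Table1Fixture",
    "RatFixture",
    "make_table1_fixture",
    "make_rat_fixture",
    "make_film_fixture",
]


@dataclass(frozen=True)
class AnalyticKernel:
    """Closed-form single-microbeam lateral kernel (peak value ~1)."""

    core_width_um: float = 50.0
    core_blur_um: float = 0.0
    tail_amplitude: float = 0.01
    tail_scale_um: float = 300.0

    def __post_init__(self):
        if min(self.core_width_um, self.core_blur_um, self.tail_amplitude,
               self.tail_scale_um) < 0:
            raise ConfigurationError("kernel parameters must be non-negative")

    def value(self, x_um):
        """Closed-form kernel value at any position."""
        x = np.asarray(x_um, dtype=float)
        hw = self.core_width_um / 2.0
        if self.core_blur_um > 0:
            s = self.core_blur_um * np.sqrt(2.0)
            core = 0.5 * (erf((x + hw) / s) - erf((x - hw) / s))
        else:
            core = ((x >= -hw) & (x < hw)).astype(float)
        tail = self.tail_amplitude * np.exp(-np.abs(x) / self.tail_scale_um) \
            if self.tail_amplitude > 0 else 0.0
        out = core + tail
        return out if np.ndim(out) else float(out)

    def composite_value(self, x_um: float, array: ArraySpec) -> float:
        """Closed-form composite value: direct sum over beam offsets."""
        return float(sum(self.value(x_um - o)
                         for o in array.beam_offsets_um()))

    def tail_sum_at_midpoint(self, array: ArraySpec) -> float:
        """Closed-form (geometric series) tail sum at the centermost
        midpoint of an even-n array: 2A q^(1/2) (1 - q^m)/(1 - q) with
        q = exp(-spacing/L), m = n/2."""
        if array.n_beams % 2 != 0:
            raise ConfigurationError("midpoint series derived for even n")
        q = np.exp(-array.spacing_um / self.tail_scale_um)
        m = array.n_beams // 2
        return float(2.0 * self.tail_amplitude * np.sqrt(q)
                     * (1.0 - q**m) / (1.0 - q))


def make_kernel(params: AnalyticKernel | None = None,
                extent_um: float = 20000.0,
                step_um: float = 1.0,
                depth_mm: float = 10.0) -> LateralProfile:
    """Evaluate an analytic kernel on the uniform profile grid."""
    k = params or AnalyticKernel()
    n = int(round(extent_um / step_um))
    x = np.arange(-n, n + 1) * step_um
    return LateralProfile(x, k.value(x), depth_mm=depth_mm)


def kernel_with_composite_pvdr(target_pvdr: float, array: ArraySpec,
                               tail_scale_um: float = 500.0) -> AnalyticKernel:
    """Kernel whose composite PVDR equals ``target_pvdr`` exactly (by the
    geometric-series closed form), for sharp-core kernels whose core does not
    reach the valley.

    Solves for the tail amplitude A in peak/valley = target, where
    peak = 1 + T(peak tails) and valley = T(valley tails), both geometric
    sums.
    """
    if array.n_beams % 2 != 0:
        raise ConfigurationError("derivation assumes an even beam count")
    s = array.spacing_um
    L = tail_scale_um
    q = np.exp(-s / L)
    m = array.n_beams // 2
    # valley tails (midpoint, unit amplitude): both sides of the gap
    t_v = 2.0 * np.sqrt(q) * (1.0 - q**m) / (1.0 - q)
    # tails at the centermost beam (offset -s/2 for even n): the beam's own
    # tail (d = 0) plus the neighbours at multiples of the spacing
    offs = (np.arange(array.n_beams) - (array.n_beams - 1) / 2.0) * s
    d = np.abs(offs - offs[m - 1])
    t_p = np.exp(-d / L).sum()
    # (1 + A t_p) / (A t_v) = target  =>  A = 1 / (target t_v - t_p)
    denom = target_pvdr * t_v - t_p
    if denom <= 0:
        raise ConfigurationError("target PVDR unattainable for this geometry")
    return AnalyticKernel(core_width_um=array.width_um, core_blur_um=0.0,
                          tail_amplitude=1.0 / denom, tail_scale_um=L)


# ------------------------------------------------------------- fixtures ----

@dataclass(frozen=True)
class Table1Row:
    """One published planning-table configuration with its printed values."""

    field_label: str
    field_side_mm: float
    spacing_um: float
    n_ports: int
    pvdr_7p5cm: float
    int_ef: float
    inbeam_dose_Gy: float
    valley_dose_7p5cm_Gy: float
    attenuation_factor: float
    entrance_peak_dose_Gy: float
    pvdr_entrance: float
    valley_entrance_Gy: float
    target_dose_Gy: float = 100.0
    source: str = ""


@dataclass(frozen=True)
class Table1Fixture:
    rows: tuple[Table1Row, ...]

    def row(self, field_label: str, spacing_um: float) -> Table1Row:
        for r in self.rows:
            if r.field_label == field_label and r.spacing_um == spacing_um:
                return r
        raise KeyError(f"no fixture row for {field_label} / {spacing_um} um")


_T1_SOURCE = ("published planning table: calculated PVDRs, peak and valley "
              "doses at 7.5 cm depth and at the entrance site, 100 Gy target")

_TABLE1_ROWS = (
    Table1Row("2x2 mm2", 2.0, 200.0, 4, 51.0, 0.14, 88.0, 1.73, 0.30,
              297.0, 71.0, 4.2, source=_T1_SOURCE),
    Table1Row("2x2 mm2", 2.0, 400.0, 8, 197.5, 0.15, 87.0, 0.45, 0.30,
              293.0, 342.0, 0.9, source=_T1_SOURCE),
    Table1Row("1x1 cm2", 10.0, 200.0, 4, 19.7, 0.22, 82.0, 4.16, 0.30,
              273.0, 38.0, 7.1, source=_T1_SOURCE),
    Table1Row("1x1 cm2", 10.0, 400.0, 8, 45.9, 0.23, 81.0, 1.76, 0.30,
              270.0, 118.0, 2.3, source=_T1_SOURCE),
    Table1Row("3x3 cm2", 30.0, 200.0, 4, 7.9, 0.43, 70.0, 8.7, 0.32,
              216.0, 22.0, 9.8, source=_T1_SOURCE),
    Table1Row("3x3 cm2", 30.0, 400.0, 8, 15.9, 0.52, 66.0, 4.1, 0.31,
              210.0, 52.0, 4.0, source=_T1_SOURCE),
)


def make_table1_fixture() -> Table1Fixture:
    """The six published human-head planning configurations."""
    return Table1Fixture(_TABLE1_ROWS)


@dataclass(frozen=True)
class RatFixture:
    """Published rat-head dosimetry constants."""

    entrance_peak_dose_Gy: float = 200.0
    inbeam_dose_1cm_Gy: float = 175.0
    valley_dose_1cm_Gy: float = 3.1
    pvdr_1cm: float = 56.0
    target_dose_Gy: float = 200.0
    n_ports: int = 4
    n_beams: int = 10
    spacing_um: float = 200.0
    interlace_step_um: float = 50.0
    source: str = ("published rat dosimetry: target dose 200 Gy, in-beam "
                   "dose 175 Gy at 1 cm, valley 3.1 Gy, PVDR ~56")


def make_rat_fixture() -> RatFixture:
    return RatFixture()


def make_film_fixture(plan=None, seed: int = 0, noise_sigma: float = 0.0,
                      pitch_um: float = 5.0):
    """Film-like 2-D dose image of an interlaced irradiation, rendered from
    the analytic kernel: outer rows show the spatially fractionated single
    array, the central band the interlaced plateau."""
    from .filmio import render_film
    from .interlace import build_interlaced_profile, \
        build_single_port_profile, rat_plan

    plan = plan or rat_plan()
    kern = make_kernel(AnalyticKernel(core_width_um=plan.array.width_um,
                                      core_blur_um=2.0,
                                      tail_amplitude=0.004,
                                      tail_scale_um=400.0),
                       extent_um=6000.0)
    inter = build_interlaced_profile(kern.scaled(1.0 / 200.0), plan)
    single = build_single_port_profile(kern.scaled(1.0 / 200.0), plan)
    x = inter.positions_um
    n_rows = 240
    target_rows = slice(n_rows // 3, 2 * n_rows // 3)
    dose_map = np.tile(np.interp(x, single.positions_um, single.dose),
                       (n_rows, 1))
    dose_map[target_rows, :] = inter.dose
    return render_film(dose_map, map_pitch_um=inter.step_um,
                       pixel_pitch_um=pitch_um, noise_sigma=noise_sigma,
                       seed=seed)
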