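"""Entrance-dose back-planning for interlaced microbeam configurations.

Given a prescribed uniform target dose D_t at depth, the planning chain is

    in-beam dose at depth   D_ib = D_t / (1 + Int.EF)
    valley dose at depth    D_v  = D_ib / PVDR(depth)
    entrance peak dose      D_e  = D_ib / A        (A = depth attenuation)
    valley dose at entrance D_ve = D_e / PVDR(entrance)

where Int.EF is the interlacement enhancement factor and A the ratio of the
in-beam peak dose at depth to the entrance peak dose.  "table" rounding mode
rounds the in-beam dose to integer Gy before the valley division, which is
the convention the published planning table follows; "exact" keeps full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, RangeError

__all__ = [
    "PlannerInput",
    "PlannerResult",
    "required_inbeam_dose",
    "valley_dose",
    "entrance_peak_dose",
    "plan_configuration",
    "depth_attenuation_factor",
]


@dataclass(frozen=True)
class PlannerInput:
    target_dose_Gy: float
    int_ef: float
    pvdr_depth: float
    pvdr_entrance: float
    attenuation_factor: float
    field_label: str = ""
    spacing_um: float = 200.0
    n_ports: int = 4

    def __post_init__(self):
        if self.target_dose_Gy <= 0:
            raise ConfigurationError("target dose must be positive")
        if self.int_ef < 0:
            raise ConfigurationError("Int.EF must be >= 0")
        if self.pvdr_depth <= 0 or self.pvdr_entrance <= 0:
            raise ConfigurationError("PVDRs must be positive")
        if not (0 < self.attenuation_factor <= 1):
            raise ConfigurationError("attenuation factor must be in (0, 1]")


@dataclass(frozen=True)
class PlannerResult:
    inbeam_dose_at_depth_Gy: float
    valley_dose_at_depth_Gy: float
    entrance_peak_dose_Gy: float
    valley_dose_at_entrance_Gy: float
    rounding_mode: str
    field_label: str = ""


def required_inbeam_dose(target_dose_Gy: float, int_ef: float,
                         rounding_mode: str = "exact") -> float:
    """In-beam dose one array must deliver at depth: target / (1 + Int.EF)."""
    if int_ef < 0:
        raise ConfigurationError("Int.EF must be >= 0")
    _check_mode(rounding_mode)
    d = target_dose_Gy / (1.0 + int_ef)
    return float(round(d)) if rounding_mode == "table" else float(d)


def valley_dose(inbeam_dose_Gy: float, pvdr: float) -> float:
    """Valley dose at the same depth: in-beam dose / PVDR."""
    if pvdr <= 0:
        raise ConfigurationError("PVDR must be positive")
    return float(inbeam_dose_Gy / pvdr)


def entrance_peak_dose(inbeam_dose_Gy: float,
                       attenuation_factor: float) -> float:
    """Entrance peak dose: in-beam dose at depth / depth attenuation."""
    if not (0 < attenuation_factor <= 1):
        raise ConfigurationError("attenuation factor must be in (0, 1]")
    return float(inbeam_dose_Gy / attenuation_factor)


def plan_configuration(inp: PlannerInput,
                       rounding_mode: str = "table") -> PlannerResult:
    """One planning-table row: chain the three planning operations."""
    _check_mode(rounding_mode)
    inb = required_inbeam_dose(inp.target_dose_Gy, inp.int_ef, rounding_mode)
    v_depth = valley_dose(inb, inp.pvdr_depth)
    ent = entrance_peak_dose(inb, inp.attenuation_factor)
    if rounding_mode == "table":
        ent = float(round(ent))
    v_ent = valley_dose(ent, inp.pvdr_entrance)
    return PlannerResult(inb, v_depth, ent, v_ent, rounding_mode,
                         inp.field_label)


def depth_attenuation_factor(grid, depth_cm: float, array=None) -> float:
    """In-beam peak dose at depth / entrance peak dose, from a DoseGrid.

    With ``array`` given, the ratio is taken between composite-array peak
    doses (the centermost beam) at depth and at the entrance, so the scatter
    contributed by neighbouring microbeams is included at both depths.
    """
    from .compose import compute_pvdr, extract_profile, superpose_array

    depth_mm = depth_cm * 10.0
    if depth_mm > grid.z_edges_mm[-1]:
        raise RangeError(
            f"depth {depth_cm} cm beyond phantom "
            f"({grid.z_edges_mm[-1] / 10.0} cm)"
        )
    entrance_mm = float(grid.z_edges_mm[1]) / 2.0
    prof_d = extract_profile(grid, depth_mm)
    prof_0 = extract_profile(grid, entrance_mm)
    if array is None or array.n_beams < 2:
        peak_d = prof_d.window_mean(0.0, 10.0)
        peak_0 = prof_0.window_mean(0.0, 10.0)
    else:
        peak_d = compute_pvdr(superpose_array(prof_d, array), array).peak_dose
        peak_0 = compute_pvdr(superpose_array(prof_0, array), array).peak_dose
    return float(peak_d / peak_0)


def _check_mode(mode: str) -> None:
    if mode not in ("exact", "table"):
        raise ConfigurationError("rounding_mode must be 'exact' or 'table'")
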