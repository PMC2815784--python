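"""Interlaced and intersecting multi-port composition."""

import numpy as np
import pytest

from interbeam import compose as cp
from interbeam import interlace as il
from interbeam import synthetic as syn
from interbeam.errors import ConfigurationError, UnsupportedConfigurationError


def _kernel(extent=15000.0):
    return syn.make_kernel(syn.AnalyticKernel(50.0, 1.0, 0.01, 400.0),
                           extent_um=extent)


def _plan(n_ports=4, n_beams=10, spacing=200.0, dose=200.0):
    array = cp.ArraySpec(n_beams, spacing)
    return il.InterlacePlan(array, il.canonical_ports(n_ports, array, dose))


def test_single_port_equals_superpose_array():
    kern = _kernel()
    plan = _plan(n_ports=1, dose=1.0)
    inter = il.build_interlaced_profile(kern, plan)
    comp = cp.superpose_array(kern, plan.array)
    sel = np.isin(comp.positions_um, inter.positions_um)
    assert np.allclose(inter.dose, comp.dose[sel], rtol=0, atol=1e-12)


def test_interlaced_equals_brute_force_40_term_sum():
    kern = _kernel()
    plan = _plan()
    inter = il.build_interlaced_profile(kern, plan)
    # independent oracle: explicit 40-term loop at sample points
    offsets = []
    for p in range(4):
        for k in range(10):
            offsets.append((k - 4.5) * 200.0 + p * 50.0 - 75.0)
    for x in (-900.0, -125.0, 0.0, 33.0, 444.0, 2111.0):
        expected = 200.0 * sum(
            np.interp(x - o, kern.positions_um, kern.dose) for o in offsets)
        assert inter.value_at(x) == pytest.approx(expected, rel=1e-12)


def test_rat_plan_plateau_near_200Gy_analytic():
    # the tiled core alone gives 200 Gy; tails raise it slightly
    kern = syn.make_kernel(syn.AnalyticKernel(50.0, 0.0, 0.002, 400.0),
                           extent_um=15000.0)
    plan = _plan()
    inter = il.build_interlaced_profile(kern, plan)
    rep = il.target_report(inter, plan)
    assert not rep.no_plateau
    assert rep.mean_target_dose == pytest.approx(200.0, rel=0.05)
    assert rep.plateau_width_mm == pytest.approx(2.0, abs=0.2)


def test_unequal_port_depths_unsupported():
    array = cp.ArraySpec(10, 200.0)
    ports = (il.PortSpec(0, 0, 200.0, 1.0), il.PortSpec(45, 50, 200.0, 2.0))
    plan = il.InterlacePlan(array, ports)
    with pytest.raises(UnsupportedConfigurationError):
        il.build_interlaced_profile(_kernel(), plan)


def test_intersecting_control_peak_and_valley():
    array = cp.ArraySpec(10, 200.0)
    plan = il.InterlacePlan(array, il.canonical_ports(4, array, 200.0),
                            mode="intersecting")
    peak, valley = il.build_intersecting_peak(plan, 175.0, 3.125)
    assert peak == 700.0
    assert valley == 12.5


def test_intersecting_single_port_identity():
    array = cp.ArraySpec(10, 200.0)
    plan = il.InterlacePlan(array, il.canonical_ports(1, array, 200.0),
                            mode="intersecting")
    peak, valley = il.build_intersecting_peak(plan, 175.0, 3.1)
    assert peak == 175.0 and valley == 3.1


def test_mode_mismatch_raises():
    plan = _plan()
    with pytest.raises(ConfigurationError):
        il.build_intersecting_peak(plan, 175.0)


def test_int_ef_zero_for_delta_tails():
    assert il.interlacement_enhancement(100.0, 100.0) == 0.0
    assert il.interlacement_enhancement(1.0, 0.0) is None


def test_int_ef_nonnegative_for_nonnegative_kernel():
    kern = _kernel()
    plan = _plan()
    inter = il.build_interlaced_profile(kern, plan)
    single = il.build_single_port_profile(kern, plan)
    plateau = inter.window_mean(0.0, 100.0)
    inbeam = single.window_mean(-100.0, 10.0)
    ef = il.interlacement_enhancement(plateau, inbeam)
    assert ef >= 0.0


def test_interlaced_linear_outside_plateau():
    # beyond the plateau + one spacing, the composite equals the sum of the
    # individual port array profiles
    kern = _kernel()
    plan = _plan()
    inter = il.build_interlaced_profile(kern, plan)
    ports_sum = None
    beam_offsets = plan.array.beam_offsets_um()
    shifts = np.array([p.lateral_shift_um for p in plan.ports])
    shifts -= shifts.mean()
    for x in (1300.0, 2500.0, 5000.0):
        expected = sum(
            200.0 * np.interp(x - (b + s), kern.positions_um, kern.dose)
            for b in beam_offsets for s in shifts)
        assert inter.value_at(x) == pytest.approx(expected, rel=1e-12)


def test_doubling_entrance_dose_doubles_everything():
    kern = _kernel()
    p1 = il.build_interlaced_profile(kern, _plan(dose=200.0))
    p2 = il.build_interlaced_profile(kern, _plan(dose=400.0))
    assert np.allclose(p2.dose, 2.0 * p1.dose, rtol=1e-12)


def test_no_plateau_for_single_beam_single_port():
    kern = _kernel()
    array = cp.ArraySpec(1, 200.0)
    plan = il.InterlacePlan(array, il.canonical_ports(1, array, 200.0))
    inter = il.build_interlaced_profile(kern, plan)
    rep = il.target_report(inter, plan)
    assert rep.no_plateau


def test_plateau_heterogeneity_matches_brute_scan():
    kern = syn.make_kernel(syn.AnalyticKernel(50.0, 0.0, 0.002, 400.0),
                           extent_um=15000.0)
    plan = _plan()
    inter = il.build_interlaced_profile(kern, plan)
    rep = il.target_report(inter, plan)
    # brute-force oracle on the smoothed profile over the reported plateau
    step = plan.array.spacing_um / plan.n_ports
    n_sm = int(round(step / inter.step_um))
    smooth = np.convolve(inter.dose, np.ones(n_sm) / n_sm, mode="same")
    half_w = rep.plateau_width_mm * 500.0
    mask = np.abs(inter.positions_um) <= half_w
    seg = smooth[mask]
    expected = (seg.max() - seg.min()) / seg.mean()
    assert rep.heterogeneity == pytest.approx(expected, abs=5e-3)


def test_table1_fixture_int_ef_ordering():
    fx = syn.make_table1_fixture()
    efs_200 = [fx.row(lbl, 200.0).int_ef
               for lbl in ("2x2 mm2", "1x1 cm2", "3x3 cm2")]
    assert efs_200 == sorted(efs_200)
    assert efs_200 == [0.14, 0.22, 0.43]
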