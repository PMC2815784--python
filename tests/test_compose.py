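"""Profile extraction, superposition, PVDR and penumbra operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interbeam import compose as cp
from interbeam import synthetic as syn
from interbeam.errors import ConfigurationError, RangeError, TruncationError


def _flat_profile(value=1.0, extent=3000.0):
    x = np.arange(-extent, extent + 1.0)
    return cp.LateralProfile(x, np.full_like(x, value), depth_mm=10.0)


# ---------------------------------------------------------------- extract --

def test_extract_preserves_integral(rat_grid):
    prof = cp.extract_profile(rat_grid, 10.0)
    x_edges = rat_grid.x_edges_um
    iz = 10
    src_integral = float((rat_grid.dose[:, iz] * np.diff(x_edges)).sum())
    lo, hi = prof.positions_um[0] - 0.5, prof.positions_um[-1] + 0.5
    # compare over the common support (the uniform grid clips half-bins)
    cum = np.concatenate([[0.0],
                          np.cumsum(rat_grid.dose[:, iz] * np.diff(x_edges))])
    clipped = np.interp(hi, x_edges, cum) - np.interp(lo, x_edges, cum)
    assert prof.dose.sum() * prof.step_um == pytest.approx(clipped, rel=1e-6)
    assert abs(clipped - src_integral) / src_integral < 1e-3


def test_extract_entrance_reproduces_normalization(rat_grid):
    prof = cp.extract_profile(rat_grid, 0.5)
    assert prof.window_mean(0.0, 10.0) == pytest.approx(1.0, rel=1e-6)


def test_extract_deep_profile_attenuated(human_grid_2mm):
    p0 = cp.extract_profile(human_grid_2mm, 0.5)
    p75 = cp.extract_profile(human_grid_2mm, 75.0)
    assert p75.window_mean(0, 10) < p0.window_mean(0, 10)


def test_extract_outside_phantom_raises(rat_grid):
    with pytest.raises(RangeError):
        cp.extract_profile(rat_grid, 31.0)


# -------------------------------------------------------------- superpose --

def test_superpose_single_beam_is_identity():
    prof = syn.make_kernel(extent_um=4000.0)
    out = cp.superpose_array(prof, cp.ArraySpec(1, 200.0))
    assert out is prof


def _brute_force_sum(profile, offsets):
    """Independent oracle: explicit per-point interpolation sum."""
    x = profile.positions_um
    max_off = max(abs(o) for o in offsets)
    n_out = int(np.floor((profile.extent_um - max_off) / profile.step_um))
    x_out = np.arange(-n_out, n_out + 1) * profile.step_um
    total = np.zeros_like(x_out)
    for i, xo in enumerate(x_out):
        for off in offsets:
            total[i] += np.interp(xo - off, x, profile.dose)
    return x_out, total


def test_superpose_equals_brute_force_on_analytic_kernel():
    kern = syn.make_kernel(syn.AnalyticKernel(50.0, 2.0, 0.02, 300.0),
                           extent_um=4000.0)
    array = cp.ArraySpec(10, 200.0)
    out = cp.superpose_array(kern, array, tail_margin_um=1000.0)
    x_bf, bf = _brute_force_sum(kern, array.beam_offsets_um())
    sel = np.isin(x_bf, out.positions_um)
    assert np.array_equal(out.dose, bf[sel])  # bit-for-bit


@settings(max_examples=20, deadline=None)
@given(st.integers(2, 8), st.sampled_from([150.0, 200.0, 400.0]),
       st.integers(0, 2**31 - 1))
def test_superpose_matches_brute_force_on_random_kernels(n, spacing, seed):
    rng = np.random.default_rng(seed)
    x = np.arange(-4000.0, 4001.0)
    dose = rng.random(x.size)
    prof = cp.LateralProfile(x, dose, depth_mm=10.0)
    array = cp.ArraySpec(n, spacing)
    out = cp.superpose_array(prof, array, tail_margin_um=500.0)
    x_bf, bf = _brute_force_sum(prof, array.beam_offsets_um())
    sel = np.isin(x_bf, out.positions_um)
    assert np.allclose(out.dose, bf[sel], rtol=0, atol=0)


def test_superpose_symmetric_kernel_gives_symmetric_composite():
    kern = syn.make_kernel(syn.AnalyticKernel(50.0, 1.0, 0.01, 400.0),
                           extent_um=5000.0)
    out = cp.superpose_array(kern, cp.ArraySpec(10, 200.0))
    assert np.allclose(out.dose, out.dose[::-1], atol=1e-9 * out.dose.max())


def test_superpose_insufficient_extent_names_requirement():
    prof = syn.make_kernel(extent_um=1500.0)
    with pytest.raises(TruncationError, match="um"):
        cp.superpose_array(prof, cp.ArraySpec(10, 200.0),
                           tail_margin_um=2000.0)


# ------------------------------------------------------------------- PVDR --

def test_pvdr_flat_profile_is_one():
    prof = _flat_profile(2.5)
    res = cp.compute_pvdr(prof, cp.ArraySpec(4, 200.0))
    assert res.pvdr == pytest.approx(1.0, rel=1e-12)


def test_pvdr_delta_kernel_undefined():
    x = np.arange(-3000.0, 3001.0)
    dose = np.zeros_like(x)
    dose[x == 0] = 100.0
    prof = cp.LateralProfile(x, dose, depth_mm=0.0)
    array = cp.ArraySpec(10, 200.0)
    comp = cp.superpose_array(prof, array, tail_margin_um=500.0)
    assert (comp.dose > 0).sum() == 10  # ten spikes
    res = cp.compute_pvdr(comp, array)
    assert res.undefined and np.isinf(res.pvdr)


def test_pvdr_closed_form_construction():
    # peak 100x valley by construction of the analytic kernel
    array = cp.ArraySpec(10, 200.0)
    kern_params = syn.kernel_with_composite_pvdr(50.0, array)
    kern = syn.make_kernel(kern_params, extent_um=15000.0)
    comp = cp.superpose_array(kern, array, tail_margin_um=2000.0)
    res = cp.compute_pvdr(comp, array)
    assert res.pvdr == pytest.approx(50.0, rel=2e-3)
    assert res.peak_position_um == -100.0  # even n ties to negative side
    assert res.valley_position_um == 0.0


def test_pvdr_decreases_with_tighter_spacing():
    kern_params = syn.AnalyticKernel(50.0, 0.0, 0.01, 400.0)
    kern = syn.make_kernel(kern_params, extent_um=30000.0)
    pvdrs = []
    for spacing in (100.0, 200.0, 400.0):
        array = cp.ArraySpec(10, spacing)
        comp = cp.superpose_array(kern, array, tail_margin_um=2000.0)
        pvdrs.append(cp.compute_pvdr(comp, array).pvdr)
    assert pvdrs[0] < pvdrs[1] < pvdrs[2]


def test_pvdr_requires_composite():
    with pytest.raises(ConfigurationError):
        cp.compute_pvdr(_flat_profile(), cp.ArraySpec(1, 200.0))


# --------------------------------------------------------------- penumbra --

def _edge_profile(ramp_um):
    """Plateau of 100 ending at x=0, linear ramp to 0 over ramp_um."""
    x = np.arange(-2000.0, 2001.0)
    dose = np.where(x <= 0, 100.0,
                    np.clip(100.0 * (1 - x / max(ramp_um, 1e-9)), 0, None))
    return cp.LateralProfile(x, dose, depth_mm=0.0)


def test_penumbra_linear_ramp():
    prof = _edge_profile(100.0)
    dist, warn = cp.penumbra_90_10(prof, "right")
    assert dist == pytest.approx(80.0, abs=2.5)  # 3 um smoothing allowance
    assert not warn


def test_penumbra_step_profile_is_zero():
    prof = _edge_profile(0.0)
    dist, warn = cp.penumbra_90_10(prof, "right")
    assert dist <= 3.0  # within the smoothing width
    assert not warn


def test_penumbra_left_side_mirrors_right():
    prof = _edge_profile(100.0)
    mirrored = cp.LateralProfile(prof.positions_um, prof.dose[::-1],
                                 depth_mm=0.0)
    d_r, _ = cp.penumbra_90_10(prof, "right")
    d_l, _ = cp.penumbra_90_10(mirrored, "left")
    assert d_l == pytest.approx(d_r, abs=1e-9)


def test_penumbra_nonmonotone_tail_flags_warning():
    x = np.arange(-500.0, 1501.0)
    dose = np.where(x <= 0, 100.0,
                    np.clip(100.0 * (1 - x / 50.0), 0, None))
    dose[(x > 300) & (x < 400)] = 30.0  # recovery above 10% further out
    prof = cp.LateralProfile(x, dose, depth_mm=0.0)
    dist, warn = cp.penumbra_90_10(prof, "right")
    assert warn
    assert dist == pytest.approx(40.0, abs=3.0)  # first-crossing convention


# ---------------------------------------------------------------- file IO --

def test_profile_tsv_round_trip(tmp_path):
    kern = syn.make_kernel(extent_um=500.0)
    path = tmp_path / "p.tsv"
    cp.write_profile_tsv(kern, path, ["hdr"])
    back = cp.read_profile_tsv(path)
    assert back.depth_mm == kern.depth_mm
    assert np.allclose(back.dose, kern.dose, atol=1e-7)
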