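"""Numba kernels for coupled photon-electron transport in a water cylinder.

Geometry: the cylinder axis is z (depth), the beam enters the top face
(z = 0) travelling in +z.  x is the transverse profile direction, y the
microbeam height direction.  Scoring collapses y over a central band of the
beam height (translational symmetry along the slit), in 2-D voxels
(non-uniform x bins, uniform z bins).

All energies are in keV, all lengths in cm inside these kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WATER_RHO = 1.0


@njit(cache=True, inline="always")
def _interp_lin(x, xs, ys):
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    i = np.searchsorted(xs, x) - 1
    f = (x - xs[i]) / (xs[i + 1] - xs[i])
    return ys[i] + f * (ys[i + 1] - ys[i])


@njit(cache=True, inline="always")
def _score(dose, dep_out, x, y, z, e_kev, x_edges, dz, nz, y_half, r2, h):
    """Deposit e_kev at (x, y, z); returns energy deposited inside phantom."""
    if z < 0.0 or z > h or x * x + y * y > r2:
        return 0.0
    dep_out[0] += e_kev
    if abs(y) > y_half:
        return e_kev
    if x < x_edges[0] or x >= x_edges[x_edges.shape[0] - 1]:
        return e_kev
    iz = int(z / dz)
    if iz >= nz:
        iz = nz - 1
    ix = np.searchsorted(x_edges, x) - 1
    dose[ix, iz] += e_kev
    return e_kev


@njit(cache=True)
def _electron(t0, x, y, z, u, v, w, mode, e_cut, de_frac, sp_e, sp_val,
              dose, dep_out, x_edges, dz, nz, y_half, r2, h):
    """Transport one electron, returning the energy that escaped the phantom.

    The initial direction (u, v, w) is the kinematic emission direction.
    mode 0: deposit locally. mode 1: straight-line CSDA kernel. mode 2:
    condensed history with Gaussian multiple-scattering deflections
    (Highland) per step.
    """
    if t0 <= 0.0:
        return 0.0
    if mode == 0 or t0 <= e_cut:
        dep = _score(dose, dep_out, x, y, z, t0, x_edges, dz, nz, y_half, r2, h)
        return t0 - dep
    e = t0
    escaped = 0.0
    while e > e_cut:
        de = e * de_frac
        if e - de < e_cut:
            de = e - e_cut * 0.999
        emid = e - 0.5 * de
        sp = _interp_lin(np.log(emid), sp_e, sp_val)  # MeV cm2/g, log-E grid
        ds = (de * 1e-3) / (sp * WATER_RHO)
        xm = x + 0.5 * ds * u
        ym = y + 0.5 * ds * v
        zm = z + 0.5 * ds * w
        dep = _score(dose, dep_out, xm, ym, zm, de, x_edges, dz, nz,
                     y_half, r2, h)
        escaped += de - dep
        x += ds * u
        y += ds * v
        z += ds * w
        e -= de
        if mode == 2:
            # Highland multiple-scattering angle over the step
            tau = emid / 510.99895
            pbeta = 0.51099895 * tau * (tau + 2.0) / (tau + 1.0)  # p*beta, MeV
            th0 = 13.6e-3 / pbeta * np.sqrt(ds * WATER_RHO / 36.08)
            tht = th0 * np.random.normal()
            cph = 2.0 * np.pi * np.random.random()
            ct = np.cos(tht)
            st = np.sin(tht)
            if abs(w) < 0.99999:
                sq = np.sqrt(1.0 - w * w)
                un = u * ct + st * (u * w * np.cos(cph) - v * np.sin(cph)) / sq
                vn = v * ct + st * (v * w * np.cos(cph) + u * np.sin(cph)) / sq
                wn = w * ct - sq * st * np.cos(cph)
            else:
                un = st * np.cos(cph)
                vn = st * np.sin(cph)
                wn = ct if w > 0 else -ct
            u, v, wv = un, vn, wn
            w = wv
    # residual below cutoff deposited locally
    dep = _score(dose, dep_out, x, y, z, e, x_edges, dz, nz, y_half, r2, h)
    escaped += e - dep
    return escaped


@njit(cache=True, inline="always")
def _rotate(u, v, w, ct, phi):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cph = np.cos(phi)
    sph = np.sin(phi)
    if abs(w) < 0.99999:
        sq = np.sqrt(1.0 - w * w)
        un = u * ct + st * (u * w * cph - v * sph) / sq
        vn = v * ct + st * (v * w * cph + u * sph) / sq
        wn = w * ct - sq * st * cph
    else:
        un = st * cph
        vn = st * sph
        wn = ct if w > 0.0 else -ct
    return un, vn, wn


@njit(cache=True, inline="always")
def _sample_compton_eps(e_kev):
    """Sample eps = E'/E from the Klein-Nishina DCS (EGS-style rejection)."""
    a = e_kev / 510.99895
    e0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(e0)
    a2 = 0.5 * (1.0 - e0 * e0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = e0 * np.exp(a1 * np.random.random())
        else:
            eps = np.sqrt(e0 * e0 + (1.0 - e0 * e0) * np.random.random())
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps, 1.0 - t


@njit(cache=True)
def run_photon_batch(
    energies,            # sampled source energies, keV
    seed,
    # cross-section tables on log-energy grid
    xs_loge, xs_mu, xs_fpe, xs_finc,   # mu (1/cm), cumulative type fractions
    # electron stopping power on log-energy grid
    sp_loge, sp_val,
    # geometry
    radius, height, beam_hw, beam_hh, y_half,
    # scoring
    x_edges, dz, nz,
    dose,                # (nx, nz) accumulator, keV
    # config
    e_cut, ph_cut, electron_mode, diag_mode, de_frac,
):
    """Transport one batch; returns (emitted, deposited, escaped) in keV."""
    np.random.seed(seed)
    r2 = radius * radius
    emitted = 0.0
    escaped = 0.0
    dep_out = np.zeros(1)
    n = energies.shape[0]
    for i in range(n):
        e = energies[i]
        emitted += e
        x = beam_hw * (2.0 * np.random.random() - 1.0)
        y = beam_hh * (2.0 * np.random.random() - 1.0)
        z = 0.0
        if diag_mode == 1:
            # expected-value estimator: absorb on first collision along the ray
            mu = np.exp(_interp_lin(np.log(e), xs_loge, xs_mu))
            ix = np.searchsorted(x_edges, x) - 1
            inband = (abs(y) <= y_half and x >= x_edges[0]
                      and x < x_edges[x_edges.shape[0] - 1])
            prev = 1.0
            for iz in range(nz):
                att = np.exp(-mu * (iz + 1) * dz)
                d = e * (prev - att)
                dep_out[0] += d
                if inband:
                    dose[ix, iz] += d
                prev = att
            escaped += e * prev
            continue
        u = 0.0
        v = 0.0
        w = 1.0
        alive = True
        while alive:
            if e < ph_cut or e < 2.0:
                dep = _score(dose, dep_out, x, y, z, e, x_edges, dz, nz,
                             y_half, r2, height)
                escaped += e - dep
                break
            le = np.log(e)
            mu = np.exp(_interp_lin(le, xs_loge, xs_mu))
            s = -np.log(np.random.random()) / mu
            # distance to exit
            if w > 0.0:
                t_ax = (height - z) / w
            elif w < 0.0:
                t_ax = -z / w
            else:
                t_ax = 1e30
            a_lat = u * u + v * v
            if a_lat > 1e-14:
                b = 2.0 * (x * u + y * v)
                c = x * x + y * y - r2
                disc = b * b - 4.0 * a_lat * c
                t_lat = (-b + np.sqrt(max(disc, 0.0))) / (2.0 * a_lat)
            else:
                t_lat = 1e30
            t_exit = min(t_ax, t_lat)
            if s >= t_exit:
                escaped += e
                break
            x += s * u
            y += s * v
            z += s * w
            fpe = _interp_lin(le, xs_loge, xs_fpe)
            finc = _interp_lin(le, xs_loge, xs_finc)
            r = np.random.random()
            if r < fpe:
                # photoelectric: full photon energy to an electron; the
                # photoelectron direction is taken isotropic (rare channel)
                ew = 2.0 * np.random.random() - 1.0
                eph = 2.0 * np.pi * np.random.random()
                es = np.sqrt(max(0.0, 1.0 - ew * ew))
                escaped += _electron(e, x, y, z, es * np.cos(eph),
                                     es * np.sin(eph), ew, electron_mode,
                                     e_cut, de_frac, sp_loge, sp_val,
                                     dose, dep_out,
                                     x_edges, dz, nz, y_half, r2, height)
                break
            elif r < fpe + finc:
                eps, ct = _sample_compton_eps(e)
                t_e = e * (1.0 - eps)
                u0, v0, w0 = u, v, w
                u, v, w = _rotate(u, v, w, ct, 2.0 * np.pi * np.random.random())
                # electron direction from momentum conservation
                pu = e * u0 - e * eps * u
                pv = e * v0 - e * eps * v
                pw = e * w0 - e * eps * w
                pn = np.sqrt(pu * pu + pv * pv + pw * pw)
                if pn > 0.0 and t_e > 0.0:
                    escaped += _electron(t_e, x, y, z, pu / pn, pv / pn,
                                         pw / pn, electron_mode, e_cut,
                                         de_frac, sp_loge, sp_val,
                                         dose, dep_out,
                                         x_edges, dz, nz, y_half, r2, height)
                e = e * eps
            else:
                # coherent: no energy loss; forward-peaked deflection with a
                # form-factor-like characteristic angle ~ 4 deg at 100 keV,
                # scaling as 1/E (Rayleigh-distributed polar angle)
                th_c = 0.07 * (100.0 / e)
                tht = th_c * np.sqrt(-2.0 * np.log(np.random.random()))
                if tht > np.pi:
                    tht = np.pi
                u, v, w = _rotate(u, v, w, np.cos(tht),
                                  2.0 * np.pi * np.random.random())
    return emitted, dep_out[0], escaped
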