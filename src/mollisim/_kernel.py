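"""Numba-compiled inner loops for discrete-event Bloch propagation.

The propagation convention mirrors :func:`mollisim.bloch.step` exactly:
per event, rotate about the effective field through -|omega|*dt (left-handed
precession, dM/dt = gamma M x B), then apply relaxation; crusher events are
instantaneous projections of the transverse plane to zero.
"""

import numpy as np
from numba import njit, prange

# Gyromagnetic ratio of 1H, rad / s / T.
GAMMA = 2.0 * np.pi * 42.577478518e6

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=False)
def propagate_spin(dur_s, rf_amp_uT, rf_phase, grad_mT_m, is_crusher, adc_index,
                   z_m, t1_s, t2_s, off_hz, m0, out_re, out_im):
    """Propagate one isochromat through the event arrays.

    Complex transverse samples are *added* into ``out_re/out_im`` at every
    ADC-flagged event (sampled at the end of that event), so callers can
    accumulate an ensemble in place.  Returns -1 on success or the index of
    the first event at which a non-finite magnetization was produced.
    """
    mx = 0.0
    my = 0.0
    mz = m0
    n = dur_s.shape[0]
    for i in range(n):
        if is_crusher[i]:
            mx = 0.0
            my = 0.0
        else:
            dt = dur_s[i]
            wx = 0.0
            wy = 0.0
            amp = rf_amp_uT[i]
            if amp != 0.0:
                b1 = amp * 1e-6
                ph = rf_phase[i]
                wx = GAMMA * b1 * np.cos(ph)
                wy = GAMMA * b1 * np.sin(ph)
            wz = GAMMA * grad_mT_m[i] * 1e-3 * z_m + TWO_PI * off_hz
            w2 = wx * wx + wy * wy + wz * wz
            if w2 > 0.0:
                w = np.sqrt(w2)
                ux = wx / w
                uy = wy / w
                uz = wz / w
                # rotation by phi = -w*dt about u (Rodrigues)
                phi = -w * dt
                c = np.cos(phi)
                s = np.sin(phi)
                dot = ux * mx + uy * my + uz * mz
                cx = uy * mz - uz * my
                cy = uz * mx - ux * mz
                cz = ux * my - uy * mx
                k = dot * (1.0 - c)
                nmx = mx * c + cx * s + ux * k
                nmy = my * c + cy * s + uy * k
                nmz = mz * c + cz * s + uz * k
                mx = nmx
                my = nmy
                mz = nmz
            if dt > 0.0:
                e2 = np.exp(-dt / t2_s)
                e1 = np.exp(-dt / t1_s)
                mx *= e2
                my *= e2
                mz = m0 + (mz - m0) * e1
        if not (np.isfinite(mx) and np.isfinite(my) and np.isfinite(mz)):
            return i
        j = adc_index[i]
        if j >= 0:
            out_re[j] += mx
            out_im[j] += my
    return -1


@njit(cache=True)
def propagate_ensemble(dur_s, rf_amp_uT, rf_phase, grad_mT_m, is_crusher,
                       adc_index, z_m, t1_s, t2_s, off_hz, m0, n_images):
    """Sum of complex per-spin signals for a heterogeneous ensemble."""
    out_re = np.zeros(n_images)
    out_im = np.zeros(n_images)
    for k in range(z_m.shape[0]):
        status = propagate_spin(dur_s, rf_amp_uT, rf_phase, grad_mT_m,
                                is_crusher, adc_index, z_m[k], t1_s[k],
                                t2_s[k], off_hz[k], m0[k], out_re, out_im)
        if status >= 0:
            return out_re, out_im, status
    return out_re, out_im, -1


@njit(cache=True, parallel=True)
def propagate_grid(dur_s, rf_amp_uT, rf_phase, grad_mT_m, is_crusher,
                   adc_index, z_m, t1_grid_s, t2_grid_s, n_images):
    """Slice-profile ensemble magnitude per image for every (T1,T2) entry.

    Entries are independent, so the parallel schedule cannot change the
    result: each row of the output is written by exactly one entry.
    """
    n_entries = t1_grid_s.shape[0]
    n_spins = z_m.shape[0]
    out = np.zeros((n_entries, n_images))
    status = np.full(n_entries, -1, dtype=np.int64)
    for e in prange(n_entries):
        sig_re = np.zeros(n_images)
        sig_im = np.zeros(n_images)
        t1 = t1_grid_s[e]
        t2 = t2_grid_s[e]
        for k in range(n_spins):
            st = propagate_spin(dur_s, rf_amp_uT, rf_phase, grad_mT_m,
                                is_crusher, adc_index, z_m[k], t1, t2,
                                0.0, 1.0, sig_re, sig_im)
            if st >= 0:
                status[e] = st
        for j in range(n_images):
            out[e, j] = np.sqrt(sig_re[j] * sig_re[j] + sig_im[j] * sig_im[j])
    return out, status
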