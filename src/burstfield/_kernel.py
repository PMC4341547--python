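"""Fused compiled forward-Euler stepper.

This is the production inner loop: a numba-compiled chunk advance that
performs the identical operations to the plain-numpy reference in
``field_dynamics.euler_step`` (regression-tested against it), fused per
grid point to keep the working set in cache.  One call advances all fields
by a chunk of substeps lying within a single noise-knot interval;
per-substep anesthetic scalars (rate constants and PSP gains, which change
during concentration ramps) are precomputed by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["advance_chunk"]


@njit(cache=True, fastmath=True)
def advance_chunk(he, hi, I, J, phi, phi_prev, phi_new, Ce, Ci,
                  fe, fi, k0, k1, k2, k3, wts,
                  gam, gtil, gain, rec_slot, rec_he, rec_ce,
                  dt, dx, tau_e, tau_i, hr_e, hr_i,
                  heq, psid, Nb, Na, p_ee_mean, p_ei,
                  smax_e, smax_i, mu_e, mu_i, qse, qsi,
                  S0e, S0i, trec_e, trec_i,
                  lam, vel, phi_ix_ee, phi_ix_ei, freeze_C,
                  Se_buf, Si_buf, src_buf):
    """Advance the full state by wts.shape[0] forward-Euler substeps.

    Field layout: I/J are (4, ny, nx) in class order (ee, ei, ie, ii);
    phi is (nphi, ny, nx).  heq/psid/Nb are per-class; psid holds the
    precomputed 1/|h_eq - h_r| weights.  qse/qsi are sigmoid_slope/sigma.
    Recording slots copy h_e and C_e (float32) before applying a substep.
    Returns 0, or 1 if a non-finite membrane potential appeared.
    """
    ny, nx = he.shape
    nsub = wts.shape[0]
    nphi = phi.shape[0]
    inv_dx2 = 1.0 / (dx * dx)

    for s in range(nsub):
        slot = rec_slot[s]
        if slot >= 0:
            for j in range(ny):
                for i in range(nx):
                    rec_he[slot, j, i] = np.float32(he[j, i])
                    rec_ce[slot, j, i] = np.float32(Ce[j, i])

        w0 = wts[s, 0]
        w1 = wts[s, 1]
        w2 = wts[s, 2]
        w3 = wts[s, 3]
        g_ee = gam[s, 0]; g_ei = gam[s, 1]; g_ie = gam[s, 2]; g_ii = gam[s, 3]
        gt_ee = gtil[s, 0]; gt_ei = gtil[s, 1]; gt_ie = gtil[s, 2]; gt_ii = gtil[s, 3]
        ga_ee = gain[s, 0]; ga_ei = gain[s, 1]; ga_ie = gain[s, 2]; ga_ii = gain[s, 3]

        # firing rates and depletion-scaled local source (time level t)
        for j in range(ny):
            for i in range(nx):
                Se_buf[j, i] = smax_e / (1.0 + np.exp(-qse * (he[j, i] - mu_e)))
                Si_buf[j, i] = smax_i / (1.0 + np.exp(-qsi * (hi[j, i] - mu_i)))
                src_buf[j, i] = Ce[j, i] * Se_buf[j, i]

        # local (pointwise) updates, all RHS at time level t
        for j in range(ny):
            for i in range(nx):
                Se = Se_buf[j, i]
                Si = Si_buf[j, i]
                src = src_buf[j, i]
                p_ee = p_ee_mean + (w0 * k0[j, i] + w1 * k1[j, i]
                                    + w2 * k2[j, i] + w3 * k3[j, i])
                A_ee = Nb[0] * src + Na[0] * phi[phi_ix_ee, j, i] + p_ee
                A_ei = Nb[1] * src + Na[1] * phi[phi_ix_ei, j, i] + p_ei
                loc_i = Ci[j, i] * Si
                A_ie = Nb[2] * loc_i
                A_ii = Nb[3] * loc_i

                I_ee = I[0, j, i]; I_ei = I[1, j, i]
                I_ie = I[2, j, i]; I_ii = I[3, j, i]

                h = he[j, i]
                dhe = (hr_e - h + (heq[0] - h) * psid[0] * I_ee
                       + (heq[2] - h) * psid[2] * I_ie) / tau_e
                h = hi[j, i]
                dhi = (hr_i - h + (heq[1] - h) * psid[1] * I_ei
                       + (heq[3] - h) * psid[3] * I_ii) / tau_i

                I[0, j, i] = I_ee + dt * gt_ee * (J[0, j, i] - I_ee)
                I[1, j, i] = I_ei + dt * gt_ei * (J[1, j, i] - I_ei)
                I[2, j, i] = I_ie + dt * gt_ie * (J[2, j, i] - I_ie)
                I[3, j, i] = I_ii + dt * gt_ii * (J[3, j, i] - I_ii)
                J[0, j, i] += dt * g_ee * (ga_ee * A_ee - J[0, j, i])
                J[1, j, i] += dt * g_ei * (ga_ei * A_ei - J[1, j, i])
                J[2, j, i] += dt * g_ie * (ga_ie * A_ie - J[2, j, i])
                J[3, j, i] += dt * g_ii * (ga_ii * A_ii - J[3, j, i])

                he[j, i] += dt * dhe
                hi[j, i] += dt * dhi

                if not freeze_C:
                    Ce[j, i] += dt * (1.0 + fe[j, i]
                                      - (1.0 + (Se / S0e) * fe[j, i]) * Ce[j, i]) / trec_e
                    Ci[j, i] += dt * (1.0 + fi[j, i]
                                      - (1.0 + (Si / S0i) * fi[j, i]) * Ci[j, i]) / trec_i

        # damped-wave flux: three-level scheme, periodic five-point stencil
        for f in range(nphi):
            lam2 = lam[f] * lam[f]
            a = 1.0 / (vel[f] * dt) ** 2
            b = 1.0 / (vel[f] * lam[f] * dt)
            inv_ab = 1.0 / (a + b)
            for j in range(ny):
                jm = j - 1 if j > 0 else ny - 1
                jp = j + 1 if j < ny - 1 else 0
                for i in range(nx):
                    im = i - 1 if i > 0 else nx - 1
                    ip = i + 1 if i < nx - 1 else 0
                    lap = (phi[f, jm, i] + phi[f, jp, i] + phi[f, j, im]
                           + phi[f, j, ip] - 4.0 * phi[f, j, i]) * inv_dx2
                    phi_new[f, j, i] = (src_buf[j, i] / lam2 + lap
                                        - phi[f, j, i] / lam2
                                        + 2.0 * a * phi[f, j, i]
                                        - a * phi_prev[f, j, i]
                                        + b * phi_prev[f, j, i]) * inv_ab
            for j in range(ny):
                for i in range(nx):
                    phi_prev[f, j, i] = phi[f, j, i]
                    phi[f, j, i] = phi_new[f, j, i]

    # cheap divergence probe (full check done by the driver per chunk)
    bad = 0
    for j in range(ny):
        for i in range(nx):
            if not (np.isfinite(he[j, i]) and np.isfinite(hi[j, i])):
                bad = 1
    return bad
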