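"""Compiled Euler marching kernel for the mock circulation.

The kernel is deliberately a single flat loop mirroring the readable
reference implementation in :func:`aortasv.simulator.step`; a test
cross-checks the two.  Status codes: 0 ok, 1 bad aortic segment,
2 bad pump, 3 bad venous reservoir (index of the offending compartment
is returned alongside).
"""

import numpy as np
from numba import njit

from .params import MMHG_CGS


@njit(cache=False)
def march(n_steps, dt, omega, p_max,
          r_i, r_o, r_junc, up, down, r_s,
          c_seg, c_v, c_p, seg_len, rho,
          fung, p_ref, p_init,
          seg_vol0, pump_vol0, ven_vol0,
          sample_ks, rec_t0, rec_t1):
    nseg = 10
    njunc = r_junc.shape[0]

    seg_vol = seg_vol0.copy()
    seg_p = np.full(nseg, p_init)
    pump_vol = pump_vol0
    pump_p = p_init
    ven_vol = ven_vol0
    ven_p = p_init
    iflow = np.zeros(njunc)
    dv_seg = np.zeros(nseg)

    n_samp = sample_ks.shape[0]
    out_t = np.empty(n_samp)
    out_p = np.empty((n_samp, nseg))
    out_r = np.empty((n_samp, nseg))
    out_q = np.empty(n_samp)
    out_pp = np.empty(n_samp)
    out_pv = np.empty(n_samp)

    outflow_int = 0.0
    total0 = pump_vol + ven_vol + seg_vol.sum()
    drift = 0.0
    si = 0
    status = 0
    bad = -1

    for k in range(n_steps + 1):
        t = k * dt

        # valve flows (one-way)
        q_in = (ven_p - pump_p) / r_i
        if q_in < 0.0:
            q_in = 0.0
        q_out = (pump_p - seg_p[0]) / r_o
        if q_out < 0.0:
            q_out = 0.0

        if si < n_samp and k == sample_ks[si]:
            out_t[si] = t
            for m in range(nseg):
                out_p[si, m] = seg_p[m]
                out_r[si, m] = np.sqrt(seg_vol[m] / (np.pi * seg_len))
            out_q[si] = q_out
            out_pp[si] = pump_p
            out_pv[si] = ven_p
            si += 1

        if k == n_steps:
            break

        # inline aortic flows: implicit inertial update through each junction
        for j in range(njunc):
            area = seg_vol[up[j]] / seg_len
            L = rho * seg_len / area / MMHG_CGS
            dp = seg_p[up[j]] - seg_p[down[j]]
            iflow[j] = (dp * dt + L * iflow[j]) / (r_junc[j] * dt + L)

        # flow balances
        for m in range(nseg):
            dv_seg[m] = 0.0
        dv_seg[0] += q_out
        runoff_sum = 0.0
        for m in range(1, nseg):
            qs = (seg_p[m] - ven_p) / r_s
            dv_seg[m] -= qs
            runoff_sum += qs
        for j in range(njunc):
            dv_seg[up[j]] -= iflow[j]
            dv_seg[down[j]] += iflow[j]
        dv_pump = q_in - q_out
        dv_ven = runoff_sum - q_in

        # external squeezing pressure rate (half-sinusoid drive)
        if np.sin(omega * t) > 0.0:
            pext_rate = p_max * omega * np.cos(omega * t)
        else:
            pext_rate = 0.0

        # pressure and volume updates
        for m in range(nseg):
            c = c_seg[m]
            if fung:
                c = 2.0 * c * p_ref / (seg_p[m] + p_ref)
            seg_p[m] += dv_seg[m] * dt / c
            seg_vol[m] += dv_seg[m] * dt
        pump_p += dv_pump * dt / c_p + pext_rate * dt
        pump_vol += dv_pump * dt
        ven_p += dv_ven * dt / c_v
        ven_vol += dv_ven * dt

        if rec_t0 - 0.5 * dt <= t < rec_t1 - 0.5 * dt:
            outflow_int += q_out * dt

        if k % 1000 == 0 or k == n_steps - 1:
            tot = pump_vol + ven_vol + seg_vol.sum()
            d = abs(tot - total0) / total0
            if d > drift:
                drift = d
            # aortic segments must keep positive volume (radius = sqrt(V/..));
            # the pump may transiently over-eject on a cold start, so only
            # non-finite pump/venous states abort.
            for m in range(nseg):
                if not np.isfinite(seg_p[m]) or seg_vol[m] <= 0.0:
                    status = 1
                    bad = m
            if not np.isfinite(pump_p):
                status = 2
                bad = 10
            if not np.isfinite(ven_p):
                status = 3
                bad = 11
            if status != 0:
                break

    return out_t, out_p, out_r, out_q, out_pp, out_pv, outflow_int, drift, status, bad
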