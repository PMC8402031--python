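"""Numba-accelerated inner solver for the conditional (empirical-Bayes) modes.

This mirrors the vectorised numpy implementation in :mod:`cipropk.population`
subject for subject: a damped Newton iteration with Gauss-Newton curvature on
the conditional objective

    l_i(eta) = sum_j [ ln g_ij^2 + (y_ij - f_ij)^2 / g_ij^2 ] + eta' Omega^-1 eta

with analytic derivatives of the closed-form infusion model with respect to
the log-scale random effects.  An equivalence test keeps the two paths honest;
when numba is unavailable the numpy path is used transparently.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _subject_f_s(p0, p1, d_start, d_amt, d_dur, obs_t, eta1, eta2, tv_cl, tv_vd,
                 f_out, s_out):
    """f and S = df/dke for the observations of one subject at (eta1, eta2)."""
    for j in range(p0, p1):
        cl = tv_cl[j] * np.exp(eta1)
        vd = tv_vd[j] * np.exp(eta2)
        ke = cl / vd
        fj = 0.0
        sj = 0.0
        for k in range(d_start.shape[1]):
            amt = d_amt[j, k]
            if amt <= 0.0:
                continue
            tau = obs_t[j] - d_start[j, k]
            if tau <= 0.0:
                continue
            dur = d_dur[j, k]
            tin = tau if tau < dur else dur
            dec = tau - dur if tau > dur else 0.0
            e_inf = np.exp(-ke * tin)
            e_dec = np.exp(-ke * dec)
            base = (amt / dur) / cl
            fj += base * (1.0 - e_inf) * e_dec
            sj += base * e_dec * (tin * e_inf - dec * (1.0 - e_inf))
        f_out[j] = fj
        s_out[j] = sj


@njit(cache=False)
def _subject_obj(p0, p1, d_start, d_amt, d_dur, obs_t, y, eta1, eta2,
                 tv_cl, tv_vd, sa2, sp2, iw1, iw2):
    """Conditional objective of one subject at (eta1, eta2)."""
    obj = eta1 * eta1 * iw1 + eta2 * eta2 * iw2
    for j in range(p0, p1):
        cl = tv_cl[j] * np.exp(eta1)
        vd = tv_vd[j] * np.exp(eta2)
        ke = cl / vd
        fj = 0.0
        for k in range(d_start.shape[1]):
            amt = d_amt[j, k]
            if amt <= 0.0:
                continue
            tau = obs_t[j] - d_start[j, k]
            if tau <= 0.0:
                continue
            dur = d_dur[j, k]
            tin = tau if tau < dur else dur
            dec = tau - dur if tau > dur else 0.0
            fj += (amt / dur) / cl * (1.0 - np.exp(-ke * tin)) * np.exp(-ke * dec)
        g2 = sa2 + sp2 * fj * fj
        if g2 < 1e-12:
            g2 = 1e-12
        r = y[j] - fj
        obj += np.log(g2) + r * r / g2
    return obj


@njit(cache=False)
def solve_inner_fast(subj_ptr, d_start, d_amt, d_dur, obs_t, y,
                     tv_cl, tv_vd, omega_cl, omega_vd, sa, sp, eta,
                     max_iter, gtol, omega_floor):
    """Per-subject damped Newton for the conditional modes.

    ``eta`` (n_subj, 2) is updated in place; returns (li, logdet) arrays with
    the conditional objective and ln det(Omega * H / 2) at the modes.
    """
    n_subj = subj_ptr.shape[0] - 1
    wc = omega_cl if omega_cl > omega_floor else omega_floor
    wv = omega_vd if omega_vd > omega_floor else omega_floor
    iw1 = 1.0 / (wc * wc)
    iw2 = 1.0 / (wv * wv)
    sa2 = sa * sa
    sp2 = sp * sp
    n_obs = obs_t.shape[0]
    f = np.empty(n_obs)
    s = np.empty(n_obs)
    li = np.empty(n_subj)
    logdet = np.empty(n_subj)
    log_om = 2.0 * (np.log(wc) + np.log(wv))

    for i in range(n_subj):
        p0 = subj_ptr[i]
        p1 = subj_ptr[i + 1]
        e1 = eta[i, 0]
        e2 = eta[i, 1]
        lcur = _subject_obj(p0, p1, d_start, d_amt, d_dur, obs_t, y, e1, e2,
                            tv_cl, tv_vd, sa2, sp2, iw1, iw2)
        for _ in range(max_iter):
            g1 = 2.0 * e1 * iw1
            g2s = 2.0 * e2 * iw2
            h11 = 2.0 * iw1
            h12 = 0.0
            h22 = 2.0 * iw2
            _subject_f_s(p0, p1, d_start, d_amt, d_dur, obs_t, e1, e2,
                         tv_cl, tv_vd, f, s)
            for j in range(p0, p1):
                cl = tv_cl[j] * np.exp(e1)
                vd = tv_vd[j] * np.exp(e2)
                ke = cl / vd
                j1 = -f[j] + ke * s[j]
                j2 = -ke * s[j]
                g2v = sa2 + sp2 * f[j] * f[j]
                if g2v < 1e-12:
                    g2v = 1e-12
                w = 1.0 / g2v
                r = y[j] - f[j]
                common = 2.0 * sp2 * f[j] * (w - r * r * w * w)
                g1 += common * j1 - 2.0 * r * j1 * w
                g2s += common * j2 - 2.0 * r * j2 * w
                h11 += 2.0 * j1 * j1 * w
                h12 += 2.0 * j1 * j2 * w
                h22 += 2.0 * j2 * j2 * w
            gn = abs(g1)
            if abs(g2s) > gn:
                gn = abs(g2s)
            if gn < gtol:
                break
            det = h11 * h22 - h12 * h12
            if det <= 0.0:
                det = 1e-12
            s1 = (h22 * g1 - h12 * g2s) / det
            s2 = (h11 * g2s - h12 * g1) / det
            smax = abs(s1) if abs(s1) > abs(s2) else abs(s2)
            if smax < 1e-8:
                break
            t = 1.0
            accepted = False
            lnew = lcur
            c1 = e1
            c2 = e2
            for _h in range(10):
                c1 = e1 - t * s1
                c2 = e2 - t * s2
                lc = _subject_obj(p0, p1, d_start, d_amt, d_dur, obs_t, y, c1, c2,
                                  tv_cl, tv_vd, sa2, sp2, iw1, iw2)
                if lc <= lcur + 1e-12:
                    accepted = True
                    lnew = lc
                    break
                t *= 0.5
            if not accepted:
                break
            move = abs(c1 - e1)
            if abs(c2 - e2) > move:
                move = abs(c2 - e2)
            improvement = lcur - lnew
            e1 = c1
            e2 = c2
            lcur = lnew
            if move < 1e-8 or improvement < 1e-9:
                break
        # curvature at the accepted mode
        h11 = 2.0 * iw1
        h12 = 0.0
        h22 = 2.0 * iw2
        _subject_f_s(p0, p1, d_start, d_amt, d_dur, obs_t, e1, e2,
                     tv_cl, tv_vd, f, s)
        for j in range(p0, p1):
            cl = tv_cl[j] * np.exp(e1)
            vd = tv_vd[j] * np.exp(e2)
            ke = cl / vd
            j1 = -f[j] + ke * s[j]
            j2 = -ke * s[j]
            g2v = sa2 + sp2 * f[j] * f[j]
            if g2v < 1e-12:
                g2v = 1e-12
            w = 1.0 / g2v
            h11 += 2.0 * j1 * j1 * w
            h12 += 2.0 * j1 * j2 * w
            h22 += 2.0 * j2 * j2 * w
        det_h = (h11 * h22 - h12 * h12) / 4.0
        if det_h < 1e-300:
            det_h = 1e-300
        eta[i, 0] = e1
        eta[i, 1] = e2
        li[i] = lcur
        logdet[i] = np.log(det_h) + log_om
    return li, logdet
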