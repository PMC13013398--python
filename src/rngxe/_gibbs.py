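"""Numba kernel for the one-step reaction norm Gibbs sampler.

All location parameters (fixed effects, contemporary-group effects, animal
intercept/slope pairs, maternal permanent environment effects) and all
dispersion parameters are updated from their full conditionals in a fixed
order each iteration.  The contemporary-group effect draws serve as the
environmental covariate of the slope inside the same iteration, which is what
makes the model one-step.

The kernel works on flat arrays only: records are pre-grouped by CG, by
animal and by dam in CSR-style (ptr, index) pairs, and the A-inverse is
passed in CSR form.  Everything random comes from numba's np.random state,
seeded once at entry, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_G_NOT_PD = 1


@njit(cache=False)
def _draw_iw2(c00, c01, c11, df):
    """Inverse-Wishart draw of a 2x2 matrix with scale C and df degrees.

    Samples W ~ Wishart(df, C^{-1}) by Bartlett decomposition and returns
    W^{-1} as (g00, g01, g11, ok).
    """
    det = c00 * c11 - c01 * c01
    if det <= 0.0 or c00 <= 0.0:
        return 0.0, 0.0, 0.0, False
    i00 = c11 / det
    i01 = -c01 / det
    i11 = c00 / det
    L00 = np.sqrt(i00)
    L10 = i01 / L00
    arg = i11 - L10 * L10
    if arg <= 0.0:
        return 0.0, 0.0, 0.0, False
    L11 = np.sqrt(arg)
    t00 = np.sqrt(np.random.chisquare(df))
    t11 = np.sqrt(np.random.chisquare(df - 1.0))
    t10 = np.random.standard_normal()
    F00 = L00 * t00
    F10 = L10 * t00 + L11 * t10
    F11 = L11 * t11
    w00 = F00 * F00
    w01 = F00 * F10
    w11 = F10 * F10 + F11 * F11
    dw = w00 * w11 - w01 * w01
    if dw <= 0.0:
        return 0.0, 0.0, 0.0, False
    return w11 / dw, -w01 / dw, w00 / dw, True


@njit(cache=False)
def _update_beta(X, XtX, Lt, e, beta, s2e):
    p = beta.shape[0]
    rhs = X.T @ e + XtX @ beta
    mean = np.linalg.solve(XtX, rhs)
    z = np.random.standard_normal(p)
    noise = np.linalg.solve(Lt, z) * np.sqrt(s2e)
    new = mean + noise
    delta = new - beta
    n = X.shape[0]
    for m in range(n):
        acc = 0.0
        for k in range(p):
            acc += X[m, k] * delta[k]
        e[m] -= acc
    for k in range(p):
        beta[k] = new[k]


@njit(cache=False)
def _update_cg(e, lcg, b, rec_an, cg_ptr, cg_rec, s2e, s2cg, freeze):
    ncg = cg_ptr.shape[0] - 1
    for j in range(ncg):
        old = lcg[j]
        sw = 0.0
        swr = 0.0
        for m in range(cg_ptr[j], cg_ptr[j + 1]):
            rec = cg_rec[m]
            w = 1.0 if freeze else 1.0 + b[rec_an[rec]]
            swr += w * (e[rec] + w * old)
            sw += w * w
        prec = sw / s2e + 1.0 / s2cg
        mean = (swr / s2e) / prec
        new = mean + np.random.standard_normal() / np.sqrt(prec)
        for m in range(cg_ptr[j], cg_ptr[j + 1]):
            rec = cg_rec[m]
            w = 1.0 if freeze else 1.0 + b[rec_an[rec]]
            e[rec] -= w * (new - old)
        lcg[j] = new


@njit(cache=False)
def _update_ab(
    e, a, b, lcg, rec_cg, an_ptr, an_rec,
    ai_indptr, ai_indices, ai_data, ai_diag,
    g00, g01, g11, s2e, freeze,
):
    q = ai_diag.shape[0]
    if freeze:
        inv_g = 1.0 / g00
        for i in range(q):
            s0v = 0.0
            for ptr in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[ptr]
                if j != i:
                    s0v += ai_data[ptr] * a[j]
            prec = ai_diag[i] * inv_g
            rhs = -s0v * inv_g
            for m in range(an_ptr[i], an_ptr[i + 1]):
                rec = an_rec[m]
                rhs += (e[rec] + a[i]) / s2e
                prec += 1.0 / s2e
            mean = rhs / prec
            new = mean + np.random.standard_normal() / np.sqrt(prec)
            for m in range(an_ptr[i], an_ptr[i + 1]):
                e[an_rec[m]] -= new - a[i]
            a[i] = new
        return
    det = g00 * g11 - g01 * g01
    gi00 = g11 / det
    gi01 = -g01 / det
    gi11 = g00 / det
    for i in range(q):
        s0v = 0.0
        s1v = 0.0
        for ptr in range(ai_indptr[i], ai_indptr[i + 1]):
            j = ai_indices[ptr]
            if j != i:
                v = ai_data[ptr]
                s0v += v * a[j]
                s1v += v * b[j]
        dii = ai_diag[i]
        C00 = dii * gi00
        C01 = dii * gi01
        C11 = dii * gi11
        r0 = -(gi00 * s0v + gi01 * s1v)
        r1 = -(gi01 * s0v + gi11 * s1v)
        for m in range(an_ptr[i], an_ptr[i + 1]):
            rec = an_rec[m]
            x = lcg[rec_cg[rec]]
            r = e[rec] + a[i] + b[i] * x
            r0 += r / s2e
            r1 += r * x / s2e
            C00 += 1.0 / s2e
            C01 += x / s2e
            C11 += x * x / s2e
        L00 = np.sqrt(C00)
        L10 = C01 / L00
        L11 = np.sqrt(C11 - L10 * L10)
        t0 = r0 / L00
        t1 = (r1 - L10 * t0) / L11
        mu1 = t1 / L11
        mu0 = (t0 - L10 * mu1) / L00
        z0 = np.random.standard_normal()
        z1 = np.random.standard_normal()
        w1 = z1 / L11
        w0 = (z0 - L10 * w1) / L00
        na = mu0 + w0
        nb = mu1 + w1
        da = na - a[i]
        db = nb - b[i]
        for m in range(an_ptr[i], an_ptr[i + 1]):
            rec = an_rec[m]
            e[rec] -= da + db * lcg[rec_cg[rec]]
        a[i] = na
        b[i] = nb


@njit(cache=False)
def _update_pm(e, pm, pm_ptr, pm_rec, s2e, s2pe):
    ndam = pm_ptr.shape[0] - 1
    for j in range(ndam):
        old = pm[j]
        cnt = pm_ptr[j + 1] - pm_ptr[j]
        sr = 0.0
        for m in range(pm_ptr[j], pm_ptr[j + 1]):
            sr += e[pm_rec[m]] + old
        prec = cnt / s2e + 1.0 / s2pe
        mean = (sr / s2e) / prec
        new = mean + np.random.standard_normal() / np.sqrt(prec)
        for m in range(pm_ptr[j], pm_ptr[j + 1]):
            e[pm_rec[m]] -= new - old
        pm[j] = new


@njit(cache=False)
def _recompute_residual(e, y, X, beta, lcg, a, b, pm, rec_an, rec_cg, rec_pm, freeze):
    n = y.shape[0]
    p = beta.shape[0]
    for m in range(n):
        acc = y[m]
        for k in range(p):
            acc -= X[m, k] * beta[k]
        i = rec_an[m]
        w = 1.0 if freeze else 1.0 + b[i]
        acc -= w * lcg[rec_cg[m]] + a[i]
        if rec_pm[m] >= 0:
            acc -= pm[rec_pm[m]]
        e[m] = acc


@njit(cache=False)
def run_chain(
    y, X, rec_an, rec_cg, rec_pm,
    cg_ptr, cg_rec, an_ptr, an_rec, pm_ptr, pm_rec,
    ai_indptr, ai_indices, ai_data, ai_diag,
    beta_init, init_lcg, init_a, init_b, init_pm, init_disp,
    nu_g, s0_g00, s0_g11, s0_g01,
    nu_cg, s0_cg, nu_pe, s0_pe, nu_e, s0_e,
    n_iter, burn_in, thin, seed,
    freeze_slopes, center_cg, alt_order,
    out_beta, out_cg, out_a, out_b, out_pm,
    out_G, out_s2cg, out_s2pe, out_s2e,
):
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    q = ai_diag.shape[0]
    ncg = cg_ptr.shape[0] - 1
    ndam = pm_ptr.shape[0] - 1

    beta = beta_init.copy()
    lcg = init_lcg.copy()
    a = init_a.copy()
    b = init_b.copy()
    pm = init_pm.copy()
    g00 = init_disp[0]
    g11 = 0.0 if freeze_slopes else init_disp[1]
    g01 = 0.0 if freeze_slopes else init_disp[2]
    s2cg = init_disp[3]
    s2pe = init_disp[4]
    s2e = init_disp[5]

    XtX = X.T @ X
    Lt = np.linalg.cholesky(XtX).T.copy()
    e = np.empty(n)
    _recompute_residual(e, y, X, beta, lcg, a, b, pm, rec_an, rec_cg, rec_pm, freeze_slopes)

    for it in range(n_iter):
        if alt_order == 0:
            _update_beta(X, XtX, Lt, e, beta, s2e)
            _update_cg(e, lcg, b, rec_an, cg_ptr, cg_rec, s2e, s2cg, freeze_slopes)
            if center_cg:
                mshift = lcg.sum() / ncg
                for j in range(ncg):
                    lcg[j] -= mshift
                beta[0] += mshift
                if not freeze_slopes:
                    for i in range(q):
                        a[i] += b[i] * mshift
            _update_ab(e, a, b, lcg, rec_cg, an_ptr, an_rec,
                       ai_indptr, ai_indices, ai_data, ai_diag,
                       g00, g01, g11, s2e, freeze_slopes)
            if ndam > 0:
                _update_pm(e, pm, pm_ptr, pm_rec, s2e, s2pe)
        else:
            _update_ab(e, a, b, lcg, rec_cg, an_ptr, an_rec,
                       ai_indptr, ai_indices, ai_data, ai_diag,
                       g00, g01, g11, s2e, freeze_slopes)
            if ndam > 0:
                _update_pm(e, pm, pm_ptr, pm_rec, s2e, s2pe)
            _update_beta(X, XtX, Lt, e, beta, s2e)
            _update_cg(e, lcg, b, rec_an, cg_ptr, cg_rec, s2e, s2cg, freeze_slopes)
            if center_cg:
                mshift = lcg.sum() / ncg
                for j in range(ncg):
                    lcg[j] -= mshift
                beta[0] += mshift
                if not freeze_slopes:
                    for i in range(q):
                        a[i] += b[i] * mshift

        # dispersion parameters
        Saa = 0.0
        Sab = 0.0
        Sbb = 0.0
        for i in range(q):
            ti0 = 0.0
            ti1 = 0.0
            for ptr in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[ptr]
                v = ai_data[ptr]
                ti0 += v * a[j]
                ti1 += v * b[j]
            Saa += a[i] * ti0
            Sab += a[i] * ti1
            Sbb += b[i] * ti1
        if freeze_slopes:
            g00 = (nu_g * s0_g00 + Saa) / np.random.chisquare(nu_g + q)
        else:
            c00 = s0_g00 + Saa
            c01 = s0_g01 + Sab
            c11 = s0_g11 + Sbb
            ng00, ng01, ng11, ok = _draw_iw2(c00, c01, c11, nu_g + q)
            if not ok:
                return STATUS_G_NOT_PD * 1000000 + it
            g00, g01, g11 = ng00, ng01, ng11

        scg = 0.0
        for j in range(ncg):
            scg += lcg[j] * lcg[j]
        s2cg = (nu_cg * s0_cg + scg) / np.random.chisquare(nu_cg + ncg)

        spm = 0.0
        for j in range(ndam):
            spm += pm[j] * pm[j]
        s2pe = (nu_pe * s0_pe + spm) / np.random.chisquare(nu_pe + ndam)

        see = 0.0
        for m in range(n):
            see += e[m] * e[m]
        s2e = (nu_e * s0_e + see) / np.random.chisquare(nu_e + n)

        if (it + 1) % 1000 == 0:
            _recompute_residual(e, y, X, beta, lcg, a, b, pm,
                                rec_an, rec_cg, rec_pm, freeze_slopes)

        if it >= burn_in and (it + 1 - burn_in) % thin == 0:
            s = (it + 1 - burn_in) // thin - 1
            if s < out_s2e.shape[0]:
                for k in range(p):
                    out_beta[s, k] = beta[k]
                for j in range(ncg):
                    out_cg[s, j] = lcg[j]
                for i in range(q):
                    out_a[s, i] = a[i]
                    out_b[s, i] = b[i]
                for j in range(ndam):
                    out_pm[s, j] = pm[j]
                out_G[s, 0] = g00
                out_G[s, 1] = g11
                out_G[s, 2] = g01
                out_s2cg[s] = s2cg
                out_s2pe[s] = s2pe
                out_s2e[s] = s2e
    return STATUS_OK
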