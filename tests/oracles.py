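"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the relationship
matrix is built by the dense tabular method, the record filters by literal
re-scanning, and the reduced-model variance components by direct REML
maximisation of the dense multivariate-normal likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def tabular_a(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = len(sire_idx)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = A[j, i] = v
    return A


def random_pedigree(rng: np.random.Generator, n_max: int = 12):
    """A random valid pedigree as (sire_idx, dam_idx) arrays, -1 = unknown."""
    n = int(rng.integers(1, n_max + 1))
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        # each parent independently unknown or one of the earlier animals
        if rng.random() < 0.7:
            sire[i] = int(rng.integers(0, i))
        if rng.random() < 0.7:
            dam[i] = int(rng.integers(0, i))
        if sire[i] >= 0 and sire[i] == dam[i] and i >= 2:
            dam[i] = int(rng.integers(0, i))  # avoid selfing when possible
    return sire, dam


def brute_force_edits(records, min_cg_size: int, min_progeny: int):
    """Literal re-scanning filter: drop undersized CGs, then under-used
    sires, repeat from scratch until nothing changes."""
    kept = list(records)
    while True:
        cg_sizes = {}
        for r in kept:
            cg_sizes[r.cg] = cg_sizes.get(r.cg, 0) + 1
        new = [r for r in kept if cg_sizes[r.cg] >= min_cg_size]
        sire_counts = {}
        for r in new:
            if r.sire is not None:
                sire_counts[r.sire] = sire_counts.get(r.sire, 0) + 1
        new = [r for r in new if r.sire is None or sire_counts[r.sire] >= min_progeny]
        if len(new) == len(kept):
            return new
        kept = new


def reml_animal_model(y, X, A, z_animal, cg_index, pm_index):
    """REML estimates for y = X b + cg + animal + pm + e by direct
    maximisation of the restricted log-likelihood over dense V.

    ``z_animal`` maps each record to its row/col of A; ``cg_index`` and
    ``pm_index`` are integer group labels per record (pm may be -1 for
    none).  Returns dict of variance components.
    """
    n = len(y)
    Zc = np.zeros((n, cg_index.max() + 1))
    Zc[np.arange(n), cg_index] = 1.0
    has_pm = pm_index >= 0
    npm = pm_index.max() + 1 if has_pm.any() else 0
    Zp = np.zeros((n, max(npm, 1)))
    if npm:
        Zp[np.flatnonzero(has_pm), pm_index[has_pm]] = 1.0
    Az = A[np.ix_(z_animal, z_animal)]
    ZcZc = Zc @ Zc.T
    ZpZp = Zp @ Zp.T
    eye = np.eye(n)

    def negloglik(theta):
        s2cg, s2a, s2pe, s2e = np.exp(theta)
        V = s2cg * ZcZc + s2a * Az + s2pe * ZpZp + s2e * eye
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        return 0.5 * (logdetV + logdetX + float(y @ Py))

    v0 = np.var(y, ddof=1)
    x0 = np.log([v0 / 4, v0 / 4, v0 / 8, v0 / 2])
    res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000})
    est = np.exp(res.x)
    # asymptotic 95% intervals from the observed information in log-variance
    # space (finite differences); a boundary-flat profile yields a huge SE
    se = np.full(4, np.inf)
    h = 1e-3
    f0 = negloglik(res.x)
    for k in range(4):
        xp = res.x.copy(); xp[k] += h
        xm = res.x.copy(); xm[k] -= h
        d2 = (negloglik(xp) - 2 * f0 + negloglik(xm)) / h**2
        if d2 > 0:
            se[k] = 1.0 / np.sqrt(d2)
    lo = np.exp(res.x - 1.96 * se)
    hi = np.exp(res.x + 1.96 * se)
    names = ("sigma2_cg", "sigma2_i", "sigma2_pe", "sigma2_e")
    out = {n: est[k] for k, n in enumerate(names)}
    out["ci"] = {n: (float(lo[k]), float(hi[k])) for k, n in enumerate(names)}
    out["converged"] = bool(res.success)
    return out
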