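"""Specialized Levenberg-Marquardt solvers for the two nonlinear fitting
stages (knee-mode aperiodic fit, joint Gaussian peak refit).

Both implement the same algorithm: damped Gauss-Newton with an active-set
reduction (variables pinned at a bound with an outward-pointing gradient are
frozen for the iteration) and projection of the step onto the box.
Termination mirrors `specparam._lm_box`: step norm below xtol*(1+|x|), a
negligible gain from a full-size (small-damping) step, five consecutive
near-zero gains, or - reported as non-convergence - exhaustion of the
function-evaluation budget.

The hot loops are numba-compiled when numba is available (it is a hard
dependency in practice; the pure-Python path exists so the package still
imports and runs without it, only slower).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


_LN10 = float(np.log(10.0))


@njit(cache=True)
def _knee_resid(freqs, yc, u, chi):
    # residual of (profiled-offset) knee model: (mean(g) - g) - yc
    n = freqs.size
    g = np.empty(n)
    k = np.exp(min(u, 700.0))
    for i in range(n):
        g[i] = np.log10(k + freqs[i] ** chi)
    gm = g.mean()
    out = np.empty(n)
    for i in range(n):
        out[i] = (gm - g[i]) - yc[i]
    return out


@njit(cache=True)
def _knee_jac(freqs, logf, u, chi):
    n = freqs.size
    k = np.exp(min(u, 700.0))
    gu = np.empty(n)
    gc = np.empty(n)
    for i in range(n):
        fc = freqs[i] ** chi
        s = (k + fc) * _LN10
        gu[i] = k / s
        gc[i] = fc * logf[i] / s
    gum = gu.mean()
    gcm = gc.mean()
    out = np.empty((n, 2))
    for i in range(n):
        out[i, 0] = gum - gu[i]
        out[i, 1] = gcm - gc[i]
    return out


@njit(cache=True)
def knee_lm(freqs, yc, logf, u0, chi0, u_lo, u_hi, chi_lo, chi_hi, xtol, max_nfev):
    """LM for the 2-parameter projected knee problem; returns (u, chi, ok)."""
    u = min(max(u0, u_lo), u_hi)
    chi = min(max(chi0, chi_lo), chi_hi)
    r = _knee_resid(freqs, yc, u, chi)
    cost = float(r @ r)
    nfev = 1
    lam = 1e-3
    J = _knee_jac(freqs, logf, u, chi)
    stagnant = 0
    eps = 1e-12
    for _ in range(1000):
        g0 = 0.0
        g1 = 0.0
        a00 = 0.0
        a01 = 0.0
        a11 = 0.0
        for i in range(r.size):
            j0 = J[i, 0]
            j1 = J[i, 1]
            g0 += j0 * r[i]
            g1 += j1 * r[i]
            a00 += j0 * j0
            a01 += j0 * j1
            a11 += j1 * j1
        free0 = not ((u <= u_lo + eps and g0 > 0) or (u >= u_hi - eps and g0 < 0))
        free1 = not ((chi <= chi_lo + eps and g1 > 0) or (chi >= chi_hi - eps and g1 < 0))
        if not (free0 or free1):
            return u, chi, True
        d0 = a00 if a00 > 0 else 1.0
        d1 = a11 if a11 > 0 else 1.0
        improved = False
        while nfev < max_nfev:
            s0 = 0.0
            s1 = 0.0
            if free0 and free1:
                m00 = a00 + lam * d0
                m11 = a11 + lam * d1
                det = m00 * m11 - a01 * a01
                if det == 0.0 or not np.isfinite(det):
                    lam *= 10.0
                    if lam > 1e14:
                        return u, chi, True
                    continue
                s0 = (-g0 * m11 + g1 * a01) / det
                s1 = (-g1 * m00 + g0 * a01) / det
            elif free0:
                s0 = -g0 / (a00 + lam * d0)
            else:
                s1 = -g1 / (a11 + lam * d1)
            un = min(max(u + s0, u_lo), u_hi)
            chin = min(max(chi + s1, chi_lo), chi_hi)
            rn = _knee_resid(freqs, yc, un, chin)
            nfev += 1
            cn = float(rn @ rn)
            if not np.isfinite(cn):
                lam *= 10.0
                if lam > 1e14:
                    return u, chi, True
                continue
            if cn <= cost:
                moved = np.sqrt((un - u) ** 2 + (chin - chi) ** 2)
                gain = (cost - cn) / max(cost, 1e-300)
                u, chi, r, cost = un, chin, rn, cn
                J = _knee_jac(freqs, logf, u, chi)
                lam = max(lam * 0.3, 1e-12)
                improved = True
                if moved <= xtol * (1.0 + np.sqrt(u * u + chi * chi)):
                    return u, chi, True
                if gain <= xtol and lam <= 1e-3:
                    return u, chi, True
                if gain <= 1e-10:
                    stagnant += 1
                    if stagnant >= 5:
                        return u, chi, True
                else:
                    stagnant = 0
                break
            lam *= 10.0
            if lam > 1e14:
                return u, chi, True
        if not improved:
            return u, chi, False
    return u, chi, False


@njit(cache=True)
def _gauss_resid(f, flat, x):
    n = f.size
    P = x.size // 3
    out = np.empty(n)
    for i in range(n):
        v = -flat[i]
        for p in range(P):
            c = x[3 * p]
            h = x[3 * p + 1]
            w = x[3 * p + 2]
            d = f[i] - c
            v += h * np.exp(-(d * d) / (2.0 * w * w))
        out[i] = v
    return out


@njit(cache=True)
def _gauss_jac(f, x):
    n = f.size
    P = x.size // 3
    out = np.empty((n, 3 * P))
    for i in range(n):
        for p in range(P):
            c = x[3 * p]
            h = x[3 * p + 1]
            w = x[3 * p + 2]
            d = f[i] - c
            e = np.exp(-(d * d) / (2.0 * w * w))
            out[i, 3 * p] = h * e * d / (w * w)
            out[i, 3 * p + 1] = e
            out[i, 3 * p + 2] = h * e * d * d / (w * w * w)
    return out


@njit(cache=True)
def _solve_ppiv(M, b):
    """Gaussian elimination with partial pivoting; returns (x, ok)."""
    n = b.size
    A = M.copy()
    x = b.copy()
    for col in range(n):
        piv = col
        best = abs(A[col, col])
        for row in range(col + 1, n):
            if abs(A[row, col]) > best:
                best = abs(A[row, col])
                piv = row
        if best == 0.0 or not np.isfinite(best):
            return x, False
        if piv != col:
            for j in range(n):
                tmp = A[col, j]
                A[col, j] = A[piv, j]
                A[piv, j] = tmp
            tmp = x[col]
            x[col] = x[piv]
            x[piv] = tmp
        for row in range(col + 1, n):
            fac = A[row, col] / A[col, col]
            if fac != 0.0:
                for j in range(col, n):
                    A[row, j] -= fac * A[col, j]
                x[row] -= fac * x[col]
    for col in range(n - 1, -1, -1):
        s = x[col]
        for j in range(col + 1, n):
            s -= A[col, j] * x[j]
        x[col] = s / A[col, col]
    return x, True


@njit(cache=True)
def gauss_lm(f, flat, p0, lo, hi, xtol, max_nfev):
    """LM for the joint multi-Gaussian refit; returns (x, ok)."""
    P = p0.size
    x = np.empty(P)
    for j in range(P):
        x[j] = min(max(p0[j], lo[j]), hi[j])
    r = _gauss_resid(f, flat, x)
    cost = float(r @ r)
    nfev = 1
    lam = 1e-3
    J = _gauss_jac(f, x)
    stagnant = 0
    eps = 1e-12
    for _ in range(1000):
        g = np.ascontiguousarray(J.T) @ r
        free = np.empty(P, np.bool_)
        nfree = 0
        for j in range(P):
            pinned = (x[j] <= lo[j] + eps and g[j] > 0) or (x[j] >= hi[j] - eps and g[j] < 0)
            free[j] = not pinned
            if not pinned:
                nfree += 1
        if nfree == 0:
            return x, True
        idx = np.empty(nfree, np.int64)
        kk = 0
        for j in range(P):
            if free[j]:
                idx[kk] = j
                kk += 1
        Jf = np.ascontiguousarray(J[:, idx])
        A = np.ascontiguousarray(Jf.T) @ Jf
        gf = g[idx]
        diag = np.empty(nfree)
        for j in range(nfree):
            diag[j] = A[j, j] if A[j, j] > 0 else 1.0
        improved = False
        while nfev < max_nfev:
            M = A.copy()
            for j in range(nfree):
                M[j, j] += lam * diag[j]
            step_f, ok_solve = _solve_ppiv(M, -gf)
            if not ok_solve or not np.all(np.isfinite(step_f)):
                lam *= 10.0
                if lam > 1e14:
                    return x, True
                continue
            xn = x.copy()
            for j in range(nfree):
                jj = idx[j]
                xn[jj] = min(max(x[jj] + step_f[j], lo[jj]), hi[jj])
            rn = _gauss_resid(f, flat, xn)
            nfev += 1
            cn = float(rn @ rn)
            if not np.isfinite(cn):
                lam *= 10.0
                if lam > 1e14:
                    return x, True
                continue
            if cn <= cost:
                moved = 0.0
                xnorm = 0.0
                for j in range(P):
                    moved += (xn[j] - x[j]) ** 2
                    xnorm += xn[j] * xn[j]
                moved = np.sqrt(moved)
                xnorm = np.sqrt(xnorm)
                gain = (cost - cn) / max(cost, 1e-300)
                x, r, cost = xn, rn, cn
                J = _gauss_jac(f, x)
                lam = max(lam * 0.3, 1e-12)
                improved = True
                if moved <= xtol * (1.0 + xnorm):
                    return x, True
                if gain <= xtol and lam <= 1e-3:
                    return x, True
                if gain <= 1e-10:
                    stagnant += 1
                    if stagnant >= 5:
                        return x, True
                else:
                    stagnant = 0
                break
            lam *= 10.0
            if lam > 1e14:
                return x, True
        if not improved:
            return x, False
    return x, False
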