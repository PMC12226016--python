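"""Independent brute-force oracles used by the test suite.

Each oracle computes a quantity the library also computes, but by a
different route: explicit isochromat rotation matrices instead of the
configuration-state recursion, direct ODE integration of the coupled
longitudinal system instead of the closed-form bi-exponential, and a
profiled restricted-likelihood grid instead of the packaged mixed-model
optimizer.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def isochromat_mese(t2, t1, esp, n_echoes, refocus_deg, exc_deg=90.0,
                    n_iso=2048):
    """Multi-echo spin-echo train by explicit isochromat summation.

    n_iso isochromats with uniformly spaced dephasing angles per half
    echo spacing (crusher-equivalent), excitation about +y, refocusing
    about +x; returns echo magnitudes |<Mx + i My>|.
    """
    theta = 2.0 * np.pi * np.arange(n_iso) / n_iso
    m = np.zeros((n_iso, 3))
    m[:, 2] = 1.0
    m = m @ _rot_y(np.radians(exc_deg)).T

    e2 = np.exp(-0.5 * esp / t2)
    e1 = np.exp(-0.5 * esp / t1)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    def half_period(m):
        # simultaneous relaxation and z-precession (they commute)
        mx = (m[:, 0] * cos_t - m[:, 1] * sin_t) * e2
        my = (m[:, 0] * sin_t + m[:, 1] * cos_t) * e2
        mz = m[:, 2] * e1 + (1.0 - e1)
        return np.column_stack([mx, my, mz])

    refocus = np.broadcast_to(np.atleast_1d(refocus_deg), (n_echoes,))
    echoes = np.empty(n_echoes)
    for n in range(n_echoes):
        m = half_period(m)
        m = m @ _rot_x(np.radians(refocus[n])).T
        m = half_period(m)
        echoes[n] = np.abs(np.mean(m[:, 0] + 1j * m[:, 1]))
    return echoes


def coupled_ode_recovery(r1f, r1m, kmf, psr, delta_f, delta_m, t_eval):
    """Normalized free-pool recovery by direct integration of the
    coupled two-pool longitudinal equations (cross-relaxation form)."""
    kfm = psr * kmf
    m_inf_f, m_inf_m = 1.0, psr

    def rhs(_t, y):
        mzf, mzm = y
        return [r1f * (m_inf_f - mzf) - kfm * mzf + kmf * mzm,
                r1m * (m_inf_m - mzm) - kmf * mzm + kfm * mzf]

    y0 = [delta_f * m_inf_f, delta_m * m_inf_m]
    sol = solve_ivp(rhs, (0.0, float(np.max(t_eval))), y0,
                    t_eval=np.sort(t_eval), method="LSODA",
                    rtol=1e-12, atol=1e-14)
    assert sol.success
    return sol.y[0] / m_inf_f


def profiled_reml(y, X, groups):
    """Random-intercept REML estimates by profiling the variance ratio.

    For psi = sigma_b^2 / sigma^2 the GLS coefficients and the residual
    variance have closed forms; the scalar psi is found by bounded
    search on the profiled restricted log-likelihood.

    Returns (beta, sigma_b^2, sigma^2).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    n, p = X.shape

    def fit_for(psi):
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        for g in labels:
            idx = groups == g
            Xg, yg = X[idx], y[idx]
            ng = idx.sum()
            shrink = psi / (1.0 + ng * psi)
            WX = Xg - shrink * np.outer(np.ones(ng), Xg.sum(axis=0))
            Wy = yg - shrink * np.ones(ng) * yg.sum()
            xtwx += Xg.T @ WX
            xtwy += Xg.T @ Wy
        beta = np.linalg.solve(xtwx, xtwy)
        rss = 0.0
        logdet_v = 0.0
        for g in labels:
            idx = groups == g
            rg = y[idx] - X[idx] @ beta
            ng = idx.sum()
            shrink = psi / (1.0 + ng * psi)
            rss += rg @ rg - shrink * rg.sum() ** 2
            logdet_v += np.log(1.0 + ng * psi)
        sigma2 = rss / (n - p)
        _, logdet_xwx = np.linalg.slogdet(xtwx)
        reml = -0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_xwx
                       + (n - p))
        return beta, sigma2, reml

    def neg(log_psi):
        return -fit_for(np.exp(log_psi))[2]

    res = minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-12})
    psi = float(np.exp(res.x))
    beta, sigma2, _ = fit_for(psi)
    return beta, psi * sigma2, sigma2
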