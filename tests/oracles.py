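"""Independent reference implementations used only to check hsekit.

Each oracle takes a deliberately different computational route from the
package: numerical quadrature instead of the closed-form marginal
likelihood, exhaustive vertex enumeration instead of an LP solver, and
literal formula evaluation for the simpler statistics.
"""

import itertools

import numpy as np
from scipy import integrate, stats


def bc92_loglik_quadrature(eps, sigma_sq, gamma, mu, eta):
    """Marginal log-likelihood by direct quadrature over u_i >= 0."""
    n, T = eps.shape
    s_u = np.sqrt(gamma * sigma_sq)
    s_v = np.sqrt((1.0 - gamma) * sigma_sq)
    b = np.exp(-eta * (np.arange(1, T + 1) - T))
    total = 0.0
    for i in range(n):
        def integrand(u):
            return (np.prod(stats.norm.pdf(eps[i] + b * u, scale=s_v))
                    * stats.norm.pdf(u, loc=mu, scale=s_u)
                    / stats.norm.cdf(mu / s_u))
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400,
                                epsabs=1e-14, epsrel=1e-11)
        total += np.log(val)
    return total


def bc92_te_quadrature(eps_i, sigma_sq, gamma, mu, eta):
    """E[exp(-b_t u) | eps_i] per period, by quadrature on the joint density."""
    T = eps_i.size
    s_u = np.sqrt(gamma * sigma_sq)
    s_v = np.sqrt((1.0 - gamma) * sigma_sq)
    b = np.exp(-eta * (np.arange(1, T + 1) - T))

    def posterior_kernel(u):
        return (np.prod(stats.norm.pdf(eps_i + b * u, scale=s_v))
                * stats.norm.pdf(u, loc=mu, scale=s_u))

    denom, _ = integrate.quad(posterior_kernel, 0.0, np.inf, limit=200)
    te = np.empty(T)
    for t in range(T):
        num, _ = integrate.quad(lambda u: np.exp(-b[t] * u) * posterior_kernel(u),
                                0.0, np.inf, limit=200)
        te[t] = num / denom
    return te


def dea_max_phi_enumeration(E, P, e0, p0, vrs, tol=1e-9):
    """Max radial output expansion by exhaustive vertex enumeration.

    Variables x = (phi, lambda).  Every vertex of the feasible polyhedron is
    the solution of some square system of active constraints; enumerate all
    candidate active sets, solve, keep feasible points, return max phi.
    """
    E = np.atleast_2d(np.asarray(E, float))
    P = np.atleast_2d(np.asarray(P, float))
    e0 = np.atleast_1d(np.asarray(e0, float))
    p0 = np.atleast_1d(np.asarray(p0, float))
    n = E.shape[0]
    m = n + 1
    rows, rhs = [], []
    for k in range(E.shape[1]):                      # sum lam e_k <= e0_k
        rows.append(np.concatenate([[0.0], E[:, k]])); rhs.append(e0[k])
    for k in range(P.shape[1]):                      # phi p0_k - sum lam p_k <= 0
        rows.append(np.concatenate([[p0[k]], -P[:, k]])); rhs.append(0.0)
    for j in range(n):                               # -lam_j <= 0
        r = np.zeros(m); r[j + 1] = -1.0
        rows.append(r); rhs.append(0.0)
    rows = np.array(rows); rhs = np.array(rhs)
    eq_rows, eq_rhs = (np.ones((1, m)), np.array([1.0])) if vrs else (np.zeros((0, m)), np.zeros(0))
    if vrs:
        eq_rows[0, 0] = 0.0
    n_active = m - eq_rows.shape[0]
    best = -np.inf
    for active in itertools.combinations(range(len(rows)), n_active):
        A = np.vstack([eq_rows, rows[list(active)]])
        b = np.concatenate([eq_rhs, rhs[list(active)]])
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if np.all(rows @ x <= rhs + tol) and (not vrs or abs(x[1:].sum() - 1) <= tol):
            best = max(best, x[0])
    return best


def moran_i_formula(y, W):
    """Literal evaluation of the global Moran's I double sum."""
    y = np.asarray(y, float)
    n = y.size
    ybar = y.mean()
    num = sum(W[i, j] * (y[i] - ybar) * (y[j] - ybar)
              for i in range(n) for j in range(n))
    den = sum((y[i] - ybar) ** 2 for i in range(n))
    return num / den * n / W.sum()


def moran_exhaustive_mean(y, W):
    """Mean of Moran's I over all n! relabelings of the values."""
    y = np.asarray(y, float)
    vals = [moran_i_formula(np.array(perm), W)
            for perm in itertools.permutations(y)]
    return float(np.mean(vals))


def gaussian_mixture_density(x, points, h):
    """Closed-form KDE value: equal-weight normal mixture at the data points."""
    return float(np.mean(stats.norm.pdf(x, loc=np.asarray(points, float), scale=h)))
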