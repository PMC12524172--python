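"""Independent oracles used by the test suite.

These deliberately avoid the package's own formulas: the magnetic field of
a dipole in a spherical conductor is reconstructed from the magnetic scalar
potential, itself obtained by integrating the radial field component along
an outward ray (volume currents in a spherically symmetric conductor
contribute no radial field, so the radial component comes from the primary
current alone, i.e. plain Biot-Savart).  Wilcoxon distributions are built
by exhaustive enumeration.
"""

from itertools import combinations, product

import numpy as np
from scipy.integrate import quad

_MU0 = 4e-7 * np.pi
_MU0_OVER_4PI = 1e-7


def _primary_radial_field(x, moment, location):
    """Radial component of the bare (Biot-Savart) dipole field at x."""
    d = x - location
    B = _MU0_OVER_4PI * np.cross(moment, d) / np.linalg.norm(d) ** 3
    return B @ (x / np.linalg.norm(x))


def _scalar_potential(x, moment, location):
    """U(x) = (1/mu0) * integral_{|x|}^{inf} B_r(s x_hat) ds (outside)."""
    r = np.linalg.norm(x)
    xhat = x / r
    val, _ = quad(lambda s: _primary_radial_field(s * xhat, moment, location),
                  r, np.inf, epsabs=1e-24, epsrel=1e-13, limit=400)
    return val / _MU0


def conductor_field_oracle(x, moment, location, h=1e-3):
    """B = -mu0 grad U via Richardson-extrapolated 4th-order differences.

    Agrees with the closed form to ~1e-10 relative; every ingredient
    (Biot-Savart radial field, quadrature, finite differences) is
    independent of the implementation under test.
    """
    def f(p):
        return _scalar_potential(p, moment, location)

    def d4(e, step):
        return (-f(x + 2 * step * e) + 8 * f(x + step * e)
                - 8 * f(x - step * e) + f(x - 2 * step * e)) / (12 * step)

    B = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        D1, D2 = d4(e, h), d4(e, h / 2)
        B[k] = -_MU0 * (16 * D2 - D1) / 15.0
    return B


def signed_rank_p_exact(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n_stat = 2.0 ** n
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / n_stat


def rank_sum_p_exact(a, b):
    """Two-sided rank-sum p by enumerating all group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    total = 0
    hits = 0
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total
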