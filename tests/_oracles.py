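"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own solution paths: tensor
algebra in full Mandel notation for the equivalent-inclusion problem,
direct numerical quadrature for the Eshelby I-integrals, and exhaustive
grid search for the exponential fit.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

_SQRT2 = np.sqrt(2.0)
# Mandel basis index pairs: 11, 22, 33, 23, 13, 12
_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def _mandel_matrix(T4: np.ndarray) -> np.ndarray:
    """Fourth-order tensor -> 6x6 Mandel matrix."""
    M = np.zeros((6, 6))
    for a, (i, j) in enumerate(_PAIRS):
        for b, (k, l) in enumerate(_PAIRS):
            fa = 1.0 if i == j else _SQRT2
            fb = 1.0 if k == l else _SQRT2
            M[a, b] = fa * fb * T4[i, j, k, l]
    return M


def _mandel_vector(E3: np.ndarray) -> np.ndarray:
    return np.array(
        [E3[i, j] * (1.0 if i == j else _SQRT2) for (i, j) in _PAIRS]
    )


def _unmandel_vector(v: np.ndarray) -> np.ndarray:
    E = np.zeros((3, 3))
    for a, (i, j) in enumerate(_PAIRS):
        val = v[a] / (1.0 if i == j else _SQRT2)
        E[i, j] = E[j, i] = val
    return E


def iso_stiffness_tensor(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    I = np.eye(3)
    C = np.einsum("ij,kl->ijkl", I, I) * lam
    C += mu * (
        np.einsum("ik,jl->ijkl", I, I) + np.einsum("il,jk->ijkl", I, I)
    )
    return C


def equivalent_inclusion_mandel(
    E_b: float,
    nu_b: float,
    E_i: float,
    nu_i: float,
    S4: np.ndarray,
    eps0_tensor: np.ndarray,
) -> np.ndarray:
    """Interior strain of an inhomogeneity by a full 6x6 Mandel solve.

    C_i (e0 + S e*) = C_b (e0 + S e* - e*), solved for the eigenstrain
    e* with every quantity as a 6-vector / 6x6 matrix.
    """
    Cb = _mandel_matrix(iso_stiffness_tensor(E_b, nu_b))
    Ci = _mandel_matrix(iso_stiffness_tensor(E_i, nu_i))
    S = _mandel_matrix(S4)
    e0 = _mandel_vector(eps0_tensor)
    A = (Ci - Cb) @ S + Cb
    estar = np.linalg.solve(A, (Cb - Ci) @ e0)
    return _unmandel_vector(e0 + S @ estar)


def spheroid_I_quadrature(aspect: float):
    """Eshelby I-integrals of a spheroid (a1=a2=1, a3=aspect) by
    direct quadrature of their defining improper integrals."""
    a1 = a2 = 1.0
    a3 = aspect

    def delta(s):
        return np.sqrt((a1**2 + s) * (a2**2 + s) * (a3**2 + s))

    def I(i):
        ai2 = [a1**2, a2**2, a3**2][i]
        val, _ = quad(lambda s: 1.0 / ((ai2 + s) * delta(s)), 0, np.inf)
        return 2 * np.pi * a1 * a2 * a3 * val

    def Iij(i, j):
        ai2 = [a1**2, a2**2, a3**2][i]
        aj2 = [a1**2, a2**2, a3**2][j]
        val, _ = quad(
            lambda s: 1.0 / ((ai2 + s) * (aj2 + s) * delta(s)), 0, np.inf
        )
        return 2 * np.pi * a1 * a2 * a3 * val

    return {
        "I1": I(0),
        "I3": I(2),
        "I11": Iij(0, 0),
        "I13": Iij(0, 2),
        "I33": Iij(2, 2),
    }


def eshelby_components_quadrature(nu: float, aspect: float) -> dict[str, float]:
    """Eshelby tensor components assembled from quadrature I-integrals."""
    q = spheroid_I_quadrature(aspect)
    I1, I3, I11, I13, I33 = q["I1"], q["I3"], q["I11"], q["I13"], q["I33"]
    a1sq, a3sq = 1.0, aspect**2
    f = 1.0 / (8 * np.pi * (1 - nu))
    g = (1 - 2 * nu) * f
    return {
        "S1111": 3 * f * a1sq * I11 + g * I1,
        "S3333": 3 * f * a3sq * I33 + g * I3,
        "S1122": f * a1sq * I11 - g * I1,
        "S1133": f * a3sq * I13 - g * I1,
        "S3311": f * a1sq * I13 - g * I3,
        "S1212": f * a1sq * I11 + g * I1,
        "S1313": 0.5 * f * (a1sq + a3sq) * I13 + 0.5 * g * (I1 + I3),
    }


def grid_search_exponential(times, values, n_grid=10_000):
    """Exhaustive tau grid search for s(t) = eta + (alpha-eta)e^(-t/tau).

    Returns (alpha, eta, tau, rss) from a dense log-spaced grid over the
    same bracket convention as the fitter (0.1x to 10x window).
    """
    t = np.asarray(times, float) - times[0]
    y = np.asarray(values, float)
    window = t[-1] - t[0]
    taus = np.geomspace(0.1 * window, 10.0 * window, n_grid)
    best = None
    for tau in taus:
        A = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ coef - y) ** 2).sum())
        if best is None or rss < best[3]:
            best = (coef[0] + coef[1], coef[0], tau, rss)
    return best
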