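"""Elastic-parameter inversion from steady-state strain images.

Estimates the Young's modulus and Poisson's ratio of an ellipsoidal
inclusion embedded in a softer/stiffer background from the axial and
lateral strains measured under remote uniaxial compression.  The theory
is Eshelby's equivalent-inclusion method: the interior strain of an
ellipsoidal inhomogeneity is spatially uniform and related to the remote
strain through the (geometry- and background-PR-dependent) Eshelby
tensor and a fictitious eigenstrain.  Two independent expressions of
that eigenstrain -- one purely geometric, one involving the moduli of
both media -- must coincide; their squared mismatch is the inversion
cost function.

Axis convention: axes 1 and 2 are lateral (the spheroid's equatorial
plane), axis 3 is axial (the symmetry / loading axis).  Strain vectors
in the normal-component subspace are ordered (e11, e22, e33).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "EshelbyTensor",
    "ElasticEstimate",
    "eshelby_tensor_sphere",
    "eshelby_tensor_spheroid",
    "eshelby_tensor",
    "equivalent_inclusion_strain",
    "background_moduli",
    "invert_inclusion",
    "fit_ellipsoid",
]

#: aspect ratios closer to 1 than this are treated as spheres; the
#: spheroid I-integral relations divide by (a3^2 - a1^2) and lose all
#: precision closer to unity than ~1e-4
_SPHERE_TOL = 1e-4


@dataclass(frozen=True)
class EshelbyTensor:
    """Eshelby tensor of an axisymmetric (spheroidal) inclusion.

    Only the components entering the axisymmetric problem are stored.
    ``nu_b`` is the background Poisson's ratio the tensor was built from
    and ``aspect`` the axial/lateral semi-axis ratio (1 for a sphere).
    """

    nu_b: float
    aspect: float
    components: dict[str, float] = field(repr=False)

    def normal_block(self) -> np.ndarray:
        """3x3 matrix acting on normal-strain vectors (e11, e22, e33)."""
        c = self.components
        return np.array(
            [
                [c["S1111"], c["S1122"], c["S1133"]],
                [c["S1122"], c["S1111"], c["S1133"]],
                [c["S3311"], c["S3311"], c["S3333"]],
            ]
        )

    def full_tensor(self) -> np.ndarray:
        """Full 3x3x3x3 tensor (minor symmetries filled in)."""
        c = self.components
        S = np.zeros((3, 3, 3, 3))
        normal = {
            (0, 0, 0, 0): c["S1111"],
            (1, 1, 1, 1): c["S1111"],
            (2, 2, 2, 2): c["S3333"],
            (0, 0, 1, 1): c["S1122"],
            (1, 1, 0, 0): c["S1122"],
            (0, 0, 2, 2): c["S1133"],
            (1, 1, 2, 2): c["S1133"],
            (2, 2, 0, 0): c["S3311"],
            (2, 2, 1, 1): c["S3311"],
        }
        for (i, j, k, l), v in normal.items():
            S[i, j, k, l] = v
        shears = {(0, 1): c["S1212"], (0, 2): c["S1313"], (1, 2): c["S1313"]}
        for (i, j), v in shears.items():
            for a, b in ((i, j), (j, i)):
                for cc, d in ((i, j), (j, i)):
                    S[a, b, cc, d] = v
        return S


@dataclass
class ElasticEstimate:
    """Result of the inclusion/background modulus reconstruction."""

    E_i: float
    nu_i: float
    E_b: float
    nu_b: float
    cost: float
    boundary: bool = False  # minimiser ended on the search-box edge

    def __post_init__(self) -> None:
        if self.E_i <= 0 or self.E_b <= 0:
            raise ValueError("Young's moduli must be positive")
        if not (0 <= self.nu_i < 0.5 and 0 <= self.nu_b < 0.5):
            raise ValueError("Poisson's ratios must lie in [0, 0.5)")
        if self.cost < 0:
            raise ValueError("cost must be non-negative")


def _check_nu(nu_b: float) -> None:
    if not 0 <= nu_b < 0.5:
        raise ValueError(f"background Poisson's ratio must be in [0, 0.5), got {nu_b}")


def eshelby_tensor_sphere(nu_b: float) -> EshelbyTensor:
    """Eshelby tensor of a sphere in an isotropic background.

    Classical closed forms: S_1111 = (7-5nu)/(15(1-nu)),
    S_1122 = (5nu-1)/(15(1-nu)), S_1212 = (4-5nu)/(15(1-nu)).
    """
    _check_nu(nu_b)
    d = 15.0 * (1.0 - nu_b)
    s1111 = (7.0 - 5.0 * nu_b) / d
    s1122 = (5.0 * nu_b - 1.0) / d
    s1212 = (4.0 - 5.0 * nu_b) / d
    comps = {
        "S1111": s1111,
        "S3333": s1111,
        "S1122": s1122,
        "S1133": s1122,
        "S3311": s1122,
        "S1212": s1212,
        "S1313": s1212,
    }
    return EshelbyTensor(nu_b=nu_b, aspect=1.0, components=comps)


def _spheroid_I_integrals(aspect: float) -> tuple[float, float, float, float, float]:
    """First- and second-order Eshelby I-integrals for a spheroid.

    Semi-axes a1 = a2 = 1 (lateral), a3 = aspect (axial).  Returns
    (I1, I3, I11, I13, I33); I2 = I1, I12 = I11 by symmetry.
    """
    a1 = 1.0
    a3 = aspect
    if aspect < 1.0:  # oblate: a1 > a3
        q = a3 / a1
        e = np.sqrt(1.0 - q * q)
        I1 = (2.0 * np.pi * a1**2 * a3 / (a1**2 - a3**2) ** 1.5) * (
            np.arccos(q) - q * e
        )
    else:  # prolate: a3 > a1
        q = a3 / a1
        e = np.sqrt(q * q - 1.0)
        I1 = (2.0 * np.pi * a1**2 * a3 / (a3**2 - a1**2) ** 1.5) * (
            q * e - np.arccosh(q)
        )
    I3 = 4.0 * np.pi - 2.0 * I1
    I13 = (I1 - I3) / (a3**2 - a1**2)
    I11 = np.pi / a1**2 - I13 / 4.0  # from 3*I11 + I12 + I13 = 4*pi/a1^2, I12 = I11
    I33 = (4.0 * np.pi / a3**2 - 2.0 * I13) / 3.0
    return I1, I3, I11, I13, I33


def eshelby_tensor_spheroid(nu_b: float, aspect: float) -> EshelbyTensor:
    """Eshelby tensor of a spheroid with symmetry axis along the load.

    ``aspect`` is the axial over lateral semi-axis ratio: < 1 oblate
    (e.g. the 5 mm axial x 7.5 mm lateral tumour gives 2/3), > 1
    prolate.  Aspect ratios within 1e-4 of unity delegate to the sphere
    closed forms; the spheroid expressions themselves are numerically
    stable once more than ~1e-4 away from the sphere.
    """
    _check_nu(nu_b)
    if aspect <= 0:
        raise ValueError(f"aspect ratio must be positive, got {aspect}")
    if abs(aspect - 1.0) < _SPHERE_TOL:
        sphere = eshelby_tensor_sphere(nu_b)
        return EshelbyTensor(nu_b=nu_b, aspect=aspect, components=sphere.components)

    I1, I3, I11, I13, I33 = _spheroid_I_integrals(aspect)
    a1sq, a3sq = 1.0, aspect**2
    f = 1.0 / (8.0 * np.pi * (1.0 - nu_b))
    g = (1.0 - 2.0 * nu_b) * f
    comps = {
        "S1111": 3.0 * f * a1sq * I11 + g * I1,
        "S3333": 3.0 * f * a3sq * I33 + g * I3,
        "S1122": f * a1sq * I11 - g * I1,  # I12 = I11, a2 = a1
        "S1133": f * a3sq * I13 - g * I1,
        "S3311": f * a1sq * I13 - g * I3,
        "S1212": f * a1sq * I11 + g * I1,  # (a1^2+a2^2)/2 * I12 -> a1^2*I11
        "S1313": 0.5 * f * (a1sq + a3sq) * I13 + 0.5 * g * (I1 + I3),
    }
    return EshelbyTensor(nu_b=nu_b, aspect=aspect, components=comps)


def eshelby_tensor(nu_b: float, aspect: float = 1.0) -> EshelbyTensor:
    """Dispatch to the sphere or spheroid tensor by aspect ratio."""
    if abs(aspect - 1.0) < _SPHERE_TOL:
        return eshelby_tensor_sphere(nu_b)
    return eshelby_tensor_spheroid(nu_b, aspect)


def _iso_normal_stiffness(E: float, nu: float) -> np.ndarray:
    """Normal-component block of the isotropic stiffness (3x3, Pa)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam * np.ones((3, 3)) + 2.0 * mu * np.eye(3)


def equivalent_inclusion_strain(
    E_b: float,
    nu_b: float,
    E_i: float,
    nu_i: float,
    S_normal: np.ndarray,
    eps0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Interior strain and eigenstrain of an inhomogeneity.

    Solves the equivalent-inclusion equivalency
    ``C_i (eps0 + S eps*) = C_b (eps0 + S eps* - eps*)`` for the
    eigenstrain ``eps*`` in the normal-component subspace, given the
    remote strain ``eps0`` (signed tensor components, length 3).

    Returns ``(eps_interior, eps_star)``.
    """
    Cb = _iso_normal_stiffness(E_b, nu_b)
    Ci = _iso_normal_stiffness(E_i, nu_i)
    A = (Ci - Cb) @ S_normal + Cb
    rhs = (Cb - Ci) @ eps0
    try:
        eps_star = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological moduli
        raise np.linalg.LinAlgError(
            "equivalent-inclusion system is singular for these moduli"
        ) from exc
    return eps0 + S_normal @ eps_star, eps_star


def background_moduli(
    sigma0: float, eps_zz_b: float, eps_rr_b: float
) -> tuple[float, float]:
    """Background Young's modulus and Poisson's ratio from far-field strains.

    Uniaxial definitions: E_b = sigma0/|eps_zz|, nu_b = |eps_rr|/|eps_zz|
    (clamped to [0, 0.499]).  Inputs may be signed or magnitudes; the
    strains should be steady-state values averaged over a background ROI
    far from the inclusion.
    """
    if eps_zz_b == 0:
        raise ValueError("background axial strain is zero; cannot form E_b")
    E_b = sigma0 / abs(eps_zz_b)
    nu_b = min(max(abs(eps_rr_b) / abs(eps_zz_b), 0.0), 0.499)
    return E_b, nu_b


def _signed_normal_strains(eps_zz_mag: float, eps_rr_mag: float) -> np.ndarray:
    """Magnitude convention -> signed tensor strains (e11, e22, e33).

    Axial strains are stored compression-positive, lateral strains
    expansion-positive; the elevational component is set equal to the
    lateral one by axisymmetry.
    """
    return np.array([eps_rr_mag, eps_rr_mag, -eps_zz_mag])


def _inversion_cost(
    E_i: float,
    nu_i: float,
    E_b: float,
    nu_b: float,
    S_normal: np.ndarray,
    eps0: np.ndarray,
    eps_star_g: np.ndarray,
    scale: float,
) -> float:
    _, eps_star_m = equivalent_inclusion_strain(E_b, nu_b, E_i, nu_i, S_normal, eps0)
    d = eps_star_g - eps_star_m
    return float(d @ d) / scale


def invert_inclusion(
    eps_in: tuple[float, float],
    eps_bg: tuple[float, float],
    E_b: float,
    nu_b: float,
    shape: float | str = "sphere",
    n_starts: int = 5,
    seed: int = 0,
    bounds_ratio: tuple[float, float] = (0.05, 50.0),
) -> ElasticEstimate:
    """Reconstruct inclusion (E_i, nu_i) from measured interior strains.

    Parameters
    ----------
    eps_in, eps_bg
        ``(axial, lateral)`` strain magnitudes inside the inclusion and
        in the far background (axial compression-positive, lateral
        expansion-positive), e.g. steady-state values from the
        exponential fit.
    shape
        ``"sphere"`` or the axial/lateral aspect ratio of the best-fit
        spheroid.
    n_starts, seed
        Multi-start local minimisation over the bounded box
        ``E_i in bounds_ratio * E_b``, ``nu_i in [0.01, 0.499]``; the
        cost surface can be locally flat in nu_i.
    """
    eps_in = (float(eps_in[0]), float(eps_in[1]))
    eps_bg = (float(eps_bg[0]), float(eps_bg[1]))
    if not all(np.isfinite(v) for v in (*eps_in, *eps_bg)):
        raise ValueError("non-finite strain inputs")
    aspect = 1.0 if shape == "sphere" else float(shape)
    S_normal = eshelby_tensor(nu_b, aspect).normal_block()
    eps0 = _signed_normal_strains(*eps_bg)
    eps_in_vec = _signed_normal_strains(*eps_in)
    eps_star_g = np.linalg.solve(S_normal, eps_in_vec - eps0)
    scale = float(eps0 @ eps0)
    if scale == 0:
        raise ValueError("background strain is identically zero")

    lo, hi = np.log(bounds_ratio[0]), np.log(bounds_ratio[1])
    nu_lo, nu_hi = 0.01, 0.499

    def objective(x: np.ndarray) -> float:
        return _inversion_cost(
            E_b * np.exp(x[0]), x[1], E_b, nu_b, S_normal, eps0, eps_star_g, scale
        )

    rng = np.random.default_rng(seed)
    starts = [np.array([0.0, min(max(nu_b, 0.05), 0.45)])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.array([rng.uniform(lo, hi), rng.uniform(0.05, 0.45)])
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi), (nu_lo, nu_hi)],
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    at_edge = (
        min(x[0] - lo, hi - x[0]) < 1e-6 or min(x[1] - nu_lo, nu_hi - x[1]) < 1e-6
    )
    if at_edge:
        warnings.warn(
            "inclusion modulus inversion converged on the search-box boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    return ElasticEstimate(
        E_i=float(E_b * np.exp(x[0])),
        nu_i=float(x[1]),
        E_b=float(E_b),
        nu_b=float(nu_b),
        cost=float(best.fun),
        boundary=bool(at_edge),
    )


def invert_inclusion_map(
    eta_axial: np.ndarray,
    eta_lateral: np.ndarray,
    eps_bg: tuple[float, float],
    E_b: float,
    nu_b: float,
    mask: np.ndarray,
    shape: float | str = "sphere",
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (E_i, nu_i) maps over ``mask``.

    Identical strain pairs are inverted once and cached, so piecewise
    uniform maps (e.g. noise-free phantoms) cost a single minimisation.
    Pixels with non-finite strains yield NaN.  The third returned map
    flags pixels whose minimiser ended on the search-box boundary
    (unreliable estimates).
    """
    E_map = np.full(eta_axial.shape, np.nan)
    nu_map = np.full(eta_axial.shape, np.nan)
    boundary = np.zeros(eta_axial.shape, dtype=bool)
    cache: dict[tuple[float, float], tuple[float, float, bool]] = {}
    rows, cols = np.nonzero(mask)
    for r, cidx in zip(rows, cols):
        key = (float(eta_axial[r, cidx]), float(eta_lateral[r, cidx]))
        if not (np.isfinite(key[0]) and np.isfinite(key[1])):
            continue
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est = invert_inclusion(key, eps_bg, E_b, nu_b, shape, **kwargs)
            cache[key] = (est.E_i, est.nu_i, est.boundary)
        E_map[r, cidx], nu_map[r, cidx], boundary[r, cidx] = cache[key]
    return E_map, nu_map, boundary


def fit_ellipsoid(
    mask: np.ndarray, pixel_spacing_mm: float | tuple[float, float] = 1.0
) -> tuple[float, float, float]:
    """Best-fit ellipse of a binary mask by second-moment decomposition.

    Returns ``(l1_mm, l2_mm, orientation_rad)`` with l1 the minor and l2
    the major semi-axis; the axes are scaled so the ellipse area equals
    the mask area.  Orientation is the major-axis angle in radians,
    measured from the row (axial) axis, modulo pi.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"mask must contain at least 10 pixels, got {n}")
    if np.isscalar(pixel_spacing_mm):
        dr = dc = float(pixel_spacing_mm)
    else:
        dr, dc = (float(v) for v in pixel_spacing_mm)
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows * dr, cols * dc])
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / n
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("degenerate (collinear) mask")
    semi = 2.0 * np.sqrt(evals)  # filled-ellipse variance = a^2/4
    area = n * dr * dc
    scale = np.sqrt(area / (np.pi * semi[0] * semi[1]))
    semi *= scale
    major_vec = evecs[:, 1]
    orientation = float(np.arctan2(major_vec[1], major_vec[0]) % np.pi)
    return float(semi[0]), float(semi[1]), orientation
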