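"""Per-pixel exponential fitting of creep strain curves.

The creep model s(t) = eta + (alpha - eta) * exp(-t/tau) is linear in
(eta, alpha - eta) once tau is fixed, so it is fitted by variable
projection: for each candidate tau the linear coefficients are solved in
closed form against the basis {1, exp(-t/tau)} and tau itself is found
by one-dimensional minimisation of the projected residual (log-spaced
grid scan followed by golden-section refinement).

Strain-vs-time stacks are optionally denoised first by truncated SVD of
the pixels-by-time data matrix (empirical orthogonal functions), and
time-constant maps are cleaned with the fixed outlier rule: in-mask
pixels with tau > 100 s are replaced by the in-mask median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .phantom_forward import StrainFieldSeries

__all__ = [
    "ExponentialFit",
    "ParameterMaps",
    "eof_denoise",
    "varpro_fit",
    "fit_field",
    "replace_tc_outliers",
    "strain_bound_coefficient",
    "TC_OUTLIER_THRESHOLD_S",
]

logger = logging.getLogger(__name__)

#: time-constant outlier threshold inside the inclusion [s]
TC_OUTLIER_THRESHOLD_S = 100.0

#: points in the log-spaced tau scan
_TAU_GRID_POINTS = 160
#: golden-section iterations for tau refinement
_GOLDEN_ITERS = 48
_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ExponentialFit:
    """Per-curve creep fit: strain at 0+, steady state, time constant."""

    alpha: float
    eta: float
    tau: float
    rss: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not self.tau > 0:
            raise ValueError("tau must be positive for a non-degenerate fit")
        if self.rss < -0.0:
            raise ValueError("rss must be non-negative")

    @property
    def transient_magnitude(self) -> float:
        """|eta - alpha|, the total transient swing bounding the error
        of using s(t) in place of the steady state."""
        return abs(self.eta - self.alpha)


@dataclass
class ParameterMaps:
    """Pixel maps of the exponential-fit parameters over one window."""

    alpha_map: np.ndarray
    eta_map: np.ndarray
    tau_map: np.ndarray
    window_len_s: float
    mask: np.ndarray
    rss_map: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.alpha_map.shape, self.eta_map.shape, self.tau_map.shape}
        if len(shapes) != 1:
            raise ValueError("parameter maps must share shape")
        if self.mask.shape != self.alpha_map.shape:
            raise ValueError("mask shape must match maps")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("alpha", data=self.alpha_map)
            f.create_dataset("eta", data=self.eta_map)
            f.create_dataset("tau", data=self.tau_map)
            f.create_dataset("mask", data=self.mask)
            f.attrs["window_len_s"] = self.window_len_s

    @classmethod
    def load(cls, path) -> "ParameterMaps":
        with h5py.File(path, "r") as f:
            return cls(
                alpha_map=f["alpha"][:],
                eta_map=f["eta"][:],
                tau_map=f["tau"][:],
                mask=f["mask"][:].astype(bool),
                window_len_s=float(f.attrs["window_len_s"]),
            )


def strain_bound_coefficient(t_over_tau: float) -> float:
    """Fraction of the creep transient remaining after t/tau time units.

    This is exp(-t/tau): the worst-case deviation of s(t) from the
    steady state eta is this fraction of the total transient swing, so
    observing for 2 time constants leaves at most 13.5% of it.
    """
    t = np.asarray(t_over_tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("t/tau must be non-negative")
    out = np.exp(-t)
    return float(out) if np.isscalar(t_over_tau) else out


def eof_denoise(series: StrainFieldSeries, n_modes: int = 3) -> StrainFieldSeries:
    """Truncated-SVD (empirical orthogonal function) denoising.

    Each strain stack is reshaped to (time x pixels) and replaced by its
    rank-``n_modes`` approximation.  The retained-energy fraction per
    stack is stored in ``meta['eof_energy']``.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    out = series.copy()
    energy: dict[str, float] = {}
    for name in ("axial", "lateral"):
        stack = getattr(series, name)
        T = stack.shape[0]
        X = stack.reshape(T, -1)
        if n_modes > min(X.shape):
            raise ValueError(
                f"n_modes={n_modes} exceeds the data rank bound {min(X.shape)}"
            )
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        Xr = U[:, :n_modes] @ (s[:n_modes, None] * Vt[:n_modes])
        setattr(out, name, Xr.reshape(stack.shape))
        total = float(np.sum(s**2))
        energy[name] = float(np.sum(s[:n_modes] ** 2) / total) if total > 0 else 1.0
    out.meta["eof_energy"] = energy
    logger.debug("EOF retained energy: %s", energy)
    return out


def _rss_for_taus(taus: np.ndarray, t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Projected residual of the varpro fit.

    ``taus`` has one entry per pixel (shape P), ``Y`` is (P, N).
    Returns rss per pixel; linear coefficients are solved in closed form
    from the 2x2 normal equations of the basis {1, exp(-t/tau)}.
    """
    E = np.exp(-t[None, :] / taus[:, None])
    n = t.size
    Se = E.sum(axis=1)
    See = (E * E).sum(axis=1)
    Sy = Y.sum(axis=1)
    Sey = (E * Y).sum(axis=1)
    Syy = (Y * Y).sum(axis=1)
    det = n * See - Se * Se
    det = np.where(det <= 0, np.finfo(float).tiny, det)
    c0 = (See * Sy - Se * Sey) / det  # eta
    c1 = (n * Sey - Se * Sy) / det  # alpha - eta
    rss = Syy - c0 * Sy - c1 * Sey
    return np.maximum(rss, 0.0), c0, c1


def _tau_bracket(t: np.ndarray) -> tuple[float, float]:
    window = float(t[-1] - t[0])
    return 0.1 * window, 10.0 * window


def _fit_curves(
    t: np.ndarray, Y: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised varpro fit of many curves sharing one time vector.

    Returns (alpha, eta, tau, rss, degenerate) arrays of shape (P,).
    """
    P = Y.shape[0]
    rng_vals = Y.max(axis=1) - Y.min(axis=1)
    degenerate = rng_vals < tol
    alpha = np.full(P, np.nan)
    eta = np.full(P, np.nan)
    tau = np.full(P, np.nan)
    rss = np.zeros(P)
    if degenerate.any():
        eta[degenerate] = Y[degenerate].mean(axis=1)
        alpha[degenerate] = eta[degenerate]
        rss[degenerate] = ((Y[degenerate] - eta[degenerate, None]) ** 2).sum(axis=1)
    live = ~degenerate
    if not live.any():
        return alpha, eta, tau, rss, degenerate
    Yl = Y[live]
    lo, hi = _tau_bracket(t)
    grid = np.geomspace(lo, hi, _TAU_GRID_POINTS)
    n_live = Yl.shape[0]
    best_rss = np.full(n_live, np.inf)
    best_idx = np.zeros(n_live, dtype=int)
    for i, tv in enumerate(grid):
        r, _, _ = _rss_for_taus(np.full(n_live, tv), t, Yl)
        better = r < best_rss
        best_rss[better] = r[better]
        best_idx[better] = i
    # golden-section refinement in log tau between the neighbours of the
    # best grid point
    llo = np.log(grid[np.maximum(best_idx - 1, 0)])
    lhi = np.log(grid[np.minimum(best_idx + 1, grid.size - 1)])
    a, b = llo.copy(), lhi.copy()
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, _, _ = _rss_for_taus(np.exp(c), t, Yl)
    fd, _, _ = _rss_for_taus(np.exp(d), t, Yl)
    for _ in range(_GOLDEN_ITERS):
        left = fc < fd  # minimum lies in [a, d]
        b_new = np.where(left, d, b)
        a_new = np.where(left, a, c)
        c_new = np.where(left, b_new - _INVPHI * (b_new - a_new), d)
        d_new = np.where(left, c, a_new + _INVPHI * (b_new - a_new))
        probe = np.where(left, c_new, d_new)
        fe, _, _ = _rss_for_taus(np.exp(probe), t, Yl)
        fc, fd = np.where(left, fe, fd), np.where(left, fc, fe)
        a, b, c, d = a_new, b_new, c_new, d_new
    tau_live = np.exp((a + b) / 2.0)
    r, c0, c1 = _rss_for_taus(tau_live, t, Yl)
    alpha[live] = c0 + c1
    eta[live] = c0
    tau[live] = tau_live
    rss[live] = r
    return alpha, eta, tau, rss, degenerate


def varpro_fit(
    times: np.ndarray, values: np.ndarray, tol: float = 1e-12
) -> ExponentialFit:
    """Fit one strain-vs-time curve by variable projection.

    ``tol`` is the dynamic-range floor: if max - min of ``values`` falls
    below it the curve is flagged degenerate, eta is set to the mean and
    tau to NaN.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size < 4:
        raise ValueError("at least 4 samples are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t0 = t - t[0]
    alpha, eta, tau, rss, degenerate = _fit_curves(t0, y[None, :], tol)
    return ExponentialFit(
        alpha=float(alpha[0]),
        eta=float(eta[0]),
        tau=float(tau[0]),
        rss=float(rss[0]),
        degenerate=bool(degenerate[0]),
    )


def fit_field(
    series: StrainFieldSeries,
    window_len_s: float,
    mask: np.ndarray | None = None,
    which: str = "axial",
    tol: float = 1e-12,
    chunk_pixels: int = 20_000,
) -> ParameterMaps:
    """Fit the creep model per pixel over a window of observation.

    The series is truncated to t - t0 <= ``window_len_s`` and every
    pixel selected by ``mask`` (default: all) is fitted independently.
    ``which`` selects the axial or lateral strain stack.  Degenerate
    pixels yield NaN tau.
    """
    stack = getattr(series, which)
    t = series.times - series.times[0]
    keep = t <= window_len_s * (1 + 1e-9)
    if keep.sum() < 10:
        raise ValueError(
            f"window {window_len_s}s keeps only {int(keep.sum())} samples (< 10)"
        )
    t = t[keep]
    stack = stack[keep]
    shape = stack.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    Y = stack.reshape(stack.shape[0], -1).T[idx]

    alpha_map = np.full(shape, np.nan).ravel()
    eta_map = np.full(shape, np.nan).ravel()
    tau_map = np.full(shape, np.nan).ravel()
    rss_map = np.full(shape, np.nan).ravel()
    n_degenerate = 0
    for start in range(0, idx.size, chunk_pixels):
        sl = slice(start, start + chunk_pixels)
        a, e, ta, r, dg = _fit_curves(t, Y[sl], tol)
        alpha_map[idx[sl]] = a
        eta_map[idx[sl]] = e
        tau_map[idx[sl]] = ta
        rss_map[idx[sl]] = r
        n_degenerate += int(dg.sum())
    if n_degenerate:
        logger.info("fit_field: %d degenerate pixels (tau = NaN)", n_degenerate)
    return ParameterMaps(
        alpha_map=alpha_map.reshape(shape),
        eta_map=eta_map.reshape(shape),
        tau_map=tau_map.reshape(shape),
        window_len_s=float(window_len_s),
        mask=np.asarray(mask, dtype=bool),
        rss_map=rss_map.reshape(shape),
        meta={"which": which, "n_degenerate": n_degenerate},
    )


def replace_tc_outliers(
    tau_map: np.ndarray,
    mask: np.ndarray,
    threshold_s: float = TC_OUTLIER_THRESHOLD_S,
) -> np.ndarray:
    """Replace in-mask time-constant outliers by the in-mask median.

    Pixels inside ``mask`` with tau > ``threshold_s`` or NaN are set to
    the median of the remaining in-mask values.  The 100 s default is
    the fixed rule used for inclusion maps; a different threshold is
    logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if threshold_s != TC_OUTLIER_THRESHOLD_S:
        logger.info(
            "replace_tc_outliers: non-default threshold %.3g s", threshold_s
        )
    out = np.array(tau_map, dtype=float, copy=True)
    vals = out[mask]
    bad = ~np.isfinite(vals) | (vals > threshold_s)
    if bad.all():
        raise ValueError("all in-mask time constants are outliers")
    if bad.any():
        med = float(np.median(vals[~bad]))
        vals[bad] = med
        out[mask] = vals
        logger.info(
            "replace_tc_outliers: replaced %d/%d pixels with median %.3g s",
            int(bad.sum()),
            int(mask.sum()),
            med,
        )
    return out
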