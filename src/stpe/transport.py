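"""Vascular-permeability estimation and experimental conversions.

Inside a tumour the creep strain time constant is set by drainage
through the capillary walls: tau = 1/(H_A * chi) with microfiltration
coefficient chi = L_p * S/V, where L_p is the vascular permeability
(hydraulic conductivity) and S/V the capillary surface-to-volume ratio.
Inverting this with the fitted tau and the reconstructed Young's
modulus / Poisson's ratio of the inclusion yields L_p.

Also provided: the tumour-volume regression S/V = 10 * f * V_t^g
(f = 54.68, g = -0.2021, V_t in mm^3, S/V in 1/cm) used when S/V is not
known a priori, and the force-sensor reading -> applied stress
conversion sigma0 = F_r * 4.4 / (255 * A_r) for the 0-4.4 N, 0-255
count sensor with sensing area A_r = 7.1331e-5 m^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom_forward import aggregate_modulus
from .temporal_fit import replace_tc_outliers

__all__ = [
    "TumorGeometry",
    "AppliedStress",
    "surface_to_volume",
    "applied_stress",
    "vascular_permeability",
    "vp_map",
    "SENSOR_AREA_M2",
    "SENSOR_FULL_SCALE_N",
]

logger = logging.getLogger(__name__)

SENSOR_AREA_M2 = 7.1331e-5
SENSOR_FULL_SCALE_N = 4.4
_SV_F = 54.68
_SV_G = -0.2021


@dataclass(frozen=True)
class TumorGeometry:
    """Best-fit ellipsoid of a tumour and the derived S/V ratio.

    The third (elevational) semi-axis is taken equal to the minor one,
    so V_t = (4/3) * pi * l1^2 * l2 with l1, l2 in mm.
    """

    l1_mm: float
    l2_mm: float

    def __post_init__(self) -> None:
        if self.l1_mm <= 0 or self.l2_mm <= 0:
            raise ValueError("semi-axes must be positive")
        if self.l1_mm > self.l2_mm:
            raise ValueError("l1 must be the minor semi-axis (l1 <= l2)")

    @property
    def Vt_mm3(self) -> float:
        return (4.0 / 3.0) * np.pi * self.l1_mm**2 * self.l2_mm

    @property
    def SV_cm1(self) -> float:
        return surface_to_volume(self.l1_mm, self.l2_mm)[0]

    @property
    def SV_m1(self) -> float:
        return surface_to_volume(self.l1_mm, self.l2_mm)[1]


@dataclass(frozen=True)
class AppliedStress:
    """Raw force-sensor reading and the stress it converts to."""

    Fr: float

    def __post_init__(self) -> None:
        if not 0 <= self.Fr <= 255:
            raise ValueError(f"sensor reading must be in [0, 255], got {self.Fr}")

    @property
    def sigma0_pa(self) -> float:
        return applied_stress(self.Fr)


def surface_to_volume(l1_mm: float, l2_mm: float) -> tuple[float, float]:
    """Capillary S/V from the tumour's best-fit ellipsoid semi-axes.

    Empirical allometric regression on tumour volume:
    S/V [1/cm] = 10 * 54.68 * V_t^(-0.2021) with V_t in mm^3.
    Returns ``(SV_cm1, SV_m1)``; 1 cm^-1 = 100 m^-1.
    """
    if l1_mm <= 0 or l2_mm <= 0:
        raise ValueError("semi-axes must be positive")
    Vt = (4.0 / 3.0) * np.pi * l1_mm**2 * l2_mm
    sv_cm = 10.0 * _SV_F * Vt**_SV_G
    return float(sv_cm), float(100.0 * sv_cm)


def applied_stress(Fr: float) -> float:
    """Applied axial stress [Pa] from a 0-255 force-sensor count."""
    if not 0 <= Fr <= 255:
        raise ValueError(f"sensor reading must be in [0, 255], got {Fr}")
    return Fr * SENSOR_FULL_SCALE_N / (255.0 * SENSOR_AREA_M2)


def vascular_permeability(
    tau_s: float, E_pa: float, nu: float, SV_m1: float
) -> float:
    """Vascular permeability L_p = 1/(tau * H_A * S/V) [m/(Pa s)].

    ``SV_m1`` must be in 1/m (use :func:`surface_to_volume` for the
    explicit cm->m conversion).  A NaN tau (degenerate fit) propagates
    to NaN.
    """
    if SV_m1 <= 0:
        raise ValueError("S/V must be positive and in units of 1/m")
    if np.isnan(tau_s):
        return float("nan")
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / (tau_s * aggregate_modulus(E_pa, nu) * SV_m1)


def vp_map(
    tau_map: np.ndarray,
    E_map: np.ndarray | float,
    nu_map: np.ndarray | float,
    SV_m1: float,
    mask: np.ndarray,
    replace_outliers: bool = True,
    include_background: bool = False,
) -> np.ndarray:
    """Per-pixel vascular permeability inside the inclusion mask.

    The tau map is first cleaned with the in-mask outlier rule, then
    L_p = 1/(tau * H_A(E, nu) * S/V) is applied pixel-wise.  Pixels
    outside the mask are NaN unless ``include_background`` is set --
    the tau model assumes vascular drainage dominates, which may not
    hold in normal tissue, so background output is opt-in.
    """
    mask = np.asarray(mask, dtype=bool)
    tau = np.array(tau_map, dtype=float, copy=True)
    if replace_outliers:
        tau = replace_tc_outliers(tau, mask)
    E = np.broadcast_to(np.asarray(E_map, dtype=float), tau.shape)
    nu = np.broadcast_to(np.asarray(nu_map, dtype=float), tau.shape)
    if np.nanmax(nu) >= 0.5:
        raise ValueError("Poisson's ratio map contains values >= 0.5")
    with np.errstate(divide="ignore", invalid="ignore"):
        HA = E * (1.0 - nu) / ((1.0 - 2.0 * nu) * (1.0 + nu))
        lp = 1.0 / (tau * HA * SV_m1)
    out = np.full(tau.shape, np.nan)
    region = mask if not include_background else np.ones_like(mask)
    if include_background:
        warnings.warn(
            "background vascular permeability assumes chi >> k/a^2, which "
            "may not hold in normal tissue",
            RuntimeWarning,
            stacklevel=2,
        )
    out[region] = lp[region]
    n_nan = int(np.sum(~np.isfinite(out[mask])))
    if n_nan:
        logger.info("vp_map: %d non-finite pixels inside the mask", n_nan)
    return out
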