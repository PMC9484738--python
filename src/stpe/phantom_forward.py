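"""Ground-truth creep strain movies for inclusion phantoms.

A cylindrical poroelastic sample containing a spherical or spheroidal
inclusion is held under constant uniaxial stress.  Immediately after
loading the tissue behaves as an incompressible solid (effective
Poisson's ratio ~0.5); as fluid leaves the vasculature the strains relax
exponentially toward the drained elastic state.  Each pixel follows the
first-order creep model

    s(t) = eta + (alpha - eta) * exp(-t / tau)

where ``alpha`` is the strain at t = 0+, ``eta`` the steady-state strain
and ``tau`` the strain time constant.  The spatial fields ``alpha`` and
``eta`` come from the analytic Eshelby interior/far-field solution
evaluated at the undrained (nu ~ 0.5) and drained material parameters
respectively; ``tau`` follows from the region's aggregate modulus and
microfiltration coefficient, tau = 1/(H_A * L_p * S/V).

Sign convention: axial strain is stored as a positive compression
magnitude and lateral strain as a positive expansion magnitude, so all
creep curves vary monotonically and the lateral/axial ratio is a
positive effective Poisson's ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .inversion import eshelby_tensor, equivalent_inclusion_strain

__all__ = [
    "MaterialParams",
    "PhantomSpec",
    "StrainFieldSeries",
    "aggregate_modulus",
    "strain_time_constant",
    "eshelby_forward_strain",
    "generate_strain_series",
    "add_strain_noise",
    "save_strain_series",
    "load_strain_series",
]

#: effective Poisson's ratio of the instantaneous (undrained) response;
#: 0.499 rather than 0.5 to keep the aggregate modulus finite
NU_UNDRAINED = 0.499


@dataclass(frozen=True)
class MaterialParams:
    """Poroelastic material parameters of one region.

    E : Young's modulus [Pa]; nu : Poisson's ratio; Lp : vascular
    permeability (hydraulic conductivity of capillary walls)
    [m/(Pa s)]; k : interstitial permeability [m^2/(Pa s)].
    """

    E: float
    nu: float
    Lp: float = 0.0
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not 0 <= self.nu < 0.5:
            raise ValueError(f"Poisson's ratio must be in [0, 0.5), got {self.nu}")
        if self.Lp < 0 or self.k < 0:
            raise ValueError("permeabilities must be non-negative")


@dataclass
class PhantomSpec:
    """Geometry, materials and acquisition timing of a phantom.

    Defaults mirror a 20 x 40 mm solution plane with a 7.5 mm diameter
    spherical inclusion under 1 kPa creep stress, capillary-wall
    surface-to-volume ratio 20,000 1/m, recorded for 60 s at 0.1 s.
    """

    inclusion: MaterialParams
    background: MaterialParams
    plane_lateral_mm: float = 20.0
    plane_axial_mm: float = 40.0
    inclusion_shape: str = "sphere"
    semi_axis_lateral_mm: float = 3.75
    semi_axis_axial_mm: float = 3.75
    center_mm: tuple[float, float] = (10.0, 20.0)  # (lateral, axial)
    SV: float = 20_000.0  # capillary surface-to-volume ratio, 1/m
    sigma0: float = 1000.0  # applied axial stress magnitude, Pa (compression)
    duration_s: float = 60.0
    dt_s: float = 0.1
    grid_pixels_per_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.inclusion_shape not in ("sphere", "spheroid"):
            raise ValueError("inclusion_shape must be 'sphere' or 'spheroid'")
        if self.inclusion_shape == "sphere":
            if self.semi_axis_axial_mm != self.semi_axis_lateral_mm:
                raise ValueError("a sphere needs equal semi-axes")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 is a compression magnitude and must be > 0")
        cx, cz = self.center_mm
        if (
            cx - self.semi_axis_lateral_mm < 0
            or cx + self.semi_axis_lateral_mm > self.plane_lateral_mm
            or cz - self.semi_axis_axial_mm < 0
            or cz + self.semi_axis_axial_mm > self.plane_axial_mm
        ):
            raise ValueError("inclusion does not fit inside the plane")
        if self.duration_s / self.dt_s < 10:
            raise ValueError("duration/dt must yield at least 10 samples")

    @property
    def aspect(self) -> float:
        """Axial over lateral semi-axis ratio."""
        return self.semi_axis_axial_mm / self.semi_axis_lateral_mm

    def to_yaml(self) -> str:
        d = asdict(self)
        d["center_mm"] = list(self.center_mm)
        return yaml.safe_dump({"phantom": d}, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)["phantom"]
        d["inclusion"] = MaterialParams(**d["inclusion"])
        d["background"] = MaterialParams(**d["background"])
        d["center_mm"] = tuple(d["center_mm"])
        return cls(**d)


@dataclass
class StrainFieldSeries:
    """Time-stamped stacks of axial and lateral strain images.

    ``axial``/``lateral`` have shape (n_times, n_axial, n_lateral);
    axial strain is compression-positive, lateral expansion-positive.
    ``pixel_spacing_mm`` is (axial, lateral) pixel pitch.
    """

    times: np.ndarray
    axial: np.ndarray
    lateral: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    inclusion_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axial.shape != self.lateral.shape:
            raise ValueError("axial and lateral stacks must share shape")
        if len(self.times) != self.axial.shape[0]:
            raise ValueError("times length must match stack depth")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.inclusion_mask.shape != self.axial.shape[1:]:
            raise ValueError("mask shape must match image shape")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def copy(self) -> "StrainFieldSeries":
        return StrainFieldSeries(
            times=self.times.copy(),
            axial=self.axial.copy(),
            lateral=self.lateral.copy(),
            pixel_spacing_mm=self.pixel_spacing_mm,
            inclusion_mask=self.inclusion_mask.copy(),
            meta=dict(self.meta),
        )


def aggregate_modulus(E: float, nu: float) -> float:
    """Confined-compression (aggregate) modulus H_A = E(1-nu)/((1-2nu)(1+nu)).

    H_A >= E on [0, 0.5) with equality at nu = 0; diverges at the
    incompressible limit nu = 0.5.
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not 0 <= nu < 0.5:
        raise ValueError(
            f"Poisson's ratio must be in [0, 0.5) (H_A diverges at 0.5), got {nu}"
        )
    return E * (1.0 - nu) / ((1.0 - 2.0 * nu) * (1.0 + nu))


def strain_time_constant(mat: MaterialParams, SV: float, a: float = 3.75e-3) -> float:
    """Creep strain time constant tau = 1/(H_A * chi), chi = Lp * S/V.

    ``a`` is the inclusion radius in metres, used only to check the
    underlying assumption chi >> k/a^2 (vascular drainage dominates
    interstitial flow); a warning is raised when chi < 10 * k/a^2.
    """
    if mat.Lp == 0 or SV == 0:
        raise ValueError("Lp = 0 or S/V = 0 gives an infinite time constant")
    if SV < 0:
        raise ValueError("S/V must be positive")
    chi = mat.Lp * SV
    if mat.k > 0 and a > 0 and chi < 10.0 * mat.k / a**2:
        warnings.warn(
            "chi = Lp*S/V is not large against k/a^2; the single-exponential "
            "time-constant model may be invalid for this region",
            RuntimeWarning,
            stacklevel=2,
        )
    return 1.0 / (aggregate_modulus(mat.E, mat.nu) * chi)


def eshelby_forward_strain(
    bg: MaterialParams,
    inc: MaterialParams,
    shape: float | str = "sphere",
    sigma0: float = 1000.0,
) -> tuple[float, float, float, float]:
    """Uniform interior and far-field strains under remote uniaxial stress.

    Returns ``(eps_zz_in, eps_rr_in, eps_zz_bg, eps_rr_bg)`` as positive
    magnitudes (axial compression, lateral expansion).  The interior
    strain comes from the equivalent-inclusion solution
    eps_in = eps0 + S . eps*; the far field is the homogeneous uniaxial
    solution eps_zz = sigma0/E_b, eps_rr = nu_b * eps_zz.
    """
    aspect = 1.0 if shape == "sphere" else float(shape)
    S_normal = eshelby_tensor(bg.nu, aspect).normal_block()
    eps_zz0 = -sigma0 / bg.E
    eps0 = np.array([-bg.nu * eps_zz0, -bg.nu * eps_zz0, eps_zz0])
    eps_in, _ = equivalent_inclusion_strain(
        bg.E, bg.nu, inc.E, inc.nu, S_normal, eps0
    )
    return (-float(eps_in[2]), float(eps_in[0]), -eps_zz0, -bg.nu * eps_zz0)


def _region_curve(alpha: float, eta: float, tau: float, times: np.ndarray) -> np.ndarray:
    return eta + (alpha - eta) * np.exp(-times / tau)


def generate_strain_series(spec: PhantomSpec) -> StrainFieldSeries:
    """Analytic creep strain movie for a phantom.

    Steady-state fields use the drained Eshelby solution; the t = 0+
    fields recompute it with both regions at the undrained effective
    Poisson's ratio 0.499 (same Young's moduli).  Each region relaxes
    with its own tau = 1/(H_A * Lp * S/V).
    """
    g = spec.grid_pixels_per_mm
    nx = int(round(spec.plane_lateral_mm * g))
    nz = int(round(spec.plane_axial_mm * g))
    dx = 1.0 / g
    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dx
    cx, cz = spec.center_mm
    X, Z = np.meshgrid(x, z)
    mask = (
        ((X - cx) / spec.semi_axis_lateral_mm) ** 2
        + ((Z - cz) / spec.semi_axis_axial_mm) ** 2
    ) <= 1.0

    shape_arg = "sphere" if spec.inclusion_shape == "sphere" else spec.aspect
    eta_zz_in, eta_rr_in, eta_zz_bg, eta_rr_bg = eshelby_forward_strain(
        spec.background, spec.inclusion, shape_arg, spec.sigma0
    )
    und_bg = MaterialParams(E=spec.background.E, nu=NU_UNDRAINED)
    und_in = MaterialParams(E=spec.inclusion.E, nu=NU_UNDRAINED)
    alp_zz_in, alp_rr_in, alp_zz_bg, alp_rr_bg = eshelby_forward_strain(
        und_bg, und_in, shape_arg, spec.sigma0
    )

    a_m = spec.semi_axis_lateral_mm * 1e-3
    tau_in = strain_time_constant(spec.inclusion, spec.SV, a_m)
    tau_bg = strain_time_constant(spec.background, spec.SV, a_m)

    times = np.arange(0.0, spec.duration_s + spec.dt_s / 2, spec.dt_s)
    curves = {
        "ax_in": _region_curve(alp_zz_in, eta_zz_in, tau_in, times),
        "lat_in": _region_curve(alp_rr_in, eta_rr_in, tau_in, times),
        "ax_bg": _region_curve(alp_zz_bg, eta_zz_bg, tau_bg, times),
        "lat_bg": _region_curve(alp_rr_bg, eta_rr_bg, tau_bg, times),
    }
    m = mask[None, :, :]
    axial = curves["ax_bg"][:, None, None] * (~m) + curves["ax_in"][:, None, None] * m
    lateral = (
        curves["lat_bg"][:, None, None] * (~m) + curves["lat_in"][:, None, None] * m
    )
    meta = {
        "sigma0_pa": spec.sigma0,
        "SV_per_m": spec.SV,
        "tau_inclusion_s": tau_in,
        "tau_background_s": tau_bg,
        "eta": {
            "zz_in": eta_zz_in,
            "rr_in": eta_rr_in,
            "zz_bg": eta_zz_bg,
            "rr_bg": eta_rr_bg,
        },
        "alpha": {
            "zz_in": alp_zz_in,
            "rr_in": alp_rr_in,
            "zz_bg": alp_zz_bg,
            "rr_bg": alp_rr_bg,
        },
        "spec": spec,
    }
    return StrainFieldSeries(
        times=times,
        axial=axial,
        lateral=lateral,
        pixel_spacing_mm=(dx, dx),
        inclusion_mask=mask,
        meta=meta,
    )


def add_strain_noise(
    series: StrainFieldSeries, snr_db: float, seed: int
) -> StrainFieldSeries:
    """Add zero-mean Gaussian noise at a prescribed SNR to both stacks.

    The noise standard deviation is set from the rms of each stack so
    that 20*log10(rms(signal)/rms(noise)) equals ``snr_db``.  An
    infinite ``snr_db`` returns an identical copy.
    """
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return series.copy()
        raise ValueError("snr_db must be finite or +inf")
    out = series.copy()
    rng = np.random.default_rng(seed)
    for name in ("axial", "lateral"):
        stack = getattr(out, name)
        sigma = np.sqrt(np.mean(stack**2)) / 10.0 ** (snr_db / 20.0)
        stack += rng.normal(0.0, sigma, size=stack.shape)
    out.meta["snr_db"] = snr_db
    return out


def save_strain_series(path: str | Path, series: StrainFieldSeries) -> None:
    """Write a strain series to HDF5 (+ YAML phantom spec if present)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=series.times)
        f.create_dataset("axial", data=series.axial, compression="gzip")
        f.create_dataset("lateral", data=series.lateral, compression="gzip")
        f.create_dataset("mask", data=series.inclusion_mask)
        f.attrs["pixel_spacing_mm"] = series.pixel_spacing_mm
        f.attrs["sigma0_pa"] = series.meta.get("sigma0_pa", np.nan)
        f.attrs["SV_per_m"] = series.meta.get("SV_per_m", np.nan)
    spec = series.meta.get("spec")
    if isinstance(spec, PhantomSpec):
        path.with_suffix(".yaml").write_text(spec.to_yaml())


def load_strain_series(path: str | Path) -> StrainFieldSeries:
    """Read a strain series written by :func:`save_strain_series`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        series = StrainFieldSeries(
            times=f["times"][:],
            axial=f["axial"][:],
            lateral=f["lateral"][:],
            pixel_spacing_mm=tuple(f.attrs["pixel_spacing_mm"]),
            inclusion_mask=f["mask"][:].astype(bool),
            meta={
                "sigma0_pa": float(f.attrs["sigma0_pa"]),
                "SV_per_m": float(f.attrs["SV_per_m"]),
            },
        )
    yaml_path = path.with_suffix(".yaml")
    if yaml_path.exists():
        series.meta["spec"] = PhantomSpec.from_yaml(yaml_path.read_text())
    return series
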