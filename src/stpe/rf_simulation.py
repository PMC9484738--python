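"""Convolution-model ultrasound RF simulation.

Pre- and post-compression RF frames are synthesised by convolving a
random scatterer (speckle) field with the separable point-spread
function of a linear-array transducer: axially a Gaussian-enveloped
cosine at the centre frequency whose amplitude spectrum has the
prescribed -6 dB fractional bandwidth, laterally a Gaussian whose
-6 dB full width equals the beamwidth at focus.  Scatterers are moved
by bilinear interpolation of the mechanical displacement fields and
Gaussian noise of a prescribed SNR is added to every frame.

Image convention: frames are (n_lines, n_samples) with axis 0 lateral
(beam lines, pitch ``line_pitch_mm``) and axis 1 axial (fast time,
sample pitch c/(2 fs)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

__all__ = [
    "TransducerSpec",
    "ScattererField",
    "RFFrameSeries",
    "make_scatterer_field",
    "make_psf",
    "displace_scatterers",
    "synthesize_rf",
    "displacement_movie_from_strain",
    "simulate_rf_series",
]

logger = logging.getLogger(__name__)

SPEED_OF_SOUND_M_S = 1540.0


@dataclass(frozen=True)
class TransducerSpec:
    """Linear-array acquisition parameters (defaults: 38 mm array,
    6.6 MHz centre frequency, 50% fractional bandwidth at -6 dB,
    40 MHz sampling, ~1 mm beamwidth at focus)."""

    fc: float = 6.6e6
    fbw: float = 0.5
    fs: float = 40e6
    beamwidth_mm: float = 1.0
    aperture_mm: float = 38.0
    n_lines: int = 128
    line_pitch_mm: float = 38.0 / 128.0
    c: float = SPEED_OF_SOUND_M_S

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.fc * (1.0 + self.fbw):
            raise ValueError("sampling frequency violates the Nyquist margin")
        if self.beamwidth_mm <= 0:
            raise ValueError("beamwidth must be positive")

    @property
    def sample_pitch_mm(self) -> float:
        """Axial distance between RF samples (two-way travel)."""
        return self.c / (2.0 * self.fs) * 1e3

    @property
    def resolution_cell_mm2(self) -> float:
        """Nominal resolution-cell area: beamwidth x bandwidth-limited
        axial pulse length c/(2 B)."""
        pulse_len_mm = self.c / (2.0 * self.fbw * self.fc) * 1e3
        return self.beamwidth_mm * pulse_len_mm


@dataclass
class ScattererField:
    """Point scatterers: continuous (lateral, axial) positions in mm and
    unitless reflectivity amplitudes."""

    positions: np.ndarray  # (n, 2): lateral x, axial z [mm]
    amplitudes: np.ndarray
    extent_mm: tuple[float, float]  # (lateral, axial)

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if self.amplitudes.shape != (self.positions.shape[0],):
            raise ValueError("amplitudes must match positions")

    def copy(self) -> "ScattererField":
        return ScattererField(
            self.positions.copy(), self.amplitudes.copy(), self.extent_mm
        )


@dataclass
class RFFrameSeries:
    """RF frames aligned with a strain movie.

    ``reference`` is the undeformed (pre-compression) frame; ``frames``
    [shape (T, n_lines, n_samples)] follow the creep deformation at
    ``times``.
    """

    times: np.ndarray
    frames: np.ndarray
    reference: np.ndarray
    spec: TransducerSpec
    snr_db: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape[0] != len(self.times):
            raise ValueError("frame count must match times")
        if self.frames.shape[1:] != self.reference.shape:
            raise ValueError("all frames must share geometry")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("frames", data=self.frames, compression="gzip")
            f.create_dataset("reference", data=self.reference, compression="gzip")
            f.attrs["snr_db"] = self.snr_db
            for k in ("fc", "fbw", "fs", "beamwidth_mm", "line_pitch_mm", "c"):
                f.attrs[k] = getattr(self.spec, k)
            f.attrs["n_lines"] = self.spec.n_lines

    @classmethod
    def load(cls, path) -> "RFFrameSeries":
        with h5py.File(path, "r") as f:
            spec = TransducerSpec(
                fc=float(f.attrs["fc"]),
                fbw=float(f.attrs["fbw"]),
                fs=float(f.attrs["fs"]),
                beamwidth_mm=float(f.attrs["beamwidth_mm"]),
                n_lines=int(f.attrs["n_lines"]),
                line_pitch_mm=float(f.attrs["line_pitch_mm"]),
                c=float(f.attrs["c"]),
            )
            return cls(
                times=f["times"][:],
                frames=f["frames"][:],
                reference=f["reference"][:],
                spec=spec,
                snr_db=float(f.attrs["snr_db"]),
            )


def make_scatterer_field(
    extent_mm: tuple[float, float],
    density_per_cell: float = 10.0,
    seed: int = 0,
    spec: TransducerSpec | None = None,
) -> ScattererField:
    """Uniform random scatterers with standard-normal amplitudes.

    ``density_per_cell`` scatterers per resolution cell (default 10,
    enough for fully developed Rayleigh speckle).
    """
    if density_per_cell < 1:
        raise ValueError("density_per_cell must be >= 1")
    lat, ax = extent_mm
    if lat <= 0 or ax <= 0:
        raise ValueError("extent must have positive area")
    spec = spec or TransducerSpec()
    n = int(round(density_per_cell * lat * ax / spec.resolution_cell_mm2))
    rng = np.random.default_rng(seed)
    pos = rng.uniform([0.0, 0.0], [lat, ax], size=(n, 2))
    amp = rng.standard_normal(n)
    return ScattererField(positions=pos, amplitudes=amp, extent_mm=(lat, ax))


def _gauss_sigma_from_6db_width(full_width: float) -> float:
    # amplitude Gaussian: exp(-x^2/(2 s^2)) = 0.5 at x = half width
    return full_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_psf(spec: TransducerSpec) -> np.ndarray:
    """Separable PSF kernel (lateral lines x axial samples).

    Axial: cosine at fc under a Gaussian envelope whose amplitude
    spectrum has -6 dB full width fbw*fc.  Lateral: Gaussian with -6 dB
    full width equal to the focal beamwidth.  Truncated at +-3 sigma,
    odd-length, peak-normalised.
    """
    sigma_f = _gauss_sigma_from_6db_width(spec.fbw * spec.fc)
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    n_ax = int(np.ceil(3.0 * sigma_t * spec.fs))
    t = np.arange(-n_ax, n_ax + 1) / spec.fs
    axial = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.cos(2.0 * np.pi * spec.fc * t)

    sigma_x = _gauss_sigma_from_6db_width(spec.beamwidth_mm)
    n_lat = max(int(np.ceil(3.0 * sigma_x / spec.line_pitch_mm)), 1)
    xx = np.arange(-n_lat, n_lat + 1) * spec.line_pitch_mm
    lateral = np.exp(-(xx**2) / (2.0 * sigma_x**2))

    kernel = np.outer(lateral, axial)
    return kernel / np.abs(kernel).max()


def displace_scatterers(
    field: ScattererField,
    disp_axial_mm: np.ndarray,
    disp_lateral_mm: np.ndarray,
    lateral_coords_mm: np.ndarray,
    axial_coords_mm: np.ndarray,
) -> ScattererField:
    """Move scatterers by bilinearly interpolated displacements.

    The displacement maps are (n_axial, n_lateral) images on the grid
    (``axial_coords_mm``, ``lateral_coords_mm``).  Scatterers outside
    the map domain are clamped to the nearest edge value (count
    logged).  Amplitudes are preserved.
    """
    pts = field.positions
    x = pts[:, 0]
    z = pts[:, 1]
    outside = (
        (x < lateral_coords_mm[0])
        | (x > lateral_coords_mm[-1])
        | (z < axial_coords_mm[0])
        | (z > axial_coords_mm[-1])
    )
    if outside.any():
        logger.info(
            "displace_scatterers: %d scatterers clamped to the map edge",
            int(outside.sum()),
        )
    xq = np.clip(x, lateral_coords_mm[0], lateral_coords_mm[-1])
    zq = np.clip(z, axial_coords_mm[0], axial_coords_mm[-1])
    query = np.column_stack([zq, xq])
    interp_ax = RegularGridInterpolator(
        (axial_coords_mm, lateral_coords_mm), disp_axial_mm, method="linear"
    )
    interp_lat = RegularGridInterpolator(
        (axial_coords_mm, lateral_coords_mm), disp_lateral_mm, method="linear"
    )
    new_pos = pts + np.column_stack([interp_lat(query), interp_ax(query)])
    return ScattererField(new_pos, field.amplitudes.copy(), field.extent_mm)


def synthesize_rf(
    field: ScattererField,
    spec: TransducerSpec,
    snr_db: float = np.inf,
    seed: int = 0,
    n_lines: int | None = None,
    n_samples: int | None = None,
    noise_floor: float = 1.0,
) -> np.ndarray:
    """One RF frame: bin scatterers on the line/sample grid, convolve
    with the PSF, add Gaussian noise at ``snr_db``.

    For an empty field the output is pure noise with rms
    ``noise_floor``.  Bit-identical for identical inputs and seed.
    """
    lat_extent, ax_extent = field.extent_mm
    if n_lines is None:
        n_lines = int(round(lat_extent / spec.line_pitch_mm))
    if n_samples is None:
        n_samples = int(round(ax_extent / spec.sample_pitch_mm))
    grid = np.zeros((n_lines, n_samples))
    if field.positions.shape[0]:
        # bilinear splatting of the object field preserves sub-sample
        # scatterer positions (nearest-node binning would quantise the
        # displacement phase and alias into strain artefacts)
        lf = field.positions[:, 0] / spec.line_pitch_mm
        sf = field.positions[:, 1] / spec.sample_pitch_mm
        l0 = np.floor(lf).astype(int)
        s0 = np.floor(sf).astype(int)
        wl = lf - l0
        ws = sf - s0
        for dl, dsamp, w in (
            (0, 0, (1 - wl) * (1 - ws)),
            (0, 1, (1 - wl) * ws),
            (1, 0, wl * (1 - ws)),
            (1, 1, wl * ws),
        ):
            li = l0 + dl
            si = s0 + dsamp
            ok = (li >= 0) & (li < n_lines) & (si >= 0) & (si < n_samples)
            np.add.at(grid, (li[ok], si[ok]), field.amplitudes[ok] * w[ok])
    frame = fftconvolve(grid, make_psf(spec), mode="same")
    rms = float(np.sqrt(np.mean(frame**2)))
    if np.isfinite(snr_db):
        sigma = (rms if rms > 0 else noise_floor) / 10.0 ** (snr_db / 20.0)
        if rms == 0:
            sigma = noise_floor
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, sigma, size=frame.shape)
    return frame


def displacement_movie_from_strain(series) -> tuple[np.ndarray, np.ndarray]:
    """Mechanical displacement movies [mm] from a strain movie.

    Axial displacement is measured relative to the transducer face at
    z = 0: u_z(z) = -integral_0^z eps_zz dz' (compression-positive
    strain moves tissue toward the transducer with depth).  Lateral
    displacement expands symmetrically about the image centre line:
    u_x(x) = integral_xc^x eps_rr dx'.

    Returns ``(disp_axial_mm, disp_lateral_mm)`` of shape
    (T, n_axial, n_lateral).
    """
    dz, dx = series.pixel_spacing_mm
    eps_ax = series.axial
    eps_lat = series.lateral
    u_ax = -np.cumsum(eps_ax, axis=1) * dz
    u_lat = np.cumsum(eps_lat, axis=2) * dx
    centre = eps_lat.shape[2] // 2
    u_lat = u_lat - u_lat[:, :, centre : centre + 1]
    return u_ax, u_lat


def simulate_rf_series(
    series,
    spec: TransducerSpec | None = None,
    snr_db: float = 40.0,
    seed: int = 0,
    density_per_cell: float = 10.0,
) -> RFFrameSeries:
    """Full RF acquisition for a phantom strain movie.

    One scatterer field is drawn over the phantom extent; the reference
    frame images it undeformed, and each creep frame images it after
    displacement by the movie at that time.  Independent noise is drawn
    per frame from seeds spawned deterministically from ``seed``.
    """
    spec = spec or TransducerSpec()
    nz, nx = series.axial.shape[1:]
    dz, dx = series.pixel_spacing_mm
    extent = (nx * dx, nz * dz)
    z_coords = (np.arange(nz) + 0.5) * dz
    x_coords = (np.arange(nx) + 0.5) * dx
    u_ax, u_lat = displacement_movie_from_strain(series)

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(series.times) + 2)
    field = make_scatterer_field(
        extent, density_per_cell, seed=int(seeds[0] % 2**31), spec=spec
    )
    n_lines = int(round(extent[0] / spec.line_pitch_mm))
    n_samples = int(round(extent[1] / spec.sample_pitch_mm))
    reference = synthesize_rf(
        field, spec, snr_db, int(seeds[1] % 2**31), n_lines, n_samples
    )
    frames = np.empty((len(series.times), n_lines, n_samples))
    for j in range(len(series.times)):
        moved = displace_scatterers(field, u_ax[j], u_lat[j], x_coords, z_coords)
        frames[j] = synthesize_rf(
            moved, spec, snr_db, int(seeds[j + 2] % 2**31), n_lines, n_samples
        )
    return RFFrameSeries(
        times=series.times.copy(),
        frames=frames,
        reference=reference,
        spec=spec,
        snr_db=snr_db,
        meta={"extent_mm": extent},
    )
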