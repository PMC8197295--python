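"""Multi-view tomographic reconstruction from lenslet projection images.

Each lenslet records a parallel projection of the fluorophore distribution
O(x,y,z) along its viewing direction, blurred by the lenslet PSF:

    I_mn(x, y) = P_mn O * h.

Reconstruction inverts this by (1) Richardson-Lucy deconvolution of each
sub-image, (2) Fourier-slice inverse projection -- the 2D transform of each
projection is placed on the tilted central plane of the 3D Fourier volume
whose normal is parallel to the viewing direction, with gridding weights --
(3) weight-normalized 3D inverse transform, and (4) an alternating-projection
positivity constraint that refills part of the missing cone.

Geometry: z is the optical axis; volumes are indexed (z, y, x); the shear of
slice z for viewing angles (alpha, beta) is (z - z_c)(tan alpha, tan beta)
with z_c = nz // 2, so the Fourier plane of a projection is
k_z = -(k_x tan alpha + k_y tan beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from skimage.restoration import richardson_lucy as _skimage_rl

from .optics import LensletGrid, SystemConfig, ViewingAngle, viewing_angles

__all__ = [
    "ProjectionSet",
    "PSFModel",
    "Tomogram",
    "FourierVolume",
    "extract_lenslet_subimages",
    "richardson_lucy",
    "fourier_slice_insert",
    "invert_fourier_volume",
    "positivity_refine",
    "reconstruct",
    "measure_fwhm_3d",
]


@dataclass(frozen=True)
class PSFModel:
    """Isotropic blur kernel h(x, y) of one lenslet sub-image.

    ``kind="gaussian"`` (default) uses a Gaussian of the given FWHM, the
    lenslet diffraction limit at the working wavelength; ``kind="sinc2"``
    uses the separable sinc^2 pattern of the square lenslet aperture with
    the same first-zero scaling.  Kernels are non-negative and unit-sum.
    """

    fwhm_um: float
    kind: str = "gaussian"
    support_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm_um <= 0:
            raise ValueError("PSF FWHM must be positive")
        if self.kind not in ("gaussian", "sinc2"):
            raise ValueError("PSF kind must be 'gaussian' or 'sinc2'")

    @classmethod
    def from_config(cls, config: SystemConfig, wavelength_nm: float | None = None,
                    kind: str = "gaussian") -> "PSFModel":
        from .optics import lenslet_diffraction_limit

        return cls(lenslet_diffraction_limit(config, "width", wavelength_nm), kind)

    def kernel(self, pitch_um: float) -> np.ndarray:
        sigma_px = self.fwhm_um / 2.3548 / pitch_um
        half = max(2, int(math.ceil(self.support_sigmas * sigma_px)))
        ax = np.arange(-half, half + 1, dtype=float)
        if self.kind == "gaussian":
            g = np.exp(-0.5 * (ax / sigma_px) ** 2)
            k = np.outer(g, g)
        else:
            # first zero of sinc^2 at the diffraction-limit half-width scale
            arg = ax / (self.fwhm_um / pitch_um)
            s = np.sinc(arg) ** 2
            k = np.outer(s, s)
        return k / k.sum()

    def blur(self, image: np.ndarray, pitch_um: float) -> np.ndarray:
        return fftconvolve(image, self.kernel(pitch_um), mode="same")


@dataclass
class ProjectionSet:
    """Per-lenslet sub-images in sample-plane coordinates with their angles."""

    subimages: np.ndarray  # (n_views, side, side)
    angles: list[ViewingAngle]
    indices: list[tuple[float, float]]
    pitch_um: float

    def __post_init__(self) -> None:
        imgs = np.asarray(self.subimages, dtype=float)
        if imgs.ndim != 3:
            raise ValueError("subimages must be a (views, H, W) array")
        if imgs.shape[0] != len(self.angles):
            raise ValueError("one viewing angle required per sub-image")
        if self.indices and len(self.indices) != imgs.shape[0]:
            raise ValueError("one lenslet index required per sub-image")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        self.subimages = imgs

    def __len__(self) -> int:
        return self.subimages.shape[0]


@dataclass
class Tomogram:
    """Reconstructed 3D fluorescence intensity on an isotropic voxel grid."""

    data: np.ndarray
    voxel_um: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError("tomogram must be 3D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("tomogram must be finite")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        self.data = arr


@dataclass
class FourierVolume:
    """Accumulator for Fourier-slice insertions: complex values plus gridding
    weights on the (k_z, k_y, k_x) grid (numpy fft index order).

    The stored spectrum is referenced to z' = z - side//2 (the object's axial
    center at the z origin), which keeps it smooth in k_z so that linear
    gridding between k_z planes is accurate; ``invert_fourier_volume`` rolls
    the real-space result back to the centered convention."""

    values: np.ndarray
    weights: np.ndarray
    pitch_um: float

    @classmethod
    def empty(cls, side: int, pitch_um: float) -> "FourierVolume":
        return cls(
            np.zeros((side, side, side), dtype=complex),
            np.zeros((side, side, side)),
            pitch_um,
        )

    @property
    def side(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# forward helper shared with the simulator
# ---------------------------------------------------------------------------


def _fourier_shear_project(volume: np.ndarray, angle: ViewingAngle) -> np.ndarray:
    """Sum of z-slices sheared by (z - z_c)(tan alpha, tan beta), with the
    shifts applied as exact (periodic) Fourier phase ramps."""
    nz, ny, nx = volume.shape
    tan_a, tan_b = angle.tangents
    zc = nz // 2
    fx = np.fft.fftfreq(nx)[None, :]
    fy = np.fft.fftfreq(ny)[:, None]
    spectrum2d = np.zeros((ny, nx), dtype=complex)
    ft_slices = np.fft.fft2(volume, axes=(1, 2))
    for z in range(nz):
        sx = (z - zc) * tan_a
        sy = (z - zc) * tan_b
        # shifted slice g(x) = f(x + s) has spectrum F(k) exp(+2 pi i k s)
        spectrum2d += ft_slices[z] * np.exp(2j * np.pi * (fx * sx + fy * sy))
    return np.real(np.fft.ifft2(spectrum2d))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_lenslet_subimages(
    frame: np.ndarray,
    grid: LensletGrid,
    config: SystemConfig,
    subimage_px: int | None = None,
    origin: tuple[int, int] = (0, 0),
) -> ProjectionSet:
    """Tile a raw camera frame into per-lenslet sub-images.

    The sub-image side defaults to the lenslet pitch in camera pixels
    (mla_pitch * relay2_mag / camera_pixel).  Only usable lenslets (in-pupil,
    angle defined) are returned, each tagged with its viewing angle; tiles
    are laid out with m increasing along columns and n along rows, anchored
    at ``origin`` (row, col).
    """
    frame = np.asarray(frame, dtype=float)
    if subimage_px is None:
        subimage_px = int(round(
            config.mla_pitch_um * config.relay2_mag / config.camera_pixel_um
        ))
    m_values = sorted({mn[0] for mn in grid.indices})
    n_values = sorted({mn[1] for mn in grid.indices})
    r0, c0 = origin
    if r0 < 0 or c0 < 0 or r0 >= frame.shape[0] or c0 >= frame.shape[1]:
        raise ValueError("tiling origin lies outside the frame")
    need_rows = r0 + len(n_values) * subimage_px
    need_cols = c0 + len(m_values) * subimage_px
    if frame.shape[0] < need_rows or frame.shape[1] < need_cols:
        raise ValueError(
            f"frame {frame.shape} too small for a "
            f"{len(n_values)}x{len(m_values)} grid of {subimage_px} px tiles"
        )
    angles = viewing_angles(grid, config)
    indices = grid.valid_indices()
    tiles = []
    for m, n in indices:
        row = n_values.index(n)
        col = m_values.index(m)
        r = r0 + row * subimage_px
        c = c0 + col * subimage_px
        tiles.append(frame[r : r + subimage_px, c : c + subimage_px])
    from .optics import pixel_resolution_at_sample

    return ProjectionSet(
        np.stack(tiles), angles, indices, pixel_resolution_at_sample(config)
    )


def richardson_lucy(
    image: np.ndarray, psf: PSFModel | np.ndarray, iterations: int = 10,
    pitch_um: float = 1.0,
) -> np.ndarray:
    """Richardson-Lucy deconvolution (multiplicative, flux-conserving).

    ``psf`` may be a PSFModel (kernel rendered at ``pitch_um``) or an explicit
    non-negative unit-sum kernel.  Negative input pixels raise: clip or offset
    first.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("Richardson-Lucy requires a non-negative image")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    kernel = psf.kernel(pitch_um) if isinstance(psf, PSFModel) else np.asarray(psf, float)
    if np.any(kernel < 0):
        raise ValueError("PSF kernel must be non-negative")
    kernel = kernel / kernel.sum()
    return _skimage_rl(image, kernel, num_iter=iterations, clip=False)


def fourier_slice_insert(
    volume: FourierVolume, projection: np.ndarray, angle: ViewingAngle
) -> FourierVolume:
    """Accumulate one projection onto its tilted central Fourier plane.

    The 2D transform of the projection equals the 3D object transform
    (z-centered convention, see FourierVolume) on the plane
    k_z = -(k_x tan alpha + k_y tan beta), whose normal is parallel to the
    viewing direction.  Values are spread onto the two nearest k_z grid
    planes with linear gridding weights; samples beyond the k_z band are
    dropped rather than wrapped.
    """
    projection = np.asarray(projection, dtype=float)
    n = volume.side
    if projection.shape != (n, n):
        raise ValueError(
            f"projection shape {projection.shape} must match the volume side {n}"
        )
    if not (abs(angle.alpha_rad) < math.pi / 2 and abs(angle.beta_rad) < math.pi / 2):
        raise ValueError("viewing angle magnitude must be below 90 degrees")
    tan_a, tan_b = angle.tangents
    spectrum = np.fft.fft2(projection)
    kx = np.fft.fftfreq(n) * n  # integer frequency index
    ky = kx
    kxg, kyg = np.meshgrid(kx, ky)  # (ky rows, kx cols)
    kz = -(kxg * tan_a + kyg * tan_b)

    in_band = np.abs(kz) <= n / 2 - 1
    kz_in = kz[in_band]
    vals = spectrum[in_band]
    cols = kxg[in_band].astype(int) % n
    rows = kyg[in_band].astype(int) % n
    k0 = np.floor(kz_in).astype(int)
    w1 = kz_in - k0
    w0 = 1.0 - w1
    for kidx, w in ((k0, w0), (k0 + 1, w1)):
        np.add.at(volume.values, (kidx % n, rows, cols), vals * w)
        np.add.at(volume.weights, (kidx % n, rows, cols), w)
    return volume


def invert_fourier_volume(volume: FourierVolume) -> Tomogram:
    """Weight-normalized inverse 3D transform of the accumulated planes.
    Unfilled regions (the missing cone) stay zero."""
    if not np.any(volume.weights > 0):
        raise ValueError("no Fourier planes have been inserted")
    filled = volume.weights > 0
    spectrum = np.zeros_like(volume.values)
    spectrum[filled] = volume.values[filled] / volume.weights[filled]
    # roll from the z-centered convention back to a centered volume
    data = np.roll(np.real(np.fft.ifftn(spectrum)), volume.side // 2, axis=0)
    return Tomogram(data, volume.pitch_um)


def positivity_refine(
    tomogram: Tomogram,
    volume: FourierVolume,
    iterations: int = 50,
    tol: float = 1e-4,
) -> Tomogram:
    """Alternating-projection positivity constraint.

    Repeat: clip negatives in real space, transform, restore the measured
    Fourier samples (weight > 0), invert.  Stops early once the negativity
    energy falls below ``tol`` of the total energy.  The result is clipped,
    hence non-negative everywhere; a fully measured, already non-negative
    volume is a fixed point.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    filled = volume.weights > 0
    measured = volume.values[filled] / volume.weights[filled]
    zc = volume.side // 2
    # work in the volume's z-centered convention; clipping is pointwise so
    # it commutes with the roll
    x = np.roll(tomogram.data, -zc, axis=0)
    for _ in range(iterations):
        clipped = np.clip(x, 0.0, None)
        neg_energy = float(np.sum((x - clipped) ** 2))
        total = float(np.sum(x * x))
        if total == 0 or neg_energy <= tol * total:
            x = clipped
            break
        spectrum = np.fft.fftn(clipped)
        spectrum[filled] = measured
        x = np.real(np.fft.ifftn(spectrum))
    data = np.roll(np.clip(x, 0.0, None), zc, axis=0)
    return Tomogram(data, tomogram.voxel_um, tomogram.wavelength_nm)


def reconstruct(
    projections: ProjectionSet,
    psf: PSFModel | None,
    rl_iterations: int = 10,
    positivity_iterations: int = 50,
    wavelength_nm: float | None = None,
) -> Tomogram:
    """Full pipeline: RL-deconvolve each sub-image, insert all Fourier
    planes, invert, refine with the positivity constraint.

    The reconstruction grid is isotropic: side = sub-image side, voxel =
    sub-image pixel pitch, z extent = x extent.  Deterministic.
    """
    n_views = len(projections)
    if n_views < 2:
        raise ValueError("need at least two projections")
    tangents = {a.tangents for a in projections.angles}
    if len(tangents) < 2:
        raise ValueError("need at least two distinct viewing angles")
    side = projections.subimages.shape[1]
    if projections.subimages.shape[2] != side:
        raise ValueError("sub-images must be square")
    volume = FourierVolume.empty(side, projections.pitch_um)
    for img, ang in zip(projections.subimages, projections.angles):
        if psf is not None and rl_iterations >= 1:
            img = richardson_lucy(
                np.clip(img, 0.0, None), psf, rl_iterations, projections.pitch_um
            )
            img = np.clip(img, 0.0, None)
        fourier_slice_insert(volume, img, ang)
    tomo = invert_fourier_volume(volume)
    tomo = positivity_refine(tomo, volume, positivity_iterations)
    tomo.wavelength_nm = wavelength_nm
    return tomo


def _gaussian(x, amplitude, mu, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def measure_fwhm_3d(tomogram: Tomogram, axis: str = "x") -> float:
    """FWHM (um) of the dominant blob along one axis.

    Extracts the 1D intensity profile through the maximum-intensity voxel
    along ``axis`` ('x', 'y' or 'z'), fits a Gaussian, and returns
    2.3548 * sigma_fit * voxel size.
    """
    ax = {"z": 0, "y": 1, "x": 2}.get(axis)
    if ax is None:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    data = tomogram.data
    peak = np.unravel_index(int(np.argmax(data)), data.shape)
    slicer = list(peak)
    slicer[ax] = slice(None)
    profile = data[tuple(slicer)]
    coords = np.arange(profile.size, dtype=float)
    amp0 = float(profile.max() - profile.min())
    if amp0 <= 0:
        raise ValueError("profile has no peak to fit")
    p0 = (amp0, float(peak[ax]), 2.0, float(profile.min()))
    try:
        popt, _ = curve_fit(_gaussian, coords, profile, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ValueError(f"Gaussian fit failed: {exc}") from exc
    sigma = abs(popt[2])
    return 2.3548 * sigma * tomogram.voxel_um
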