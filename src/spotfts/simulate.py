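"""Forward simulation: phantoms, projections, snapshots, and interferograms.

Generates synthetic raw data with the statistical and geometric structure of
the instrument: a labeled 3D phantom is projected through each lenslet's
viewing direction (parallel line integrals, then blurring by the lenslet
PSF), the per-lenslet projections are tiled into one camera frame, and the
frame intensities are modulated over the OPD sweep according to each label's
emission spectrum:

    I(delta) = B * integral S(sigma) (1 + cos(2 pi sigma delta)) dsigma,

so at zero OPD the noiseless intensity is twice the mean level.  Stage
positioning nonlinearity enters as seeded jitter on the OPD axis; camera
noise as scaled-Poisson shot noise plus additive read noise.

Array convention: volumes are indexed (z, y, x); images (y, x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fts import OPDAxis, InterferogramStack, UM_TO_CM
from .optics import LensletGrid, SystemConfig, ViewingAngle, viewing_angles
from .tomo import PSFModel, _fourier_shear_project

__all__ = [
    "EmissionSpectrum",
    "Phantom",
    "NoiseModel",
    "make_shell_bead",
    "make_point_bead",
    "project",
    "render_snapshot",
    "sample_opd_axis",
    "synth_interferograms",
    "simulate_acquisition",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission density S(sigma) >= 0 on a wavenumber grid, or a
    single monochromatic line.  Normalized so integral S dsigma = 1."""

    wavenumber_cm1: np.ndarray | None = None
    density: np.ndarray | None = None
    line_sigma_cm1: float | None = None

    def __post_init__(self) -> None:
        if self.line_sigma_cm1 is not None:
            if self.line_sigma_cm1 <= 0:
                raise ValueError("line wavenumber must be positive")
            return
        sig = np.asarray(self.wavenumber_cm1, dtype=float)
        den = np.asarray(self.density, dtype=float)
        if sig.ndim != 1 or sig.shape != den.shape:
            raise ValueError("wavenumber grid and density must be matching 1D arrays")
        if np.any(den < 0):
            raise ValueError("spectral density must be non-negative")
        total = np.trapezoid(den, sig)
        if total <= 0:
            raise ValueError("spectral density must have positive integral")
        object.__setattr__(self, "wavenumber_cm1", sig)
        object.__setattr__(self, "density", den / total)

    @classmethod
    def monochromatic(cls, wavelength_nm: float) -> "EmissionSpectrum":
        return cls(line_sigma_cm1=1e7 / wavelength_nm)

    @classmethod
    def gaussian_band(
        cls,
        peak_nm: float,
        fwhm_nm: float,
        cut_on_nm: float | None = None,
        cut_off_nm: float | None = None,
        n: int = 801,
    ) -> "EmissionSpectrum":
        """Smooth emission band peaked at ``peak_nm``, optionally truncated by
        ideal filter edges at ``cut_on_nm``/``cut_off_nm`` (e.g. the 512 and
        545 nm emission-filter cutoffs)."""
        lam = np.linspace(400.0, 750.0, n)
        s = np.exp(-0.5 * ((lam - peak_nm) / (fwhm_nm / 2.3548)) ** 2)
        if cut_on_nm is not None:
            s[lam < cut_on_nm] = 0.0
        if cut_off_nm is not None:
            s[lam > cut_off_nm] = 0.0
        sigma = 1e7 / lam[::-1]
        return cls(wavenumber_cm1=sigma, density=s[::-1])

    def peak_wavelength_nm(self) -> float:
        if self.line_sigma_cm1 is not None:
            return 1e7 / self.line_sigma_cm1
        return 1e7 / self.wavenumber_cm1[int(np.argmax(self.density))]

    def interferogram_kernel(self, delta_um: np.ndarray) -> np.ndarray:
        """g(delta) = integral S(sigma) (1 + cos(2 pi sigma delta)) dsigma
        for unit-normalized S; for a line spectrum, exactly 1 + cos."""
        delta_cm = np.asarray(delta_um, dtype=float) * UM_TO_CM
        if self.line_sigma_cm1 is not None:
            return 1.0 + np.cos(2 * np.pi * self.line_sigma_cm1 * delta_cm)
        phases = np.cos(2 * np.pi * np.outer(delta_cm, self.wavenumber_cm1))
        return 1.0 + np.trapezoid(phases * self.density, self.wavenumber_cm1, axis=1)


@dataclass
class Phantom:
    """3D fluorophore concentration with an integer label map assigning each
    voxel an emission spectrum (label 0 = unlabeled background)."""

    density: np.ndarray
    voxel_um: float
    labels: np.ndarray
    spectra: dict[int, EmissionSpectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        den = np.asarray(self.density, dtype=float)
        lab = np.asarray(self.labels)
        if den.ndim != 3 or den.shape != lab.shape:
            raise ValueError("density and labels must be matching 3D arrays")
        if np.any(den < 0):
            raise ValueError("fluorophore density must be non-negative")
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        used = set(np.unique(lab[den > 0]).tolist()) - {0}
        missing = used - set(self.spectra)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no emission spectrum")
        self.density, self.labels = den, lab

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    def component(self, label: int) -> np.ndarray:
        """Density restricted to one label."""
        return np.where(self.labels == label, self.density, 0.0)


def _radius_grid(shape: tuple[int, int, int], voxel_um: float,
                 center_um: tuple[float, float, float]) -> np.ndarray:
    zz, yy, xx = np.indices(shape).astype(float) * voxel_um
    cz, cy, cx = center_um
    return np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)


def _default_center(shape, voxel_um):
    return tuple((s - 1) / 2.0 * voxel_um for s in shape)


def make_shell_bead(
    shape: tuple[int, int, int],
    voxel_um: float,
    spectrum: EmissionSpectrum,
    diameter_um: float = 6.0,
    shell_thickness_um: float = 0.8,
    center_um: tuple[float, float, float] | None = None,
    label: int = 1,
) -> Phantom:
    """Surface-stained bead: unit density on the spherical shell
    r in [R - t, R] with R = diameter/2, zero elsewhere."""
    radius = diameter_um / 2.0
    if not diameter_um > 2.0 * shell_thickness_um > 0:
        raise ValueError("need diameter > 2 * shell thickness > 0")
    center = center_um or _default_center(shape, voxel_um)
    extent = min(s * voxel_um for s in shape)
    if 2.0 * radius >= extent:
        raise ValueError("bead larger than the phantom grid")
    r = _radius_grid(shape, voxel_um, center)
    shell = (r >= radius - shell_thickness_um) & (r <= radius)
    density = shell.astype(float)
    labels = np.where(shell, label, 0)
    return Phantom(density, voxel_um, labels, {label: spectrum})


def make_point_bead(
    shape: tuple[int, int, int],
    voxel_um: float,
    spectrum: EmissionSpectrum,
    diameter_um: float = 0.5,
    center_um: tuple[float, float, float] | None = None,
    label: int = 1,
) -> Phantom:
    """Solid sub-resolution bead: unit density inside r <= diameter/2."""
    radius = diameter_um / 2.0
    if radius <= 0:
        raise ValueError("diameter must be positive")
    center = center_um or _default_center(shape, voxel_um)
    extent = min(s * voxel_um for s in shape)
    if 2.0 * radius >= extent:
        raise ValueError("bead larger than the phantom grid")
    r = _radius_grid(shape, voxel_um, center)
    ball = r <= radius
    if not ball.any():  # sub-voxel bead: keep at least the center voxel
        ball = r == r.min()
    density = ball.astype(float)
    labels = np.where(ball, label, 0)
    return Phantom(density, voxel_um, labels, {label: spectrum})


def make_pollen_phantom(
    shape: tuple[int, int, int],
    voxel_um: float,
    core_spectrum: EmissionSpectrum,
    envelope_spectrum: EmissionSpectrum,
    core_diameter_um: float = 8.0,
    envelope_thickness_um: float = 1.5,
    center_um: tuple[float, float, float] | None = None,
) -> Phantom:
    """Two-compartment pollen-like phantom: a solid core with one emission
    spectrum wrapped in a distinct-spectrum envelope shell."""
    r_core = core_diameter_um / 2.0
    r_out = r_core + envelope_thickness_um
    center = center_um or _default_center(shape, voxel_um)
    extent = min(s * voxel_um for s in shape)
    if 2.0 * r_out >= extent:
        raise ValueError("phantom larger than the grid")
    r = _radius_grid(shape, voxel_um, center)
    core = r <= r_core
    env = (r > r_core) & (r <= r_out)
    density = (core | env).astype(float)
    labels = np.where(core, 1, np.where(env, 2, 0))
    return Phantom(density, voxel_um, labels, {1: core_spectrum, 2: envelope_spectrum})


# ---------------------------------------------------------------------------
# projection and snapshot rendering
# ---------------------------------------------------------------------------


def project(
    volume_or_phantom,
    angle: ViewingAngle,
    psf: PSFModel | None = None,
    voxel_um: float | None = None,
) -> np.ndarray:
    """Parallel projection of a volume along the viewing direction, then
    blurring with the lenslet PSF.

    The line integral is evaluated by shearing: slice z is shifted by
    (z - z_c) * (tan alpha, tan beta) via Fourier phase ramps (periodic,
    exact), and slices are summed.  The phantom support plus the maximum
    shear must fit inside the grid, otherwise content would wrap and an
    error is raised.
    """
    if isinstance(volume_or_phantom, Phantom):
        volume = volume_or_phantom.density
        voxel_um = volume_or_phantom.voxel_um
    else:
        volume = np.asarray(volume_or_phantom, dtype=float)
        if voxel_um is None:
            voxel_um = 1.0
    _check_shear_fits(volume, angle)
    image = _fourier_shear_project(volume, angle)
    if psf is not None:
        image = psf.blur(image, voxel_um)
    return image


def _check_shear_fits(volume: np.ndarray, angle: ViewingAngle) -> None:
    nz, ny, nx = volume.shape
    support = np.nonzero(volume)
    if support[0].size == 0:
        return
    zc = nz // 2
    tan_a, tan_b = angle.tangents
    zmax = float(np.max(np.abs(support[0] - zc)))
    x_lo, x_hi = support[2].min(), support[2].max()
    y_lo, y_hi = support[1].min(), support[1].max()
    if (
        x_lo - zmax * abs(tan_a) < 0
        or x_hi + zmax * abs(tan_a) > nx - 1
        or y_lo - zmax * abs(tan_b) < 0
        or y_hi + zmax * abs(tan_b) > ny - 1
    ):
        raise ValueError(
            "shear at this viewing angle pushes the phantom support outside "
            "the grid; pad the phantom or reduce the angle"
        )


def render_snapshot(
    phantom: Phantom,
    grid: LensletGrid,
    config: SystemConfig,
    psf: PSFModel | None = None,
    density: np.ndarray | None = None,
) -> np.ndarray:
    """Tile the per-lenslet projections into one synthetic camera frame.

    Lenslet (m, n) occupies the tile at (row, col) determined by its index
    within the sorted m/n values; unusable lenslets leave dark tiles.  The
    sub-image side equals the phantom's transverse extent, i.e. the phantom
    voxel size stands in for the camera pixel referred to the sample plane.
    """
    vol = phantom.density if density is None else density
    side = vol.shape[2]
    if vol.shape[1] != side:
        raise ValueError("phantom must have square transverse extent")
    m_values = sorted({mn[0] for mn in grid.indices})
    n_values = sorted({mn[1] for mn in grid.indices})
    frame = np.zeros((len(n_values) * side, len(m_values) * side))
    angles = viewing_angles(grid, config)
    for (m, n), ang in zip(grid.valid_indices(), angles):
        row = n_values.index(n)
        col = m_values.index(m)
        tile = project(vol, ang, psf, phantom.voxel_um)
        frame[row * side : (row + 1) * side, col * side : (col + 1) * side] = tile
    return frame


# ---------------------------------------------------------------------------
# OPD axis and interferogram synthesis
# ---------------------------------------------------------------------------


def sample_opd_axis(
    n: int = 2000,
    span_um: float = 200.0,
    nonlinearity_rms_um: float = 0.0,
    seed: int | None = None,
    start_um: float | None = None,
) -> OPDAxis:
    """Nominally uniform OPD sweep with seeded stage-nonlinearity jitter.

    Interior positions receive independent Gaussian jitter of the given RMS;
    the end points stay fixed, so the mean step is exactly span/(n-1).
    Jitter that breaks monotonicity raises rather than silently sorting.
    """
    if n < 8:
        raise ValueError("need at least 8 OPD samples")
    if span_um <= 0:
        raise ValueError("span must be positive")
    start = -span_um / 2.0 if start_um is None else start_um
    positions = np.linspace(start, start + span_um, n)
    if nonlinearity_rms_um > 0:
        rng = np.random.default_rng(seed)
        positions = positions.copy()
        positions[1:-1] += rng.normal(0.0, nonlinearity_rms_um, n - 2)
        if not np.all(np.diff(positions) > 0):
            raise ValueError(
                "stage jitter this large breaks monotonic OPD ordering"
            )
    return OPDAxis(positions)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: scaled-Poisson shot noise (photon_scale photons per
    intensity unit) plus Gaussian read noise, from a seeded generator."""

    photon_scale: float = 0.0
    read_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_noise < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, intensities: np.ndarray) -> np.ndarray:
        if self.photon_scale == 0 and self.read_noise == 0:
            return intensities
        rng = np.random.default_rng(self.seed)
        out = intensities
        if self.photon_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale) / self.photon_scale
        if self.read_noise > 0:
            out = out + rng.normal(0.0, self.read_noise, out.shape)
        return out


def synth_interferograms(
    emitters: list[tuple[np.ndarray, EmissionSpectrum]],
    opd: OPDAxis,
    noise: NoiseModel | None = None,
) -> InterferogramStack:
    """Per-pixel interferograms for brightness maps with known spectra.

    ``emitters`` is a list of (brightness image, spectrum) pairs; pixel
    intensities add incoherently:
    I(delta) = sum_l B_l * integral S_l(sigma) (1 + cos(2 pi sigma delta)) dsigma.
    """
    if not emitters:
        raise ValueError("need at least one emitter layer")
    shape = np.asarray(emitters[0][0]).shape
    delta = opd.positions_um
    stack = np.zeros((len(opd),) + shape)
    for brightness, spectrum in emitters:
        b = np.asarray(brightness, dtype=float)
        if b.shape != shape:
            raise ValueError("emitter brightness maps must share one shape")
        kernel = spectrum.interferogram_kernel(delta)
        stack += kernel[:, None, None] * b[None]
    if noise is not None:
        stack = np.clip(noise.apply(stack), 0.0, None)
    return InterferogramStack(stack, opd)


def simulate_acquisition(
    phantom: Phantom,
    grid: LensletGrid,
    config: SystemConfig,
    opd: OPDAxis,
    psf: PSFModel | None = None,
    noise: NoiseModel | None = None,
) -> InterferogramStack:
    """Full synthetic acquisition: snapshot per label, interferogram per OPD.

    Each labeled compartment is rendered to its own snapshot frame (spectra
    mix linearly along rays, as incoherent fluorescence adds), and the stack
    frame at OPD delta is the spectrum-weighted sum of the label snapshots.
    Byte-identical across runs for a fixed noise seed.
    """
    emitters = []
    for label, spectrum in sorted(phantom.spectra.items()):
        component = phantom.component(label)
        if not component.any():
            continue
        snapshot = render_snapshot(phantom, grid, config, psf, density=component)
        emitters.append((snapshot, spectrum))
    if not emitters:
        raise ValueError("phantom has no labeled fluorophores")
    return synth_interferograms(emitters, opd, noise)
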