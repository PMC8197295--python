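"""Fourier-transform spectroscopy: interferogram stacks to spectral cubes.

A Michelson interferometer sweeps the optical path difference (OPD) delta
while the camera records one frame per OPD position.  Each pixel's intensity
trace I(delta) is an interferogram whose Fourier transform over delta is the
emission spectrum at that pixel.  The per-pixel chain is

    mask -> linear detrend -> envelope-center at zero OPD -> apodize
         -> nonuniform Fourier transform (magnitude)

Phase correction is deliberately omitted: the magnitude spectrum is reported.

Units: OPD in micrometers, wavenumber sigma in cm^-1, wavelength in nm
(lambda_nm = 1e7 / sigma_cm1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, hilbert

from .nufft import nufft

__all__ = [
    "OPDAxis",
    "InterferogramStack",
    "ApodizationSpec",
    "Spectrum",
    "SpectralCube",
    "build_signal_mask",
    "detrend_and_center",
    "upper_envelope",
    "apodize",
    "default_wavenumber_grid",
    "spectrum_via_nufft",
    "process_stack",
    "instrument_line_shape_fwhm",
    "spectral_resolution_nm",
    "fwhm_of_spectral_peak",
]

logger = logging.getLogger(__name__)

UM_TO_CM = 1e-4

#: Norton-Beer coefficient sets, A(u) = sum_i c_i (1 - u^2)^i with u = delta/delta_max.
#: The weights sum to 1 so the interferogram is unweighted at zero OPD.
NORTON_BEER_COEFFS: dict[str, tuple[float, ...]] = {
    "boxcar": (1.0,),
    "norton_beer_weak": (0.384093, -0.087577, 0.703484),
    "norton_beer_medium": (0.152442, -0.136176, 0.983734),
    "norton_beer_strong": (0.045335, 0.0, 0.554883, 0.0, 0.399782),
}


@dataclass(frozen=True)
class OPDAxis:
    """Strictly increasing optical-path-difference sample positions (um)."""

    positions_um: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        if pos.ndim != 1 or pos.size < 8:
            raise ValueError("OPD axis needs at least 8 one-dimensional samples")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("OPD positions must be strictly increasing")

    def __len__(self) -> int:
        return self.positions_um.size

    @property
    def nominal_step_um(self) -> float:
        return float(np.mean(np.diff(self.positions_um)))

    @property
    def span_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])

    @property
    def nyquist_cm1(self) -> float:
        """Highest recoverable wavenumber, 1 / (2 * nominal step)."""
        return 1.0 / (2.0 * self.nominal_step_um * UM_TO_CM)

    def shifted(self, delta0_um: float) -> "OPDAxis":
        return OPDAxis(self.positions_um - delta0_um)


@dataclass
class InterferogramStack:
    """N x H x W intensity frames indexed by an OPD axis of length N."""

    intensities: np.ndarray
    opd: OPDAxis
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a frames x H x W array")
        if arr.shape[0] != len(self.opd):
            raise ValueError(
                f"frame count {arr.shape[0]} != OPD length {len(self.opd)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class ApodizationSpec:
    """Norton-Beer family taper A(u) = sum_i c_i (1-u^2)^i, u = delta/delta_max."""

    kind: str = "norton_beer_medium"

    def __post_init__(self) -> None:
        if self.kind not in NORTON_BEER_COEFFS:
            raise ValueError(
                f"unknown apodization {self.kind!r}; "
                f"choose from {sorted(NORTON_BEER_COEFFS)}"
            )

    @property
    def coefficients(self) -> tuple[float, ...]:
        return NORTON_BEER_COEFFS[self.kind]

    def weights(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        one_minus = 1.0 - u * u
        out = np.zeros_like(u)
        for i, c in enumerate(self.coefficients):
            out += c * one_minus**i
        return out


@dataclass
class Spectrum:
    """Magnitude spectrum on a uniform ascending wavenumber grid (cm^-1)."""

    wavenumber_cm1: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.wavenumber_cm1, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if sig.shape != amp.shape or sig.ndim != 1:
            raise ValueError("wavenumber and amplitude must be matching 1D arrays")
        if not np.all(sig > 0) or not np.all(np.diff(sig) > 0):
            raise ValueError("wavenumber grid must be positive and ascending")
        if np.any(amp < 0):
            raise ValueError("magnitude spectrum must be non-negative")
        self.wavenumber_cm1, self.amplitude = sig, amp

    @property
    def wavelength_nm(self) -> np.ndarray:
        return 1e7 / self.wavenumber_cm1

    def peak_wavelength_nm(self) -> float:
        """Wavelength of the spectral maximum, with 3-point parabolic
        refinement of the peak position in the wavenumber domain."""
        i = int(np.argmax(self.amplitude))
        sigma = self.wavenumber_cm1
        if 0 < i < sigma.size - 1:
            y0, y1, y2 = self.amplitude[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # proper concave peak
                frac = 0.5 * (y0 - y2) / denom
                frac = float(np.clip(frac, -0.5, 0.5))
                step = sigma[i + 1] - sigma[i] if frac >= 0 else sigma[i] - sigma[i - 1]
                return 1e7 / (sigma[i] + frac * step)
        return 1e7 / sigma[i]


@dataclass
class SpectralCube:
    """Per-pixel magnitude spectra: amplitudes (n_sigma x H x W) on a shared
    wavenumber axis; ``wavelength_nm`` is the derived (descending) axis."""

    amplitudes: np.ndarray
    wavenumber_cm1: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        sig = np.asarray(self.wavenumber_cm1, dtype=float)
        if amp.ndim != 3 or amp.shape[0] != sig.size:
            raise ValueError("amplitudes must be (n_sigma, H, W) matching the grid")
        if np.any(amp < 0):
            raise ValueError("cube amplitudes must be non-negative")
        self.amplitudes, self.wavenumber_cm1 = amp, sig

    @property
    def wavelength_nm(self) -> np.ndarray:
        return 1e7 / self.wavenumber_cm1

    def plane_at_wavelength(self, wavelength_nm: float) -> np.ndarray:
        """The H x W amplitude image at the grid wavelength nearest the request."""
        i = int(np.argmin(np.abs(self.wavelength_nm - wavelength_nm)))
        return self.amplitudes[i]

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.wavenumber_cm1, self.amplitudes[:, row, col])


# ---------------------------------------------------------------------------
# per-pixel interferogram processing
# ---------------------------------------------------------------------------


def build_signal_mask(stack: InterferogramStack, k: float = 6.0) -> np.ndarray:
    """Binary H x W mask of pixels that carry sample signal.

    A pixel is kept iff its maximum intensity over the OPD sweep exceeds the
    robust background level: median + k * MAD of the per-pixel maxima.  The
    maximum is permutation-invariant over frames, so the mask does not depend
    on acquisition order.
    """
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    peak = stack.intensities.max(axis=0)
    med = float(np.median(peak))
    mad = float(np.median(np.abs(peak - med)))
    if mad == 0.0 and np.all(peak == peak.flat[0]):
        logger.warning("constant stack: signal mask is empty")
        return np.zeros(peak.shape, dtype=bool)
    return peak > med + k * mad


def upper_envelope(series: np.ndarray, opd: OPDAxis) -> np.ndarray:
    """Upper envelope of an oscillating (centered) interferogram.

    Cubic spline through the local maxima; if fewer than 4 maxima exist the
    analytic-signal magnitude is used instead.  A monotone series has no
    oscillation to envelope and raises.
    """
    series = np.asarray(series, dtype=float)
    if series.shape != (len(opd),):
        raise ValueError("series length must match the OPD axis")
    diffs = np.diff(series)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise ValueError("monotone series has no envelope")
    peaks, _ = find_peaks(series)
    if peaks.size >= 4:
        pos = opd.positions_um
        spline = CubicSpline(pos[peaks], series[peaks], extrapolate=True)
        env = spline(pos)
        # extrapolated tails can dive; never fall below the data there
        env[: peaks[0]] = np.maximum(env[: peaks[0]], series[: peaks[0]])
        env[peaks[-1] :] = np.maximum(env[peaks[-1] :], series[peaks[-1] :])
        return env
    return np.abs(hilbert(series))


def detrend_and_center(
    series: np.ndarray, opd: OPDAxis
) -> tuple[np.ndarray, OPDAxis]:
    """Remove the best straight-line fit and shift the OPD origin to the
    envelope peak (the zero-OPD burst).

    The burst center is located on the upper envelope with sub-sample
    precision by a parabola through the envelope maximum and its neighbors.
    A near-flat envelope (monochromatic light: the burst is everywhere) has
    no localizable peak, and the axis is centered on its midpoint.  An
    envelope peaking at either end means the burst was not captured in the
    scan range, which raises.
    """
    series = np.asarray(series, dtype=float)
    pos = opd.positions_um
    if series.shape != pos.shape:
        raise ValueError("series length must match the OPD axis")
    coeffs = np.polynomial.polynomial.polyfit(pos, series, 1)
    detrended = series - np.polynomial.polynomial.polyval(pos, coeffs)

    env = upper_envelope(detrended, opd)
    lo, hi = float(env.min()), float(env.max())
    if hi <= 0 or lo > 0.3 * hi:
        # Envelope never decays: monochromatic light has no localizable
        # zero-OPD burst (any residual wobble is a sampling artifact).
        # Assume a symmetric scan and center on the midpoint.
        delta0 = 0.5 * (pos[0] + pos[-1])
        return detrended, opd.shifted(delta0)

    i = int(np.argmax(env))
    if i == 0 or i == env.size - 1:
        raise ValueError("envelope peaks at the scan edge: burst not captured")
    y0, y1, y2 = env[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom >= 0 else float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    step = pos[i + 1] - pos[i] if frac >= 0 else pos[i] - pos[i - 1]
    delta0 = pos[i] + frac * step
    return detrended, opd.shifted(delta0)


def apodize(
    series: np.ndarray, opd: OPDAxis, spec: ApodizationSpec
) -> np.ndarray:
    """Multiply the centered interferogram by the taper A(delta/delta_max)."""
    series = np.asarray(series, dtype=float)
    pos = opd.positions_um
    if series.shape != pos.shape:
        raise ValueError("series length must match the OPD axis")
    if not (pos[0] < 0 < pos[-1]):
        raise ValueError("OPD axis must be centered (zero inside the span)")
    if spec.kind == "boxcar":
        return series.copy()
    delta_max = float(np.max(np.abs(pos)))
    return series * spec.weights(pos / delta_max)


def default_wavenumber_grid(
    opd: OPDAxis,
    n: int = 2048,
    lambda_min_nm: float = 400.0,
    lambda_max_nm: float = 750.0,
) -> np.ndarray:
    """Uniform wavenumber grid from 1/lambda_max up to the Nyquist limit
    (or 1/lambda_min if that is lower)."""
    sigma_min = 1e7 / lambda_max_nm
    sigma_max = min(1e7 / lambda_min_nm, opd.nyquist_cm1)
    if sigma_max <= sigma_min:
        raise ValueError("OPD sampling too coarse for the requested band")
    return np.linspace(sigma_min, sigma_max, n)


def spectrum_via_nufft(
    series: np.ndarray, opd: OPDAxis, grid: np.ndarray
) -> Spectrum:
    """Magnitude of the nonuniform Fourier transform of the (centered,
    apodized) interferogram on a uniform wavenumber grid.

    Phase is discarded (no phase correction): the reported spectrum is
    |sum_j s_j exp(-2 pi i sigma delta_j)|.
    """
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if grid.ndim != 1 or grid.size < 2 or not np.allclose(steps, steps[0]):
        raise ValueError("wavenumber grid must be uniform and ascending")
    if grid[0] <= 0:
        raise ValueError("wavenumber grid must be positive")
    if grid[-1] > opd.nyquist_cm1 * (1 + 1e-12):
        raise ValueError(
            f"grid extends to {grid[-1]:.1f} cm^-1, beyond the Nyquist limit "
            f"{opd.nyquist_cm1:.1f} cm^-1 of this OPD sampling"
        )
    x_cm = opd.positions_um * UM_TO_CM
    coeff = nufft(np.asarray(series, float), x_cm, grid[0], float(steps[0]), grid.size)
    return Spectrum(grid, np.abs(coeff))


def _process_pixel(
    series: np.ndarray, opd: OPDAxis, spec: ApodizationSpec, grid: np.ndarray
) -> np.ndarray:
    detrended, centered = detrend_and_center(series, opd)
    weighted = apodize(detrended, centered, spec)
    return spectrum_via_nufft(weighted, centered, grid).amplitude


def process_stack(
    stack: InterferogramStack,
    spec: ApodizationSpec | None = None,
    grid: np.ndarray | None = None,
    mask_k: float = 6.0,
) -> SpectralCube:
    """Per-pixel FTS processing of a full interferogram stack.

    Pixels outside the signal mask are zero; pixels whose interferogram
    cannot be processed (e.g. burst outside the scan) are zeroed and counted
    in the log.  Deterministic for a fixed input.
    """
    spec = spec or ApodizationSpec()
    if grid is None:
        grid = default_wavenumber_grid(stack.opd)
    mask = build_signal_mask(stack, k=mask_k)
    n_sigma = grid.size
    _, height, width = stack.shape
    cube = np.zeros((n_sigma, height, width))
    failures = 0
    for row, col in zip(*np.nonzero(mask)):
        try:
            cube[:, row, col] = _process_pixel(
                stack.intensities[:, row, col], stack.opd, spec, grid
            )
        except ValueError:
            failures += 1
    if failures:
        logger.warning("process_stack: %d masked pixels failed and were zeroed", failures)
    return SpectralCube(
        cube, grid, provenance={"apodization": spec.kind, "mask_k": mask_k}
    )


# ---------------------------------------------------------------------------
# instrument line shape and resolution metrics
# ---------------------------------------------------------------------------


def _fwhm_about_peak(x: np.ndarray, y: np.ndarray, i_peak: int) -> float:
    """Full width at half maximum of the peak at index i_peak, crossings by
    linear interpolation."""
    half = y[i_peak] / 2.0
    i = i_peak
    while i > 0 and y[i - 1] >= half:
        i -= 1
    if i == 0 and y[0] >= half:
        raise ValueError("half-maximum crossing outside the sampled range")
    x_lo = np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
    j = i_peak
    while j < y.size - 1 and y[j + 1] >= half:
        j += 1
    if j == y.size - 1 and y[-1] >= half:
        raise ValueError("half-maximum crossing outside the sampled range")
    x_hi = np.interp(-half, [-y[j], -y[j + 1]], [x[j], x[j + 1]])
    return float(x_hi - x_lo)


def instrument_line_shape_fwhm(
    opd_span_um: float,
    spec: ApodizationSpec | None = None,
    n_delta: int = 2001,
    n_sigma: int = 6001,
) -> float:
    """FWHM (cm^-1) of the instrument line shape for a centered double-sided
    interferogram of total OPD span ``opd_span_um``.

    The line shape is the Fourier transform of the apodization taper over
    delta in [-span/2, +span/2], sampled on a fine wavenumber grid; the
    width is read off by linear interpolation at half maximum.  For the
    boxcar this reproduces the classic 1.2067/(2 delta_max) sinc width.
    """
    if opd_span_um <= 0:
        raise ValueError("OPD span must be positive")
    spec = spec or ApodizationSpec()
    delta_max_cm = 0.5 * opd_span_um * UM_TO_CM
    delta = np.linspace(-delta_max_cm, delta_max_cm, n_delta)
    taper = spec.weights(delta / delta_max_cm)
    # a few main-lobe widths suffice to bracket the half-max crossing
    sigma = np.linspace(0.0, 4.0 / delta_max_cm, n_sigma)
    if n_sigma < 64:
        raise ValueError("wavenumber grid too coarse for the span")
    ils = np.empty(n_sigma)
    block = 2048
    for start in range(0, n_sigma, block):
        sl = sigma[start : start + block]
        ils[start : start + block] = np.abs(
            np.trapezoid(
                taper * np.cos(2 * np.pi * np.outer(sl, delta)), delta, axis=1
            )
        )
    # line shape is symmetric about sigma=0: FWHM = 2 * half-crossing
    half = ils[0] / 2.0
    idx = int(np.argmax(ils < half))
    if idx == 0:
        raise ValueError("no half-maximum crossing on the sampled grid")
    sigma_half = np.interp(-half, [-ils[idx - 1], -ils[idx]], [sigma[idx - 1], sigma[idx]])
    return float(2.0 * sigma_half)


def spectral_resolution_nm(
    opd_span_um: float,
    wavelength_nm: float,
    spec: ApodizationSpec | None = None,
) -> float:
    """Instrument-limited spectral resolution in nm at a reference wavelength:
    d_lambda = lambda^2 * d_sigma."""
    dsigma = instrument_line_shape_fwhm(opd_span_um, spec)
    return wavelength_nm**2 * dsigma * 1e-7


def fwhm_of_spectral_peak(spectrum: Spectrum) -> float:
    """FWHM (nm) of a single dominant spectral peak.

    Crossings are found in the wavenumber domain by linear interpolation and
    converted at the peak wavelength via d_lambda = lambda^2 * d_sigma.
    Raises if more than one region of the spectrum rises above half maximum
    (comparable multi-modal peaks).
    """
    amp = spectrum.amplitude
    i_peak = int(np.argmax(amp))
    half = amp[i_peak] / 2.0
    above = amp >= half
    n_regions = int(np.sum(np.diff(above.astype(int)) == 1) + (1 if above[0] else 0))
    if n_regions > 1:
        raise ValueError("spectrum has multiple comparable peaks")
    dsigma = _fwhm_about_peak(spectrum.wavenumber_cm1, amp, i_peak)
    lam = spectrum.peak_wavelength_nm()
    return lam**2 * dsigma * 1e-7
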