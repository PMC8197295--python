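"""Monochromatic line recovery through the full per-pixel processing chain.

Synthesizes the interferogram of an ideal laser line, I(delta) = 1 +
cos(2 pi sigma0 delta), sampled at 2000 OPD positions over +-100 um, then
runs the complete chain -- linear detrend, envelope centering, Norton-Beer
medium apodization, nonuniform Fourier transform -- and reports the peak
wavelength and measured line width.
"""

import numpy as np

from spotfts import (
    ApodizationSpec,
    OPDAxis,
    apodize,
    default_wavenumber_grid,
    detrend_and_center,
    fwhm_of_spectral_peak,
    spectrum_via_nufft,
)

axis = OPDAxis(np.linspace(-100.0, 100.0, 2000))
for wavelength_nm in (632.8, 488.0):
    sigma0 = 1e7 / wavelength_nm  # cm^-1
    interferogram = 1.0 + np.cos(2 * np.pi * sigma0 * axis.positions_um * 1e-4)
    detrended, centered = detrend_and_center(interferogram, axis)
    weighted = apodize(detrended, centered, ApodizationSpec("norton_beer_medium"))
    spectrum = spectrum_via_nufft(weighted, centered, default_wavenumber_grid(centered))
    print(
        f"input {wavelength_nm:6.1f} nm -> peak {spectrum.peak_wavelength_nm():7.2f} nm"
        f" (nearest nm: {round(spectrum.peak_wavelength_nm())}),"
        f" line FWHM {fwhm_of_spectral_peak(spectrum):.2f} nm"
    )

# The recovered peaks land on the nearest nanometer and the line widths match
# the theoretical instrument-limited resolution (3.4 nm at 632.8 nm, 2.0 nm
# at 488 nm for this span and taper): a monochromatic source measures the
# instrument line shape itself.
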