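"""End-to-end pipeline on a surface-stained 6 um bead phantom.

Simulates a full acquisition (320 interferogram frames over a 40 um OPD
sweep, EMCCD-like noise), processes every masked pixel into a hyperspectral
cube, reconstructs the 530 nm plane into a 3D tomogram, and measures the
ring left by the stained surface.  Runs in roughly half a minute.
"""

import numpy as np
from scipy.signal import find_peaks

from spotfts import (
    ApodizationSpec,
    EmissionSpectrum,
    LensletGrid,
    NoiseModel,
    PSFModel,
    SystemConfig,
    default_wavenumber_grid,
    extract_lenslet_subimages,
    make_shell_bead,
    process_stack,
    reconstruct,
    sample_opd_axis,
    simulate_acquisition,
)

config = SystemConfig()
grid = LensletGrid.build(config)
psf = PSFModel.from_config(config)
voxel_um = 0.27

emission = EmissionSpectrum.gaussian_band(530.0, 33.0, cut_on_nm=512.0, cut_off_nm=545.0)
shell = make_shell_bead((64, 64, 64), voxel_um, emission,
                        diameter_um=6.0, shell_thickness_um=0.8)

opd = sample_opd_axis(n=320, span_um=40.0, nonlinearity_rms_um=0.01, seed=42)
noise = NoiseModel(photon_scale=100.0, read_noise=0.02, seed=42)
stack = simulate_acquisition(shell, grid, config, opd, psf, noise)
print(f"acquisition: {stack.shape[0]} frames of {stack.shape[1]}x{stack.shape[2]} px")

cube = process_stack(stack, ApodizationSpec("norton_beer_medium"),
                     default_wavenumber_grid(stack.opd, n=512))
bright = stack.intensities.max(axis=0)
row, col = np.unravel_index(int(np.argmax(bright)), bright.shape)
print(f"emission peak at brightest pixel: "
      f"{cube.spectrum_at(row, col).peak_wavelength_nm():.1f} nm")

plane = cube.plane_at_wavelength(530.0)
projections = extract_lenslet_subimages(plane, grid, config, subimage_px=64)
projections.pitch_um = voxel_um
tomogram = reconstruct(projections, psf)

profile = tomogram.data[32, 32, :]
peaks, _ = find_peaks(profile, height=0.3 * profile.max())
refined = []
for p in (peaks.min(), peaks.max()):
    y0, y1, y2 = profile[p - 1 : p + 2]
    denom = y0 - 2 * y1 + y2
    refined.append(p + (0.5 * (y0 - y2) / denom if denom < 0 else 0.0))
print(f"mid-plane ring: center/rim intensity ratio "
      f"{profile[32] / profile.max():.2f}, "
      f"ring diameter {(refined[1] - refined[0]) * voxel_um:.2f} um")

# The raw projections show a filled disk (the stained surface integrates
# through the bead), while the reconstructed mid-plane shows a hollow ring
# near the mid-diameter of the 0.8 um stained shell (5.2 um for the 6 um
# bead, pulled slightly inward by the blur): the tomographic step, not the
# projections, carries the 3D information.
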