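"""Readers and writers for interferogram stacks, spectral cubes, tomograms.

HDF5 is the canonical interchange format (datasets carry unit attributes:
OPD in um, wavenumber in cm^-1, wavelength in nm); multi-page TIFF plus a
YAML sidecar listing the OPD positions is supported for import/export
convenience.  ``RunConfig`` validates a full pipeline configuration up
front and rejects unknown keys.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .fts import InterferogramStack, OPDAxis, SpectralCube
from .optics import SystemConfig
from .tomo import Tomogram

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_cube",
    "write_cube",
    "read_tomogram",
    "write_tomogram",
]


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    input_path: str | None = None
    output_path: str | None = None
    system: dict = Field(default_factory=dict)
    apodization: str = "norton_beer_medium"
    wavenumber_points: int = 2048
    mask_k: float = 6.0
    rl_iterations: int = 10
    positivity_iterations: int = 50
    seed: int = 0
    verbosity: int = 1

    def system_config(self) -> SystemConfig:
        return SystemConfig(**self.system)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".opd.yaml")


def write_stack(path: str | Path, stack: InterferogramStack) -> None:
    """Write a stack as HDF5 (.h5/.hdf5) or multi-page TIFF + OPD sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("intensities", data=stack.intensities)
            d.attrs["units"] = "camera counts"
            o = f.create_dataset("opd_um", data=stack.opd.positions_um)
            o.attrs["units"] = "um"
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.intensities.astype(np.float32))
        _sidecar_path(path).write_text(
            yaml.safe_dump({"opd_um": stack.opd.positions_um.tolist()})
        )
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")


def read_stack(path: str | Path) -> InterferogramStack:
    """Read a stack written by :func:`write_stack`; enforces frame/OPD count
    agreement and OPD monotonicity."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            intensities = f["intensities"][()]
            opd_um = f["opd_um"][()]
    elif path.suffix in (".tif", ".tiff"):
        intensities = np.asarray(tifffile.imread(path), dtype=float)
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing OPD sidecar {sidecar}")
        opd_um = np.asarray(yaml.safe_load(sidecar.read_text())["opd_um"], float)
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}")
    if intensities.ndim == 2:  # single-frame TIFF edge case
        intensities = intensities[None]
    if intensities.shape[0] != opd_um.size:
        raise ValueError(
            f"frame count {intensities.shape[0]} does not match "
            f"OPD count {opd_um.size}"
        )
    return InterferogramStack(intensities, OPDAxis(opd_um))


def write_cube(
    path: str | Path, cube: SpectralCube, tiff_dir: str | Path | None = None
) -> None:
    """Write a spectral cube as HDF5; optionally export per-wavelength TIFFs."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        a = f.create_dataset("amplitudes", data=cube.amplitudes)
        a.attrs["units"] = "spectral magnitude"
        s = f.create_dataset("wavenumber_cm1", data=cube.wavenumber_cm1)
        s.attrs["units"] = "cm^-1"
        w = f.create_dataset("wavelength_nm", data=cube.wavelength_nm)
        w.attrs["units"] = "nm"
    if tiff_dir is not None:
        tiff_dir = Path(tiff_dir)
        tiff_dir.mkdir(parents=True, exist_ok=True)
        for i, lam in enumerate(cube.wavelength_nm):
            tifffile.imwrite(
                tiff_dir / f"plane_{lam:07.2f}nm.tif",
                cube.amplitudes[i].astype(np.float32),
            )


def read_cube(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        return SpectralCube(f["amplitudes"][()], f["wavenumber_cm1"][()])


def write_tomogram(path: str | Path, tomogram: Tomogram) -> None:
    """Write a tomogram as an HDF5 volume or a z-stack TIFF (one page per z)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("intensity", data=tomogram.data)
            d.attrs["units"] = "fluorescence intensity"
            d.attrs["voxel_um"] = tomogram.voxel_um
            if tomogram.wavelength_nm is not None:
                d.attrs["wavelength_nm"] = tomogram.wavelength_nm
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            tomogram.data.astype(np.float32),
            metadata={"voxel_um": tomogram.voxel_um},
        )
    else:
        raise ValueError(f"unsupported tomogram format {path.suffix!r}")


def read_tomogram(path: str | Path, voxel_um: float | None = None) -> Tomogram:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["intensity"]
            return Tomogram(
                d[()],
                float(d.attrs["voxel_um"]),
                float(d.attrs["wavelength_nm"]) if "wavelength_nm" in d.attrs else None,
            )
    if path.suffix in (".tif", ".tiff"):
        if voxel_um is None:
            raise ValueError("voxel_um required when reading a TIFF tomogram")
        return Tomogram(np.asarray(tifffile.imread(path), float), voxel_um)
    raise ValueError(f"unsupported tomogram format {path.suffix!r}")
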