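"""Optical train geometry for snapshot projection tomography.

A micro-lens array (MLA) placed in a plane conjugate to the objective back
focal plane (BFP) splits the fluorescence light into a grid of sub-images,
each a parallel projection of the sample seen from the direction set by the
lenslet's position in the pupil.  This module computes the viewing angles,
magnifications, field of view and per-lenslet diffraction limits from the
catalog parameters of the optical components.

Angles follow the convention that the viewing direction of lenslet (m, n)
has direction-cosine signs matching the signs of m and n; ``alpha`` is the
angle of the direction projected onto the x-z plane, ``beta`` onto y-z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "SystemConfig",
    "LensletGrid",
    "ViewingAngle",
    "viewing_angles",
    "overall_magnification",
    "field_of_view",
    "pixel_resolution_at_sample",
    "lenslet_diffraction_limit",
]

#: half-integer lenslet indices of the 6x6 array
DEFAULT_LENSLET_INDICES = tuple(
    (m / 2, n / 2) for m in (-5, -3, -1, 1, 3, 5) for n in (-5, -3, -1, 1, 3, 5)
)

_IMMERSION_INDEX = 1.518  # oil immersion


@dataclass(frozen=True)
class SystemConfig:
    """All optical parameters governing the system geometry.

    Defaults are the demonstrated system: 60x/1.4NA oil objective (200 mm
    reference tube length), a 2.86x demagnifying relay to the BFP conjugate,
    a 500 um pitch / 13.8 mm focal MLA acting as tube lens, a 4x second
    relay, and a 13 um pixel EMCCD.
    """

    objective_magnification: float = 60.0
    objective_na: float = 1.4
    reference_tube_focal_mm: float = 200.0
    relay_demag: float = 2.86
    mla_pitch_um: float = 500.0
    mla_focal_mm: float = 13.8
    relay2_mag: float = 4.0
    camera_pixel_um: float = 13.0
    design_wavelength_nm: float = 530.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"SystemConfig.{name} must be positive, got {value!r}")
        if self.objective_na >= _IMMERSION_INDEX:
            raise ValueError(
                f"objective NA {self.objective_na} must be below the immersion "
                f"index {_IMMERSION_INDEX}"
            )

    @property
    def objective_focal_mm(self) -> float:
        """f1 from the manufacturer's reference tube length convention."""
        return self.reference_tube_focal_mm / self.objective_magnification

    @property
    def bfp_pitch_mm(self) -> float:
        """Lenslet pitch referred to the objective back focal plane."""
        return self.mla_pitch_um * 1e-3 * self.relay_demag

    @property
    def pupil_radius_mm(self) -> float:
        return self.objective_na * self.objective_focal_mm

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SystemConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown SystemConfig keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ViewingAngle:
    """Viewing direction of one lenslet, as angles of its projections onto
    the x-z (alpha) and y-z (beta) planes measured from the optical axis."""

    alpha_rad: float
    beta_rad: float

    def __post_init__(self) -> None:
        if not (abs(self.alpha_rad) < math.pi / 2 and abs(self.beta_rad) < math.pi / 2):
            raise ValueError("viewing angles must satisfy |alpha|, |beta| < pi/2")

    @property
    def alpha_deg(self) -> float:
        return math.degrees(self.alpha_rad)

    @property
    def beta_deg(self) -> float:
        return math.degrees(self.beta_rad)

    @property
    def tangents(self) -> tuple[float, float]:
        """(tan alpha, tan beta): transverse slopes of the viewing ray."""
        return math.tan(self.alpha_rad), math.tan(self.beta_rad)


@dataclass
class LensletGrid:
    """The lenslet index set with per-lenslet usability flags.

    A lenslet is usable for reconstruction only if (a) its center falls
    inside the objective pupil (radius NA*f1) and (b) its viewing angle is
    real, i.e. f1^2 > (m^2+n^2) p^2 with p the pitch at the BFP.
    """

    indices: tuple[tuple[float, float], ...]
    pitch_at_bfp_um: float
    in_pupil: tuple[bool, ...]
    angle_defined: tuple[bool, ...] = field(default=())

    @classmethod
    def build(
        cls,
        config: SystemConfig,
        indices: tuple[tuple[float, float], ...] = DEFAULT_LENSLET_INDICES,
    ) -> "LensletGrid":
        p_mm = config.bfp_pitch_mm
        f1 = config.objective_focal_mm
        in_pupil = []
        angle_defined = []
        for m, n in indices:
            r = math.hypot(m * p_mm, n * p_mm)
            in_pupil.append(r <= config.pupil_radius_mm)
            angle_defined.append(f1 * f1 > (m * m + n * n) * p_mm * p_mm)
        return cls(
            indices=tuple(indices),
            pitch_at_bfp_um=p_mm * 1e3,
            in_pupil=tuple(in_pupil),
            angle_defined=tuple(angle_defined),
        )

    @property
    def valid(self) -> tuple[bool, ...]:
        return tuple(p and a for p, a in zip(self.in_pupil, self.angle_defined))

    def valid_indices(self) -> list[tuple[float, float]]:
        return [idx for idx, ok in zip(self.indices, self.valid) if ok]


def viewing_angles(grid: LensletGrid, config: SystemConfig) -> list[ViewingAngle]:
    """Viewing angles for the usable lenslets of ``grid``, in index order.

    alpha_m = atan( m p / sqrt(f1^2 - (m^2+n^2) p^2) ), beta_n analogous,
    with p the lenslet pitch referred to the BFP and f1 the objective focal
    length.  Lenslets whose angle is undefined (argument of the square root
    non-positive) or whose center lies outside the pupil are excluded, not
    silently zeroed; use ``grid.valid`` to know which entries survive.
    """
    p = grid.pitch_at_bfp_um * 1e-3  # mm
    f1 = config.objective_focal_mm
    out: list[ViewingAngle] = []
    for (m, n), ok in zip(grid.indices, grid.valid):
        if not ok:
            continue
        denom_sq = f1 * f1 - (m * m + n * n) * p * p
        # guaranteed > 0 by the valid flag, but guard against misuse
        if denom_sq <= 0:
            raise ValueError(f"lenslet {(m, n)} has no real viewing angle")
        denom = math.sqrt(denom_sq)
        out.append(ViewingAngle(math.atan2(m * p, denom), math.atan2(n * p, denom)))
    return out


def overall_magnification(config: SystemConfig) -> float:
    """Lateral magnification of the full train: (f_MLA/f1) * relay_demag * relay2."""
    return (
        config.mla_focal_mm / config.objective_focal_mm
    ) * config.relay_demag * config.relay2_mag


def field_of_view(config: SystemConfig) -> float:
    """Extent (um) of one lenslet sub-image referred to the sample plane."""
    return config.mla_pitch_um * config.relay2_mag / overall_magnification(config)


def pixel_resolution_at_sample(config: SystemConfig) -> float:
    """Camera pixel pitch referred to the sample plane (um)."""
    return config.camera_pixel_um / overall_magnification(config)


def lenslet_diffraction_limit(
    config: SystemConfig,
    aperture: str = "width",
    wavelength_nm: float | None = None,
) -> float:
    """Diffraction-limited transverse resolution (um) of one lenslet sub-image.

    The effective NA of a single lenslet is set by the fraction of the pupil
    it samples: NA_lenslet = (aperture_extent * relay_demag / 2) / f1, where
    the aperture extent is the lenslet pitch (``aperture="width"``) or
    pitch*sqrt(2) (``aperture="diagonal"`` of the square aperture).  Returns
    wavelength / (2 NA_lenslet).
    """
    if wavelength_nm is None:
        wavelength_nm = config.design_wavelength_nm
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    if aperture == "width":
        extent_mm = config.mla_pitch_um * 1e-3
    elif aperture == "diagonal":
        extent_mm = config.mla_pitch_um * 1e-3 * math.sqrt(2.0)
    else:
        raise ValueError(f"aperture must be 'width' or 'diagonal', got {aperture!r}")
    na_lenslet = (extent_mm * config.relay_demag / 2.0) / config.objective_focal_mm
    if na_lenslet >= config.objective_na:
        raise ValueError(
            f"lenslet NA {na_lenslet:.3f} exceeds the objective NA "
            f"{config.objective_na}; the lenslet cannot out-resolve the full pupil"
        )
    return wavelength_nm * 1e-3 / (2.0 * na_lenslet)
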