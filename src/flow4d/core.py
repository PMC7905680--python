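"""Core domain types and unit conventions.

All numerics run in CGS units (cm, s, g, erg, poise) to match the blood
constants used in cardiovascular 4D-flow work (density 1.06 g/cm^3,
viscosity 0.04 poise).  Grid spacings are user-facing in millimetres (the
scanner convention) and converted to centimetres internally; velocities are
cm/s throughout.

Coordinate convention: voxel index (0-based) times spacing gives the
physical position of the voxel centre; the velocity component order is
(x, y, z), matching the spatial axis order of the arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

MM_PER_CM = 10.0

#: Blood density (g/cm^3) and dynamic viscosity (poise) used throughout.
BLOOD_DENSITY = 1.06
BLOOD_VISCOSITY = 0.04


class AlignmentError(ValueError):
    """A mask or field does not share the grid it is combined with."""


class GeometryError(ValueError):
    """A generated object does not fit inside the voxel grid."""


class ResolutionError(ValueError):
    """The grid is too coarse to resolve the requested structure."""


class ReductionError(ValueError):
    """A masked reduction has no valid voxels to reduce over."""


class DesignError(ValueError):
    """A cohort design violates its preconditions."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid with uniform frame timing over one cardiac cycle.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``; each must be >= 8.
    spacing_mm
        Voxel spacing per axis in millimetres (scanner convention).
    n_frames
        Reconstructed time frames per cardiac cycle (>= 2).
    rr_interval
        Cardiac cycle length in seconds.
    """

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float] = (1.25, 1.25, 1.25)
    n_frames: int = 20
    rr_interval: float = 1.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"grid shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.rr_interval <= 0:
            raise ValueError(f"rr_interval must be positive, got {self.rr_interval}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def spacing_cm(self) -> Tuple[float, float, float]:
        return tuple(s / MM_PER_CM for s in self.spacing_mm)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_cm
        return sx * sy * sz

    @property
    def frame_times(self) -> np.ndarray:
        """Uniform frame times t_k = k * RR / n_frames (s)."""
        return np.arange(self.n_frames) * self.rr_interval / self.n_frames

    @property
    def dt(self) -> float:
        return self.rr_interval / self.n_frames

    def coordinates_cm(self, centered: bool = True):
        """Per-axis physical coordinates of voxel centres (cm).

        With ``centered=True`` the origin sits at the grid centre, which is
        where the synthetic generators place their structures.
        """
        out = []
        for n, h in zip(self.shape, self.spacing_cm):
            c = np.arange(n) * h
            if centered:
                c = c - c.mean()
            out.append(c)
        return out

    def meshgrid_cm(self, centered: bool = True):
        return np.meshgrid(*self.coordinates_cm(centered), indexing="ij")


@dataclass
class VelocityField4D:
    """Time-resolved 3-component velocity on a voxel grid.

    ``values`` is indexed ``[frame, component, x, y, z]`` in cm/s with
    component order (x, y, z).  ``venc`` is the velocity-encoding limit of
    the emulated acquisition; magnitudes may exceed it only when the
    generator flags ``aliased``.
    """

    values: np.ndarray
    grid: GridSpec
    venc: float = 150.0
    aliased: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_frames, 3, *self.grid.shape)
        if self.values.shape != expected:
            raise AlignmentError(
                f"velocity array shape {self.values.shape} does not match grid "
                f"expectation {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def speed(self) -> np.ndarray:
        """|u| per frame per voxel (cm/s)."""
        return np.sqrt((self.values**2).sum(axis=1))

    def scaled(self, factor: float) -> "VelocityField4D":
        return VelocityField4D(self.values * factor, self.grid, self.venc, self.aliased)


@dataclass
class VentricleMask:
    """Static boolean voxel set segmented from the end-diastolic frame."""

    voxels: np.ndarray
    chamber: str = "LV"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3-D boolean grid")
        if not self.voxels.any():
            raise ValueError("ventricle mask is empty")
        if self.chamber not in ("LV", "RV"):
            raise ValueError(f"chamber must be 'LV' or 'RV', got {self.chamber!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class FluidConstants:
    """Blood density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = BLOOD_DENSITY
    mu: float = BLOOD_VISCOSITY

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity (cm^2/s)."""
        return self.mu / self.rho
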