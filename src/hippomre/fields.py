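"""Core voxel-grid containers shared across the pipeline.

All grids are axis-aligned and isotropic; voxel index ``i`` maps to the
physical coordinate ``i * spacing_mm`` along each axis (voxel centres sit on
the lattice, 0-based).  Fields may live on 2-D or 3-D grids; the forward
solver and inversion treat both uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ComplexModulusField", "DisplacementField", "grid_affine"]


def grid_affine(spacing_mm: float, ndim: int = 3) -> np.ndarray:
    """4x4 voxel->mm affine for an isotropic grid with the origin at voxel 0."""
    aff = np.eye(4)
    for k in range(min(ndim, 3)):
        aff[k, k] = spacing_mm
    return aff


@dataclass
class ComplexModulusField:
    """Voxelwise complex shear modulus G* = G' + iG''.

    Attributes
    ----------
    gp : ndarray
        Storage modulus G' in Pa (elastic part); must be positive wherever
        the material is evaluated.
    gpp : ndarray
        Loss modulus G'' in Pa (viscous part); non-negative.
    spacing_mm : float
        Isotropic voxel edge length in millimetres.
    """

    gp: np.ndarray
    gpp: np.ndarray
    spacing_mm: float = 1.6

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=float)
        self.gpp = np.asarray(self.gpp, dtype=float)
        if self.gp.shape != self.gpp.shape:
            raise ValueError("G' and G'' grids must share a shape")
        if self.gp.ndim not in (2, 3):
            raise ValueError("modulus fields must be 2-D or 3-D")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gp.shape

    @property
    def ndim(self) -> int:
        return self.gp.ndim

    @property
    def gstar(self) -> np.ndarray:
        """Complex modulus G' + iG'' [Pa]."""
        return self.gp + 1j * self.gpp

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.spacing_mm, self.ndim)

    def copy(self) -> "ComplexModulusField":
        return ComplexModulusField(self.gp.copy(), self.gpp.copy(), self.spacing_mm)


@dataclass
class DisplacementField:
    """Complex harmonic displacement amplitude on the modulus grid.

    Scalar mode stores one complex value per voxel (the out-of-plane shear
    component in 2-D plane-strain, or a single polarisation in 3-D).
    """

    u: np.ndarray
    spacing_mm: float = 1.6
    frequency_hz: float = 50.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.ndim not in (2, 3):
            raise ValueError("displacement fields must be 2-D or 3-D")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.u.shape

    @property
    def ndim(self) -> int:
        return self.u.ndim

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.spacing_mm, self.u.ndim)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.u.copy(), self.spacing_mm, self.frequency_hz)
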