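"""Synthetic viscoelastic phantoms with known ground truth.

A phantom is a voxel grid of complex shear modulus G* = G' + iG'' holding a
soft-tissue background, one or more stiff/damped inclusions that emulate
hippocampus-like structures, and optional fluid (CSF-like) regions described
by a partial-volume map.  Every downstream stage — forward wave simulation,
nonlinear inversion, ROI summarisation — is exercised against these phantoms,
so the rasterisation here is deliberately simple and exactly reproducible:
a voxel belongs to a primitive iff its centre does.

Geometry primitives are spheres, axis-aligned ellipsoids and boxes; centres
are given in voxel units, sizes in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fields import ComplexModulusField
from .roi import RegionMaskSet

__all__ = [
    "Inclusion",
    "CsfRegion",
    "PhantomSpec",
    "make_phantom",
    "reference_phantom_spec",
]

#: Fluid-like moduli used for CSF voxels in the forward model.  CSF is close
#: to an inviscid fluid at 50 Hz; a very small storage modulus keeps the
#: Helmholtz operator well defined while making the region mechanically
#: "fluid" (high damping, short wavelength).
CSF_GP_PA = 10.0
CSF_GPP_PA = 10.0


@dataclass
class Inclusion:
    """A homogeneous viscoelastic inclusion.

    ``shape`` is one of ``sphere``, ``ellipsoid``, ``box``.  ``radius_mm`` is
    the sphere radius, the per-axis semi-axes of an ellipsoid, or the
    per-axis half-extents of a box.
    """

    center_vox: tuple[float, ...]
    radius_mm: float | tuple[float, ...]
    gp_pa: float
    gpp_pa: float
    label: str
    shape: str = "sphere"


@dataclass
class CsfRegion:
    """A fluid region contributing to the CSF partial-volume map.

    The partial volume is 1 inside the primitive and falls off linearly to 0
    over ``feather_mm`` outside its surface (feather 0 gives a binary map),
    mimicking the partial-volume profile of a resampled tissue segmentation.
    """

    center_vox: tuple[float, ...]
    radius_mm: float | tuple[float, ...]
    shape: str = "sphere"
    feather_mm: float = 1.6


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom."""

    grid_shape: tuple[int, ...] = (40, 40)
    voxel_size_mm: float = 1.6
    background_gp_pa: float = 2150.0
    background_gpp_pa: float = 430.0
    inclusions: Sequence[Inclusion] = field(default_factory=list)
    csf_regions: Sequence[CsfRegion] = field(default_factory=list)
    density_kg_m3: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) not in (2, 3):
            raise ValueError("grid_shape must be 2-D or 3-D")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape dimensions must be >= 8")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.background_gp_pa <= 0:
            raise ValueError("background G' must be positive")
        if self.background_gpp_pa < 0:
            raise ValueError("background G'' must be non-negative")
        if self.density_kg_m3 <= 0:
            raise ValueError("density must be positive")
        labels = [inc.label for inc in self.inclusions]
        if len(labels) != len(set(labels)):
            raise ValueError("inclusion labels must be unique")
        for inc in self.inclusions:
            if np.any(np.asarray(inc.radius_mm, dtype=float) <= 0):
                raise ValueError(f"inclusion {inc.label!r} has non-positive size")
            if inc.gp_pa <= 0 or inc.gpp_pa < 0:
                raise ValueError(f"inclusion {inc.label!r} has invalid moduli")


def _primitive_membership(
    shape: str,
    center_vox: tuple[float, ...],
    size_mm: float | tuple[float, ...],
    grid_shape: tuple[int, ...],
    spacing: float,
) -> np.ndarray:
    """Boolean mask of voxel centres inside the primitive; vectorised."""
    coords = np.meshgrid(
        *[np.arange(n) * spacing for n in grid_shape], indexing="ij"
    )
    center_mm = np.asarray(center_vox, dtype=float) * spacing
    if shape == "sphere":
        r = float(np.asarray(size_mm).reshape(()))
        d2 = sum((c - cc) ** 2 for c, cc in zip(coords, center_mm))
        return d2 <= r**2
    size = np.broadcast_to(np.asarray(size_mm, dtype=float), (len(grid_shape),))
    if shape == "ellipsoid":
        q = sum(((c - cc) / s) ** 2 for c, cc, s in zip(coords, center_mm, size))
        return q <= 1.0
    if shape == "box":
        inside = np.ones(grid_shape, dtype=bool)
        for c, cc, s in zip(coords, center_mm, size):
            inside &= np.abs(c - cc) <= s
        return inside
    raise ValueError(f"unknown primitive shape {shape!r}")


def _surface_distance(
    region: CsfRegion, grid_shape: tuple[int, ...], spacing: float
) -> np.ndarray:
    """Signed-ish distance outside the primitive surface (0 inside), in mm."""
    coords = np.meshgrid(
        *[np.arange(n) * spacing for n in grid_shape], indexing="ij"
    )
    center_mm = np.asarray(region.center_vox, dtype=float) * spacing
    if region.shape == "sphere":
        r = float(np.asarray(region.radius_mm).reshape(()))
        d = np.sqrt(sum((c - cc) ** 2 for c, cc in zip(coords, center_mm)))
        return np.maximum(d - r, 0.0)
    size = np.broadcast_to(
        np.asarray(region.radius_mm, dtype=float), (len(grid_shape),)
    )
    if region.shape == "ellipsoid":
        # Approximate outside distance by scaling the normalized radius with
        # the smallest semi-axis; exact enough for a feathered profile.
        q = np.sqrt(
            sum(((c - cc) / s) ** 2 for c, cc, s in zip(coords, center_mm, size))
        )
        return np.maximum(q - 1.0, 0.0) * size.min()
    if region.shape == "box":
        out = np.zeros(grid_shape)
        for c, cc, s in zip(coords, center_mm, size):
            out += np.maximum(np.abs(c - cc) - s, 0.0) ** 2
        return np.sqrt(out)
    raise ValueError(f"unknown primitive shape {region.shape!r}")


def make_phantom(spec: PhantomSpec) -> tuple[ComplexModulusField, RegionMaskSet]:
    """Rasterise a phantom onto its voxel grid.

    Returns the complex modulus field and a mask set holding one binary label
    per inclusion, the CSF partial-volume map in [0, 1], and a brain mask
    (all voxels).  Moduli inside CSF are blended linearly with fluid-like
    values according to the partial-volume fraction, so partially
    contaminated voxels are mechanically intermediate — the situation the
    CSF-exclusion pipeline exists to guard against.

    Deterministic: the same spec always produces the same phantom (the seed
    is carried for downstream noise stages, not used here).
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    h = spec.voxel_size_mm

    gp = np.full(shape, spec.background_gp_pa, dtype=float)
    gpp = np.full(shape, spec.background_gpp_pa, dtype=float)

    masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    for inc in spec.inclusions:
        member = _primitive_membership(inc.shape, inc.center_vox, inc.radius_mm, shape, h)
        if not member.any():
            raise ValueError(f"inclusion {inc.label!r} lies outside the grid")
        # the primitive must be fully contained: check its bounding extent
        center_mm = np.asarray(inc.center_vox, dtype=float) * h
        ext = np.broadcast_to(np.asarray(inc.radius_mm, dtype=float), (len(shape),))
        hi = np.array([(n - 1) * h for n in shape])
        if np.any(center_mm - ext < -h / 2) or np.any(center_mm + ext > hi + h / 2):
            raise ValueError(f"inclusion {inc.label!r} extends outside the grid")
        if (member & occupied).any():
            raise ValueError(f"inclusion {inc.label!r} overlaps another label")
        occupied |= member
        masks[inc.label] = member.astype(np.uint8)
        gp[member] = inc.gp_pa
        gpp[member] = inc.gpp_pa

    csf_pv = np.zeros(shape, dtype=float)
    for region in spec.csf_regions:
        if region.feather_mm > 0:
            dist = _surface_distance(region, shape, h)
            pv = np.clip(1.0 - dist / region.feather_mm, 0.0, 1.0)
        else:
            pv = _primitive_membership(
                region.shape, region.center_vox, region.radius_mm, shape, h
            ).astype(float)
        csf_pv = np.maximum(csf_pv, pv)

    if spec.csf_regions:
        gp = (1.0 - csf_pv) * gp + csf_pv * CSF_GP_PA
        gpp = (1.0 - csf_pv) * gpp + csf_pv * CSF_GPP_PA

    props = ComplexModulusField(gp, gpp, h)
    mask_set = RegionMaskSet(
        masks=masks,
        csf_pv=csf_pv,
        brain=np.ones(shape, dtype=np.uint8),
        spacing_mm=h,
    )
    return props, mask_set


def reference_phantom_spec(
    grid_shape: tuple[int, ...] = (40, 40),
    voxel_size_mm: float = 1.6,
    with_csf: bool = False,
    csf_center: tuple[float, ...] | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """Two-region reference phantom used throughout the test battery.

    Background mimics cerebrum-like tissue (G' = 2150 Pa, G'' = 430 Pa,
    damping ratio 0.10, stiffness ~2.2 kPa); the central spherical inclusion
    is hippocampus-like (G' = 2750 Pa, G'' = 990 Pa, damping ratio 0.18,
    stiffness ~3.0 kPa), radius 8 mm.  Optionally a fluid region abuts the
    inclusion border to emulate periventricular CSF contamination.
    """
    center = tuple((n - 1) / 2 for n in grid_shape)
    inclusions = [
        Inclusion(
            center_vox=center,
            radius_mm=8.0,
            gp_pa=2750.0,
            gpp_pa=990.0,
            label="hippocampus",
        )
    ]
    csf_regions: list[CsfRegion] = []
    if with_csf:
        if csf_center is None:
            # touch the inclusion border from the +axis0 side
            csf_center = (center[0] + 8.0 / voxel_size_mm + 1.0,) + center[1:]
        csf_regions.append(
            CsfRegion(center_vox=csf_center, radius_mm=4.0, feather_mm=2.4)
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        inclusions=inclusions,
        csf_regions=csf_regions,
        seed=seed,
    )
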