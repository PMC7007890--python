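"""ROI mask handling and regional viscoelastic summaries.

Implements the mask chain used to read out hippocampal properties from an
inverted modulus field: affine mask transfer onto the measurement grid with
a high occupancy threshold (95%) against partial-volume dilution, strict
exclusion of any voxel containing CSF, voxelwise damping-ratio and
shear-stiffness maps, and per-region summaries with head-size (eTIV)
volume normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fields import ComplexModulusField

__all__ = [
    "RegionMaskSet",
    "DerivedMaps",
    "RegionalSummary",
    "transform_mask",
    "exclude_csf",
    "derived_maps",
    "regional_summary",
    "damping_ratio",
    "shear_stiffness",
]


@dataclass
class RegionMaskSet:
    """Named binary masks plus a CSF partial-volume map on one grid.

    ``provenance`` records, per mask, the processing flags applied so far
    (``raw``, ``thresholded``, ``csf_excluded``).  ``csf_removed`` stores,
    for masks that went through CSF exclusion, the voxels removed — the
    inversion leaves these as freely updating distributed properties with
    no soft-prior coupling.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    csf_pv: np.ndarray | None = None
    brain: np.ndarray | None = None
    spacing_mm: float = 1.6
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)
    csf_removed: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            arr = np.asarray(m)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"mask {name!r} is not binary")
            self.masks[name] = arr.astype(np.uint8)
            self.provenance.setdefault(name, ("raw",))
        if self.csf_pv is not None:
            pv = np.asarray(self.csf_pv, dtype=float)
            if pv.min() < 0 or pv.max() > 1:
                raise ValueError("csf_pv must lie in [0, 1]")
            self.csf_pv = pv

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def with_bilateral(self, left: str = "left_hc", right: str = "right_hc") -> "RegionMaskSet":
        """Add the union mask ``bilateral_hc`` from left/right if present."""
        if left in self.masks and right in self.masks:
            self.masks["bilateral_hc"] = (
                (self.masks[left] | self.masks[right]).astype(np.uint8)
            )
            prov = tuple(
                sorted(set(self.provenance[left]) & set(self.provenance[right]))
            )
            self.provenance["bilateral_hc"] = prov or ("raw",)
        return self


def transform_mask(
    mask: np.ndarray,
    affine: np.ndarray,
    target_shape: tuple[int, ...],
    threshold: float = 0.95,
) -> np.ndarray:
    """Resample a binary mask through an affine and re-binarise.

    The mask is interpolated trilinearly at each target voxel centre mapped
    through ``affine`` (target voxel coords -> source voxel coords); only
    voxels whose interpolated occupancy reaches ``threshold`` survive.  The
    default 95% threshold discards partial-volume rims introduced by the
    resampling.
    """
    mask = np.asarray(mask, dtype=float)
    affine = np.asarray(affine, dtype=float)
    nd = mask.ndim
    if affine.shape not in ((nd, nd), (nd + 1, nd + 1)):
        raise ValueError("affine must be (n)x(n) linear or (n+1)x(n+1) homogeneous")
    if affine.shape == (nd, nd):
        hom = np.eye(nd + 1)
        hom[:nd, :nd] = affine
        affine = hom
    det = np.linalg.det(affine[:nd, :nd])
    if abs(det) < 1e-12:
        raise ValueError("affine is not invertible")
    # affine maps target voxel coordinates into source voxel coordinates;
    # ndimage.affine_transform pulls values from input at matrix@output+offset.
    resampled = ndimage.affine_transform(
        mask,
        matrix=affine[:nd, :nd],
        offset=affine[:nd, nd],
        output_shape=tuple(target_shape),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return (resampled >= threshold).astype(np.uint8)


def exclude_csf(
    mask: np.ndarray, csf_pv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop every mask voxel containing any CSF.

    Only voxels with exactly 0% CSF partial volume survive.  Returns the
    cleaned mask and the removed-voxel mask (the latter feeds the inversion,
    which releases those voxels from soft-prior coupling).
    """
    mask = np.asarray(mask)
    csf_pv = np.asarray(csf_pv, dtype=float)
    if mask.shape != csf_pv.shape:
        raise ValueError("mask and csf_pv shapes differ")
    if csf_pv.min() < 0 or csf_pv.max() > 1:
        raise ValueError("csf_pv must lie in [0, 1]")
    keep = (mask > 0) & (csf_pv == 0)
    removed = (mask > 0) & ~keep
    return keep.astype(np.uint8), removed.astype(np.uint8)


def exclude_csf_in_set(mask_set: RegionMaskSet, names: list[str] | None = None) -> RegionMaskSet:
    """Apply :func:`exclude_csf` to named masks of a set, updating provenance."""
    if mask_set.csf_pv is None:
        raise ValueError("mask set has no CSF partial-volume map")
    for name in names or list(mask_set.masks):
        cleaned, removed = exclude_csf(mask_set.masks[name], mask_set.csf_pv)
        mask_set.masks[name] = cleaned
        mask_set.csf_removed[name] = removed
        mask_set.provenance[name] = tuple(
            dict.fromkeys(mask_set.provenance.get(name, ()) + ("csf_excluded",))
        )
    return mask_set


def damping_ratio(gp: np.ndarray, gpp: np.ndarray) -> np.ndarray:
    """xi = G'' / (2 G'), the relative viscous-to-elastic behaviour."""
    return np.asarray(gpp, float) / (2.0 * np.asarray(gp, float))


def shear_stiffness(gp: np.ndarray, gpp: np.ndarray) -> np.ndarray:
    """mu = 2|G*|^2 / (|G*| + G'), in Pa.

    Equals rho c^2 for the plane-shear-wave phase speed c in a viscoelastic
    solid; reduces to G' in the elastic limit G'' = 0.
    """
    gp = np.asarray(gp, float)
    gpp = np.asarray(gpp, float)
    gabs = np.hypot(gp, gpp)
    return 2.0 * gabs**2 / (gabs + gp)


@dataclass
class DerivedMaps:
    """Voxelwise damping ratio and shear stiffness derived from G*."""

    xi: np.ndarray
    mu: np.ndarray
    valid: np.ndarray
    spacing_mm: float


def derived_maps(props: ComplexModulusField) -> DerivedMaps:
    """Compute xi and mu maps; voxels with G' <= 0 are masked out."""
    valid = props.gp > 0
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels with G' <= 0 masked out of derived maps")
    xi = np.full(props.shape, np.nan)
    mu = np.full(props.shape, np.nan)
    xi[valid] = damping_ratio(props.gp[valid], props.gpp[valid])
    mu[valid] = shear_stiffness(props.gp[valid], props.gpp[valid])
    return DerivedMaps(xi=xi, mu=mu, valid=valid, spacing_mm=props.spacing_mm)


@dataclass
class RegionalSummary:
    """Per-region central tendencies and volume, mirroring a cohort table row."""

    region: str
    mean_xi: float
    median_xi: float
    mean_mu_kpa: float
    median_mu_kpa: float
    voxel_count: int
    volume_cm3: float
    normalized_volume: float | None = None


def regional_summary(
    maps: DerivedMaps,
    masks: RegionMaskSet,
    etiv_cm3: float | None = None,
    regions: list[str] | None = None,
    require_csf_excluded: bool = True,
) -> dict[str, RegionalSummary]:
    """Summarise xi/mu over each named region.

    Volume is voxel count times voxel volume; normalised volume is the
    simple ratio volume / eTIV.  By default the masks are required to carry
    the ``csf_excluded`` provenance flag, since raw masks bias the regional
    damping ratio wherever fluid touches the ROI border.
    """
    out: dict[str, RegionalSummary] = {}
    voxel_cm3 = (masks.spacing_mm / 10.0) ** len(maps.xi.shape)
    for name in regions or list(masks.masks):
        m = masks.masks[name] > 0
        if require_csf_excluded and "csf_excluded" not in masks.provenance.get(name, ()):
            raise ValueError(f"region {name!r} has not been CSF-excluded")
        sel = m & maps.valid
        if not sel.any():
            raise ValueError(f"region {name!r} is empty after exclusion")
        xi = maps.xi[sel]
        mu = maps.mu[sel] / 1000.0  # Pa -> kPa
        count = int(sel.sum())
        vol = count * voxel_cm3
        out[name] = RegionalSummary(
            region=name,
            mean_xi=float(xi.mean()),
            median_xi=float(np.median(xi)),
            mean_mu_kpa=float(mu.mean()),
            median_mu_kpa=float(np.median(mu)),
            voxel_count=count,
            volume_cm3=float(vol),
            normalized_volume=(float(vol / etiv_cm3) if etiv_cm3 else None),
        )
    return out
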