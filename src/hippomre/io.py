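"""NIfTI / CSV / YAML input-output for pipeline artifacts.

Conventions: modulus fields are stored as paired float32 NIfTI volumes
(``*_gp.nii`` storage modulus, ``*_gpp.nii`` loss modulus, Pa); complex
displacement fields as ``*_re.nii`` / ``*_im.nii`` pairs; label masks as
uint8 and partial-volume maps as float32.  2-D grids are written as
single-slice 3-D volumes.  The voxel size is carried in the NIfTI affine.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec
from .fields import ComplexModulusField, DisplacementField, grid_affine
from .phantom import CsfRegion, Inclusion, PhantomSpec
from .roi import RegionMaskSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_modulus_field",
    "load_modulus_field",
    "save_displacement_field",
    "load_displacement_field",
    "save_mask_set",
    "save_cohort",
    "load_cohort",
    "phantom_spec_from_yaml",
    "cohort_spec_from_yaml",
]


def _to3d(arr: np.ndarray) -> np.ndarray:
    return arr[..., np.newaxis] if arr.ndim == 2 else arr


def save_volume(
    arr: np.ndarray, path: str | Path, spacing_mm: float, dtype=np.float32
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(_to3d(np.asarray(arr)).astype(dtype), grid_affine(spacing_mm))
    nib.save(img, path)
    return path


def load_volume(path: str | Path, squeeze: bool = True) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if squeeze and arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    spacing = float(img.header.get_zooms()[0])
    return arr, spacing


def save_modulus_field(props: ComplexModulusField, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    return [
        save_volume(props.gp, prefix.with_name(prefix.name + "_gp.nii"), props.spacing_mm),
        save_volume(props.gpp, prefix.with_name(prefix.name + "_gpp.nii"), props.spacing_mm),
    ]


def load_modulus_field(prefix: str | Path) -> ComplexModulusField:
    prefix = Path(prefix)
    gp, spacing = load_volume(prefix.with_name(prefix.name + "_gp.nii"))
    gpp, _ = load_volume(prefix.with_name(prefix.name + "_gpp.nii"))
    return ComplexModulusField(gp, gpp, spacing)


def save_displacement_field(field: DisplacementField, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    return [
        save_volume(field.u.real, prefix.with_name(prefix.name + "_re.nii"), field.spacing_mm),
        save_volume(field.u.imag, prefix.with_name(prefix.name + "_im.nii"), field.spacing_mm),
    ]


def load_displacement_field(
    prefix: str | Path, frequency_hz: float = 50.0
) -> DisplacementField:
    prefix = Path(prefix)
    re, spacing = load_volume(prefix.with_name(prefix.name + "_re.nii"))
    im, _ = load_volume(prefix.with_name(prefix.name + "_im.nii"))
    return DisplacementField(re + 1j * im, spacing, frequency_hz)


def save_mask_set(masks: RegionMaskSet, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, m in masks.masks.items():
        written.append(
            save_volume(m, directory / f"mask_{name}.nii", masks.spacing_mm, np.uint8)
        )
    if masks.csf_pv is not None:
        written.append(save_volume(masks.csf_pv, directory / "csf_pv.nii", masks.spacing_mm))
    if masks.brain is not None:
        written.append(
            save_volume(masks.brain, directory / "mask_brain.nii", masks.spacing_mm, np.uint8)
        )
    return written


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def phantom_spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Build a PhantomSpec from a YAML document.

    Expected keys mirror the dataclass fields; ``inclusions`` and
    ``csf_regions`` are lists of mappings.
    """
    raw = yaml.safe_load(Path(path).read_text())
    inclusions = [Inclusion(**d) for d in raw.pop("inclusions", [])]
    csf_regions = [CsfRegion(**d) for d in raw.pop("csf_regions", [])]
    for key in ("grid_shape",):
        if key in raw:
            raw[key] = tuple(raw[key])
    for inc in inclusions:
        inc.center_vox = tuple(inc.center_vox)
    for reg in csf_regions:
        reg.center_vox = tuple(reg.center_vox)
    return PhantomSpec(inclusions=inclusions, csf_regions=csf_regions, **raw)


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("age_range_years", "score_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "regional_params" in raw:
        raw["regional_params"] = {
            k: tuple(v) for k, v in raw["regional_params"].items()
        }
    return CohortSpec(**raw)
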