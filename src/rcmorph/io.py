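"""Reading and writing labeled segmentation volumes (NIfTI-1).

All downstream geometry assumes one *canonical* orientation: the first array
axis is the sagittal slice axis with slice index increasing lateral→medial,
and the anatomy has right-shoulder chirality.  Left shoulders are mirrored
across the sagittal plane at read time so left and right scans can be pooled
in a single morphometric analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .schema import RoiSchema, ScanRecord, SchemaError

__all__ = [
    "LabelVolume",
    "FormatError",
    "read_label_volume",
    "write_label_volume",
    "read_manifest",
]

# Scan-quality guard thresholds (mm/voxel): warn when exceeded.
MAX_SAGITTAL_SPACING_MM = 6.0
MAX_INPLANE_SPACING_MM = 1.0


class FormatError(ValueError):
    """Raised for non-3D volumes or missing/invalid spacing metadata."""


@dataclass(frozen=True)
class LabelVolume:
    """A canonicalized 3D integer label map with physical voxel spacing.

    Attributes
    ----------
    voxels
        3D integer array; axis 0 is sagittal (lateral→medial), axes 1 and 2
        are the in-plane row and column directions.
    spacing
        (sagittal, row, column) voxel spacing in mm.
    schema
        The :class:`~rcmorph.schema.RoiSchema` validating the voxel values.
    laterality
        Side the scan was acquired on; after canonicalization the array is
        in right-shoulder convention regardless.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    schema: RoiSchema
    laterality: str = "right"

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {self.voxels.ndim}D")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label volume must have an integer dtype")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        present = set(np.unique(self.voxels).tolist()) - {0}
        unknown = present - set(self.schema.valid_labels())
        if unknown:
            raise SchemaError(f"labels {sorted(unknown)} not in schema")

    # -- geometry helpers -------------------------------------------------

    @property
    def slice_spacing_mm(self) -> float:
        return float(self.spacing[0])

    @property
    def inplane_area_mm2(self) -> float:
        return float(self.spacing[1] * self.spacing[2])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing[0] * self.spacing[1] * self.spacing[2])

    def roi_mask(self, roi_name: str) -> np.ndarray:
        """Boolean mask of the voxels carrying ``roi_name``'s label."""
        return self.voxels == self.schema.label(roi_name)

    def muscle_boundary_mask(self, muscle: str) -> np.ndarray:
        """Muscle compartment mask: muscle voxels plus paired intramuscular fat."""
        return self.roi_mask(muscle) | self.roi_mask(self.schema.fat_roi(muscle))

    def roi_volume_ml(self, roi_name: str) -> float:
        return float(self.roi_mask(roi_name).sum()) * self.voxel_volume_mm3 / 1000.0


def roi_mask(vol: LabelVolume, roi_name: str) -> np.ndarray:
    """Functional alias for :meth:`LabelVolume.roi_mask`."""
    return vol.roi_mask(roi_name)


def _check_resolution(spacing: tuple[float, float, float]) -> None:
    if spacing[0] > MAX_SAGITTAL_SPACING_MM:
        warnings.warn(
            f"sagittal spacing {spacing[0]:.2f} mm exceeds the {MAX_SAGITTAL_SPACING_MM} mm "
            "scan-quality guideline",
            stacklevel=3,
        )
    if max(spacing[1], spacing[2]) > MAX_INPLANE_SPACING_MM:
        warnings.warn(
            f"in-plane spacing {max(spacing[1], spacing[2]):.2f} mm exceeds the "
            f"{MAX_INPLANE_SPACING_MM} mm scan-quality guideline",
            stacklevel=3,
        )


def canonicalize(vol: LabelVolume, lateral_to_medial: bool) -> LabelVolume:
    """Return ``vol`` in canonical orientation.

    ``lateral_to_medial`` states whether the stored axis-0 direction already
    runs lateral→medial.  If it does not, the volume is mirrored across the
    sagittal plane (axis-0 flip), which simultaneously fixes the slice
    ordering and converts a left shoulder to right-shoulder chirality.
    Canonicalizing an already-canonical volume is the identity.
    """
    if lateral_to_medial:
        return vol
    return replace(vol, voxels=np.ascontiguousarray(vol.voxels[::-1]))


def read_label_volume(
    path: str | Path,
    schema: RoiSchema,
    laterality: str = "right",
    lateral_to_medial: bool | None = None,
) -> LabelVolume:
    """Read a NIfTI label volume and canonicalize its orientation.

    Parameters
    ----------
    path
        NIfTI-1 file (.nii or .nii.gz) holding a 3D integer label map;
        voxel spacing is taken from the header.
    schema
        ROI schema; any voxel value outside it raises :class:`SchemaError`.
    laterality
        'left' or 'right'.  Used to infer the slice direction when
        ``lateral_to_medial`` is not given: by convention the stored axis 0
        increases toward the patient's left, so a right shoulder is already
        lateral→medial and a left shoulder must be mirrored.
    lateral_to_medial
        Explicit override: whether the file's axis 0 already runs
        lateral→medial.  ``None`` infers it from ``laterality``.
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"invalid voxel spacing in header: {zooms}")
    if not np.allclose(data, np.round(data)):
        raise FormatError("label volume contains non-integer voxel values")
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    _check_resolution(spacing)
    vol = LabelVolume(
        voxels=np.ascontiguousarray(data.astype(np.int16)),
        spacing=spacing,
        schema=schema,
        laterality=laterality,
    )
    if lateral_to_medial is None:
        lateral_to_medial = laterality == "right"
    return canonicalize(vol, lateral_to_medial=lateral_to_medial)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a canonical label volume to NIfTI-1 with spacing in the header."""
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> list[ScanRecord]:
    """Read a cohort manifest CSV.

    Expected columns: ``scan_id, path, age_years, sex, laterality``.
    """
    df = pd.read_csv(path)
    required = {"scan_id", "path", "age_years", "sex", "laterality"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            scan_id=str(row.scan_id),
            age_years=float(row.age_years),
            sex=str(row.sex),
            laterality=str(row.laterality),
            path=str(row.path),
        )
        for row in df.itertuples()
    ]
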