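"""Scapular cross-sectional-area profile and lateral morphometrics.

Clinical shoulder MRI captures only the lateral portion of the scapula.  The
slice containing the peak scapular cross-sectional area (CSA) is a landmark
that is reliably visible in that lateral window; four measures taken at and
relative to it summarize the lateral scapular morphology:

PD  sagittal distance (mm) from the most lateral scapular point to the
    peak-CSA slice;
PC  the peak CSA itself (mm²);
VB  vertical extent (mm) of the scapula's tight axis-aligned bounding box in
    the peak slice;
HB  horizontal extent (mm) of that bounding box.

These four predictors drive the total-scapula-length regression in
:mod:`rcmorph.length`.  The peak is searched only within the lateral half of
the *captured* scapular extent — a second, more medial CSA peak can exist
but lies outside the coverage of typical clinical scans and is not needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import LabelVolume

__all__ = [
    "CsaProfile",
    "LateralMorphometrics",
    "GeometryError",
    "compute_csa_profile",
    "find_peak_csa",
    "measure_lateral_morphometrics",
]


class GeometryError(ValueError):
    """Raised when a geometric measure is undefined (e.g. empty scapula)."""


@dataclass(frozen=True)
class CsaProfile:
    """Per-slice scapular CSA, ordered from the most lateral scapular slice.

    ``areas[i]`` is the scapular cross-sectional area (mm²) in sagittal
    slice ``lateral_origin_index + i``; the profile runs from the first to
    the last slice containing scapula.
    """

    areas: np.ndarray
    slice_spacing_mm: float
    lateral_origin_index: int

    def __post_init__(self) -> None:
        if len(self.areas) == 0:
            raise GeometryError("empty CSA profile")
        if self.areas[0] <= 0 or self.areas[-1] <= 0:
            raise GeometryError("CSA profile must start and end on nonzero scapula slices")
        if np.any(self.areas < 0):
            raise GeometryError("negative cross-sectional area")

    @property
    def captured_extent_mm(self) -> float:
        """Physical sagittal extent (slab thickness) of the captured scapula."""
        return float(len(self.areas) * self.slice_spacing_mm)


@dataclass(frozen=True)
class LateralMorphometrics:
    """The four scapula-length predictors plus the captured extent, in mm/mm²."""

    PD_mm: float
    PC_mm2: float
    VB_mm: float
    HB_mm: float
    captured_extent_mm: float

    def __post_init__(self) -> None:
        if self.PD_mm < 0 or self.PC_mm2 <= 0 or self.VB_mm <= 0 or self.HB_mm <= 0:
            raise GeometryError("morphometrics out of range (PD≥0, PC/VB/HB>0 required)")
        if self.PD_mm > self.captured_extent_mm:
            raise GeometryError("peak-CSA distance exceeds captured extent")

    def as_array(self) -> np.ndarray:
        """Predictor vector in the fixed order (PD, PC, VB, HB)."""
        return np.array([self.PD_mm, self.PC_mm2, self.VB_mm, self.HB_mm])


def compute_csa_profile(vol: LabelVolume) -> CsaProfile:
    """Per-slice scapular CSA from the most lateral scapular slice medially.

    Each area is the scapula voxel count in that slice times the in-plane
    voxel area, so summing ``areas * slice_spacing`` recovers the scapular
    volume exactly.
    """
    counts = vol.roi_mask("scapula").sum(axis=(1, 2))
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        raise GeometryError("scapula ROI is empty")
    origin, last = int(nz[0]), int(nz[-1])
    areas = counts[origin : last + 1].astype(float) * vol.inplane_area_mm2
    return CsaProfile(
        areas=areas,
        slice_spacing_mm=vol.slice_spacing_mm,
        lateral_origin_index=origin,
    )


def find_peak_csa(profile: CsaProfile, search_fraction: float = 0.5) -> int:
    """Index (into the profile) of the peak CSA within the lateral window.

    The search is restricted to the first ``ceil(search_fraction * n)``
    slices of the captured scapular extent; ties break to the most lateral
    slice.
    """
    if not 0 < search_fraction <= 1:
        raise ValueError(f"search_fraction must be in (0, 1], got {search_fraction}")
    n = len(profile.areas)
    window = max(1, math.ceil(search_fraction * n))
    return int(np.argmax(profile.areas[:window]))


def measure_lateral_morphometrics(
    vol: LabelVolume,
    profile: CsaProfile,
    peak_index: int,
    vertical_axis: int = 1,
) -> LateralMorphometrics:
    """Measure PD, PC, VB, HB at the peak-CSA slice.

    PD is the slice-center-to-slice-center distance from the lateral origin;
    VB/HB are extents of the tight axis-aligned bounding box of the scapula
    mask in the peak slice (voxel span × in-plane spacing).  ``vertical_axis``
    selects which in-plane array axis (1 or 2) maps to the anatomical
    vertical; the other is horizontal.
    """
    if not 0 <= peak_index < len(profile.areas):
        raise GeometryError(f"peak index {peak_index} outside profile of length {len(profile.areas)}")
    if vertical_axis not in (1, 2):
        raise ValueError("vertical_axis must be 1 or 2")
    plane = vol.roi_mask("scapula")[profile.lateral_origin_index + peak_index]
    if not plane.any():
        raise GeometryError("empty scapula mask at peak slice")
    rows = np.flatnonzero(plane.any(axis=1))
    cols = np.flatnonzero(plane.any(axis=0))
    row_extent = float((rows[-1] - rows[0] + 1) * vol.spacing[1])
    col_extent = float((cols[-1] - cols[0] + 1) * vol.spacing[2])
    if vertical_axis == 1:
        vb, hb = row_extent, col_extent
    else:
        vb, hb = col_extent, row_extent
    return LateralMorphometrics(
        PD_mm=float(peak_index * profile.slice_spacing_mm),
        PC_mm2=float(profile.areas[peak_index]),
        VB_mm=vb,
        HB_mm=hb,
        captured_extent_mm=profile.captured_extent_mm,
    )


def measure_scan(vol: LabelVolume, search_fraction: float = 0.5, vertical_axis: int = 1) -> LateralMorphometrics:
    """Convenience: profile → peak → morphometrics in one call."""
    profile = compute_csa_profile(vol)
    peak = find_peak_csa(profile, search_fraction)
    return measure_lateral_morphometrics(vol, profile, peak, vertical_axis=vertical_axis)
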