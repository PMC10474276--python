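"""ROI naming schema for shoulder segmentation label maps.

A label map holds up to eleven regions of interest: three bones (humerus,
scapula, clavicle) and, for each of the four rotator-cuff muscles
(supraspinatus, infraspinatus, teres minor, subscapularis), one muscle
compartment plus one paired intramuscular-fat compartment.  The schema maps
ROI names to integer voxel labels and records the muscle->fat pairing; it is
supplied as a JSON sidecar so third-party segmentations and synthetic
phantoms interoperate with the same code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "MUSCLES",
    "BONES",
    "RoiSchema",
    "ScanRecord",
    "SchemaError",
]

#: The four rotator-cuff muscles, in conventional reporting order.
MUSCLES: tuple[str, ...] = (
    "supraspinatus",
    "infraspinatus",
    "teres_minor",
    "subscapularis",
)

BONES: tuple[str, ...] = ("humerus", "scapula", "clavicle")


class SchemaError(ValueError):
    """Raised when a label map or schema violates the ROI contract."""


@dataclass(frozen=True)
class RoiSchema:
    """Mapping of ROI names to positive integer labels plus fat pairing.

    Parameters
    ----------
    labels
        ``{roi_name: integer label}``.  Labels must be positive and unique;
        background is implicitly 0 and never appears in the mapping.
    fat_pairs
        ``{muscle_name: fat_roi_name}`` linking each muscle to its
        intramuscular-fat compartment.  Every muscle present in ``labels``
        must have exactly one paired fat ROI that is also in ``labels``.
    """

    labels: Mapping[str, int]
    fat_pairs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = list(self.labels.values())
        if any((not isinstance(v, int)) or v <= 0 for v in vals):
            raise SchemaError("ROI labels must be positive integers (background is 0)")
        if len(set(vals)) != len(vals):
            raise SchemaError("ROI labels must be unique")
        for muscle, fat in self.fat_pairs.items():
            if muscle not in self.labels:
                raise SchemaError(f"fat pairing references unknown muscle {muscle!r}")
            if fat not in self.labels:
                raise SchemaError(f"fat pairing references unknown fat ROI {fat!r}")
        for muscle in self.muscles:
            if muscle not in self.fat_pairs:
                raise SchemaError(f"muscle {muscle!r} has no paired fat ROI")

    # -- lookups ---------------------------------------------------------

    @property
    def muscles(self) -> tuple[str, ...]:
        """Rotator-cuff muscles present in this schema, in canonical order."""
        return tuple(m for m in MUSCLES if m in self.labels)

    def label(self, roi_name: str) -> int:
        try:
            return self.labels[roi_name]
        except KeyError:
            raise SchemaError(f"unknown ROI name {roi_name!r}") from None

    def fat_roi(self, muscle: str) -> str:
        """Name of the intramuscular-fat ROI paired with ``muscle``."""
        try:
            return self.fat_pairs[muscle]
        except KeyError:
            raise SchemaError(f"no fat pairing for muscle {muscle!r}") from None

    def valid_labels(self) -> frozenset[int]:
        return frozenset(self.labels.values())

    # -- construction / serialization ------------------------------------

    @classmethod
    def default(cls) -> "RoiSchema":
        """The standard 11-ROI schema with labels 1..11."""
        names = [
            "humerus",
            "scapula",
            "clavicle",
            "supraspinatus",
            "supraspinatus_fat",
            "infraspinatus",
            "infraspinatus_fat",
            "teres_minor",
            "teres_minor_fat",
            "subscapularis",
            "subscapularis_fat",
        ]
        labels = {name: i + 1 for i, name in enumerate(names)}
        fat_pairs = {m: f"{m}_fat" for m in MUSCLES}
        return cls(labels=labels, fat_pairs=fat_pairs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSchema":
        with open(path) as fh:
            payload = json.load(fh)
        fat_pairs = payload.pop("fat_pairs", {})
        return cls(labels={k: int(v) for k, v in payload.items()}, fat_pairs=fat_pairs)

    def to_json(self, path: str | Path) -> None:
        payload: dict = dict(self.labels)
        payload["fat_pairs"] = dict(self.fat_pairs)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


#: Age-bin edges (years) for the normative subgrouping; bins are
#: right-open except the last: [15,30), [30,40), ..., [70,90).
AGE_BIN_EDGES: tuple[int, ...] = (15, 30, 40, 50, 60, 70, 90)
AGE_BIN_LABELS: tuple[str, ...] = ("15-29", "30-39", "40-49", "50-59", "60-69", "70-89")


def age_bin_label(age_years: float) -> str:
    """Normative age-bin label for an age, or raise if outside [15, 90)."""
    for lo, hi, label in zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:], AGE_BIN_LABELS):
        if lo <= age_years < hi:
            return label
    raise ValueError(f"age {age_years} outside the binned range [15, 90)")


@dataclass(frozen=True)
class ScanRecord:
    """Per-scan demographics and provenance for cohort analyses."""

    scan_id: str
    age_years: float
    sex: str
    laterality: str
    path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_years <= 120.0):
            raise ValueError(f"age {self.age_years} outside [0, 120]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
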