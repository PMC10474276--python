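"""Cumulative ROI-volume curves along the scapula and the three muscle metrics.

Every per-muscle quantity is expressed as a function of the percent location
``p`` along the *predicted* total scapula length, measured medially from the
most lateral scapular voxel.  Cumulative ROI volumes are exact at sagittal
slice boundaries (voxel count × voxel volume) and linearly interpolated
between boundaries onto the integer percent grid p = 1..100.  Grid points
beyond the captured coverage are missing (NaN), never extrapolated.

Three metrics are derived from the cumulative curves at each location p:

normalized muscle size      (muscle + intramuscular fat) / scapula   [–]
relative contribution       muscle share of the 4-muscle RC unit     [%]
fatty infiltration          fat / (muscle + fat)                     [%]

Muscle volume always includes the paired intramuscular fat except in the
fatty-infiltration numerator, which is the fat alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, LateralMorphometrics, compute_csa_profile, find_peak_csa, measure_lateral_morphometrics
from .io import LabelVolume
from .length import PredictedLength, ScapulaLengthRegressor, predict_length
from .schema import RoiSchema

__all__ = [
    "VolumeCurveSet",
    "ScanMetrics",
    "build_volume_curves",
    "normalized_muscle_size",
    "relative_contribution",
    "fat_infiltration",
    "compute_scan_metrics",
    "DEFAULT_COVERAGE_THRESHOLD_PCT",
]

PERCENT_GRID = np.arange(1, 101)

#: Scans covering less than this fraction of the predicted scapula length are
#: flagged as unreliable for population analysis.
DEFAULT_COVERAGE_THRESHOLD_PCT = 30.0


@dataclass(frozen=True)
class VolumeCurveSet:
    """Cumulative per-ROI volumes (ml) on the 1..100 percent grid.

    ``cumulative_ml`` is indexed by p = 1..100 with one column per ROI;
    values at p beyond ``coverage_percent`` are NaN.
    """

    cumulative_ml: pd.DataFrame
    predicted_length_mm: float
    coverage_percent: float
    schema: RoiSchema = field(repr=False)

    def value(self, roi: str, p: int) -> float:
        """Cumulative volume (ml) of ``roi`` at percent location ``p``."""
        if p not in self.cumulative_ml.index:
            raise ValueError(f"p must be an integer in 1..100, got {p}")
        v = self.cumulative_ml.at[p, roi]
        if np.isnan(v):
            raise ValueError(
                f"p={p} exceeds the captured coverage ({self.coverage_percent:.1f}%)"
            )
        return float(v)

    def muscle_with_fat(self, muscle: str, p: int) -> float:
        """Muscle-boundary volume (muscle + paired fat) in ml at ``p``."""
        return self.value(muscle, p) + self.value(self.schema.fat_roi(muscle), p)

    @property
    def defined_grid(self) -> np.ndarray:
        """The percent locations with defined (non-missing) values."""
        mask = ~self.cumulative_ml.iloc[:, 0].isna().to_numpy()
        return PERCENT_GRID[mask]


def build_volume_curves(
    vol: LabelVolume,
    predicted_length_mm: float | None = None,
) -> VolumeCurveSet:
    """Cumulative ROI-volume curves against percent of predicted scapula length.

    The depth origin is the most lateral scapular voxel; ROI voxels lateral
    to it (possible for teres minor insertions) are folded into the first
    percent bin.  ``predicted_length_mm=None`` treats the captured scapular
    extent as the full length (i.e. a complete-coverage scan).

    Cumulative volume at a sagittal slice boundary equals the exact voxel
    count up to that boundary times the voxel volume; the percent grid is
    filled by linear interpolation of the boundary values.
    """
    scap_counts = vol.roi_mask("scapula").sum(axis=(1, 2))
    nz = np.flatnonzero(scap_counts)
    if nz.size == 0:
        raise GeometryError("scapula ROI is empty")
    origin, last = int(nz[0]), int(nz[-1])
    dz = vol.slice_spacing_mm
    extent_mm = (last - origin + 1) * dz
    if predicted_length_mm is None:
        predicted_length_mm = extent_mm
    if predicted_length_mm < extent_mm - 1e-9:
        raise ValueError(
            f"predicted length {predicted_length_mm:.2f} mm is below the captured "
            f"scapular extent {extent_mm:.2f} mm (prediction should have been clamped)"
        )
    coverage = min(100.0, extent_mm / predicted_length_mm * 100.0)

    # Boundary cumulative volumes: boundaries k = 0..K sit at depth k*dz from
    # the scapular origin; boundary k accumulates all slices < origin + k,
    # including any ROI voxels lateral to the origin (folded into depth 0+).
    n_bound = last - origin + 2
    depths = np.arange(n_bound) * dz
    vox_ml = vol.voxel_volume_mm3 / 1000.0
    data = {}
    for roi in vol.schema.labels:
        counts = vol.roi_mask(roi).sum(axis=(1, 2)).astype(float)
        lateral_extra = counts[:origin].sum()
        cum = np.concatenate([[0.0], np.cumsum(counts[origin : last + 1])]) + lateral_extra
        cum_ml = cum * vox_ml
        d_grid = PERCENT_GRID / 100.0 * predicted_length_mm
        vals = np.interp(d_grid, depths, cum_ml)
        vals[d_grid > extent_mm + 1e-9] = np.nan
        data[roi] = vals
    frame = pd.DataFrame(data, index=pd.Index(PERCENT_GRID, name="p"))
    return VolumeCurveSet(
        cumulative_ml=frame,
        predicted_length_mm=float(predicted_length_mm),
        coverage_percent=float(coverage),
        schema=vol.schema,
    )


def normalized_muscle_size(curves: VolumeCurveSet, muscle: str, p: int) -> float:
    """Muscle size normalized for patient size at location ``p``.

    Ratio of cumulative muscle-plus-intramuscular-fat volume to cumulative
    scapular volume; dimensionless.
    """
    scap = curves.value("scapula", p)
    if scap <= 0:
        raise ValueError(f"zero scapula volume at p={p}")
    return curves.muscle_with_fat(muscle, p) / scap


def relative_contribution(curves: VolumeCurveSet, muscle: str, p: int) -> float:
    """One muscle's percent share of the four-muscle RC unit volume at ``p``.

    Each muscle's volume includes its paired intramuscular fat; the four
    contributions sum to 100% at every defined location.
    """
    total = sum(curves.muscle_with_fat(m, p) for m in curves.schema.muscles)
    if total <= 0:
        raise ValueError(f"zero total RC unit volume at p={p}")
    return curves.muscle_with_fat(muscle, p) / total * 100.0


def fat_infiltration(curves: VolumeCurveSet, muscle: str, p: int) -> float:
    """Percent of the muscle-boundary volume occupied by intramuscular fat at ``p``."""
    boundary = curves.muscle_with_fat(muscle, p)
    if boundary <= 0:
        raise ValueError(f"zero muscle boundary volume for {muscle} at p={p}")
    return curves.value(curves.schema.fat_roi(muscle), p) / boundary * 100.0


@dataclass(frozen=True)
class ScanMetrics:
    """Full per-scan output: long-format metric table plus coverage report."""

    table: pd.DataFrame
    morphometrics: LateralMorphometrics
    predicted_length: PredictedLength
    coverage_percent: float
    low_coverage: bool
    missing_muscles: tuple[str, ...]
    curves: VolumeCurveSet = field(repr=False)


def compute_scan_metrics(
    vol: LabelVolume,
    length_model: ScapulaLengthRegressor | None = None,
    coverage_threshold_pct: float = DEFAULT_COVERAGE_THRESHOLD_PCT,
    scan_id: str = "",
) -> ScanMetrics:
    """Run the whole per-scan pipeline: morphometrics → length → metrics.

    With ``length_model=None`` the captured scapular extent is used as the
    total length (complete-coverage analysis).  Muscles with no labeled
    voxels are reported in ``missing_muscles`` and excluded from the RC-unit
    denominator; their own metrics are NaN.
    """
    profile = compute_csa_profile(vol)
    peak = find_peak_csa(profile)
    morpho = measure_lateral_morphometrics(vol, profile, peak)
    if length_model is not None:
        pred = predict_length(length_model, morpho)
    else:
        pred = PredictedLength(length_mm=morpho.captured_extent_mm, clamped=False)
    curves = build_volume_curves(vol, pred.length_mm)

    muscles = curves.schema.muscles
    present = tuple(m for m in muscles if vol.roi_mask(m).any() or vol.roi_mask(curves.schema.fat_roi(m)).any())
    missing = tuple(m for m in muscles if m not in present)

    rows = []
    for p in curves.defined_grid:
        total = sum(curves.muscle_with_fat(m, int(p)) for m in present)
        scap = curves.value("scapula", int(p))
        for m in muscles:
            if m in missing:
                rows.append((scan_id, m, int(p), np.nan, np.nan, np.nan, np.nan))
                continue
            mv = curves.muscle_with_fat(m, int(p))
            fat = curves.value(curves.schema.fat_roi(m), int(p))
            rows.append(
                (
                    scan_id,
                    m,
                    int(p),
                    mv,
                    mv / scap if scap > 0 else np.nan,
                    mv / total * 100.0 if total > 0 else np.nan,
                    fat / mv * 100.0 if mv > 0 else np.nan,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "scan_id",
            "muscle",
            "p",
            "cumulative_ml",
            "normalized_size",
            "relative_contribution_pct",
            "fat_infiltration_pct",
        ],
    )
    table["coverage_pct"] = curves.coverage_percent
    return ScanMetrics(
        table=table,
        morphometrics=morpho,
        predicted_length=pred,
        coverage_percent=curves.coverage_percent,
        low_coverage=curves.coverage_percent < coverage_threshold_pct,
        missing_muscles=missing,
        curves=curves,
    )
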