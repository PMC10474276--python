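"""Rigid alignment of a full-coverage label map to a partial label map.

Full-coverage CT-derived segmentations are aligned to partial MRI-derived
segmentations with a rigid transform (rotation + translation, no scaling or
shearing) that maximizes overlap of a chosen ROI — by default the scapula,
the structure common to both scans.  The approach is purpose-built for label
maps: initialization by centroid and principal-axes alignment of the ROI
masks (trying the four proper-rotation sign combinations to resolve the
axis-sign ambiguity), followed by derivative-free local refinement of a
soft-Dice overlap.  Label resampling is always nearest-neighbor so label
identities are never blended.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .io import LabelVolume

__all__ = ["RigidTransform", "register_rigid", "apply_transform", "dice"]


@dataclass(frozen=True)
class RigidTransform:
    """A rigid map from moving-volume physical space to fixed-volume physical space.

    ``x_fixed = rotation @ x_moving + translation`` with physical coordinates
    in mm (voxel index × spacing).  ``dice`` is the hard-Dice overlap of the
    transformed moving ROI against the fixed ROI; the fixed grid geometry is
    carried along so the transform can be applied stand-alone.
    """

    rotation: np.ndarray
    translation: np.ndarray
    dice: float
    fixed_shape: tuple[int, int, int]
    fixed_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1): no reflection/scaling")

    def inverse(self) -> "RigidTransform":
        R = np.asarray(self.rotation)
        return replace(self, rotation=R.T, translation=-R.T @ np.asarray(self.translation))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two (possibly soft) masks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a * b).sum() / denom)


def _resample(
    moving: np.ndarray,
    moving_spacing: np.ndarray,
    fixed_shape: tuple[int, ...],
    fixed_spacing: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    order: int,
) -> np.ndarray:
    """Pull ``moving`` onto the fixed grid under x_f = R x_m + t (physical mm)."""
    # ndimage.affine_transform maps output index -> input index via
    # i_m = matrix @ i_f + offset;  i_m = D_m^-1 R^T (D_f i_f - t).
    Dm_inv = np.diag(1.0 / moving_spacing)
    matrix = Dm_inv @ R.T @ np.diag(fixed_spacing)
    offset = -Dm_inv @ R.T @ t
    # snap near-integer coefficients: round-off a few ulp below an integer
    # otherwise flips boundary voxels under nearest-neighbor resampling
    for arr in (matrix, offset):
        near = np.round(arr)
        snap = np.abs(arr - near) < 1e-9
        arr[snap] = near[snap]
    return ndimage.affine_transform(
        moving, matrix, offset=offset, output_shape=fixed_shape, order=order,
        mode="constant", cval=0.0, prefilter=False,
    )


def _principal_axes(mask: np.ndarray, spacing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid (mm) and right-handed principal-axes basis of a binary mask."""
    pts = np.argwhere(mask) * spacing
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    eigval, eigvec = np.linalg.eigh(cov)
    # descending eigenvalue order; enforce a right-handed basis
    V = eigvec[:, ::-1]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return centroid, V


def register_rigid(
    moving: LabelVolume,
    fixed: LabelVolume,
    roi: str = "scapula",
    seed: int = 0,
) -> RigidTransform:
    """Find the rigid transform aligning ``moving``'s ROI onto ``fixed``'s.

    Initialization: centroid + principal-axes alignment; the eigenvector
    sign ambiguity is resolved by scoring all four proper sign combinations
    and keeping the best.  Refinement: Powell search over the six rigid
    parameters (three rotation-vector components, three translations)
    maximizing soft Dice (linear interpolation of the moving mask), which is
    smooth in the parameters where the hard overlap is piecewise constant.
    The procedure is deterministic; ``seed`` is accepted for API symmetry
    with the stochastic stages of the pipeline.

    The returned transform's Dice is always at least the initialization's.
    """
    del seed  # deterministic: principal-axes init + Powell refinement
    m_mask = moving.roi_mask(roi)
    f_mask = fixed.roi_mask(roi)
    if not m_mask.any() or not f_mask.any():
        raise ValueError(f"ROI {roi!r} is empty in moving and/or fixed volume")
    m_sp = np.asarray(moving.spacing)
    f_sp = np.asarray(fixed.spacing)
    m_float = m_mask.astype(np.float32)
    f_float = f_mask.astype(np.float32)

    c_m, V_m = _principal_axes(m_mask, m_sp)
    c_f, V_f = _principal_axes(f_mask, f_sp)

    def soft_dice(R: np.ndarray, t: np.ndarray) -> float:
        warped = _resample(m_float, m_sp, f_mask.shape, f_sp, R, t, order=1)
        return dice(warped, f_float)

    # 4 proper sign combinations of the principal axes
    best_R, best_t, best_score = None, None, -1.0
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        S = np.diag(signs).astype(float)
        R0 = V_f @ S @ V_m.T
        t0 = c_f - R0 @ c_m
        score = soft_dice(R0, t0)
        if score > best_score:
            best_R, best_t, best_score = R0, t0, score

    # local refinement: parameters are a rotation-vector delta (rad) composed
    # with the init rotation, plus a translation delta (mm)
    def params_to_rt(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        R = Rotation.from_rotvec(params[:3]).as_matrix() @ best_R
        t = best_t + params[3:]
        return R, t

    def objective(params: np.ndarray) -> float:
        R, t = params_to_rt(params)
        return -soft_dice(R, t)

    res = optimize.minimize(
        objective,
        x0=np.zeros(6),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 20},
    )
    R_ref, t_ref = params_to_rt(res.x)
    if -res.fun >= best_score:
        R_fin, t_fin = R_ref, t_ref
    else:  # refinement failed to improve: keep the initialization
        R_fin, t_fin = best_R, best_t

    warped_hard = _resample(m_mask.astype(np.int16), m_sp, f_mask.shape, f_sp, R_fin, t_fin, order=0)
    return RigidTransform(
        rotation=R_fin,
        translation=t_fin,
        dice=dice(warped_hard > 0, f_mask),
        fixed_shape=tuple(f_mask.shape),
        fixed_spacing=tuple(float(s) for s in fixed.spacing),
    )


def apply_transform(vol: LabelVolume, t: RigidTransform) -> LabelVolume:
    """Resample a label volume onto the transform's fixed grid.

    Nearest-neighbor resampling: label identities are preserved exactly and
    no new labels are created.
    """
    warped = _resample(
        vol.voxels.astype(np.int16),
        np.asarray(vol.spacing),
        t.fixed_shape,
        np.asarray(t.fixed_spacing),
        np.asarray(t.rotation),
        np.asarray(t.translation),
        order=0,
    )
    return LabelVolume(
        voxels=warped.astype(np.int16),
        spacing=t.fixed_spacing,
        schema=vol.schema,
        laterality=vol.laterality,
    )
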