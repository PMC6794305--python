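"""Hemispheric lateralization of volumetric t-maps in a symmetric grid.

A group t-map registered to a left/right symmetric template can be compared
voxel-by-voxel across hemispheres.  The map is first *sign-restricted* —
activation keeps positive t-values (negatives zeroed), deactivation keeps
negative t-values — then *folded* along the longitudinal (midline) axis so
left and mirrored-right voxels are co-indexed, and the difference R - L is
taken on the restricted maps.

Sign conventions (recorded on every LateralityVolume):

* activation mode: R - L on non-negative maps equals |R| - |L|; positive
  values mean right-lateralized activation, negative mean left.
* deactivation mode: R - L on non-positive maps equals |L| - |R| of the
  magnitudes; *negative* values mean right-lateralized deactivation,
  positive mean left.

ROI statistics use probabilistic masks thresholded at 95% probability and
require at least 100 suprathreshold voxels to count as reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatVolume",
    "ROIMask",
    "LateralityVolume",
    "ROILateralitySummary",
    "SpaceError",
    "sign_restrict",
    "mirror",
    "fold_hemispheres",
    "laterality_map",
    "extract_roi",
    "sex_contrast",
    "read_volume",
    "write_volume",
    "summaries_to_tsv",
]

ROI_NAMES = ("Te1.0", "Te1.1", "Te1.2", "LB", "CM", "SP")
DEFAULT_THRESHOLD = 0.95
MIN_VOXELS = 100
#: zero tolerance for "no leaning"
EPS_LEANING = 1e-9


class SpaceError(ValueError):
    """Raised when a volume is not tagged/shaped for symmetric-space analysis."""


@dataclass
class StatVolume:
    """3-D grid of t-values with midline metadata.

    ``axis`` is the left-right (midline) axis; with the default neurological
    orientation, increasing index along that axis runs left -> right, so the
    lower half-grid is the left hemisphere.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0)
    space: str = "symmetric"
    axis: int = 0
    orientation: str = "neurological"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("StatVolume requires a 3-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    def require_symmetric(self) -> None:
        if self.space != "symmetric":
            raise SpaceError(f"volume space is {self.space!r}; laterality needs 'symmetric'")
        if self.data.shape[self.axis] % 2:
            raise SpaceError(
                f"extent {self.data.shape[self.axis]} along midline axis must be even"
            )


@dataclass
class ROIMask:
    """Probabilistic ROI in the same grid as the stat volumes."""

    prob: np.ndarray
    name: str
    hemisphere: str = "bilateral"  # left | right | bilateral
    threshold: float = DEFAULT_THRESHOLD
    min_voxels: int = MIN_VOXELS

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("ROI probabilities must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        return self.prob >= self.threshold

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def valid(self) -> bool:
        return self.n_voxels >= self.min_voxels


@dataclass
class LateralityVolume:
    """Half-grid of R-L differences with its sign convention."""

    data: np.ndarray  # left-half-shaped grid
    mode: str  # activation | deactivation
    axis: int = 0
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 3.0)
    convention: str = ""

    def __post_init__(self) -> None:
        if not self.convention:
            self.convention = (
                "positive => right-lateralized activation"
                if self.mode == "activation"
                else "negative => right-lateralized deactivation"
            )


@dataclass
class ROILateralitySummary:
    """Per-ROI laterality statistics."""

    name: str
    hemisphere: str
    mean: float
    sd: float
    n_voxels: int
    valid: bool
    leaning: str  # left | right | none
    mode: str | None = None


def sign_restrict(vol: StatVolume, mode: str) -> StatVolume:
    """Keep one sign of the t-map: activation zeroes negatives, deactivation
    zeroes positives; surviving voxels are preserved exactly."""
    if mode == "activation":
        data = np.where(vol.data > 0, vol.data, 0.0)
    elif mode == "deactivation":
        data = np.where(vol.data < 0, vol.data, 0.0)
    else:
        raise ValueError(f"mode must be 'activation' or 'deactivation', got {mode!r}")
    return replace(vol, data=data)


def mirror(vol: StatVolume) -> StatVolume:
    """Flip the volume across its midline axis (left-right reflection)."""
    return replace(vol, data=np.flip(vol.data, axis=vol.axis))


def fold_hemispheres(vol: StatVolume) -> tuple[np.ndarray, np.ndarray]:
    """Split into (left half, mirrored right half), co-indexed voxelwise.

    The right half is reversed along the midline axis so index ``i`` in both
    halves refers to mirror-symmetric voxels.  With an even extent both halves
    are equal-sized; otherwise both would be truncated to the shorter one,
    which the symmetric-space check rules out up front.
    """
    vol.require_symmetric()
    h = vol.data.shape[vol.axis] // 2
    left = np.take(vol.data, np.arange(h), axis=vol.axis)
    right = np.take(vol.data, np.arange(vol.data.shape[vol.axis] - 1, h - 1, -1), axis=vol.axis)
    return left, right


def laterality_map(vol: StatVolume, mode: str) -> LateralityVolume:
    """Sign-restricted, hemisphere-folded R - L difference map.

    Activation: R - L on the positive-restricted map (equals |R| - |L|);
    deactivation: R - L on the negative-restricted map, so a right hemisphere
    that is more deactivated yields a negative value, per convention.
    """
    vol.require_symmetric()
    restricted = sign_restrict(vol, mode)
    left, right = fold_hemispheres(restricted)
    return LateralityVolume(
        data=right - left, mode=mode, axis=vol.axis, voxel_size=vol.voxel_size
    )


def _half_mask(mask: ROIMask, axis: int, shape: tuple) -> np.ndarray:
    """Fold a full-grid probabilistic mask onto the half grid."""
    h = shape[axis] // 2
    left = np.take(mask.prob, np.arange(h), axis=axis)
    right = np.take(mask.prob, np.arange(shape[axis] - 1, h - 1, -1), axis=axis)
    if mask.hemisphere == "left":
        prob = left
    elif mask.hemisphere == "right":
        prob = right
    else:
        prob = np.maximum(left, right)
    return prob >= mask.threshold


def _leaning(mean: float, mode: str | None) -> str:
    if abs(mean) <= EPS_LEANING:
        return "none"
    if mode == "deactivation":
        return "right" if mean < 0 else "left"
    # activation-mode convention (also used for plain signed means)
    return "right" if mean > 0 else "left"


def extract_roi(vol: StatVolume | LateralityVolume, mask: ROIMask) -> ROILateralitySummary:
    """Mean/SD of a volume over a thresholded probabilistic ROI.

    A summary with fewer than ``mask.min_voxels`` suprathreshold voxels is
    marked invalid.  For a LateralityVolume the full-grid mask is folded onto
    the half grid first and the leaning follows the volume's mode convention.
    """
    if isinstance(vol, LateralityVolume):
        m = _half_mask(mask, vol.axis, tuple(
            (s * 2 if ax == vol.axis else s) for ax, s in enumerate(vol.data.shape)
        ))
        mode: str | None = vol.mode
    else:
        if mask.prob.shape != vol.data.shape:
            raise ValueError(
                f"grid mismatch: mask {mask.prob.shape} vs volume {vol.data.shape}"
            )
        m = mask.mask
        mode = None
    if m.shape != vol.data.shape:
        raise ValueError(f"grid mismatch: mask {m.shape} vs volume {vol.data.shape}")
    n = int(m.sum())
    vals = vol.data[m]
    mean = float(vals.mean()) if n else float("nan")
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ROILateralitySummary(
        name=mask.name,
        hemisphere=mask.hemisphere,
        mean=mean,
        sd=sd,
        n_voxels=n,
        valid=n >= mask.min_voxels,
        leaning=_leaning(mean, mode) if n else "none",
        mode=mode,
    )


def sex_contrast(
    vols_f: list[StatVolume],
    vols_m: list[StatVolume],
    masks: list[ROIMask] | None = None,
) -> tuple[StatVolume, pd.DataFrame]:
    """Voxelwise [mean |F|] - [mean |M|] difference with per-ROI two-sample t.

    Follows the figure convention of absolute-magnitude group means; per-ROI
    statistics compare subject-level ROI means of |t| between groups.
    """
    if len(vols_f) < 2 or len(vols_m) < 2:
        raise ValueError("each group needs >= 2 volumes")
    ref = vols_f[0]
    for v in vols_f + vols_m:
        if v.data.shape != ref.data.shape:
            raise ValueError("all volumes must share one grid")
    f_stack = np.stack([np.abs(v.data) for v in vols_f])
    m_stack = np.stack([np.abs(v.data) for v in vols_m])
    diff = replace(ref, data=f_stack.mean(axis=0) - m_stack.mean(axis=0))
    rows = []
    for mask in masks or []:
        sel = mask.mask
        f_means = f_stack[:, sel].mean(axis=1)
        m_means = m_stack[:, sel].mean(axis=1)
        t, p = stats.ttest_ind(f_means, m_means)
        rows.append(
            {
                "roi": mask.name,
                "hemisphere": mask.hemisphere,
                "diff": float(f_means.mean() - m_means.mean()),
                "t": float(t),
                "df": len(f_means) + len(m_means) - 2,
                "p": float(p),
                "valid": mask.valid,
            }
        )
    return diff, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, space: str = "symmetric", axis: int = 0) -> StatVolume:
    """Load a NIfTI-1 volume; voxel size is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return StatVolume(data=data, voxel_size=zooms, space=space, axis=axis)


def write_volume(path, vol: StatVolume | LateralityVolume) -> None:
    """Write a volume as NIfTI-1 with a diagonal voxel-size affine."""
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def summaries_to_tsv(summaries: list[ROILateralitySummary], path) -> None:
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(path, sep="\t", index=False)
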