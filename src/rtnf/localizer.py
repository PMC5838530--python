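"""Functional localizer GLM and region-of-interest construction.

The neurofeedback target is defined functionally: a fist-clenching
localizer run is fit with an ordinary-least-squares GLM, the
clench-versus-rest t-map is thresholded at t > 3, and the surviving
voxels inside an anatomical constraint (the SMA, in the original
protocol) become the target ROI.  Because the ROI is redrawn at each
visit, group analyses use the inclusive-OR union of all per-visit masks.
Sphere seeds around activation peaks support connectivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "RoiMask",
    "GlmFit",
    "RoiSelectConfig",
    "fit_glm",
    "select_roi",
    "union_mask",
    "sphere_seed",
    "smooth_volume",
]


@dataclass
class RoiMask:
    """Boolean voxel set on a named grid (voxel size in mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D boolean array")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        return np.argwhere(self.data)

    def intersect(self, other: "RoiMask") -> "RoiMask":
        if self.data.shape != other.data.shape:
            raise ValueError("mask grids differ")
        return RoiMask(self.data & other.data, self.voxel_size)

    def save(self, path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path) -> "RoiMask":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0, vox)


@dataclass
class GlmFit:
    """Voxelwise OLS fit of a design matrix.

    ``betas`` is (p, n_voxels); ``spatial_shape``, when set, lets t-maps
    be returned as volumes.
    """

    design: np.ndarray
    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    xtx_inv: np.ndarray
    spatial_shape: tuple[int, ...] | None = None

    def t_contrast(self, contrast) -> np.ndarray:
        """t-statistic map for a fixed contrast vector c: c'b / se(c'b)."""
        c = np.asarray(contrast, dtype=float)
        if c.shape != (self.design.shape[1],):
            raise ValueError("contrast length must match the number of regressors")
        effect = c @ self.betas
        var_scale = float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(self.sigma2 * var_scale)
        t = np.where(np.isnan(t), 0.0, t)  # 0/0 (flat data, zero effect) -> 0
        if self.spatial_shape is not None:
            return t.reshape(self.spatial_shape)
        return t

    def contrast_estimate(self, contrast) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        est = c @ self.betas
        if self.spatial_shape is not None:
            return est.reshape(self.spatial_shape)
        return est


def fit_glm(Y: np.ndarray, X: np.ndarray, spatial_shape=None) -> GlmFit:
    """Ordinary least squares per voxel.

    Parameters
    ----------
    Y : (n_volumes, n_voxels) or (nx, ny, nz, n_volumes) array
        Data; a 4-D volume is flattened (and its spatial shape recorded).
    X : (n_volumes, p) design matrix, full column rank.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 4:
        spatial_shape = Y.shape[:3]
        Y = Y.reshape(-1, Y.shape[3]).T
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"time dimensions differ: Y has {Y.shape[0]}, X has {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ (X.T @ Y)
    resid = Y - X @ betas
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(
        design=X,
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        xtx_inv=xtx_inv,
        spatial_shape=spatial_shape,
    )


@dataclass
class RoiSelectConfig:
    """Thresholds for target-ROI definition and seed construction."""

    t_threshold: float = 3.0
    anatomical_mask: RoiMask | None = None
    sphere_radius: float = 6.0
    group_threshold: int = 1

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be > 0")
        if self.group_threshold < 1:
            raise ValueError("group_threshold must be >= 1")


def select_roi(tmap: np.ndarray, cfg: RoiSelectConfig | None = None) -> RoiMask:
    """Voxels with t strictly above threshold, inside the anatomical mask.

    An empty selection is legitimate (the per-visit redraw produces
    variable ROI sizes) and is returned with a warning, not an error.
    """
    cfg = cfg or RoiSelectConfig()
    tmap = np.asarray(tmap)
    sel = tmap > cfg.t_threshold
    voxel_size = (3.0, 3.0, 3.0)
    if cfg.anatomical_mask is not None:
        if cfg.anatomical_mask.data.shape != tmap.shape:
            raise ValueError("t-map and anatomical mask grids differ")
        sel = sel & cfg.anatomical_mask.data
        voxel_size = cfg.anatomical_mask.voxel_size
    if not sel.any():
        warnings.warn("ROI selection is empty at this threshold", stacklevel=2)
    return RoiMask(sel, voxel_size)


def union_mask(masks: list[RoiMask], group_threshold: int = 1) -> RoiMask:
    """Voxels present in at least ``group_threshold`` of the masks.

    With threshold 1 this is the inclusive-OR group mask; with threshold
    equal to the number of masks it is the intersection.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].data.shape
    for m in masks:
        if m.data.shape != shape:
            raise ValueError("mask grids differ")
    counts = np.zeros(shape, dtype=int)
    for m in masks:
        counts += m.data.astype(int)
    return RoiMask(counts >= group_threshold, masks[0].voxel_size)


def sphere_seed(
    peak: tuple[int, int, int],
    radius_mm: float,
    constraint: RoiMask | None = None,
    shape: tuple[int, int, int] | None = None,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> RoiMask:
    """Sphere of voxels around a peak, intersected with a constraint mask.

    A voxel belongs to the sphere when the Euclidean distance between its
    center and the peak's center is at most ``radius_mm``.
    """
    if constraint is not None:
        shape = constraint.data.shape
        voxel_size = constraint.voxel_size
        if not constraint.data[tuple(peak)]:
            raise ValueError("peak voxel lies outside the constraint mask")
    if shape is None:
        raise ValueError("either a constraint mask or an explicit shape is required")
    vs = np.asarray(voxel_size, dtype=float)
    max_off = np.floor(radius_mm / vs).astype(int)
    out = np.zeros(shape, dtype=bool)
    px, py, pz = (int(c) for c in peak)
    for di in range(-max_off[0], max_off[0] + 1):
        for dj in range(-max_off[1], max_off[1] + 1):
            for dk in range(-max_off[2], max_off[2] + 1):
                if np.linalg.norm(np.array([di, dj, dk]) * vs) <= radius_mm + 1e-9:
                    i, j, k = px + di, py + dj, pz + dk
                    if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                        out[i, j, k] = True
    if constraint is not None:
        out &= constraint.data
    return RoiMask(out, tuple(vs))


def smooth_volume(
    data: np.ndarray,
    fwhm_mm: float,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> np.ndarray:
    """Isotropic Gaussian smoothing with full-width-half-maximum in mm.

    Applied pre-GLM for group analyses; the real-time chain never smooths.
    """
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigmas = [sigma_mm / v for v in voxel_size]
    if data.ndim == 4:
        sigmas = sigmas + [0.0]
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigmas)
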