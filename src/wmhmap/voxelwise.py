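"""Mass-univariate lesion-probability mapping over a binary mask stack.

Each subject contributes one binary lesion mask on a shared grid. At every
voxel with sufficient lesion incidence (>= 4 subjects by default) an
independent binary GLM (bias-reduced probit by default) is fitted with a
shared subject-level design; p-value maps are corrected across in-mask
voxels by Benjamini-Hochberg FDR, separately per coefficient. Statistic
volumes are written as NIfTI-1 with out-of-mask voxels set to NaN so they
render transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import br_glm
from ._design import build_design

__all__ = [
    "LesionStack",
    "VoxelMapSet",
    "read_lesion_stack",
    "compute_wmh_load",
    "build_incidence_mask",
    "empirical_probability_map",
    "fit_voxelwise_model",
    "fdr_correct",
    "summarize_significant_voxels",
    "write_stat_map",
]


@dataclass
class LesionStack:
    """N binary lesion volumes on a shared grid with brain mask and affine."""

    data: np.ndarray            # (N, X, Y, Z), values in {0, 1}
    brain_mask: np.ndarray      # (X, Y, Z) boolean
    affine: np.ndarray          # 4x4
    subject_ids: list = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("stack data must be (subjects, x, y, z)")
        if not np.isin(np.unique(self.data), [0, 1]).all():
            raise ValueError("lesion masks must be binary 0/1")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.grid_dims:
            raise ValueError("brain mask does not match the stack grid")
        if self.subject_ids is None:
            self.subject_ids = list(range(self.n_subjects))
        if len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_dims(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class VoxelMapSet:
    """Per-coefficient statistic volumes plus the analysis mask."""

    maps: dict                       # name -> dict of 3-d arrays
    coef_names: list
    analysis_mask: np.ndarray
    alpha_fdr: float
    affine: np.ndarray
    n_nonconverged: int = 0
    nonconverged_mask: np.ndarray = None

    @property
    def n_analysis_voxels(self) -> int:
        return int(self.analysis_mask.sum())


def read_lesion_stack(paths, brain_mask_path, affine_tol: float = 1e-4) -> LesionStack:
    """Load per-subject binary NIfTI masks plus a brain mask into a stack.

    All volumes must share dimensions and affine (within ``affine_tol``);
    non-binary voxel values are an error, never silently thresholded.
    """
    mask_img = nib.load(str(brain_mask_path))
    brain = np.asarray(mask_img.dataobj)
    if not np.isin(np.unique(brain), [0, 1]).all():
        raise ValueError(f"brain mask {brain_mask_path} is not binary")
    affine = mask_img.affine
    vols, ids = [], []
    for path in paths:
        img = nib.load(str(path))
        if img.shape != brain.shape:
            raise ValueError(f"{path}: dimensions {img.shape} != {brain.shape}")
        if np.max(np.abs(img.affine - affine)) > affine_tol:
            raise ValueError(f"{path}: affine mismatch with brain mask")
        vol = np.asarray(img.dataobj)
        if not np.isin(np.unique(vol), [0, 1]).all():
            raise ValueError(f"{path}: non-binary voxel values")
        vols.append(vol.astype(np.uint8))
        ids.append(str(path))
    return LesionStack(data=np.stack(vols), brain_mask=brain.astype(bool),
                       affine=affine, subject_ids=ids)


def compute_wmh_load(mask: np.ndarray) -> int:
    """WMH load: number of lesion-affected voxels in one binary mask."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), [0, 1]).all():
        raise ValueError("mask must be binary")
    return int(mask.sum())


def build_incidence_mask(stack: LesionStack, min_count: int = 4) -> np.ndarray:
    """Voxels with at least ``min_count`` lesioned subjects, inside the brain."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    incidence = stack.data.sum(axis=0)
    return (incidence >= min_count) & stack.brain_mask


def empirical_probability_map(stack: LesionStack,
                              sqrt_transform: bool = False) -> np.ndarray:
    """Per-voxel lesion frequency; optional square root for visualisation."""
    prob = stack.data.mean(axis=0)
    return np.sqrt(prob) if sqrt_transform else prob


def fit_voxelwise_model(stack: LesionStack, covariate_table: pd.DataFrame,
                        terms, interactions=(), estimator: str = "BR",
                        link: str = "probit", min_count: int = 4,
                        alpha_fdr: float = 0.05,
                        analysis_mask: np.ndarray | None = None,
                        tol: float = 1e-8, max_iter: int = 100) -> VoxelMapSet:
    """Fit one binary GLM per in-mask voxel with a shared design.

    Covariate rows must align with the stack's subject order. Voxels whose
    fit does not converge are excluded from FDR correction and counted in
    ``n_nonconverged`` (with BR this is rare). Fits are independent across
    voxels; execution is serial and deterministic.
    """
    if len(covariate_table) != stack.n_subjects:
        raise ValueError(
            f"covariate table has {len(covariate_table)} rows for "
            f"{stack.n_subjects} subjects")
    if analysis_mask is None:
        analysis_mask = build_incidence_mask(stack, min_count=min_count)
    if analysis_mask.sum() == 0:
        raise ValueError("empty analysis mask: no voxel reaches the incidence threshold")
    design = build_design(covariate_table, terms, interactions)
    X = design.X
    names = design.names
    vox_idx = np.flatnonzero(analysis_mask.ravel())
    Y = stack.data.reshape(stack.n_subjects, -1)[:, vox_idx]

    p = len(names)
    m = vox_idx.size
    est = np.full((m, p), np.nan)
    se = np.full((m, p), np.nan)
    ok = np.zeros(m, dtype=bool)
    for j in range(m):
        # the shared design was validated once by build_design; the per-voxel
        # separation diagnostic is skipped (BR proceeds regardless)
        d = br_glm.BinaryDesign(X=X, y=Y[:, j], link=link, validate=False)
        fit = br_glm.fit_binary_glm(d, estimator=estimator, tol=tol,
                                    max_iter=max_iter, check_separation=False)
        est[j] = fit.estimates
        se[j] = fit.se
        ok[j] = fit.converged

    from scipy import stats as _stats
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    pvals = 2.0 * _stats.norm.sf(np.abs(z))

    maps = {}
    shape = stack.grid_dims
    for k, name in enumerate(names):
        vols = {}
        for arr, label in ((est[:, k], "estimate"), (se[:, k], "se"),
                           (z[:, k], "z"), (pvals[:, k], "p")):
            vol = np.full(np.prod(shape), np.nan)
            vol[vox_idx] = arr
            vols[label] = vol.reshape(shape)
        # FDR over converged in-mask voxels only
        q = np.full(m, np.nan)
        sig = np.zeros(m, dtype=bool)
        if ok.any():
            q[ok], sig[ok] = _bh(pvals[ok, k], alpha_fdr)
        qvol = np.full(np.prod(shape), np.nan)
        qvol[vox_idx] = q
        svol = np.full(np.prod(shape), np.nan)
        svol[vox_idx] = sig.astype(float)
        vols["q"] = qvol.reshape(shape)
        vols["significant"] = svol.reshape(shape)
        maps[name] = vols

    ncmask = np.zeros(np.prod(shape), dtype=bool)
    ncmask[vox_idx[~ok]] = True
    return VoxelMapSet(maps=maps, coef_names=names,
                       analysis_mask=analysis_mask, alpha_fdr=alpha_fdr,
                       affine=stack.affine,
                       n_nonconverged=int((~ok).sum()),
                       nonconverged_mask=ncmask.reshape(shape))


def _bh(pvec: np.ndarray, alpha: float):
    reject, q, *_ = multipletests(pvec, alpha=alpha, method="fdr_bh")
    return q, reject


def fdr_correct(p_map: np.ndarray, analysis_mask: np.ndarray,
                alpha: float = 0.05):
    """Benjamini-Hochberg step-up over in-mask voxels.

    Returns (q_map, significance_map); q is the BH-adjusted p-value with
    cumulative-minimum enforcement, significance = (q <= alpha). Outside the
    mask both maps are NaN.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if analysis_mask.sum() == 0:
        raise ValueError("empty analysis mask")
    pvals = np.asarray(p_map, dtype=float)[analysis_mask]
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values inside the mask must be in [0, 1]")
    q, reject = _bh(pvals, alpha)
    q_map = np.full(p_map.shape, np.nan)
    s_map = np.full(p_map.shape, np.nan)
    q_map[analysis_mask] = q
    s_map[analysis_mask] = reject.astype(float)
    return q_map, s_map


def summarize_significant_voxels(mapset: VoxelMapSet) -> pd.DataFrame:
    """Count and percentage of FDR-significant voxels per coefficient.

    Percent is 100 x count / n_analysis_voxels, reported to one decimal.
    """
    total = mapset.n_analysis_voxels
    rows = []
    for name in mapset.coef_names:
        sig = mapset.maps[name]["significant"]
        count = int(np.nansum(sig))
        pct = round(100.0 * count / total, 1) if total else 0.0
        rows.append({"term": name, "count": count, "percent": pct})
    return pd.DataFrame(rows)


def write_stat_map(volume: np.ndarray, analysis_mask: np.ndarray, path,
                   affine: np.ndarray | None = None) -> None:
    """Write a statistic volume as NIfTI-1 with NaN outside the mask.

    NaN background renders transparent in standard viewers, leaving the
    anatomical underlay visible. Values are stored as float32.
    """
    volume = np.asarray(volume, dtype=np.float32)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if volume.shape != analysis_mask.shape:
        raise ValueError("volume and analysis mask shapes differ")
    out = np.where(analysis_mask, volume, np.nan).astype(np.float32)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(out, affine)
    nib.save(img, str(path))
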