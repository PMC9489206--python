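"""Image-based random-effects meta-analysis (DerSimonian-Laird).

Per-study group-level effect and variance maps are resampled to a common
grid with linear interpolation (resampled values clipped to the range
observed in the source map), and combined per voxel with the
DerSimonian-Laird moment estimator of between-study variance tau^2:

    w_i = 1/v_i;  ybar = sum(w y)/sum(w);  Q = sum w (y - ybar)^2
    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))
    w*_i = 1/(v_i + tau^2);  mu = sum(w* y)/sum(w*);  se = 1/sqrt(sum w*)
    z = mu / se

Whenever Q <= k - 1 the estimator collapses exactly to inverse-variance
fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nilearn.image import resample_img

from .stimio import StatMap, ValidationError

__all__ = [
    "MetaResult",
    "resample_and_clip",
    "dl_meta",
    "run_ibma",
    "threshold_z",
    "roi_summary",
    "Z_CRIT_P001",
    "META_GRID_MM",
]

Z_CRIT_P001 = 3.29
"""Two-sided normal critical value at p = 0.001 (2 dp)."""

META_GRID_MM = 2.0
"""Default isotropic voxel size of the meta-analysis grid, in mm."""


@dataclass
class MetaResult:
    """Per-voxel combined effect, tau^2, standard error, z and study count."""

    mu: np.ndarray
    tau2: np.ndarray
    se_mu: np.ndarray
    z: np.ndarray
    k_map: np.ndarray
    affine: np.ndarray
    mask: np.ndarray


def resample_and_clip(
    statmap: StatMap, target_shape: tuple[int, int, int], target_affine: np.ndarray
) -> StatMap:
    """Linearly resample a map onto a target grid, clipping to the source range.

    Effect and variance are interpolated linearly; resampled values are
    clipped to the min/max of the source map's in-mask values.  The mask is
    resampled by nearest-equivalent thresholding at 0.5.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValidationError("degenerate target affine")
    if abs(np.linalg.det(np.asarray(statmap.affine)[:3, :3])) < 1e-12:
        raise ValidationError("degenerate source affine")
    if not statmap.mask.any():
        raise ValidationError("cannot resample a map with an empty mask")
    same_grid = statmap.shape == tuple(target_shape) and np.allclose(
        statmap.affine, target_affine
    )
    if same_grid:
        return statmap

    def _resample(field: np.ndarray, interpolation: str) -> np.ndarray:
        img = nib.Nifti1Image(field.astype(np.float64), statmap.affine)
        with warnings.catch_warnings():
            # the mask channel is binary on purpose; linear interpolation
            # followed by thresholding at 0.5 is the intended behaviour
            warnings.simplefilter("ignore", UserWarning)
            out = resample_img(
                img,
                target_affine=target_affine,
                target_shape=tuple(target_shape),
                interpolation=interpolation,
                force_resample=True,
                copy_header=True,
            )
        return np.asarray(out.dataobj, dtype=float)

    mask = _resample(statmap.mask.astype(float), "linear") >= 0.5
    eff_src = statmap.effect[statmap.mask]
    var_src = statmap.variance[statmap.mask]
    eff = np.clip(_resample(np.where(statmap.mask, statmap.effect, 0.0), "linear"),
                  eff_src.min(), eff_src.max())
    var = np.clip(_resample(np.where(statmap.mask, statmap.variance, 0.0), "linear"),
                  max(var_src.min(), 0.0), var_src.max())
    return StatMap(
        effect=np.where(mask, eff, 0.0),
        variance=np.where(mask, var, 0.0),
        dof=statmap.dof,
        kind=statmap.kind,
        affine=target_affine,
        mask=mask,
    )


def dl_meta(y: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """DerSimonian-Laird combination along axis 0 (studies).

    ``y`` and ``v`` are (k, ...) arrays of per-study effects and variances;
    returns (mu, tau2, se_mu, z) with the study axis reduced.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if y.shape != v.shape:
        raise ValidationError("effects and variances must share one shape")
    if y.shape[0] < 1:
        raise ValidationError("need at least one study")
    if np.any(v <= 0):
        raise ValidationError("all study variances must be > 0")
    k = y.shape[0]
    w = 1.0 / v
    sw = w.sum(axis=0)
    ybar = (w * y).sum(axis=0) / sw
    q = (w * (y - ybar) ** 2).sum(axis=0)
    if k == 1:
        tau2 = np.zeros_like(ybar)
    else:
        c = sw - (w**2).sum(axis=0) / sw
        tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    ws = 1.0 / (v + tau2)
    sws = ws.sum(axis=0)
    mu = (ws * y).sum(axis=0) / sws
    se = 1.0 / np.sqrt(sws)
    return mu, tau2, se, mu / se


def run_ibma(
    maps: list[StatMap],
    target_shape: tuple[int, int, int] | None = None,
    target_affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> MetaResult:
    """Resample-and-clip study maps to a common grid and combine per voxel.

    Voxels covered by fewer than 2 studies are excluded from the result
    mask (their study count is still recorded in ``k_map``).  An optional
    analysis ``mask`` (e.g. a gray-matter mask on the target grid) is
    intersected with the per-voxel coverage.
    """
    if len(maps) < 2:
        raise ValidationError("meta-analysis requires at least 2 studies")
    if target_shape is None or target_affine is None:
        target_shape = maps[0].shape
        target_affine = maps[0].affine
    resampled = [resample_and_clip(m, target_shape, target_affine) for m in maps]
    present = np.array([m.mask for m in resampled])
    k_map = present.sum(axis=0)
    analysis = k_map >= 2
    if mask is not None:
        analysis &= np.asarray(mask, dtype=bool)
    if not analysis.any():
        raise ValidationError("no voxel is covered by at least 2 studies")

    shape = tuple(target_shape)
    mu = np.zeros(shape)
    tau2 = np.zeros(shape)
    se = np.zeros(shape)
    z = np.zeros(shape)

    y_all = np.array([m.effect for m in resampled])
    v_all = np.array([m.variance for m in resampled])
    full = analysis & np.all(present, axis=0) & np.all(v_all > 0, axis=0)
    if full.any():
        m_, t_, s_, z_ = dl_meta(y_all[:, full], v_all[:, full])
        mu[full], tau2[full], se[full], z[full] = m_, t_, s_, z_
    partial = analysis & ~full
    for idx in zip(*np.nonzero(partial)):
        have = present[(slice(None),) + idx] & (v_all[(slice(None),) + idx] > 0)
        if have.sum() < 2:
            analysis[idx] = False
            continue
        yv = y_all[(slice(None),) + idx][have]
        vv = v_all[(slice(None),) + idx][have]
        m_, t_, s_, z_ = dl_meta(yv[:, None], vv[:, None])
        mu[idx], tau2[idx], se[idx], z[idx] = m_[0], t_[0], s_[0], z_[0]
    return MetaResult(
        mu=np.where(analysis, mu, 0.0),
        tau2=np.where(analysis, tau2, 0.0),
        se_mu=np.where(analysis, se, 0.0),
        z=np.where(analysis, z, 0.0),
        k_map=k_map,
        affine=np.asarray(target_affine, dtype=float),
        mask=analysis,
    )


def threshold_z(z: np.ndarray, z_crit: float = Z_CRIT_P001) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided voxelwise threshold: keep |z| >= z_crit, zero the rest.

    Returns (thresholded map, boolean suprathreshold mask).
    """
    if z_crit < 0:
        raise ValidationError("z_crit must be >= 0")
    z = np.asarray(z, dtype=float)
    supra = np.abs(z) >= z_crit
    return np.where(supra, z, 0.0), supra


@dataclass(frozen=True)
class ROISummary:
    mean: float
    peak: float
    peak_index: tuple[int, ...]


def roi_summary(statmap: StatMap, roi: np.ndarray) -> ROISummary:
    """In-ROI mean and signed extreme of a statistic map.

    The peak is the in-ROI value of largest magnitude, with its voxel
    index; the ROI must overlap the map's mask.
    """
    roi = np.asarray(roi, dtype=bool)
    sel = roi & statmap.mask
    if not sel.any():
        raise ValidationError("ROI does not overlap the map's mask")
    vals = statmap.effect[sel]
    idx_in = np.argmax(np.abs(vals))
    coords = tuple(int(c[idx_in]) for c in np.nonzero(sel))
    return ROISummary(mean=float(vals.mean()), peak=float(vals[idx_in]), peak_index=coords)
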