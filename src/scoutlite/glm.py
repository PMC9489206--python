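"""Three-level GLM estimation.

Run level: OLS residuals give a pooled lag-1 autocorrelation estimate; data
and design are prewhitened with the AR(1) square-root filter and refit by
OLS on the unsmoothed images.  Run-level parameter-estimate maps are then
smoothed (4 mm FWHM Gaussian, renormalized within the analysis mask),
combined within subject by inverse-variance fixed effects, and summarized
at the group level by a one-sample t test per voxel, converted to z by a
two-sided p-preserving quantile transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special, stats

from .design import DesignMatrix
from .stimio import BoldRun, StatMap, ValidationError

__all__ = [
    "NoiseModel",
    "RunFit",
    "GroupResult",
    "estimate_ar1",
    "fit_run",
    "contrast_map",
    "smooth_map",
    "fixed_effects",
    "group_onesample",
    "t_to_z",
    "DEFAULT_SMOOTHING_FWHM_MM",
    "FWHM_TO_SIGMA",
]

DEFAULT_SMOOTHING_FWHM_MM = 4.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
RHO_CLIP = 0.99


@dataclass(frozen=True)
class NoiseModel:
    """Temporal noise model of a run fit."""

    kind: str  # "ols" | "ar1"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ols", "ar1"):
            raise ValidationError(f"unknown noise model {self.kind!r}")
        if not -1 < self.rho < 1:
            raise ValidationError("|rho| must be < 1")


@dataclass
class RunFit:
    """Per-column beta maps with variances, residual variance and dof.

    ``cov_unscaled`` is (X'WX)^-1 of the (whitened) design; together with
    ``sigma2`` it gives the full beta covariance needed for multi-column
    contrasts.
    """

    betas: dict[str, StatMap]
    sigma2: np.ndarray
    dof: float
    noise: NoiseModel
    columns: list[str] = None
    cov_unscaled: np.ndarray = None
    mask: np.ndarray = None
    affine: np.ndarray = None


@dataclass
class GroupResult:
    """Group-level one-sample summary: mean/variance map plus z map."""

    effect: StatMap  # kind beta: mean across subjects, variance sd^2/k
    z: StatMap  # kind z
    dof: float


def estimate_ar1(residuals: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals (time x voxel).

    Per-voxel lag-1 correlations (normalized by the geometric mean of the
    leading/trailing sums of squares, so a perfectly alternating series
    gives exactly -1) are averaged across voxels with non-zero variance
    and clipped to (-0.99, 0.99).
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if residuals.shape[0] < 3:
        raise ValidationError("need at least 3 time points to estimate AR(1)")
    num = np.sum(residuals[1:] * residuals[:-1], axis=0)
    den = np.sqrt(
        np.sum(residuals[:-1] ** 2, axis=0) * np.sum(residuals[1:] ** 2, axis=0)
    )
    ok = den > 0
    if not np.any(ok):
        raise ValidationError("all residual time series are zero")
    rho = float(np.mean(num[ok] / den[ok]))
    return float(np.clip(rho, -RHO_CLIP, RHO_CLIP))


def _whiten(x: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) square-root prewhitening filter along axis 0."""
    out = np.empty_like(x, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * x[0]
    out[1:] = x[1:] - rho * x[:-1]
    return out


def fit_run(bold: BoldRun, dm: DesignMatrix, noise: str = "ar1") -> RunFit:
    """Fit the run-level GLM with optional AR(1) prewhitening.

    OLS residuals provide the pooled rho; data and design are filtered and
    refit.  Beta variances come from the whitened normal equations with
    ``dof = n_volumes - rank(X)``.
    """
    if noise not in ("ols", "ar1"):
        raise ValidationError(f"unknown noise model {noise!r}")
    if dm.n_volumes != bold.n_volumes:
        raise ValidationError("design and BOLD run disagree on volume count")
    if not bold.mask.any():
        raise ValidationError("mask is empty")
    x = dm.matrix()
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValidationError("design matrix is rank-deficient")
    y = bold.data[bold.mask].T  # time x voxel

    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    if noise == "ar1":
        resid = y - x @ beta_ols
        rho = estimate_ar1(resid)
        xw, yw = _whiten(x, rho), _whiten(y, rho)
        model = NoiseModel(kind="ar1", rho=rho)
    else:
        xw, yw = x, y
        model = NoiseModel(kind="ols")

    xtx_inv = np.linalg.inv(xw.T @ xw)
    beta = xtx_inv @ xw.T @ yw
    resid_w = yw - xw @ beta
    dof = float(n - p)
    sigma2 = np.sum(resid_w**2, axis=0) / dof
    var_diag = np.diag(xtx_inv)

    shape = bold.mask.shape
    sigma2_map = np.zeros(shape)
    sigma2_map[bold.mask] = sigma2
    betas: dict[str, StatMap] = {}
    for j, name in enumerate(dm.columns):
        eff = np.zeros(shape)
        var = np.zeros(shape)
        eff[bold.mask] = beta[j]
        var[bold.mask] = var_diag[j] * sigma2
        betas[name] = StatMap(
            effect=eff, variance=var, dof=dof, kind="beta",
            affine=bold.affine, mask=bold.mask,
        )
    return RunFit(
        betas=betas, sigma2=sigma2_map, dof=dof, noise=model,
        columns=list(dm.columns), cov_unscaled=xtx_inv,
        mask=bold.mask, affine=bold.affine,
    )


def contrast_map(fit: RunFit, conditions: list[str], weights: list[float]) -> StatMap:
    """Linear contrast over named design columns of a run fit.

    Effect = sum(w beta); variance = sigma2 * w' (X'X)^-1 w using the full
    (whitened) unscaled covariance, so correlated columns are handled.
    """
    if len(conditions) != len(weights):
        raise ValidationError("conditions and weights must have equal length")
    idx = []
    for c in conditions:
        if c not in fit.columns:
            raise ValidationError(f"unknown design column {c!r}")
        idx.append(fit.columns.index(c))
    w_full = np.zeros(len(fit.columns))
    for i, w in zip(idx, weights):
        w_full[i] = w
    mask = fit.mask
    eff = np.zeros(mask.shape)
    for c, w in zip(conditions, weights):
        eff += w * fit.betas[c].effect
    var_scale = float(w_full @ fit.cov_unscaled @ w_full)
    var = np.where(mask, var_scale * fit.sigma2, 0.0)
    return StatMap(
        effect=np.where(mask, eff, 0.0), variance=var, dof=fit.dof,
        kind="beta", affine=fit.affine, mask=mask,
    )


def smooth_map(
    statmap: StatMap,
    fwhm_mm: float = DEFAULT_SMOOTHING_FWHM_MM,
    voxel_size_mm: float | None = None,
) -> StatMap:
    """Gaussian-smooth a map within its mask with a renormalized kernel.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` mm; the kernel is renormalized over
    in-mask voxels so no mass leaks across the mask boundary and constant
    maps are preserved.  ``fwhm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return statmap
    if voxel_size_mm is None:
        voxel_size_mm = float(np.abs(np.diag(statmap.affine)[:3]).mean())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    mask = statmap.mask.astype(float)
    norm = ndimage.gaussian_filter(mask, sigma_vox)

    def _smooth(field: np.ndarray) -> np.ndarray:
        sm = ndimage.gaussian_filter(np.where(statmap.mask, field, 0.0), sigma_vox)
        out = np.zeros_like(sm)
        inside = statmap.mask & (norm > 0)
        out[inside] = sm[inside] / norm[inside]
        return out

    return StatMap(
        effect=_smooth(statmap.effect),
        variance=np.maximum(_smooth(statmap.variance), 0.0),
        dof=statmap.dof,
        kind=statmap.kind,
        affine=statmap.affine,
        mask=statmap.mask,
    )


def fixed_effects(estimates: list[StatMap]) -> StatMap:
    """Inverse-variance-weighted fixed-effects combination of maps.

    Combined variance is ``1 / sum(1 / v_i)`` per voxel; all inputs must
    share one grid and have strictly positive in-mask variances.
    """
    if not estimates:
        raise ValidationError("need at least one estimate")
    first = estimates[0]
    mask = first.mask.copy()
    for m in estimates[1:]:
        if m.shape != first.shape or not np.allclose(m.affine, first.affine):
            raise ValidationError("estimates must share one grid")
        mask &= m.mask
    if not mask.any():
        raise ValidationError("combined mask is empty")
    v = np.array([m.variance[mask] for m in estimates])
    if np.any(v <= 0):
        raise ValidationError("fixed effects require strictly positive variances")
    y = np.array([m.effect[mask] for m in estimates])
    w = 1.0 / v
    var = 1.0 / w.sum(axis=0)
    eff = (w * y).sum(axis=0) * var
    out_eff = np.zeros(first.shape)
    out_var = np.zeros(first.shape)
    out_eff[mask] = eff
    out_var[mask] = var
    return StatMap(
        effect=out_eff, variance=out_var, dof=float(sum(m.dof for m in estimates)),
        kind="beta", affine=first.affine, mask=mask,
    )


def t_to_z(t, dof: float):
    """Convert t statistics to z scores preserving two-sided p values.

    Uses log tail probabilities so large |t| stays finite and accurate;
    antisymmetric in t.
    """
    if dof <= 0:
        raise ValidationError("dof must be > 0")
    t = np.asarray(t, dtype=float)
    abs_t = np.abs(t)
    logp = stats.t.logsf(abs_t, dof)
    z = -special.ndtri_exp(logp)
    out = np.sign(t) * z
    return out if out.ndim else float(out)


def group_onesample(estimates: list[StatMap]) -> GroupResult:
    """One-sample t test across subject-level maps, per voxel.

    ``t = mean / (sd / sqrt(k))`` with ``df = k - 1``; z by quantile
    transform.  Emits the mean map (variance ``sd^2 / k``) and the z map.
    """
    k = len(estimates)
    if k < 2:
        raise ValidationError("group level requires at least 2 subjects")
    first = estimates[0]
    mask = first.mask.copy()
    for m in estimates[1:]:
        if m.shape != first.shape or not np.allclose(m.affine, first.affine):
            raise ValidationError("estimates must share one grid")
        mask &= m.mask
    if not mask.any():
        raise ValidationError("combined mask is empty")
    y = np.array([m.effect[mask] for m in estimates])
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    var = sd**2 / k
    dof = float(k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / np.where(sd > 0, np.sqrt(var), 1.0), 0.0)
        t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    z = t_to_z(t, dof)

    def _full(vals: np.ndarray) -> np.ndarray:
        out = np.zeros(first.shape)
        out[mask] = vals
        return out

    effect_map = StatMap(
        effect=_full(mean), variance=_full(var), dof=dof, kind="beta",
        affine=first.affine, mask=mask,
    )
    z_map = StatMap(
        effect=_full(z), variance=_full(np.ones_like(z)), dof=dof, kind="z",
        affine=first.affine, mask=mask,
    )
    return GroupResult(effect=effect_map, z=z_map, dof=dof)
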