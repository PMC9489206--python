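"""Predictor transformations and run-level design-matrix assembly.

Predictor streams are (optionally) transformed — scaling, thresholding,
orthogonalization — convolved with the SPM-style double-gamma hemodynamic
response function plus its dispersion derivative, and sampled on the TR
grid.  The design matrix is completed with the selected confound columns
(verbatim), a discrete-cosine drift basis and an intercept.

The HRF is the difference of two gamma densities — a positive peak and a
delayed undershoot — parameterized by delay and dispersion in seconds and
peak-normalized to a maximum of 1.  The dispersion derivative is a finite
difference of the HRF with respect to the peak-dispersion parameter and
absorbs voxelwise variability in response width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .stimio import FeatureStream, ModelSpec, ValidationError, select_confounds

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "demean_rescale",
    "threshold",
    "orthogonalize",
    "canonical_hrf",
    "dispersion_derivative",
    "convolve_to_tr",
    "cosine_drift",
    "build_design",
    "correlation_report",
    "DEFAULT_OVERSAMPLING",
    "DEFAULT_DRIFT_CUTOFF_S",
]

DEFAULT_OVERSAMPLING = 50
DEFAULT_DRIFT_CUTOFF_S = 128.0


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF constants (SPM convention), in seconds."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    length: float = 32.0
    dispersion_delta: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "length",
            "dispersion_delta",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.length < self.undershoot_delay:
            raise ValidationError("length must cover the undershoot delay")


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma density, 0 for t <= 0 (all shapes here exceed 1)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def _hrf_unnormalized(t: np.ndarray, p: HRFParams, peak_dispersion: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    peak = _gamma_pdf(t, p.peak_delay / peak_dispersion, peak_dispersion)
    under = _gamma_pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, p.undershoot_dispersion
    )
    h = peak - under / p.undershoot_ratio
    h[(t < 0) | (t > p.length)] = 0.0
    return h


@lru_cache(maxsize=32)
def _peak_value(p: HRFParams) -> float:
    grid = np.arange(0.0, p.length + 1e-9, 1e-3)
    return float(_hrf_unnormalized(grid, p, p.peak_dispersion).max())


def canonical_hrf(t, p: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF, peak-normalized to max 1, 0 past ``length``."""
    return _hrf_unnormalized(np.asarray(t, dtype=float), p, p.peak_dispersion) / _peak_value(p)


def dispersion_derivative(t, p: HRFParams = HRFParams()) -> np.ndarray:
    """Finite-difference derivative of the HRF w.r.t. peak dispersion.

    Both evaluations share the canonical peak normalization, so the
    derivative scales linearly with any overall scaling of the HRF.
    """
    t = np.asarray(t, dtype=float)
    h0 = _hrf_unnormalized(t, p, p.peak_dispersion)
    h1 = _hrf_unnormalized(t, p, p.peak_dispersion + p.dispersion_delta)
    return (h0 - h1) / p.dispersion_delta / _peak_value(p)


# ---------------------------------------------------------------------------
# vector transformations
# ---------------------------------------------------------------------------


def demean_rescale(x: np.ndarray) -> np.ndarray:
    """Z-score with population standard deviation (mean 0, sd 1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValidationError("cannot rescale a constant vector")
    return (x - x.mean()) / sd


def threshold(x: np.ndarray, cutoff: float, binarize: bool = False) -> np.ndarray:
    """Zero values below ``cutoff``; optionally binarize the survivors to 1."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < cutoff, 0.0, x)
    if binarize:
        out = np.where(x >= cutoff, 1.0, 0.0)
    return out


def orthogonalize(x: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Residualize ``x`` against span(others + intercept) by least squares."""
    x = np.asarray(x, dtype=float)
    basis = np.column_stack([np.ones(len(x))] + [np.asarray(o, dtype=float) for o in others])
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValidationError("orthogonalization basis is rank-deficient")
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return x - basis @ coef


# ---------------------------------------------------------------------------
# convolution and drift
# ---------------------------------------------------------------------------


def _render_fine(
    stream: FeatureStream, dt: float, n_fine: int
) -> np.ndarray:
    """Render a stream on the fine grid t = k * dt.

    Sparse events become boxcars of height ``value`` over [onset,
    onset + duration); zero-duration events become single-sample impulses
    of area ``value`` (height value / dt).  Dense streams are rendered by
    zero-order hold of the containing source sample.
    """
    signal = np.zeros(n_fine)
    if stream.kind == "sparse":
        for onset, dur, val in zip(stream.onsets, stream.durations, stream.values):
            if dur == 0:
                i0 = int(np.floor(onset / dt + 1e-9))
                if i0 < n_fine:
                    signal[i0] += val / dt
            else:
                # samples k with onset <= k*dt < onset + dur (half-open)
                i0 = int(np.ceil(onset / dt - 1e-9))
                i1 = int(np.ceil((onset + dur) / dt - 1e-9))
                signal[i0 : min(i1, n_fine)] += val
    else:
        src = np.floor(np.arange(n_fine) * dt * stream.sampling_rate).astype(int)
        valid = src < len(stream.values)
        signal[valid] = stream.values[src[valid]]
    return signal


def convolve_to_tr(
    stream: FeatureStream,
    tr: float,
    n_volumes: int,
    p: HRFParams = HRFParams(),
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve a stream with the HRF and dispersion derivative on the TR grid.

    The stream is rendered on a fine grid with spacing ``tr / oversampling``,
    convolved (Riemann approximation of the continuous convolution), and
    sampled at volume onsets t = k * tr.  Returns the canonical and the
    dispersion-derivative columns.
    """
    if oversampling < 1:
        raise ValidationError("oversampling must be >= 1")
    dt = tr / oversampling
    n_fine = n_volumes * oversampling
    signal = _render_fine(stream, dt, n_fine)
    t_kernel = np.arange(0.0, p.length + dt / 2, dt)
    cols = []
    for kernel in (canonical_hrf(t_kernel, p), dispersion_derivative(t_kernel, p)):
        conv = np.convolve(signal, kernel)[:n_fine] * dt
        cols.append(conv[::oversampling].copy())
    return cols[0], cols[1]


def cosine_drift(n_volumes: int, tr: float, cutoff: float = DEFAULT_DRIFT_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff`` seconds.

    Returns ``floor(2 * n_volumes * tr / cutoff)`` unit-norm DCT-II columns
    (the intercept term is excluded; it enters the design separately).
    """
    if cutoff <= 2 * tr:
        raise ValidationError("cutoff must exceed 2 * tr")
    total = n_volumes * tr
    n_cols = int(np.floor(2 * total / cutoff))
    k = np.arange(n_volumes)
    cols = [np.cos(np.pi * (k + 0.5) * j / n_volumes) for j in range(1, n_cols + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Named TR-gridded columns with per-column roles."""

    frame: pd.DataFrame
    tr: float
    column_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValidationError("design column names must be unique")
        n_icept = sum(1 for r in self.column_roles.values() if r == "intercept")
        if n_icept != 1:
            raise ValidationError("design must contain exactly one intercept")

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.columns if self.column_roles[c] == role]


_TRANSFORM_OPS = {"demean_rescale", "scale", "threshold", "orthogonalize"}


def _apply_transformations(
    streams: dict[str, FeatureStream], spec: ModelSpec
) -> dict[str, FeatureStream]:
    """Apply the spec's transformation list, in order, to stream values.

    All transformations act on the value vector of a stream before
    convolution; orthogonalization requires its operands to share one
    support (same events, or same dense grid).
    """
    out = dict(streams)
    for t in spec.transformations:
        if t.operation == "convolve":
            continue  # convolution is applied to every predictor at build time
        if t.operation not in _TRANSFORM_OPS:
            raise ValidationError(f"unknown transformation {t.operation!r}")
        missing = [i for i in t.inputs if i not in out]
        if missing:
            raise ValidationError(f"transformation inputs not found: {missing}")
        primary = out[t.inputs[0]]
        if t.operation in ("demean_rescale", "scale"):
            values = demean_rescale(primary.values)
        elif t.operation == "threshold":
            values = threshold(
                primary.values,
                cutoff=float(t.arguments.get("cutoff", 0.0)),
                binarize=bool(t.arguments.get("binarize", False)),
            )
        else:  # orthogonalize
            others = [out[nm].values for nm in t.inputs[1:]]
            if any(len(o) != len(primary.values) for o in others):
                raise ValidationError("orthogonalize operands must share one support")
            values = orthogonalize(primary.values, others)
        out[t.output] = primary.with_values(values, name=t.output)
    return out


def build_design(
    streams: dict[str, FeatureStream],
    confounds: pd.DataFrame,
    spec: ModelSpec,
    tr: float,
    n_volumes: int,
    hrf: HRFParams = HRFParams(),
    oversampling: int = DEFAULT_OVERSAMPLING,
    drift_cutoff: float = DEFAULT_DRIFT_CUTOFF_S,
    include_derivatives: bool = True,
) -> DesignMatrix:
    """Assemble the run-level design matrix on the TR grid.

    Column order: convolved predictors (each followed by its dispersion
    derivative when enabled), selected confounds verbatim, cosine drift
    columns, intercept.
    """
    missing = [p for p in spec.predictors if p not in streams]
    if missing:
        raise ValidationError(f"predictor streams not provided: {missing}")
    transformed = _apply_transformations(streams, spec)
    design_predictors = [
        name for name in spec.final_predictors() if name in spec.predictors
        or any(t.output == name for t in spec.transformations)
    ]
    # transformation outputs replace their primary input when renamed onto it;
    # otherwise both the original predictors and new outputs can enter.  Only
    # names listed as predictors or produced by transformations enter the design.
    entering = []
    consumed: set[str] = set()
    for t in spec.transformations:
        if t.operation == "convolve":
            continue
        if t.output != t.inputs[0]:
            consumed.add(t.inputs[0])
    for name in design_predictors:
        if name not in consumed and name not in entering:
            entering.append(name)

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}

    def _add(name: str, values: np.ndarray, role: str) -> None:
        if name in cols:
            raise ValidationError(f"duplicate design column {name!r}")
        cols[name] = np.asarray(values, dtype=float)
        roles[name] = role

    for name in entering:
        canonical, deriv = convolve_to_tr(
            transformed[name], tr=tr, n_volumes=n_volumes, p=hrf, oversampling=oversampling
        )
        _add(name, canonical, "predictor")
        if include_derivatives:
            _add(f"{name}_derivative", deriv, "dispersion_derivative")

    selected = select_confounds(confounds, spec.confound_selector)
    if len(selected.columns) and len(selected) != n_volumes:
        raise ValidationError("confound row count must equal n_volumes")
    for c in selected.columns:
        _add(c, selected[c].to_numpy(dtype=float), "confound")

    drift = cosine_drift(n_volumes, tr, cutoff=drift_cutoff)
    for j in range(drift.shape[1]):
        _add(f"drift_{j + 1}", drift[:, j], "drift")

    _add("intercept", np.ones(n_volumes), "intercept")
    return DesignMatrix(frame=pd.DataFrame(cols), tr=tr, column_roles=roles)


def correlation_report(dm: DesignMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations between design columns.

    Constant columns (e.g. the intercept) have undefined correlation;
    their entries are reported as 0 and the column names returned as
    warning flags.  The diagonal is 1.
    """
    x = dm.matrix()
    names = dm.columns
    sd = x.std(axis=0)
    flagged = [n for n, s in zip(names, sd) if s == 0]
    xc = x - x.mean(axis=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    xn = xc / safe_sd
    r = (xn.T @ xn) / len(x)
    const = sd == 0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names), flagged
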