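"""Synthetic data with known ground truth for the full pipeline.

Generates (i) named stimulus streams — binary speech-like and face-like
indicators as thresholded latent Gaussian processes with a calibrated
pairwise correlation, plus a smooth dense brightness-like stream in
[0, 1]; (ii) face observations as tight 512-d embedding blobs per
identity; (iii) BOLD runs as design x true-betas plus confound signal and
AR(1) noise, with a 6-motion + 6-component confound table; and (iv)
multi-study collections whose per-study true effect is the global effect
plus a Normal(0, between_study_sd^2) draw, for meta-analysis recovery and
calibration experiments.

Everything is seed-deterministic; generators write a provenance JSON
beside on-disk outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import HRFParams, convolve_to_tr
from .stimio import (
    EMBEDDING_DIM,
    BoldRun,
    FaceObservation,
    FeatureStream,
    ValidationError,
    write_events,
    write_bold,
    write_dense_stream,
    write_faces,
)

__all__ = [
    "SimSpec",
    "RunData",
    "Subject",
    "Study",
    "StudyCollection",
    "simulate_streams",
    "simulate_faces",
    "simulate_bold",
    "simulate_multistudy",
    "simulate_study_maps",
    "N_MOTION_CONFOUNDS",
    "N_COMPCOR_CONFOUNDS",
]

N_MOTION_CONFOUNDS = 6
N_COMPCOR_CONFOUNDS = 6

DEFAULT_VOXEL_SIZE_MM = 2.0


@dataclass
class SimSpec:
    """Study-generation settings; defaults define the standard conditions.

    An 8x8x8 grid (2 mm voxels) with ~10% active voxels keeps the full
    three-level pipeline plus a 20-study meta-analysis tractable on one
    CPU while leaving enough voxels for calibration statements.
    """

    n_studies: int = 20
    n_subjects: int = 4
    n_runs: int = 2
    n_volumes: int = 100
    tr: float = 2.0
    grid: tuple[int, int, int] = (8, 8, 8)
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    active_fraction: float = 0.1
    amplitude: float = 1.0
    active_predictor: str = "speech"
    predictors: tuple[str, ...] = ("speech", "face")
    ar_rho: float = 0.3
    noise_sd: float = 1.0
    between_study_sd: float = 0.1
    feature_correlation: float = 0.5
    p_on: float = 0.3
    stream_rate: float = 1.0
    confound_amp: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.ar_rho < 1:
            raise ValidationError("|ar_rho| must be < 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not -1 < self.feature_correlation < 1:
            raise ValidationError("|feature_correlation| must be < 1")
        if not 0 < self.p_on < 1:
            raise ValidationError("p_on must lie in (0, 1)")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def to_json(self) -> str:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["predictors"] = list(self.predictors)
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# correlated binary streams
# ---------------------------------------------------------------------------


def _binary_corr(latent_r: float, c: float, p: float) -> float:
    """Pearson correlation of two indicators 1{X>c}, 1{Y>c} with latent r."""
    cov = np.array([[1.0, latent_r], [latent_r, 1.0]])
    # P(X>c, Y>c) by inclusion-exclusion from the lower-orthant CDF
    p11 = 1.0 - 2.0 * stats.norm.cdf(c) + stats.multivariate_normal.cdf(
        [c, c], mean=[0.0, 0.0], cov=cov
    )
    return (p11 - p**2) / (p * (1.0 - p))


def _solve_latent_r(target_r: float, p: float) -> float:
    """Latent Gaussian correlation achieving a target binary correlation."""
    if target_r == 0.0:
        return 0.0
    lo, hi = -0.999, 0.999
    c = stats.norm.ppf(1.0 - p)
    f_lo, f_hi = _binary_corr(lo, c, p), _binary_corr(hi, c, p)
    if not f_lo - 1e-9 <= target_r <= f_hi + 1e-9:
        raise ValidationError(
            f"binary correlation {target_r} infeasible for on-probability {p}"
        )
    from scipy.optimize import brentq

    return float(brentq(lambda r: _binary_corr(r, c, p) - target_r, lo, hi, xtol=1e-6))


def _binary_to_sparse(binary: np.ndarray, rate: float, name: str) -> FeatureStream:
    """Run-length encode a binary grid into sparse unit-value events."""
    onsets, durations = [], []
    in_run = False
    start = 0
    for i, b in enumerate(binary):
        if b and not in_run:
            in_run, start = True, i
        elif not b and in_run:
            in_run = False
            onsets.append(start / rate)
            durations.append((i - start) / rate)
    if in_run:
        onsets.append(start / rate)
        durations.append((len(binary) - start) / rate)
    return FeatureStream(
        name=name, kind="sparse",
        onsets=np.array(onsets), durations=np.array(durations),
        values=np.ones(len(onsets)),
    )


def simulate_streams(spec: SimSpec, seed: int | None = None) -> dict[str, FeatureStream]:
    """Generate the named stimulus streams for one run.

    Binary sparse speech-like and face-like streams come from thresholded
    latent bivariate Gaussians whose latent correlation is solved
    numerically so the *binary* Pearson correlation matches
    ``spec.feature_correlation``; the dense brightness-like stream is
    smoothed Gaussian noise squashed into [0, 1].
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(spec.duration * spec.stream_rate))
    latent_r = _solve_latent_r(spec.feature_correlation, spec.p_on)
    cov = np.array([[1.0, latent_r], [latent_r, 1.0]])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation matrix not positive semidefinite") from exc
    latents = rng.standard_normal((2, n))
    latents = chol @ latents
    c = stats.norm.ppf(1.0 - spec.p_on)
    streams: dict[str, FeatureStream] = {}
    for name, lat in zip(spec.predictors[:2], latents):
        streams[name] = _binary_to_sparse(lat > c, spec.stream_rate, name)
    raw = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=3.0)
    lo, hi = raw.min(), raw.max()
    bright = (raw - lo) / (hi - lo) if hi > lo else np.full(n, 0.5)
    streams["brightness"] = FeatureStream(
        name="brightness", kind="dense", values=bright, sampling_rate=spec.stream_rate
    )
    return streams


# ---------------------------------------------------------------------------
# faces
# ---------------------------------------------------------------------------


def simulate_faces(
    n_identities: int,
    appearances: int | dict[int, list[float]] = 20,
    seed: int = 0,
    duration: float = 60.0,
    within_sd: float = 0.05,
    center_sd: float = 1.0,
) -> tuple[list[FaceObservation], np.ndarray]:
    """Sample face observations as tight per-identity embedding blobs.

    ``appearances`` is either the number of observations per identity
    (times drawn uniformly over [0, duration)) or an explicit schedule
    mapping identity -> observation times.  Within-identity spread is much
    smaller than the typical between-identity distance.  Returns the
    observations sorted by time and the true identity label per
    observation.
    """
    if n_identities < 1:
        raise ValidationError("need at least one identity")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, center_sd, size=(n_identities, EMBEDDING_DIM))
    times: list[float] = []
    labels: list[int] = []
    if isinstance(appearances, dict):
        for ident, ts in appearances.items():
            times.extend(float(t) for t in ts)
            labels.extend([int(ident)] * len(ts))
    else:
        for ident in range(n_identities):
            ts = rng.uniform(0.0, duration, size=appearances)
            times.extend(ts.tolist())
            labels.extend([ident] * appearances)
    order = np.argsort(times, kind="stable")
    obs = []
    out_labels = []
    for i in order:
        ident = labels[i]
        emb = centers[ident] + rng.normal(0.0, within_sd, size=EMBEDDING_DIM)
        obs.append(
            FaceObservation(
                time=times[i], embedding=emb, probability=float(rng.uniform(0.7, 1.0))
            )
        )
        out_labels.append(ident)
    return obs, np.array(out_labels, dtype=int)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------


def _confound_table(n_volumes: int, rng: np.random.Generator) -> pd.DataFrame:
    """6 motion-like random-walk columns + 6 white-noise component columns."""
    cols = {}
    for i in range(N_MOTION_CONFOUNDS):
        axis = ("x", "y", "z")[i % 3]
        kind = "trans" if i < 3 else "rot"
        cols[f"{kind}_{axis}"] = np.cumsum(rng.normal(0.0, 0.02, n_volumes))
    for i in range(N_COMPCOR_CONFOUNDS):
        cols[f"a_comp_cor_{i:02d}"] = rng.standard_normal(n_volumes)
    return pd.DataFrame(cols)


def _ar1_noise(
    shape: tuple[int, ...], n_volumes: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``.

    The recursion starts at the stationary distribution and uses
    innovations of sd ``sd * sqrt(1 - rho^2)`` so every sample has
    marginal sd ``sd``.
    """
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=shape + (n_volumes,))
    noise = np.empty(shape + (n_volumes,))
    noise[..., 0] = rng.normal(0.0, sd, size=shape)
    for t in range(1, n_volumes):
        noise[..., t] = rho * noise[..., t - 1] + innov[..., t]
    return noise


def simulate_bold(
    truth_columns: dict[str, np.ndarray],
    true_betas: dict[str, np.ndarray],
    ar_rho: float,
    noise_sd: float,
    grid: tuple[int, int, int],
    seed: int,
    tr: float = 2.0,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
    confound_amp: float = 0.1,
) -> BoldRun:
    """Generate one BOLD run: sum(beta * column) + confound signal + AR(1) noise.

    ``truth_columns`` maps predictor names to TR-gridded signal columns
    (typically HRF-convolved streams); ``true_betas`` maps a subset of
    those names to 3-D beta maps on ``grid``.  The emitted confound table
    has 6 motion-like and 6 component-like columns whose signal enters
    each voxel with independent random weights of scale ``confound_amp``.
    """
    rng = np.random.default_rng(seed)
    n_volumes = len(next(iter(truth_columns.values())))
    confounds = _confound_table(n_volumes, rng)
    data = np.zeros(grid + (n_volumes,))
    for name, beta_map in true_betas.items():
        if name not in truth_columns:
            raise ValidationError(f"no truth column for predictor {name!r}")
        beta_map = np.asarray(beta_map, dtype=float)
        if beta_map.shape != tuple(grid):
            raise ValidationError("beta map shape must equal the grid")
        data += beta_map[..., None] * truth_columns[name][None, None, None, :]
    cmat = confounds.to_numpy()
    cmat = (cmat - cmat.mean(axis=0)) / np.where(cmat.std(axis=0) == 0, 1, cmat.std(axis=0))
    weights = rng.normal(0.0, confound_amp, size=grid + (cmat.shape[1],))
    data += weights @ cmat.T
    data += _ar1_noise(tuple(grid), n_volumes, ar_rho, noise_sd, rng)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return BoldRun(
        data=data, tr=tr, mask=np.ones(grid, dtype=bool),
        confounds=confounds, affine=aff,
    )


# ---------------------------------------------------------------------------
# multi-study collections
# ---------------------------------------------------------------------------


@dataclass
class RunData:
    bold: BoldRun
    streams: dict[str, FeatureStream]


@dataclass
class Subject:
    subject_id: str
    runs: list[RunData]


@dataclass
class Study:
    study_id: str
    subjects: list[Subject]
    true_betas: dict[str, np.ndarray]


@dataclass
class StudyCollection:
    spec: SimSpec
    studies: list[Study]
    global_betas: dict[str, np.ndarray]
    active_mask: np.ndarray

    @property
    def affine(self) -> np.ndarray:
        return self.spec.affine


def default_true_betas(spec: SimSpec, rng: np.random.Generator) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Global beta maps: ``active_fraction`` of voxels active at ``amplitude``."""
    n_vox = int(np.prod(spec.grid))
    n_active = int(round(spec.active_fraction * n_vox))
    active = np.zeros(n_vox, dtype=bool)
    if n_active:
        active[rng.choice(n_vox, size=n_active, replace=False)] = True
    active = active.reshape(spec.grid)
    betas = {p: np.zeros(spec.grid) for p in spec.predictors}
    betas[spec.active_predictor] = np.where(active, spec.amplitude, 0.0)
    return betas, active


def simulate_multistudy(
    spec: SimSpec,
    seed: int | None = None,
    global_betas: dict[str, np.ndarray] | None = None,
    out_dir: str | Path | None = None,
    hrf: HRFParams = HRFParams(),
) -> StudyCollection:
    """Generate a multi-study collection with known ground truth.

    Per-study true betas are the global betas plus an independent
    Normal(0, between_study_sd^2) draw at each active (non-zero) voxel.
    When ``out_dir`` is given, a BIDS-lite directory tree is written
    (events.tsv, dense-stream TSVs, confounds TSV, BOLD and mask NIfTIs,
    plus the generating spec JSON as provenance).
    """
    if spec.n_studies < 2:
        raise ValidationError("need at least 2 studies")
    master = np.random.default_rng(spec.seed if seed is None else seed)
    if global_betas is None:
        global_betas, active = default_true_betas(spec, master)
    else:
        active = np.zeros(spec.grid, dtype=bool)
        for b in global_betas.values():
            active |= np.asarray(b) != 0

    studies = []
    for s in range(spec.n_studies):
        study_betas = {}
        for name, base in global_betas.items():
            base = np.asarray(base, dtype=float)
            jitter = master.normal(0.0, spec.between_study_sd, size=spec.grid)
            study_betas[name] = np.where(base != 0, base + jitter, base)
        subjects = []
        for subj in range(spec.n_subjects):
            runs = []
            for run in range(spec.n_runs):
                run_seed = int(master.integers(2**31))
                streams = simulate_streams(spec, seed=run_seed)
                truth_cols = {}
                for name in spec.predictors:
                    canonical, _ = convolve_to_tr(
                        streams[name], tr=spec.tr, n_volumes=spec.n_volumes, p=hrf
                    )
                    truth_cols[name] = canonical
                bold = simulate_bold(
                    truth_cols,
                    study_betas,
                    ar_rho=spec.ar_rho,
                    noise_sd=spec.noise_sd,
                    grid=spec.grid,
                    seed=int(master.integers(2**31)),
                    tr=spec.tr,
                    voxel_size_mm=spec.voxel_size_mm,
                    confound_amp=spec.confound_amp,
                )
                runs.append(RunData(bold=bold, streams=streams))
            subjects.append(Subject(subject_id=f"sub-{subj + 1:02d}", runs=runs))
        studies.append(Study(study_id=f"study-{s + 1:02d}", subjects=subjects, true_betas=study_betas))

    collection = StudyCollection(
        spec=spec, studies=studies, global_betas=global_betas, active_mask=active
    )
    if out_dir is not None:
        write_collection(collection, out_dir)
    return collection


def write_collection(collection: StudyCollection, out_dir: str | Path) -> None:
    """Write a collection as per-study BIDS-lite directories plus provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "sim_spec.json").write_text(collection.spec.to_json())
    for study in collection.studies:
        for subject in study.subjects:
            for r, run in enumerate(subject.runs, start=1):
                stem = out / study.study_id / subject.subject_id / f"run-{r:02d}"
                stem.parent.mkdir(parents=True, exist_ok=True)
                sparse = [s for s in run.streams.values() if s.kind == "sparse"]
                for s in sparse:
                    write_events([s], str(stem) + f"_{s.name}_events.tsv")
                for s in run.streams.values():
                    if s.kind == "dense":
                        write_dense_stream(s, str(stem) + f"_{s.name}.tsv")
                write_bold(run.bold, stem)


def simulate_study_maps(
    n_studies: int,
    grid: tuple[int, int, int],
    effect: np.ndarray | float,
    within_variance: float,
    between_study_sd: float,
    seed: int,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
) -> list:
    """Directly simulate per-study group-level (effect, variance) maps.

    Observed study effect = global effect + Normal(0, between_study_sd^2)
    + Normal(0, within_variance); the variance map carries the true
    within-study sampling variance.  Bypasses the time-series levels for
    meta-analysis recovery and calibration experiments.
    """
    from .stimio import StatMap

    rng = np.random.default_rng(seed)
    grid = tuple(grid)
    base = np.broadcast_to(np.asarray(effect, dtype=float), grid)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    maps = []
    for _ in range(n_studies):
        study_true = base + rng.normal(0.0, between_study_sd, size=grid)
        observed = study_true + rng.normal(0.0, np.sqrt(within_variance), size=grid)
        maps.append(
            StatMap(
                effect=observed,
                variance=np.full(grid, within_variance),
                dof=np.inf,
                kind="beta",
                affine=aff,
                mask=np.ones(grid, dtype=bool),
            )
        )
    return maps
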