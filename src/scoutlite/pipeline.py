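"""End-to-end orchestration: run -> subject -> study -> meta-analysis.

The library-level entry points (`analyze_study`, `analyze_collection`)
execute the three-level GLM and the image-based meta-analysis on
in-memory study collections.  `run_pipeline` drives the same stages over
an on-disk bundle (the BIDS-lite layout the simulator writes plus a model
spec JSON) and records a run manifest with input checksums so a completed
bundle is locked against silent modification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .design import (
    DEFAULT_DRIFT_CUTOFF_S,
    DEFAULT_OVERSAMPLING,
    DesignMatrix,
    HRFParams,
    build_design,
    correlation_report,
)
from .glm import (
    DEFAULT_SMOOTHING_FWHM_MM,
    GroupResult,
    RunFit,
    contrast_map,
    fit_run,
    fixed_effects,
    group_onesample,
    smooth_map,
)
from .ibma import MetaResult, Z_CRIT_P001, run_ibma, threshold_z
from .simulate import RunData, Study, StudyCollection
from .stimio import (
    BoldRun,
    Contrast,
    FeatureStream,
    ModelSpec,
    StatMap,
    ValidationError,
    read_bold,
    read_dense_stream,
    read_events,
    read_model_spec,
    write_statmap,
)

__all__ = [
    "RunManifest",
    "analyze_run",
    "analyze_study",
    "analyze_collection",
    "run_pipeline",
    "STAGES",
]

STAGES = ("extract", "design", "glm", "meta")


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------


def _analysis_contrasts(spec: ModelSpec) -> list[Contrast]:
    """Contrasts to carry through the levels; default one per predictor.

    Contrasts address the canonical predictor columns only (the dispersion
    derivative columns absorb shape variability but are not tested).
    """
    if spec.contrasts:
        return list(spec.contrasts)
    entering = [
        n for n in spec.final_predictors()
        if not any(t.inputs[0] == n and t.output != n for t in spec.transformations)
    ]
    return [Contrast(name=n, conditions=(n,), weights=(1.0,)) for n in entering]


def analyze_run(
    bold: BoldRun,
    streams: dict[str, FeatureStream],
    spec: ModelSpec,
    hrf: HRFParams = HRFParams(),
    noise: str = "ar1",
    oversampling: int = DEFAULT_OVERSAMPLING,
    drift_cutoff: float = DEFAULT_DRIFT_CUTOFF_S,
    include_derivatives: bool = True,
) -> tuple[RunFit, DesignMatrix]:
    """Build the run design matrix and fit the prewhitened GLM."""
    dm = build_design(
        streams,
        bold.confounds,
        spec,
        tr=bold.tr,
        n_volumes=bold.n_volumes,
        hrf=hrf,
        oversampling=oversampling,
        drift_cutoff=drift_cutoff,
        include_derivatives=include_derivatives,
    )
    return fit_run(bold, dm, noise=noise), dm


def analyze_study(
    study: Study | list[list[RunData]],
    spec: ModelSpec,
    hrf: HRFParams = HRFParams(),
    noise: str = "ar1",
    smoothing_fwhm_mm: float = DEFAULT_SMOOTHING_FWHM_MM,
    include_derivatives: bool = True,
) -> dict[str, GroupResult]:
    """Three-level estimation for one study, per contrast.

    Run-level contrast maps are smoothed, combined within subject by fixed
    effects, and summarized across subjects by a one-sample t (z by
    quantile transform).
    """
    subjects = study.subjects if isinstance(study, Study) else study
    contrasts = _analysis_contrasts(spec)
    per_contrast_subject: dict[str, list[StatMap]] = {c.name: [] for c in contrasts}
    for subject in subjects:
        runs = subject.runs if hasattr(subject, "runs") else subject
        run_maps: dict[str, list[StatMap]] = {c.name: [] for c in contrasts}
        for run in runs:
            fit, _ = analyze_run(
                run.bold, run.streams, spec, hrf=hrf, noise=noise,
                include_derivatives=include_derivatives,
            )
            for c in contrasts:
                cmap = contrast_map(fit, list(c.conditions), list(c.weights))
                run_maps[c.name].append(smooth_map(cmap, fwhm_mm=smoothing_fwhm_mm))
        for c in contrasts:
            per_contrast_subject[c.name].append(fixed_effects(run_maps[c.name]))
    return {
        name: group_onesample(maps) for name, maps in per_contrast_subject.items()
    }


def analyze_collection(
    collection: StudyCollection,
    spec: ModelSpec,
    hrf: HRFParams = HRFParams(),
    noise: str = "ar1",
    smoothing_fwhm_mm: float = DEFAULT_SMOOTHING_FWHM_MM,
    include_derivatives: bool = True,
    mask: np.ndarray | None = None,
) -> dict[str, tuple[list[GroupResult], MetaResult]]:
    """Run every study through the three levels and meta-analyze per contrast."""
    per_contrast: dict[str, list[GroupResult]] = {}
    for study in collection.studies:
        results = analyze_study(
            study, spec, hrf=hrf, noise=noise,
            smoothing_fwhm_mm=smoothing_fwhm_mm,
            include_derivatives=include_derivatives,
        )
        for name, gr in results.items():
            per_contrast.setdefault(name, []).append(gr)
    out: dict[str, tuple[list[GroupResult], MetaResult]] = {}
    for name, groups in per_contrast.items():
        meta = run_ibma([g.effect for g in groups], mask=mask)
        out[name] = (groups, meta)
    return out


# ---------------------------------------------------------------------------
# on-disk bundles
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record of one bundle execution."""

    manifest_id: str
    spec_hash: str
    version: str
    seed: int | None
    inputs: dict[str, str]  # relative path -> sha256
    stages: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _bundle_inputs(bundle: Path) -> dict[str, str]:
    exts = (".tsv", ".json", ".nii.gz", ".nii")
    files = sorted(
        p for p in bundle.rglob("*")
        if p.is_file()
        and any(str(p).endswith(e) for e in exts)
        and "derivatives" not in p.parts
        and p.name != "manifest.json"
    )
    return {str(p.relative_to(bundle)): _sha256(p) for p in files}


def _run_stems(bundle: Path) -> list[Path]:
    return sorted(
        Path(str(p)[: -len("_bold.nii.gz")])
        for p in bundle.rglob("*_bold.nii.gz")
        if "derivatives" not in p.parts
    )


def _load_run(stem: Path) -> RunData:
    bold = read_bold(stem)
    streams: dict[str, FeatureStream] = {}
    for ev in sorted(stem.parent.glob(stem.name + "_*_events.tsv")):
        for s in read_events(ev):
            streams[s.name] = s
    for dn in sorted(stem.parent.glob(stem.name + "_*.tsv")):
        if dn.name.endswith(("_events.tsv", "_confounds.tsv")):
            continue
        s = read_dense_stream(dn)
        streams[s.name] = s
    return RunData(bold=bold, streams=streams)


def run_pipeline(
    bundle_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    seed: int | None = None,
    noise: str = "ar1",
    z_crit: float = Z_CRIT_P001,
    force_new_id: bool = False,
) -> RunManifest:
    """Execute pipeline stages over a bundle and write a manifest.

    Pre-flight checks (model spec, inputs, prior-manifest integrity) run
    before any computation; a bundle whose recorded inputs changed since
    its last run is refused unless ``force_new_id`` issues a fresh
    manifest id.  Outputs land under ``<bundle>/derivatives``.
    """
    bundle = Path(bundle_dir)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages {unknown}")
    spec_path = bundle / "model_spec.json"
    if not spec_path.exists():
        raise ValidationError("bundle is missing model_spec.json")
    spec = read_model_spec(spec_path)  # pre-flight validation
    stems = _run_stems(bundle)
    if any(s in stages for s in ("design", "glm")) and not stems:
        raise ValidationError("bundle contains no BOLD runs")

    inputs = _bundle_inputs(bundle)
    spec_hash = _sha256(spec_path)
    manifest_path = bundle / "manifest.json"
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("inputs") != inputs and not force_new_id:
            raise ValidationError(
                "bundle inputs changed since the recorded run; "
                "pass force_new_id=True to issue a new manifest"
            )
    manifest = RunManifest(
        manifest_id=hashlib.sha256(
            (spec_hash + json.dumps(inputs, sort_keys=True)).encode()
        ).hexdigest()[:12],
        spec_hash=spec_hash,
        version=__version__,
        seed=seed,
        inputs=inputs,
    )

    deriv = bundle / "derivatives"
    executed = [s for s in STAGES if s in stages]
    if "extract" in executed:
        manifest.stages["extract"] = _stage_extract(bundle, deriv, manifest)
    if "design" in executed:
        manifest.stages["design"] = _stage_design(stems, spec, deriv, manifest)
    group_results: dict[str, dict[str, GroupResult]] = {}
    if "glm" in executed:
        manifest.stages["glm"] = _stage_glm(
            bundle, stems, spec, deriv, manifest, noise, group_results
        )
    if "meta" in executed:
        manifest.stages["meta"] = _stage_meta(
            bundle, spec, deriv, manifest, noise, z_crit, group_results
        )
    manifest_path.write_text(manifest.to_json())
    return manifest


def _stage_extract(bundle: Path, deriv: Path, manifest: RunManifest) -> str:
    """Derive feature streams from raw proxies (transcripts, face tables)."""
    from .face_identity import adaptation_stream, any_faces_stream, cluster_faces, prune_clusters
    from .features import speech_indicator
    from .stimio import read_faces, read_transcript, write_dense_stream

    n_done = 0
    for transcript in sorted(bundle.rglob("*_transcript.tsv")):
        words = read_transcript(transcript)
        duration = max((w.onset + w.duration for w in words), default=0.0)
        stream = speech_indicator(words, rate=2.0, duration=np.ceil(duration))
        out = deriv / "features" / (transcript.stem.replace("_transcript", "") + "_speech.tsv")
        out.parent.mkdir(parents=True, exist_ok=True)
        write_dense_stream(stream, out)
        manifest.outputs.append(str(out.relative_to(bundle)))
        n_done += 1
    for faces in sorted(bundle.rglob("*_faces.tsv")):
        obs = read_faces(faces)
        duration = np.ceil(max(o.time for o in obs) + 1.0)
        assign = prune_clusters(cluster_faces(obs, edge_threshold=10.0, seed=0), obs)
        for maker, suffix in (
            (lambda: adaptation_stream(assign, obs, 1.0, duration), "_log_mean_time_cum.tsv"),
            (lambda: any_faces_stream(obs, 1.0, duration), "_any_faces.tsv"),
        ):
            out = deriv / "features" / (faces.stem.replace("_faces", "") + suffix)
            out.parent.mkdir(parents=True, exist_ok=True)
            write_dense_stream(maker(), out)
            manifest.outputs.append(str(out.relative_to(bundle)))
        n_done += 1
    return f"completed ({n_done} inputs)"


def _stage_design(
    stems: list[Path], spec: ModelSpec, deriv: Path, manifest: RunManifest
) -> str:
    for stem in stems:
        run = _load_run(stem)
        dm = build_design(
            run.streams, run.bold.confounds, spec,
            tr=run.bold.tr, n_volumes=run.bold.n_volumes,
        )
        rel = stem.relative_to(stem.parents[2])
        out_dir = deriv / "design" / rel.parent
        out_dir.mkdir(parents=True, exist_ok=True)
        dm_path = out_dir / (stem.name + "_design.tsv")
        dm.frame.to_csv(dm_path, sep="\t", index=False)
        corr, _ = correlation_report(dm)
        corr_path = out_dir / (stem.name + "_design_corr.tsv")
        corr.to_csv(corr_path, sep="\t")
        bundle = deriv.parent
        manifest.outputs.extend(
            [str(dm_path.relative_to(bundle)), str(corr_path.relative_to(bundle))]
        )
    return f"completed ({len(stems)} runs)"


def _study_dirs(bundle: Path) -> list[Path]:
    return sorted(
        {p.parents[1] for p in bundle.rglob("*_bold.nii.gz") if "derivatives" not in p.parts}
    )


def _stage_glm(
    bundle: Path,
    stems: list[Path],
    spec: ModelSpec,
    deriv: Path,
    manifest: RunManifest,
    noise: str,
    group_results: dict[str, dict[str, GroupResult]],
) -> str:
    for study_dir in _study_dirs(bundle):
        subjects = []
        for subj_dir in sorted(d for d in study_dir.iterdir() if d.is_dir()):
            run_stems = sorted(
                Path(str(p)[: -len("_bold.nii.gz")])
                for p in subj_dir.glob("*_bold.nii.gz")
            )
            subjects.append([_load_run(s) for s in run_stems])
        results = analyze_study(subjects, spec, noise=noise)
        group_results[study_dir.name] = results
        out_dir = deriv / "glm" / study_dir.name
        for name, gr in results.items():
            for statmap, tag in ((gr.effect, "effect"), (gr.z, "z")):
                stem_out = out_dir / f"{name}_{tag}"
                write_statmap(statmap, stem_out)
                manifest.outputs.append(
                    str(stem_out.relative_to(bundle)) + "_{effect,variance,mask}.nii.gz"
                )
    return f"completed ({len(_study_dirs(bundle))} studies)"


def _stage_meta(
    bundle: Path,
    spec: ModelSpec,
    deriv: Path,
    manifest: RunManifest,
    noise: str,
    z_crit: float,
    group_results: dict[str, dict[str, GroupResult]],
) -> str:
    import nibabel as nib

    from .stimio import read_statmap

    if not group_results:
        # load previously written group maps
        glm_dir = deriv / "glm"
        if not glm_dir.exists():
            raise ValidationError("meta stage requires glm outputs")
        for study_dir in sorted(glm_dir.iterdir()):
            maps = {}
            for eff in sorted(study_dir.glob("*_effect_effect.nii.gz")):
                name = eff.name[: -len("_effect_effect.nii.gz")]
                maps[name] = read_statmap(study_dir / f"{name}_effect")
            group_results[study_dir.name] = maps
        per_contrast: dict[str, list[StatMap]] = {}
        for study, maps in group_results.items():
            for name, m in maps.items():
                per_contrast.setdefault(name, []).append(m)
    else:
        per_contrast = {}
        for study, results in group_results.items():
            for name, gr in results.items():
                per_contrast.setdefault(name, []).append(gr.effect)

    out_dir = deriv / "meta"
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, maps in per_contrast.items():
        meta = run_ibma(maps)
        thresholded, supra = threshold_z(meta.z, z_crit=z_crit)
        for arr, tag in (
            (meta.mu, "mu"), (meta.tau2, "tau2"), (meta.z, "z"), (thresholded, "z_thresh"),
        ):
            path = out_dir / f"{name}_{tag}.nii.gz"
            nib.save(nib.Nifti1Image(arr.astype(np.float32), meta.affine), path)
            manifest.outputs.append(str(path.relative_to(bundle)))
        summary[name] = {
            "n_suprathreshold": int(supra.sum()),
            "peak_z": float(meta.z[meta.mask].max(initial=0.0)) if meta.mask.any() else 0.0,
            "k_studies": len(maps),
        }
    (out_dir / "meta_summary.json").write_text(json.dumps(summary, indent=2))
    manifest.outputs.append(str((out_dir / "meta_summary.json").relative_to(bundle)))
    return f"completed ({len(per_contrast)} contrasts)"
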