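"""Domain types and file I/O for the analysis pipeline.

All external formats the pipeline touches are plain text or NIfTI-1:

* BIDS-style ``events.tsv`` (``onset``, ``duration``, one column per value
  stream) for sparse stimulus annotations;
* confounds TSV, one row per acquired volume, named columns;
* transcript TSV (``text``, ``onset``, ``duration``) for word-timed speech;
* face-observation TSV (``time``, ``probability``, ``e000``..``e511``);
* lexical-norm TSV (``word``, ``value``);
* a JSON model specification describing predictors, transformations,
  confound selection and contrasts at the run/subject/dataset levels;
* NIfTI-1 volumes for BOLD runs and statistical maps (stored float32).

Times are 0-based stimulus seconds and event intervals are half-open
``[onset, onset + duration)`` throughout, matching the BIDS convention.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "FeatureStream",
    "TranscriptWord",
    "LexicalNorms",
    "FaceObservation",
    "BoldRun",
    "Transformation",
    "Contrast",
    "ModelSpec",
    "StatMap",
    "read_events",
    "write_events",
    "read_dense_stream",
    "write_dense_stream",
    "read_transcript",
    "write_transcript",
    "read_lexical_norms",
    "write_lexical_norms",
    "read_faces",
    "write_faces",
    "read_confounds",
    "write_confounds",
    "read_bold",
    "write_bold",
    "read_statmap",
    "write_statmap",
    "read_model_spec",
    "parse_model_spec",
    "select_confounds",
]

EMBEDDING_DIM = 512
"""Length of a face embedding vector (FaceNet output dimensionality)."""


class FormatError(ValueError):
    """An on-disk file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureStream:
    """A named stimulus predictor, sparse (events) or dense (uniform grid).

    Sparse streams hold ``onsets``/``durations``/``values`` per event with
    onsets strictly ascending.  Dense streams hold ``values`` sampled on a
    uniform grid starting at t = 0 with spacing ``1 / sampling_rate``.
    """

    name: str
    kind: str  # "sparse" | "dense"
    values: np.ndarray
    onsets: np.ndarray | None = None
    durations: np.ndarray | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "sparse":
            if self.onsets is None or self.durations is None:
                raise ValidationError("sparse stream requires onsets and durations")
            self.onsets = np.asarray(self.onsets, dtype=float)
            self.durations = np.asarray(self.durations, dtype=float)
            if not (len(self.onsets) == len(self.durations) == len(self.values)):
                raise ValidationError("onsets, durations, values must have equal length")
            if len(self.onsets) and np.any(self.onsets < 0):
                raise ValidationError("onsets must be non-negative")
            if len(self.onsets) and np.any(self.durations < 0):
                raise ValidationError("durations must be non-negative")
            if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
                raise ValidationError("onsets must be strictly ascending")
        elif self.kind == "dense":
            if self.sampling_rate is None or self.sampling_rate <= 0:
                raise ValidationError("dense stream requires sampling_rate > 0")
        else:
            raise ValidationError(f"unknown stream kind {self.kind!r}")

    @property
    def end_time(self) -> float:
        """Time at which the stream's support ends, in seconds."""
        if self.kind == "sparse":
            if len(self.values) == 0:
                return 0.0
            return float(np.max(self.onsets + self.durations))
        return len(self.values) / float(self.sampling_rate)

    def times(self) -> np.ndarray:
        """Sample times of a dense stream (t = k / rate)."""
        if self.kind != "dense":
            raise ValidationError("times() defined for dense streams only")
        return np.arange(len(self.values)) / float(self.sampling_rate)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "FeatureStream":
        """Copy of this stream with ``values`` replaced (same support)."""
        return FeatureStream(
            name=name or self.name,
            kind=self.kind,
            values=np.asarray(values, dtype=float),
            onsets=None if self.onsets is None else self.onsets.copy(),
            durations=None if self.durations is None else self.durations.copy(),
            sampling_rate=self.sampling_rate,
        )


@dataclass(frozen=True)
class TranscriptWord:
    """One force-aligned word: text plus its on-screen/on-air interval."""

    text: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError("word onset must be >= 0")
        if self.duration <= 0:
            raise ValidationError("word duration must be > 0")


@dataclass
class LexicalNorms:
    """A word -> value dictionary with its own moments, e.g. Log10WF norms.

    Lookup is case-insensitive (keys are lowercased).  ``mean`` and ``sd``
    are the population moments of the dictionary values and define the
    z-scoring applied when the norms are turned into a regressor.
    """

    table: dict[str, float]
    name: str = "norms"
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.table:
            raise ValidationError("lexical-norm dictionary must not be empty")
        self.table = {str(k).lower(): float(v) for k, v in self.table.items()}
        vals = np.array(list(self.table.values()), dtype=float)
        self.mean = float(vals.mean())
        self.sd = float(vals.std())
        if self.sd <= 0:
            raise ValidationError("lexical-norm values must not be constant")

    def lookup(self, word: str) -> float | None:
        return self.table.get(word.lower())


@dataclass
class FaceObservation:
    """A single detected face: time, 512-d embedding, detection probability."""

    time: float
    embedding: np.ndarray
    probability: float = 1.0

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        if self.embedding.shape != (EMBEDDING_DIM,):
            raise ValidationError(
                f"embedding must have length {EMBEDDING_DIM}, got {self.embedding.shape}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError("probability must lie in [0, 1]")


@dataclass
class BoldRun:
    """One preprocessed BOLD run plus its confound table."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) boolean
    confounds: pd.DataFrame
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("BOLD data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValidationError("mask shape must equal spatial shape")
        if len(self.confounds) != self.data.shape[3]:
            raise ValidationError("confound row count must equal number of volumes")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class Transformation:
    """One step of the predictor-transformation graph."""

    operation: str
    inputs: tuple[str, ...]
    output: str
    arguments: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Contrast:
    """A named linear contrast over named design columns."""

    name: str
    conditions: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.weights):
            raise ValidationError(
                "contrast weight vector length must equal the number of "
                "named design columns it addresses"
            )


KNOWN_TRANSFORMS = {"demean_rescale", "scale", "threshold", "orthogonalize", "convolve"}
LEVELS = ("run", "subject", "dataset")


@dataclass
class ModelSpec:
    """Declarative multi-level model description (BIDS-stats-model flavour)."""

    dataset: str
    predictors: list[str]
    transformations: list[Transformation] = field(default_factory=list)
    confound_selector: list[str] = field(default_factory=list)
    contrasts: list[Contrast] = field(default_factory=list)
    levels: dict[str, str] = field(
        default_factory=lambda: {"run": "ar1_glm", "subject": "fixed_effects", "dataset": "one_sample_t"}
    )

    def __post_init__(self) -> None:
        for lev in self.levels:
            if lev not in LEVELS:
                raise ValidationError(f"unknown level {lev!r}")
        self.transformations = list(self._ordered_transformations())

    def _ordered_transformations(self) -> list[Transformation]:
        """Topologically order transformations; reject cycles and unknown ops."""
        for t in self.transformations:
            if t.operation not in KNOWN_TRANSFORMS:
                raise ValidationError(f"unknown transformation {t.operation!r}")
        g = nx.DiGraph()
        known = set(self.predictors)
        by_output = {t.output: t for t in self.transformations}
        for t in self.transformations:
            g.add_node(t.output)
            for inp in t.inputs:
                if inp == t.output:
                    if inp in known:
                        continue  # in-place update of an existing predictor
                    raise ValidationError(
                        f"transformation {t.operation!r} references its own output {inp!r}"
                    )
                if inp in by_output:
                    g.add_edge(inp, t.output)
                elif inp not in known:
                    raise ValidationError(f"unknown predictor reference {inp!r}")
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("transformation graph is cyclic")
        order = list(nx.topological_sort(g))
        rank = {name: i for i, name in enumerate(order)}
        return sorted(self.transformations, key=lambda t: rank[t.output])

    def final_predictors(self) -> list[str]:
        """Design-entering predictor names after applying transformations."""
        names = list(self.predictors)
        for t in self.transformations:
            if t.output not in names:
                names.append(t.output)
        return names


@dataclass
class StatMap:
    """A voxelwise effect map with companion variance, dof and grid metadata."""

    effect: np.ndarray
    variance: np.ndarray
    dof: float
    kind: str  # "beta" | "t" | "z"
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ("beta", "t", "z"):
            raise ValidationError(f"unknown map kind {self.kind!r}")
        if self.effect.shape != self.variance.shape or self.effect.shape != self.mask.shape:
            raise FormatError("effect, variance and mask must share one 3-D shape")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if self.mask.any() and np.any(self.variance[self.mask] < 0):
            raise ValidationError("variance must be non-negative where defined")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.effect.shape


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_events(path) -> list[FeatureStream]:
    """Read a BIDS-style events.tsv into one sparse stream per value column.

    Rows are sorted by onset; value columns keep their header order.
    """
    df = _read_tsv(path)
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise FormatError(f"events table missing required column {col!r}")
    value_cols = [c for c in df.columns if c not in ("onset", "duration")]
    if not value_cols:
        raise FormatError("events table has no value column")
    for col in ("onset", "duration"):
        if df.empty:
            df[col] = df[col].astype(float)
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"column {col!r} must be numeric")
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    streams = []
    for col in value_cols:
        streams.append(
            FeatureStream(
                name=col,
                kind="sparse",
                onsets=df["onset"].to_numpy(dtype=float),
                durations=df["duration"].to_numpy(dtype=float),
                values=df[col].to_numpy(dtype=float),
            )
        )
    return streams


def write_events(streams: Sequence[FeatureStream], path) -> None:
    """Write sparse streams sharing one event grid to an events.tsv."""
    if not streams:
        raise ValidationError("need at least one stream")
    first = streams[0]
    cols = {"onset": first.onsets, "duration": first.durations}
    for s in streams:
        if s.kind != "sparse":
            raise ValidationError("write_events accepts sparse streams only")
        if len(s.values) != len(first.values) or not np.array_equal(s.onsets, first.onsets):
            raise ValidationError("streams must share one event grid")
        cols[s.name] = s.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_dense_stream(path) -> FeatureStream:
    """Read a dense stream TSV (columns ``time``, ``value``; uniform grid)."""
    df = _read_tsv(path)
    for col in ("time", "value"):
        if col not in df.columns:
            raise FormatError(f"dense stream table missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("dense stream needs >= 2 samples to infer its rate")
    dt = np.diff(t)
    if t[0] != 0 or not np.allclose(dt, dt[0]):
        raise FormatError("dense stream must lie on a uniform grid starting at 0")
    name = str(df["name"].iloc[0]) if "name" in df.columns else Path(path).stem
    return FeatureStream(
        name=name, kind="dense", values=df["value"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
    )


def write_dense_stream(stream: FeatureStream, path) -> None:
    if stream.kind != "dense":
        raise ValidationError("write_dense_stream accepts dense streams only")
    pd.DataFrame(
        {"time": stream.times(), "value": stream.values, "name": stream.name}
    ).to_csv(path, sep="\t", index=False)


def read_transcript(path) -> list[TranscriptWord]:
    """Read a word-timed transcript TSV (columns text, onset, duration)."""
    df = _read_tsv(path)
    for col in ("text", "onset", "duration"):
        if col not in df.columns:
            raise FormatError(f"transcript missing column {col!r}")
    df = df.sort_values("onset", kind="stable")
    return [
        TranscriptWord(text=str(r.text), onset=float(r.onset), duration=float(r.duration))
        for r in df.itertuples()
    ]


def write_transcript(words: Sequence[TranscriptWord], path) -> None:
    pd.DataFrame(
        {
            "text": [w.text for w in words],
            "onset": [w.onset for w in words],
            "duration": [w.duration for w in words],
        }
    ).to_csv(path, sep="\t", index=False)


def read_lexical_norms(path, name: str | None = None) -> LexicalNorms:
    """Read a lexical-norm TSV (columns word, value)."""
    df = _read_tsv(path)
    for col in ("word", "value"):
        if col not in df.columns:
            raise FormatError(f"lexical-norm table missing column {col!r}")
    table = dict(zip(df["word"].astype(str), df["value"].astype(float)))
    return LexicalNorms(table=table, name=name or Path(path).stem)


def write_lexical_norms(norms: LexicalNorms, path) -> None:
    pd.DataFrame(
        {"word": list(norms.table), "value": list(norms.table.values())}
    ).to_csv(path, sep="\t", index=False)


def read_faces(path) -> list[FaceObservation]:
    """Read face observations (columns time, probability, e000..e511)."""
    df = _read_tsv(path)
    emb_cols = [f"e{i:03d}" for i in range(EMBEDDING_DIM)]
    for col in ("time", "probability", emb_cols[0], emb_cols[-1]):
        if col not in df.columns:
            raise FormatError(f"face table missing column {col!r}")
    df = df.sort_values("time", kind="stable")
    emb = df[emb_cols].to_numpy(dtype=float)
    return [
        FaceObservation(time=float(t), embedding=e, probability=float(p))
        for t, p, e in zip(df["time"], df["probability"], emb)
    ]


def write_faces(obs: Sequence[FaceObservation], path) -> None:
    emb = np.array([o.embedding for o in obs])
    cols = {"time": [o.time for o in obs], "probability": [o.probability for o in obs]}
    cols.update({f"e{i:03d}": emb[:, i] for i in range(EMBEDDING_DIM)})
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_confounds(path) -> pd.DataFrame:
    """Read a confounds TSV (one row per volume, named columns)."""
    df = _read_tsv(path)
    if df.shape[1] == 0:
        raise FormatError("confound table has no columns")
    return df


def write_confounds(confounds: pd.DataFrame, path) -> None:
    confounds.to_csv(path, sep="\t", index=False)


def select_confounds(confounds: pd.DataFrame, selector: Sequence[str]) -> pd.DataFrame:
    """Select confound columns by exact name or fnmatch pattern, in table order.

    Raises :class:`FormatError` if a non-pattern selector matches nothing.
    """
    chosen: list[str] = []
    for sel in selector:
        is_pattern = any(ch in sel for ch in "*?[")
        matches = [c for c in confounds.columns if fnmatch.fnmatch(c, sel)]
        if not matches and not is_pattern:
            raise FormatError(f"confound column {sel!r} not found")
        chosen.extend(m for m in matches if m not in chosen)
    ordered = [c for c in confounds.columns if c in chosen]
    return confounds[ordered]


# ---------------------------------------------------------------------------
# NIfTI readers / writers
# ---------------------------------------------------------------------------


def write_bold(run: BoldRun, stem) -> None:
    """Write a run as ``<stem>_bold.nii.gz``, mask, confounds and TR sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), str(stem) + "_bold.nii.gz")
    nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine), str(stem) + "_mask.nii.gz")
    write_confounds(run.confounds, str(stem) + "_confounds.tsv")
    Path(str(stem) + "_bold.json").write_text(json.dumps({"RepetitionTime": run.tr}))


def read_bold(stem) -> BoldRun:
    stem = str(stem)
    img = nib.load(stem + "_bold.nii.gz")
    mask = nib.load(stem + "_mask.nii.gz")
    meta = json.loads(Path(stem + "_bold.json").read_text())
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=float),
        tr=float(meta["RepetitionTime"]),
        mask=np.asarray(mask.dataobj) > 0,
        confounds=read_confounds(stem + "_confounds.tsv"),
        affine=img.affine,
    )


def write_statmap(statmap: StatMap, stem) -> None:
    """Write a stat map as effect/variance/mask NIfTIs plus a JSON sidecar.

    Arrays are stored float32; values outside the mask are written as 0.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    eff = np.where(statmap.mask, statmap.effect, 0.0).astype(np.float32)
    var = np.where(statmap.mask, statmap.variance, 0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(eff, statmap.affine), str(stem) + "_effect.nii.gz")
    nib.save(nib.Nifti1Image(var, statmap.affine), str(stem) + "_variance.nii.gz")
    nib.save(nib.Nifti1Image(statmap.mask.astype(np.uint8), statmap.affine), str(stem) + "_mask.nii.gz")
    Path(str(stem) + "_stat.json").write_text(
        json.dumps({"dof": statmap.dof, "kind": statmap.kind})
    )


def read_statmap(stem) -> StatMap:
    stem = str(stem)
    eff_img = nib.load(stem + "_effect.nii.gz")
    var_img = nib.load(stem + "_variance.nii.gz")
    mask_img = nib.load(stem + "_mask.nii.gz")
    eff = np.asarray(eff_img.dataobj, dtype=float)
    var = np.asarray(var_img.dataobj, dtype=float)
    if eff.shape != var.shape:
        raise FormatError("paired effect/variance files must share one shape")
    if not np.allclose(eff_img.affine, var_img.affine, atol=1e-4):
        raise FormatError("paired effect/variance files must share one affine")
    meta = json.loads(Path(stem + "_stat.json").read_text())
    return StatMap(
        effect=eff,
        variance=var,
        dof=float(meta["dof"]),
        kind=str(meta["kind"]),
        affine=eff_img.affine,
        mask=np.asarray(mask_img.dataobj) > 0,
    )


# ---------------------------------------------------------------------------
# model-spec JSON
# ---------------------------------------------------------------------------


def parse_model_spec(obj: dict) -> ModelSpec:
    """Build and validate a :class:`ModelSpec` from a decoded JSON object."""
    try:
        transformations = [
            Transformation(
                operation=t["operation"],
                inputs=tuple(t.get("inputs", ())),
                output=t["output"],
                arguments=dict(t.get("arguments", {})),
            )
            for t in obj.get("transformations", [])
        ]
        contrasts = [
            Contrast(
                name=c["name"],
                conditions=tuple(c["conditions"]),
                weights=tuple(float(w) for w in c["weights"]),
            )
            for c in obj.get("contrasts", [])
        ]
        spec = ModelSpec(
            dataset=obj.get("dataset", "dataset"),
            predictors=list(obj["predictors"]),
            transformations=transformations,
            confound_selector=list(obj.get("confound_selector", [])),
            contrasts=contrasts,
            levels=dict(
                obj.get(
                    "levels",
                    {"run": "ar1_glm", "subject": "fixed_effects", "dataset": "one_sample_t"},
                )
            ),
        )
    except KeyError as exc:
        raise ValidationError(f"model spec missing required field {exc}") from exc
    return spec


def read_model_spec(path) -> ModelSpec:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse model spec {path}: {exc}") from exc
    return parse_model_spec(obj)


def write_model_spec(spec: ModelSpec, path) -> None:
    obj = {
        "dataset": spec.dataset,
        "predictors": spec.predictors,
        "transformations": [
            {
                "operation": t.operation,
                "inputs": list(t.inputs),
                "output": t.output,
                "arguments": t.arguments,
            }
            for t in spec.transformations
        ],
        "confound_selector": spec.confound_selector,
        "contrasts": [
            {"name": c.name, "conditions": list(c.conditions), "weights": list(c.weights)}
            for c in spec.contrasts
        ],
        "levels": spec.levels,
    }
    Path(path).write_text(json.dumps(obj, indent=2))
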