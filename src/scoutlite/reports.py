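"""Static quality-control reports and the method bibliography.

Reports are markdown documents with PNG heatmaps of the design matrix and
its correlation structure, plus per-contrast thresholded-map summaries
(suprathreshold voxel counts and peaks) — the desk-scale counterpart of an
interactive model-inspection UI.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .design import DesignMatrix
from .ibma import Z_CRIT_P001, threshold_z

__all__ = ["make_report", "make_bibliography", "CITATIONS"]

CITATIONS: dict[str, tuple[str, ...]] = {
    "extract": (
        "McFee et al. (2015). librosa: audio and music signal analysis in Python.",
        "Brysbaert & New (2009). Moving beyond Kucera and Francis: SUBTLEX-US word frequency norms.",
        "Biemann (2006). Chinese Whispers: an efficient graph clustering algorithm.",
        "Schroff, Kalenichenko & Philbin (2015). FaceNet: a unified embedding for face recognition.",
    ),
    "design": (
        "Friston et al. (1998). Event-related fMRI: characterizing differential responses.",
    ),
    "glm": (
        "Friston et al. (1998). Event-related fMRI: characterizing differential responses.",
        "Worsley & Friston (1995). Analysis of fMRI time-series revisited - again.",
    ),
    "meta": (
        "DerSimonian & Laird (1986). Meta-analysis in clinical trials.",
        "Kacker (2004). Combining information from interlaboratory evaluations using a random effects model.",
    ),
}


def make_bibliography(stages: list[str] | dict) -> list[str]:
    """Deduplicated citation list for the methods used in executed stages.

    Accepts either a list of stage names or a manifest-like object with a
    ``stages`` mapping.
    """
    if hasattr(stages, "stages"):
        stages = list(stages.stages)
    elif isinstance(stages, dict):
        stages = list(stages)
    seen: list[str] = []
    for stage in stages:
        for cite in CITATIONS.get(stage, ()):
            if cite not in seen:
                seen.append(cite)
    return seen


def _heatmap(ax, data: np.ndarray, title: str, labels: list[str] | None = None) -> None:
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax.set_title(title)
    if labels is not None and len(labels) <= 40:
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
    plt.colorbar(im, ax=ax, fraction=0.046)


def make_report(
    dm: DesignMatrix,
    correlation: pd.DataFrame,
    maps: dict[str, np.ndarray] | None = None,
    out_dir: str | Path = "report",
    z_crit: float = Z_CRIT_P001,
) -> Path:
    """Write a static QC report: design/correlation heatmaps + map summaries.

    Returns the path of the generated ``report.md``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    x = dm.matrix()
    sd = x.std(axis=0)
    x_norm = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    fig, axes = plt.subplots(1, 2, figsize=(12, 5))
    _heatmap(axes[0], x_norm, "Design matrix (columns standardized)", dm.columns)
    _heatmap(axes[1], correlation.to_numpy(), "Predictor correlation (Pearson r)", dm.columns)
    fig.tight_layout()
    fig.savefig(out / "design_report.png", dpi=110)
    plt.close(fig)

    lines = [
        "# Model quality-control report",
        "",
        f"- volumes: {dm.n_volumes}, TR: {dm.tr} s",
        f"- columns ({len(dm.columns)}):",
    ]
    for name in dm.columns:
        lines.append(f"  - `{name}` ({dm.column_roles[name]})")
    lines += ["", "![design and correlation heatmaps](design_report.png)", ""]

    if maps:
        lines += ["## Statistical map summaries", ""]
        lines.append("| contrast | suprathreshold voxels | peak |")
        lines.append("|---|---|---|")
        for name, z in maps.items():
            _, supra = threshold_z(np.asarray(z), z_crit=z_crit)
            peak = float(np.asarray(z).flat[np.argmax(np.abs(z))]) if np.asarray(z).size else 0.0
            lines.append(f"| {name} | {int(supra.sum())} | {peak:.3f} |")
        lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
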