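"""Static export of the phenotype map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .phenomap import PhenotypeMap

__all__ = ["plot_map"]

# marker shapes vary with cluster so the plot stays readable in gray scale
_MARKERS = ("o", "s", "^", "D", "v", "P", "X", "*")


def plot_map(pmap: PhenotypeMap, path: str | Path, title: str | None = None) -> Path:
    """Scatter the 2-D phenotype coordinates with labels, colored by cluster."""
    path = Path(path)
    coords = pmap.coords
    names = list(pmap.phenotype_names) or [
        f"pheno_{k + 1}" for k in range(coords.shape[0])
    ]
    labels = (
        pmap.cluster_labels
        if pmap.cluster_labels is not None
        else [1] * coords.shape[0]
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10")
    for k, (x, y) in enumerate(coords[:, :2]):
        c = int(labels[k])
        ax.scatter(
            x, y,
            color=cmap((c - 1) % 10),
            marker=_MARKERS[(c - 1) % len(_MARKERS)],
            s=60, zorder=3,
        )
        ax.annotate(names[k], (x, y), textcoords="offset points", xytext=(5, 5))
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if title:
        ax.set_title(title)
    ax.axhline(0, color="0.85", lw=0.8, zorder=1)
    ax.axvline(0, color="0.85", lw=0.8, zorder=1)
    fig.tight_layout()
    if path.suffix.lower() == ".pdf":
        # drop the creation date so identical runs produce identical bytes
        fig.savefig(path, metadata={"CreationDate": None})
    else:
        fig.savefig(path)
    plt.close(fig)
    return path
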