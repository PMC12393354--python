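"""Cosmetic rendering of similarity matrices as heatmap images.

A thin optional layer over the CSV matrices: darker cells mean higher
similarity.  Images are never part of the reproducibility contract.
"""

from __future__ import annotations

from .metrics import SimilarityMatrix

__all__ = ["save_heatmap"]


def save_heatmap(M: SimilarityMatrix, path, title: str | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(M.scores, cmap="Greys", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(M.subject_ids)))
    ax.set_yticks(range(len(M.subject_ids)))
    ax.set_xticklabels(M.subject_ids, rotation=90, fontsize=7)
    ax.set_yticklabels(M.subject_ids, fontsize=7)
    ax.set_title(title or f"{M.method} BA (theta = {M.theta:g} mm)")
    fig.colorbar(im, ax=ax, label="bundle adjacency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
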