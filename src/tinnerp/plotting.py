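"""Minimal topographic display of per-channel values (non-core)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .montage import MONTAGE_POSITIONS


def topomap(values, channels, path: str | Path, title: str = "",
            cmap: str = "RdBu_r"):
    """Scatter per-channel values on a schematic head and save to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    xs = [MONTAGE_POSITIONS[ch][0] for ch in channels]
    ys = [MONTAGE_POSITIONS[ch][1] for ch in channels]
    vmax = max(np.max(np.abs(values)), 1e-12)
    fig, ax = plt.subplots(figsize=(4, 4))
    head = plt.Circle((0, 0), 1.0, fill=False, lw=1.5)
    ax.add_patch(head)
    ax.plot([0, -0.08, 0.08, 0], [1.0, 1.08, 1.08, 1.0], "k-", lw=1.5)  # nose
    sc = ax.scatter(xs, ys, c=values, s=320, cmap=cmap, vmin=-vmax, vmax=vmax,
                    edgecolors="k")
    for x, y, ch in zip(xs, ys, channels):
        ax.annotate(ch, (x, y), ha="center", va="center", fontsize=6)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
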