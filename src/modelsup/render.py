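"""Minimal static-image renderer for superpositions.

Draws the superposed CA traces as orthographically projected polylines on a
fixed 800x800 canvas, coloured by the shared colour map (or flat per-model
colours as a fallback), with a painter's-order depth sort so nearer segments
overdraw farther ones.  This is deliberately simple — it exists so a
superposition can be inspected without any molecular viewer.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection
import numpy as np

from .colouring import ColourMap
from .struct_io import ModelChain
from .superpose import RigidTransform, rotate_view

logger = logging.getLogger(__name__)

__all__ = ["render_png"]

CANVAS_PX = 800
_FLAT_PALETTE = ["#4c72b0", "#dd8452", "#55a868", "#c44e52", "#8172b3",
                 "#937860", "#da8bc3", "#8c8c8c", "#ccb974", "#64b5cd"]
_CHAIN_BREAK = 4  # sequence gap beyond which the trace is not connected


def render_png(models: Sequence[ModelChain],
               transforms: Sequence[RigidTransform],
               colourmap: ColourMap | None,
               view_angles_deg: tuple[float, float, float],
               path: str | Path) -> None:
    """Render the superposed ensemble to ``path`` as a PNG.

    Best-effort: an empty or partial colour map falls back to flat
    per-model colours; problems are logged rather than raised.
    """
    coords = {m.model_id: tr.apply(m.ca_coords())
              for m, tr in zip(models, transforms)}
    coords = rotate_view(coords, view_angles_deg)

    segments: list[tuple[float, np.ndarray, np.ndarray, tuple]] = []
    use_map = colourmap is not None and len(colourmap) > 0
    if not use_map and colourmap is not None:
        logger.info("empty colour map; falling back to per-model colours")
    for mi, model in enumerate(models):
        xyz = coords[model.model_id]
        flat = matplotlib.colors.to_rgb(_FLAT_PALETTE[mi % len(_FLAT_PALETTE)])
        for i in range(len(model.residues) - 1):
            r0, r1 = model.residues[i], model.residues[i + 1]
            if r1.seq_pos - r0.seq_pos > _CHAIN_BREAK:
                continue
            if use_map and r0.key in colourmap:
                r, g, b = colourmap[r0.key].rgb
                colour = (r / 255, g / 255, b / 255)
            else:
                colour = flat
            depth = float(xyz[i, 2] + xyz[i + 1, 2]) / 2
            segments.append((depth, xyz[i, :2], xyz[i + 1, :2], colour))

    # painter's order: draw far (low z) first so near segments overdraw
    segments.sort(key=lambda s: s[0])

    fig, ax = plt.subplots(figsize=(CANVAS_PX / 100, CANVAS_PX / 100), dpi=100)
    if segments:
        lc = LineCollection([(tuple(a), tuple(b)) for _, a, b, _ in segments],
                            colors=[c for _, _, _, c in segments],
                            linewidths=2.5, capstyle="round")
        ax.add_collection(lc)
        allpts = np.vstack([np.vstack((a, b)) for _, a, b, _ in segments])
        lo = allpts.min(axis=0)
        hi = allpts.max(axis=0)
        span = max(float((hi - lo).max()), 1.0) * 0.55
        centre = (lo + hi) / 2
        ax.set_xlim(centre[0] - span, centre[0] + span)
        ax.set_ylim(centre[1] - span, centre[1] + span)
    else:
        logger.warning("nothing to render")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(Path(path), format="png")
    plt.close(fig)
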