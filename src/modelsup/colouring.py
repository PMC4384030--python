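"""Conservation-weighted rainbow colouring shared across all models.

Every modelled sequence position gets exactly one colour, used to paint that
residue in every model, so equivalent residues are visually identical across
the superposition.  The gradient runs blue (N-terminus) through to red
(C-terminus), but its rate of change is driven by the per-column consistency
scores: divergent stretches consume little of the spectrum, reserving most
of the colour range for the well-conserved regions.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

from .align import MultiModelAlignment
from .divergence import PositionScore

__all__ = ["ColourEntry", "ColourMap", "gradient_params", "t_to_rgb",
           "build_colourmap", "DEFAULT_WEIGHT_FLOOR"]

DEFAULT_WEIGHT_FLOOR = 0.05   # weight for singleton / unscored positions


@dataclass(frozen=True)
class ColourEntry:
    t: float                       # gradient parameter in [0, 1]
    rgb: tuple[int, int, int]      # 0-255


@dataclass(frozen=True)
class ColourMap:
    """Ordered map (seq_pos, icode) -> gradient parameter and RGB colour."""

    entries: dict[tuple[int, str], ColourEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: tuple[int, str]) -> ColourEntry:
        return self.entries[key]

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.entries

    def items(self):
        return self.entries.items()

    def to_tsv(self, path: str | Path) -> None:
        rows = ["seq_pos\ticode\tt\tr\tg\tb"]
        for (pos, icode), e in self.entries.items():
            rows.append(f"{pos}\t{icode.strip() or '-'}\t{e.t:.6f}\t"
                        f"{e.rgb[0]}\t{e.rgb[1]}\t{e.rgb[2]}")
        Path(path).write_text("\n".join(rows) + "\n")


def gradient_params(aln: MultiModelAlignment, scores: PositionScore,
                    w_floor: float = DEFAULT_WEIGHT_FLOOR
                    ) -> dict[tuple[int, str], float]:
    """Gradient parameter t per modelled position, weighted by conservation.

    Scoreable columns weigh in with their consistency score; singleton or
    otherwise unscored columns get the floor weight ``w_floor`` (treated as
    divergent).  t is the cumulative normalised weight: t = 0 at the first
    modelled position, 1 at the last, and monotone non-decreasing, with
    low-weight stretches advancing t only slowly.
    """
    if not 0 < w_floor <= 1:
        raise ValueError("w_floor must be in (0, 1]")
    n = len(aln.columns)
    if n < 2:
        raise ValueError("gradient needs at least 2 modelled positions")
    weights = [scores.scores.get(i, w_floor) for i in range(n)]
    total = sum(weights[1:])
    t_map: dict[tuple[int, str], float] = {}
    acc = 0.0
    for i, col in enumerate(aln.columns):
        if i > 0:
            acc += weights[i]
        t_map[col.key] = acc / total
    return t_map


def t_to_rgb(t: float) -> tuple[int, int, int]:
    """Rainbow palette: hue 240° (blue) at t=0 linearly to 0° (red) at t=1,
    full saturation and value."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    hue = 240.0 * (1.0 - t) / 360.0
    r, g, b = colorsys.hsv_to_rgb(hue, 1.0, 1.0)
    return (round(r * 255), round(g * 255), round(b * 255))


def build_colourmap(aln: MultiModelAlignment, scores: PositionScore,
                    w_floor: float = DEFAULT_WEIGHT_FLOOR) -> ColourMap:
    """Full colour map over every position covered by at least one model."""
    t_map = gradient_params(aln, scores, w_floor=w_floor)
    return ColourMap(entries={key: ColourEntry(t, t_to_rgb(t))
                              for key, t in t_map.items()})
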