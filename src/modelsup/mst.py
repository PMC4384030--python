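"""Per-alignment-column minimal spanning trees ("alignment lines").

Drawing every pairwise connection between equivalent residues clutters a
superposition; instead each alignment column is represented by the minimal
spanning tree over its members' superposed CA coordinates, which connects
all equivalents with the fewest, shortest lines.  Lines are emitted for
trimmed-out columns too — long lines on divergent columns are exactly the
signal that reveals where models disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import dist

import numpy as np

from .align import MultiModelAlignment
from .superpose import SuperpositionResult

__all__ = ["MSTEdge", "ColumnMST", "column_mst", "alignment_lines"]


@dataclass(frozen=True)
class MSTEdge:
    model_id_a: str
    model_id_b: str
    coord_a: tuple[float, float, float]
    coord_b: tuple[float, float, float]
    length: float


@dataclass(frozen=True)
class ColumnMST:
    column_index: int
    seq_pos: int
    icode: str
    edges: tuple[MSTEdge, ...]

    @property
    def total_length(self) -> float:
        return sum(e.length for e in self.edges)


def column_mst(points: dict[str, np.ndarray], *,
               column_index: int = -1, seq_pos: int = 0,
               icode: str = " ") -> ColumnMST:
    """Minimal spanning tree over one column's points (Prim's algorithm on
    the complete Euclidean graph).

    Deterministic: growth starts from the lexicographically smallest model
    id and equal-weight candidate edges are taken in lexicographic
    (model_id_a, model_id_b) order.
    """
    if len(points) < 2:
        raise ValueError("MST needs at least 2 points")
    ids = sorted(points)
    coords = {m: tuple(float(v) for v in np.asarray(points[m], dtype=float))
              for m in ids}
    in_tree = {ids[0]}
    edges: list[MSTEdge] = []
    while len(in_tree) < len(ids):
        best: tuple[float, str, str] | None = None
        for a in sorted(in_tree):
            for b in ids:
                if b in in_tree:
                    continue
                cand = (dist(coords[a], coords[b]), *sorted((a, b)))
                if best is None or cand < best:
                    best = cand
        length, a, b = best  # type: ignore[misc]
        edges.append(MSTEdge(a, b, coords[a], coords[b], length))
        in_tree.update((a, b))
    return ColumnMST(column_index=column_index, seq_pos=seq_pos,
                     icode=icode, edges=tuple(edges))


def alignment_lines(result: SuperpositionResult,
                    aln: MultiModelAlignment,
                    *, only_included: bool = False) -> list[ColumnMST]:
    """One MST per column with >= 2 members, on superposed CA coordinates,
    in sequence order.  By default all such columns are drawn, including
    trimmed-out ones; ``only_included`` restricts to the fitted set."""
    out: list[ColumnMST] = []
    for i, col in enumerate(aln.columns):
        if col.n_members < 2:
            continue
        if only_included and i not in result.included:
            continue
        points = {m: result.transforms[m].apply(res.ca)
                  for m, res in col.members.items()}
        out.append(column_mst(points, column_index=i,
                              seq_pos=col.seq_pos, icode=col.icode))
    return out
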