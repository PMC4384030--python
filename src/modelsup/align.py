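"""Residue-number-based alignment of overlapping models.

All models describe (regions of) the same source sequence, so residues are
equivalent exactly when they carry the same author residue number.  No
sequence or structure alignment is attempted: numbering by source position is
simpler, faster, and is the meaning of the superposition.  Mismatched
numbering is the caller's responsibility; suspiciously low overlap is
surfaced as a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .struct_io import ModelChain, Residue

logger = logging.getLogger(__name__)

__all__ = ["AlignmentColumn", "MultiModelAlignment", "build_alignment",
           "shared_columns"]


@dataclass(frozen=True)
class AlignmentColumn:
    """One sequence position and the residues modelling it, per model."""

    seq_pos: int
    icode: str
    members: dict[str, Residue]

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_pos, self.icode)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MultiModelAlignment:
    """Columns over the union of modelled positions, in sequence order."""

    columns: tuple[AlignmentColumn, ...]
    model_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)

    def column_keys(self) -> list[tuple[int, str]]:
        return [c.key for c in self.columns]

    def to_tsv(self, path: str | Path) -> None:
        """Debug dump: one row per column with its member model ids."""
        rows = ["seq_pos\ticode\tmembers"]
        for col in self.columns:
            rows.append(f"{col.seq_pos}\t{col.icode.strip() or '-'}\t"
                        + ",".join(sorted(col.members)))
        Path(path).write_text("\n".join(rows) + "\n")


def build_alignment(models: Sequence[ModelChain]) -> MultiModelAlignment:
    """Align models by residue number.

    The column universe is the union of (seq_pos, icode) keys over all
    models; each column's members are exactly the models containing that
    position.  Every residue of every model lands in exactly one column.
    """
    if not models:
        raise ValueError("at least one model required")
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate model ids: {ids}")
    universe: dict[tuple[int, str], dict[str, Residue]] = {}
    for model in models:
        for res in model:
            universe.setdefault(res.key, {})[model.model_id] = res
    columns = tuple(
        AlignmentColumn(seq_pos=key[0], icode=key[1], members=universe[key])
        for key in sorted(universe))
    if len(models) >= 2:
        n_shared = sum(1 for c in columns if c.n_members >= 2)
        if n_shared < 3:
            logger.warning(
                "only %d column(s) shared by >=2 models — check that the "
                "models use consistent residue numbering", n_shared)
    return MultiModelAlignment(columns=columns, model_ids=tuple(ids))


def shared_columns(aln: MultiModelAlignment, min_members: int) -> list[int]:
    """Indices of columns with at least ``min_members`` member models."""
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    return [i for i, c in enumerate(aln.columns) if c.n_members >= min_members]
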