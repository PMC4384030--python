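"""Read single-chain PDB models; write superposed coordinates and PyMOL scripts.

Predicted models of one protein are exchanged as plain PDB files whose author
residue numbers carry the source-sequence position.  Parsing therefore keeps
the author numbering verbatim: the (residue number, insertion code) pair is
the identity that the alignment, scoring and colouring stages key on.

Only ATOM records are read (waters and ligands play no role in model
comparison), alternate locations are collapsed to the highest-occupancy copy,
and residues without an alpha-carbon are dropped with a warning, since every
downstream computation is CA-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import gemmi
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .colouring import ColourMap
    from .mst import ColumnMST
    from .superpose import RigidTransform

logger = logging.getLogger(__name__)

__all__ = ["AtomRecord", "Residue", "ModelChain", "read_model",
           "write_superposed", "write_model", "write_pml"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a residue (name, element symbol, position in Å)."""

    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass(frozen=True)
class Residue:
    """A modelled residue keyed by its source-sequence position.

    ``seq_pos`` is the author residue number; ``icode`` the insertion code
    (space when absent).  ``ca`` is the alpha-carbon coordinate used for
    alignment, scoring and line drawing.
    """

    seq_pos: int
    icode: str
    name: str
    ca: np.ndarray
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float))
        if self.ca.shape != (3,):
            raise ValueError("CA coordinate must be a 3-vector")
        if not self.atoms:
            raise ValueError("residue must carry at least one atom")

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_pos, self.icode)


@dataclass
class ModelChain:
    """One predicted model: a single chain of residues, ordered by sequence
    position then insertion code, with no duplicate positions."""

    model_id: str
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        self.residues = tuple(self.residues)
        if not self.residues:
            raise ValueError(f"model {self.model_id!r}: no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"model {self.model_id!r}: duplicate (seq_pos, icode)")
        if keys != sorted(keys):
            raise ValueError(f"model {self.model_id!r}: residues not ordered by "
                             "(seq_pos, icode)")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def residue_keys(self) -> list[tuple[int, str]]:
        return [r.key for r in self.residues]

    def by_key(self) -> dict[tuple[int, str], Residue]:
        return {r.key: r for r in self.residues}

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of CA coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse altlocs: per atom name keep the highest occupancy, ties going
    to the copy that appears first in the file."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # preserve original file order of the surviving atoms
    picked = set(id(a) for a in chosen.values())
    return [a for a in res if id(a) in picked]


def read_model(path: str | Path, chain: str | None = None, *,
               model_id: str | None = None) -> ModelChain:
    """Parse a PDB file into a :class:`ModelChain`.

    Parameters
    ----------
    path : path to a PDB-format text file.
    chain : chain identifier to select; may be omitted only when the file
        contains exactly one chain.
    model_id : label for the returned model; defaults to the file stem.

    Raises
    ------
    ValueError
        If the file has multiple chains and no selector was given, the chain
        is absent, or no residue with a CA atom survives parsing.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate model in file")
    gm = st[0]
    chain_names = [c.name for c in gm]
    if not chain_names:
        raise ValueError(f"{path}: no coordinate records in file")
    if chain is None:
        if len(chain_names) > 1:
            raise ValueError(
                f"{path}: multiple chains {chain_names}; pass an explicit chain")
        gchain = gm[0]
    else:
        matches = [c for c in gm if c.name == chain]
        if not matches:
            raise ValueError(f"{path}: chain {chain!r} not found "
                             f"(available: {chain_names})")
        gchain = matches[0]

    residues: list[Residue] = []
    for gres in gchain:
        if gres.het_flag != "A":  # HETATM (waters, ligands) ignored
            continue
        atoms = _resolve_altlocs(gres)
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            logger.warning("%s: residue %s %d%s has no CA atom; dropped",
                           path.name, gres.name, gres.seqid.num,
                           gres.seqid.icode.strip())
            continue
        icode = gres.seqid.icode if gres.seqid.icode.strip() else " "
        residues.append(Residue(
            seq_pos=gres.seqid.num,
            icode=icode,
            name=gres.name,
            ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
            atoms=tuple(AtomRecord(a.name, a.element.name,
                                   (a.pos.x, a.pos.y, a.pos.z),
                                   a.occ, a.b_iso) for a in atoms),
        ))
    if not residues:
        raise ValueError(f"{path}: no parseable residue with a CA atom")
    residues.sort(key=lambda r: r.key)
    return ModelChain(model_id=model_id or path.stem,
                      chain_id=gchain.name, residues=tuple(residues))


def _to_gemmi_model(model: ModelChain, transform: "RigidTransform",
                    num: int) -> gemmi.Model:
    gm = gemmi.Model(num)
    ch = gemmi.Chain(model.chain_id)
    for res in model.residues:
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.seq_pos, res.icode)
        gr.het_flag = "A"
        for at in res.atoms:
            ga = gemmi.Atom()
            ga.name = at.name
            ga.element = gemmi.Element(at.element)
            x, y, z = transform.apply(np.asarray(at.xyz, dtype=float))
            ga.pos = gemmi.Position(x, y, z)
            ga.occ = at.occupancy
            ga.b_iso = at.b_factor
            gr.add_atom(ga)
        ch.add_residue(gr)
    gm.add_chain(ch)
    return gm


def write_superposed(models: Sequence[ModelChain],
                     transforms: Sequence["RigidTransform"],
                     path: str | Path) -> None:
    """Write all models, each under its rigid transform, as one multi-MODEL
    PDB file (wwPDB v3.3 fixed-width; MODEL/ENDMDL per input model, input
    order, atom order and residue numbering preserved)."""
    if len(models) != len(transforms):
        raise ValueError(f"{len(models)} models but {len(transforms)} transforms")
    st = gemmi.Structure()
    for i, (model, tr) in enumerate(zip(models, transforms), start=1):
        st.add_model(_to_gemmi_model(model, tr, i))
    Path(path).write_text(st.make_pdb_string())


def write_model(model: ModelChain, path: str | Path,
                transform: "RigidTransform | None" = None) -> None:
    """Write a single model as a plain (single-MODEL) PDB file, optionally
    under a rigid transform."""
    from .superpose import RigidTransform
    tr = transform if transform is not None else RigidTransform.identity()
    st = gemmi.Structure()
    st.add_model(_to_gemmi_model(model, tr, 1))
    Path(path).write_text(st.make_pdb_string())


def _f(x: float) -> str:
    """Fixed 3-decimal float formatting; avoids '-0.000'."""
    v = float(x)
    if abs(v) < 5e-4:
        v = 0.0
    return f"{v:.3f}"


def write_pml(models: Sequence[ModelChain],
              transforms: Sequence["RigidTransform"],
              colourmap: "ColourMap | None",
              mst_edges: "Iterable[ColumnMST] | None",
              path: str | Path,
              *, line_width: float = 1.0) -> None:
    """Write a PyMOL ``.pml`` script presenting the superposition.

    The script loads each model from a sibling file ``<model_id>.pdb`` as an
    object named by its model id, colours every residue by the shared colour
    map (same colour for the same sequence position in every model), and
    emits the per-column minimal-spanning-tree segments as black CGO line
    primitives collected into a single object literally named ``alignment``,
    so PyMOL's object panel exposes an 'alignment' toggle button.

    Output is byte-stable for identical inputs: no timestamps, floats at
    three decimals.
    """
    if not models:
        raise ValueError("empty model list")
    if len(models) != len(transforms):
        raise ValueError(f"{len(models)} models but {len(transforms)} transforms")
    lines: list[str] = ["# modelsup superposition script", "bg_color white"]
    for model in models:
        lines.append(f"load {model.model_id}.pdb, {model.model_id}")
    lines.append("hide everything")
    lines.append("show cartoon")
    if colourmap is not None and len(colourmap) > 0:
        for (seq_pos, icode), entry in colourmap.items():
            r, g, b = entry.rgb
            cname = f"msup_{seq_pos}{icode.strip()}"
            resi = f"{seq_pos}{icode.strip()}"
            lines.append(f"set_color {cname}, "
                         f"[{_f(r / 255)}, {_f(g / 255)}, {_f(b / 255)}]")
            lines.append(f"color {cname}, resi {resi}")
    else:
        # fall back to one flat colour per model
        palette = ["skyblue", "salmon", "palegreen", "wheat", "violet",
                   "grey70", "slate", "olive", "deepteal", "hotpink"]
        for i, model in enumerate(models):
            lines.append(f"color {palette[i % len(palette)]}, {model.model_id}")
    if mst_edges is not None:
        msts = list(mst_edges)
        if any(m.edges for m in msts):
            lines.append("python")
            lines.append("from pymol.cgo import LINEWIDTH, COLOR, BEGIN, "
                         "LINES, VERTEX, END")
            lines.append(f"aln_obj = [LINEWIDTH, {_f(line_width)}, "
                         "COLOR, 0.000, 0.000, 0.000, BEGIN, LINES]")
            for mst in msts:
                for edge in mst.edges:
                    ax, ay, az = edge.coord_a
                    bx, by, bz = edge.coord_b
                    lines.append(
                        f"aln_obj += [VERTEX, {_f(ax)}, {_f(ay)}, {_f(az)}, "
                        f"VERTEX, {_f(bx)}, {_f(by)}, {_f(bz)}]")
            lines.append("aln_obj += [END]")
            lines.append('cmd.load_cgo(aln_obj, "alignment")')
            lines.append("python end")
    lines.append("zoom")
    Path(path).write_text("\n".join(lines) + "\n")
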