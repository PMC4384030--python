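"""Shared fixtures: tiny hand-built models and the core+tail ensemble."""

from __future__ import annotations

import numpy as np
import pytest

from modelsup.align import build_alignment
from modelsup.fixtures import EnsembleSpec, make_ensemble
from modelsup.struct_io import AtomRecord, ModelChain, Residue


def make_chain(model_id: str, coords: np.ndarray,
               start_pos: int = 1, chain_id: str = "A") -> ModelChain:
    """Build a CA-only ModelChain from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, ca in enumerate(coords):
        residues.append(Residue(
            seq_pos=start_pos + i, icode=" ", name="ALA", ca=ca,
            atoms=(AtomRecord("CA", "C", tuple(ca)),)))
    return ModelChain(model_id=model_id, chain_id=chain_id,
                      residues=tuple(residues))


@pytest.fixture
def helix_coords():
    k = np.arange(1, 13)
    th = np.deg2rad(100 * k)
    return np.column_stack([2.3 * np.cos(th), 2.3 * np.sin(th), 1.5 * k])


@pytest.fixture
def two_identical_models(helix_coords):
    return [make_chain("m1", helix_coords), make_chain("m2", helix_coords)]


@pytest.fixture
def core_tail_ensemble():
    """Three models: 30-residue agreeing core, 10-residue tail displaced
    8 Å in per-model random directions (the canonical trimming fixture)."""
    spec = EnsembleSpec(n_models=3, core_len=30, tail_len=10,
                        core_noise_sigma=0.2, tail_displacement=8.0, seed=11)
    models, labels = make_ensemble(spec)
    return models, labels


@pytest.fixture
def core_tail_alignment(core_tail_ensemble):
    models, labels = core_tail_ensemble
    return models, labels, build_alignment(models)
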