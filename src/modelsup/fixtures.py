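"""Deterministic synthetic data: model ensembles and paired classifications.

Everything downstream is testable without any database download.  Two
generators are provided:

* :func:`make_ensemble` emulates sets of predicted models of one sequence —
  a conserved helical core that all models agree on (up to coordinate noise
  and an arbitrary rigid pre-transform) plus an optional divergent tail that
  each model places in its own random direction, and per-model coverage
  windows that create a patchwork of overlapping regions.  Ground-truth
  core/tail labels are returned alongside.

* :func:`make_classifications` builds paired toy domain-classification
  tables whose segment layouts provably realise a requested consensus tier
  per superfamily pair (bronze / silver / gold / none), with the expected
  tier returned for each constructed pair.

All randomness flows from an explicit integer seed; the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .classmap import ClassifiedDomain, ConsensusTier, Segment
from .struct_io import AtomRecord, ModelChain, Residue

__all__ = ["EnsembleSpec", "make_ensemble", "make_classifications"]

# idealized alpha-helix CA-trace geometry
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_RADIUS = 2.3     # Å
HELIX_TWIST_DEG = 100  # degrees per residue

# minimal backbone fabricated around each CA (local offsets, Å)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.40, 0.00]),
    "C": np.array([1.20, 0.40, 0.00]),
    "O": np.array([1.60, 1.50, 0.00]),
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Conditions for one synthetic model ensemble.

    ``coverage_offsets`` gives per-model (start, end) sequence windows
    (1-based inclusive); ``None`` means full coverage for every model.
    """

    n_models: int = 3
    core_len: int = 30
    tail_len: int = 10
    core_noise_sigma: float = 0.2      # Å, isotropic CA noise
    tail_displacement: float = 8.0     # Å, rigid per-model tail shift
    coverage_offsets: tuple[tuple[int, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")
        if self.core_len < 10:
            raise ValueError("core_len must be >= 10")
        if self.tail_len < 0:
            raise ValueError("tail_len must be >= 0")
        if self.core_noise_sigma < 0 or self.tail_displacement < 0:
            raise ValueError("noise and displacement must be non-negative")
        if self.coverage_offsets is not None:
            if len(self.coverage_offsets) != self.n_models:
                raise ValueError("one coverage window per model required")
            total = self.core_len + self.tail_len
            for start, end in self.coverage_offsets:
                if not (1 <= start <= end <= total):
                    raise ValueError(f"invalid coverage window ({start}, {end})")

    @property
    def total_len(self) -> int:
        return self.core_len + self.tail_len


def _helix_trace(n: int) -> np.ndarray:
    k = np.arange(1, n + 1)
    theta = np.deg2rad(HELIX_TWIST_DEG * k)
    return np.column_stack([HELIX_RADIUS * np.cos(theta),
                            HELIX_RADIUS * np.sin(theta),
                            HELIX_RISE * k])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_ensemble(spec: EnsembleSpec
                  ) -> tuple[list[ModelChain], dict[int, str]]:
    """Generate the ensemble described by ``spec``.

    Returns the models (ids ``model1`` ...) and ground-truth labels mapping
    each sequence position to ``"core"`` or ``"tail"``.
    """
    trace = _helix_trace(spec.total_len)
    labels = {pos: ("core" if pos <= spec.core_len else "tail")
              for pos in range(1, spec.total_len + 1)}
    models: list[ModelChain] = []
    for m in range(spec.n_models):
        rng = np.random.default_rng([spec.seed, m])
        coords = trace + rng.normal(scale=spec.core_noise_sigma,
                                    size=trace.shape)
        if spec.tail_len and spec.tail_displacement:
            coords[spec.core_len:] += spec.tail_displacement * _random_unit(rng)
        # arbitrary rigid pre-transform: models arrive in unrelated frames
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        coords = coords @ R.T + t
        if spec.coverage_offsets is not None:
            start, end = spec.coverage_offsets[m]
        else:
            start, end = 1, spec.total_len
        residues = []
        for pos in range(start, end + 1):
            ca = coords[pos - 1]
            atoms = [AtomRecord("N", "N", tuple(ca + _BACKBONE_OFFSETS["N"])),
                     AtomRecord("CA", "C", tuple(ca)),
                     AtomRecord("C", "C", tuple(ca + _BACKBONE_OFFSETS["C"])),
                     AtomRecord("O", "O", tuple(ca + _BACKBONE_OFFSETS["O"]))]
            residues.append(Residue(seq_pos=pos, icode=" ", name="ALA",
                                    ca=ca.copy(), atoms=tuple(atoms)))
        models.append(ModelChain(model_id=f"model{m + 1}", chain_id="A",
                                 residues=tuple(residues)))
    return models, labels


def _gold_pair(k: int, rng: np.random.Generator
               ) -> tuple[list[ClassifiedDomain], list[ClassifiedDomain]]:
    n_dom = int(rng.integers(3, 6))
    a, b = [], []
    for j in range(n_dom):
        length = int(rng.integers(60, 121))
        struct = f"p{k}g{j}"
        trim = int(rng.integers(0, length // 10 + 1))  # keeps frac >= 0.9
        a.append(ClassifiedDomain(f"a{k}_{j}", f"sfA{k}",
                                  (Segment(struct, "A", 1, length),)))
        b.append(ClassifiedDomain(f"b{k}_{j}", f"sfB{k}",
                                  (Segment(struct, "A", 1 + trim, length),)))
    return a, b


def _silver_pair(k: int, rng: np.random.Generator
                 ) -> tuple[list[ClassifiedDomain], list[ClassifiedDomain]]:
    # fractions {1, 1, 1, 0.5} on side A: mean 0.875 >= 0.8, min 0.5 < 0.8
    length = int(rng.integers(60, 121)) * 2  # even so half is exact
    a, b = [], []
    for j in range(4):
        struct = f"p{k}s{j}"
        a.append(ClassifiedDomain(f"a{k}_{j}", f"sfA{k}",
                                  (Segment(struct, "A", 1, length),)))
        end = length // 2 if j == 3 else length
        b.append(ClassifiedDomain(f"b{k}_{j}", f"sfB{k}",
                                  (Segment(struct, "A", 1, end),)))
    return a, b


def _bronze_pair(k: int, rng: np.random.Generator
                 ) -> tuple[list[ClassifiedDomain], list[ClassifiedDomain]]:
    # 3 of 5 classifiable A domains map to sfB -> domain-map fraction 0.6;
    # the two unmapped A domains sit on chains carrying only a helper B
    # superfamily (zero overlap), so they count as classifiable
    length = int(rng.integers(60, 121))
    a, b = [], []
    for j in range(5):
        struct = f"p{k}b{j}"
        a.append(ClassifiedDomain(f"a{k}_{j}", f"sfA{k}",
                                  (Segment(struct, "A", 1, length),)))
        if j < 3:
            b.append(ClassifiedDomain(f"b{k}_{j}", f"sfB{k}",
                                      (Segment(struct, "A", 1, length),)))
        else:
            b.append(ClassifiedDomain(f"b{k}_{j}", f"sfBhelper{k}",
                                      (Segment(struct, "A", length + 50,
                                               length + 100),)))
    return a, b


def _none_pair(k: int, rng: np.random.Generator
               ) -> tuple[list[ClassifiedDomain], list[ClassifiedDomain]]:
    # two B superfamilies overlap the A domain by exactly the same residue
    # count with equal tie-breaks: the best partner of sfA is ambiguous, so
    # no consensus forms
    ov = int(rng.integers(30, 61))
    struct = f"p{k}n0"
    a = [ClassifiedDomain(f"a{k}_0", f"sfA{k}",
                          (Segment(struct, "A", 1, 3 * ov),))]
    b = [ClassifiedDomain(f"b{k}_0", f"sfB{k}",
                          (Segment(struct, "A", 1, ov),)),
         ClassifiedDomain(f"b{k}_1", f"sfBalt{k}",
                          (Segment(struct, "A", 2 * ov + 1, 3 * ov),))]
    return a, b


_BUILDERS = {
    ConsensusTier.GOLD: _gold_pair,
    ConsensusTier.SILVER: _silver_pair,
    ConsensusTier.BRONZE: _bronze_pair,
    ConsensusTier.NONE: _none_pair,
}


def make_classifications(target_tiers: list[ConsensusTier | str],
                         seed: int = 0,
                         n_sf_a: int | None = None,
                         n_sf_b: int | None = None
                         ) -> tuple[list[ClassifiedDomain],
                                    list[ClassifiedDomain],
                                    dict[tuple[str, str], ConsensusTier]]:
    """Build two toy classifications realising the requested tiers.

    One (sfA<k>, sfB<k>) pair is constructed per entry of ``target_tiers``,
    each on its own structures so pairs cannot interfere.  ``n_sf_a`` /
    ``n_sf_b`` optionally request a minimum superfamily count per side;
    extra superfamilies are isolated (no counterpart in the other
    classification).  Returns (classification_a, classification_b,
    expected tier per constructed pair).
    """
    tiers = [ConsensusTier[t] if isinstance(t, str) else ConsensusTier(t)
             for t in target_tiers]
    if not tiers:
        raise ValueError("at least one target tier required")
    rng = np.random.default_rng([seed, 0xC1A55])
    class_a: list[ClassifiedDomain] = []
    class_b: list[ClassifiedDomain] = []
    expected: dict[tuple[str, str], ConsensusTier] = {}
    used_a = used_b = 0
    for k, tier in enumerate(tiers):
        a, b = _BUILDERS[tier](k, rng)
        class_a.extend(a)
        class_b.extend(b)
        expected[(f"sfA{k}", f"sfB{k}")] = tier
        used_a += 1
        used_b += len({d.superfamily_id for d in b})
    for side, used, want, prefix, out in (
            ("A", used_a, n_sf_a, "sfAiso", class_a),
            ("B", used_b, n_sf_b, "sfBiso", class_b)):
        if want is None:
            continue
        if want < used:
            raise ValueError(
                f"unsatisfiable request: tiers need {used} side-{side} "
                f"superfamilies but n_sf_{side.lower()}={want}")
        for j in range(want - used):
            out.append(ClassifiedDomain(
                f"{prefix}{j}_0", f"{prefix}{j}",
                (Segment(f"iso{side}{j}", "A", 1, 80),)))
    return class_a, class_b, expected
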