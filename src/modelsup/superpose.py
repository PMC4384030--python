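"""Rigid-body superposition of a model ensemble on its included columns.

The ensemble is fitted jointly and reference-free: models are first placed
by walking the overlap graph from the first model, then refined by
alternating (a) a least-squares rigid fit of every model onto the current
mean structure over the included columns it covers, and (b) recomputing the
mean structure from the fitted coordinates.  No single low-quality model
dominates the frame.  Afterwards the frame is re-anchored so the first
model's transform is exactly the identity, which makes output coordinates
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .align import MultiModelAlignment
from .divergence import PositionScore, TrimResult
from .struct_io import ModelChain

__all__ = ["RigidTransform", "SuperpositionResult", "kabsch",
           "superpose_ensemble", "rotate_view"]

MIN_EDGE_COLUMNS = 3   # shared included columns needed to link two models
CONV_TOL = 1e-6        # Å RMS movement of the mean structure
MAX_REFINE_ITER = 50


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation has det != +1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array or a single 3-vector."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=atol)
                and np.allclose(self.translation, 0.0, atol=atol))


@dataclass(frozen=True)
class SuperpositionResult:
    """Transforms and fit statistics for one superposed ensemble.

    ``rmsd_included`` / ``rmsd_all_shared`` are ensemble RMSDs (deviation of
    every member CA from its column mean) over the included columns and over
    all columns shared by >= 2 models respectively.  ``pairwise_rmsd`` is
    the model-by-model RMSD matrix over shared included columns (NaN when a
    pair shares none).
    """

    transforms: dict[str, RigidTransform]
    included: frozenset[int]
    scores: PositionScore
    rmsd_included: float
    rmsd_all_shared: float
    pairwise_rmsd: np.ndarray
    model_ids: tuple[str, ...]
    iterations: int

    def superposed_ca(self, model: ModelChain) -> np.ndarray:
        """CA coordinates of ``model`` after its transform."""
        return self.transforms[model.model_id].apply(model.ca_coords())


def kabsch(P: np.ndarray, Q: np.ndarray,
           weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid fit of point set ``Q`` onto point set ``P``.

    Returns the proper rigid transform T minimising (weighted) RMSD(T(Q), P)
    (Kabsch, via SVD of the cross-covariance; a reflection in the
    least-squares optimum is corrected by flipping the sign of the smallest
    singular direction).  ``weights`` are optional non-negative per-point
    weights.

    Raises ``ValueError`` for fewer than 3 points or degenerate (collinear
    or coincident) point sets, for which the rotation is not unique.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    p_mean = w @ P
    q_mean = w @ Q
    Pc = P - p_mean
    Qc = Q - q_mean
    for name, M in (("P", Pc), ("Q", Qc)):
        sv = np.linalg.svd(M * np.sqrt(w)[:, None], compute_uv=False)
        if sv[1] < 1e-8 * max(1.0, sv[0]):
            kind = "coincident" if sv[0] < 1e-8 else "collinear"
            raise ValueError(f"degenerate point set {name}: points are {kind}")
    H = (Qc * w[:, None]).T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = p_mean - R @ q_mean
    return RigidTransform(R, t)


def _model_columns(aln: MultiModelAlignment, included: frozenset[int]
                   ) -> dict[str, list[int]]:
    cols: dict[str, list[int]] = {m: [] for m in aln.model_ids}
    for i in sorted(included):
        for m in aln.columns[i].members:
            cols[m].append(i)
    return cols


def _connected_components(model_ids: tuple[str, ...],
                          edges: dict[tuple[str, str], int]) -> list[set[str]]:
    seen: set[str] = set()
    comps: list[set[str]] = []
    adj: dict[str, set[str]] = {m: set() for m in model_ids}
    for (a, b), n in edges.items():
        if n >= MIN_EDGE_COLUMNS:
            adj[a].add(b)
            adj[b].add(a)
    for m in model_ids:
        if m in seen:
            continue
        comp = {m}
        stack = [m]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def _ensemble_rmsd(coords: dict[str, dict[int, np.ndarray]],
                   columns: list[int]) -> float:
    """RMS deviation of member CAs from their column means."""
    sq_sum = 0.0
    n = 0
    for i in columns:
        pts = np.array([coords[m][i] for m in coords if i in coords[m]])
        if len(pts) < 2:
            continue
        mean = pts.mean(axis=0)
        sq_sum += float(((pts - mean) ** 2).sum())
        n += len(pts)
    return float(np.sqrt(sq_sum / n)) if n else 0.0


def superpose_ensemble(models: list[ModelChain],
                       aln: MultiModelAlignment,
                       trim_result: TrimResult,
                       scores: PositionScore | None = None
                       ) -> SuperpositionResult:
    """Jointly superpose the ensemble on the trim-included columns.

    Requires the overlap graph — models as nodes, an edge where two models
    share at least 3 included columns — to be connected, and every model to
    cover at least 3 included columns.  The first model anchors the frame:
    its returned transform is exactly the identity.
    """
    included = frozenset(trim_result.included)
    by_model = _model_columns(aln, included)
    ids = tuple(aln.model_ids)
    for m in ids:
        if len(by_model[m]) < MIN_EDGE_COLUMNS:
            raise ValueError(
                f"model {m!r} covers only {len(by_model[m])} included "
                f"column(s); need >= {MIN_EDGE_COLUMNS}")
    shared_counts: dict[tuple[str, str], int] = {}
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            shared_counts[(a, b)] = len(set(by_model[a]) & set(by_model[b]))
    comps = _connected_components(ids, shared_counts)
    if len(comps) > 1:
        pretty = "; ".join("{" + ", ".join(sorted(c)) + "}" for c in comps)
        raise ValueError(
            f"models do not overlap enough to superpose (need >= "
            f"{MIN_EDGE_COLUMNS} shared included columns to link two "
            f"models); disconnected components: {pretty}")

    ca_by_col: dict[str, dict[int, np.ndarray]] = {
        m: {i: aln.columns[i].members[m].ca for i in by_model[m]} for m in ids}

    # initial placement: walk the overlap graph out from the first model,
    # fitting each newly reached model onto its already-placed neighbour
    transforms: dict[str, RigidTransform] = {ids[0]: RigidTransform.identity()}
    placed = [ids[0]]
    while len(placed) < len(ids):
        progressed = False
        for m in ids:
            if m in transforms:
                continue
            # best already-placed neighbour by shared included columns
            best, best_n = None, 0
            for p in placed:
                key = (p, m) if (p, m) in shared_counts else (m, p)
                if shared_counts[key] > best_n:
                    best, best_n = p, shared_counts[key]
            if best is None or best_n < MIN_EDGE_COLUMNS:
                continue
            cols = sorted(set(by_model[m]) & set(by_model[best]))
            target = np.array([transforms[best].apply(ca_by_col[best][i])
                               for i in cols])
            source = np.array([ca_by_col[m][i] for i in cols])
            transforms[m] = kabsch(target, source)
            placed.append(m)
            progressed = True
        if not progressed:  # pragma: no cover - guarded by connectivity check
            raise ValueError("internal error: could not place all models")

    # iterative refinement toward the mean structure
    def current(m: str) -> dict[int, np.ndarray]:
        tr = transforms[m]
        return {i: tr.apply(x) for i, x in ca_by_col[m].items()}

    def mean_structure() -> dict[int, np.ndarray]:
        ref: dict[int, np.ndarray] = {}
        for i in sorted(included):
            pts = [current(m)[i] for m in ids if i in ca_by_col[m]]
            ref[i] = np.mean(pts, axis=0)
        return ref

    ref = mean_structure()
    iterations = 0
    for iterations in range(1, MAX_REFINE_ITER + 1):
        for m in ids:
            cols = by_model[m]
            target = np.array([ref[i] for i in cols])
            source = np.array([ca_by_col[m][i] for i in cols])
            transforms[m] = kabsch(target, source)
        new_ref = mean_structure()
        move = np.sqrt(np.mean(
            [np.sum((new_ref[i] - ref[i]) ** 2) for i in ref]))
        ref = new_ref
        if move < CONV_TOL:
            break

    # anchor the frame to the first model (exact identity)
    anchor_inv = transforms[ids[0]].inverse()
    for m in ids:
        transforms[m] = anchor_inv.compose(transforms[m])
    transforms[ids[0]] = RigidTransform.identity()

    # statistics use every column a model covers, not just the fitted ones
    full_fitted: dict[str, dict[int, np.ndarray]] = {}
    for m in ids:
        tr = transforms[m]
        full_fitted[m] = {i: tr.apply(col.members[m].ca)
                          for i, col in enumerate(aln.columns)
                          if m in col.members}
    fitted = full_fitted
    all_shared = [i for i, c in enumerate(aln.columns) if c.n_members >= 2]
    rmsd_included = _ensemble_rmsd(fitted, sorted(included))
    rmsd_all = _ensemble_rmsd(fitted, all_shared)

    pw = np.full((len(ids), len(ids)), np.nan)
    for a_i in range(len(ids)):
        pw[a_i, a_i] = 0.0
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            cols = sorted(set(by_model[a]) & set(by_model[b]))
            if cols:
                pa = np.array([fitted[a][i] for i in cols])
                pb = np.array([fitted[b][i] for i in cols])
                pw[a_i, b_i] = pw[b_i, a_i] = float(
                    np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))

    if scores is None:
        scores = PositionScore(scores={})
    return SuperpositionResult(
        transforms=transforms, included=included, scores=scores,
        rmsd_included=rmsd_included, rmsd_all_shared=rmsd_all,
        pairwise_rmsd=pw, model_ids=ids, iterations=iterations)


def rotate_view(coords_by_model: dict[str, np.ndarray],
                euler_angles_deg: tuple[float, float, float]
                ) -> dict[str, np.ndarray]:
    """Apply a global view rotation (x, y, z extrinsic Euler angles in
    degrees) about the ensemble centroid to every coordinate set.

    Composing two view rotations equals a single rotation by the composed
    matrix, since the centroid is a fixed point of the rotation.
    """
    if not coords_by_model:
        return {}
    R = Rotation.from_euler("xyz", euler_angles_deg, degrees=True).as_matrix()
    allpts = np.vstack([np.asarray(c, dtype=float).reshape(-1, 3)
                        for c in coords_by_model.values()])
    centre = allpts.mean(axis=0)
    return {m: (np.asarray(c, dtype=float) - centre) @ R.T + centre
            for m, c in coords_by_model.items()}
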