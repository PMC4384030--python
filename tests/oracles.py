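"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and stays independent of the code
paths it checks: rotations come from an exhaustive Euler grid, spanning
trees from Prüfer-sequence enumeration, and the classification tiers from a
direct residue-set transcription of the bronze/silver/gold criteria.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from modelsup.classmap import ClassifiedDomain


# ---------------------------------------------------------------- rotations

def grid_search_rmsd(P: np.ndarray, Q: np.ndarray, step_deg: float = 2.0
                     ) -> float:
    """Best RMSD of Q onto P over a z-y-z Euler grid with centroid
    translation.

    Uses the closed form RMSD^2 = (|Pc|^2 + |Qc|^2 - 2 tr(R H)) / n with
    H = Qc^T Pc, maximising tr(R H) over the grid; the alpha rotation is
    folded in analytically per (beta, gamma) grid cell, so only the
    two inner angles are looped.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = len(P)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    sp = float((Pc ** 2).sum())
    sq = float((Qc ** 2).sum())

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

    def ry(b):
        c, s = np.cos(b), np.sin(b)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    step = np.deg2rad(step_deg)
    alphas = np.arange(0.0, 2 * np.pi, step)
    best_tr = -np.inf
    for beta in np.arange(0.0, np.pi + step / 2, step):
        for gamma in np.arange(0.0, 2 * np.pi, step):
            M = ry(beta) @ rz(gamma) @ H
            # tr(Rz(alpha) M) = cos a (M00+M11) + sin a (M10-M01) + M22
            vals = (np.cos(alphas) * (M[0, 0] + M[1, 1])
                    + np.sin(alphas) * (M[1, 0] - M[0, 1]) + M[2, 2])
            m = float(vals.max())
            if m > best_tr:
                best_tr = m
    return float(np.sqrt(max(0.0, (sp + sq - 2 * best_tr) / n)))


# ------------------------------------------------------------ spanning trees

def _prufer_to_edges(seq: Sequence[int], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    for x in seq:
        for y in range(n):
            if degree[y] == 1:
                edges.append((x, y))
                degree[x] -= 1
                degree[y] -= 1
                break
    last = [y for y in range(n) if degree[y] == 1]
    edges.append((last[0], last[1]))
    return edges


def min_spanning_total(points: np.ndarray) -> float:
    """Exhaustive minimum spanning-tree total length via Cayley/Prüfer
    enumeration of all n^(n-2) labelled trees (n <= 7 kept practical)."""
    pts = np.asarray(points, float)
    n = len(pts)
    if n == 2:
        return float(np.linalg.norm(pts[0] - pts[1]))
    dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        total = sum(dmat[a, b] for a, b in _prufer_to_edges(seq, n))
        best = min(best, total)
    return float(best)


# ------------------------------------------------------------ classification

def _residue_set(d: ClassifiedDomain) -> set[tuple[str, str, int]]:
    out = set()
    for s in d.segments:
        for p in range(s.start, s.end + 1):
            out.add((s.structure_id, s.chain_id, p))
    return out


def brute_force_tiers(class_a: Sequence[ClassifiedDomain],
                      class_b: Sequence[ClassifiedDomain],
                      threshold: float = 0.80
                      ) -> dict[tuple[str, str], str]:
    """Direct residue-set transcription of the consensus-tier criteria.

    Returns tier name per overlapping superfamily pair: mutual unique best
    by shared residues (domain-count sum tie-break, remaining tie -> no
    consensus) gives BRONZE; >= threshold domain-mapping fraction on both
    sides (ignoring domains whose chains carry no partner-classification
    domain) and >= threshold mean residue-overlap fraction gives SILVER;
    >= threshold minimum fraction gives GOLD.
    """
    res_a = {d.domain_id: _residue_set(d) for d in class_a}
    res_b = {d.domain_id: _residue_set(d) for d in class_b}
    sfs_a = sorted({d.superfamily_id for d in class_a})
    sfs_b = sorted({d.superfamily_id for d in class_b})
    doms_a = {sf: [d for d in class_a if d.superfamily_id == sf] for sf in sfs_a}
    doms_b = {sf: [d for d in class_b if d.superfamily_id == sf] for sf in sfs_b}

    shared = {}
    mapped = {}
    for sa in sfs_a:
        for sb in sfs_b:
            tot = sum(len(res_a[da.domain_id] & res_b[db.domain_id])
                      for da in doms_a[sa] for db in doms_b[sb])
            if tot > 0:
                ma = sum(1 for da in doms_a[sa]
                         if any(res_a[da.domain_id] & res_b[db.domain_id]
                                for db in doms_b[sb]))
                mb = sum(1 for db in doms_b[sb]
                         if any(res_b[db.domain_id] & res_a[da.domain_id]
                                for da in doms_a[sa]))
                shared[(sa, sb)] = tot
                mapped[(sa, sb)] = (ma, mb)

    def unique_best(keys: list[tuple[str, str]], pick) -> str | None:
        scored = sorted(
            ((shared[k], sum(mapped[k]), pick(k)) for k in keys),
            reverse=True)
        if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
            return None
        return scored[0][2]

    consensus = set()
    for sa in sfs_a:
        keys = [k for k in shared if k[0] == sa]
        if not keys:
            continue
        sb = unique_best(keys, lambda k: k[1])
        if sb is None:
            continue
        back = unique_best([k for k in shared if k[1] == sb], lambda k: k[0])
        if back == sa:
            consensus.add((sa, sb))

    chains_a = {c for d in class_a
                for c in {(s.structure_id, s.chain_id) for s in d.segments}}
    chains_b = {c for d in class_b
                for c in {(s.structure_id, s.chain_id) for s in d.segments}}

    tiers = {}
    for (sa, sb) in shared:
        if (sa, sb) not in consensus:
            tiers[(sa, sb)] = "NONE"
            continue
        tier = "BRONZE"
        cls_a = [d for d in doms_a[sa]
                 if {(s.structure_id, s.chain_id) for s in d.segments}
                 & chains_b]
        cls_b = [d for d in doms_b[sb]
                 if {(s.structure_id, s.chain_id) for s in d.segments}
                 & chains_a]
        union_b = set().union(*(res_b[db.domain_id] for db in doms_b[sb]))
        union_a = set().union(*(res_a[da.domain_id] for da in doms_a[sa]))
        fr_a = [len(res_a[da.domain_id] & union_b) / len(res_a[da.domain_id])
                for da in doms_a[sa]
                if any(res_a[da.domain_id] & res_b[db.domain_id]
                       for db in doms_b[sb])]
        fr_b = [len(res_b[db.domain_id] & union_a) / len(res_b[db.domain_id])
                for db in doms_b[sb]
                if any(res_b[db.domain_id] & res_a[da.domain_id]
                       for da in doms_a[sa])]
        ma, mb = mapped[(sa, sb)]
        if (cls_a and cls_b
                and ma / len(cls_a) >= threshold
                and mb / len(cls_b) >= threshold
                and fr_a and fr_b
                and sum(fr_a) / len(fr_a) >= threshold
                and sum(fr_b) / len(fr_b) >= threshold):
            tier = "SILVER"
            if min(fr_a) >= threshold and min(fr_b) >= threshold:
                tier = "GOLD"
        tiers[(sa, sb)] = tier
    return tiers


def random_classifications(rng: np.random.Generator,
                           max_sf: int = 5, max_dom: int = 8
                           ) -> tuple[list[ClassifiedDomain],
                                      list[ClassifiedDomain]]:
    """Random two-classification instance on a small shared structure set."""
    from modelsup.classmap import Segment

    structures = [f"s{i}" for i in range(int(rng.integers(2, 5)))]
    out = []
    for side in "ab":
        n_sf = int(rng.integers(1, max_sf + 1))
        domains = []
        counter = 0
        for sf in range(n_sf):
            for _ in range(int(rng.integers(1, max_dom + 1))):
                n_seg = int(rng.integers(1, 3))
                segs = []
                starts = sorted(rng.integers(1, 200, size=n_seg).tolist())
                struct = structures[int(rng.integers(0, len(structures)))]
                prev_end = 0
                for st in starts:
                    st = max(st, prev_end + 1)
                    ln = int(rng.integers(10, 60))
                    segs.append(Segment(struct, "A", st, st + ln - 1))
                    prev_end = st + ln - 1
                domains.append(ClassifiedDomain(
                    f"{side}{counter}", f"sf_{side}{sf}", tuple(segs)))
                counter += 1
        out.append(domains)
    return out[0], out[1]
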