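"""Reconciliation of two domain classifications (SCOP/CATH style).

Two resources that classify protein domains into superfamilies can be
compared by computing, for every pair of domains (one from each resource),
how many residues they share — a residue being a (structure, chain,
position) triple — and aggregating those overlaps to the superfamily level.
Superfamily pairs that are mutually each other's most similar partner are
*consensus pairs*, graded bronze / silver / gold:

* **Bronze** — the two superfamilies are more similar to each other than to
  any other superfamily (mutual best, similarity = shared residue count).
* **Silver** — bronze, and at least 80% of each superfamily's domains map to
  the other (ignoring domains not yet classified by the other resource),
  and the mapped domains overlap the partner superfamily over an average of
  at least 80% of their residues, on both sides.
* **Gold** — silver, and the overlap covers a minimum of at least 80% of
  their residues, on both sides.

All thresholds are inclusive ("at least 80%") and configurable.

A domain of resource A counts as *not yet classified* with respect to B when
no segment of it lies on a (structure, chain) carrying any B domain; such
domains are excluded from the silver denominator.  A domain is *mapped* to a
partner superfamily as soon as it shares one residue with it — the overlap
fractions then carry the stringency.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = ["Segment", "ClassifiedDomain", "SuperfamilyPairStats",
           "ConsensusTier", "domain_overlap", "aggregate_pairs",
           "consensus_pairs", "assign_tier", "classify",
           "read_classification_tsv", "write_classification_tsv",
           "write_report_tsv", "DEFAULT_TIER_THRESHOLD"]

DEFAULT_TIER_THRESHOLD = 0.80


class ConsensusTier(enum.IntEnum):
    NONE = 0
    BRONZE = 1
    SILVER = 2
    GOLD = 3


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range on one chain, 1-based inclusive."""

    structure_id: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClassifiedDomain:
    """One classified domain: possibly multi-segment, one superfamily."""

    domain_id: str
    superfamily_id: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"domain {self.domain_id!r}: no segments")
        by_chain: dict[tuple[str, str], list[Segment]] = {}
        for seg in self.segments:
            by_chain.setdefault((seg.structure_id, seg.chain_id), []).append(seg)
        for segs in by_chain.values():
            segs = sorted(segs, key=lambda s: s.start)
            for s1, s2 in zip(segs, segs[1:]):
                if s2.start <= s1.end:
                    raise ValueError(
                        f"domain {self.domain_id!r}: overlapping segments")

    @property
    def n_residues(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def chains(self) -> set[tuple[str, str]]:
        return {(s.structure_id, s.chain_id) for s in self.segments}


def _overlap_on_chain(segs1: Sequence[Segment], segs2: Sequence[Segment]) -> int:
    total = 0
    for s1 in segs1:
        for s2 in segs2:
            total += max(0, min(s1.end, s2.end) - max(s1.start, s2.start) + 1)
    return total


def domain_overlap(d1: ClassifiedDomain, d2: ClassifiedDomain) -> int:
    """Number of (structure, chain, position) residues in both domains."""
    total = 0
    for key in d1.chains & d2.chains:
        segs1 = [s for s in d1.segments if (s.structure_id, s.chain_id) == key]
        segs2 = [s for s in d2.segments if (s.structure_id, s.chain_id) == key]
        total += _overlap_on_chain(segs1, segs2)
    return total


@dataclass
class SuperfamilyPairStats:
    """Residue/domain overlap aggregates for one (A-superfamily,
    B-superfamily) pair."""

    sf_a: str
    sf_b: str
    shared_residues: int
    mapped_domains_a: int
    mapped_domains_b: int
    classifiable_domains_a: int
    classifiable_domains_b: int
    overlap_fracs_a: tuple[float, ...]
    overlap_fracs_b: tuple[float, ...]


def _covered_count(domain: ClassifiedDomain,
                   partner_domains: Iterable[ClassifiedDomain]) -> int:
    """Residues of ``domain`` covered by the union of partner domains."""
    partner_positions: dict[tuple[str, str], set[int]] = {}
    for pd in partner_domains:
        for seg in pd.segments:
            partner_positions.setdefault(
                (seg.structure_id, seg.chain_id), set()
            ).update(range(seg.start, seg.end + 1))
    covered = 0
    for seg in domain.segments:
        pos = partner_positions.get((seg.structure_id, seg.chain_id))
        if pos:
            covered += sum(1 for p in range(seg.start, seg.end + 1) if p in pos)
    return covered


def _check_unique_ids(domains: Sequence[ClassifiedDomain], label: str) -> None:
    ids = [d.domain_id for d in domains]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate domain ids in classification {label}: {dupes}")


def aggregate_pairs(classification_a: Sequence[ClassifiedDomain],
                    classification_b: Sequence[ClassifiedDomain]
                    ) -> list[SuperfamilyPairStats]:
    """Aggregate all domain-vs-domain overlaps to superfamily pairs.

    Emits one record per (A-superfamily, B-superfamily) pair that shares at
    least one residue.  Records are ordered by (sf_a, sf_b).
    """
    _check_unique_ids(classification_a, "A")
    _check_unique_ids(classification_b, "B")

    by_sf_a: dict[str, list[ClassifiedDomain]] = {}
    for d in classification_a:
        by_sf_a.setdefault(d.superfamily_id, []).append(d)
    by_sf_b: dict[str, list[ClassifiedDomain]] = {}
    for d in classification_b:
        by_sf_b.setdefault(d.superfamily_id, []).append(d)

    chains_with_b = {c for d in classification_b for c in d.chains}
    chains_with_a = {c for d in classification_a for c in d.chains}

    shared: dict[tuple[str, str], int] = {}
    for da in classification_a:
        for db in classification_b:
            ov = domain_overlap(da, db)
            if ov > 0:
                key = (da.superfamily_id, db.superfamily_id)
                shared[key] = shared.get(key, 0) + ov

    out: list[SuperfamilyPairStats] = []
    for (sf_a, sf_b) in sorted(shared):
        doms_a = by_sf_a[sf_a]
        doms_b = by_sf_b[sf_b]
        partner_b = by_sf_b[sf_b]
        partner_a = by_sf_a[sf_a]
        fracs_a = []
        for da in doms_a:
            if any(domain_overlap(da, db) > 0 for db in partner_b):
                fracs_a.append(_covered_count(da, partner_b) / da.n_residues)
        fracs_b = []
        for db in doms_b:
            if any(domain_overlap(db, da) > 0 for da in partner_a):
                fracs_b.append(_covered_count(db, partner_a) / db.n_residues)
        out.append(SuperfamilyPairStats(
            sf_a=sf_a, sf_b=sf_b, shared_residues=shared[(sf_a, sf_b)],
            mapped_domains_a=len(fracs_a), mapped_domains_b=len(fracs_b),
            classifiable_domains_a=sum(
                1 for d in doms_a if d.chains & chains_with_b),
            classifiable_domains_b=sum(
                1 for d in doms_b if d.chains & chains_with_a),
            overlap_fracs_a=tuple(fracs_a), overlap_fracs_b=tuple(fracs_b)))
    return out


def consensus_pairs(stats: Sequence[SuperfamilyPairStats]
                    ) -> set[tuple[str, str]]:
    """Mutual-best superfamily pairs.

    (a, b) is consensus iff b is a's unique most similar B-superfamily and a
    is b's unique most similar A-superfamily.  Similarity is the shared
    residue count; ties are broken by the larger total of mapped domains;
    any remaining tie makes the best ambiguous (logged) and yields no
    consensus for that side.
    """
    def best(records: list[SuperfamilyPairStats], other_key) -> str | None:
        ranked = sorted(
            records,
            key=lambda s: (s.shared_residues,
                           s.mapped_domains_a + s.mapped_domains_b),
            reverse=True)
        if len(ranked) > 1:
            k0 = (ranked[0].shared_residues,
                  ranked[0].mapped_domains_a + ranked[0].mapped_domains_b)
            k1 = (ranked[1].shared_residues,
                  ranked[1].mapped_domains_a + ranked[1].mapped_domains_b)
            if k0 == k1:
                logger.info("ambiguous best partner among %s — no consensus",
                            [other_key(r) for r in ranked[:2]])
                return None
        return other_key(ranked[0])

    by_a: dict[str, list[SuperfamilyPairStats]] = {}
    by_b: dict[str, list[SuperfamilyPairStats]] = {}
    for s in stats:
        by_a.setdefault(s.sf_a, []).append(s)
        by_b.setdefault(s.sf_b, []).append(s)
    best_b_of_a = {a: best(recs, lambda s: s.sf_b) for a, recs in by_a.items()}
    best_a_of_b = {b: best(recs, lambda s: s.sf_a) for b, recs in by_b.items()}
    return {(a, b) for a, b in best_b_of_a.items()
            if b is not None and best_a_of_b.get(b) == a}


def assign_tier(pair: SuperfamilyPairStats, is_consensus: bool,
                threshold: float = DEFAULT_TIER_THRESHOLD) -> ConsensusTier:
    """Grade one superfamily pair (see module docstring for the criteria)."""
    if not is_consensus:
        return ConsensusTier.NONE
    tier = ConsensusTier.BRONZE
    if pair.classifiable_domains_a == 0 or pair.classifiable_domains_b == 0:
        logger.warning("pair (%s, %s): zero classifiable domains on one side; "
                       "silver criteria fail", pair.sf_a, pair.sf_b)
        return tier
    dommap_a = pair.mapped_domains_a / pair.classifiable_domains_a
    dommap_b = pair.mapped_domains_b / pair.classifiable_domains_b
    if not (dommap_a >= threshold and dommap_b >= threshold):
        return tier
    if not pair.overlap_fracs_a or not pair.overlap_fracs_b:
        return tier
    mean_a = sum(pair.overlap_fracs_a) / len(pair.overlap_fracs_a)
    mean_b = sum(pair.overlap_fracs_b) / len(pair.overlap_fracs_b)
    if not (mean_a >= threshold and mean_b >= threshold):
        return tier
    tier = ConsensusTier.SILVER
    if (min(pair.overlap_fracs_a) >= threshold
            and min(pair.overlap_fracs_b) >= threshold):
        tier = ConsensusTier.GOLD
    return tier


def classify(classification_a: Sequence[ClassifiedDomain],
             classification_b: Sequence[ClassifiedDomain],
             threshold: float = DEFAULT_TIER_THRESHOLD
             ) -> list[tuple[SuperfamilyPairStats, ConsensusTier]]:
    """Full pipeline: aggregate overlaps, find consensus pairs, grade them.

    Returns every overlapping superfamily pair with its tier, sorted by
    (tier descending, shared residues descending, sf ids).
    """
    stats = aggregate_pairs(classification_a, classification_b)
    consensus = consensus_pairs(stats)
    graded = [(s, assign_tier(s, (s.sf_a, s.sf_b) in consensus, threshold))
              for s in stats]
    graded.sort(key=lambda st: (-int(st[1]), -st[0].shared_residues,
                                st[0].sf_a, st[0].sf_b))
    return graded


def read_classification_tsv(path: str | Path) -> list[ClassifiedDomain]:
    """Read a classification table: one row per segment, tab-separated
    columns ``domain_id superfamily_id structure_id chain_id start end``.
    A header row is allowed and detected by the literal ``domain_id``."""
    path = Path(path)
    segments: dict[str, tuple[str, list[Segment]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "domain_id":  # header row
            continue
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 tab-separated "
                             f"fields, got {len(fields)}")
        dom_id, sf_id, struct_id, chain_id, start_s, end_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: residue range bounds must be "
                             f"integers ({start_s!r}, {end_s!r})") from exc
        if start > end:
            raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
        if dom_id not in segments:
            segments[dom_id] = (sf_id, [])
            order.append(dom_id)
        elif segments[dom_id][0] != sf_id:
            raise ValueError(f"{path}:{lineno}: domain {dom_id!r} listed "
                             "under two superfamilies")
        segments[dom_id][1].append(Segment(struct_id, chain_id, start, end))
    return [ClassifiedDomain(domain_id=d, superfamily_id=segments[d][0],
                             segments=tuple(segments[d][1])) for d in order]


def write_classification_tsv(domains: Sequence[ClassifiedDomain],
                             path: str | Path) -> None:
    """Write a classification table in the format read back by
    :func:`read_classification_tsv` (one row per segment, with header)."""
    rows = ["domain_id\tsuperfamily_id\tstructure_id\tchain_id\tstart\tend"]
    for d in domains:
        for s in d.segments:
            rows.append(f"{d.domain_id}\t{d.superfamily_id}\t"
                        f"{s.structure_id}\t{s.chain_id}\t{s.start}\t{s.end}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_report_tsv(graded: Sequence[tuple[SuperfamilyPairStats, ConsensusTier]],
                     path: str | Path) -> None:
    """Write the pair report (tier + aggregate fractions per side)."""
    def frac(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    rows = ["sf_a\tsf_b\ttier\tshared_residues\tdommap_frac_a\tdommap_frac_b"
            "\tmean_frac_a\tmean_frac_b\tmin_frac_a\tmin_frac_b"]
    for s, tier in graded:
        dm_a = (s.mapped_domains_a / s.classifiable_domains_a
                if s.classifiable_domains_a else None)
        dm_b = (s.mapped_domains_b / s.classifiable_domains_b
                if s.classifiable_domains_b else None)
        mean_a = (sum(s.overlap_fracs_a) / len(s.overlap_fracs_a)
                  if s.overlap_fracs_a else None)
        mean_b = (sum(s.overlap_fracs_b) / len(s.overlap_fracs_b)
                  if s.overlap_fracs_b else None)
        min_a = min(s.overlap_fracs_a) if s.overlap_fracs_a else None
        min_b = min(s.overlap_fracs_b) if s.overlap_fracs_b else None
        rows.append(f"{s.sf_a}\t{s.sf_b}\t{tier.name}\t{s.shared_residues}\t"
                    f"{frac(dm_a)}\t{frac(dm_b)}\t{frac(mean_a)}\t"
                    f"{frac(mean_b)}\t{frac(min_a)}\t{frac(min_b)}")
    Path(path).write_text("\n".join(rows) + "\n")
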