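"""Per-column structural consistency scores and divergent-region trimming.

Before superposing, the toolkit identifies positions where the models
disagree, so that divergent regions (unfolded tails, differently-placed
segments) do not disrupt the superposition of the regions the models agree
on.  Consistency is judged pairwise: for every pair of models, the shared
columns are brought into a robust rigid fit and the residual per-column
deviation is passed through the distance-difference kernel the SSAP
structure comparison algorithm uses,

    S_pq(i) = 1 / (1 + (delta_i / sigma)^2),

where delta_i is the CA deviation of column i after the pairwise fit and
sigma an Å-scale (default 2 Å).  The fit is made robust by iterative
reweighting — three rounds of a kernel-weighted rigid fit — so a divergent
tail cannot drag the fit away from the region the two models agree on, and
the procedure stays deterministic and invariant under any rigid motion of
any input model.

The per-column score s_i is the *minimum* of S_pq(i) over all model pairs
sharing column i: a position counts as conserved only when every pair of
models agrees there, so a single dissenting model marks a region divergent
(a mean would let two models that happen to place a divergent segment
similarly outvote the third).  Scores lie in (0, 1], higher = more
mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .align import MultiModelAlignment
from .struct_io import ModelChain

logger = logging.getLogger(__name__)

__all__ = ["PositionScore", "TrimResult", "position_scores", "trim",
           "DEFAULT_SIGMA", "DEFAULT_SCORE_THRESHOLD", "DEFAULT_KEEP_FLOOR",
           "DEFAULT_MAX_ITER"]

DEFAULT_SIGMA = 2.0          # Å; deviation scale of the score kernel
DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_KEEP_FLOOR = 0.3     # never trim below this fraction (and >= 3 columns)
DEFAULT_MAX_ITER = 10
N_ROBUST_ROUNDS = 3          # reweighting rounds of the pairwise fit
WINDOW = 7                   # columns per local fit hypothesis


@dataclass(frozen=True)
class PositionScore:
    """Map column index -> consistency score in (0, 1].

    Defined exactly on the scoreable columns: columns with >= 2 members for
    which at least one model pair could be fitted (>= 3 shared,
    non-degenerate columns).
    """

    scores: dict[int, float]

    def __getitem__(self, idx: int) -> float:
        return self.scores[idx]

    def __contains__(self, idx: int) -> bool:
        return idx in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def items(self):
        return self.scores.items()


@dataclass(frozen=True)
class TrimResult:
    included: frozenset[int]
    excluded: frozenset[int]
    iterations: int

    def to_tsv(self, aln: MultiModelAlignment, scores: PositionScore,
               path: str | Path) -> None:
        rows = ["seq_pos\ticode\tscore\tincluded"]
        for idx in sorted(self.included | self.excluded):
            col = aln.columns[idx]
            s = scores.scores.get(idx)
            rows.append(f"{col.seq_pos}\t{col.icode.strip() or '-'}\t"
                        f"{'NA' if s is None else format(s, '.6f')}\t"
                        f"{1 if idx in self.included else 0}")
        Path(path).write_text("\n".join(rows) + "\n")


def _pair_kernel(xp: np.ndarray, xq: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel scores per shared column for one model pair.

    Robust rigid fit of ``xq`` onto ``xp``: an unweighted fit, then
    ``N_ROBUST_ROUNDS`` rounds re-weighted by the previous kernel values so
    that well-agreeing columns dominate the fit.  Returns the final kernel
    values (in (0, 1]).
    """
    from .superpose import kabsch  # deferred: superpose imports this module

    n = len(xp)
    w = min(WINDOW, n)
    # hypothesis stage: fit every contiguous window of shared columns and
    # keep the fit with the largest consensus support.  A plain least
    # squares fit over everything would split the error between a divergent
    # segment and the agreeing majority, leaving nothing to discriminate on;
    # a local window lies inside one rigid segment, and the majority
    # segment's windows gather the most support.
    best_kern: np.ndarray | None = None
    best_support = -1.0
    for s in range(n - w + 1):
        try:
            tr = kabsch(xp[s:s + w], xq[s:s + w])
        except ValueError:
            continue
        delta = np.linalg.norm(tr.apply(xq) - xp, axis=1)
        kern = 1.0 / (1.0 + (delta / sigma) ** 2)
        support = float(kern.sum())
        if support > best_support:
            best_support = support
            best_kern = kern
    if best_kern is None:
        raise ValueError("no non-degenerate window for the pairwise fit")
    # refinement stage: iteratively reweighted fit from the winning
    # hypothesis
    weights = best_kern
    kern = best_kern
    for _ in range(N_ROBUST_ROUNDS):
        tr = kabsch(xp, xq, weights=weights)
        delta = np.linalg.norm(tr.apply(xq) - xp, axis=1)
        kern = 1.0 / (1.0 + (delta / sigma) ** 2)
        weights = kern
    return kern


def position_scores(models: Sequence[ModelChain],
                    aln: MultiModelAlignment,
                    sigma: float = DEFAULT_SIGMA,
                    columns: Sequence[int] | None = None) -> PositionScore:
    """Score the mutual consistency of every shared column.

    ``columns`` optionally restricts scoring (and the pairwise fits) to a
    subset of column indices — used by :func:`trim` when re-scoring the
    currently included set.
    """
    if len(models) < 2:
        raise ValueError("scoring requires at least two models")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if columns is None:
        candidate = [i for i, c in enumerate(aln.columns) if c.n_members >= 2]
    else:
        candidate = [i for i in columns if aln.columns[i].n_members >= 2]
    if len(candidate) < 2:
        raise ValueError("fewer than 2 scoreable columns")

    ids = list(aln.model_ids)
    per_col_min: dict[int, float] = {}
    any_pair = False
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            p, q = ids[a], ids[b]
            shared = [i for i in candidate
                      if p in aln.columns[i].members
                      and q in aln.columns[i].members]
            if len(shared) < 3:
                if shared:
                    logger.info("model pair (%s, %s) shares only %d scoreable "
                                "column(s); contributes no scores",
                                p, q, len(shared))
                continue
            xp = np.array([aln.columns[i].members[p].ca for i in shared])
            xq = np.array([aln.columns[i].members[q].ca for i in shared])
            try:
                kern = _pair_kernel(xp, xq, sigma)
            except ValueError as exc:
                logger.info("model pair (%s, %s) not scoreable: %s", p, q, exc)
                continue
            any_pair = True
            for idx, val in zip(shared, kern):
                v = float(val)
                if idx not in per_col_min or v < per_col_min[idx]:
                    per_col_min[idx] = v
    if not any_pair:
        raise ValueError("no model pair shares enough columns for a rigid "
                         "fit (need >= 3 non-degenerate shared columns)")
    return PositionScore(scores=dict(sorted(per_col_min.items())))


def trim(models: Sequence[ModelChain],
         aln: MultiModelAlignment,
         scores_fn: Callable[..., PositionScore] = position_scores,
         score_threshold: float = DEFAULT_SCORE_THRESHOLD,
         keep_fraction_floor: float = DEFAULT_KEEP_FLOOR,
         max_iter: int = DEFAULT_MAX_ITER,
         sigma: float = DEFAULT_SIGMA) -> tuple[TrimResult, PositionScore]:
    """Iteratively exclude the most divergent columns.

    Each round scores the currently included columns, drops those scoring
    below ``score_threshold``, and re-scores the survivors, stopping at a
    fixed point or after ``max_iter`` rounds.  Trimming never goes below
    max(3, keep_fraction_floor * scoreable columns): if the threshold would
    violate the floor, the highest-scoring columns are kept up to the floor,
    ties broken toward retaining lower sequence positions first.

    Returns the trim result together with the scores of the final round
    (computed on the included set).
    """
    scoreable = [i for i, c in enumerate(aln.columns) if c.n_members >= 2]
    if len(scoreable) < 3:
        raise ValueError(f"need at least 3 scoreable columns, got {len(scoreable)}")
    floor = max(3, int(np.ceil(keep_fraction_floor * len(scoreable))))
    included = list(scoreable)
    iterations = 0
    scores = scores_fn(models, aln, sigma=sigma, columns=included)
    while iterations < max_iter:
        iterations += 1
        keep = [i for i in included if scores[i] >= score_threshold]
        if len(keep) < floor:
            # rank by (-score, column index): high score first, earlier
            # sequence position wins ties
            ranked = sorted(included, key=lambda i: (-scores[i], i))
            keep = sorted(ranked[:floor])
        if keep == included:
            break
        included = keep
        scores = scores_fn(models, aln, sigma=sigma, columns=included)
    result = TrimResult(included=frozenset(included),
                        excluded=frozenset(scoreable) - frozenset(included),
                        iterations=iterations)
    return result, scores
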