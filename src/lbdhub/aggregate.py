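"""Unsupervised rank aggregation and score normalization.

Each metapath schema produces its own ranking of candidate source nodes
(best first, by DWPC-weighted HeteSim).  ULARA-style aggregation treats the
schemas as voters: a consensus rank is the weight-averaged rank per node,
each voter is penalized by its squared disagreement with the consensus, and
weights are refreshed proportional to inverse disagreement until they
stabilize.  The aggregated relevance of a node is then the weighted mean of
its per-schema HeteSim scores — a convex combination, so it stays in [0, 1].

Downstream utilities: min–max normalization, midrank percentile ranking and
Kendall tau-b rank correlation (tie-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pathscore import MetapathSchema


@dataclass
class RankList:
    """One schema's ranking of source nodes.

    ``scores`` maps source CUI -> HeteSim; ``keys`` maps source CUI -> the
    sort key used for ranking (DWPC-weighted HeteSim).  Ranks are 1 = best,
    descending in the key, with midranks on ties.
    """

    schema: MetapathSchema
    scores: dict[str, float]
    keys: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("a rank list must rank at least one node")
        if not self.keys:
            self.keys = dict(self.scores)

    def ranks(self) -> dict[str, float]:
        """Midrank positions, 1 = best (largest key)."""
        cuis = sorted(self.keys)
        values = np.array([self.keys[c] for c in cuis], dtype=float)
        # rankdata ranks ascending; negate for descending-is-best.
        r = stats.rankdata(-values, method="average")
        return dict(zip(cuis, r.tolist()))


@dataclass
class AggregationResult:
    """Converged voter weights and aggregated per-node relevance."""

    weights: dict[MetapathSchema, float]
    relevance: dict[str, float]
    iterations: int
    converged: bool


def ulara(
    rank_lists: Sequence[RankList],
    tol: float = 1e-8,
    max_iter: int = 500,
    eps: float = 1e-9,
) -> AggregationResult:
    """Aggregate per-schema rankings by iterative inverse-disagreement voting.

    Nodes absent from a list are assigned rank ``N + 1`` (N = size of the
    common node universe) and HeteSim 0 there, so unranked sources are never
    rewarded.  Iteration: consensus ``mu(i) = sum_m w_m r_m(i)``;
    disagreement ``d_m = sum_i (r_m(i) - mu(i))**2``; ``w_m ~ 1/(d_m+eps)``;
    stop when the largest weight change drops below ``tol``.
    """
    if not rank_lists:
        raise ValueError("ulara requires at least one rank list")
    universe = sorted({cui for rl in rank_lists for cui in rl.scores})
    n = len(universe)
    m = len(rank_lists)
    missing_rank = float(n + 1)

    ranks = np.full((m, n), missing_rank)
    hetesims = np.zeros((m, n))
    for j, rl in enumerate(rank_lists):
        rj = rl.ranks()
        for i, cui in enumerate(universe):
            if cui in rj:
                ranks[j, i] = rj[cui]
                hetesims[j, i] = rl.scores[cui]

    w = np.full(m, 1.0 / m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = w @ ranks
        d = ((ranks - mu) ** 2).sum(axis=1)
        w_new = 1.0 / (d + eps)
        w_new /= w_new.sum()
        delta = np.abs(w_new - w).max()
        w = w_new
        if delta < tol:
            converged = True
            break

    relevance = dict(zip(universe, (w @ hetesims).tolist()))
    weights = {rl.schema: float(w[j]) for j, rl in enumerate(rank_lists)}
    return AggregationResult(weights, relevance, it, converged)


def minmax(scores: Sequence[float]) -> np.ndarray:
    """Min–max normalization onto [0, 1]; an all-equal input maps to 0.5."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("minmax requires at least one score")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def percentile_rank(scores: Sequence[float]) -> np.ndarray:
    """Midrank percentile of each score within its own distribution.

    ``100 * (count(strictly less) + 0.5 * count(equal)) / N``, in [0, 100].
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_rank requires at least one score")
    midranks = stats.rankdata(arr, method="average")  # = less + (equal+1)/2
    return 100.0 * (midranks - 0.5) / arr.size


def kendall_tau_b(a: Sequence[float], b: Sequence[float]) -> float:
    """Kendall tau-b rank correlation (tie-corrected), over paired vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("kendall_tau_b requires at least two paired values")
    return float(stats.kendalltau(a, b, variant="b").statistic)


def ranked_table(
    relevance: Mapping[str, float],
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """(cuis, raw, min–max normalized, percentile) in a fixed sorted order."""
    cuis = sorted(relevance)
    raw = np.array([relevance[c] for c in cuis], dtype=float)
    return cuis, raw, minmax(raw), percentile_rank(raw)
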