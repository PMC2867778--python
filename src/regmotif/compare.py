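"""Motif-motif similarity search against a library.

Each target is aligned to the query at every offset with at least
``min_overlap`` overlapping columns, in both orientations.  Column pairs
are scored with Pearson correlation (default) or negative Euclidean
distance between regularized frequency columns; the alignment score is the
column sum.  Significance comes from a discretized null distribution of
column scores built from the library's own columns, convolved over the
overlap length by dynamic programming, with a Bonferroni correction across
the offsets and orientations tried for that target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .motif import Background, Motif, regularize

Metric = Literal["pearson", "euclidean"]

N_BINS = 100
MIN_LIBRARY_FOR_NULL = 10


@dataclass
class ComparisonResult:
    query: str
    target: str
    offset: int  # target start relative to query start, query orientation
    orientation: Literal["same", "revcomp"]
    column_scores: list[float]
    score: float
    combined_p: float


def column_score(a: np.ndarray, b: np.ndarray, metric: Metric) -> float:
    if metric == "pearson":
        sa, sb = np.std(a), np.std(b)
        if sa < 1e-12 or sb < 1e-12:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    return -float(np.linalg.norm(a - b))


class _Null:
    """Discretized null distribution of a single column score."""

    def __init__(self, edges: np.ndarray, probs: np.ndarray):
        self.edges = edges  # N_BINS + 1 bin edges
        self.probs = probs  # N_BINS probabilities

    @classmethod
    def from_columns(cls, columns: np.ndarray, metric: Metric) -> "_Null":
        n = len(columns)
        vals = []
        for i in range(n):
            for j in range(i + 1, n):
                vals.append(column_score(columns[i], columns[j], metric))
        vals = np.asarray(vals)
        lo, hi = _score_range(metric, vals)
        edges = np.linspace(lo, hi, N_BINS + 1)
        hist, _ = np.histogram(vals, bins=edges)
        probs = hist / hist.sum()
        probs = np.maximum(probs, 1e-12)
        return cls(edges, probs / probs.sum())

    @classmethod
    def analytic(cls, metric: Metric, rng: np.random.Generator) -> "_Null":
        """Fallback null for tiny libraries.  For Pearson on 4-point columns
        the exact independence null density of r is uniform on [-1, 1]
        (f(r) proportional to (1 - r^2)^((n-4)/2) with n = 4); for the
        Euclidean metric the null is sampled from Dirichlet(1,1,1,1) column
        pairs."""
        if metric == "pearson":
            edges = np.linspace(-1.0, 1.0, N_BINS + 1)
            probs = np.full(N_BINS, 1.0 / N_BINS)
            return cls(edges, probs)
        cols = rng.dirichlet(np.ones(4), size=2000)
        vals = np.array(
            [column_score(cols[2 * i], cols[2 * i + 1], metric) for i in range(1000)]
        )
        lo, hi = _score_range(metric, vals)
        edges = np.linspace(lo, hi, N_BINS + 1)
        hist, _ = np.histogram(vals, bins=edges)
        probs = np.maximum(hist / hist.sum(), 1e-12)
        return cls(edges, probs / probs.sum())

    def bin_of(self, x: float) -> int:
        i = int(np.searchsorted(self.edges, x, side="right")) - 1
        return int(np.clip(i, 0, N_BINS - 1))

    def tail_of_sum(self, scores: Sequence[float]) -> float:
        """P(sum of len(scores) i.i.d. null column scores >= observed sum),
        computed on the discretized bin-index lattice."""
        L = len(scores)
        dist = np.ones(1)  # distribution over summed bin indices
        for _ in range(L):
            dist = np.convolve(dist, self.probs)
        obs = sum(self.bin_of(s) for s in scores)
        p = float(dist[obs:].sum())
        return min(1.0, max(p, float(dist[-1])))


def _score_range(metric: Metric, vals: np.ndarray) -> tuple[float, float]:
    if metric == "pearson":
        return -1.0, 1.0
    lo = float(min(vals.min(), -math.sqrt(2)))
    return lo, 0.0


def _alignments(wq: int, wt: int, min_overlap: int):
    for off in range(-(wt - min_overlap), wq - min_overlap + 1):
        lo_q, hi_q = max(0, off), min(wq, off + wt)
        if hi_q - lo_q >= min_overlap:
            yield off, lo_q, hi_q


def compare_motifs(
    query: Motif,
    library: Sequence[Motif],
    min_overlap: int = 5,
    column_metric: Metric = "pearson",
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
    seed: int = 0,
) -> list[ComparisonResult]:
    """Rank library motifs by similarity to the query.

    Returns the best offset/orientation per target, ranked by combined
    p-value (ties broken by score, then name).
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if not library:
        raise ValueError("empty motif library")
    background = background or Background.uniform()

    def reg(m: Motif) -> np.ndarray:
        if m.kind != "frequency":
            raise ValueError("comparison requires frequency motifs")
        return regularize(m, background, pseudo_weight).matrix

    lib_mats = [reg(m) for m in library]
    q_mat = reg(query)

    if len(library) >= MIN_LIBRARY_FOR_NULL:
        null = _Null.from_columns(np.vstack(lib_mats), column_metric)
    else:
        null = _Null.analytic(column_metric, np.random.default_rng(seed))

    results = []
    for target, t_mat in zip(library, lib_mats):
        candidates = []
        n_configs = 0
        for orientation, mat in (("same", t_mat), ("revcomp", t_mat[::-1, ::-1])):
            for off, lo_q, hi_q in _alignments(
                query.width, target.width, min_overlap
            ):
                n_configs += 1
                cols = [
                    column_score(q_mat[i], mat[i - off], column_metric)
                    for i in range(lo_q, hi_q)
                ]
                total = float(sum(cols))
                p_raw = null.tail_of_sum(cols)
                candidates.append((p_raw, -total, off, orientation, cols))
        p_raw, neg_total, off, orientation, cols = min(candidates)
        results.append(
            ComparisonResult(
                query=query.name,
                target=target.name,
                offset=off,
                orientation=orientation,  # type: ignore[arg-type]
                column_scores=cols,
                score=-neg_total,
                combined_p=min(1.0, p_raw * n_configs),
            )
        )
    results.sort(key=lambda r: (r.combined_p, -r.score, r.target))
    return results


__all__ = ["ComparisonResult", "column_score", "compare_motifs"]
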