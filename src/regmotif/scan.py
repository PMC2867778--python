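"""Motif scanning: LOD and affinity scores, match p-values (exact
enumeration and compound importance sampling), genome/region scans,
cumulative LOD, the HMM w-score, and conservation filtering.

Null model for match p-values: a single window of W i.i.d. draws from the
order-0 background, one strand.  Multiple testing across windows is the
caller's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .core import AlignmentBlock, Genome, Location, LocationSet, encode
from .motif import Background, Motif, PSSM, to_pssm

NEG_INF = -np.inf


def lod_score(pssm: PSSM, word: str) -> float:
    """Sum of per-position log-odds for an N-free word of the PSSM's width."""
    codes = encode(word.upper())
    if len(codes) != pssm.width:
        raise ValueError(f"word length {len(codes)} != motif width {pssm.width}")
    if np.any(codes >= 4):
        raise ValueError("word contains N; no score")
    return float(pssm.matrix[np.arange(pssm.width), codes].sum())


def affinity_score(motif: Motif, word: str) -> float:
    """Product of normalized affinity weights over the word."""
    if motif.kind != "affinity":
        raise ValueError("affinity_score requires an affinity motif")
    codes = encode(word.upper())
    if len(codes) != motif.width:
        raise ValueError("word length != motif width")
    if np.any(codes >= 4):
        raise ValueError("word contains N; no score")
    return float(np.prod(motif.matrix[np.arange(motif.width), codes]))


def window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every window of a coded sequence against a W x 4 matrix;
    windows containing N score -inf."""
    W = matrix.shape[0]
    m = len(codes) - W + 1
    if m <= 0:
        return np.empty(0)
    out = np.zeros(m)
    for j in range(W):
        col = np.append(matrix[j], NEG_INF)  # code 4 (N) -> -inf
        out += col[codes[j : j + m]]
    return out


@dataclass
class ScoreDistribution:
    """P(score >= t) for single-window scores under the background.

    ``exhaustive``: exact survival function over all 4^W words.
    ``importance_sampling``: estimate from words drawn from a defensive
    mixture (half background, half PSSM-tilted product), with standard
    errors from the weighted indicator.
    """

    method: Literal["exhaustive", "importance_sampling"]
    scores: np.ndarray  # sorted ascending (unique for exhaustive)
    tail: Optional[np.ndarray] = None  # P(score >= scores[i]), exhaustive
    weights: Optional[np.ndarray] = None  # importance weights, sampling
    n_samples: int = 0
    seed: Optional[int] = None

    @property
    def min_score(self) -> float:
        return float(self.scores[0])

    @property
    def max_score(self) -> float:
        return float(self.scores[-1])

    def sf(self, t: float) -> float:
        """P(score >= t)."""
        if self.method == "exhaustive":
            i = np.searchsorted(self.scores, t, side="left")
            if i >= len(self.scores):
                return 0.0
            return float(self.tail[i])
        ind = self.scores >= t
        return float(np.mean(self.weights * ind))

    def se(self, t: float) -> float:
        """Standard error of the estimate at threshold t (sampling only)."""
        if self.method != "importance_sampling":
            return 0.0
        x = self.weights * (self.scores >= t)
        return float(np.std(x, ddof=1) / math.sqrt(len(x)))

    def score_at_pvalue(self, p: float) -> float:
        """Smallest score threshold t with sf(t) <= p (max_score + eps if none)."""
        if self.method == "exhaustive":
            idx = np.where(self.tail <= p)[0]
            if idx.size == 0:
                return self.max_score + 1e-9
            return float(self.scores[idx[0]])
        order = np.argsort(self.scores)[::-1]
        cum = np.cumsum(self.weights[order]) / len(self.scores)
        ok = np.where(cum <= p)[0]
        if ok.size == 0:
            return self.max_score + 1e-9
        return float(self.scores[order[ok[-1]]])


def _enumerate_scores(pssm: PSSM, background: Background):
    """All-word scores and probabilities by iterated outer sums/products."""
    scores = np.zeros(1)
    logp = np.zeros(1)
    logb = np.log(background.probs)
    for i in range(pssm.width):
        scores = (scores[:, None] + pssm.matrix[i][None, :]).ravel()
        logp = (logp[:, None] + logb[None, :]).ravel()
    return scores, np.exp(logp)


def score_pvalue(
    pssm: PSSM,
    background: Optional[Background] = None,
    method: Literal["exhaustive", "importance_sampling"] = "exhaustive",
    n_samples: int = 100_000,
    seed: Optional[int] = None,
    betas: Sequence[float] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
) -> ScoreDistribution:
    """Distribution of single-window LOD scores under the background.

    Exhaustive enumeration (W <= 10) sums exact word probabilities.  The
    compound importance sampler draws each word from an equal-weight
    mixture of geometrically tilted proposals q_beta(word) proportional to
    prod_i f'(i, w_i)^beta * b(w_i)^(1-beta); the temperature ladder
    ``betas`` spans background (beta = 0, the defensive component bounding
    the weights) through the fully motif-tilted distribution (beta = 1), so
    every score level is well sampled and the estimator
    mean[b(word)/q(word) * 1{score >= t}] has low variance at both lax and
    stringent thresholds.
    """
    background = background or Background(pssm.background)
    if method == "exhaustive":
        if pssm.width > 10:
            raise ValueError("exhaustive enumeration limited to width <= 10")
        scores, probs = _enumerate_scores(pssm, background)
        order = np.argsort(scores)
        scores, probs = scores[order], probs[order]
        uniq, start = np.unique(scores, return_index=True)
        agg = np.add.reduceat(probs, start)
        agg /= agg.sum()  # analytic total is 1; remove float dust
        tail = np.minimum(np.cumsum(agg[::-1])[::-1], 1.0)
        tail[0] = 1.0
        return ScoreDistribution("exhaustive", uniq, tail=tail)

    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    W = pssm.width
    b = background.probs
    f = pssm.freq
    # per-position tilted distributions, one (W, 4) table per temperature
    tables = []
    for beta in betas:
        t = f**beta * b ** (1 - beta)
        tables.append(t / t.sum(axis=1, keepdims=True))
    comp = rng.integers(len(betas), size=n_samples)
    u = rng.random((n_samples, W))
    draws = np.empty((n_samples, W), dtype=np.int64)
    for ci, table in enumerate(tables):
        rows = comp == ci
        cums = np.cumsum(table, axis=1)
        for j in range(W):
            draws[rows, j] = np.searchsorted(cums[j], u[rows, j], side="right")
    draws = np.clip(draws, 0, 3)
    idx = np.arange(W)
    logb = np.log(b)[draws].sum(axis=1)
    log_comps = np.stack(
        [np.log(table)[idx, draws].sum(axis=1) for table in tables]
    )
    logq = logsumexp(log_comps, axis=0) - math.log(len(betas))
    weights = np.exp(logb - logq)
    scores = pssm.matrix[idx, draws].sum(axis=1)
    return ScoreDistribution(
        "importance_sampling",
        scores,
        weights=weights,
        n_samples=n_samples,
        seed=seed,
    )


@dataclass
class MotifMatch:
    """A scored, strand-aware motif occurrence."""

    location: Location
    score: float
    word: str
    pvalue: Optional[float] = None

    @property
    def strand(self) -> str:
        return self.location.strand


def _scan_codes(
    codes: np.ndarray, pssm: PSSM, threshold: float, strands: str
) -> list[tuple[int, str, float]]:
    hits = []
    if strands in ("+", "both"):
        sc = window_scores(codes, pssm.matrix)
        for i in np.where(sc >= threshold)[0]:
            hits.append((int(i), "+", float(sc[i])))
    if strands in ("-", "both"):
        sc = window_scores(codes, pssm.matrix[::-1, ::-1])
        for i in np.where(sc >= threshold)[0]:
            hits.append((int(i), "-", float(sc[i])))
    return hits


def scan(
    target: Union[Genome, LocationSet],
    motif: Union[Motif, PSSM],
    threshold: float,
    threshold_type: Literal["lod", "pvalue"] = "lod",
    strands: Literal["+", "-", "both"] = "both",
    genome: Optional[Genome] = None,
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
    distribution: Optional[ScoreDistribution] = None,
) -> list[MotifMatch]:
    """Every window on the requested strands scoring >= threshold (or with
    match p-value <= threshold).  Windows containing N are skipped; matches
    are sorted by (sequence_id, start, strand).

    ``target`` is a Genome, or a LocationSet with ``genome`` supplied; a
    minus-strand hit means the reverse complement of the window matches.
    """
    if isinstance(motif, PSSM):
        pssm = motif
    else:
        if background is None:
            src = target if isinstance(target, Genome) else genome
            background = Background.from_genome(src) if src else Background.uniform()
        pssm = to_pssm(motif, background, pseudo_weight)

    if threshold_type == "pvalue":
        if distribution is None:
            if pssm.width <= 10:
                distribution = score_pvalue(pssm, method="exhaustive")
            else:
                distribution = score_pvalue(
                    pssm, method="importance_sampling", seed=0
                )
        cutoff = distribution.score_at_pvalue(threshold)
    else:
        cutoff = threshold

    if isinstance(target, Genome):
        pieces = [
            (sid, 0, seq) for sid, seq in target.items()
        ]
    else:
        if genome is None:
            raise ValueError("scanning a LocationSet requires a genome")
        pieces = [
            (loc.sequence_id, loc.start, genome[loc.sequence_id][loc.start : loc.end])
            for loc in target
        ]

    matches = []
    for sid, offset, seq in pieces:
        codes = encode(seq)
        for i, strand, score in _scan_codes(codes, pssm, cutoff, strands):
            start = offset + i
            word = seq[i : i + pssm.width]
            matches.append(
                MotifMatch(
                    Location(sid, start, start + pssm.width, strand, value=score),
                    score=score,
                    word=word,
                    pvalue=distribution.sf(score) if distribution else None,
                )
            )
    matches.sort(key=lambda m: (m.location.sequence_id, m.location.start, m.strand))
    return matches


def cumulative_lod(
    sequence: str,
    motif: Union[Motif, PSSM],
    background: Optional[Background] = None,
    floor: float = 0.0,
    pseudo_weight: float = 0.01,
) -> float:
    """Sum over all windows on both strands of max(lod - floor, 0).

    This positive-part window sum is this package's reading of a
    "cumulative" LOD enrichment score for a full sequence; the floor is
    configurable (default 0 bits).
    """
    pssm = motif if isinstance(motif, PSSM) else to_pssm(
        motif, background or Background.uniform(), pseudo_weight
    )
    codes = encode(sequence.upper())
    total = 0.0
    for mat in (pssm.matrix, pssm.matrix[::-1, ::-1]):
        sc = window_scores(codes, mat)
        finite = sc[np.isfinite(sc)]
        total += float(np.clip(finite - floor, 0.0, None).sum())
    return total


def _hmm_loglik(codes: np.ndarray, log_w: float, log_1mw: float,
                logb: np.ndarray, logm: np.ndarray, W: int) -> float:
    """Forward recursion log-likelihood: each step emits one background base
    (weight 1-w) or one motif W-mer (weight w)."""
    n = len(codes)
    ll = np.full(n + 1, NEG_INF)
    ll[0] = 0.0
    for i in range(1, n + 1):
        a = log_1mw + logb[codes[i - 1]] + ll[i - 1]
        if i >= W and np.isfinite(logm[i - W]):
            a = np.logaddexp(a, log_w + logm[i - W] + ll[i - W])
        ll[i] = a
    return float(ll[n])


def w_score(
    sequence: str,
    motif: Union[Motif, PSSM],
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
) -> float:
    """HMM-based whole-sequence motif enrichment score, in bits.

    The sequence is modeled as a concatenation of single background bases
    and motif-emitted W-mers; at each step the motif state is entered with
    weight w.  The score is log2 of the likelihood ratio between the model
    with the maximum-likelihood w-hat and the background-only model (w = 0).
    w-hat is found by bounded scalar search on log10 w in [-6, log10 0.5];
    the score is clamped at 0 since w -> 0 recovers the background model.
    """
    background = background or Background.uniform()
    pssm = motif if isinstance(motif, PSSM) else to_pssm(
        motif, background, pseudo_weight
    )
    codes = encode(sequence.upper())
    if np.any(codes >= 4):
        raise ValueError("w_score requires an N-free sequence")
    W = pssm.width
    logb = np.log(background.probs)
    logm = window_scores(codes, np.log(pssm.freq)) if len(codes) >= W else np.empty(0)

    ll0 = float(logb[codes].sum())

    def negll(u: float) -> float:
        w = 10.0 ** u
        return -_hmm_loglik(codes, math.log(w), math.log1p(-w), logb, logm, W)

    res = minimize_scalar(
        negll, bounds=(-6.0, math.log10(0.5)), method="bounded",
        options={"xatol": 1e-6},
    )
    best = -res.fun
    return max(0.0, (best - ll0) / math.log(2))


def filter_conserved(
    matches: Sequence[MotifMatch],
    blocks: Sequence[AlignmentBlock],
    pssm: PSSM,
    min_other_genomes: int = 1,
    score_fraction: float = 0.8,
    mode: Literal["strict", "lenient"] = "strict",
) -> list[MotifMatch]:
    """Keep matches conserved in aligned genomes (phylogenetic footprinting).

    A match is kept when, in the alignment block covering it, at least
    ``min_other_genomes`` non-reference rows contain — after gap removal,
    within the aligned span widened by one motif width on each side — a
    window scoring at least ``score_fraction`` times the reference match
    score (either strand).  Matches outside any block are dropped in strict
    mode, kept in lenient mode.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    W = pssm.width
    kept = []
    for match in matches:
        loc = match.location
        block = next(
            (
                b
                for b in blocks
                if b.reference.sequence_id == loc.sequence_id
                and b.reference.start <= loc.start
                and loc.end <= b.reference.end
            ),
            None,
        )
        if block is None:
            if mode == "lenient":
                kept.append(match)
            continue
        c1 = block.column_of(loc.start)
        c2 = block.column_of(loc.end - 1)
        lo = max(0, c1 - W)
        hi = min(block.width, c2 + 1 + W)
        needed = match.score * score_fraction
        n_ok = 0
        for name, row in block.rows.items():
            if name == block.reference_genome:
                continue
            sub = row[lo:hi].replace("-", "")
            if len(sub) < W:
                continue
            codes = encode(sub)
            best = NEG_INF
            for mat in (pssm.matrix, pssm.matrix[::-1, ::-1]):
                sc = window_scores(codes, mat)
                finite = sc[np.isfinite(sc)]
                if finite.size:
                    best = max(best, float(finite.max()))
            if best >= needed:
                n_ok += 1
        if n_ok >= min_other_genomes:
            kept.append(match)
    return kept


__all__ = [
    "MotifMatch",
    "ScoreDistribution",
    "affinity_score",
    "cumulative_lod",
    "filter_conserved",
    "lod_score",
    "scan",
    "score_pvalue",
    "w_score",
    "window_scores",
]
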