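"""Motif enrichment, positional-distribution and spacing tests, and GO
term enrichment.

Multiplicity conventions: Benjamini-Hochberg across a motif library and
across spacing gap-windows; Bonferroni across tested GO terms (the
GO TermFinder convention).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import Genome, Location, LocationSet, revcomp
from .intervals import GeneModel
from .motif import Background, Motif, PSSM, to_pssm
from .scan import MotifMatch, window_scores
from .core import encode

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Fisher exact (conditional hypergeometric, two-sided)

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    Conditional on the match total m = k1 + k2, sums the hypergeometric
    probabilities of all tables at most as probable as the observed one
    (with a tiny relative tolerance for float ties).
    """
    m = k1 + k2
    lo, hi = max(0, m - n2), min(n1, m)
    j = np.arange(lo, hi + 1)
    logpmf = (
        _log_binom(n1, j) + _log_binom(n2, m - j) - _log_binom(n1 + n2, m)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    obs = pmf[k1 - lo]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul-Erikson) for control-free enrichment

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts."""
    n = len(seq)
    if n <= 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [v for v in edges]
    for _ in range(200):
        lasts = {}
        for v in vertices:
            if v == last:
                continue
            lasts[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in lasts:
            seen = set()
            u = v
            while u != last:
                if u in seen or (u != last and u not in lasts):
                    ok = False
                    break
                seen.add(u)
                u = lasts[u]
            if not ok:
                break
        if ok:
            break
    else:  # pathological composition; give up rather than loop forever
        return seq
    pools = {}
    for v in vertices:
        lst = list(edges[v])
        if v in lasts:
            lst.remove(lasts[v])
        order = rng.permutation(len(lst))
        pools[v] = [lst[i] for i in order] + ([lasts[v]] if v in lasts else [])
    out = [seq[0]]
    u = seq[0]
    used = defaultdict(int)
    for _ in range(n - 1):
        nxt = pools[u][used[u]]
        used[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# motif enrichment

@dataclass
class EnrichmentResult:
    motif: str
    cutoffs: list[float]
    n_target_with_match: list[int]
    n_target: int
    n_control_with_match: list[int]
    n_control: int
    ratio: list[Optional[float]]
    p: list[float]
    q: Optional[list[float]] = None  # BH across a library, filled by caller


def _max_scores(sequences: Iterable[str], pssm: PSSM) -> np.ndarray:
    out = []
    for seq in sequences:
        codes = encode(seq)
        best = NEG_INF
        for mat in (pssm.matrix, pssm.matrix[::-1, ::-1]):
            sc = window_scores(codes, mat)
            finite = sc[np.isfinite(sc)]
            if finite.size:
                best = max(best, float(finite.max()))
        out.append(best)
    return np.array(out)


def motif_enrichment(
    motif: Union[Motif, PSSM],
    targets: LocationSet,
    controls: Optional[LocationSet],
    genome: Genome,
    cutoffs: Sequence[float],
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
    shuffle_seed: int = 0,
) -> EnrichmentResult:
    """Fraction of target vs control locations containing a match (best
    window on either strand >= cutoff), with a two-sided Fisher exact p per
    cutoff.  When ``controls`` is None the control sequences are
    dinucleotide-shuffled copies of the targets (seeded)."""
    cutoffs = list(cutoffs)
    if any(b >= a for a, b in zip(cutoffs[1:], cutoffs)):
        raise ValueError("cutoffs must be strictly increasing")
    if len(targets) == 0:
        raise ValueError("empty target set")
    if controls is not None and len(controls) == 0:
        raise ValueError("empty control set")
    if isinstance(motif, PSSM):
        pssm = motif
    else:
        pssm = to_pssm(motif, background or Background.from_genome(genome),
                       pseudo_weight)
    t_seqs = [genome.fetch(loc) for loc in targets]
    if controls is None:
        rng = np.random.default_rng(shuffle_seed)
        c_seqs = [dinucleotide_shuffle(s, rng) for s in t_seqs]
    else:
        c_seqs = [genome.fetch(loc) for loc in controls]
    ts = _max_scores(t_seqs, pssm)
    cs = _max_scores(c_seqs, pssm)
    nt, nc = len(ts), len(cs)
    kt_list, kc_list, ratios, ps = [], [], [], []
    for cut in cutoffs:
        kt = int((ts >= cut).sum())
        kc = int((cs >= cut).sum())
        kt_list.append(kt)
        kc_list.append(kc)
        ratios.append((kt / nt) / (kc / nc) if kc > 0 else None)
        ps.append(fisher_exact_two_sided(kt, nt, kc, nc))
    return EnrichmentResult(
        pssm.name, cutoffs, kt_list, nt, kc_list, nc, ratios, ps
    )


def library_enrichment(
    library: Sequence[Union[Motif, PSSM]],
    targets: LocationSet,
    controls: Optional[LocationSet],
    genome: Genome,
    cutoff_policy,
    **kwargs,
) -> list[EnrichmentResult]:
    """Per-motif enrichment with BH q-values across the library at each
    cutoff index.  ``cutoff_policy`` is either a shared list of cutoffs or a
    callable motif -> cutoffs (e.g. fractions of each motif's max score)."""
    if not library:
        raise ValueError("empty motif library")
    results = []
    for m in library:
        cuts = cutoff_policy(m) if callable(cutoff_policy) else cutoff_policy
        results.append(motif_enrichment(m, targets, controls, genome, cuts, **kwargs))
    n_cut = len(results[0].cutoffs)
    for ci in range(n_cut):
        ps = [r.p[ci] for r in results]
        qs = multipletests(ps, method="fdr_bh")[1]
        for r, q in zip(results, qs):
            if r.q is None:
                r.q = [None] * n_cut
            r.q[ci] = float(q)
    return results


# ---------------------------------------------------------------------------
# positional distribution

@dataclass
class DistributionResult:
    n: int
    mode: str
    method: str
    statistic: float
    pvalue: float
    ks_pvalue: float
    positions: np.ndarray  # values in [0, 1] actually tested
    underpowered: bool


def _match_locations(matches) -> list[Location]:
    out = []
    for m in matches:
        out.append(m.location if isinstance(m, MotifMatch) else m)
    return out


def positional_distribution(
    matches,
    anchors: LocationSet,
    mode: Literal["relative_in_region", "distance_to_point"] = "relative_in_region",
    n_bins: int = 10,
    min_n: int = 10,
) -> DistributionResult:
    """Test motif matches for non-uniform placement relative to anchors.

    Each match is assigned to its nearest anchor (midpoint distance, ties to
    the leftmost anchor).  The primary statistic is a chi-square
    goodness-of-fit against uniform over ``n_bins`` equal bins of the
    relative position; a KS test against uniform is reported alongside.
    """
    locs = _match_locations(matches)
    if len(locs) < 2:
        raise ValueError("need at least 2 matches")
    anchor_list = list(anchors)
    if not anchor_list:
        raise ValueError("empty anchor set")
    # geometric interval centers (base b occupies [b, b+1)); keeps positions
    # off the bin-edge lattice so boundary floats cannot bias the bin counts
    center = lambda x: (x.start + x.end) / 2.0
    rel = []
    for loc in locs:
        cands = [a for a in anchor_list if a.sequence_id == loc.sequence_id]
        if not cands:
            continue
        best = min(cands, key=lambda a: (abs(center(loc) - center(a)), a.start))
        if mode == "relative_in_region":
            rel.append(
                np.clip((center(loc) - best.start) / len(best), 0.0, 1.0)
            )
        else:
            rel.append(center(loc) - center(best))
    if len(rel) < 2:
        raise ValueError("fewer than 2 matches assignable to anchors")
    rel = np.asarray(rel, dtype=float)
    if mode == "distance_to_point":
        d = float(np.max(np.abs(rel)))
        rel = (rel + d) / (2 * d) if d > 0 else np.full_like(rel, 0.5)
    counts, _ = np.histogram(rel, bins=np.linspace(0.0, 1.0, n_bins + 1))
    chi2 = sps.chisquare(counts)
    ks = sps.kstest(rel, "uniform")
    return DistributionResult(
        n=len(rel),
        mode=mode,
        method="chi_square_bins",
        statistic=float(chi2.statistic),
        pvalue=float(max(chi2.pvalue, np.finfo(float).tiny)),
        ks_pvalue=float(max(ks.pvalue, np.finfo(float).tiny)),
        positions=rel,
        underpowered=len(rel) < min_n,
    )


# ---------------------------------------------------------------------------
# spacing

@dataclass
class SpacingResult:
    gap_histogram: np.ndarray  # counts for gaps 0..max_gap
    window: int
    window_starts: np.ndarray
    observed: np.ndarray  # per-window pair counts
    p: np.ndarray
    q: np.ndarray
    n_pairs: int
    empty: bool


def _edges_by_seq(locs: list[Location]):
    out: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for loc in locs:
        out[loc.sequence_id].append((loc.start, loc.end))
    return {k: np.array(v) for k, v in out.items()}


def _pair_gaps(a: np.ndarray, b: np.ndarray, same_set: bool) -> np.ndarray:
    """Facing-edge gaps for all (a, b) pairs; overlapping pairs excluded."""
    g1 = b[None, :, 0] - a[:, None, 1]  # b after a
    g2 = a[:, None, 0] - b[None, :, 1]  # a after b
    g = np.maximum(g1, g2)
    if same_set:
        np.fill_diagonal(g, -1)
    return g[g >= 0]


def spacing_analysis(
    matches_a,
    matches_b,
    max_gap: int,
    window: int,
    n_permutations: int = 1000,
    seed: int = 0,
    sequence_lengths: Optional[dict[str, int]] = None,
    genome: Optional[Genome] = None,
) -> SpacingResult:
    """Detect non-random spacing between two sets of motif matches.

    The observed gap histogram (facing-edge distances 0..max_gap, ordered
    pairs, same sequence, self-pairs excluded when the sets coincide) is
    compared per gap-window against a null in which B's matches are
    re-placed uniformly within their sequences (lengths preserved);
    empirical p per window is (1 + #{null >= observed}) / (1 + n_perms),
    BH-adjusted across windows.
    """
    if not (max_gap >= window >= 1):
        raise ValueError("need max_gap >= window >= 1")
    if sequence_lengths is None:
        if genome is None:
            raise ValueError("need sequence_lengths or genome")
        sequence_lengths = {sid: len(s) for sid, s in genome.items()}
    la = _match_locations(matches_a)
    lb = _match_locations(matches_b)
    same_set = matches_a is matches_b
    ea, eb = _edges_by_seq(la), _edges_by_seq(lb)

    n_windows = (max_gap + 1 + window - 1) // window
    window_starts = np.arange(n_windows) * window

    def hist_and_windows(b_edges: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        hist = np.zeros(max_gap + 1, dtype=int)
        for sid, a in ea.items():
            if sid not in b_edges:
                continue
            g = _pair_gaps(a, b_edges[sid], same_set)
            g = g[g <= max_gap]
            hist += np.bincount(g, minlength=max_gap + 1)
        wc = np.add.reduceat(
            np.pad(hist, (0, n_windows * window - len(hist))), window_starts
        )
        return hist, wc

    obs_hist, obs_windows = hist_and_windows(eb)
    n_pairs = int(obs_hist.sum())
    if n_pairs == 0:
        return SpacingResult(
            obs_hist, window, window_starts, obs_windows,
            np.ones(n_windows), np.ones(n_windows), 0, empty=True,
        )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_windows, dtype=int)
    b_lengths = {sid: arr[:, 1] - arr[:, 0] for sid, arr in eb.items()}
    for _ in range(n_permutations):
        perm = {}
        for sid, lens in b_lengths.items():
            L = sequence_lengths[sid]
            starts = rng.integers(0, np.maximum(L - lens + 1, 1))
            perm[sid] = np.column_stack([starts, starts + lens])
        _, wc = hist_and_windows(perm)
        exceed += wc >= obs_windows
    p = (1 + exceed) / (1 + n_permutations)
    q = multipletests(p, method="fdr_bh")[1]
    return SpacingResult(
        obs_hist, window, window_starts, obs_windows, p, q, n_pairs, empty=False
    )


# ---------------------------------------------------------------------------
# GO enrichment

@dataclass
class GOResult:
    term: str
    k: int  # study genes with term (ancestors propagated)
    n: int  # study size
    K: int  # universe genes with term
    N: int  # universe size
    p: float
    p_corrected: float
    name: Optional[str] = None


def _ancestor_closure(ancestry: dict[str, Iterable[str]]) -> dict[str, frozenset]:
    memo: dict[str, frozenset] = {}
    visiting: set[str] = set()

    def visit(term: str) -> frozenset:
        if term in memo:
            return memo[term]
        if term in visiting:
            raise ValueError(f"cycle in term ancestry at {term!r}")
        visiting.add(term)
        anc: set[str] = set()
        for parent in ancestry.get(term, ()):  # roots have no parents
            anc.add(parent)
            anc |= visit(parent)
        visiting.discard(term)
        memo[term] = frozenset(anc)
        return memo[term]

    for t in list(ancestry):
        visit(t)
    return memo


def propagate_annotations(
    annotations: dict[str, Iterable[str]], ancestry: dict[str, Iterable[str]]
) -> dict[str, frozenset]:
    """Extend each gene's terms with all ancestor terms (raises on cycles)."""
    closure = _ancestor_closure(ancestry)
    out = {}
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            full.add(t)
            if t in closure:
                full |= closure[t]
            else:
                full |= _ancestor_closure({t: ancestry.get(t, ())}).get(t, frozenset())
        out[gene] = frozenset(full)
    return out


def go_enrichment(
    study_genes: Iterable[str],
    annotations: dict[str, Iterable[str]],
    ancestry: dict[str, Iterable[str]],
    universe_genes: Iterable[str],
) -> list[GOResult]:
    """Hypergeometric upper-tail enrichment per term with >= 1 study gene,
    Bonferroni-corrected by the number of tested terms."""
    study = list(dict.fromkeys(study_genes))
    universe = list(dict.fromkeys(universe_genes))
    uset = set(universe)
    missing = [g for g in study if g not in uset]
    if missing:
        raise ValueError(f"study genes not in universe: {missing[:5]}")
    full = propagate_annotations(annotations, ancestry)
    term_universe: dict[str, int] = defaultdict(int)
    term_study: dict[str, int] = defaultdict(int)
    sset = set(study)
    for gene in universe:
        for t in full.get(gene, ()):
            term_universe[t] += 1
            if gene in sset:
                term_study[t] += 1
    tested = sorted(t for t, k in term_study.items() if k >= 1)
    n, N = len(study), len(universe)
    results = []
    for t in tested:
        k, K = term_study[t], term_universe[t]
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(
            GOResult(t, k, n, K, N, p, min(1.0, p * len(tested)))
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


# ---------------------------------------------------------------------------
# upstream-region utilities

def upstream_region(
    gene: GeneModel,
    genes: Sequence[GeneModel],
    genome: Genome,
    upstream_bp: int,
    truncate_at_neighbors: bool = True,
) -> Optional[Location]:
    """The strand-aware upstream window (TSS - upstream_bp, TSS), truncated
    at sequence edges and, by default, at neighboring gene bodies (the
    sub-interval touching the TSS is kept)."""
    gl = gene.location
    L = genome.length(gl.sequence_id)
    if gl.strand == "+":
        ws, we = max(0, gl.start - upstream_bp), gl.start
    else:
        ws, we = gl.end, min(L, gl.end + upstream_bp)
    if ws >= we:
        return None
    if truncate_at_neighbors:
        for other in genes:
            if other.gene_id == gene.gene_id:
                continue
            ol = other.location
            if ol.sequence_id != gl.sequence_id or ol.end <= ws or ol.start >= we:
                continue
            if gl.strand == "+":
                ws = max(ws, ol.end)
            else:
                we = min(we, ol.start)
    if ws >= we:
        return None
    return Location(gl.sequence_id, ws, we, gl.strand)


def best_upstream_scores(
    library: Sequence[Union[Motif, PSSM]],
    genes: Sequence[GeneModel],
    genome: Genome,
    upstream_bp: int,
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
    truncate_at_neighbors: bool = True,
) -> pd.DataFrame:
    """Per gene, per motif: the maximum window score (both strands) in the
    gene's upstream region; -inf when no N-free window exists."""
    background = background or Background.from_genome(genome)
    pssms = [
        m if isinstance(m, PSSM) else to_pssm(m, background, pseudo_weight)
        for m in library
    ]
    rows = {}
    for gene in genes:
        region = upstream_region(
            gene, genes, genome, upstream_bp, truncate_at_neighbors
        )
        seq = genome[region.sequence_id][region.start : region.end] if region else ""
        scores = []
        for pssm in pssms:
            scores.append(_max_scores([seq], pssm)[0] if seq else NEG_INF)
        rows[gene.gene_id] = scores
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[p.name for p in pssms]
    )


def motif_go_association(
    motif: Union[Motif, PSSM],
    genes: Sequence[GeneModel],
    genome: Genome,
    upstream_bp: int,
    score_cutoff: float,
    annotations: dict[str, Iterable[str]],
    ancestry: dict[str, Iterable[str]],
    background: Optional[Background] = None,
    pseudo_weight: float = 0.01,
) -> list[GOResult]:
    """GO enrichment of genes whose upstream region contains a strong motif
    instance (best window score >= cutoff), against all genes as universe."""
    width = motif.width
    if upstream_bp < width:
        raise ValueError("upstream_bp must be >= motif width")
    table = best_upstream_scores(
        [motif], genes, genome, upstream_bp, background, pseudo_weight
    )
    study = [g for g in table.index if table.loc[g].iloc[0] >= score_cutoff]
    if not study:
        return []
    return go_enrichment(
        study, annotations, ancestry, [g.gene_id for g in genes]
    )


__all__ = [
    "DistributionResult",
    "EnrichmentResult",
    "GOResult",
    "SpacingResult",
    "best_upstream_scores",
    "dinucleotide_shuffle",
    "fisher_exact_two_sided",
    "go_enrichment",
    "library_enrichment",
    "motif_enrichment",
    "motif_go_association",
    "positional_distribution",
    "propagate_annotations",
    "spacing_analysis",
    "upstream_region",
]
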