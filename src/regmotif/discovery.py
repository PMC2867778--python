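"""De-novo motif discovery by Gibbs sampling (ZOOPS site model).

One site per sequence is held as latent state; each update holds one
sequence out, builds the count matrix from the remaining sites, and
re-samples the held-out sequence's site (or no site, with the ZOOPS
prior) proportional to the motif/background likelihood ratio.  The
best-scoring configuration seen at any sweep (the predictive-update
maximum) is reported; restarts are independent chains and the best
``n_motifs`` motifs are returned with previously found sites masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import Genome, LocationSet, encode, revcomp
from .motif import BASES, Background, Motif


@dataclass
class GibbsConfig:
    """Sampler settings.

    ``zoops_prob`` is the prior probability that a sequence contains no
    site; ``iterations`` counts single-sequence updates (taken round-robin);
    restart r uses RNG seed ``seed + r``.
    """

    width: int
    n_motifs: int = 1
    iterations: int = 2000
    n_restarts: int = 5
    seed: int = 0
    background_order: int = 0
    zoops_prob: float = 0.1
    both_strands: bool = True
    pseudocount: float = 1.0  # total pseudo-sites, spread as background

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if self.iterations < 100:
            raise ValueError("need >= 100 iterations")
        if not 0 <= self.zoops_prob < 1:
            raise ValueError("zoops_prob must be in [0, 1)")


@dataclass
class GibbsResult:
    motif: Motif
    sites: list[tuple[int, int, str]]  # (sequence index, start, strand)
    score: float  # sum over sites of log2 f'(site)/bg(site)


Site = Optional[tuple[int, int]]  # (window start, strand index 0='+' 1='-')


class _Sampler:
    def __init__(self, codes: list[np.ndarray], config: GibbsConfig,
                 background: Background):
        self.cfg = config
        self.codes = codes
        W = config.width
        self.logb = np.log(background.probs)
        # per sequence: window index matrices for + and - words, and the
        # background log-prob of each genomic window (strand independent)
        self.windows: list[Optional[dict]] = []
        for c in codes:
            m = len(c) - W + 1
            if m <= 0:
                self.windows.append(None)
                continue
            idx = np.lib.stride_tricks.sliding_window_view(c, W)
            ok = np.all(idx < 4, axis=1)
            if not ok.any():
                self.windows.append(None)
                continue
            pos = np.where(ok)[0]
            fwd = idx[pos].astype(np.int64)
            rev = 3 - fwd[:, ::-1]
            bglp = np.array(
                [background.logp_word(w, log2=False) for w in fwd]
            )
            self.windows.append({"pos": pos, "fwd": fwd, "rev": rev, "bglp": bglp})

    def _site_word(self, i: int, site: Site) -> np.ndarray:
        win = self.windows[i]
        j = int(np.searchsorted(win["pos"], site[0]))
        return win["fwd"][j] if site[1] == 0 else win["rev"][j]

    def _counts(self, sites: list[Site], skip: int = -1) -> tuple[np.ndarray, int]:
        W = self.cfg.width
        counts = np.zeros((W, 4))
        n = 0
        for i, site in enumerate(sites):
            if i == skip or site is None:
                continue
            counts[np.arange(W), self._site_word(i, site)] += 1
            n += 1
        return counts, n

    def _log_freq(self, counts: np.ndarray, n: int) -> np.ndarray:
        pc = self.cfg.pseudocount
        f = (counts + pc * np.exp(self.logb)) / (n + pc)
        return np.log(f)

    def config_score(self, sites: list[Site]) -> float:
        counts, n = self._counts(sites)
        if n == 0:
            return 0.0
        logf = self._log_freq(counts, n)
        total = 0.0
        for i, site in enumerate(sites):
            if site is None:
                continue
            w = self._site_word(i, site)
            total += float((logf[np.arange(self.cfg.width), w]
                            - self.logb[w]).sum())
        return total / math.log(2)

    def run(self, seed: int) -> tuple[list[Site], float]:
        rng = np.random.default_rng(seed)
        cfg = self.cfg
        n_seq = len(self.codes)
        strands = (0, 1) if cfg.both_strands else (0,)

        sites: list[Site] = []
        for win in self.windows:
            if win is None:
                sites.append(None)
            else:
                sites.append(
                    (int(rng.choice(win["pos"])), int(rng.choice(strands)))
                )

        gamma = cfg.zoops_prob
        log_gamma = math.log(gamma) if gamma > 0 else -math.inf
        best_sites, best_score = list(sites), self.config_score(sites)
        arangeW = np.arange(cfg.width)

        for it in range(cfg.iterations):
            i = it % n_seq
            win = self.windows[i]
            if win is not None:
                counts, n = self._counts(sites, skip=i)
                logf = self._log_freq(counts, n)
                ratios = []
                for s in strands:
                    words = win["fwd"] if s == 0 else win["rev"]
                    lm = logf[arangeW, words].sum(axis=1)
                    ratios.append(lm - win["bglp"])
                logr = np.concatenate(ratios)
                m_total = len(logr)
                logw = np.concatenate(
                    [[log_gamma], math.log((1 - gamma) / m_total) + logr]
                )
                logw -= logw.max()
                p = np.exp(logw)
                p /= p.sum()
                pick = int(rng.choice(len(p), p=p))
                if pick == 0:
                    sites[i] = None
                else:
                    k = pick - 1
                    s, j = divmod(k, len(win["pos"]))
                    sites[i] = (int(win["pos"][j]), strands[s])
            if i == n_seq - 1:  # end of sweep: predictive-update tracking
                sc = self.config_score(sites)
                if sc > best_score:
                    best_score, best_sites = sc, list(sites)
        return best_sites, best_score


def _extract_sequences(
    target: Union[Sequence[str], LocationSet], genome: Optional[Genome]
) -> list[str]:
    if isinstance(target, LocationSet):
        if genome is None:
            raise ValueError("LocationSet input requires a genome")
        return [genome.fetch(loc) for loc in target]
    return [s.upper() for s in target]


def gibbs_discover(
    sequences: Union[Sequence[str], LocationSet],
    config: GibbsConfig,
    genome: Optional[Genome] = None,
    background: Optional[Background] = None,
) -> list[GibbsResult]:
    """Discover up to ``config.n_motifs`` motifs de novo.

    Returns one :class:`GibbsResult` per motif, best restart first; sites of
    each reported motif are masked (set to N) before searching for the next.
    """
    seqs = _extract_sequences(sequences, genome)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if all(len(s) < config.width for s in seqs):
        raise ValueError("all sequences shorter than the motif width")
    if background is None:
        background = Background.from_sequences(
            seqs, order=config.background_order
        )

    results = []
    work = list(seqs)
    for motif_index in range(config.n_motifs):
        sampler = _Sampler([encode(s) for s in work], config, background)
        best: Optional[tuple[list[Site], float]] = None
        for r in range(config.n_restarts):
            seed = config.seed + r + 100_003 * motif_index
            sites, score = sampler.run(seed)
            if best is None or score > best[1]:
                best = (sites, score)
        sites, score = best
        W = config.width
        counts = np.zeros((W, 4))
        site_list: list[tuple[int, int, str]] = []
        for i, site in enumerate(sites):
            if site is None:
                continue
            word = sampler._site_word(i, site)
            counts[np.arange(W), word] += 1
            site_list.append((i, site[0], "+" if site[1] == 0 else "-"))
        if not site_list:
            break
        motif = Motif(f"gibbs_{motif_index + 1}", counts)
        results.append(GibbsResult(motif, site_list, score))
        work = mask_sites(
            work, [(i, s, s + W) for i, s, _ in site_list]
        )
    return results


def mask_sites(
    sequences: Sequence[str], sites: Sequence[tuple[int, int, int]]
) -> list[str]:
    """Replace site spans (sequence index, start, end) with N."""
    out = [list(s) for s in sequences]
    for i, start, end in sites:
        if not (0 <= start < end <= len(out[i])):
            raise ValueError(f"site ({i}, {start}, {end}) out of bounds")
        out[i][start:end] = "N" * (end - start)
    return ["".join(s) for s in out]


def motif_correlation(a: Motif, b: Motif, min_overlap: int = 6) -> float:
    """Best Pearson correlation between two motifs' frequency matrices over
    all offsets (>= min_overlap overlapping columns) and both orientations.
    A convenience for recovery metrics."""
    best = -1.0
    for cand in (b, b.revcomp()):
        wa, wb = a.width, cand.width
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, off), min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            xa = a.matrix[lo_a:hi_a].ravel()
            xb = cand.matrix[lo_a - off : hi_a - off].ravel()
            if np.std(xa) < 1e-12 or np.std(xb) < 1e-12:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            best = max(best, r)
    return best


__all__ = [
    "GibbsConfig",
    "GibbsResult",
    "gibbs_discover",
    "mask_sites",
    "motif_correlation",
]
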