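"""Synthetic data generators: random genomes, planted motif sites,
ChIP-like tracks, alignment blocks, gene models and GO annotations.

Every generator is a pure function of its arguments and seed, and every
planted structure is returned together with its truth set so recovery
metrics can be computed without re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .core import (
    AlignmentBlock,
    DataTrack,
    Genome,
    Location,
    LocationSet,
    TrackRun,
    revcomp,
)
from .intervals import GeneModel
from .motif import BASES, Motif


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic dataset (CLI entry point)."""

    seed: int
    genome_length: int = 10_000
    gc_fraction: float = 0.5
    motif_consensus: str = "TTGACGTCAA"
    motif_major_prob: float = 0.95
    n_sites: int = 20
    site_rule: Literal["uniform", "fixed_offset", "fixed_gap"] = "uniform"
    peak_width: int = 60
    peak_height: float = 10.0
    peak_noise_sd: float = 0.5
    n_species: int = 3
    substitution_rate: float = 0.1
    n_genes: int = 20
    n_terms: int = 3
    enriched_term_size: int = 5


def make_genome(
    length: int,
    seed: int,
    gc_fraction: float = 0.5,
    name: str = "synthetic",
    sequence_ids: Sequence[str] = ("chr1",),
) -> Genome:
    """I.i.d. random genome with P(G) + P(C) = gc_fraction."""
    if length < 100:
        raise ValueError("length must be >= 100")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    seqs = {
        sid: "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
        for sid in sequence_ids
    }
    return Genome(name, seqs)


def planted_pwm(
    consensus: str = "TTGACGTCAA", major_prob: float = 0.95, name: str = "planted"
) -> Motif:
    """A frequency motif concentrated on a consensus word: the consensus
    base gets ``major_prob`` and the rest is split evenly.  major_prob 0.95
    over 10 columns gives ~16.3 bits of information content."""
    rows = []
    minor = (1 - major_prob) / 3
    for ch in consensus.upper():
        row = [minor] * 4
        row[BASES.index(ch)] = major_prob
        rows.append(row)
    return Motif(name, np.array(rows))


def sample_site(motif: Motif, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=motif.matrix[i])] for i in range(motif.width)
    )


def plant_sites(
    genome: Genome,
    motif: Motif,
    n_sites: int,
    seed: int,
    rule: Literal["uniform", "fixed_offset"] = "uniform",
    consensus_mode: bool = False,
    fixed_offset: int = 0,
    sequence_id: Optional[str] = None,
    min_gap: int = 1,
) -> tuple[Genome, LocationSet]:
    """Splice ``n_sites`` motif instances into a genome without overlap.

    Sites are sampled from the motif's frequency columns (or the consensus
    word in ``consensus_mode``).  Returns the modified genome and the truth
    location set (labels carry the planted words).
    """
    rng = np.random.default_rng(seed)
    W = motif.width
    sid = sequence_id or next(iter(genome.sequences))
    seq = list(genome[sid])
    L = len(seq)
    placed: list[tuple[int, int]] = []
    locs = []
    attempts = 0
    while len(placed) < n_sites:
        attempts += 1
        if attempts > 1000 * max(n_sites, 1):
            raise ValueError("cannot place sites without overlap")
        if rule == "fixed_offset":
            start = fixed_offset + len(placed) * (W + min_gap)
            if start + W > L:
                raise ValueError("cannot place sites without overlap")
        else:
            start = int(rng.integers(0, L - W + 1))
        if any(start < e + min_gap and s - min_gap < start + W for s, e in placed):
            continue
        word = motif.consensus() if consensus_mode else sample_site(motif, rng)
        seq[start : start + W] = word
        placed.append((start, start + W))
        locs.append(Location(sid, start, start + W, "+", label=word))
    new_sequences = dict(genome.sequences)
    new_sequences[sid] = "".join(seq)
    return Genome(genome.name, new_sequences), LocationSet("true_sites", locs)


def planted_sequence_set(
    seed: int,
    motif: Optional[Motif] = None,
    n_sequences: int = 20,
    length: int = 100,
    plant: bool = True,
) -> tuple[list[str], list[int]]:
    """Uniform-random sequences with (optionally) one motif site sampled
    from the PWM and planted per sequence.  Returns sequences and the true
    site start per sequence (-1 when nothing was planted)."""
    motif = motif or planted_pwm()
    rng = np.random.default_rng(seed)
    W = motif.width
    seqs, starts = [], []
    for _ in range(n_sequences):
        seq = list("".join(BASES[c] for c in rng.choice(4, size=length)))
        if plant:
            start = int(rng.integers(0, length - W + 1))
            seq[start : start + W] = sample_site(motif, rng)
            starts.append(start)
        else:
            starts.append(-1)
        seqs.append("".join(seq))
    return seqs, starts


def make_chip_track(
    genome: Genome,
    sites: LocationSet,
    peak_width: int,
    height: float,
    noise_sd: float,
    seed: int,
) -> DataTrack:
    """Baseline-0 track with a triangular bump of the given height centered
    on each site, plus i.i.d. Gaussian noise."""
    if peak_width < 1:
        raise ValueError("peak_width must be >= 1")
    rng = np.random.default_rng(seed)
    runs = []
    by_seq: dict[str, list[Location]] = {}
    for loc in sites:
        by_seq.setdefault(loc.sequence_id, []).append(loc)
    for sid, seq in genome.items():
        L = len(seq)
        values = rng.normal(0.0, noise_sd, size=L) if noise_sd > 0 else np.zeros(L)
        for loc in by_seq.get(sid, []):
            center = int(round(loc.midpoint))
            half = peak_width // 2
            for pos in range(max(0, center - half), min(L, center + half + 1)):
                values[pos] += height * (1 - abs(pos - center) / (half + 1))
        runs.append(TrackRun(sid, 0, 1, 1, values))
    return DataTrack(runs, validate=False)


def make_alignment(
    genome: Genome,
    regions: LocationSet,
    n_species: int,
    substitution_rate: float,
    seed: int,
    conserve: Optional[LocationSet] = None,
) -> list[AlignmentBlock]:
    """One gapless alignment block per region: each non-reference row is the
    reference with i.i.d. substitutions at ``substitution_rate``, except
    within ``conserve`` truth sites (rate 0 there)."""
    if not 0 <= substitution_rate <= 0.75:
        raise ValueError("substitution_rate must be in [0, 0.75]")
    rng = np.random.default_rng(seed)
    conserved_mask: dict[str, np.ndarray] = {}
    if conserve is not None:
        for loc in conserve:
            mask = conserved_mask.setdefault(
                loc.sequence_id, np.zeros(genome.length(loc.sequence_id), dtype=bool)
            )
            mask[loc.start : loc.end] = True
    blocks = []
    for region in regions:
        ref = genome[region.sequence_id][region.start : region.end]
        rows = {genome.name: ref}
        keep = conserved_mask.get(region.sequence_id)
        for s in range(1, n_species):
            row = list(ref)
            for i in range(len(row)):
                if keep is not None and keep[region.start + i]:
                    continue
                if rng.random() < substitution_rate:
                    choices = [b for b in BASES if b != row[i]]
                    row[i] = choices[int(rng.integers(3))]
            rows[f"species_{s}"] = "".join(row)
        blocks.append(
            AlignmentBlock(
                reference=Location(region.sequence_id, region.start, region.end),
                reference_genome=genome.name,
                rows=rows,
            )
        )
    return blocks


def make_genes_and_go(
    genome: Genome,
    n_genes: int,
    n_terms: int,
    enriched_term_size: int,
    seed: int,
    gene_length: int = 120,
    spacing: int = 200,
    sequence_id: Optional[str] = None,
) -> tuple[list[GeneModel], dict[str, set[str]], dict[str, set[str]]]:
    """Non-overlapping genes on alternating strands plus a shallow two-level
    GO DAG in which term_1 is annotated to the first ``enriched_term_size``
    genes (the designated enriched subset); remaining genes get random other
    terms."""
    rng = np.random.default_rng(seed)
    sid = sequence_id or next(iter(genome.sequences))
    L = genome.length(sid)
    if n_genes * (gene_length + spacing) > L:
        raise ValueError("genes do not fit with the requested spacing")
    genes = []
    for i in range(n_genes):
        start = i * (gene_length + spacing) + spacing
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(
                f"gene_{i + 1}",
                Location(sid, start, start + gene_length, strand),
            )
        )
    terms = [f"term_{i + 1}" for i in range(n_terms)]
    root = "term_root"
    ancestry = {t: {root} for t in terms}
    ancestry[root] = set()
    annotations: dict[str, set[str]] = {}
    for i, gene in enumerate(genes):
        if i < enriched_term_size:
            annotations[gene.gene_id] = {terms[0]}
        elif n_terms > 1:
            annotations[gene.gene_id] = {terms[1 + int(rng.integers(n_terms - 1))]}
        else:
            annotations[gene.gene_id] = set()
    return genes, annotations, ancestry


__all__ = [
    "FixtureSpec",
    "make_alignment",
    "make_chip_track",
    "make_genes_and_go",
    "make_genome",
    "plant_sites",
    "planted_pwm",
    "planted_sequence_set",
    "sample_site",
]
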