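"""Set algebra on location sets, gene assignment, and peak extraction.

Set operations use per-base semantics: the result of union / intersection /
subtraction is the per-base membership set re-assembled into maximal
disjoint intervals.  Record identity (labels, values) is not preserved —
this is interval algebra, not an overlap join.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import DataTrack, Genome, Location, LocationSet, UNSTRANDED, merge_intervals

SetOp = Literal["union", "intersection", "subtraction"]


@dataclass
class GeneModel:
    """A gene with a stranded body interval and optional exons.

    The transcription start site (TSS) is the strand-aware 5' end:
    ``start`` for + genes and ``end - 1`` for - genes.
    """

    gene_id: str
    location: Location
    exons: Optional[list[Location]] = None

    def __post_init__(self) -> None:
        if self.location.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: location must be stranded")
        if self.exons:
            for ex in self.exons:
                if ex.start < self.location.start or ex.end > self.location.end:
                    raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        loc = self.location
        return loc.start if loc.strand == "+" else loc.end - 1

    @property
    def strand(self) -> str:
        return self.location.strand


@dataclass
class GeneAssignment:
    region: Location
    genes: list[tuple[str, int, str]]  # (gene_id, distance bp, relation)


def _pairs_by_seq(locset: LocationSet) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for loc in locset:
        out.setdefault(loc.sequence_id, []).append((loc.start, loc.end))
    return out


def _subtract_merged(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def _intersect_merged(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def set_operation(
    op: SetOp,
    a: LocationSet,
    b: LocationSet,
    stranded: bool = False,
    name: Optional[str] = None,
) -> LocationSet:
    """Union, intersection or subtraction of two location sets (per-base).

    By default strand is ignored and the result is unstranded; with
    ``stranded=True`` each strand class (+, -, unstranded) is handled
    separately and preserved in the output.
    """
    if op not in ("union", "intersection", "subtraction"):
        raise ValueError(f"unknown set operation {op!r}")

    def groups(ls: LocationSet):
        out: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for loc in ls:
            key = loc.strand if stranded else UNSTRANDED
            out.setdefault(key, {}).setdefault(loc.sequence_id, []).append(
                (loc.start, loc.end)
            )
        return out

    ga, gb = groups(a), groups(b)
    locs = []
    for strand in sorted(set(ga) | set(gb)):
        seqs_a = ga.get(strand, {})
        seqs_b = gb.get(strand, {})
        for sid in sorted(set(seqs_a) | set(seqs_b)):
            ma = merge_intervals(seqs_a.get(sid, []))
            mb = merge_intervals(seqs_b.get(sid, []))
            if op == "union":
                res = merge_intervals(ma + mb)
            elif op == "intersection":
                res = _intersect_merged(ma, mb)
            else:
                res = _subtract_merged(ma, mb)
            locs.extend(Location(sid, s, e, strand) for s, e in res)
    return LocationSet(name or f"{a.name}_{op}_{b.name}", locs)


def assign_to_genes(
    regions: LocationSet,
    genes: Sequence[GeneModel],
    max_upstream: int,
    max_downstream: int = 0,
    allow_multiple: bool = True,
) -> list[GeneAssignment]:
    """Assign regions to genes by overlap or strand-aware upstream/downstream
    proximity.

    A gene is assigned when the region overlaps its body (distance 0), or
    when the region lies on the gene's upstream (5') side with its nearest
    edge within ``max_upstream`` bp of the TSS, or on the downstream side
    within ``max_downstream`` bp of the gene's 3' end.  With
    ``allow_multiple=False`` only the nearest gene(s) are kept; equal
    distances keep all tied genes.
    """
    if max_upstream < 0 or max_downstream < 0:
        raise ValueError("distances must be >= 0")
    out = []
    for region in regions:
        hits: list[tuple[str, int, str]] = []
        for gene in genes:
            gl = gene.location
            if gl.sequence_id != region.sequence_id:
                continue
            if region.overlaps(gl):
                hits.append((gene.gene_id, 0, "overlapping"))
                continue
            if region.end <= gl.start:
                d = gl.start - region.end + 1  # gap from last region base to gene
                side = "upstream" if gl.strand == "+" else "downstream"
            else:
                d = region.start - gl.end + 1
                side = "downstream" if gl.strand == "+" else "upstream"
            limit = max_upstream if side == "upstream" else max_downstream
            if d <= limit:
                hits.append((gene.gene_id, d, side))
        if not allow_multiple and hits:
            dmin = min(h[1] for h in hits)
            hits = [h for h in hits if h[1] == dmin]
        hits.sort(key=lambda h: (h[1], h[0]))
        out.append(GeneAssignment(region, hits))
    return out


def extract_peaks(
    track: DataTrack,
    threshold: float,
    min_width: int = 1,
    merge_gap: int = 0,
    name: str = "peaks",
) -> LocationSet:
    """Threshold-based peak extraction from a numeric track.

    Maximal runs of bases with value >= threshold are found; runs separated
    by <= ``merge_gap`` uncovered/sub-threshold bases are merged; merged runs
    shorter than ``min_width`` are dropped.  Each peak's value is the maximum
    over the run and its label records the leftmost summit base.
    """
    if min_width < 1 or merge_gap < 0:
        raise ValueError("min_width >= 1 and merge_gap >= 0 required")
    locs = []
    for sid in track.sequence_ids():
        dense = track.dense(sid)
        above = np.where(np.nan_to_num(dense, nan=-np.inf) >= threshold)[0]
        if above.size == 0:
            continue
        # group consecutive above-threshold bases, then merge across small gaps
        breaks = np.where(np.diff(above) > 1)[0]
        runs = [
            (seg[0], seg[-1] + 1)
            for seg in np.split(above, breaks + 1)
        ]
        merged: list[tuple[int, int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        for s, e in merged:
            if e - s < min_width:
                continue
            window = np.nan_to_num(dense[s:e], nan=-np.inf)
            summit = s + int(np.argmax(window))
            locs.append(
                Location(
                    sid, int(s), int(e),
                    value=float(np.max(window)),
                    label=f"summit={summit}",
                )
            )
    return LocationSet(name, locs)


def filter_by_flag(
    locset: LocationSet, keep: Iterable[Optional[str]]
) -> LocationSet:
    """Keep locations whose tri-state flag is in ``keep`` (order preserved).

    ``None`` in ``keep`` retains unflagged locations.
    """
    keep = set(keep)
    return LocationSet(
        locset.name,
        [loc for loc in locset if loc.flag in keep],
        sort=False,
    )


__all__ = [
    "GeneAssignment",
    "GeneModel",
    "assign_to_genes",
    "extract_peaks",
    "filter_by_flag",
    "set_operation",
]
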