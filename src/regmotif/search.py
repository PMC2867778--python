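"""Exact/degenerate (IUPAC) pattern search and direct/inverted repeat finding.

Pattern symbols use the 15 IUPAC codes; a genome N never matches any
pattern symbol (including pattern N, which stands for {A,C,G,T} only).
All overlapping hits are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .core import Genome, Location, LocationSet, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def _compile(pattern: str) -> re.Pattern:
    try:
        body = "".join(f"[{IUPAC[c]}]" for c in pattern)
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC symbol {exc.args[0]!r}") from None
    return re.compile(f"(?=({body}))")  # lookahead -> overlapping matches


def find_pattern(
    genome: Genome,
    pattern: str,
    strands: Literal["+", "-", "both"] = "both",
    name: str | None = None,
) -> LocationSet:
    """All positions where every pattern symbol's base set contains the
    genome base.  Minus-strand hits are matches of the reverse-complement
    pattern, reported with strand '-'; the label is the plus-strand word.
    """
    if not pattern:
        raise ValueError("empty pattern")
    pattern = pattern.upper()
    wanted = ("+", "-") if strands == "both" else (strands,)
    locs = []
    for strand in wanted:
        pat = _compile(pattern if strand == "+" else iupac_revcomp(pattern))
        for sid, seq in genome.items():
            for m in pat.finditer(seq):
                s = m.start()
                e = s + len(pattern)
                locs.append(Location(sid, s, e, strand, label=seq[s:e]))
    return LocationSet(name or f"pattern_{pattern}", locs)


@dataclass
class RepeatHit:
    """Two equal-length arms separated by a gap; ``inverted`` arms are
    reverse complements, ``direct`` arms are identical."""

    arm1: Location
    arm2: Location
    gap: int
    kind: Literal["direct", "inverted"]

    def verify(self, genome: Genome) -> None:
        s1 = genome[self.arm1.sequence_id][self.arm1.start : self.arm1.end]
        s2 = genome[self.arm2.sequence_id][self.arm2.start : self.arm2.end]
        if len(s1) != len(s2):
            raise ValueError("arm lengths differ")
        if self.gap != self.arm2.start - self.arm1.end or self.gap < 0:
            raise ValueError("gap inconsistent with arm coordinates")
        expected = s1 if self.kind == "direct" else revcomp(s1)
        if s2 != expected or "N" in s1 or "N" in s2:
            raise ValueError("repeat property violated")


def _is_repeat(seq: str, i: int, arm: int, gap: int, kind: str) -> bool:
    j = i + arm + gap
    if j + arm > len(seq):
        return False
    s1 = seq[i : i + arm]
    s2 = seq[j : j + arm]
    if "N" in s1 or "N" in s2:
        return False
    return s2 == (s1 if kind == "direct" else revcomp(s1))


def find_repeats(
    genome: Genome,
    kind: Literal["direct", "inverted"],
    arm_min: int,
    arm_max: int,
    gap_min: int = 0,
    gap_max: int = 0,
) -> list[RepeatHit]:
    """All maximal direct/inverted repeats within the parameter box.

    A hit (position i, arm length a, gap g) is maximal when its arms cannot
    be extended to a+1 (leftward or rightward, same gap) while staying
    within ``arm_max`` and keeping the repeat property.
    """
    if not (1 <= arm_min <= arm_max) or not (0 <= gap_min <= gap_max):
        raise ValueError("invalid parameter box")
    hits = []
    for sid, seq in genome.items():
        n = len(seq)
        for gap in range(gap_min, gap_max + 1):
            for arm in range(arm_min, arm_max + 1):
                for i in range(0, n - (2 * arm + gap) + 1):
                    if not _is_repeat(seq, i, arm, gap, kind):
                        continue
                    if arm + 1 <= arm_max and (
                        _is_repeat(seq, i, arm + 1, gap, kind)
                        or (i >= 1 and _is_repeat(seq, i - 1, arm + 1, gap, kind))
                    ):
                        continue  # extendable, not maximal
                    hit = RepeatHit(
                        arm1=Location(sid, i, i + arm),
                        arm2=Location(sid, i + arm + gap, i + 2 * arm + gap),
                        gap=gap,
                        kind=kind,
                    )
                    hit.verify(genome)
                    hits.append(hit)
    return hits


__all__ = ["IUPAC", "RepeatHit", "find_pattern", "find_repeats", "iupac_revcomp"]
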