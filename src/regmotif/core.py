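"""Core data model: genomes, strand-aware intervals, numeric tracks, alignment blocks.

All internal coordinates are 0-based half-open; conversions to 1-based
conventions (GFF, WIG) happen only at format boundaries.  The scanning
alphabet is {A, C, G, T, N}; N never matches anything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

DNA_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# integer encoding: A=0 C=1 G=2 T=3 N=4 (complement of code c<4 is 3-c)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

UNSTRANDED = "."
STRANDS = ("+", "-", UNSTRANDED)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@dataclass
class Location:
    """A strand-aware genomic interval, 0-based half-open.

    ``value``, ``label`` and ``flag`` are the optional per-record
    annotations a location set carries (score, name, and the tri-state
    true/false/undecided curation flag).
    """

    sequence_id: str
    start: int
    end: int
    strand: str = UNSTRANDED
    value: Optional[float] = None
    label: Optional[str] = None
    flag: Optional[str] = None  # "true" | "false" | "undecided" | None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.flag is not None and self.flag not in ("true", "false", "undecided"):
            raise ValueError(f"invalid flag {self.flag!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0

    def sort_key(self):
        return (self.sequence_id, self.start, self.end)

    def overlaps(self, other: "Location") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """A named set of DNA sequences over {A,C,G,T,N}, uppercased on load."""

    def __init__(self, name: str, sequences: dict[str, str], validate: bool = True):
        self.name = name
        self.sequences = dict(sequences)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self.sequences) == 0:
            raise ValueError("genome has no sequences")
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {sid!r} is empty")
            bad = set(seq) - set(DNA_ALPHABET)
            if bad:
                raise ValueError(f"sequence {sid!r} has illegal characters {bad}")

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self.sequences

    def __getitem__(self, sequence_id: str) -> str:
        return self.sequences[sequence_id]

    def length(self, sequence_id: str) -> int:
        return len(self.sequences[sequence_id])

    def fetch(self, loc: Location) -> str:
        """Sequence of a location; minus-strand locations are reverse-complemented."""
        seq = self.sequences[loc.sequence_id][loc.start : loc.end]
        return revcomp(seq) if loc.strand == "-" else seq

    def items(self):
        return self.sequences.items()


class LocationSet:
    """An ordered, named collection of locations.

    Locations are kept sorted by (sequence_id, start, end) unless
    ``sort=False`` is requested (some callers need input order preserved).
    """

    def __init__(self, name: str, locations: Iterable[Location], sort: bool = True):
        self.name = name
        self.locations = list(locations)
        if sort:
            self.locations.sort(key=Location.sort_key)

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self) -> Iterator[Location]:
        return iter(self.locations)

    def __getitem__(self, i: int) -> Location:
        return self.locations[i]

    def sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.locations:
            seen.setdefault(loc.sequence_id, None)
        return list(seen)

    def validate_against(self, genome: Genome) -> None:
        for loc in self.locations:
            if loc.sequence_id not in genome:
                raise ValueError(f"unknown sequence {loc.sequence_id!r}")
            if loc.end > genome.length(loc.sequence_id):
                raise ValueError(
                    f"location {loc.sequence_id}:{loc.start}-{loc.end} exceeds "
                    f"sequence length {genome.length(loc.sequence_id)}"
                )


@dataclass
class TrackRun:
    """A run of numeric values: positions start + i*step, each covering span bases."""

    sequence_id: str
    start: int  # 0-based
    step: int
    span: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.start < 0 or self.step < 1 or self.span < 1:
            raise ValueError("invalid run geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    def covered(self) -> Iterator[tuple[int, float]]:
        for i, v in enumerate(self.values):
            pos = self.start + i * self.step
            for j in range(self.span):
                yield pos + j, float(v)


class DataTrack:
    """Per-base numeric values stored as runs (the WIG data model)."""

    def __init__(self, runs: Iterable[TrackRun], validate: bool = True):
        self.runs = list(runs)
        if validate:
            self._validate()

    def _validate(self) -> None:
        per_seq: dict[str, list[tuple[int, int]]] = {}
        for run in self.runs:
            for i in range(len(run.values)):
                s = run.start + i * run.step
                per_seq.setdefault(run.sequence_id, []).append((s, s + run.span))
        for sid, spans in per_seq.items():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping spans on {sid} at base {s2}")

    def sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for run in self.runs:
            seen.setdefault(run.sequence_id, None)
        return list(seen)

    def max_end(self, sequence_id: str) -> int:
        end = 0
        for run in self.runs:
            if run.sequence_id == sequence_id and len(run.values):
                end = max(end, run.start + (len(run.values) - 1) * run.step + run.span)
        return end

    def dense(self, sequence_id: str, length: Optional[int] = None) -> np.ndarray:
        """Materialize per-base values; uncovered bases are NaN."""
        n = length if length is not None else self.max_end(sequence_id)
        out = np.full(n, np.nan)
        for run in self.runs:
            if run.sequence_id != sequence_id:
                continue
            for pos, v in run.covered():
                if pos < n:
                    out[pos] = v
        return out

    def value_at(self, sequence_id: str, base: int) -> Optional[float]:
        for run in self.runs:
            if run.sequence_id != sequence_id:
                continue
            off = base - run.start
            if off < 0:
                continue
            i, j = divmod(off, run.step)
            if i < len(run.values) and j < run.span:
                return float(run.values[i])
            # span may exceed step only in variableStep-like runs with step>=span
            if run.step < run.span:
                for i2, v in enumerate(run.values):
                    p = run.start + i2 * run.step
                    if p <= base < p + run.span:
                        return float(v)
        return None


@dataclass
class AlignmentBlock:
    """A reference interval plus gapped aligned rows from several genomes.

    ``rows`` maps genome name to a gapped sequence (alphabet + '-'); the row
    named ``reference_genome`` must, with gaps removed, equal the reference
    genome subsequence at ``reference``.
    """

    reference: Location
    reference_genome: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_genome not in self.rows:
            raise ValueError("reference row missing from alignment block")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def reference_row(self) -> str:
        return self.rows[self.reference_genome]

    def validate_against(self, genome: Genome) -> None:
        degapped = self.reference_row().replace("-", "")
        expected = genome[self.reference.sequence_id][
            self.reference.start : self.reference.end
        ]
        if degapped != expected:
            raise ValueError(
                "reference row (degapped) does not match genome subsequence for "
                f"{self.reference.sequence_id}:{self.reference.start}-{self.reference.end}"
            )

    def column_of(self, genome_pos: int) -> int:
        """Alignment column holding reference base at absolute position genome_pos."""
        if not (self.reference.start <= genome_pos < self.reference.end):
            raise ValueError("position outside block")
        target = genome_pos - self.reference.start
        seen = -1
        for col, ch in enumerate(self.reference_row()):
            if ch != "-":
                seen += 1
                if seen == target:
                    return col
        raise ValueError("reference row shorter than block span")  # pragma: no cover


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge (start, end) half-open pairs into maximal disjoint intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


__all__ = [
    "AlignmentBlock",
    "DataTrack",
    "Genome",
    "Location",
    "LocationSet",
    "TrackRun",
    "UNSTRANDED",
    "decode",
    "encode",
    "merge_intervals",
    "replace",
    "revcomp",
]
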