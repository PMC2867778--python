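"""Readers and writers for FASTA, BED, GFF, WIG and alignment-block text.

Internal coordinates are always 0-based half-open.  BED is already 0-based
half-open and is kept verbatim; GFF start/end (1-based inclusive) and WIG
starts (1-based) are converted at the boundary, so BED (s, e) corresponds to
GFF (s+1, e).

FASTA normalization: sequences are uppercased, U becomes T, and other IUPAC
ambiguity letters map to N with a warning; in strict mode any character
outside {A,C,G,T,N,U} is an error.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignmentBlock,
    DataTrack,
    Genome,
    Location,
    LocationSet,
    TrackRun,
    UNSTRANDED,
)

PathLike = Union[str, Path]

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


def _normalize_sequence(seq: str, strict: bool) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        if strict or not bad <= _IUPAC_AMBIGUOUS:
            raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
        warnings.warn(
            f"ambiguity codes {sorted(bad)} mapped to N", stacklevel=3
        )
        for ch in bad:
            s = s.replace(ch, "N")
    return s


def read_fasta(path: PathLike, name: Optional[str] = None, strict: bool = False) -> Genome:
    """Read one FASTA file into a :class:`Genome`.

    Raises on empty files, duplicate record ids, and (in strict mode) any
    character outside the {A,C,G,T,N,U} alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        sequences[rec.id] = _normalize_sequence(str(rec.seq), strict)
    return Genome(name or Path(path).stem, sequences)


def write_fasta(genome: Genome, path: PathLike, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


_NONE = "."


def _fmt_value(v: Optional[float]) -> str:
    if v is None:
        return _NONE
    return format(v, ".17g")


def read_bed(path: PathLike, name: Optional[str] = None) -> LocationSet:
    """Read a 3-6 column BED file (coordinates kept verbatim)."""
    locs = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        label = cols[3] if len(cols) > 3 and cols[3] != _NONE else None
        value = (
            float(cols[4]) if len(cols) > 4 and cols[4] != _NONE else None
        )
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else UNSTRANDED
        locs.append(
            Location(cols[0], start, end, strand, value=value, label=label)
        )
    return LocationSet(name or Path(path).stem, locs)


def write_bed(location_set: LocationSet, path: PathLike, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for loc in location_set:
            cols = [loc.sequence_id, str(loc.start), str(loc.end)]
            if loc.label is not None or loc.value is not None or loc.strand != UNSTRANDED:
                cols.append(loc.label if loc.label is not None else _NONE)
            if loc.value is not None or loc.strand != UNSTRANDED:
                cols.append(_fmt_value(loc.value))
            if loc.strand != UNSTRANDED:
                cols.append(loc.strand)
            fh.write("\t".join(cols) + "\n")


def _parse_gff_attributes(attrs: str) -> tuple[Optional[str], Optional[str]]:
    label = flag = None
    if attrs and attrs != _NONE:
        for part in attrs.split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" in part:
                key, _, val = part.partition("=")
            else:
                key, _, val = part.partition(" ")
            key = key.strip()
            val = val.strip().strip('"')
            if key == "Name":
                label = val
            elif key == "flag":
                flag = val
    return label, flag


def read_gff(path: PathLike, name: Optional[str] = None) -> LocationSet:
    """Read 9-column GFF (v2/v3 tolerant); converts to 0-based half-open."""
    locs = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
        try:
            start1, end1 = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start1 > end1:
            raise ValueError(f"{path}:{lineno}: start > end")
        value = float(cols[5]) if cols[5] != _NONE else None
        strand = cols[6] if cols[6] in "+-" else UNSTRANDED
        label, flag = _parse_gff_attributes(cols[8])
        locs.append(
            Location(cols[0], start1 - 1, end1, strand, value=value, label=label, flag=flag)
        )
    return LocationSet(name or Path(path).stem, locs)


def write_gff(
    location_set: LocationSet,
    path: PathLike,
    source: str = "regmotif",
    feature: str = "region",
    header: Optional[str] = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for loc in location_set:
            attrs = []
            if loc.label is not None:
                attrs.append(f"Name={loc.label}")
            if loc.flag is not None:
                attrs.append(f"flag={loc.flag}")
            fh.write(
                "\t".join(
                    [
                        loc.sequence_id,
                        source,
                        feature,
                        str(loc.start + 1),
                        str(loc.end),
                        _fmt_value(loc.value),
                        loc.strand,
                        _NONE,
                        ";".join(attrs) if attrs else _NONE,
                    ]
                )
                + "\n"
            )


def read_wig(path: PathLike) -> DataTrack:
    """Read fixedStep/variableStep WIG; 1-based starts become 0-based."""
    runs: list[TrackRun] = []
    mode = None  # ("fixed", chrom, start0, step, span) | ("variable", chrom, span)
    values: list[float] = []
    fixed_meta = None

    def flush():
        nonlocal values, fixed_meta
        if fixed_meta is not None and values:
            chrom, start0, step, span = fixed_meta
            runs.append(TrackRun(chrom, start0, step, span, values))
        values = []

    for lineno, line in _data_lines(path):
        fields = line.split()
        if fields[0] in ("fixedStep", "variableStep"):
            flush()
            kv = dict(f.split("=", 1) for f in fields[1:])
            if "chrom" not in kv:
                raise ValueError(f"{path}:{lineno}: missing chrom")
            span = int(kv.get("span", 1))
            if fields[0] == "fixedStep":
                start0 = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                mode = "fixed"
                fixed_meta = (kv["chrom"], start0, step, span)
            else:
                mode = "variable"
                fixed_meta = None
                var_meta = (kv["chrom"], span)
        elif mode == "fixed":
            values.append(float(fields[0]))
        elif mode == "variable":
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: variableStep needs pos value")
            chrom, span = var_meta
            pos0 = int(fields[0]) - 1
            runs.append(TrackRun(chrom, pos0, 1, span, [float(fields[1])]))
        else:
            raise ValueError(f"{path}:{lineno}: value line before declaration")
    flush()
    return DataTrack(runs)


def write_wig(track: DataTrack, path: PathLike, header: Optional[str] = None) -> None:
    """Write each run as a fixedStep block (span and step preserved)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for run in track.runs:
            fh.write(
                f"fixedStep chrom={run.sequence_id} start={run.start + 1} "
                f"step={run.step} span={run.span}\n"
            )
            for v in run.values:
                fh.write(format(float(v), ".17g") + "\n")


def read_alignment_blocks(
    path: PathLike, genome: Optional[Genome] = None
) -> list[AlignmentBlock]:
    """Read the block text format: ``=block <seq_id> <start> <end>`` then one
    ``name<TAB>gapped_seq`` row per genome; the first row is the reference."""
    blocks: list[AlignmentBlock] = []
    header = None
    rows: list[tuple[str, str]] = []

    def flush():
        nonlocal rows
        if header is None:
            return
        if not rows:
            raise ValueError("alignment block with no rows")
        sid, start, end = header
        block = AlignmentBlock(
            reference=Location(sid, start, end),
            reference_genome=rows[0][0],
            rows=dict(rows),
        )
        if genome is not None:
            block.validate_against(genome)
        blocks.append(block)
        rows = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("=block"):
                flush()
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: bad block header")
                header = (parts[1], int(parts[2]), int(parts[3]))
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: row before block header")
                name, _, gapped = line.partition("\t")
                if not gapped:
                    raise ValueError(f"{path}:{lineno}: expected name<TAB>sequence")
                rows.append((name, gapped.upper()))
    flush()
    return blocks


def write_alignment_blocks(blocks: list[AlignmentBlock], path: PathLike) -> None:
    with open(path, "w") as fh:
        for block in blocks:
            ref = block.reference
            fh.write(f"=block {ref.sequence_id} {ref.start} {ref.end}\n")
            ordered = [block.reference_genome] + [
                n for n in block.rows if n != block.reference_genome
            ]
            for name in ordered:
                fh.write(f"{name}\t{block.rows[name]}\n")


__all__ = [
    "read_alignment_blocks",
    "read_bed",
    "read_fasta",
    "read_gff",
    "read_wig",
    "write_alignment_blocks",
    "write_bed",
    "write_fasta",
    "write_gff",
    "write_wig",
]
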