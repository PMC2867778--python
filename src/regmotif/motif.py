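"""Motif data model: frequency/affinity matrices, backgrounds, PSSMs,
information content, and motif file formats.

Conventions (stated because they are choices, not forced by the data):

* Log base 2 throughout; scores and information content are in bits.
* Regularization mixes each frequency column with the background:
  f'(i, b) = (1 - p) f(i, b) + p bg(b), default pseudo-weight p = 0.01.
* Matrix text format (bit-exact, written by :func:`write_motifs`):
  a ``>name`` header (optionally ``>name kind=affinity``) followed by one
  line per motif position holding 4 values in A C G T order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np

from .core import Genome, encode

BASES = "ACGT"
PathLike = Union[str, Path]

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class Motif:
    """A motif: W columns of base weights over A, C, G, T.

    ``kind='frequency'`` columns are probability distributions;
    ``kind='affinity'`` columns are relative binding weights normalized so
    the column maximum is 1 (the MatrixREDUCE-style representation scored
    multiplicatively).
    """

    def __init__(
        self,
        name: str,
        matrix: np.ndarray,
        kind: Literal["frequency", "affinity"] = "frequency",
        normalize: bool = True,
    ):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError("motif matrix must be W x 4 with W >= 1")
        if np.any(mat < 0) or not np.all(np.isfinite(mat)):
            raise ValueError("motif entries must be finite and non-negative")
        if kind == "frequency":
            sums = mat.sum(axis=1)
            if np.any(sums <= 0):
                raise ValueError("empty motif column")
            if normalize:
                mat = mat / sums[:, None]
            elif np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("frequency columns must sum to 1")
        elif kind == "affinity":
            maxes = mat.max(axis=1)
            if np.any(maxes <= 0):
                raise ValueError("empty affinity column")
            if normalize:
                mat = mat / maxes[:, None]
            elif np.any(mat > 1 + 1e-9):
                raise ValueError("affinity entries must be in [0, 1]")
        else:
            raise ValueError(f"unknown motif kind {kind!r}")
        self.name = name
        self.matrix = mat
        self.kind = kind

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def revcomp(self) -> "Motif":
        """Reverse columns and swap A<->T, C<->G."""
        return Motif(
            self.name + "_rc", self.matrix[::-1, ::-1], self.kind, normalize=False
        )

    def allclose(self, other: "Motif", atol: float = 1e-9) -> bool:
        return (
            self.kind == other.kind
            and self.width == other.width
            and np.allclose(self.matrix, other.matrix, atol=atol)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Motif({self.name!r}, W={self.width}, kind={self.kind})"


class Background:
    """A base-composition model: order-0 probabilities plus optional
    order-k conditional tables (k <= 3) estimated from sequences."""

    def __init__(
        self,
        probs: Sequence[float],
        conditionals: Optional[dict[int, np.ndarray]] = None,
    ):
        p = np.asarray(probs, dtype=float)
        if p.shape != (4,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("background must be 4 positive probabilities summing to 1")
        self.probs = p / p.sum()
        self.conditionals = conditionals or {}
        for k, table in self.conditionals.items():
            if table.shape != (4,) * k + (4,):
                raise ValueError(f"order-{k} table has wrong shape")
            if np.any(table <= 0) or not np.allclose(table.sum(axis=-1), 1.0):
                raise ValueError(f"order-{k} table rows must be positive and sum to 1")

    @property
    def order(self) -> int:
        return max(self.conditionals, default=0)

    @classmethod
    def uniform(cls) -> "Background":
        return cls([0.25, 0.25, 0.25, 0.25])

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], order: int = 0, pseudocount: float = 1.0
    ) -> "Background":
        """Estimate from sequences (N bases are ignored); k-mer counts get a
        flat pseudocount so every probability is positive."""
        if not 0 <= order <= 3:
            raise ValueError("background order must be in 0..3")
        seqs = [encode(s) for s in sequences]
        counts0 = np.full(4, pseudocount)
        for codes in seqs:
            counts0 += np.bincount(codes[codes < 4], minlength=4)[:4]
        conditionals: dict[int, np.ndarray] = {}
        for k in range(1, order + 1):
            table = np.full((4,) * k + (4,), pseudocount)
            for codes in seqs:
                ok = codes < 4
                for i in range(k, len(codes)):
                    if ok[i - k : i + 1].all():
                        table[tuple(codes[i - k : i + 1])] += 1
            conditionals[k] = table / table.sum(axis=-1, keepdims=True)
        return cls(counts0 / counts0.sum(), conditionals)

    @classmethod
    def from_genome(cls, genome: Genome, order: int = 0) -> "Background":
        return cls.from_sequences(genome.sequences.values(), order=order)

    def logp_word(self, codes: np.ndarray, log2: bool = True) -> float:
        """Log probability of an N-free word, using the highest-order
        conditional available for each position's context."""
        if np.any(codes >= 4):
            raise ValueError("word contains N")
        order = self.order
        lp = 0.0
        for i, c in enumerate(codes):
            k = min(i, order)
            if k == 0:
                p = self.probs[c]
            else:
                p = self.conditionals[k][tuple(codes[i - k : i]) + (int(c),)]
            lp += math.log2(p) if log2 else math.log(p)
        return lp


def motif_from_degenerate(iupac: str, name: Optional[str] = None) -> Motif:
    """Build a frequency motif from an IUPAC string: each column is uniform
    over the symbol's base set."""
    iupac = iupac.upper()
    rows = []
    for ch in iupac:
        if ch not in _IUPAC_SETS:
            raise ValueError(f"illegal IUPAC symbol {ch!r}")
        allowed = _IUPAC_SETS[ch]
        rows.append([1.0 / len(allowed) if b in allowed else 0.0 for b in BASES])
    return Motif(name or iupac, np.array(rows))


def regularize(motif: Motif, background: Background, pseudo_weight: float = 0.01) -> Motif:
    """Mix each frequency column with the background: (1-p) f + p bg."""
    if not 0 <= pseudo_weight < 1:
        raise ValueError("pseudo_weight must be in [0, 1)")
    if motif.kind != "frequency":
        raise ValueError("can only regularize frequency motifs")
    mat = (1 - pseudo_weight) * motif.matrix + pseudo_weight * background.probs
    return Motif(motif.name, mat, normalize=False)


@dataclass
class PSSM:
    """Log-odds scoring matrix s(i, b) = log2(f'(i, b) / bg(b)) in bits.

    Carries the regularized frequencies and the order-0 background so
    p-value machinery can re-derive proposal and null distributions.
    """

    name: str
    matrix: np.ndarray  # W x 4 log-odds
    freq: np.ndarray  # W x 4 regularized frequencies
    background: np.ndarray  # 4 order-0 probabilities

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def revcomp(self) -> "PSSM":
        return PSSM(
            self.name + "_rc",
            self.matrix[::-1, ::-1],
            self.freq[::-1, ::-1],
            self.background,  # note: bg kept as-is (order-0 symmetric use)
        )


def to_pssm(
    motif: Motif, background: Optional[Background] = None, pseudo_weight: float = 0.01
) -> PSSM:
    if motif.kind != "frequency":
        raise ValueError("affinity motifs are scored multiplicatively, not as PSSMs")
    background = background or Background.uniform()
    reg = regularize(motif, background, pseudo_weight)
    logodds = np.log2(reg.matrix / background.probs)
    return PSSM(motif.name, logodds, reg.matrix, background.probs.copy())


def information_content(
    motif: Motif, background: Optional[Background] = None
) -> tuple[np.ndarray, float]:
    """Per-column relative entropy vs the background, in bits (0 log 0 = 0)."""
    if motif.kind != "frequency":
        raise ValueError("information content is defined for frequency motifs")
    background = background or Background.uniform()
    f = motif.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / background.probs), 0.0)
    per_column = terms.sum(axis=1)
    return per_column, float(per_column.sum())


# ---------------------------------------------------------------------------
# file formats

_FLOAT = ".17g"


def _parse_matrix_blocks(text: str):
    name = None
    kind = "frequency"
    rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if name is not None:
                yield name, kind, rows
            header = line[1:].split()
            name = header[0] if header else "motif"
            kind = "frequency"
            for tok in header[1:]:
                if tok.startswith("kind="):
                    kind = tok[5:]
            rows = []
        else:
            vals = [float(x) for x in line.split()]
            if len(vals) != 4:
                raise ValueError("matrix rows must have 4 values (A C G T)")
            if name is None:
                raise ValueError("matrix row before >name header")
            rows.append(vals)
    if name is not None:
        yield name, kind, rows


def _read_matrix(text: str) -> list[Motif]:
    out = []
    for name, kind, rows in _parse_matrix_blocks(text):
        if not rows:
            raise ValueError(f"motif {name!r} has no rows")
        out.append(Motif(name, np.array(rows), kind=kind))  # type: ignore[arg-type]
    return out


_MEME_MOTIF = re.compile(r"^MOTIF\s+(\S+)", re.M)


def _read_meme(text: str) -> list[Motif]:
    """MEME minimal format: MOTIF blocks with letter-probability matrices."""
    out = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        m = _MEME_MOTIF.match(lines[i])
        if not m:
            i += 1
            continue
        name = m.group(1)
        i += 1
        while i < len(lines) and "letter-probability matrix" not in lines[i]:
            if _MEME_MOTIF.match(lines[i]):
                raise ValueError(f"MEME motif {name!r} lacks a probability matrix")
            i += 1
        if i == len(lines):
            raise ValueError(f"MEME motif {name!r} lacks a probability matrix")
        wm = re.search(r"w=\s*(\d+)", lines[i])
        i += 1
        rows = []
        while i < len(lines):
            vals = lines[i].split()
            if len(vals) == 4:
                try:
                    rows.append([float(v) for v in vals])
                    i += 1
                    continue
                except ValueError:
                    pass
            break
        if wm and int(wm.group(1)) != len(rows):
            raise ValueError(f"MEME motif {name!r}: w= disagrees with matrix rows")
        if not rows:
            raise ValueError(f"MEME motif {name!r} has an empty matrix")
        out.append(Motif(name, np.array(rows)))
    return out


def _read_bioprospector(text: str) -> list[Motif]:
    """Simplified BioProspector-style output: ``Motif #k`` headers followed by
    site lines whose final whitespace-separated token is the aligned word."""
    out = []
    name = None
    sites: list[str] = []

    def flush():
        if name is None:
            return
        if not sites:
            raise ValueError(f"{name}: no sites")
        widths = {len(s) for s in sites}
        if len(widths) != 1:
            raise ValueError(f"{name}: sites have unequal widths")
        counts = np.zeros((len(sites[0]), 4))
        for site in sites:
            for i, ch in enumerate(site):
                counts[i, BASES.index(ch)] += 1
        out.append(Motif(name, counts))

    for raw in text.splitlines():
        line = raw.strip()
        hm = re.match(r"Motif\s*#\s*(\d+)", line)
        if hm:
            flush()
            name = f"motif_{hm.group(1)}"
            sites = []
        elif name is not None and line:
            word = line.split()[-1].upper()
            if re.fullmatch(r"[ACGT]+", word):
                sites.append(word)
    flush()
    return out


def _read_degenerate_list(text: str) -> list[Motif]:
    """One IUPAC pattern per line, optionally preceded by a name and a tab."""
    out = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, _, pat = line.partition("\t")
            out.append(motif_from_degenerate(pat.strip(), name.strip()))
        else:
            out.append(motif_from_degenerate(line))
    return out


MotifFormat = Literal["matrix", "meme", "bioprospector", "degenerate_list"]

_READERS = {
    "matrix": _read_matrix,
    "meme": _read_meme,
    "bioprospector": _read_bioprospector,
    "degenerate_list": _read_degenerate_list,
}


def read_motifs(path: PathLike, format: MotifFormat = "matrix") -> list[Motif]:
    if format not in _READERS:
        raise ValueError(f"unknown motif format {format!r}")
    text = Path(path).read_text()
    return _READERS[format](text)


def write_motifs(
    motifs: Sequence[Motif], path: PathLike, format: MotifFormat = "matrix"
) -> None:
    with open(path, "w") as fh:
        if format == "matrix":
            for m in motifs:
                kind = "" if m.kind == "frequency" else f" kind={m.kind}"
                fh.write(f">{m.name}{kind}\n")
                for row in m.matrix:
                    fh.write(" ".join(format_float(v) for v in row) + "\n")
        elif format == "meme":
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write(
                "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            )
            for m in motifs:
                if m.kind != "frequency":
                    raise ValueError("MEME format holds frequency motifs only")
                fh.write(f"MOTIF {m.name}\n")
                fh.write(
                    f"letter-probability matrix: alength= 4 w= {m.width} "
                    f"nsites= 20 E= 0\n"
                )
                for row in m.matrix:
                    fh.write(" ".join(format_float(v) for v in row) + "\n")
                fh.write("\n")
        else:
            raise ValueError(f"no writer for motif format {format!r}")


def format_float(v: float) -> str:
    return format(float(v), _FLOAT)


def write_logo_table(
    motif: Motif, path: PathLike, background: Optional[Background] = None
) -> None:
    """Export per-column IC-scaled letter heights (the numeric content of a
    sequence logo) as a TSV."""
    ic, _ = information_content(motif, background)
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(BASES) + "\ttotal_bits\n")
        for i in range(motif.width):
            heights = motif.matrix[i] * ic[i]
            fh.write(
                f"{i + 1}\t"
                + "\t".join(format(h, ".6g") for h in heights)
                + f"\t{ic[i]:.6g}\n"
            )


__all__ = [
    "BASES",
    "Background",
    "Motif",
    "PSSM",
    "information_content",
    "motif_from_degenerate",
    "read_motifs",
    "regularize",
    "to_pssm",
    "write_logo_table",
    "write_motifs",
]
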