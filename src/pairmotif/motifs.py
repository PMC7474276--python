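"""Letter-probability-matrix motifs and information content.

A motif is a matrix of per-position base frequencies ``f[i, b]`` over the
alphabet ACGT.  Information content of a column is ``2 + Σ_b f_b log2 f_b``
bits (0 for a uniform column, 2 for a deterministic one), with the usual
entropy convention ``0 · log2 0 = 0`` and no pseudocount.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_SUM_TOL = 1e-3


class MotifParseError(ValueError):
    """Raised for malformed motif files; carries motif name and line number."""


@dataclass(frozen=True)
class Motif:
    """A named letter-probability matrix over ACGT.

    ``matrix`` has shape ``(width, 4)`` with columns ordered A, C, G, T;
    each row sums to 1 (renormalized at construction when off by <= 1e-3).
    """

    motif_id: str
    matrix: np.ndarray
    tf_name: str | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError(
                f"motif {self.motif_id!r}: matrix must have shape (width, 4)"
            )
        if np.any(mat < 0) or np.any(mat > 1 + _SUM_TOL):
            raise ValueError(f"motif {self.motif_id!r}: frequencies outside [0, 1]")
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _SUM_TOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id!r}: position {bad} frequencies sum to "
                f"{sums[bad]:.6f}, not 1 within {_SUM_TOL}"
            )
        mat = mat / sums[:, None]
        mat.flags.writeable = False
        object.__setattr__(self, "matrix", mat)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def consensus(self) -> str:
        """Most probable base at each position (ties broken A<C<G<T)."""
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Motif):
            return NotImplemented
        return (
            self.motif_id == other.motif_id
            and self.matrix.shape == other.matrix.shape
            and bool(np.allclose(self.matrix, other.matrix, atol=1e-12))
        )

    def __hash__(self) -> int:
        return hash((self.motif_id, self.width))


@dataclass(frozen=True)
class Background:
    """Zero-order base composition used as the scanning null model."""

    freq: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.25, 0.25, 0.25])
    )

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies (A, C, G, T)")
        if np.any(f <= 0):
            raise ValueError("background frequencies must all be > 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1 within 1e-9")
        f = f / f.sum()
        f.flags.writeable = False
        object.__setattr__(self, "freq", f)

    @classmethod
    def uniform(cls) -> "Background":
        return cls()

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "Background":
        """Estimate the composition of a promoter set (N bases ignored)."""
        counts = np.zeros(4, dtype=float)
        for seq in sequences:
            for base, idx in _BASE_INDEX.items():
                counts[idx] += seq.count(base) + seq.count(base.lower())
        if counts.sum() == 0:
            raise ValueError("no A/C/G/T bases found to estimate a background")
        return cls(counts / counts.sum())

    def reverse_complement(self) -> "Background":
        return Background(self.freq[::-1])


def column_ic(motif: Motif, i: int) -> float:
    """Information content of column ``i`` in bits, in [0, 2]."""
    if not 0 <= i < motif.width:
        raise IndexError(f"position {i} outside motif of width {motif.width}")
    f = motif.matrix[i]
    return float(2.0 + np.sum(xlogy(f, f)) / np.log(2.0))


def interval_ic(motif: Motif, positions: Iterable[int]) -> float:
    """Total information content over a set of positions (empty set -> 0)."""
    return float(sum(column_ic(motif, i) for i in set(positions)))


def reverse_complement_motif(motif: Motif) -> Motif:
    """Reverse the position order and swap A<->T, C<->G.

    Involution: applying it twice returns the original matrix.
    """
    return Motif(motif.motif_id, motif.matrix[::-1, ::-1], tf_name=motif.tf_name)


# ---------------------------------------------------------------------------
# file formats


def parse_motif_file(path: str | Path) -> list[Motif]:
    """Parse motifs from a MEME minimal file or the 4-column TSV dialect.

    The dialect is chosen by content: files containing a
    ``letter-probability matrix`` line are treated as MEME minimal format,
    files with ``>``-headed frequency blocks as TSV.  An empty file yields
    an empty list.
    """
    text = Path(path).read_text()
    if "letter-probability matrix" in text:
        return _parse_meme(text)
    first = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
        "",
    )
    if first.startswith(">"):
        return _parse_tsv(text)
    if first == "" or first.startswith("MEME version"):
        return _parse_meme(text)
    raise MotifParseError(f"{path}: unrecognized motif file format")


def _parse_frequency_row(line: str, motif_id: str, lineno: int) -> list[float]:
    fields = line.replace(",", " ").split()
    if len(fields) != 4:
        raise MotifParseError(
            f"motif {motif_id!r}, line {lineno}: expected 4 frequencies, "
            f"got {len(fields)}"
        )
    try:
        row = [float(x) for x in fields]
    except ValueError as exc:
        raise MotifParseError(
            f"motif {motif_id!r}, line {lineno}: non-numeric frequency"
        ) from exc
    if any(x < 0 for x in row):
        raise MotifParseError(
            f"motif {motif_id!r}, line {lineno}: negative frequency"
        )
    return row


def _finish_motif(motif_id: str, tf_name: str | None, rows: list[list[float]],
                  lineno: int, expected_width: int | None) -> Motif:
    if not rows:
        raise MotifParseError(f"motif {motif_id!r}, line {lineno}: empty matrix")
    if expected_width is not None and len(rows) != expected_width:
        raise MotifParseError(
            f"motif {motif_id!r}, line {lineno}: declared w= {expected_width} "
            f"but found {len(rows)} rows"
        )
    try:
        return Motif(motif_id, np.array(rows), tf_name=tf_name)
    except ValueError as exc:
        raise MotifParseError(f"line {lineno}: {exc}") from exc


def _parse_meme(text: str) -> list[Motif]:
    motifs: list[Motif] = []
    motif_id: str | None = None
    tf_name: str | None = None
    expected_width: int | None = None
    rows: list[list[float]] = []
    in_matrix = False
    last_line = 0

    def flush(lineno: int) -> None:
        nonlocal motif_id, tf_name, expected_width, rows, in_matrix
        if motif_id is not None:
            motifs.append(
                _finish_motif(motif_id, tf_name, rows, lineno, expected_width)
            )
        motif_id, tf_name, expected_width, rows, in_matrix = None, None, None, [], False

    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        last_line = lineno
        if line.startswith("MOTIF"):
            flush(lineno)
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"line {lineno}: MOTIF line without a name")
            motif_id = parts[1]
            tf_name = parts[2] if len(parts) > 2 else None
        elif line.startswith("letter-probability matrix"):
            if motif_id is None:
                raise MotifParseError(
                    f"line {lineno}: matrix block before any MOTIF line"
                )
            m = re.search(r"\bw=\s*(\d+)", line)
            expected_width = int(m.group(1)) if m else None
            in_matrix = True
        elif in_matrix and line and (line[0].isdigit() or line[0] in ".+-"):
            rows.append(_parse_frequency_row(line, motif_id or "?", lineno))
        elif in_matrix and (not line or not (line[0].isdigit() or line[0] in ".+-")):
            in_matrix = False
    flush(last_line + 1)
    return motifs


def _parse_tsv(text: str) -> list[Motif]:
    motifs: list[Motif] = []
    motif_id: str | None = None
    tf_name: str | None = None
    rows: list[list[float]] = []
    last_line = 0

    def flush(lineno: int) -> None:
        nonlocal motif_id, tf_name, rows
        if motif_id is not None:
            motifs.append(_finish_motif(motif_id, tf_name, rows, lineno, None))
        motif_id, tf_name, rows = None, None, []

    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        last_line = lineno
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(lineno)
            parts = line[1:].split()
            if not parts:
                raise MotifParseError(f"line {lineno}: '>' header without a name")
            motif_id = parts[0]
            tf_name = parts[1] if len(parts) > 1 else None
        else:
            if motif_id is None:
                raise MotifParseError(f"line {lineno}: frequencies before any header")
            rows.append(_parse_frequency_row(line, motif_id, lineno))
    flush(last_line + 1)
    return motifs


def write_meme_file(motifs: Sequence[Motif], path: str | Path,
                    background: Background | None = None) -> None:
    """Write motifs in MEME minimal format (10 decimal places)."""
    bg = background if background is not None else Background.uniform()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg.freq)) + "\n\n"
        )
        for motif in motifs:
            name = f" {motif.tf_name}" if motif.tf_name else ""
            fh.write(f"MOTIF {motif.motif_id}{name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {motif.width}\n"
            )
            for row in motif.matrix:
                fh.write(" " + " ".join(f"{x:.10f}" for x in row) + "\n")
            fh.write("\n")


def write_tsv_file(motifs: Sequence[Motif], path: str | Path) -> None:
    """Write motifs in the '>name' + 4-column frequency block dialect."""
    with open(path, "w") as fh:
        fh.write("# columns: A C G T\n")
        for motif in motifs:
            name = f" {motif.tf_name}" if motif.tf_name else ""
            fh.write(f">{motif.motif_id}{name}\n")
            for row in motif.matrix:
                fh.write("\t".join(f"{x:.10f}" for x in row) + "\n")
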