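"""Domain types, coordinate conventions, and readers/writers.

All coordinates are 0-based half-open internally.  User-facing tables default
to 1-based inclusive (genome-browser style) and are converted on read/write;
pass ``coords="0-half-open"`` to the table readers/writers to disable the
shift.  Sequences are uppercase DNA over {A, C, G, T, N}; N never matches any
base in any downstream scan or metric.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import AlphabetError, ParseError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: coordinate conventions accepted by the table readers/writers
COORDS_ONE_INCLUSIVE = "1-inclusive"
COORDS_ZERO_HALF_OPEN = "0-half-open"


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and verify it is DNA over {A,C,G,T,N}."""
    up = seq.upper()
    for ch in up:
        if ch not in DNA_ALPHABET:
            raise AlphabetError(f"invalid character {ch!r} (alphabet is A/C/G/T/N)")
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Base-wise complement without reversal (literal 'complementary sequence')."""
    return normalize_sequence(seq).translate(_COMPLEMENT)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from the denominator."""
    up = normalize_sequence(seq)
    if not up:
        raise ValidationError("gc_content of an empty sequence is undefined")
    denom = sum(up.count(b) for b in "ACGT")
    if denom == 0:
        raise ValidationError("gc_content undefined: sequence is all N")
    return (up.count("G") + up.count("C")) / denom


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 36.36... -> 36.4, 4.45 -> 4.5 at 1 digit)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ReferenceSequence:
    """A named reference contig."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("reference name must be non-empty")
        object.__setattr__(self, "seq", normalize_sequence(self.seq))
        if not self.seq:
            raise ValidationError(f"reference {self.name!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a contig; strand '+', '-' or '.'."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_one_based(self) -> tuple[int, int]:
        """(start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end

    def __str__(self) -> str:
        s, e = self.to_one_based()
        return f"{self.contig}:{s}-{e}"


def distal_subinterval(interval: GenomeInterval, width: int, gene_strand: str = "+") -> GenomeInterval:
    """The distal (3' in the gene's orientation) ``width`` bp of ``interval``.

    For a minus-strand gene the 3' end of an intron is the *lower* genomic
    coordinate, so the distal sub-interval sits at the low end.
    """
    if width <= 0 or width > interval.length:
        raise ValidationError("width must be in 1..interval length")
    if gene_strand == "-":
        return GenomeInterval(interval.contig, interval.start, interval.start + width, interval.strand)
    return GenomeInterval(interval.contig, interval.end - width, interval.end, interval.strand)


@dataclass(frozen=True)
class DeletionCall:
    """One sample's deletion: bases [start, end) of the contig are absent.

    The junction sequence of the carrier is prefix R[0, start) joined to
    suffix R[end, len).
    """

    sample_id: str
    deletion: GenomeInterval
    junction_consensus: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.junction_consensus is not None:
            norm = normalize_sequence(self.junction_consensus)
            if len(norm) < 20:
                raise ValidationError(
                    f"{self.sample_id}: junction consensus shorter than 20 bp"
                )
            object.__setattr__(self, "junction_consensus", norm)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker annotation (query coordinates, repeat identity)."""

    interval: GenomeInterval
    repeat_name: str
    repeat_class: str
    score: int = 0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValidationError("repeat_class must be non-empty")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Implemented line-by-line so parse errors can name the offending line;
    sequences are normalized to uppercase and the alphabet is enforced.
    """
    records: list[ReferenceSequence] = []
    name: Optional[str] = None
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        if name is None:
            return
        if not chunks:
            raise ParseError(f"line {header_line}: record {name!r} has no sequence")
        try:
            records.append(ReferenceSequence(name, "".join(chunks)))
        except AlphabetError as exc:
            raise AlphabetError(f"record {name!r}: {exc}") from None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"line {lineno}: sequence before any FASTA header")
                chunks.append(line)
    _flush()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Breakpoint table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["sample_id", "contig", "start", "end"]


def read_breakpoint_table(
    path: str | Path,
    coords: str = COORDS_ONE_INCLUSIVE,
    junction_fasta: Optional[str | Path] = None,
) -> list[DeletionCall]:
    """Read the tab-separated breakpoint table.

    Required header columns: sample_id, contig, start, end; optional
    junction_consensus_id referring to a record in ``junction_fasta``.
    ``coords`` selects how start/end are interpreted on input.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")

    consensus_by_id: dict[str, str] = {}
    if junction_fasta is not None:
        consensus_by_id = {r.name: r.seq for r in read_fasta(junction_fasta)}

    calls: list[DeletionCall] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in seen:
            raise ValidationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            start = int(row.start)
            end = int(row.end)
        except (TypeError, ValueError):
            raise ParseError(
                f"sample {sid}: non-integer coordinate ({row.start!r}, {row.end!r})"
            ) from None
        if start >= end:
            raise ValidationError(f"sample {sid}: start >= end")
        if coords == COORDS_ONE_INCLUSIVE:
            start -= 1
        elif coords != COORDS_ZERO_HALF_OPEN:
            raise ValidationError(f"unknown coordinate convention {coords!r}")
        consensus = None
        if "junction_consensus_id" in df.columns and junction_fasta is not None:
            cid = getattr(row, "junction_consensus_id", None)
            if isinstance(cid, str) and cid and cid not in {".", "nan"}:
                if cid not in consensus_by_id:
                    raise ValidationError(
                        f"sample {sid}: junction consensus id {cid!r} not in FASTA"
                    )
                consensus = consensus_by_id[cid]
        calls.append(DeletionCall(sid, GenomeInterval(str(row.contig), start, end), consensus))
    return calls


def write_breakpoint_table(
    calls: Iterable[DeletionCall],
    path: str | Path,
    coords: str = COORDS_ONE_INCLUSIVE,
) -> None:
    calls = list(calls)
    with_consensus = any(c.junction_consensus for c in calls)
    rows = []
    for call in calls:
        start, end = call.deletion.start, call.deletion.end
        if coords == COORDS_ONE_INCLUSIVE:
            start, end = call.deletion.to_one_based()
        elif coords != COORDS_ZERO_HALF_OPEN:
            raise ValidationError(f"unknown coordinate convention {coords!r}")
        row = [call.sample_id, call.deletion.contig, start, end]
        if with_consensus:
            # id convention shared with the junction-consensus FASTA writer
            row.append(f"{call.sample_id}_junction" if call.junction_consensus else ".")
        rows.append(row)
    header = _TABLE_COLUMNS + (["junction_consensus_id"] if with_consensus else [])
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse a standard RepeatMasker .out file (3 header lines, then rows).

    Query coordinates are 1-based inclusive in the file and converted to
    0-based half-open; a 'C' in the strand column maps to '-'.
    """
    annotations: list[RepeatAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines[:4]):
        s = line.strip()
        if not s or s.lower().startswith(("sw", "score")):
            body_start = i + 1
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ParseError(f"line {lineno}: truncated RepeatMasker row ({len(fields)} fields)")
        try:
            score = int(fields[0])
            divergence = float(fields[1])
            qbegin = int(fields[5])
            qend = int(fields[6])
        except ValueError:
            raise ParseError(f"line {lineno}: malformed numeric field") from None
        strand = "-" if fields[8] == "C" else fields[8]
        annotations.append(
            RepeatAnnotation(
                interval=GenomeInterval(fields[4], qbegin - 1, qend, strand),
                repeat_name=fields[9],
                repeat_class=fields[10],
                score=score,
                divergence=divergence,
            )
        )
    return annotations
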