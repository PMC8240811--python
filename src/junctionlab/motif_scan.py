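"""Scanners for the four junction-proximal sequence classes.

Classes: reverse-complement palindromes (>= 6 bp, necessarily even length),
polypyrimidine runs (>= 7 bp of C/T), the literal TTTAAA hexamer (associated
with DNA curvature), and the degenerate hexamer TG(A/G)(A/G)(G/T)(A/C).
Scans run on the presented 5'-3' strand; ``both_strands`` adds the reverse
complement for the two fixed-motif classes (palindromes and the pyrimidine
alphabet are strand-defined as printed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

from scipy.stats import binomtest

from .errors import ValidationError
from .seq_core import (
    DeletionCall,
    ReferenceSequence,
    normalize_sequence,
    reverse_complement,
)

#: genome-wide background rate of TTTAAA (one occurrence per 1,420 bp)
TTTAAA_GENOME_RATE = 1.0 / 1420.0

PALINDROME = "PALINDROME"
POLYPYRIMIDINE = "POLYPYRIMIDINE"
TTTAAA = "TTTAAA"
TG_MOTIF = "TG_MOTIF"

_POLYPYR_RE = re.compile(r"[CT]+")
_TG_RE = re.compile(r"(?=(TG[AG][AG][GT][AC]))")
_TTTAAA_RE = re.compile(r"(?=(TTTAAA))")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a scanned window (0-based half-open)."""

    motif_class: str
    start: int
    end: int
    matched_text: str
    strand: str = "+"
    maximal: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_text):
            raise ValidationError("hit interval does not match its text")


def _is_palindrome(sub: str) -> bool:
    return "N" not in sub and sub == reverse_complement(sub)


def find_palindromes(seq: str, min_len: int = 6) -> list[MotifHit]:
    """All maximal reverse-complement palindromes of length >= ``min_len``.

    Center expansion over all even centers; hits wholly contained in a longer
    hit are suppressed (maximal extent only).
    """
    if min_len < 4 or min_len % 2:
        raise ValidationError("min_len must be even and >= 4 for DNA palindromes")
    s = normalize_sequence(seq)
    n = len(s)
    raw: list[tuple[int, int]] = []
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for c in range(1, n):  # center between c-1 and c
        i, j = c - 1, c
        while i >= 0 and j < n and s[i] != "N" and comp.get(s[i]) == s[j]:
            i -= 1
            j += 1
        length = j - (i + 1)
        if length >= min_len:
            raw.append((i + 1, j))
    hits = [
        (a, b)
        for a, b in raw
        if not any((x <= a and b <= y) and (x, y) != (a, b) for x, y in raw)
    ]
    return [MotifHit(PALINDROME, a, b, s[a:b]) for a, b in sorted(set(hits))]


def find_polypyrimidine(seq: str, min_len: int = 7) -> list[MotifHit]:
    """Maximal runs of {C, T} of length >= ``min_len``."""
    if min_len < 2:
        raise ValidationError("min_len must be >= 2")
    s = normalize_sequence(seq)
    return [
        MotifHit(POLYPYRIMIDINE, m.start(), m.end(), m.group())
        for m in _POLYPYR_RE.finditer(s)
        if m.end() - m.start() >= min_len
    ]


def find_fixed_motifs(seq: str, both_strands: bool = False) -> list[MotifHit]:
    """All (possibly overlapping) TTTAAA and TG(A/G)(A/G)(G/T)(A/C) hits."""
    s = normalize_sequence(seq)
    hits: list[MotifHit] = []
    strands = [("+", s)]
    if both_strands:
        strands.append(("-", reverse_complement(s)))
    n = len(s)
    for strand, text in strands:
        for cls, rx in ((TTTAAA, _TTTAAA_RE), (TG_MOTIF, _TG_RE)):
            for m in rx.finditer(text):
                a, b = m.start(1), m.end(1)
                if strand == "-":
                    a, b = n - b, n - a
                hits.append(MotifHit(cls, a, b, s[a:b], strand=strand))
    return sorted(hits, key=lambda h: (h.start, h.motif_class, h.strand))


@dataclass
class WindowReport:
    """Scan results for one window of sequence."""

    anchor: str  # "start", "end" or "junction"
    window_seq: str
    window_start: Optional[int]  # reference coordinate of window[0]; None for joined
    hits: dict[str, list[MotifHit]]
    truncated: bool = False

    @property
    def palindrome_count(self) -> int:
        return len(self.hits.get(PALINDROME, []))


@dataclass
class JunctionMotifReport:
    sample_id: str
    windows: dict[str, WindowReport]

    @property
    def palindrome_counts(self) -> dict[str, int]:
        return {name: w.palindrome_count for name, w in self.windows.items()}


def _scan_window(anchor: str, seq: str, window_start: Optional[int], truncated: bool,
                 min_palindrome: int, min_polypyr: int, both_strands: bool) -> WindowReport:
    hits = {
        PALINDROME: find_palindromes(seq, min_palindrome),
        POLYPYRIMIDINE: find_polypyrimidine(seq, min_polypyr),
    }
    fixed = find_fixed_motifs(seq, both_strands=both_strands)
    hits[TTTAAA] = [h for h in fixed if h.motif_class == TTTAAA]
    hits[TG_MOTIF] = [h for h in fixed if h.motif_class == TG_MOTIF]
    return WindowReport(anchor, seq, window_start, hits, truncated)


def annotate_junction(
    reference: ReferenceSequence,
    deletion: DeletionCall,
    window_half: int = 50,
    min_palindrome: int = 6,
    min_polypyr: int = 7,
    both_strands: bool = False,
) -> JunctionMotifReport:
    """Scan the window around each breakpoint and around the joined junction.

    Each reference window is 2 * ``window_half`` bp centered on a breakpoint
    (truncated at contig edges, flagged); the junction window is the last
    ``window_half`` bp of the retained prefix joined to the first
    ``window_half`` bp of the retained suffix.
    """
    R = reference.seq
    s, e = deletion.deletion.start, deletion.deletion.end
    windows: dict[str, WindowReport] = {}
    for name, pos in (("start", s), ("end", e)):
        lo, hi = pos - window_half, pos + window_half
        truncated = lo < 0 or hi > len(R)
        lo, hi = max(0, lo), min(len(R), hi)
        windows[name] = _scan_window(
            name, R[lo:hi], lo, truncated, min_palindrome, min_polypyr, both_strands
        )
    left = R[max(0, s - window_half) : s]
    right = R[e : e + window_half]
    truncated = len(left) < window_half or len(right) < window_half
    windows["junction"] = _scan_window(
        "junction", left + right, None, truncated, min_palindrome, min_polypyr, both_strands
    )
    return JunctionMotifReport(deletion.sample_id, windows)


def cohort_palindrome_median(reports: Sequence[JunctionMotifReport], anchor: str = "junction") -> float:
    """Median per-junction palindrome count across a cohort."""
    if not reports:
        raise ValidationError("empty cohort")
    return float(median(r.windows[anchor].palindrome_count for r in reports))


def motif_enrichment(hit_count: int, scanned_bp: int, background_rate: float = TTTAAA_GENOME_RATE) -> float:
    """Exact two-sided binomial p-value for a motif count vs a background rate."""
    if scanned_bp < 1:
        raise ValidationError("scanned_bp must be >= 1")
    if not (0.0 < background_rate < 1.0):
        raise ValidationError("background_rate must be in (0, 1)")
    return float(binomtest(hit_count, scanned_bp, background_rate, alternative="two-sided").pvalue)
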