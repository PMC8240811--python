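"""Secondary-structure proxy: nested base-pair maximization on DNA windows.

This module classifies where a breakpoint sits in the predicted fold of its
100-bp window: on a stem, in a hairpin loop, in a bulge/interior loop, or in
unenclosed (exterior) sequence.  The fold is the Nussinov maximum-pair nested
structure over Watson-Crick pairs (G-T wobble optional, off by default for a
DNA duplex context) with a minimum hairpin-loop size.  A thermodynamic
free-energy model is intentionally not used: the downstream consumer only
needs the loop/stem taxonomy, which the maximum-pairing structure provides
with a fully deterministic traceback.

Traceback tie-breaks (fixed so dot-bracket output is reproducible): at each
subinterval, pairing the leftmost base is preferred over leaving it unpaired,
and the smallest admissible partner wins ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ValidationError
from .seq_core import DeletionCall, ReferenceSequence, normalize_sequence, round_half_up

HAIRPIN_LOOP = "HAIRPIN_LOOP"
STEM = "STEM"
BULGE_OR_INTERIOR = "BULGE_OR_INTERIOR"
EXTERIOR = "EXTERIOR"
CONTEXTS = (HAIRPIN_LOOP, STEM, BULGE_OR_INTERIOR, EXTERIOR)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GT = {("G", "T"), ("T", "G")}


@dataclass
class FoldResult:
    seq: str
    pairing: list[Optional[int]]
    structure_string: str
    breakpoint_index: Optional[int] = None
    breakpoint_context: Optional[str] = None
    n_pairs: int = 0


def _can_pair(x: str, y: str, allow_gt: bool) -> bool:
    return (x, y) in _WC or (allow_gt and (x, y) in _GT)


def fold_window(
    seq: str,
    min_loop: int = 3,
    allow_gt: bool = False,
    breakpoint_index: Optional[int] = None,
) -> FoldResult:
    """Maximum-pair nested fold of a window, with deterministic traceback."""
    s = normalize_sequence(seq)
    n = len(s)
    if not (10 <= n <= 200):
        raise ValidationError("window length must be in 10..200")
    if min_loop < 0:
        raise ValidationError("min_loop must be >= 0")

    # N[i][j]: max pairs in s[i..j]
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k], allow_gt):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = N[k + 1][j] if k + 1 < j else 0
                    cand = 1 + inner + rest
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairing: list[Optional[int]] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = N[i][j]
        if target == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(s[i], s[k], allow_gt):
                inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                rest = N[k + 1][j] if k + 1 < j else 0
                if 1 + inner + rest == target:
                    pairing[i] = k
                    pairing[k] = i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pairing)
    )
    n_pairs = sum(1 for p in pairing if p is not None) // 2
    result = FoldResult(s, pairing, structure, breakpoint_index, None, n_pairs)
    if breakpoint_index is not None:
        if not (0 <= breakpoint_index < n):
            raise ValidationError("breakpoint_index outside the window")
        result.breakpoint_context = classify_breakpoint_context(result)
    return result


def classify_breakpoint_context(fold: FoldResult) -> str:
    """Context of the breakpoint position within the fold.

    STEM: the base is paired.  Otherwise find the innermost enclosing pair;
    if none, EXTERIOR; if its enclosed region contains no other pair, the
    position is in that stem's terminal (hairpin) loop, else in a bulge or
    interior/multibranch loop.
    """
    b = fold.breakpoint_index
    if b is None:
        raise ValidationError("fold has no breakpoint index")
    if fold.pairing[b] is not None:
        return STEM
    innermost: Optional[tuple[int, int]] = None
    for i, p in enumerate(fold.pairing):
        if p is not None and p > i and i < b < p:
            if innermost is None or i > innermost[0]:
                innermost = (i, p)
    if innermost is None:
        return EXTERIOR
    i, p = innermost
    enclosed_pairs = any(fold.pairing[k] is not None for k in range(i + 1, p))
    return BULGE_OR_INTERIOR if enclosed_pairs else HAIRPIN_LOOP


def breakpoint_windows(
    reference: ReferenceSequence, deletion: DeletionCall, window_half: int = 50
) -> list[tuple[str, str, int, bool]]:
    """The two 100-bp reference windows spanning a deletion's breakpoints.

    Returns (anchor, window sequence, breakpoint index within window,
    truncated) for the start and end breakpoints; the breakpoint sits at the
    window center unless truncated by a contig edge.
    """
    R = reference.seq
    out = []
    for anchor, pos in (("start", deletion.deletion.start), ("end", deletion.deletion.end)):
        lo, hi = pos - window_half, pos + window_half
        truncated = lo < 0 or hi > len(R)
        lo, hi = max(0, lo), min(len(R), hi)
        out.append((anchor, R[lo:hi], pos - lo, truncated))
    return out


def fold_cohort(
    reference: ReferenceSequence,
    calls: Sequence[DeletionCall],
    window_half: int = 50,
    min_loop: int = 3,
    allow_gt: bool = False,
) -> list[tuple[str, str, FoldResult]]:
    """Fold both breakpoint windows of every call; 2 folds per sample."""
    results = []
    for call in calls:
        for anchor, window, b_idx, _trunc in breakpoint_windows(reference, call, window_half):
            fold = fold_window(window, min_loop=min_loop, allow_gt=allow_gt, breakpoint_index=b_idx)
            results.append((call.sample_id, anchor, fold))
    return results


def cohort_fold_summary(folds: Sequence[FoldResult]) -> dict[str, dict[str, float]]:
    """Counts and one-decimal percentages of breakpoint contexts."""
    if not folds:
        raise ValidationError("empty fold list")
    counts = {c: 0 for c in CONTEXTS}
    for fold in folds:
        if fold.breakpoint_context is None:
            raise ValidationError("fold lacks a breakpoint context")
        counts[fold.breakpoint_context] += 1
    n = len(folds)
    return {
        c: {"count": counts[c], "percent": round_half_up(100.0 * counts[c] / n, 1)}
        for c in CONTEXTS
    }
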