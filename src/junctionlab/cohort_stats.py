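"""Cohort-level breakpoint-distribution statistics and repeat-content summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .seq_core import (
    DeletionCall,
    GenomeInterval,
    ReferenceSequence,
    RepeatAnnotation,
    gc_content,
    round_half_up,
)

UNIQUE = "UNIQUE"


def clustering_scan(
    start_positions: Sequence[int], window_width: int = 500
) -> tuple[int, Optional[int]]:
    """(max count in any half-open window of the given width, min pairwise distance).

    The minimum pairwise distance is None for a single position.  A max
    window count of 1 means no two breakpoints co-occur within the width,
    i.e. no clustering at that scale.
    """
    if not start_positions:
        raise ValidationError("need at least one position")
    if window_width < 1:
        raise ValidationError("window_width must be >= 1")
    pos = sorted(start_positions)
    max_count = 1
    left = 0
    for right in range(len(pos)):
        while pos[right] - pos[left] >= window_width:
            left += 1
        max_count = max(max_count, right - left + 1)
    min_dist = min((b - a for a, b in zip(pos, pos[1:])), default=None)
    return max_count, min_dist


def distal_fraction(
    deletion_calls: Sequence[DeletionCall], region: GenomeInterval
) -> tuple[int, float]:
    """Count and one-decimal percentage of start breakpoints inside a region."""
    if not deletion_calls:
        raise ValidationError("empty cohort")
    count = sum(
        1
        for c in deletion_calls
        if c.deletion.contig == region.contig and region.contains(c.deletion.start)
    )
    return count, round_half_up(100.0 * count / len(deletion_calls), 1)


def deletion_length_summary(
    deletion_calls: Sequence[DeletionCall], mean_ndigits: int = 1
) -> tuple[int, float, int]:
    """(min, mean, max) deletion length in bp; mean rounded half-up."""
    if not deletion_calls:
        raise ValidationError("empty cohort")
    lengths = [c.deletion.length for c in deletion_calls]
    return min(lengths), round_half_up(sum(lengths) / len(lengths), mean_ndigits), max(lengths)


@dataclass
class DistributionReport:
    n_samples: int
    start_span_fraction: Optional[float]
    max_window_count: int
    window_width: int
    min_pairwise_distance: Optional[int]
    distal_count: Optional[int]
    distal_percent: Optional[float]
    length_min: int
    length_mean: float
    length_max: int


def distribution_report(
    deletion_calls: Sequence[DeletionCall],
    reference_interval: Optional[GenomeInterval] = None,
    distal_region: Optional[GenomeInterval] = None,
    window_width: int = 500,
) -> DistributionReport:
    """Breakpoint scatter statistics: clustering, distal enrichment, lengths."""
    if not deletion_calls:
        raise ValidationError("empty cohort")
    starts = [c.deletion.start for c in deletion_calls]
    max_count, min_dist = clustering_scan(starts, window_width)
    span_fraction = None
    if reference_interval is not None:
        span_fraction = (max(starts) - min(starts)) / reference_interval.length
    distal_count = distal_percent = None
    if distal_region is not None:
        distal_count, distal_percent = distal_fraction(deletion_calls, distal_region)
    lmin, lmean, lmax = deletion_length_summary(deletion_calls)
    return DistributionReport(
        n_samples=len(deletion_calls),
        start_span_fraction=span_fraction,
        max_window_count=max_count,
        window_width=window_width,
        min_pairwise_distance=min_dist,
        distal_count=distal_count,
        distal_percent=distal_percent,
        length_min=lmin,
        length_mean=lmean,
        length_max=lmax,
    )


# ---------------------------------------------------------------------------
# repeat content
# ---------------------------------------------------------------------------

@dataclass
class RepeatContentSummary:
    region: GenomeInterval
    total_length: int
    occupied_bp: dict[str, int]  # repeat_class -> merged occupied bp in region
    percent: dict[str, float]
    gc_level: Optional[float] = None


def _merge_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for a, b in sorted(intervals):
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def repeat_content(
    annotations: Sequence[RepeatAnnotation],
    region: GenomeInterval,
    reference: Optional[ReferenceSequence] = None,
) -> RepeatContentSummary:
    """Occupied bp and percentage per repeat class within a region.

    Annotations are clipped to the region; overlaps within the same class are
    merged so a base is counted once per class.
    """
    by_class: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        if ann.interval.contig != region.contig:
            continue
        a = max(ann.interval.start, region.start)
        b = min(ann.interval.end, region.end)
        if a < b:
            by_class.setdefault(ann.repeat_class, []).append((a, b))
    occupied = {cls: _merge_length(ivs) for cls, ivs in sorted(by_class.items())}
    percent = {
        cls: round_half_up(100.0 * bp / region.length, 2) for cls, bp in occupied.items()
    }
    gc = None
    if reference is not None:
        gc = gc_content(reference.seq[region.start : region.end])
    return RepeatContentSummary(region, region.length, occupied, percent, gc)


# ---------------------------------------------------------------------------
# breakpoint / element overlap
# ---------------------------------------------------------------------------

@dataclass
class ElementOverlapReport:
    per_sample: dict[str, dict[str, str]]  # sid -> {"start": class, "end": class}
    contingency: dict[str, dict[str, int]]  # row ("start"/"end") -> class -> count
    p_value: float
    test_used: str


def _covering_class(
    annotations: Sequence[RepeatAnnotation], contig: str, pos: int, collapse: bool
) -> str:
    for ann in annotations:
        if ann.interval.contig == contig and ann.interval.contains(pos):
            cls = ann.repeat_class
            return cls.split("/")[0] if collapse else cls
    return UNIQUE


def breakpoint_element_overlap(
    deletion_calls: Sequence[DeletionCall],
    annotations: Sequence[RepeatAnnotation],
    collapse_families: bool = True,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> ElementOverlapReport:
    """Element class at each breakpoint and a start-vs-end contingency test.

    Membership is decided by the base at the breakpoint's 0-based start
    position (half-open convention).  2x2 collapses use Fisher's exact test;
    larger tables use chi-square, falling back to a permutation test when
    expected counts are small.
    """
    if not deletion_calls:
        raise ValidationError("empty cohort")
    per_sample: dict[str, dict[str, str]] = {}
    for call in deletion_calls:
        per_sample[call.sample_id] = {
            "start": _covering_class(
                annotations, call.deletion.contig, call.deletion.start, collapse_families
            ),
            "end": _covering_class(
                annotations, call.deletion.contig, call.deletion.end, collapse_families
            ),
        }
    classes = sorted({c for d in per_sample.values() for c in d.values()})
    table = {
        row: {cls: 0 for cls in classes} for row in ("start", "end")
    }
    for d in per_sample.values():
        table["start"][d["start"]] += 1
        table["end"][d["end"]] += 1
    mat = np.array([[table[row][cls] for cls in classes] for row in ("start", "end")])
    mat = mat[:, mat.sum(axis=0) > 0]
    if mat.shape[1] < 2:
        p, test_used = 1.0, "degenerate (single class)"
    elif mat.shape[1] == 2:
        p = float(stats.fisher_exact(mat)[1])
        test_used = "fisher_exact"
    else:
        def _chi2_stat(m: np.ndarray) -> float:
            expected = m.sum(axis=1, keepdims=True) * m.sum(axis=0, keepdims=True) / m.sum()
            mask = expected > 0
            return float(((m - expected)[mask] ** 2 / expected[mask]).sum())

        chi2, p, _, expected = stats.chi2_contingency(mat, correction=False)
        test_used = "chi2"
        if (expected < 5).any():
            # small expected counts: permute column labels, keep row sizes
            rng = np.random.default_rng(seed)
            observed = _chi2_stat(mat)
            n_cols = mat.shape[1]
            flat = np.repeat(np.arange(n_cols), mat.sum(axis=0))
            n_start = int(mat.sum(axis=1)[0])
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(flat)
                perm = np.array(
                    [
                        np.bincount(flat[:n_start], minlength=n_cols),
                        np.bincount(flat[n_start:], minlength=n_cols),
                    ]
                )
                if _chi2_stat(perm) >= observed - 1e-12:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
            test_used = "chi2_permutation"
        p = float(p)
    return ElementOverlapReport(per_sample, table, p, test_used)
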