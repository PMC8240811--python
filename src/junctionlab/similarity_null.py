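"""Four-metric string similarity with a seeded Monte Carlo random-sequence null.

Metrics: longest common (contiguous) substring (LCS), longest common
subsequence (LCSeq), unit-cost Levenshtein distance, and Hamming distance
(equal lengths only).  Per-pair values for observed segments come from the
pure-Python dynamic programs below; the Monte Carlo null uses an equivalent
numpy formulation vectorized across pairs (tests assert the two agree).

The null emulates the published control design: many independent pairs of
i.i.d. uniform random DNA sequences per window length, summarized as mean and
SD per metric.  Uniform composition is used because the published Hamming
null mean (75.13 / 100) matches the uniform expectation 3n/4 and excludes a
genome-like AT-rich null (which would give about 73 / 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, ValidationError
from .seq_core import (
    DeletionCall,
    ReferenceSequence,
    normalize_sequence,
    reverse_complement,
)

METRICS = ("lcs", "lcseq", "levenshtein", "hamming")
DEFAULT_WINDOWS = (10, 20, 30, 100)
QUARTET_PAIRS = ("A-A1", "B-B1", "A-B", "A-B1", "A1-B", "A1-B1")


# ---------------------------------------------------------------------------
# per-pair reference implementations (N never matches; N vs N mismatches)
# ---------------------------------------------------------------------------

def _match(x: str, y: str) -> bool:
    return x == y and x != "N"


def lcs_substring(a: str, b: str) -> int:
    """Length of the longest string that is a contiguous substring of both."""
    a, b = normalize_sequence(a), normalize_sequence(b)
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if _match(ai, b[j - 1]):
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def lcseq(a: str, b: str) -> int:
    """Length of the longest (not necessarily contiguous) common subsequence."""
    a, b = normalize_sequence(a), normalize_sequence(b)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if _match(ai, b[j - 1]):
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[len(b)]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    a, b = normalize_sequence(a), normalize_sequence(b)
    prev = list(range(len(b) + 1))
    for i in range(1, len(a) + 1):
        cur = [i] + [0] * len(b)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            cost = 0 if _match(ai, b[j - 1]) else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[len(b)]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions; defined for equal lengths only."""
    a, b = normalize_sequence(a), normalize_sequence(b)
    if len(a) != len(b):
        raise ValidationError("hamming distance requires equal-length sequences")
    return sum(0 if _match(x, y) else 1 for x, y in zip(a, b))


def similarity_vector(a: str, b: str) -> "SimilarityVector":
    return SimilarityVector(
        lcs=lcs_substring(a, b),
        lcseq=lcseq(a, b),
        levenshtein=levenshtein(a, b),
        hamming=hamming(a, b) if len(a) == len(b) else None,
    )


@dataclass(frozen=True)
class SimilarityVector:
    lcs: int
    lcseq: int
    levenshtein: int
    hamming: Optional[int]

    def as_dict(self) -> dict[str, Optional[int]]:
        return {
            "lcs": self.lcs,
            "lcseq": self.lcseq,
            "levenshtein": self.levenshtein,
            "hamming": self.hamming,
        }


# ---------------------------------------------------------------------------
# batched implementations for the Monte Carlo null (rows = pairs)
# ---------------------------------------------------------------------------

def batch_lcs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n, wa = A.shape
    prev = np.zeros((n, B.shape[1] + 1), dtype=np.int16)
    best = np.zeros(n, dtype=np.int16)
    for i in range(wa):
        cur = np.zeros_like(prev)
        match = A[:, i : i + 1] == B
        cur[:, 1:] = (prev[:, :-1] + 1) * match
        np.maximum(best, cur.max(axis=1), out=best)
        prev = cur
    return best.astype(np.int64)


def batch_lcseq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n, wa = A.shape
    wb = B.shape[1]
    prev = np.zeros((n, wb + 1), dtype=np.int16)
    cur = np.zeros((n, wb + 1), dtype=np.int16)
    for i in range(wa):
        cur[:, 0] = 0
        ai = A[:, i]
        for j in range(1, wb + 1):
            m = ai == B[:, j - 1]
            cur[:, j] = np.where(m, prev[:, j - 1] + 1, np.maximum(prev[:, j], cur[:, j - 1]))
        prev, cur = cur, prev
    return prev[:, wb].astype(np.int64)


def batch_levenshtein(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n, wa = A.shape
    wb = B.shape[1]
    prev = np.tile(np.arange(wb + 1, dtype=np.int16), (n, 1))
    cur = np.zeros((n, wb + 1), dtype=np.int16)
    for i in range(1, wa + 1):
        cur[:, 0] = i
        ai = A[:, i - 1]
        for j in range(1, wb + 1):
            cost = (ai != B[:, j - 1]).astype(np.int16)
            cur[:, j] = np.minimum(
                np.minimum(prev[:, j] + 1, cur[:, j - 1] + 1), prev[:, j - 1] + cost
            )
        prev, cur = cur, prev
    return prev[:, wb].astype(np.int64)


def batch_hamming(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if A.shape != B.shape:
        raise ValidationError("hamming distance requires equal-length sequences")
    return (A != B).sum(axis=1).astype(np.int64)


_BATCH = {
    "lcs": batch_lcs,
    "lcseq": batch_lcseq,
    "levenshtein": batch_levenshtein,
    "hamming": batch_hamming,
}


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentQuartet:
    """50-bp segments around both breakpoints of one deletion.

    A: upstream of start; A1: downstream of start (deleted side, from the
    reference); B: upstream of end (deleted side); B1: downstream of end.
    """

    A: str
    A1: str
    B: str
    B1: str
    truncated: bool = False

    def segment(self, name: str) -> str:
        return getattr(self, name)


def extract_flank_quartet(
    reference: ReferenceSequence, deletion: DeletionCall, width: int = 50
) -> SegmentQuartet:
    R = reference.seq
    s, e = deletion.deletion.start, deletion.deletion.end
    A = R[max(0, s - width) : s]
    A1 = R[s : min(len(R), s + width)]
    B = R[max(0, e - width) : e]
    B1 = R[e : min(len(R), e + width)]
    truncated = any(len(x) < width for x in (A, A1, B, B1))
    return SegmentQuartet(A, A1, B, B1, truncated)


def quartet_similarity(
    quartet: SegmentQuartet, pairs: Sequence[str] = QUARTET_PAIRS
) -> dict[str, SimilarityVector]:
    """All four metrics for each requested segment pair.

    For truncated segments the Hamming distance is computed on the common
    prefix length (the quartet carries the truncation flag).
    """
    out: dict[str, SimilarityVector] = {}
    for pair in pairs:
        if pair not in QUARTET_PAIRS:
            raise ValidationError(f"unknown quartet pair {pair!r}")
        x, y = pair.split("-")
        a, b = quartet.segment(x), quartet.segment(y)
        common = min(len(a), len(b))
        out[pair] = SimilarityVector(
            lcs=lcs_substring(a, b),
            lcseq=lcseq(a, b),
            levenshtein=levenshtein(a, b),
            hamming=hamming(a[:common], b[:common]) if common else None,
        )
    return out


def extract_root_pair(
    reference: ReferenceSequence,
    deletion: DeletionCall,
    window_length: int,
    orientation: str = "reverse-complement",
) -> tuple[str, str, bool]:
    """Root segments of a would-be giant hairpin whose stem spans the deletion.

    First segment: reference downstream of the start breakpoint; second:
    reference upstream of the end breakpoint, converted to its pairing
    partner.  An antiparallel stem pairs with the reverse complement
    (default); ``orientation="complement"`` keeps the literal base-wise
    complement reading instead.  Returns (first, second, truncated).
    """
    R = reference.seq
    s, e = deletion.deletion.start, deletion.deletion.end
    first = R[s : min(len(R), s + window_length)]
    second_raw = R[max(0, e - window_length) : e]
    if orientation == "reverse-complement":
        second = reverse_complement(second_raw)
    elif orientation == "complement":
        second = second_raw.translate(str.maketrans("ACGTN", "TGCAN"))
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    truncated = len(first) < window_length or len(second) < window_length
    return first, second, truncated


# ---------------------------------------------------------------------------
# Monte Carlo null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    metric: str
    window_length: int
    n_pairs: int
    mean: float
    sd: float
    samples: np.ndarray
    seed: int


def _window_rng(seed: int, window_length: int) -> np.random.Generator:
    # documented substream derivation: one child stream per window length,
    # so adding a window does not perturb the draws of the others
    return np.random.default_rng(np.random.SeedSequence([seed, window_length]))


def build_null(
    metric_set: Sequence[str] = METRICS,
    window_lengths: Sequence[int] = DEFAULT_WINDOWS,
    n_pairs: int = 10_000,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> list[NullDistribution]:
    """Monte Carlo null: mean/SD of each metric over ``n_pairs`` independent
    pairs of i.i.d. random sequences, per window length."""
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise ValidationError("composition must be four non-negative probabilities summing to 1")
    unknown = [m for m in metric_set if m not in METRICS]
    if unknown:
        raise ValidationError(f"unknown metric(s) {unknown}")
    out: list[NullDistribution] = []
    for w in window_lengths:
        rng = _window_rng(seed, w)
        A = rng.choice(4, size=(n_pairs, w), p=comp).astype(np.int8)
        B = rng.choice(4, size=(n_pairs, w), p=comp).astype(np.int8)
        for metric in metric_set:
            samples = _BATCH[metric](A, B)
            out.append(
                NullDistribution(
                    metric=metric,
                    window_length=w,
                    n_pairs=n_pairs,
                    mean=float(samples.mean()),
                    sd=float(samples.std()),  # population SD; 0 for n_pairs == 1
                    samples=samples,
                    seed=seed,
                )
            )
    return out


def flag_outliers(value: float, null: NullDistribution) -> tuple[float, str]:
    """z-score of a value against a null and its |z| tier (none/beyond2/beyond3)."""
    if null.sd <= 0:
        raise DegenerateTestError("null SD is zero; z-score undefined")
    z = (value - null.mean) / null.sd
    if abs(z) >= 3:
        tier = "beyond3"
    elif abs(z) >= 2:
        tier = "beyond2"
    else:
        tier = "none"
    return z, tier


def cohort_pvalue(
    sample_values: Sequence[float],
    null_samples: Sequence[float] | np.ndarray,
    method: str = "welch",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided p-value comparing patient values against the null sample.

    Default is Welch's two-sample t-test; ``method="permutation"`` compares
    the observed mean difference against resampled null subsets instead.
    """
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(null_samples, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("both groups need at least two values")
    if x.std() == 0 and y.std() == 0:
        raise DegenerateTestError("zero variance in both groups")
    if method == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        observed = abs(x.mean() - y.mean())
        pooled = np.concatenate([x, y])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[: x.size].mean() - pooled[x.size :].mean()) >= observed - 1e-12:
                count += 1
        return (count + 1) / (n_permutations + 1)
    raise ValidationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cohort-level report (root-segment analysis against the null)
# ---------------------------------------------------------------------------

@dataclass
class CohortSimilarityReport:
    window_lengths: tuple[int, ...]
    metrics: tuple[str, ...]
    per_sample: dict[str, dict[tuple[str, int], int]]  # sid -> (metric, w) -> value
    cohort_mean: dict[tuple[str, int], float]
    cohort_sd: dict[tuple[str, int], float]
    null_mean: dict[tuple[str, int], float]
    null_sd: dict[tuple[str, int], float]
    z_flags: dict[str, dict[tuple[str, int], tuple[float, str]]]
    p_values: dict[tuple[str, int], float]
    test_used: str = "welch"


def cohort_similarity(
    reference: ReferenceSequence,
    calls: Sequence[DeletionCall],
    window_lengths: Sequence[int] = DEFAULT_WINDOWS,
    metric_set: Sequence[str] = METRICS,
    n_pairs: int = 10_000,
    seed: int = 0,
    orientation: str = "reverse-complement",
    nulls: Optional[Sequence[NullDistribution]] = None,
) -> CohortSimilarityReport:
    """Root-segment similarity of every deletion vs the Monte Carlo null."""
    if not calls:
        raise ValidationError("empty cohort")
    if nulls is None:
        nulls = build_null(metric_set, window_lengths, n_pairs=n_pairs, seed=seed)
    null_by_key = {(d.metric, d.window_length): d for d in nulls}
    fns = {"lcs": lcs_substring, "lcseq": lcseq, "levenshtein": levenshtein, "hamming": hamming}
    per_sample: dict[str, dict[tuple[str, int], int]] = {}
    for call in calls:
        vals: dict[tuple[str, int], int] = {}
        for w in window_lengths:
            a, b, _ = extract_root_pair(reference, call, w, orientation)
            for metric in metric_set:
                if metric == "hamming" and len(a) != len(b):
                    continue
                vals[(metric, w)] = fns[metric](a, b)
        per_sample[call.sample_id] = vals

    keys = [(m, w) for w in window_lengths for m in metric_set]
    cohort_mean, cohort_sd, p_values = {}, {}, {}
    null_mean = {k: null_by_key[k].mean for k in keys}
    null_sd = {k: null_by_key[k].sd for k in keys}
    z_flags: dict[str, dict[tuple[str, int], tuple[float, str]]] = {
        sid: {} for sid in per_sample
    }
    for key in keys:
        values = [v[key] for v in per_sample.values() if key in v]
        cohort_mean[key] = float(np.mean(values))
        cohort_sd[key] = float(np.std(values))
        p_values[key] = cohort_pvalue(values, null_by_key[key].samples)
        for sid, vals in per_sample.items():
            if key in vals:
                z_flags[sid][key] = flag_outliers(vals[key], null_by_key[key])
    return CohortSimilarityReport(
        tuple(window_lengths),
        tuple(metric_set),
        per_sample,
        cohort_mean,
        cohort_sd,
        null_mean,
        null_sd,
        z_flags,
        p_values,
    )
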