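"""Junction fine structure: microhomology, insertions, repair-mechanism class.

A deletion [s, e) joins R[0, s) to R[e, len).  Short identical sequence shared
by the two flanks makes the exact breakpoint placement ambiguous; the total
ambiguity length is the junction microhomology.  Junctions are classified by
the standard signature table: 0-1 bp matching -> NHEJ, 2-20 bp -> MMEJ,
>20 bp -> extensive homology; inserted sequence of 1-10 bp -> AROR (aberrant
replication-origin firing / re-replication of nearby template), >10 bp ->
large insertion.  Insertion takes precedence over residual flank matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import UnresolvableJunctionError, ValidationError
from .seq_core import (
    DeletionCall,
    GenomeInterval,
    ReferenceSequence,
    normalize_sequence,
    reverse_complement,
    round_half_up,
)

#: per-side scan cap, comfortably above the >20 bp class boundary
DEFAULT_SCAN_CAP = 50


class Mechanism(str, Enum):
    NHEJ = "NHEJ"
    MMEJ = "MMEJ"
    EXTENSIVE_HOMOLOGY = "EXTENSIVE_HOMOLOGY"
    AROR = "AROR"
    LARGE_INSERTION = "LARGE_INSERTION"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class InsertionSource:
    """One exact occurrence of an inserted sequence near a breakpoint."""

    interval: GenomeInterval
    strand: str
    breakpoint: str  # "start" or "end"


@dataclass
class JunctionCall:
    """Resolved fine structure of one deletion junction."""

    sample_id: str
    mh_left: int
    mh_right: int
    inserted_seq: str
    ambiguity_interval: GenomeInterval
    mechanism: Mechanism = Mechanism.UNCLASSIFIED
    insertion_sources: list[InsertionSource] = field(default_factory=list)
    residual_flank_match: int = 0  # diagnostic only; never changes the class
    capped: bool = False

    @property
    def mh_total(self) -> int:
        return self.mh_left + self.mh_right

    def __post_init__(self) -> None:
        if self.mh_left < 0 or self.mh_right < 0:
            raise ValidationError("microhomology run lengths must be >= 0")
        if self.inserted_seq and self.mh_total != 0:
            raise ValidationError("a junction with an insertion has zero microhomology")


def _bases_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def microhomology_from_coordinates(
    reference: ReferenceSequence,
    deletion: DeletionCall | GenomeInterval,
    scan_cap: int = DEFAULT_SCAN_CAP,
) -> JunctionCall:
    """Microhomology of a coordinate-only deletion (no insertion possible).

    mh_right = maximal run with R[s+i] == R[e+i]; mh_left = maximal run with
    R[s-1-j] == R[e-1-j]; all breakpoint placements in
    [s - mh_left, s + mh_right) produce the same joined sequence.
    """
    if isinstance(deletion, DeletionCall):
        interval, sample_id = deletion.deletion, deletion.sample_id
    else:
        interval, sample_id = deletion, "anonymous"
    R = reference.seq
    s, e = interval.start, interval.end
    if e > len(R):
        raise ValidationError(f"{sample_id}: deletion end beyond contig end")

    capped = False
    mh_right = 0
    while mh_right < scan_cap and e + mh_right < len(R) and s + mh_right < e:
        if not _bases_match(R[s + mh_right], R[e + mh_right]):
            break
        mh_right += 1
    if mh_right == scan_cap or e + mh_right >= len(R):
        capped = True

    mh_left = 0
    while mh_left < scan_cap and s - 1 - mh_left >= 0 and e - 1 - mh_left >= s:
        if not _bases_match(R[s - 1 - mh_left], R[e - 1 - mh_left]):
            break
        mh_left += 1
    if mh_left == scan_cap or s - 1 - mh_left < 0:
        capped = True

    amb_end = s + mh_right if mh_right > 0 or mh_left > 0 else s + 1
    ambiguity = GenomeInterval(interval.contig, s - mh_left, max(amb_end, s - mh_left + 1))
    call = JunctionCall(sample_id, mh_left, mh_right, "", ambiguity, capped=capped)
    call.mechanism = classify_mechanism(call)
    return call


def resolve_junction(
    reference: ReferenceSequence,
    deletion: DeletionCall,
    junction_consensus: Optional[str] = None,
    min_flank: int = 30,
    anchor_search: int = 1000,
) -> JunctionCall:
    """Resolve a junction from an observed consensus spanning the breakpoint.

    The consensus is anchored to the reference by exact seed-and-extend on
    both ends (no substitutions are tolerated; upstream consensus building is
    assumed to have removed sequencing error).  If the two flank matches
    overlap in the consensus, the overlap is the junction microhomology; if
    they leave a gap, the gap is the inserted sequence.
    """
    consensus = junction_consensus if junction_consensus is not None else deletion.junction_consensus
    if consensus is None:
        return microhomology_from_coordinates(reference, deletion)
    C = normalize_sequence(consensus)
    R = reference.seq
    s, e = deletion.deletion.start, deletion.deletion.end
    sid = deletion.sample_id
    Lc = len(C)
    if Lc < 2 * min_flank:
        raise UnresolvableJunctionError(
            f"{sid}: consensus shorter than two {min_flank} bp flanks"
        )

    # left flank: anchor the first min_flank bases upstream of s, extend right
    seed = C[:min_flank]
    x = R.rfind(seed, max(0, s - anchor_search), s)
    if x < 0:
        raise UnresolvableJunctionError(
            f"{sid}: left flank of consensus not found within {anchor_search} bp upstream of start"
        )
    p = min_flank
    while p < Lc and x + p < len(R) and _bases_match(C[p], R[x + p]):
        p += 1
    left_flank = s - x
    if left_flank < min_flank or p < left_flank:
        raise UnresolvableJunctionError(
            f"{sid}: left flank match ({min(p, left_flank)} bp) does not reach the start breakpoint"
        )

    # right flank: anchor the last min_flank bases downstream of e, extend left
    seed = C[-min_flank:]
    y = R.find(seed, e, min(len(R), e + anchor_search))
    if y < 0:
        raise UnresolvableJunctionError(
            f"{sid}: right flank of consensus not found within {anchor_search} bp downstream of end"
        )
    q = min_flank
    while q < Lc and y + min_flank - 1 - q >= 0 and _bases_match(C[Lc - 1 - q], R[y + min_flank - 1 - q]):
        q += 1
    right_flank = (y + min_flank) - e
    if right_flank < min_flank or q < right_flank:
        raise UnresolvableJunctionError(
            f"{sid}: right flank match ({min(q, right_flank)} bp) does not reach the end breakpoint"
        )

    overlap = p + q - Lc
    if overlap > 0:
        coord = microhomology_from_coordinates(reference, deletion)
        mh_right = min(coord.mh_right, overlap)
        mh_left = overlap - mh_right
        call = JunctionCall(sid, mh_left, mh_right, "", coord.ambiguity_interval, capped=coord.capped)
    else:
        inserted = C[p : Lc - q]
        residual = microhomology_from_coordinates(reference, deletion)
        call = JunctionCall(
            sid,
            0,
            0,
            inserted,
            GenomeInterval(deletion.deletion.contig, s, s + 1),
            residual_flank_match=residual.mh_total,
        )
        if len(inserted) >= 3:
            call.insertion_sources = find_insertion_template(
                reference, deletion, inserted
            )
    call.mechanism = classify_mechanism(call)
    return call


def classify_mechanism(junction_call: JunctionCall) -> Mechanism:
    """Map (microhomology, insertion length) to a repair-mechanism label.

    Total function; insertion takes precedence over flank matching.
    """
    ins = len(junction_call.inserted_seq)
    if ins > 10:
        return Mechanism.LARGE_INSERTION
    if ins >= 1:
        return Mechanism.AROR
    mh = junction_call.mh_total
    if mh <= 1:
        return Mechanism.NHEJ
    if mh <= 20:
        return Mechanism.MMEJ
    return Mechanism.EXTENSIVE_HOMOLOGY


def find_insertion_template(
    reference: ReferenceSequence,
    deletion: DeletionCall,
    inserted_seq: str,
    search_radius: int = 100,
) -> list[InsertionSource]:
    """All exact occurrences of the insertion (either strand) near a breakpoint.

    Short templated insertions copied from sequence proximal to the break are
    the expected signature of replication slippage / re-replication.
    """
    ins = normalize_sequence(inserted_seq)
    if len(ins) < 3:
        raise ValidationError("inserted_seq must be at least 3 bp to search for a template")
    R = reference.seq
    hits: list[InsertionSource] = []
    probes = [(ins, "+")]
    rc = reverse_complement(ins)
    probes.append((rc, "-"))
    for bp_name, bp_pos in (("start", deletion.deletion.start), ("end", deletion.deletion.end)):
        lo = max(0, bp_pos - search_radius)
        hi = min(len(R), bp_pos + search_radius)
        window = R[lo:hi]
        for probe, strand in probes:
            start = 0
            while True:
                i = window.find(probe, start)
                if i < 0:
                    break
                hits.append(
                    InsertionSource(
                        GenomeInterval(deletion.deletion.contig, lo + i, lo + i + len(probe)),
                        strand,
                        bp_name,
                    )
                )
                start = i + 1
    return hits


@dataclass(frozen=True)
class MechanismSummary:
    """Cohort counts and one-decimal percentages per mechanism."""

    n: int
    counts: dict[str, int]
    percentages: dict[str, float]


def summarize_mechanisms(calls: Sequence[JunctionCall]) -> MechanismSummary:
    if not calls:
        raise ValidationError("cannot summarize an empty cohort")
    counts = {m.value: 0 for m in Mechanism}
    for call in calls:
        counts[call.mechanism.value] += 1
    n = len(calls)
    percentages = {m: round_half_up(100.0 * c / n, 1) for m, c in counts.items()}
    return MechanismSummary(n=n, counts=counts, percentages=percentages)
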