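"""Seeded generators for random sequences and deletion cohorts with planted truth.

The generator is the test bed for every analysis stage: it plants deletions
whose junctions carry an exact, known microhomology length (0-25 bp) or a
templated insertion (1-10 bp copied from reference sequence near the start
breakpoint), plus optional junction-proximal motifs.  Guard bases flanking
every planted homology run are forced to mismatch, so the planted length is
exact rather than a lower bound and round-trip recovery tests are sharp.

All outputs are pure functions of their seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import GenerationError, ValidationError
from .junction_mech import Mechanism
from .seq_core import (
    DeletionCall,
    GenomeInterval,
    ReferenceSequence,
    reverse_complement,
    write_breakpoint_table,
    write_fasta,
)

_BASES = "ACGT"
UNIFORM = (0.25, 0.25, 0.25, 0.25)
#: AT-rich option mirroring the gene's measured composition (GC ~ 0.36)
GENOME_LIKE = (0.32, 0.18, 0.18, 0.32)

#: mechanism mix observed in the motivating 22-sample cohort (8 NHEJ, 13 MMEJ, 1 AROR)
DEFAULT_MECHANISM_MIX = {
    Mechanism.NHEJ: 8 / 22,
    Mechanism.MMEJ: 13 / 22,
    Mechanism.AROR: 1 / 22,
}

MOTIF_CLASSES = ("PALINDROME", "POLYPYRIMIDINE", "TTTAAA", "TG_MOTIF")


def _check_composition(composition: Sequence[float]) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,):
        raise ValidationError("composition must have four probabilities (A, C, G, T)")
    if (comp < 0).any():
        raise ValidationError("composition probabilities must be non-negative")
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValidationError("composition must sum to 1 within 1e-9")
    return comp


def random_dna(
    length: int,
    composition: Sequence[float] = UNIFORM,
    seed: int | np.random.Generator = 0,
) -> str:
    """An i.i.d. random DNA string; identical inputs give identical output."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    comp = _check_composition(composition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=comp)
    return "".join(_BASES[i] for i in idx)


@dataclass(frozen=True)
class JunctionTruth:
    """Ground truth planted at one junction."""

    planted_microhomology: int
    planted_insertion: str = ""
    insertion_template_offset: Optional[int] = None
    planted_motifs: tuple[tuple[str, int], ...] = ()


@dataclass
class SyntheticCohort:
    reference: ReferenceSequence
    calls: list[DeletionCall]
    truths: dict[str, JunctionTruth]
    seed: int


def _different_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def plant_motif(
    seq: str,
    motif_class: str,
    position: int,
    seed: int | np.random.Generator = 0,
    length: Optional[int] = None,
) -> str:
    """Overwrite ``seq`` at ``position`` with an instance of a motif class.

    Palindrome instances (default 6 bp) are drawn as h + revcomp(h);
    polypyrimidine runs (default 7 bp) from {C, T}; TTTAAA is literal;
    TG_MOTIF draws the degenerate positions of TG(A/G)(A/G)(G/T)(A/C).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if motif_class == "TTTAAA":
        instance = "TTTAAA"
    elif motif_class == "TG_MOTIF":
        instance = "TG" + "".join(
            s[int(rng.integers(len(s)))] for s in ("AG", "AG", "GT", "AC")
        )
    elif motif_class == "PALINDROME":
        n = 6 if length is None else length
        if n < 4 or n % 2:
            raise ValidationError("palindrome length must be even and >= 4")
        half = random_dna(n // 2, seed=rng)
        instance = half + reverse_complement(half)
    elif motif_class == "POLYPYRIMIDINE":
        n = 7 if length is None else length
        if n < 2:
            raise ValidationError("polypyrimidine length must be >= 2")
        instance = "".join("CT"[int(rng.integers(2))] for _ in range(n))
    else:
        raise ValidationError(f"unknown motif class {motif_class!r}")
    if position < 0 or position + len(instance) > len(seq):
        raise ValidationError("motif does not fit within the sequence at that position")
    return seq[:position] + instance + seq[position + len(instance) :]


def plant_deletion(
    reference: ReferenceSequence,
    start: int,
    del_length: int,
    microhomology: int = 0,
    insertion_length: int = 0,
    insertion_template_offset: Optional[int] = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "synthetic",
    flank: int = 200,
) -> tuple[ReferenceSequence, DeletionCall, JunctionTruth]:
    """Edit ``reference`` so the junction of [start, start+del_length) carries
    exactly the requested microhomology or templated insertion.

    Right-anchored microhomology: the k bases after the start breakpoint are
    made equal to the k bases after the end breakpoint; guard bases on the
    deleted side of both breakpoints are forced to mismatch so the total run
    is exactly k.  The emitted junction consensus carries ``flank`` bp of
    (edited) reference on each side of the junction plus any insertion.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if microhomology < 0 or microhomology > 25:
        raise ValidationError("microhomology must be in 0..25")
    if insertion_length < 0 or insertion_length > 10:
        raise ValidationError("insertion_length must be in 0..10")
    if microhomology > 0 and insertion_length > 0:
        raise ValidationError("planted microhomology and insertion are mutually exclusive")
    s = start
    e = start + del_length
    k = microhomology
    if del_length < max(k, 2) + 2:
        raise GenerationError("deletion too short for the planted junction structure")
    if s < flank or e + flank + k + 1 > len(reference):
        raise GenerationError("flanks of >= %d bp are required around both breakpoints" % flank)

    R = list(reference.seq)

    if insertion_length > 0:
        if insertion_template_offset is None:
            insertion_template_offset = -int(rng.integers(insertion_length + 2, 81))
        t0 = s + insertion_template_offset
        t1 = t0 + insertion_length
        if t0 < 0 or t1 > len(R):
            raise GenerationError("insertion template window falls outside the contig")
        if any(t0 <= pos < t1 for pos in (s - 1, s, e - 1, e)):
            raise GenerationError(
                "insertion template window may not contain a breakpoint guard base"
            )
        # guards: no accidental microhomology, and exact insertion boundaries
        if R[s - 1] == R[e - 1] or R[e - 1] == "N":
            R[e - 1] = _different_base(rng, R[s - 1], "N")
        insertion = "".join(R[t0:t1])
        if R[s] == R[e] or R[s] == insertion[0] or R[s] == "N":
            R[s] = _different_base(rng, R[e], insertion[0], "N")
        if R[e - 1] == insertion[-1]:
            R[e - 1] = _different_base(rng, R[s - 1], insertion[-1], "N")
        insertion = "".join(R[t0:t1])  # guards never overlap the template window
    else:
        insertion = ""
        if k > 0:
            core = random_dna(k, seed=rng)
            R[s : s + k] = core
            R[e : e + k] = core
        # guard the run on both sides (deleted-side bases are edited)
        if R[s - 1] == R[e - 1] or R[e - 1] == "N":
            R[e - 1] = _different_base(rng, R[s - 1], "N")
        if R[s + k] == R[e + k] or R[s + k] == "N":
            R[s + k] = _different_base(rng, R[e + k], "N")

    edited = ReferenceSequence(reference.name, "".join(R))
    consensus = edited.seq[s - flank : s] + insertion + edited.seq[e : e + flank]
    call = DeletionCall(
        sample_id,
        GenomeInterval(reference.name, s, e),
        junction_consensus=consensus,
    )
    truth = JunctionTruth(
        planted_microhomology=k,
        planted_insertion=insertion,
        insertion_template_offset=insertion_template_offset if insertion else None,
    )
    return edited, call, truth


def _apportion(n: int, mix: dict[Mechanism, float]) -> dict[Mechanism, int]:
    """Largest-remainder apportionment of n samples to mixture proportions."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError("mechanism mixture proportions must sum to 1")
    quotas = {m: n * p for m, p in mix.items()}
    counts = {m: int(q) for m, q in quotas.items()}
    short = n - sum(counts.values())
    for m in sorted(mix, key=lambda m: quotas[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    return counts


def generate_cohort(
    n_samples: int,
    mechanism_mix: Optional[dict[Mechanism, float]] = None,
    seed: int = 0,
    del_length_range: tuple[int, int] = (1000, 3000),
    spacing: int = 600,
    composition: Sequence[float] = UNIFORM,
    contig_name: str = "chrSYN",
    planted_motifs: Optional[Sequence[tuple[str, int]]] = None,
) -> SyntheticCohort:
    """One contig carrying ``n_samples`` non-overlapping planted deletions.

    Mechanism labels are apportioned exactly to the mixture (largest
    remainder), then shuffled across samples.  NHEJ junctions get 0-1 bp
    microhomology, MMEJ 2-20 bp, AROR a 1-10 bp templated insertion.
    ``planted_motifs`` is a list of (motif_class, offset) planted relative to
    each start breakpoint (offsets must keep clear of the junction guards).
    """
    if n_samples < 0:
        raise ValidationError("n_samples must be >= 0")
    mix = dict(mechanism_mix) if mechanism_mix is not None else dict(DEFAULT_MECHANISM_MIX)
    rng = np.random.default_rng(seed)
    if n_samples == 0:
        ref = ReferenceSequence(contig_name, random_dna(1000, composition, rng))
        return SyntheticCohort(ref, [], {}, seed)

    counts = _apportion(n_samples, mix)
    labels: list[Mechanism] = [m for m, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)  # type: ignore[arg-type]

    max_del = del_length_range[1]
    contig_len = 2 * spacing + n_samples * (max_del + 2 * spacing)
    if contig_len < n_samples * (del_length_range[0] + 2 * spacing):
        raise GenerationError("contig too small for the requested non-overlapping deletions")
    ref = ReferenceSequence(contig_name, random_dna(contig_len, composition, rng))

    calls: list[DeletionCall] = []
    truths: dict[str, JunctionTruth] = {}
    cursor = spacing
    for i, mech in enumerate(labels):
        sample_id = f"S{i + 1:02d}"
        del_len = int(rng.integers(del_length_range[0], del_length_range[1] + 1))
        start = cursor + spacing
        mh, ins_len = 0, 0
        if mech is Mechanism.NHEJ:
            mh = int(rng.integers(0, 2))
        elif mech is Mechanism.MMEJ:
            mh = int(rng.integers(2, 21))
        elif mech is Mechanism.AROR:
            ins_len = int(rng.integers(1, 11))
        else:
            raise ValidationError(f"unsupported mechanism in mixture: {mech}")
        ref, call, truth = plant_deletion(
            ref,
            start,
            del_len,
            microhomology=mh,
            insertion_length=ins_len,
            seed=rng,
            sample_id=sample_id,
        )
        if planted_motifs:
            seq = list(ref.seq)
            planted: list[tuple[str, int]] = []
            for motif_class, offset in planted_motifs:
                motif_len = 7 if motif_class == "POLYPYRIMIDINE" else 6
                # keep motifs inside the retained left flank, clear of the
                # junction guard base at start-1
                if offset < -150 or offset + motif_len > -1:
                    raise ValidationError(
                        "planted motif offset must keep the motif within "
                        "[-150, -2] of the start breakpoint"
                    )
                new = plant_motif("".join(seq), motif_class, start + offset, rng)
                seq = list(new)
                planted.append((motif_class, offset))
            ref = ReferenceSequence(ref.name, "".join(seq))
            # re-emit the consensus from the motif-edited reference
            flank = 200
            consensus = (
                ref.seq[start - flank : start]
                + truth.planted_insertion
                + ref.seq[start + del_len : start + del_len + flank]
            )
            call = DeletionCall(sample_id, call.deletion, junction_consensus=consensus)
            truth = JunctionTruth(
                truth.planted_microhomology,
                truth.planted_insertion,
                truth.insertion_template_offset,
                tuple(planted),
            )
        calls.append(call)
        truths[sample_id] = truth
        cursor = start + del_len + spacing
    return SyntheticCohort(ref, calls, truths, seed)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Emit reference FASTA, breakpoint TSV, junction FASTA and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": str(outdir / "reference.fa"),
        "breakpoints": str(outdir / "breakpoints.tsv"),
        "junctions": str(outdir / "junctions.fa"),
        "truth": str(outdir / "truth.json"),
    }
    write_fasta([cohort.reference], paths["reference"])
    write_breakpoint_table(cohort.calls, paths["breakpoints"])
    junction_records = [
        ReferenceSequence(f"{c.sample_id}_junction", c.junction_consensus)
        for c in cohort.calls
        if c.junction_consensus
    ]
    if junction_records:
        write_fasta(junction_records, paths["junctions"])
    truth_json = {
        sid: {
            "planted_microhomology": t.planted_microhomology,
            "planted_insertion": t.planted_insertion,
            "insertion_template_offset": t.insertion_template_offset,
            "planted_motifs": [list(m) for m in t.planted_motifs],
        }
        for sid, t in cohort.truths.items()
    }
    with open(paths["truth"], "w") as fh:
        json.dump({"seed": cohort.seed, "truths": truth_json}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
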