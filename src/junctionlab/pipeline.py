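"""Pipeline orchestration: cohort in, merged junction/motif/similarity/fold/stats report out.

Stages run in dependency order on either real inputs (reference FASTA +
breakpoint TSV, optional junction FASTA / RepeatMasker .out) or a synthetic
cohort generated in place.  Every stochastic stage consumes a seed recorded
in the run report; a fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .cohort_stats import distribution_report, repeat_content
from .errors import ValidationError
from .fold_proxy import cohort_fold_summary, fold_cohort
from .junction_mech import JunctionCall, resolve_junction, summarize_mechanisms
from .motif_scan import JunctionMotifReport, annotate_junction
from .seq_core import (
    COORDS_ONE_INCLUSIVE,
    DeletionCall,
    GenomeInterval,
    ReferenceSequence,
    read_breakpoint_table,
    read_fasta,
    read_repeatmasker_out,
)
from .similarity_null import DEFAULT_WINDOWS, METRICS, cohort_similarity
from .synthetic_cohort import SyntheticCohort, generate_cohort, write_cohort


@dataclass
class PipelineConfig:
    """Declarative configuration; exactly one of real inputs or synthesis."""

    out_dir: str = "junctionlab_out"
    seed: int = 0
    # real inputs
    reference_fasta: Optional[str] = None
    breakpoint_table: Optional[str] = None
    junction_fasta: Optional[str] = None
    repeatmasker_out: Optional[str] = None
    coords: str = COORDS_ONE_INCLUSIVE
    # synthesis
    synthesize: bool = False
    n_samples: int = 22
    # stage knobs, every analysis-level default surfaced for override
    window_half: int = 50
    similarity_windows: Sequence[int] = DEFAULT_WINDOWS
    n_pairs: int = 10_000
    min_loop: int = 3
    allow_gt: bool = False
    root_orientation: str = "reverse-complement"
    clustering_window: int = 500

    def validate(self) -> None:
        real = self.reference_fasta is not None or self.breakpoint_table is not None
        if real and self.synthesize:
            raise ValidationError("choose either real inputs or synthesis, not both")
        if not real and not self.synthesize:
            raise ValidationError("no inputs: provide files or enable synthesis")
        if real and (self.reference_fasta is None or self.breakpoint_table is None):
            raise ValidationError("real input mode needs both a reference FASTA and a breakpoint table")


@dataclass
class RunReport:
    config: dict
    version: str
    seed: int
    stage_outputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)


def _dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=vars(config).copy(), version=__version__, seed=config.seed)

    def _stage(name):
        t0 = time.perf_counter()

        def _done(path: Path) -> None:
            report.stage_outputs[name] = str(path)
            report.stage_seconds[name] = round(time.perf_counter() - t0, 3)

        return _done

    # inputs
    done = _stage("inputs")
    if config.synthesize:
        cohort = generate_cohort(config.n_samples, seed=config.seed)
        paths = write_cohort(cohort, out / "cohort")
        reference, calls = cohort.reference, cohort.calls
        done(Path(paths["breakpoints"]))
    else:
        references = read_fasta(config.reference_fasta)
        calls = read_breakpoint_table(
            config.breakpoint_table, coords=config.coords, junction_fasta=config.junction_fasta
        )
        contigs = {c.deletion.contig for c in calls}
        by_name = {r.name: r for r in references}
        missing = contigs - set(by_name)
        if missing:
            raise ValidationError(f"breakpoint table names unknown contig(s) {sorted(missing)}")
        if len(contigs) > 1:
            raise ValidationError("pipeline runs one contig at a time")
        reference = by_name[contigs.pop()]
        done(Path(config.breakpoint_table))

    # junctions
    done = _stage("junctions")
    junction_calls = [resolve_junction(reference, c) for c in calls]
    summary = summarize_mechanisms(junction_calls)
    junctions_tsv = out / "junctions.tsv"
    with open(junctions_tsv, "w") as fh:
        fh.write(
            "sample_id\tmh_left\tmh_right\tmh_total\tinsertion\tinsertion_sources\t"
            "mechanism\tambiguity_interval\n"
        )
        for jc in junction_calls:
            sources = ";".join(
                f"{src.interval}({src.strand},{src.breakpoint})" for src in jc.insertion_sources
            )
            fh.write(
                f"{jc.sample_id}\t{jc.mh_left}\t{jc.mh_right}\t{jc.mh_total}\t"
                f"{jc.inserted_seq or '.'}\t{sources or '.'}\t{jc.mechanism.value}\t"
                f"{jc.ambiguity_interval}\n"
            )
    _dump(
        {"n": summary.n, "counts": summary.counts, "percentages": summary.percentages},
        out / "mechanism_summary.json",
    )
    done(junctions_tsv)

    # motifs
    done = _stage("motifs")
    motif_reports = [annotate_junction(reference, c, config.window_half) for c in calls]
    motifs_tsv = out / "motifs.tsv"
    with open(motifs_tsv, "w") as fh:
        fh.write("sample_id\twindow\tmotif_class\tstart\tend\tstrand\tmatched_text\n")
        for rep in motif_reports:
            for name, win in rep.windows.items():
                for cls, hits in win.hits.items():
                    for h in hits:
                        fh.write(
                            f"{rep.sample_id}\t{name}\t{cls}\t{h.start}\t{h.end}\t"
                            f"{h.strand}\t{h.matched_text}\n"
                        )
    panels = out / "junction_panels.txt"
    with open(panels, "w") as fh:
        for call, jc, rep in zip(calls, junction_calls, motif_reports):
            fh.write(render_junction_figure(reference, call, jc, rep) + "\n")
    done(motifs_tsv)

    # similarity
    done = _stage("similarity")
    sim = cohort_similarity(
        reference,
        calls,
        window_lengths=config.similarity_windows,
        n_pairs=config.n_pairs,
        seed=config.seed,
        orientation=config.root_orientation,
    )
    sim_tsv = out / "similarity.tsv"
    keys = [(m, w) for m in sim.metrics for w in sim.window_lengths]
    with open(sim_tsv, "w") as fh:
        fh.write("row\t" + "\t".join(f"{m}_{w}" for m, w in keys) + "\n")
        for sid, vals in sim.per_sample.items():
            fh.write(sid + "\t" + "\t".join(str(vals.get(k, "NA")) for k in keys) + "\n")
        for row, data in (
            ("mean", sim.cohort_mean),
            ("sd", sim.cohort_sd),
            ("null_mean", sim.null_mean),
            ("null_sd", sim.null_sd),
            ("p_value", sim.p_values),
        ):
            fh.write(row + "\t" + "\t".join(f"{data[k]:.4g}" for k in keys) + "\n")
    _dump(
        {
            "test": sim.test_used,
            "z_flags": {
                sid: {f"{m}_{w}": [round(z, 3), tier] for (m, w), (z, tier) in flags.items()}
                for sid, flags in sim.z_flags.items()
            },
        },
        out / "similarity_flags.json",
    )
    done(sim_tsv)

    # fold
    done = _stage("fold")
    folds = fold_cohort(reference, calls, config.window_half, config.min_loop, config.allow_gt)
    fold_tsv = out / "folds.tsv"
    with open(fold_tsv, "w") as fh:
        fh.write("sample_id\tbreakpoint\tcontext\tn_pairs\tstructure\n")
        for sid, anchor, fold in folds:
            fh.write(
                f"{sid}\t{anchor}\t{fold.breakpoint_context}\t{fold.n_pairs}\t{fold.structure_string}\n"
            )
    _dump(cohort_fold_summary([f for _, _, f in folds]), out / "fold_summary.json")
    done(fold_tsv)

    # cohort stats
    done = _stage("cohort_stats")
    ref_interval = GenomeInterval(reference.name, 0, len(reference))
    dist = distribution_report(
        calls, reference_interval=ref_interval, window_width=config.clustering_window
    )
    stats_json = out / "distribution.json"
    _dump(vars(dist), stats_json)
    if config.repeatmasker_out:
        annotations = read_repeatmasker_out(config.repeatmasker_out)
        rc = repeat_content(annotations, ref_interval, reference)
        _dump(
            {
                "region": str(rc.region),
                "total_length": rc.total_length,
                "occupied_bp": rc.occupied_bp,
                "percent": rc.percent,
                "gc_level": rc.gc_level,
            },
            out / "repeat_content.json",
        )
    done(stats_json)

    _dump(
        {
            "version": report.version,
            "seed": report.seed,
            "config": report.config,
            "stage_outputs": report.stage_outputs,
            "stage_seconds": report.stage_seconds,
        },
        out / "run_report.json",
    )
    return report


def render_junction_figure(
    reference: ReferenceSequence,
    deletion: DeletionCall,
    junction_call: JunctionCall,
    motif_report: Optional[JunctionMotifReport] = None,
    flank: int = 50,
) -> str:
    """Plain-text panel: the joined junction over its two reference flanks.

    Microhomology is bracketed on all lines, an insertion is delimited with
    [ ], and motif spans in the junction window are underlined with class
    tags on extra rows.
    """
    R = reference.seq
    s, e = deletion.deletion.start, deletion.deletion.end
    mh = junction_call.mh_total
    ins = junction_call.inserted_seq
    left = R[max(0, s - flank) : s]
    right = R[e : e + flank]
    joined = left + (f"[{ins}]" if ins else "") + right

    lines = []
    lines.append(f"# {junction_call.sample_id}  mechanism={junction_call.mechanism.value}  "
                 f"mh={junction_call.mh_left}+{junction_call.mh_right}  ins={len(ins)}bp")
    pad = " " * 8
    if mh:
        # the shared run as seen at the junction; identical at both breakpoints
        run_lo = s - junction_call.mh_left
        mh_seq = R[run_lo : s + junction_call.mh_right]
        left = R[max(0, run_lo - flank) : run_lo]
        right = R[e + junction_call.mh_right : e + junction_call.mh_right + flank]
        lines.append(f"ref_start{pad}...{left}({mh_seq})...")
        lines.append(f"junction {pad}...{left}({mh_seq}){right}...")
        lines.append(f"ref_end  {pad}...({mh_seq}){right}...")
    else:
        lines.append(f"ref_start{pad}...{left}|")
        lines.append(f"junction {pad}...{joined}...")
        lines.append(f"ref_end  {pad}|{right}...")
    if motif_report is not None:
        win = motif_report.windows.get("junction")
        if win is not None:
            for cls, hits in win.hits.items():
                for h in hits:
                    underline = " " * h.start + "~" * (h.end - h.start)
                    lines.append(f"motif {cls:>14} {underline}")
    return "\n".join(lines) + "\n"
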