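"""End-to-end orchestration: prep -> align -> classify -> call -> unanchored -> annotate.

``run_pipeline`` wires the stage modules together, threads one seed through
every source of randomness, audits read conservation (every input read ends
in exactly one terminal bin) and optionally persists the standard outputs
(BED of mapped fragments, call/cluster/unanchored TSVs, JSON run report).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .alignment import align, build_index, classify, export_bed
from .annotate import annotate_calls
from .peaks import (
    InsertionCall,
    PipelineConfig,
    calls_to_table,
    call_insertions,
    form_peaks,
)
from .readprep import (
    RawRead,
    ReadStructure,
    cluster_table,
    cluster_umis,
    demultiplex_and_extract,
    parse_fastq,
    quality_length_filter,
)
from .simulate import SimRead, SyntheticGenome
from .unanchored import (
    RepeatLibrary,
    UnanchoredPeak,
    assign_repeat,
    call_flanks,
    call_unanchored,
    cluster_by_identity,
    discard_called,
    unanchored_table,
)


@dataclass
class RunReport:
    """Per-stage accounting of a pipeline run.

    Terminal read bins (qc_failed, structure_rejected, reads_in_clusters)
    must sum to the input read count; fragment bins (anchored,
    unanchored_discarded, unanchored_assigned, unassigned) must sum to the
    fragment count.
    """

    n_input_reads: int = 0
    n_qc_failed: int = 0
    n_structure_rejected: int = 0
    n_reads_in_clusters: int = 0
    n_fragments: int = 0
    n_anchored: int = 0
    n_unanchored: int = 0
    n_unanchored_discarded: int = 0
    n_unanchored_assigned: int = 0
    n_unassigned: int = 0
    n_calls: int = 0
    n_unanchored_putative: int = 0
    rejection_reasons: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def validate(self) -> None:
        total = self.n_qc_failed + self.n_structure_rejected + self.n_reads_in_clusters
        if total != self.n_input_reads:
            raise AssertionError(
                f"read conservation violated: {total} != {self.n_input_reads}"
            )
        frag_total = (
            self.n_anchored
            + self.n_unanchored_discarded
            + self.n_unanchored_assigned
            + self.n_unassigned
        )
        if frag_total != self.n_fragments:
            raise AssertionError(
                f"fragment conservation violated: {frag_total} != {self.n_fragments}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    calls: list[InsertionCall]
    unanchored_peaks: list[UnanchoredPeak]
    report: RunReport
    bed: str
    clusters: list = field(repr=False, default_factory=list)
    alignments: list = field(repr=False, default_factory=list)


def _as_raw(reads) -> list[RawRead]:
    out = []
    for r in reads:
        if isinstance(r, RawRead):
            out.append(r)
        elif isinstance(r, SimRead):
            out.append(RawRead(r.id, r.bases, r.qualities))
        else:
            rid, bases, quals = r
            out.append(RawRead(rid, bases, tuple(quals)))
    return out


def run_pipeline(
    config: PipelineConfig,
    reads,
    reference: SyntheticGenome | dict[str, str],
    structure: ReadStructure,
    repeat_library: RepeatLibrary | None = None,
    repeat_annotation=None,
    gene_annotation=None,
    out_dir=None,
) -> PipelineResult:
    """Run the full insertion-calling workflow on a set of raw reads.

    ``reads`` may be a FASTQ path or an iterable of read records.  Unanchored
    (repeat-family) calling runs when a ``repeat_library`` is supplied; call
    annotation when ``repeat_annotation``/``gene_annotation`` are.
    """
    raw = parse_fastq(reads) if isinstance(reads, (str,)) or hasattr(reads, "__fspath__") else _as_raw(reads)
    if not raw:
        raise ValueError("no input reads")
    report = RunReport(n_input_reads=len(raw), seed=config.seed, config=dataclasses.asdict(config))

    kept = quality_length_filter(raw, config.min_mean_q, config.min_len)
    report.n_qc_failed = len(raw) - len(kept)
    if not kept:
        raise ValueError("no reads passed quality/length filtering")

    processed, rejects = demultiplex_and_extract(kept, structure)
    report.n_structure_rejected = sum(rejects.values())
    report.rejection_reasons = rejects

    clusters = []
    for barcode in sorted({p.barcode_id for p in processed}):
        group = [p for p in processed if p.barcode_id == barcode]
        clusters.extend(
            cluster_umis(group, config.max_umi_edits, config.min_fragment_identity)
        )
    report.n_reads_in_clusters = sum(c.size for c in clusters)

    fragments = [(f"cluster_{i}", c.consensus_fragment) for i, c in enumerate(clusters)]
    report.n_fragments = len(fragments)
    index = build_index(reference)
    alignments = align(fragments, index, max_edit_fraction=config.max_error_fraction + 0.05)
    anchored, unanchored_reads = classify(alignments, config.min_mapq)
    report.n_anchored = len(anchored)
    report.n_unanchored = len(unanchored_reads)

    candidates = form_peaks(anchored)
    calls, _rejected = call_insertions(candidates, config)
    report.n_calls = len(calls)

    unanchored_peaks: list[UnanchoredPeak] = []
    frag_seqs = dict(fragments)
    un_pairs = [(a.query_id, frag_seqs[a.query_id]) for a in unanchored_reads]
    if repeat_library is not None and un_pairs:
        contigs = reference.contigs if isinstance(reference, SyntheticGenome) else reference
        flanks = call_flanks(contigs, calls)
        retained, discarded = discard_called(un_pairs, flanks)
        report.n_unanchored_discarded = len(discarded)
        assignments, unassigned = assign_repeat(retained, repeat_library)
        report.n_unanchored_assigned = len(assignments)
        report.n_unassigned = len(unassigned)
        mean_cov = (
            sum(c.dedup_count for c in calls) / len(calls) if calls else None
        )
        for family in sorted(set(assignments.values())):
            fam_reads = [(rid, frag_seqs[rid]) for rid in sorted(assignments) if assignments[rid] == family]
            fam_clusters = cluster_by_identity(fam_reads, family)
            unanchored_peaks.extend(
                call_unanchored(fam_clusters, mean_cov, repeat_library, config)
            )
    else:
        report.n_unassigned = len(un_pairs)
    report.n_unanchored_putative = len(unanchored_peaks)

    if repeat_annotation is not None or gene_annotation is not None:
        annotate_calls(
            calls, repeat_annotation or (), gene_annotation, repeat_window=config.repeat_window
        )

    report.validate()
    bed = export_bed(alignments)
    result = PipelineResult(
        calls=calls,
        unanchored_peaks=unanchored_peaks,
        report=report,
        bed=bed,
        clusters=clusters,
        alignments=alignments,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mapped_reads.bed").write_text(result.bed)
    from .peaks import calls_to_bed

    (out / "calls.bed").write_text(calls_to_bed(result.calls))
    calls_to_table(result.calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    cluster_table(result.clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    unanchored_table(result.unanchored_peaks).to_csv(
        out / "unanchored_putative.tsv", sep="\t", index=False
    )
    (out / "run_report.json").write_text(result.report.to_json())
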