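"""End-to-end driver: references -> mapping -> validation -> counting ->
resistance classification, plus the full-length reconstruction stage.

The driver is pure (in-memory inputs and outputs); the CLI wraps it with
file I/O.  Stage order mirrors the dependency chain: pseudo/last references
are built once, every read of both libraries is matched against them and
the transcriptome, junction-validated reads are remapped against genome and
transcriptome to strip linear-derived reads, surviving fragments are
counted, and species are classified from their A-tailing/control ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .align import UngappedIndex
from .annotation import Annotation, CircCandidate
from .bsj import (
    ATAIL,
    CONTROL,
    LibraryTotals,
    ResistanceCall,
    classify_resistance,
    count_and_filter,
    normalized_rc,
    remap_filter,
    validate_bsj_read,
)
from .config import RunConfig
from .references import (
    LinearReference,
    PseudoReference,
    build_last_exon_reference,
    build_pseudo_reference,
)
from .structure import (
    CircIsoform,
    JunctionTable,
    assemble_isoforms,
    detect_junctions,
    exon_coverage,
)

log = logging.getLogger(__name__)

Fragments = Sequence[tuple[str, str, str]]  # (fragment_id, mate1, mate2)


@dataclass
class BsjResult:
    candidates: list[CircCandidate]
    pseudo_refs: dict[str, PseudoReference]
    last_refs: dict[str, LinearReference]
    counts: dict[str, dict[str, int]]  # circ -> library -> BSJ fragment count
    low_count: set[str]
    normalized: dict[str, float]
    calls: dict[str, ResistanceCall]
    cutoff: float
    linear_table: pd.DataFrame
    linear_counts: dict[str, dict[str, int]]
    totals: LibraryTotals
    survivors: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # library -> read_id -> set of circ ids (post remap)
    validated: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # same, before the genome/transcriptome remap filter

    def confident_circs(self) -> set[str]:
        return {
            s for s, c in self.calls.items()
            if c.kind == "circ" and c.label == "confident"
        }


def run_bsj_pipeline(
    candidates: Sequence[CircCandidate],
    annotation: Annotation,
    genome: Mapping[str, str],
    reads: Mapping[str, Fragments],
    config: Optional[RunConfig] = None,
) -> BsjResult:
    """Quantify and classify candidate junctions from paired libraries.

    ``reads`` maps library name ('control', 'atail') to paired fragments.
    Last-exon references are built for every annotated gene so the
    resistance cutoff rests on the full linear-ratio distribution.
    """
    config = config or RunConfig()
    if set(reads) != {ATAIL, CONTROL}:
        raise ValueError(f"need libraries {{'{ATAIL}', '{CONTROL}'}}, got {set(reads)}")

    pseudo_refs = {
        c.circ_id: build_pseudo_reference(
            c, genome, flank=config.flank, seed_flank=config.seed_flank
        )
        for c in candidates
    }
    last_refs = {
        gid: build_last_exon_reference(gid, annotation, genome)
        for gid in sorted(annotation.genes)
    }

    match_kw = dict(
        k=config.kmer,
        max_mismatch=config.max_mismatch,
        min_overlap=config.min_overlap,
    )
    pseudo_index = UngappedIndex(
        {k: v.sequence for k, v in pseudo_refs.items()}, **match_kw
    )
    last_index = UngappedIndex(
        {k: v.sequence for k, v in last_refs.items()}, **match_kw
    )
    tx_index = UngappedIndex(
        {
            tid: t.spliced_sequence(genome)
            for tid, t in annotation.transcripts.items()
        },
        k=config.remap_kmer,
        max_mismatch=config.max_mismatch,
        full_length=True,
    )
    genome_index = UngappedIndex(
        {name: str(genome[name][:]).upper() for name in genome.keys()},
        k=config.remap_kmer,
        max_mismatch=config.max_mismatch,
        full_length=True,
    )

    survivors: dict[str, dict[str, set[str]]] = {}
    validated_all: dict[str, dict[str, set[str]]] = {}
    linear_assign: dict[str, dict[str, set[str]]] = {}
    totals = LibraryTotals()
    for lib, frags in reads.items():
        validated: dict[str, set[str]] = {}
        val_seq: dict[str, str] = {}
        tx_hits: set[str] = set()
        lin: dict[str, set[str]] = {}
        mapped_frags: set[str] = set()
        for fid, r1, r2 in frags:
            for mate, seq in ((1, r1), (2, r2)):
                rid = f"{fid}/{mate}"
                mapped = False
                p_alns = pseudo_index.match(seq, read_id=rid)
                if p_alns:
                    mapped = True
                    refs = {
                        a.reference_id
                        for a in p_alns
                        if validate_bsj_read(a, pseudo_refs[a.reference_id], seq)
                    }
                    if refs:
                        validated[rid] = refs
                        val_seq[rid] = seq
                l_alns = last_index.match(seq, read_id=rid)
                if l_alns:
                    mapped = True
                    lin[rid] = {a.reference_id for a in l_alns}
                if tx_index.match(seq):
                    mapped = True
                    tx_hits.add(rid)
                if mapped:
                    mapped_frags.add(fid)
        genome_hits = {
            rid for rid, seq in val_seq.items() if genome_index.match(seq)
        }
        surviving_ids = remap_filter(validated, genome_hits, tx_hits)
        survivors[lib] = {rid: validated[rid] for rid in surviving_ids}
        validated_all[lib] = validated
        linear_assign[lib] = lin
        totals.total_mapped_reads[lib] = len(mapped_frags)
        totals.total_sequencing_reads[lib] = 2 * len(frags)

    counts, low = count_and_filter(survivors, min_count=config.min_count)
    for lib in reads:
        totals.total_bsj_rc[lib] = sum(c.get(lib, 0) for c in counts.values())

    from .bsj import count_fragments

    linear_counts_by_lib = {lib: count_fragments(linear_assign[lib]) for lib in reads}
    linear_counts = {
        gid: {lib: linear_counts_by_lib[lib].get(gid, 0) for lib in reads}
        for gid in last_refs
    }

    normalized = {}
    if totals.total_bsj_rc.get(ATAIL, 0) > 0:
        for circ, c in counts.items():
            normalized[circ] = normalized_rc(c.get(ATAIL, 0), totals)

    calls, cutoff, linear_table = classify_resistance(
        counts,
        linear_counts,
        {gid: ref.exon_length for gid, ref in last_refs.items()},
        totals,
        quantile=config.quantile,
        pseudocount=config.pseudocount,
        low_count=low,
        min_linear=config.min_linear_refs,
    )
    return BsjResult(
        list(candidates),
        pseudo_refs,
        last_refs,
        counts,
        low,
        normalized,
        calls,
        cutoff,
        linear_table,
        linear_counts,
        totals,
        survivors,
        validated_all,
    )


# -------------------------------------------------------- structure stage


def reads_for_circ(
    result: BsjResult,
    reads: Mapping[str, Fragments],
    circ_id: str,
    library: str = ATAIL,
) -> list[tuple[str, str]]:
    """Both mates of every fragment with a junction-validated read for circ."""
    frag_ids = {
        rid.split("/", 1)[0]
        for rid, circs in result.survivors.get(library, {}).items()
        if circ_id in circs
    }
    out = []
    for fid, r1, r2 in reads[library]:
        if fid in frag_ids:
            out.append((f"{fid}/1", r1))
            out.append((f"{fid}/2", r2))
    return out


def reconstruct_structures(
    result: BsjResult,
    reads: Mapping[str, Fragments],
    annotation: Annotation,
    genome: Mapping[str, str],
    config: Optional[RunConfig] = None,
    circ_ids: Optional[Sequence[str]] = None,
    library: str = ATAIL,
) -> dict[str, tuple[JunctionTable, list[CircIsoform]]]:
    """Junction tables and isoform chains for confident circRNAs."""
    config = config or RunConfig()
    targets = list(circ_ids) if circ_ids is not None else sorted(result.confident_circs())
    by_id = {c.circ_id: c for c in result.candidates}
    out = {}
    for circ_id in targets:
        cand = by_id[circ_id]
        if cand.host_transcript is None:
            log.warning("%s: intergenic, skipping structure stage", circ_id)
            continue
        host = annotation.transcripts[cand.host_transcript]
        exons = [
            e for e in host.exons
            if cand.bsj_acceptor <= e.start and e.end <= cand.bsj_donor
        ]
        if not exons:
            continue
        circ_reads = reads_for_circ(result, reads, circ_id, library)
        table = detect_junctions(
            {library: circ_reads},
            cand,
            exons,
            genome,
            bsj_counts={library: result.counts.get(circ_id, {}).get(library, 0)},
            min_split_reads=config.min_split_reads,
            anchor=config.anchor,
        )
        cov = exon_coverage(circ_reads, exons, cand.chrom, genome)
        isoforms = assemble_isoforms(table, exons, cov, cand)
        out[circ_id] = (table, isoforms)
    return out
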