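"""Back-splice-junction read validation, counting, and resistance calls.

A read supports a back-splice junction only if its alignment to the
pseudo-reference covers the full central seed window with an exact match
(mismatches elsewhere up to the matcher's budget are tolerated).  Validated
reads that also map end-to-end to the genome or transcriptome are treated as
linear-derived and removed.  Surviving fragments are counted per junction and
per library; species are then classified as resistant (confident) or
sensitive to the A-tailing/RNase R treatment from their A-tailing/control
abundance ratio, with the cutoff set so that >=95% of linear last-exon
references fall at or below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .references import PseudoReference
from .sequences import revcomp

ATAIL = "atail"
CONTROL = "control"


# ------------------------------------------------------------- validation


def seed_mismatches(
    aln: ReadAlignment, ref: PseudoReference, read: str
) -> Optional[int]:
    """Mismatches of the read against the seed window, or None when the
    aligned span does not cover the whole window."""
    ws, we = ref.seed_window
    if not (aln.matched_start <= ws and aln.matched_end >= we):
        return None
    oriented = revcomp(read) if aln.orientation == "revcomp" else read
    read_seg = oriented[ws - aln.ref_start : we - aln.ref_start]
    return sum(1 for a, b in zip(read_seg, ref.seed) if a != b or a == "N")


def validate_bsj_read(aln: ReadAlignment, ref: PseudoReference, read: str) -> bool:
    """True iff the aligned read covers the seed window and matches it exactly."""
    mm = seed_mismatches(aln, ref, read)
    return mm == 0


def remap_filter(
    validated: Iterable[str],
    genome_hits: set[str],
    transcriptome_hits: set[str],
) -> set[str]:
    """Reads mapping to the genome or transcriptome are linear-derived: drop."""
    return set(validated) - (genome_hits | transcriptome_hits)


# --------------------------------------------------------------- counting


def fragment_stem(read_id: str) -> str:
    """Fragment id shared by both mates (strip an optional '/1', '/2' suffix)."""
    return read_id.split("/", 1)[0]


def count_fragments(assignments: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Per-species fragment counts with mate dedup.

    ``assignments`` maps read id -> species ids the read supports (ties are
    counted for every tied species).  A fragment contributes at most 1 to any
    one species even when both mates validate it.
    """
    seen: dict[str, set[str]] = {}
    for read_id, species in assignments.items():
        stem = fragment_stem(read_id)
        seen.setdefault(stem, set()).update(species)
    counts: dict[str, int] = {}
    for species_set in seen.values():
        for s in species_set:
            counts[s] = counts.get(s, 0) + 1
    return counts


def count_and_filter(
    assignments_by_library: Mapping[str, Mapping[str, Iterable[str]]],
    min_count: int = 2,
    atail_library: str = ATAIL,
) -> tuple[dict[str, dict[str, int]], set[str]]:
    """BSJ fragment counts per species per library + the low-count set.

    Species with fewer than ``min_count`` A-tailing fragments are flagged
    ``low_count`` (they are reported but never called confident).
    """
    libraries = list(assignments_by_library)
    per_lib = {lib: count_fragments(assignments_by_library[lib]) for lib in libraries}
    species = sorted(set().union(*[set(c) for c in per_lib.values()]) if per_lib else set())
    counts = {
        s: {lib: per_lib[lib].get(s, 0) for lib in libraries} for s in species
    }
    low = {s for s in species if counts[s].get(atail_library, 0) < min_count}
    return counts, low


# ---------------------------------------------------------- normalization


@dataclass
class LibraryTotals:
    """Per-library denominators; recomputed by the pipeline, never supplied."""

    total_bsj_rc: dict[str, int] = field(default_factory=dict)
    total_mapped_reads: dict[str, int] = field(default_factory=dict)
    total_sequencing_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.total_bsj_rc, self.total_mapped_reads, self.total_sequencing_reads):
            for lib, v in d.items():
                if v < 0:
                    raise ValueError(f"negative total for library {lib!r}")


def normalized_rc(bsj_rc_atail: int, totals: LibraryTotals) -> float:
    """Cross-library normalized read count for one circRNA:

        (BSJ RC in A-tailing) / (total BSJ RC in A-tailing)
      * (total BSJ RC in control) / (total mapped reads in control)
    """
    t_at = totals.total_bsj_rc.get(ATAIL, 0)
    t_ct = totals.total_bsj_rc.get(CONTROL, 0)
    mapped_ct = totals.total_mapped_reads.get(CONTROL, 0)
    if t_at <= 0:
        raise ValueError("zero total BSJ read count in A-tailing library")
    if mapped_ct <= 0:
        raise ValueError("zero total mapped reads in control library")
    return (bsj_rc_atail / t_at) * (t_ct / mapped_ct)


def rpkm(reads_count: int, total_sequencing_reads: int, exon_length: int) -> float:
    """Reads per kilobase per million sequenced reads."""
    if total_sequencing_reads <= 0:
        raise ValueError("zero total sequencing reads")
    if exon_length <= 0:
        raise ValueError("zero exon length")
    return reads_count * 1_000_000 * 1000 / (total_sequencing_reads * exon_length)


def nearest_rank_quantile(values: Iterable[float], q: float) -> float:
    """Inclusive empirical (nearest-rank) quantile."""
    vals = sorted(values)
    if not vals:
        raise ValueError("empty sample")
    if not 0 < q <= 1:
        raise ValueError("quantile must be in (0, 1]")
    k = math.ceil(q * len(vals))
    return vals[k - 1]


# ------------------------------------------------------------ resistance


@dataclass(frozen=True)
class ResistanceCall:
    species_id: str
    kind: str  # 'circ' | 'linear'
    atail_control_ratio: float
    label: str  # 'confident' | 'sensitive' | 'low_count'
    cutoff_used: float


def classify_resistance(
    circ_counts: Mapping[str, Mapping[str, int]],
    linear_counts: Mapping[str, Mapping[str, int]],
    linear_exon_lengths: Mapping[str, int],
    totals: LibraryTotals,
    quantile: float = 0.95,
    pseudocount: float = 0.5,
    low_count: Optional[set[str]] = None,
    min_linear: int = 20,
) -> tuple[dict[str, ResistanceCall], float, pd.DataFrame]:
    """Label species resistant (confident) vs sensitive to the treatment.

    Abundances are depth-normalized per library: BSJ counts per million
    mapped reads for circRNA candidates, last-exon RPKM for linear
    references.  ratio = (A-tailing + pseudocount) / (control + pseudocount).
    The cutoff is the inclusive nearest-rank ``quantile`` of the linear
    ratios (computed over linear references with nonzero control abundance);
    a candidate is confident iff its ratio is strictly above the cutoff.

    Returns (calls keyed by species, cutoff, linear ratio table).
    """
    low_count = low_count or set()
    mapped = totals.total_mapped_reads
    seqd = totals.total_sequencing_reads
    for lib in (ATAIL, CONTROL):
        if mapped.get(lib, 0) <= 0:
            raise ValueError(f"all-zero {lib} library: no mapped reads")

    def circ_abundance(rc: int, lib: str) -> float:
        return rc * 1_000_000 / mapped[lib]

    rows = []
    for gene, counts in linear_counts.items():
        length = linear_exon_lengths[gene]
        ab_ct = rpkm(counts.get(CONTROL, 0), seqd[CONTROL], length)
        ab_at = rpkm(counts.get(ATAIL, 0), seqd[ATAIL], length)
        if ab_ct <= 0:
            continue
        rows.append((gene, ab_at, ab_ct, (ab_at + pseudocount) / (ab_ct + pseudocount)))
    linear_table = pd.DataFrame(
        rows, columns=["gene_id", "abundance_atail", "abundance_control", "ratio"]
    )
    if len(linear_table) < min_linear:
        raise ValueError(
            f"cutoff unstable: only {len(linear_table)} linear references with "
            f"nonzero control abundance (need >= {min_linear})"
        )
    cutoff = float(nearest_rank_quantile(linear_table["ratio"], quantile))

    calls: dict[str, ResistanceCall] = {}
    for species, counts in circ_counts.items():
        ab_at = circ_abundance(counts.get(ATAIL, 0), ATAIL)
        ab_ct = circ_abundance(counts.get(CONTROL, 0), CONTROL)
        ratio = (ab_at + pseudocount) / (ab_ct + pseudocount)
        if species in low_count:
            label = "low_count"
        elif ratio > cutoff:
            label = "confident"
        else:
            label = "sensitive"
        calls[species] = ResistanceCall(species, "circ", ratio, label, cutoff)
    for _, row in linear_table.iterrows():
        calls[row.gene_id] = ResistanceCall(
            row.gene_id,
            "linear",
            float(row.ratio),
            "confident" if row.ratio > cutoff else "sensitive",
            cutoff,
        )
    return calls, cutoff, linear_table


def fraction_linear_at_or_below(linear_table: pd.DataFrame, cutoff: float) -> float:
    """Share of linear references whose ratio does not exceed the cutoff."""
    if len(linear_table) == 0:
        raise ValueError("empty linear table")
    return float(np.mean(linear_table["ratio"].to_numpy() <= cutoff))
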