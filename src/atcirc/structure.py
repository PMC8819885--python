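"""Full-length circRNA structure from split reads and isoform switching.

Mates of junction-validated fragments are matched against exon-exon junction
probes built from the candidate exons inside the circularized span.  A read
is a split read for a junction when it crosses the probe's splice point with
at least ``anchor`` matched nucleotides on each side.  Junctions supported by
more than two split reads are kept; maximal paths through the retained
junctions give the isoform chains, quantified by the junction-proportion
rule: count of a junction divided by the maximum count over all junctions
and the back-splice junction itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .align import UngappedIndex
from .annotation import CircCandidate, GenomicInterval
from .sequences import fetch

log = logging.getLogger(__name__)

Junction = tuple[int, int]  # (end of upstream exon, start of downstream exon)
BSJ_KEY = "BSJ"


@dataclass
class JunctionTable:
    """Split-read support per internal junction and per sample."""

    circ_id: str
    junction_counts: dict[str, dict[Junction, int]] = field(default_factory=dict)
    bsj_counts: dict[str, int] = field(default_factory=dict)

    def samples(self) -> list[str]:
        return sorted(set(self.junction_counts) | set(self.bsj_counts))

    def junctions(self) -> list[Junction]:
        out: set[Junction] = set()
        for counts in self.junction_counts.values():
            out.update(counts)
        return sorted(out)

    def pooled(self, junction: Junction) -> int:
        return sum(c.get(junction, 0) for c in self.junction_counts.values())

    def pooled_bsj(self) -> int:
        return sum(self.bsj_counts.values())

    def count(self, sample: str, junction: Junction) -> int:
        return self.junction_counts.get(sample, {}).get(junction, 0)


@dataclass(frozen=True)
class CircIsoform:
    circ_id: str
    isoform_id: str
    exons: tuple[GenomicInterval, ...]
    junctions: tuple[Junction, ...]
    proportion: Mapping[str, float]
    support: int
    dominant: bool = False


@dataclass(frozen=True)
class SwitchResult:
    circ_id: str
    junction: Junction
    inclusion_by_group: Mapping[str, float]
    inclusion_difference: float
    p_value: float
    direction: str  # 'short_to_long' | 'long_to_short'
    p_adjusted: Optional[float] = None


# -------------------------------------------------------------- detection


def _junction_probes(
    exons: Sequence[GenomicInterval],
    chrom: str,
    genome,
    probe_flank: int,
) -> dict[str, tuple[Junction, str, int]]:
    """name -> (junction, probe sequence, splice-point offset in probe)."""
    probes = {}
    for i, left in enumerate(exons):
        for right in exons[i + 1 :]:
            if left.end >= right.start:
                continue
            lseq = fetch(genome, chrom, max(left.start, left.end - probe_flank), left.end)
            rseq = fetch(
                genome, chrom, right.start, min(right.end, right.start + probe_flank)
            )
            name = f"J:{left.end}-{right.start}"
            probes[name] = ((left.end, right.start), lseq + rseq, len(lseq))
    return probes


def detect_junctions(
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    circ: CircCandidate,
    candidate_exons: Sequence[GenomicInterval],
    genome,
    bsj_counts: Optional[Mapping[str, int]] = None,
    min_split_reads: int = 3,
    anchor: int = 8,
    max_mismatch: int = 1,
    probe_flank: int = 80,
) -> JunctionTable:
    """Count split reads per exon-exon junction; drop junctions with fewer
    than ``min_split_reads`` pooled supporting reads.

    ``reads_by_sample`` maps sample name -> iterable of (read_id, sequence)
    for reads attributed to this circRNA.  A read supports a junction when
    its best probe alignment crosses the splice point with >= ``anchor``
    matched nt on each side.
    """
    exons = sorted(candidate_exons, key=lambda e: (e.start, e.end))
    probes = _junction_probes(exons, circ.chrom, genome, probe_flank)
    table = JunctionTable(circ.circ_id, bsj_counts=dict(bsj_counts or {}))
    if not probes:
        table.junction_counts = {s: {} for s in reads_by_sample}
        return table
    index = UngappedIndex(
        {name: seq for name, (junc, seq, _c) in probes.items()},
        k=anchor,
        max_mismatch=max_mismatch,
        min_overlap=2 * anchor,
    )
    for sample, reads in reads_by_sample.items():
        counts: dict[Junction, int] = {}
        for read_id, seq in reads:
            if len(seq) < 2 * anchor:
                continue
            for aln in index.match(seq, read_id=read_id):
                junc, _probe_seq, center = probes[aln.reference_id]
                if (
                    aln.matched_start <= center - anchor
                    and aln.matched_end >= center + anchor
                ):
                    counts[junc] = counts.get(junc, 0) + 1
        table.junction_counts[sample] = counts
    retained = {
        j for j in table.junctions() if table.pooled(j) >= min_split_reads
    }
    for sample in table.junction_counts:
        table.junction_counts[sample] = {
            j: c for j, c in table.junction_counts[sample].items() if j in retained
        }
    return table


def exon_coverage(
    reads: Sequence[tuple[str, str]],
    candidate_exons: Sequence[GenomicInterval],
    chrom: str,
    genome,
    max_mismatch: int = 3,
    min_overlap: int = 32,
) -> dict[GenomicInterval, int]:
    """Reads whose best match lands on each candidate exon (body coverage)."""
    exons = sorted(candidate_exons, key=lambda e: (e.start, e.end))
    names = {f"E:{e.start}-{e.end}": e for e in exons}
    index = UngappedIndex(
        {name: fetch(genome, chrom, e.start, e.end) for name, e in names.items()},
        k=8,
        max_mismatch=max_mismatch,
        min_overlap=min_overlap,
    )
    cov = {e: 0 for e in exons}
    for read_id, seq in reads:
        for aln in index.match(seq, read_id=read_id):
            cov[names[aln.reference_id]] += 1
    return cov


# ------------------------------------------------------------ proportions


def junction_proportion(table: JunctionTable, sample: str) -> dict:
    """Per-junction proportion: count / max(all junction counts and BSJ)."""
    counts = {j: table.count(sample, j) for j in table.junctions()}
    bsj = table.bsj_counts.get(sample, 0)
    denom = max([bsj, *counts.values()]) if counts else bsj
    if denom <= 0:
        raise ValueError(f"{table.circ_id}: all-zero junction table in {sample!r}")
    out = {j: c / denom for j, c in counts.items()}
    out[BSJ_KEY] = bsj / denom
    return out


# --------------------------------------------------------------- assembly


def assemble_isoforms(
    table: JunctionTable,
    candidate_exons: Sequence[GenomicInterval],
    coverage: Mapping[GenomicInterval, int],
    circ: CircCandidate,
    max_isoforms: int = 16,
) -> list[CircIsoform]:
    """Enumerate exon chains from the BSJ acceptor to the BSJ donor.

    Chains are maximal acceptor-to-donor paths through the retained
    junctions over exons with nonzero body coverage.  The dominant isoform
    maximizes the minimum supporting-junction count (ties: lexicographically
    smallest chain).  An isoform's per-sample proportion is the minimum
    junction proportion over its distinguishing junctions (1.0 when nothing
    distinguishes it).
    """
    exons = sorted(
        (e for e in candidate_exons if coverage.get(e, 0) > 0),
        key=lambda e: (e.start, e.end),
    )
    retained = set(table.junctions())
    start = next((e for e in exons if e.start == circ.bsj_acceptor), None)
    end = next((e for e in exons if e.end == circ.bsj_donor), None)

    def _fallback() -> list[CircIsoform]:
        log.warning(
            "%s: no junction path from acceptor to donor; emitting span isoform",
            circ.circ_id,
        )
        span = GenomicInterval(circ.chrom, circ.bsj_acceptor, circ.bsj_donor, circ.strand)
        props = {s: 1.0 for s in table.samples()}
        return [
            CircIsoform(circ.circ_id, f"{circ.circ_id}.i1", (span,), (), props,
                        table.pooled_bsj(), dominant=True)
        ]

    if start is None or end is None:
        return _fallback()

    succ: dict[GenomicInterval, list[GenomicInterval]] = {e: [] for e in exons}
    for u in exons:
        for v in exons:
            if u.end < v.start and (u.end, v.start) in retained:
                succ[u].append(v)

    chains: list[tuple[GenomicInterval, ...]] = []

    def dfs(node, path):
        if node is end:
            chains.append(tuple(path))
            return
        for nxt in succ[node]:
            dfs(nxt, path + [nxt])

    if start is end:
        chains.append((start,))
    else:
        dfs(start, [start])
    if not chains:
        return _fallback()

    def chain_junctions(chain) -> tuple[Junction, ...]:
        return tuple((u.end, v.start) for u, v in zip(chain, chain[1:]))

    def chain_support(chain) -> int:
        juncs = chain_junctions(chain)
        if not juncs:
            return table.pooled_bsj()
        return min(table.pooled(j) for j in juncs)

    chains.sort(key=lambda c: (-chain_support(c), [(e.start, e.end) for e in c]))
    if len(chains) > max_isoforms:
        log.warning(
            "%s: %d chains, capping at %d (longest-support-first)",
            circ.circ_id, len(chains), max_isoforms,
        )
        chains = chains[:max_isoforms]

    shared = set(chain_junctions(chains[0]))
    for c in chains[1:]:
        shared &= set(chain_junctions(c))

    samples = table.samples()
    isoforms = []
    for i, chain in enumerate(chains):
        juncs = chain_junctions(chain)
        distinguishing = [j for j in juncs if j not in shared]
        props = {}
        for s in samples:
            try:
                jp = junction_proportion(table, s)
            except ValueError:
                props[s] = float("nan")
                continue
            basis = distinguishing or list(juncs)
            props[s] = min((jp[j] for j in basis), default=1.0)
        isoforms.append(
            CircIsoform(
                circ.circ_id,
                f"{circ.circ_id}.i{i + 1}",
                chain,
                juncs,
                props,
                chain_support(chain),
                dominant=(i == 0),
            )
        )
    return isoforms


# ------------------------------------------------------------- switching


def inclusion_ttest(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided unpaired Student's t-test on inclusion levels.

    Degenerate case: zero variance in both groups gives p=1 for equal means
    (no evidence of change) and p=0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def test_isoform_switch(
    table: JunctionTable,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    min_diff: float = 0.2,
    adjust: bool = False,
    group_order: Optional[tuple[str, str]] = None,
) -> list[SwitchResult]:
    """Alternative-junction inclusion shifts between two sample groups.

    A junction is reported when the two-sided t-test on its inclusion levels
    gives p < ``alpha`` and the absolute mean inclusion difference exceeds
    ``min_diff``.  ``group_order`` names (baseline, treated); the inclusion
    difference is treated minus baseline, and direction is read for the
    inclusion isoform: rising inclusion is 'short_to_long'.
    """
    group_names = list(group_order) if group_order else sorted(set(groups.values()))
    if set(group_names) != set(groups.values()) or len(group_names) != 2:
        raise ValueError("exactly two groups required (matching group_order)")
    g1, g2 = group_names
    by_group: dict[str, list[str]] = {g: [] for g in group_names}
    for sample, g in groups.items():
        by_group[g].append(sample)
    if min(len(v) for v in by_group.values()) < 2:
        raise ValueError("at least 2 replicates per group required")

    inclusion: dict[str, dict] = {}
    for sample in groups:
        try:
            inclusion[sample] = junction_proportion(table, sample)
        except ValueError:
            continue

    candidates = []
    for junction in table.junctions():
        levels = {
            g: [inclusion[s][junction] for s in sorted(by_group[g]) if s in inclusion]
            for g in group_names
        }
        if min(len(v) for v in levels.values()) < 2:
            continue
        p = inclusion_ttest(levels[g1], levels[g2])
        diff = float(np.mean(levels[g2]) - np.mean(levels[g1]))
        candidates.append((junction, levels, diff, p))

    adj: list[Optional[float]] = [None] * len(candidates)
    if adjust and candidates:
        adj = list(
            stats.false_discovery_control([c[3] for c in candidates], method="bh")
        )

    out = []
    for (junction, levels, diff, p), p_adj in zip(candidates, adj):
        if p < alpha and abs(diff) > min_diff:
            out.append(
                SwitchResult(
                    table.circ_id,
                    junction,
                    {g: float(np.mean(v)) for g, v in levels.items()},
                    diff,
                    p,
                    "short_to_long" if diff > 0 else "long_to_short",
                    p_adjusted=p_adj,
                )
            )
    return out


test_isoform_switch.__test__ = False  # not a pytest case despite the name


def isoforms_to_bed12(isoforms: Sequence[CircIsoform], chrom_strand: Mapping[str, tuple[str, str]], path) -> None:
    """One BED12 record per isoform; blocks are the exon chain."""
    with open(path, "w") as fh:
        for iso in isoforms:
            chrom, strand = chrom_strand[iso.circ_id]
            start = iso.exons[0].start
            end = iso.exons[-1].end
            sizes = ",".join(str(e.length) for e in iso.exons)
            starts = ",".join(str(e.start - start) for e in iso.exons)
            fh.write(
                f"{chrom}\t{start}\t{end}\t{iso.isoform_id}\t{iso.support}\t{strand}\t"
                f"{start}\t{end}\t0\t{len(iso.exons)}\t{sizes}\t{starts}\n"
            )
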