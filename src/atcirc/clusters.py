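"""Alternative-circularization clusters.

circRNAs sharing a back-splice donor (alternative 3' back-splicing) or a
back-splice acceptor (alternative 5' back-splicing) form a cluster.  All
members share a common exonic sequence adjacent to the shared endpoint, so
cluster expression — the sum of member expression — can shift even when no
member does, and the common region is the natural unit for sponge scanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CircCandidate, GenomicInterval
from .structure import inclusion_ttest


@dataclass(frozen=True)
class CircCluster:
    cluster_id: str
    anchor_kind: str  # 'shared_donor' | 'shared_acceptor'
    chrom: str
    anchor_position: int
    strand: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("reported clusters need >= 2 members")


def build_clusters(
    circs: Iterable[CircCandidate], fuzz: int = 0
) -> list[CircCluster]:
    """One cluster per shared donor and per shared acceptor with >= 2 members.

    Anchors match on exact coordinate and strand (``fuzz`` > 0 merges anchors
    within that many nt; off by default).  A circRNA may sit in one
    donor-anchored and one acceptor-anchored cluster simultaneously.
    """
    circs = sorted(circs, key=lambda c: c.key)
    out = []
    for kind, keyfun in (
        ("shared_acceptor", lambda c: c.bsj_acceptor),
        ("shared_donor", lambda c: c.bsj_donor),
    ):
        groups: dict[tuple, list[CircCandidate]] = {}
        for c in circs:
            groups.setdefault((c.chrom, c.strand, keyfun(c)), []).append(c)
        if fuzz > 0:
            groups = _merge_fuzzy(groups, fuzz)
        for (chrom, strand, pos), members in sorted(groups.items()):
            if len(members) < 2:
                continue
            out.append(
                CircCluster(
                    f"cluster|{kind}|{chrom}:{pos}({strand})",
                    kind,
                    chrom,
                    pos,
                    strand,
                    tuple(m.circ_id for m in members),
                )
            )
    return out


def _merge_fuzzy(groups, fuzz):
    merged: dict[tuple, list] = {}
    for (chrom, strand, pos) in sorted(groups):
        placed = False
        for (mc, ms, mp) in list(merged):
            if mc == chrom and ms == strand and abs(mp - pos) <= fuzz:
                merged[(mc, ms, mp)].extend(groups[(chrom, strand, pos)])
                placed = True
                break
        if not placed:
            merged[(chrom, strand, pos)] = list(groups[(chrom, strand, pos)])
    return merged


def cluster_expression(
    cluster: CircCluster, counts: Mapping[str, Mapping[str, float]]
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-sample cluster expression (member sum) and member shares.

    ``counts`` maps circ_id -> {sample: normalized count}.  Shares are
    member / sum per sample (NaN when the sum is zero).
    """
    samples = sorted({s for m in cluster.members for s in counts[m]})
    sums = {
        s: float(sum(counts[m].get(s, 0.0) for m in cluster.members)) for s in samples
    }
    rows = []
    for m in cluster.members:
        for s in samples:
            v = counts[m].get(s, 0.0)
            share = v / sums[s] if sums[s] > 0 else float("nan")
            rows.append((m, s, v, share))
    shares = pd.DataFrame(rows, columns=["circ_id", "sample", "count", "share"])
    return sums, shares


def _interval_sets_intersection(
    sets: Sequence[Sequence[tuple[int, int]]]
) -> list[tuple[int, int]]:
    """Intersection of unions of half-open intervals (sort-merge)."""

    def normalize(ivs):
        ivs = sorted(ivs)
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    current = normalize(sets[0])
    for nxt in sets[1:]:
        nxt = normalize(nxt)
        merged = []
        i = j = 0
        while i < len(current) and j < len(nxt):
            s = max(current[i][0], nxt[j][0])
            e = min(current[i][1], nxt[j][1])
            if s < e:
                merged.append((s, e))
            if current[i][1] <= nxt[j][1]:
                i += 1
            else:
                j += 1
        current = merged
    return current


def common_region(
    cluster: CircCluster,
    member_exons: Mapping[str, Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Exonic bases shared by every cluster member.

    ``member_exons`` supplies each member's exon chain (fall back to the
    genomic span when structure is unknown).  With full chains the result is
    nonempty by construction — it contains the anchor-adjacent exon portion.
    """
    sets = [
        [(e.start, e.end) for e in member_exons[m]] for m in cluster.members
    ]
    ivs = _interval_sets_intersection(sets)
    if not ivs:
        import logging

        logging.getLogger(__name__).warning(
            "%s: empty common region (span-only members?); reporting anchor base",
            cluster.cluster_id,
        )
        pos = cluster.anchor_position
        base = (pos - 1, pos) if cluster.anchor_kind == "shared_donor" else (pos, pos + 1)
        ivs = [base]
    return [GenomicInterval(cluster.chrom, s, e, cluster.strand) for s, e in ivs]


@dataclass(frozen=True)
class ClusterDEResult:
    cluster_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    member_p: Mapping[str, float]
    member_p_adjusted: Mapping[str, float]
    cluster_only: bool  # significant cluster with no significant member


def cluster_de_test(
    clusters: Sequence[CircCluster],
    member_counts: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[ClusterDEResult]:
    """Built-in two-group test on cluster sums (approximate DE).

    t-test on log2(normalized count + pseudocount) of the per-sample cluster
    sum, BH-adjusted across clusters; members are tested the same way and
    BH-adjusted across all members.  This is an approximation of a
    negative-binomial DE model — the exported count matrices are the
    canonical interface for external DE — but it reproduces the key
    behaviour: an additive shift spread over members can be significant at
    the cluster level while no member is.

    ``member_counts`` is a circ_id x sample DataFrame of normalized counts.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    g1 = [s for s in member_counts.columns if groups.get(s) == group_names[0]]
    g2 = [s for s in member_counts.columns if groups.get(s) == group_names[1]]
    if min(len(g1), len(g2)) < 2:
        raise ValueError("at least 2 replicates per group required")

    def log_t(values: pd.Series) -> tuple[float, float]:
        x = np.log2(values[g1].to_numpy(dtype=float) + pseudocount)
        y = np.log2(values[g2].to_numpy(dtype=float) + pseudocount)
        return float(np.mean(y) - np.mean(x)), inclusion_ttest(x, y)

    member_ids = sorted({m for cl in clusters for m in cl.members})
    member_stats = {m: log_t(member_counts.loc[m]) for m in member_ids}
    member_padj = dict(
        zip(
            member_ids,
            stats.false_discovery_control(
                [member_stats[m][1] for m in member_ids], method="bh"
            )
            if member_ids
            else [],
        )
    )

    cluster_stats = []
    for cl in clusters:
        sums = member_counts.loc[list(cl.members)].sum(axis=0)
        cluster_stats.append(log_t(sums))
    padj = (
        stats.false_discovery_control([p for _, p in cluster_stats], method="bh")
        if clusters
        else []
    )

    out = []
    for cl, (lfc, p), pa in zip(clusters, cluster_stats, padj):
        mp = {m: member_stats[m][1] for m in cl.members}
        mpa = {m: float(member_padj[m]) for m in cl.members}
        significant = pa < alpha
        member_significant = any(v < alpha for v in mpa.values())
        out.append(
            ClusterDEResult(
                cl.cluster_id, lfc, p, float(pa), mp, mpa,
                cluster_only=bool(significant and not member_significant),
            )
        )
    return out
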