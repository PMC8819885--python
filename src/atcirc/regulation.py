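"""cis/trans regulation of circRNA biogenesis via flanking introns.

Two signals are related to circRNA production: differential A-to-I editing
inside Alu elements of the introns flanking differentially expressed
circRNAs (editing can weaken the inverted-Alu pairing that juxtaposes the
back-splice sites), and replicated RBP CLIP peaks occupying both flanking
introns (a trans-acting factor bridging the junction).  Enrichment of
significant editing changes in flanking introns uses a binomial test against
the genome-wide significant-site rate; splicing-factor enrichment among
candidate RBPs uses a 2x2 chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomicInterval
from .structure import inclusion_ttest

log = logging.getLogger(__name__)


@dataclass
class EditingSiteRecord:
    """One A-to-I editing site with per-sample coverage and edited counts."""

    chrom: str
    pos: int  # 0-based
    coverage: dict[str, int] = field(default_factory=dict)
    edited: dict[str, int] = field(default_factory=dict)

    def fraction(self, sample: str) -> Optional[float]:
        cov = self.coverage.get(sample, 0)
        if cov <= 0:
            return None
        ed = self.edited.get(sample, 0)
        if ed > cov:
            raise ValueError(f"{self.chrom}:{self.pos}: edited reads exceed coverage")
        return ed / cov


def _overlaps_any(chrom: str, pos: int, intervals: Sequence[GenomicInterval]) -> bool:
    return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in intervals)


@dataclass(frozen=True)
class DifferentialEditingResult:
    significant_sites: tuple  # (site, p, mean_diff, in_alu, in_flank)
    n_tested: int
    n_tested_in_flank: int
    n_significant: int
    n_significant_in_flank: int
    n_significant_in_flank_alu: int
    enrichment_p: float
    n_skipped: int


def differential_editing(
    records: Iterable[EditingSiteRecord],
    groups: Mapping[str, str],
    flanking_introns: Sequence[GenomicInterval],
    alu_intervals: Sequence[GenomicInterval],
    alpha: float = 0.05,
    min_coverage: int = 10,
    group_order: Optional[tuple[str, str]] = None,
) -> DifferentialEditingResult:
    """Per-site t-test on editing fractions between conditions.

    Sites with coverage below ``min_coverage`` in any used sample are
    skipped (logged).  ``group_order`` names (baseline, treated); the
    reported mean difference is treated minus baseline.  Significant sites
    are intersected with Alu elements and with the flanking introns of
    differentially expressed circRNAs; enrichment is a one-sided binomial
    test of the flanking-intron significant count given the overall
    significant-site rate.
    """
    from intervaltree import IntervalTree

    alu_trees: dict[str, IntervalTree] = {}
    for iv in alu_intervals:
        alu_trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = True
    flank_trees: dict[str, IntervalTree] = {}
    for iv in flanking_introns:
        if iv is None:
            continue
        flank_trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = True

    group_names = list(group_order) if group_order else sorted(set(groups.values()))
    if len(group_names) != 2 or set(group_names) != set(groups.values()):
        raise ValueError("exactly two conditions required (matching group_order)")
    by_group = {g: sorted(s for s, gg in groups.items() if gg == g) for g in group_names}
    if min(len(v) for v in by_group.values()) < 2:
        raise ValueError("at least 2 replicates per condition required")

    skipped = 0
    tested = []
    for rec in records:
        fracs = {}
        ok = True
        for sample in groups:
            if rec.coverage.get(sample, 0) < max(min_coverage, 1):
                ok = False
                break
            fracs[sample] = rec.fraction(sample)
        if not ok:
            skipped += 1
            continue
        x = [fracs[s] for s in by_group[group_names[0]]]
        y = [fracs[s] for s in by_group[group_names[1]]]
        p = inclusion_ttest(x, y)
        diff = float(np.mean(y) - np.mean(x))
        in_flank = bool(
            flank_trees.get(rec.chrom) and flank_trees[rec.chrom][rec.pos]
        )
        in_alu = bool(alu_trees.get(rec.chrom) and alu_trees[rec.chrom][rec.pos])
        tested.append((rec, p, diff, in_alu, in_flank))
    if skipped:
        log.info("differential_editing: skipped %d low-coverage sites", skipped)

    significant = [t for t in tested if t[1] < alpha]
    n_tested = len(tested)
    n_flank = sum(1 for t in tested if t[4])
    k_flank = sum(1 for t in significant if t[4])
    rate = len(significant) / n_tested if n_tested else 0.0
    if n_flank > 0 and 0.0 < rate < 1.0:
        enrichment_p = float(
            stats.binomtest(k_flank, n_flank, rate, alternative="greater").pvalue
        )
    else:
        enrichment_p = float("nan")
    return DifferentialEditingResult(
        tuple(significant),
        n_tested,
        n_flank,
        len(significant),
        k_flank,
        sum(1 for t in significant if t[4] and t[3]),
        enrichment_p,
        skipped,
    )


# ----------------------------------------------------------------- RBPs


@dataclass
class RBPPeakSet:
    rbp_name: str
    replicate_peaks: tuple  # two sequences of GenomicInterval
    is_splicing_factor: bool = False
    expression_change: str = "unchanged"  # 'up' | 'down' | 'unchanged'

    def confident_peaks(self) -> list[GenomicInterval]:
        """Replicate intersection (confident binding sites)."""
        if len(self.replicate_peaks) != 2:
            raise ValueError(f"{self.rbp_name}: exactly 2 replicates required")
        by_chrom: dict[str, tuple[list, list]] = {}
        for i, peaks in enumerate(self.replicate_peaks):
            for p in peaks:
                by_chrom.setdefault(p.chrom, ([], []))[i].append((p.start, p.end))
        from .clusters import _interval_sets_intersection

        out = []
        for chrom, (a, b) in sorted(by_chrom.items()):
            if not a or not b:
                continue
            for s, e in _interval_sets_intersection([a, b]):
                out.append(GenomicInterval(chrom, s, e))
        return out


def rbp_flank_candidates(
    peaksets: Sequence[RBPPeakSet],
    circ_flanks: Mapping[str, tuple[Optional[GenomicInterval], Optional[GenomicInterval]]],
    circ_ids: Optional[Iterable[str]] = None,
) -> dict[str, list[str]]:
    """Per-RBP list of circRNAs with confident peaks in BOTH flanking introns.

    ``circ_flanks`` maps circ_id -> (upstream intron, downstream intron);
    circRNAs missing either intron cannot be candidates.  Peak sets without
    exactly two replicates are excluded with a warning.
    """
    selected = set(circ_ids) if circ_ids is not None else set(circ_flanks)
    out: dict[str, list[str]] = {}
    for ps in peaksets:
        if len(ps.replicate_peaks) != 2:
            log.warning("%s: not exactly 2 replicate peak files, excluded", ps.rbp_name)
            continue
        confident = ps.confident_peaks()
        hits = []
        for circ in sorted(selected):
            up, down = circ_flanks.get(circ, (None, None))
            if up is None or down is None:
                continue
            has_up = any(p.overlaps(up) for p in confident)
            has_down = any(p.overlaps(down) for p in confident)
            if has_up and has_down:
                hits.append(circ)
        out[ps.rbp_name] = hits
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float
    p_value: float
    candidate_fraction: float
    background_fraction: float
    exact_p: Optional[float] = None  # reported when expected cells < 5


def splicing_factor_enrichment(
    n_splicing_candidates: int,
    n_candidates: int,
    background_splicing: int,
    background_total: int,
) -> EnrichmentResult:
    """2x2 chi-squared (no continuity correction) of splicing-factor
    membership among candidate RBPs vs the background panel.

    With any expected cell < 5 a Fisher exact p is reported alongside.
    """
    if n_candidates < 1:
        raise ValueError("empty candidate set")
    if not 0 < background_splicing < background_total:
        raise ValueError("degenerate background counts")
    table = np.array(
        [
            [n_splicing_candidates, n_candidates - n_splicing_candidates],
            [background_splicing, background_total - background_splicing],
        ]
    )
    chi2, p, _dof, expected = stats.chi2_contingency(table, correction=False)
    exact = None
    if expected.min() < 5:
        log.warning("expected cell < 5; reporting Fisher exact test alongside")
        exact = float(stats.fisher_exact(table).pvalue)
    return EnrichmentResult(
        float(chi2),
        float(p),
        n_splicing_candidates / n_candidates,
        background_splicing / background_total,
        exact_p=exact,
    )


# ------------------------------------------------------------------- I/O


def read_editing_records(path, samples: Sequence[str]) -> list[EditingSiteRecord]:
    """TSV: chrom, pos, then coverage_<sample>, edited_<sample> per sample."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        rec = EditingSiteRecord(str(row["chrom"]), int(row["pos"]))
        for s in samples:
            rec.coverage[s] = int(row[f"coverage_{s}"])
            rec.edited[s] = int(row[f"edited_{s}"])
        out.append(rec)
    return out


def read_peaks_bed(path) -> list[GenomicInterval]:
    """BED/narrowPeak replicate peak file (first three columns used)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out
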