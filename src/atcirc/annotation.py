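"""Gene models, candidate back-splice junctions, and coordinate services.

All coordinates are 0-based half-open internally.  GTF input is shifted from
its 1-based inclusive convention on load; BED-like tables pass through
unchanged.  Candidate lists from upstream back-splice callers arrive in
declared dialects (never sniffed) and are normalized to one record per unique
junction.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .sequences import fetch, revcomp

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered (genomic) chain of exons on one strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        prev_end = -1
        for e in self.exons:
            if e.chrom != self.chrom or e.strand not in (self.strand, "."):
                raise ValueError(
                    f"exon {e} of {self.transcript_id} disagrees with transcript "
                    f"chrom/strand"
                )
            if e.start < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = e.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced (exonic) length."""
        return sum(e.length for e in self.exons)

    def last_exon(self) -> GenomicInterval:
        """3'-most exon in transcription order (genomically last on +, first on -)."""
        return self.exons[-1] if self.strand != "-" else self.exons[0]

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, left.end, right.start, self.strand))
        return tuple(out)

    def spliced_sequence(self, genome: Mapping[str, object]) -> str:
        seq = "".join(fetch(genome, self.chrom, e.start, e.end) for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class CircCandidate:
    """One candidate back-splice junction.

    ``bsj_acceptor`` is the genomic start of the circularized region (the 3'
    splice acceptor on the + strand) and ``bsj_donor`` its exclusive genomic
    end; the junction joins donor back to acceptor.
    """

    circ_id: str
    chrom: str
    bsj_acceptor: int
    bsj_donor: int
    strand: str
    host_transcript: Optional[str] = None
    source_callers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.bsj_acceptor < self.bsj_donor):
            raise ValueError(f"invalid junction for {self.circ_id}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.bsj_acceptor, self.bsj_donor, self.strand)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.bsj_acceptor, self.bsj_donor, self.strand)


def coordinate_id(chrom: str, acceptor: int, donor: int, strand: str) -> str:
    return f"circ|{chrom}:{acceptor}-{donor}({strand})"


class Annotation:
    """Container of transcript models with interval lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[str]] = defaultdict(list)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._exon_set: Optional[set[tuple[str, int, int]]] = None
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes[t.gene_id].append(t.transcript_id)
            self._trees[t.chrom][t.start : t.end] = t.transcript_id

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        hits = self._trees.get(chrom, IntervalTree())[start:end]
        return [self.transcripts[h.data] for h in sorted(hits, key=lambda h: h.data)]

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        if gene_id not in self.genes:
            raise KeyError(f"gene {gene_id!r} not in annotation")
        return [self.transcripts[t] for t in self.genes[gene_id]]

    def representative_transcript(self, gene_id: str) -> TranscriptModel:
        """Longest transcript (spliced length; ties broken by id)."""
        ts = self.transcripts_of_gene(gene_id)
        return max(ts, key=lambda t: (t.length, t.transcript_id))

    def exon_boundary_set(self) -> set[tuple[str, int, int]]:
        if self._exon_set is None:
            self._exon_set = {
                (t.chrom, e.start, e.end)
                for t in self.transcripts.values()
                for e in t.exons
            }
        return self._exon_set

    def flanking_introns(
        self, cand: CircCandidate
    ) -> tuple[Optional[GenomicInterval], Optional[GenomicInterval]]:
        """The annotated introns immediately outside each BSJ end.

        Returns ``(upstream, downstream)`` in genomic order: the intron whose
        end abuts the acceptor and the intron whose start abuts the donor.
        Falls back to the nearest intron containing the boundary; ``None``
        when the host has no such intron (single-exon hosts, boundary exons).
        """
        host = (
            self.transcripts.get(cand.host_transcript)
            if cand.host_transcript
            else None
        )
        if host is None:
            hits = self.overlapping(cand.chrom, cand.bsj_acceptor, cand.bsj_donor)
            if not hits:
                return (None, None)
            host = max(hits, key=lambda t: (t.length, t.transcript_id))
        up = down = None
        for intron in host.introns():
            if intron.end == cand.bsj_acceptor or intron.contains_point(cand.bsj_acceptor):
                up = intron
            if intron.start == cand.bsj_donor or intron.contains_point(cand.bsj_donor - 1):
                down = intron
        return (up, down)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_gtf(cls, path) -> "Annotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        exons: dict[str, list] = defaultdict(list)
        meta: dict[str, tuple[str, str, str]] = {}
        for ex in db.features_of_type("exon"):
            tid = ex.attributes["transcript_id"][0]
            gid = ex.attributes.get("gene_id", [tid])[0]
            meta[tid] = (gid, ex.seqid, ex.strand)
            # GTF is 1-based inclusive
            exons[tid].append((ex.start - 1, ex.end))
        transcripts = []
        for tid, ivs in exons.items():
            gid, chrom, strand = meta[tid]
            ivs.sort()
            transcripts.append(
                TranscriptModel(
                    tid,
                    gid,
                    chrom,
                    strand,
                    tuple(GenomicInterval(chrom, s, e, strand) for s, e in ivs),
                )
            )
        return cls(transcripts)

    def to_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.transcripts.values(), key=lambda t: (t.chrom, t.start)):
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tatcirc\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\tatcirc\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


# -------------------------------------------------------------- candidates


def _parse_bed6(path: Path) -> Iterable[tuple[str, int, int, str]]:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            yield (f[0], int(f[1]), int(f[2]), strand)


def _parse_circexplorer2(path: Path) -> Iterable[tuple[str, int, int, str]]:
    # BED-like, 0-based half-open; first six columns as BED6.
    yield from _parse_bed6(path)


def _parse_ciri(path: Path) -> Iterable[tuple[str, int, int, str]]:
    """CIRI-style TSV: 1-based inclusive start/end, strand in a 'strand' column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_chr = header.index("chr")
            i_start = header.index("circRNA_start")
            i_end = header.index("circRNA_end")
        except ValueError as exc:
            raise ValueError(f"{path}: not a CIRI-style table (missing columns)") from exc
        i_strand = header.index("strand") if "strand" in header else None
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[i_strand] if i_strand is not None else "."
            yield (f[i_chr], int(f[i_start]) - 1, int(f[i_end]), strand)


_DIALECTS = {
    "bed6": _parse_bed6,
    "circexplorer2": _parse_circexplorer2,
    "ciri": _parse_ciri,
}


def assign_host(
    cand: CircCandidate, annotation: Annotation
) -> Optional[str]:
    """Pick the host transcript whose exon boundaries best match both BSJ ends.

    Score = number of BSJ ends lying on an exon boundary (acceptor on an exon
    start, donor on an exon end).  Only transcripts overlapping both ends are
    considered; ties go to the longest transcript, then lexicographic id.
    Returns None for intergenic candidates.
    """
    best: tuple[int, int, str] | None = None
    best_tid = None
    for t in annotation.overlapping(cand.chrom, cand.bsj_acceptor, cand.bsj_donor):
        if not (t.start <= cand.bsj_acceptor and cand.bsj_donor <= t.end):
            continue
        score = int(any(e.start == cand.bsj_acceptor for e in t.exons)) + int(
            any(e.end == cand.bsj_donor for e in t.exons)
        )
        key = (score, t.length, t.transcript_id)
        # transcript_id descending would be wrong; want lexicographically
        # *smallest* id among equal (score, length) -- compare explicitly.
        if (
            best is None
            or key[:2] > best[:2]
            or (key[:2] == best[:2] and key[2] < best[2])
        ):
            best = key
            best_tid = t.transcript_id
    return best_tid


def load_candidates(
    files: Sequence[tuple],
    annotation: Optional[Annotation] = None,
    chroms: Optional[Iterable[str]] = None,
) -> list[CircCandidate]:
    """Pool candidate junctions from caller outputs into unique candidates.

    ``files`` holds ``(path, dialect)`` or ``(path, dialect, caller_name)``
    tuples; the dialect is declared per file, never sniffed.  Candidates on
    chromosomes absent from ``chroms`` are skipped with a warning count.
    Each surviving junction is annotated to its host transcript.
    """
    chrom_set = set(chroms) if chroms is not None else None
    merged: dict[tuple, set[str]] = defaultdict(set)
    skipped = 0
    for entry in files:
        if len(entry) == 2:
            path, dialect = entry
            caller = Path(path).stem
        else:
            path, dialect, caller = entry
        if dialect not in _DIALECTS:
            raise ValueError(f"unknown candidate dialect {dialect!r} for {path}")
        for chrom, start, end, strand in _DIALECTS[dialect](Path(path)):
            if chrom_set is not None and chrom not in chrom_set:
                skipped += 1
                continue
            merged[(chrom, start, end, strand)].add(caller)
    if skipped:
        log.warning("skipped %d candidate records on absent chromosomes", skipped)
    out = []
    for (chrom, start, end, strand), callers in sorted(merged.items()):
        cand = CircCandidate(
            coordinate_id(chrom, start, end, strand),
            chrom,
            start,
            end,
            strand,
            source_callers=frozenset(callers),
        )
        if annotation is not None:
            cand = replace(cand, host_transcript=assign_host(cand, annotation))
        out.append(cand)
    return out


def write_candidates(cands: Iterable[CircCandidate], path) -> None:
    """Normalized BED6+ output: score = caller count, column 7 = caller list."""
    with open(path, "w") as fh:
        for c in sorted(cands, key=lambda c: c.key):
            callers = ",".join(sorted(c.source_callers)) or "."
            fh.write(
                f"{c.chrom}\t{c.bsj_acceptor}\t{c.bsj_donor}\t{c.circ_id}\t"
                f"{len(c.source_callers)}\t{c.strand}\t{callers}\n"
            )


def read_candidates(path, annotation: Optional[Annotation] = None) -> list[CircCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            callers = frozenset(f[6].split(",")) if len(f) > 6 and f[6] != "." else frozenset()
            cand = CircCandidate(f[3], f[0], int(f[1]), int(f[2]), f[5], source_callers=callers)
            if annotation is not None:
                cand = replace(cand, host_transcript=assign_host(cand, annotation))
            out.append(cand)
    return out


# ------------------------------------------------------------ exon classes


def load_cassette_db(path) -> set[tuple[str, int, int]]:
    """Cassette-exon table (chrom, start, end TSV, 0-based half-open)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.add((f[0], int(f[1]), int(f[2])))
    return out


def classify_circ_exon(
    exon: GenomicInterval,
    annotation: Annotation,
    cassette_db: set[tuple[str, int, int]],
) -> str:
    """'cassette' on exact cassette-table match, else 'constitutive' on exact
    annotated-exon match, else 'novel'."""
    key = (exon.chrom, exon.start, exon.end)
    if key in cassette_db:
        return "cassette"
    if key in annotation.exon_boundary_set():
        return "constitutive"
    return "novel"


def last_exon_interval(transcript: TranscriptModel) -> GenomicInterval:
    """3'-most exon in transcription order."""
    return transcript.last_exon()
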