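"""Junction-spanning pseudo-references and last-exon linear references.

A pseudo-reference joins the 3' terminus of a circRNA body to its 5' terminus
so that reads crossing the back-splice junction align contiguously; the
central window is the seed that such reads must match exactly.  The linear
host transcript is quantified against its last exon ("last reference"),
because last exons barely circularize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotation import Annotation, CircCandidate, GenomicInterval
from .sequences import fetch, revcomp, write_fasta

DEFAULT_FLANK = 124
DEFAULT_SEED_FLANK = 4


@dataclass(frozen=True)
class PseudoReference:
    """2*flank-nt sequence centered on the back-splice junction.

    ``sequence[:flank]`` is the 3' terminus of the circular body (in
    transcript orientation) and ``sequence[flank:]`` its 5' terminus, so the
    junction sits between positions flank-1 and flank.
    """

    circ_id: str
    sequence: str
    flank: int
    seed_flank: int = DEFAULT_SEED_FLANK

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.flank:
            raise ValueError(
                f"{self.circ_id}: sequence length {len(self.sequence)} != 2*flank"
            )
        if self.seed_flank > self.flank:
            raise ValueError("seed_flank exceeds flank")

    @property
    def bsj_offset(self) -> int:
        """0-based position of the first base after the junction."""
        return self.flank

    @property
    def seed(self) -> str:
        return self.sequence[self.flank - self.seed_flank : self.flank + self.seed_flank]

    @property
    def seed_window(self) -> tuple[int, int]:
        return (self.flank - self.seed_flank, self.flank + self.seed_flank)


@dataclass(frozen=True)
class LinearReference:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty last-exon sequence")

    @property
    def exon_length(self) -> int:
        return len(self.sequence)


def circular_body_sequence(
    cand: CircCandidate,
    genome: Mapping[str, object],
    body_exons: Optional[Sequence[GenomicInterval]] = None,
) -> str:
    """Body sequence in transcript orientation.

    Spliced over ``body_exons`` when the internal structure is known,
    otherwise the contiguous genomic span of the candidate.
    """
    if body_exons:
        seq = "".join(fetch(genome, cand.chrom, e.start, e.end) for e in body_exons)
    else:
        seq = fetch(genome, cand.chrom, cand.bsj_acceptor, cand.bsj_donor)
    return revcomp(seq) if cand.strand == "-" else seq


def _tile_tail(body: str, n: int) -> str:
    """Last n nt of the infinite circular repetition of body."""
    reps = -(-n // len(body)) + 1
    return (body * reps)[-n:]


def _tile_head(body: str, n: int) -> str:
    reps = -(-n // len(body)) + 1
    return (body * reps)[:n]


def build_pseudo_reference(
    cand: CircCandidate,
    genome: Mapping[str, object],
    body_exons: Optional[Sequence[GenomicInterval]] = None,
    flank: int = DEFAULT_FLANK,
    seed_flank: int = DEFAULT_SEED_FLANK,
) -> PseudoReference:
    """Join the last ``flank`` nt of the circular body to its first ``flank`` nt.

    Bodies shorter than the flank are tiled around the circle until each half
    reaches ``flank`` nt, exactly as a read walking the circle would see them.
    """
    if flank < seed_flank:
        raise ValueError("flank must be at least the seed half-width")
    body = circular_body_sequence(cand, genome, body_exons)
    if not body:
        raise ValueError(f"{cand.circ_id}: empty circular body")
    return PseudoReference(
        cand.circ_id, _tile_tail(body, flank) + _tile_head(body, flank), flank, seed_flank
    )


def build_last_exon_reference(
    gene_id: str, annotation: Annotation, genome: Mapping[str, object]
) -> LinearReference:
    """Last exon of the gene's representative (longest) transcript,
    in transcript orientation."""
    try:
        rep = annotation.representative_transcript(gene_id)
    except KeyError as exc:
        raise KeyError(f"gene {gene_id!r} absent from annotation") from exc
    exon = rep.last_exon()
    seq = fetch(genome, exon.chrom, exon.start, exon.end)
    if rep.strand == "-":
        seq = revcomp(seq)
    return LinearReference(gene_id, seq)


def references_to_fasta(refs, path) -> None:
    """Emit references as FASTA so external aligners are interchangeable."""
    records = {}
    for r in refs:
        name = getattr(r, "circ_id", None) or getattr(r, "gene_id")
        records[name] = r.sequence
    write_fasta(records, path)
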