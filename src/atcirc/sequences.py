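"""Small nucleotide-sequence helpers shared across the package."""

from __future__ import annotations

from typing import Mapping

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N, case preserved)."""
    return seq.translate(_RC)[::-1]


def check_bases(seq: str) -> None:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")


def fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Slice a genome that may be a plain dict of strings or a pyfaidx.Fasta."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    return str(genome[chrom][start:end]).upper()


def write_fasta(records: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
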