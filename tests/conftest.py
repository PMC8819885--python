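"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive matching semantics with exhaustive
offset enumeration (no k-mer index) so they can certify the production
matcher; keep them dumb.
"""

from __future__ import annotations

import numpy as np
import pytest

from atcirc.annotation import Annotation, GenomicInterval, TranscriptModel
from atcirc.sequences import revcomp

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(7)
    return {"chrT": random_seq(rng, 6000), "chrU": random_seq(rng, 3000)}


def _make_transcript(tid, gid, chrom, strand, pairs):
    return TranscriptModel(
        tid, gid, chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
    )


@pytest.fixture(scope="session")
def toy_annotation() -> Annotation:
    return Annotation(
        [
            _make_transcript(
                "tA", "geneA", "chrT", "+",
                [(100, 300), (500, 800), (1000, 1300), (1500, 1700), (1900, 2200)],
            ),
            _make_transcript(
                "tB", "geneB", "chrT", "-",
                [(2600, 2900), (3200, 3500), (3800, 4000)],
            ),
            _make_transcript("tC", "geneC", "chrT", "+", [(4300, 4600)]),
        ]
    )


# ------------------------------------------------------------------ oracles


def _mm_count(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def oracle_placements(read: str, ref: str, max_mismatch: int, min_overlap: int,
                      full_length: bool = False):
    """Every valid (offset, orientation, mismatches, ov_start, ov_end)."""
    out = []
    for orient, r in (("forward", read), ("revcomp", revcomp(read))):
        n, L = len(r), len(ref)
        eff_min = n if full_length else min_overlap
        lo = 0 if full_length else eff_min - n
        hi = (L - n) if full_length else (L - eff_min)
        for o in range(lo, hi + 1):
            ovs, ove = max(0, o), min(L, o + n)
            if ove - ovs < eff_min:
                continue
            mm = _mm_count(ref[ovs:ove], r[ovs - o : ove - o])
            if mm <= max_mismatch:
                out.append((o, orient, mm, ovs, ove))
    return out


def oracle_best_alignments(read: str, refs: dict[str, str], max_mismatch: int,
                           min_overlap: int, full_length: bool = False):
    """Tied-best hits mirroring the production selection rule:
    best placement per reference by (mm, -overlap, forward-first, offset),
    then every reference tying on the minimum mismatch count."""
    per_ref = {}
    for name, seq in refs.items():
        best = None
        for o, orient, mm, ovs, ove in oracle_placements(
            read, seq, max_mismatch, min_overlap, full_length
        ):
            key = (mm, -(ove - ovs), 0 if orient == "forward" else 1, o)
            if best is None or key < best[0]:
                best = (key, o, orient, mm, ovs, ove)
        if best is not None:
            per_ref[name] = best
    if not per_ref:
        return []
    best_mm = min(v[3] for v in per_ref.values())
    return [
        (name, v[1], v[2], v[3], v[4], v[5])
        for name, v in sorted(per_ref.items())
        if v[3] == best_mm
    ]


def oracle_full_scan_hit(read: str, refs: dict[str, str], max_mismatch: int) -> bool:
    """End-to-end containment hit on any reference (vectorized enumeration)."""
    for seq in refs.values():
        L = len(seq)
        if len(read) > L:
            continue
        ref_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        win = np.lib.stride_tricks.sliding_window_view(ref_arr, len(read))
        for r in (read, revcomp(read)):
            q = np.frombuffer(r.encode(), dtype=np.uint8)
            bad = (win != q) | (win == ord("N")) | (q == ord("N"))
            if (bad.sum(axis=1) <= max_mismatch).any():
                return True
    return False


@pytest.fixture(scope="session")
def oracles():
    return {
        "placements": oracle_placements,
        "best": oracle_best_alignments,
        "full_scan": oracle_full_scan_hit,
    }


# -------------------------------------------------------- shared simulation


@pytest.fixture(scope="session")
def small_sim():
    from atcirc.simulate import SimConfig, simulate

    cfg = SimConfig(rng_seed=1, n_genes=40, library_size=1200)
    truth, libs = simulate(cfg)
    return cfg, truth, libs


@pytest.fixture(scope="session")
def small_result(small_sim):
    from atcirc.pipeline import run_bsj_pipeline

    _cfg, truth, libs = small_sim
    return run_bsj_pipeline(
        truth.candidates(), truth.annotation, truth.genome, libs.reads
    )
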