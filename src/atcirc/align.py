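"""Ungapped read-vs-reference matching.

The matcher finds the best ungapped occurrence of a read (or its reverse
complement) on a reference, allowing up to ``max_mismatch`` mismatches inside
the overlapping span and free overhang past the reference ends.  ``N`` never
matches anything, including another ``N``.

Candidate placements are generated from a k-mer index.  When
``min_overlap >= k * (max_mismatch + 1)`` this is *exactly* equivalent to the
brute-force scan over every offset: partition any valid overlap into
``max_mismatch + 1`` contiguous blocks of length >= k; at least one block is
mismatch-free and therefore contributes an exact k-mer on the placement's
diagonal.  When the inequality does not hold the matcher silently falls back
to the brute-force scan, so semantics never depend on the index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from .sequences import revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4

_POS_BITS = 32
_POS_MASK = (1 << _POS_BITS) - 1


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"non-ACGTN characters in read/reference: {bad}")
    return arr


@dataclass(frozen=True)
class ReadAlignment:
    """Best ungapped placement of a read on one reference.

    ``ref_start`` is the reference coordinate of the read's first base and may
    be negative (left overhang); ``matched_start``/``matched_end`` delimit the
    overlap actually compared.  ``orientation`` is the strand of the read as
    placed.
    """

    read_id: str
    reference_id: str
    ref_start: int
    orientation: str  # 'forward' | 'revcomp'
    mismatches: int
    matched_start: int
    matched_end: int

    @property
    def matched_span(self) -> tuple[int, int]:
        return (self.matched_start, self.matched_end)


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-mers; windows containing N get code -1."""
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for i in range(k):
        w = arr[i : i + m]
        codes = codes * 4 + np.minimum(w, 3)
        bad |= w > 3
    codes[bad] = -1
    return codes


def _ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo_i, hi_i) without a Python loop."""
    n = hi - lo
    cs = np.cumsum(n)
    if cs.size == 0 or cs[-1] == 0:
        return np.empty(0, dtype=np.int64)
    starts = lo - np.concatenate(([0], cs[:-1]))
    return np.arange(cs[-1], dtype=np.int64) + np.repeat(starts, n)


def _verify(
    ref: np.ndarray, read: np.ndarray, offset: int, min_overlap: int
) -> Optional[tuple[int, int, int]]:
    """(mismatches, overlap_start, overlap_end) or None if overlap too short."""
    ovs = max(0, offset)
    ove = min(ref.shape[0], offset + read.shape[0])
    if ove - ovs < min_overlap:
        return None
    r = ref[ovs:ove]
    q = read[ovs - offset : ove - offset]
    mm = int(np.count_nonzero((r != q) | (r > 3) | (q > 3)))
    return (mm, ovs, ove)


class UngappedIndex:
    """k-mer index over a set of references for repeated read matching.

    Parameters
    ----------
    references:
        mapping name -> sequence.
    k, max_mismatch, min_overlap:
        matching parameters; see module docstring for the exactness condition.
    full_length:
        require the read to be fully contained in the reference (no overhang);
        used for the genome/transcriptome remap filter.
    """

    def __init__(
        self,
        references: Mapping[str, str],
        k: int = 12,
        max_mismatch: int = 3,
        min_overlap: int = 48,
        full_length: bool = False,
        use_index: bool = True,
    ):
        self.use_index = use_index
        self.k = k
        self.max_mismatch = max_mismatch
        self.min_overlap = min_overlap
        self.full_length = full_length
        self.names = list(references)
        self.arrays = [encode(references[n]) for n in self.names]
        self.lengths = np.array([a.shape[0] for a in self.arrays], dtype=np.int64)
        if self.names and self.lengths.max() >= (1 << _POS_BITS):
            raise ValueError("reference too long for index packing")
        packed_parts = []
        for idx, arr in enumerate(self.arrays):
            codes = _kmer_codes(arr, k)
            pos = np.nonzero(codes >= 0)[0]
            packed_parts.append(
                (codes[pos], (np.int64(idx) << _POS_BITS) | pos.astype(np.int64))
            )
        if packed_parts:
            all_codes = np.concatenate([c for c, _ in packed_parts])
            all_packed = np.concatenate([p for _, p in packed_parts])
            order = np.argsort(all_codes, kind="stable")
            self._codes = all_codes[order]
            self._packed = all_packed[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._packed = np.empty(0, dtype=np.int64)
        self._maxlen = int(self.lengths.max()) if self.names else 0

    # ------------------------------------------------------------- matching

    def _candidate_diagonals(self, arr: np.ndarray) -> Iterable[tuple[int, int]]:
        """(ref_idx, offset) pairs holding every placement that could satisfy
        the mismatch budget (superset; each is verified afterwards)."""
        codes = _kmer_codes(arr, self.k)
        pos = np.nonzero(codes >= 0)[0]
        if pos.size == 0:
            return []
        c = codes[pos]
        lo = np.searchsorted(self._codes, c, side="left")
        hi = np.searchsorted(self._codes, c, side="right")
        take = _ranges(lo, hi)
        if take.size == 0:
            return []
        packed = self._packed[take]
        ref_idx = packed >> _POS_BITS
        rpos = packed & _POS_MASK
        p_rep = np.repeat(pos, hi - lo)
        diag = rpos - p_rep
        key = ref_idx * (2 * self._maxlen + arr.shape[0] + 2) + (diag + arr.shape[0])
        uniq = np.unique(key)
        base = 2 * self._maxlen + arr.shape[0] + 2
        return [(int(u // base), int(u % base) - arr.shape[0]) for u in uniq]

    def _exact_for(self, read_len: int) -> bool:
        eff_min = read_len if self.full_length else self.min_overlap
        return eff_min >= self.k * (self.max_mismatch + 1)

    def _placements_brute(self, arr: np.ndarray) -> Iterable[tuple[int, int]]:
        eff_min = arr.shape[0] if self.full_length else self.min_overlap
        out = []
        for idx, L in enumerate(self.lengths):
            lo = 0 if self.full_length else eff_min - arr.shape[0]
            hi = int(L) - (arr.shape[0] if self.full_length else eff_min)
            out.extend((idx, o) for o in range(lo, hi + 1))
        return out

    def match(self, read: str, read_id: str = "") -> list[ReadAlignment]:
        """Best alignments of a read across all references.

        The read is assigned to the reference(s) with the fewest mismatches;
        within one reference the placement with the largest overlap (then the
        smallest offset, forward before revcomp) is kept.  All references tied
        on the minimum mismatch count are returned; empty list if no valid
        placement exists.
        """
        fwd = encode(read)
        n = fwd.shape[0]
        eff_min = n if self.full_length else self.min_overlap
        if n < eff_min or not self.names:
            return []
        exact = self.use_index and self._exact_for(n)
        # best per reference: (mm, -overlap, orient_rank, offset)
        per_ref: dict[int, tuple[tuple, int, str, int, int, int]] = {}
        for orient_rank, (orient, arr) in enumerate(
            (("forward", fwd), ("revcomp", encode(revcomp(read))))
        ):
            cands = (
                self._candidate_diagonals(arr) if exact else self._placements_brute(arr)
            )
            for ref_i, offset in cands:
                if self.full_length and not (
                    offset >= 0 and offset + n <= self.lengths[ref_i]
                ):
                    continue
                res = _verify(self.arrays[ref_i], arr, offset, eff_min)
                if res is None or res[0] > self.max_mismatch:
                    continue
                mm, ovs, ove = res
                key = (mm, -(ove - ovs), orient_rank, offset)
                prev = per_ref.get(ref_i)
                if prev is None or key < prev[0]:
                    per_ref[ref_i] = (key, offset, orient, mm, ovs, ove)
        if not per_ref:
            return []
        best_mm = min(v[0][0] for v in per_ref.values())
        out = []
        for ref_i in sorted(per_ref, key=lambda i: self.names[i]):
            key, offset, orient, mm, ovs, ove = per_ref[ref_i]
            if mm != best_mm:
                continue
            out.append(
                ReadAlignment(read_id, self.names[ref_i], offset, orient, mm, ovs, ove)
            )
        return out


def match_read(
    read: str,
    reference: Union[str, object],
    reference_id: str = "ref",
    max_mismatch: int = 3,
    min_overlap: int = 48,
    read_id: str = "",
) -> Optional[ReadAlignment]:
    """Best ungapped occurrence of ``read`` on a single reference, or None.

    ``reference`` may be a plain sequence or any object with a ``sequence``
    attribute (pseudo- or last-reference).  Uses the exhaustive scan, so any
    ``min_overlap`` is honoured.
    """
    seq = getattr(reference, "sequence", reference)
    name = getattr(reference, "circ_id", None) or getattr(
        reference, "gene_id", reference_id
    )
    if len(read) < 1:
        raise ValueError("empty read")
    idx = UngappedIndex(
        {name: seq},
        max_mismatch=max_mismatch,
        min_overlap=min_overlap,
        use_index=False,
    )
    hits = idx.match(read, read_id=read_id)
    return hits[0] if hits else None
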