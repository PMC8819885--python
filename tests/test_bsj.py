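"""Seed validation, counting, normalization equations, and resistance calls."""

import numpy as np
import pytest

from atcirc.align import match_read
from atcirc.bsj import (
    LibraryTotals,
    classify_resistance,
    count_and_filter,
    fraction_linear_at_or_below,
    nearest_rank_quantile,
    normalized_rc,
    remap_filter,
    rpkm,
    validate_bsj_read,
)
from atcirc.references import PseudoReference

from conftest import random_seq


@pytest.fixture(scope="module")
def pseudo_ref():
    rng = np.random.default_rng(21)
    return PseudoReference("circX", random_seq(rng, 248), 124)


def _read_from(ref, start, end):
    return ref.sequence[start:end]


class TestSeedValidation:
    def test_exact_seed_coverage_true(self, pseudo_ref):
        read = _read_from(pseudo_ref, 104, 144)  # flank +/- 20
        aln = match_read(read, pseudo_ref, min_overlap=30)
        assert validate_bsj_read(aln, pseudo_ref, read)

    def test_three_nt_left_of_junction_fails_coverage(self, pseudo_ref):
        # covers only flank-3 .. flank+30: misses one seed base
        read = _read_from(pseudo_ref, 121, 154)
        aln = match_read(read, pseudo_ref, min_overlap=30)
        assert aln is not None
        assert not validate_bsj_read(aln, pseudo_ref, read)

    def test_single_mismatch_placement_exhaustive(self, pseudo_ref):
        """A single mismatch anywhere in the covered span invalidates the
        read iff it falls inside the seed window — checked against a
        brute-force validator over all mismatch positions."""
        start, end = 100, 160
        clean = _read_from(pseudo_ref, start, end)
        ws, we = pseudo_ref.seed_window
        for pos in range(len(clean)):
            mutated = list(clean)
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            read = "".join(mutated)
            aln = match_read(read, pseudo_ref, min_overlap=48)
            assert aln is not None and aln.ref_start == start
            got = validate_bsj_read(aln, pseudo_ref, read)
            # oracle: direct string comparison on the seed window
            expected = read[ws - start : we - start] == pseudo_ref.seed
            assert got == expected
            assert expected == (not (ws <= start + pos < we))

    def test_orientation_invariance(self, pseudo_ref):
        from atcirc.sequences import revcomp

        read = _read_from(pseudo_ref, 104, 170)
        for r in (read, revcomp(read)):
            aln = match_read(r, pseudo_ref, min_overlap=48)
            assert validate_bsj_read(aln, pseudo_ref, r)


class TestRemapAndCounting:
    def test_remap_set_logic(self):
        surv = remap_filter({"a", "b", "c", "d"}, {"a"}, {"b", "x"})
        assert surv == {"c", "d"}

    def test_fragment_dedup_counts_pair_once(self):
        assignments = {
            "atail": {"f1/1": {"circA"}, "f1/2": {"circA"}, "f2/1": {"circA"}},
            "control": {},
        }
        counts, low = count_and_filter(assignments, min_count=2)
        assert counts["circA"]["atail"] == 2
        assert "circA" not in low

    def test_min_count_boundary(self):
        one = {"atail": {"f1/1": {"c"}}, "control": {}}
        counts, low = count_and_filter(one, min_count=2)
        assert counts["c"]["atail"] == 1 and "c" in low
        two = {"atail": {"f1/1": {"c"}, "f2/2": {"c"}}, "control": {}}
        counts, low = count_and_filter(two, min_count=2)
        assert counts["c"]["atail"] == 2 and low == set()

    def test_tied_references_both_counted(self):
        assignments = {"atail": {"f1/1": {"cA", "cB"}}, "control": {}}
        counts, _ = count_and_filter(assignments, min_count=1)
        assert counts["cA"]["atail"] == 1 and counts["cB"]["atail"] == 1


class TestEquations:
    def test_normalized_rc_direct_substitution(self):
        totals = LibraryTotals(
            total_bsj_rc={"atail": 1000, "control": 500},
            total_mapped_reads={"control": 1_000_000, "atail": 1},
            total_sequencing_reads={},
        )
        assert normalized_rc(10, totals) == pytest.approx(5e-6, rel=1e-12)
        assert normalized_rc(0, totals) == 0.0

    def test_normalized_rc_scaling_identity(self):
        """Doubling every total leaves the value unchanged (the two ratio
        terms cancel)."""
        t1 = LibraryTotals({"atail": 800, "control": 300}, {"control": 5_000_00, "atail": 1}, {})
        t2 = LibraryTotals({"atail": 1600, "control": 600}, {"control": 1_000_000, "atail": 1}, {})
        assert normalized_rc(20, t1) == pytest.approx(2 * normalized_rc(20, t2))

    def test_normalized_rc_zero_denominator_named(self):
        t = LibraryTotals({"atail": 0, "control": 5}, {"control": 10, "atail": 1}, {})
        with pytest.raises(ValueError, match="A-tailing"):
            normalized_rc(1, t)
        t = LibraryTotals({"atail": 5, "control": 5}, {"control": 0, "atail": 1}, {})
        with pytest.raises(ValueError, match="control"):
            normalized_rc(1, t)

    def test_rpkm(self):
        assert rpkm(10, 1_000_000, 1000) == 10.0
        assert rpkm(0, 1_000_000, 1000) == 0.0
        assert rpkm(10, 1_000_000, 500) == 20.0  # halving length doubles RPKM
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestResistanceClassification:
    @staticmethod
    def _setup(n_linear=200, seed=0):
        rng = np.random.default_rng(seed)
        linear_counts = {
            f"g{i}": {"control": int(rng.integers(5, 60)), "atail": int(rng.integers(0, 4))}
            for i in range(n_linear)
        }
        lengths = {g: int(rng.integers(200, 500)) for g in linear_counts}
        totals = LibraryTotals(
            total_bsj_rc={"atail": 100, "control": 50},
            total_mapped_reads={"atail": 10_000, "control": 10_000},
            total_sequencing_reads={"atail": 20_000, "control": 20_000},
        )
        return linear_counts, lengths, totals

    def test_quantile_rule_bounds_linear_fraction(self):
        linear_counts, lengths, totals = self._setup()
        circ = {"c1": {"atail": 50, "control": 1}}
        _calls, cutoff, table = classify_resistance(circ, linear_counts, lengths, totals)
        assert fraction_linear_at_or_below(table, cutoff) >= 0.95

    def test_ratio_equal_to_cutoff_is_sensitive(self):
        linear_counts, lengths, totals = self._setup()
        calls, cutoff, table = classify_resistance({}, linear_counts, lengths, totals)
        at_cutoff = [c for c in calls.values() if c.atail_control_ratio == cutoff]
        assert at_cutoff and all(c.label == "sensitive" for c in at_cutoff)

    def test_confident_requires_strictly_above(self):
        linear_counts, lengths, totals = self._setup()
        circ = {
            "resistant": {"atail": 80, "control": 2},
            "depleted": {"atail": 2, "control": 80},
        }
        calls, _cutoff, _ = classify_resistance(circ, linear_counts, lengths, totals)
        assert calls["resistant"].label == "confident"
        assert calls["depleted"].label == "sensitive"

    def test_low_count_label_wins(self):
        linear_counts, lengths, totals = self._setup()
        circ = {"c": {"atail": 1, "control": 0}}
        calls, _c, _t = classify_resistance(
            circ, linear_counts, lengths, totals, low_count={"c"}
        )
        assert calls["c"].label == "low_count"

    def test_too_few_linear_references_rejected(self):
        linear_counts, lengths, totals = self._setup(n_linear=10)
        with pytest.raises(ValueError, match="cutoff unstable"):
            classify_resistance({}, linear_counts, lengths, totals)

    def test_nearest_rank_quantile(self):
        vals = list(range(1, 101))
        assert nearest_rank_quantile(vals, 0.95) == 95
        assert nearest_rank_quantile([4.0], 0.95) == 4.0
        with pytest.raises(ValueError):
            nearest_rank_quantile([], 0.5)
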