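"""Split-read junction detection, isoform assembly, and switch testing."""

import itertools

import numpy as np
import pytest

from atcirc.annotation import CircCandidate, GenomicInterval
from atcirc.structure import (
    BSJ_KEY,
    JunctionTable,
    assemble_isoforms,
    detect_junctions,
    exon_coverage,
    inclusion_ttest,
    junction_proportion,
    test_isoform_switch,
)

E2 = (500, 800)
E3 = (1000, 1300)
E4 = (1500, 1700)


@pytest.fixture(scope="module")
def circ_a():
    return CircCandidate("circA", "chrT", 500, 1700, "+", host_transcript="tA")


@pytest.fixture(scope="module")
def exons_a():
    return [GenomicInterval("chrT", s, e, "+") for s, e in (E2, E3, E4)]


def _junction_read(genome, left_end, right_start, half=30):
    g = genome["chrT"]
    return g[left_end - half : left_end] + g[right_start : right_start + half]


class TestDetectJunctions:
    def test_min_split_boundary_three_kept_two_dropped(
        self, toy_genome, circ_a, exons_a
    ):
        """'More than two split reads' keeps a junction at 3 and drops it at 2."""
        inc = _junction_read(toy_genome, 800, 1000)
        skip = _junction_read(toy_genome, 800, 1500)
        reads = [(f"i{k}/1", inc) for k in range(3)] + [
            (f"s{k}/1", skip) for k in range(2)
        ]
        table = detect_junctions({"s1": reads}, circ_a, exons_a, toy_genome)
        assert table.junctions() == [(800, 1000)]
        assert table.pooled((800, 1000)) == 3

    def test_contiguous_reads_give_empty_junction_set(
        self, toy_genome, circ_a, exons_a
    ):
        g = toy_genome["chrT"]
        reads = [(f"r{k}/1", g[520 + 10 * k : 580 + 10 * k]) for k in range(5)]
        table = detect_junctions({"s1": reads}, circ_a, exons_a, toy_genome)
        assert table.junctions() == []

    def test_anchor_rule_rejects_short_crossing(self, toy_genome, circ_a, exons_a):
        # only 5 nt on the right of the splice point: below the 8-nt anchor
        g = toy_genome["chrT"]
        read = g[760:800] + g[1000:1005]
        table = detect_junctions(
            {"s1": [(f"r{k}/1", read) for k in range(4)]}, circ_a, exons_a, toy_genome
        )
        assert table.junctions() == []


class TestProportions:
    def test_direct_substitution(self):
        table = JunctionTable(
            "c",
            junction_counts={"s1": {(1, 2): 10, (3, 4): 4}},
            bsj_counts={"s1": 10},
        )
        props = junction_proportion(table, "s1")
        assert props == {(1, 2): 1.0, (3, 4): 0.4, BSJ_KEY: 1.0}

    def test_scale_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            counts = {(i, i + 1): int(rng.integers(1, 50)) for i in range(4)}
            bsj = int(rng.integers(1, 50))
            k = int(rng.integers(2, 9))
            t1 = JunctionTable("c", {"s": dict(counts)}, {"s": bsj})
            t2 = JunctionTable(
                "c", {"s": {j: k * v for j, v in counts.items()}}, {"s": k * bsj}
            )
            assert junction_proportion(t1, "s") == junction_proportion(t2, "s")

    def test_all_zero_raises(self):
        table = JunctionTable("c", {"s": {(1, 2): 0}}, {"s": 0})
        with pytest.raises(ValueError):
            junction_proportion(table, "s")


class TestAssembly:
    def test_zero_coverage_exon_excluded(self, toy_genome, circ_a, exons_a):
        """A middle exon with no body reads and no incident junctions is
        left out of the chain (the excluded-linear-exon pattern)."""
        skip = _junction_read(toy_genome, 800, 1500)
        reads = [(f"s{k}/1", skip) for k in range(5)]
        g = toy_genome["chrT"]
        reads += [(f"b{k}/1", g[520:640]) for k in range(3)]
        reads += [(f"c{k}/1", g[1520:1640]) for k in range(3)]
        table = detect_junctions({"s1": reads}, circ_a, exons_a, toy_genome,
                                 bsj_counts={"s1": 5})
        cov = exon_coverage(reads, exons_a, "chrT", toy_genome)
        assert cov[exons_a[1]] == 0
        isoforms = assemble_isoforms(table, exons_a, cov, circ_a)
        assert len(isoforms) == 1
        assert [(e.start, e.end) for e in isoforms[0].exons] == [E2, E4]

    def test_skip_and_inclusion_paths_coexist(self, toy_genome, circ_a, exons_a):
        reads = []
        for k in range(4):
            reads.append((f"i1{k}/1", _junction_read(toy_genome, 800, 1000)))
            reads.append((f"i2{k}/1", _junction_read(toy_genome, 1300, 1500)))
        for k in range(3):
            reads.append((f"s{k}/1", _junction_read(toy_genome, 800, 1500)))
        g = toy_genome["chrT"]
        for k in range(2):
            reads += [
                (f"b{k}/1", g[520:640]),
                (f"c{k}/1", g[1020:1140]),
                (f"d{k}/1", g[1520:1640]),
            ]
        table = detect_junctions({"s1": reads}, circ_a, exons_a, toy_genome,
                                 bsj_counts={"s1": 6})
        cov = exon_coverage(reads, exons_a, "chrT", toy_genome)
        isoforms = assemble_isoforms(table, exons_a, cov, circ_a)
        chains = {tuple((e.start, e.end) for e in iso.exons) for iso in isoforms}
        assert chains == {(E2, E3, E4), (E2, E4)}
        dominant = [i for i in isoforms if i.dominant]
        assert len(dominant) == 1
        assert tuple((e.start, e.end) for e in dominant[0].exons) == (E2, E3, E4)

    @pytest.mark.parametrize("case_seed", range(25))
    def test_random_dags_match_bruteforce_path_oracle(self, case_seed):
        """Chains equal the exhaustive acceptor-to-donor path enumeration
        on random junction DAGs of up to 6 exons."""
        rng = np.random.default_rng(4000 + case_seed)
        n = int(rng.integers(2, 7))
        exon_bounds = [(100 * i, 100 * i + 50) for i in range(n)]
        exons = [GenomicInterval("chrZ", s, e, "+") for s, e in exon_bounds]
        junctions = {}
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.8 if j == i + 1 else 0.3
                if rng.random() < p:
                    junctions[(exon_bounds[i][1], exon_bounds[j][0])] = int(
                        rng.integers(3, 30)
                    )
        table = JunctionTable("c", {"s": junctions}, {"s": 10})
        cand = CircCandidate("c", "chrZ", 0, exon_bounds[-1][1], "+")
        cov = {e: 1 for e in exons}
        isoforms = assemble_isoforms(table, exons, cov, cand, max_isoforms=1000)

        # oracle: brute-force enumeration over all ordered exon subsets
        paths = []
        for r in range(1, n + 1):
            for combo in itertools.combinations(range(n), r):
                if combo[0] != 0 or combo[-1] != n - 1:
                    continue
                ok = all(
                    (exon_bounds[a][1], exon_bounds[b][0]) in junctions
                    for a, b in zip(combo, combo[1:])
                )
                if ok:
                    paths.append(tuple(exon_bounds[i] for i in combo))
        got = {tuple((e.start, e.end) for e in iso.exons) for iso in isoforms}
        if paths:
            assert got == set(paths)
        else:
            # fallback single-span isoform
            assert got == {((0, exon_bounds[-1][1]),)}


class TestSwitch:
    @staticmethod
    def _table(inclusions_by_sample, bsj=100):
        return JunctionTable(
            "c",
            {
                s: {(800, 1000): int(round(bsj * lvl))}
                for s, lvl in inclusions_by_sample.items()
            },
            {s: bsj for s in inclusions_by_sample},
        )

    def test_reported_switch_with_direction(self):
        """Inclusion rising from ~0.55 to ~0.76 across replicates is a
        short-to-long switch at p<0.05 and diff>0.2."""
        table = self._table(
            {"u1": 0.54, "u2": 0.55, "u3": 0.56, "d1": 0.75, "d2": 0.76, "d3": 0.77}
        )
        groups = {s: ("undiff" if s.startswith("u") else "diff") for s in table.samples()}
        results = test_isoform_switch(table, groups, group_order=("undiff", "diff"))
        assert len(results) == 1
        r = results[0]
        assert r.direction == "short_to_long"
        assert r.inclusion_by_group["undiff"] == pytest.approx(0.55)
        assert r.inclusion_by_group["diff"] == pytest.approx(0.76)
        assert r.p_value < 0.05 and r.inclusion_difference == pytest.approx(0.21)

    def test_identical_groups_report_nothing(self):
        table = self._table({s: 0.5 for s in ("u1", "u2", "d1", "d2")})
        groups = {"u1": "a", "u2": "a", "d1": "b", "d2": "b"}
        assert test_isoform_switch(table, groups) == []

    def test_small_difference_filtered_despite_significance(self):
        table = self._table(
            {"u1": 0.50, "u2": 0.51, "u3": 0.50, "d1": 0.60, "d2": 0.61, "d3": 0.60}
        )
        groups = {s: s[0] for s in table.samples()}
        assert test_isoform_switch(table, groups) == []

    def test_degenerate_variance_convention(self):
        assert inclusion_ttest([0.5, 0.5], [0.5, 0.5]) == 1.0
        assert inclusion_ttest([0.5, 0.5], [0.8, 0.8]) == 0.0

    def test_ttest_matches_closed_form(self):
        rng = np.random.default_rng(23)
        x, y = rng.normal(0.5, 0.1, 4), rng.normal(0.7, 0.1, 4)
        from scipy.special import stdtr

        nx, ny = len(x), len(y)
        sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
        t = (x.mean() - y.mean()) / (sp * np.sqrt(1 / nx + 1 / ny))
        p_ref = 2 * stdtr(nx + ny - 2, -abs(t))
        assert inclusion_ttest(x, y) == pytest.approx(p_ref, abs=1e-12)
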