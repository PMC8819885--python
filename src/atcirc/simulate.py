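"""Synthetic genomes, circRNA truth sets, and paired sequencing libraries.

The generator emulates the experimental contrast the pipeline is built for:
a control rRNA-depleted library and an in-vitro-polyadenylated + RNase R
("A-tailing") library sequenced from the same transcriptome.  Linear
species survive the treatment with a small Beta-distributed fraction, a
minority of structured (G4-like) linear RNAs survive partially, and
circular species are essentially untouched.  False back-splice-like
candidates are modelled as template-switching chimeras: fragments joining a
downstream mRNA position back to an upstream one, which present perfect
junction seeds but deplete with their linear host under treatment.

Truth labels live in a sidecar table keyed by fragment id; the FASTQ files
stay standard-conformant.  Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation, CircCandidate, GenomicInterval, TranscriptModel
from .sequences import revcomp, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment."""

    rng_seed: int = 0
    n_genes: int = 240
    n_chroms: int = 4
    exon_count_range: tuple[int, int] = (4, 8)
    # every exon at least as long as the pseudo-reference flank, so
    # genomic-span references are exact around the junction
    exon_length_range: tuple[int, int] = (160, 400)
    intron_length_range: tuple[int, int] = (200, 700)
    intergenic_gap: int = 300
    circ_gene_fraction: float = 0.25
    max_isoforms_per_circ: int = 3
    cluster_frequency: float = 0.15
    expression_log10_range: tuple[float, float] = (0.6, 2.0)
    nb_dispersion: float = 0.1
    linear_survival_beta: tuple[float, float] = (1.0, 19.0)
    structured_fraction: float = 0.04
    structured_survival_beta: tuple[float, float] = (8.0, 8.0)
    circ_survival_beta: tuple[float, float] = (40.0, 2.0)
    artifact_fraction: float = 0.06
    artifact_mean_range: tuple[float, float] = (8.0, 25.0)
    library_size: int = 8000
    read_length: int = 150
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("circ_gene_fraction", "structured_fraction", "artifact_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.exon_count_range[0] < 2:
            raise ValueError("genes need >= 2 exons to host circRNAs")
        if self.read_length < 20:
            raise ValueError("read length too short")


@dataclass
class LinearTruth:
    gene_id: str
    mean_expression: float
    survival: float
    structured: bool


@dataclass
class CircTruth:
    candidate: CircCandidate
    host_gene: str
    isoform_exons: list[tuple[GenomicInterval, ...]]
    isoform_weights: list[float]
    isoform_sequences: list[str]
    mean_expression: float
    survival: float

    @property
    def circ_id(self) -> str:
        return self.candidate.circ_id


@dataclass
class ArtifactTruth:
    candidate: CircCandidate
    host_gene: str
    mrna_donor: int  # mRNA coordinate of the chimeric break (exclusive end)
    mrna_acceptor: int  # mRNA coordinate where the fragment resumes
    mean_expression: float
    survival: float

    @property
    def circ_id(self) -> str:
        return self.candidate.circ_id


@dataclass
class Truth:
    config: SimConfig
    genome: dict[str, str]
    annotation: Annotation
    linear: dict[str, LinearTruth]
    circs: list[CircTruth]
    artifacts: list[ArtifactTruth]

    def candidates(self) -> list[CircCandidate]:
        """The candidate list an upstream caller pool would deliver."""
        return [c.candidate for c in self.circs] + [a.candidate for a in self.artifacts]

    def true_circ_ids(self) -> set[str]:
        return {c.circ_id for c in self.circs}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        self.annotation.to_gtf(outdir / "annotation.gtf")
        with open(outdir / "circ_truth.bed", "w") as fh:
            for c in self.circs:
                for i, chain in enumerate(c.isoform_exons):
                    start = chain[0].start
                    end = chain[-1].end
                    sizes = ",".join(str(e.length) for e in chain)
                    starts = ",".join(str(e.start - start) for e in chain)
                    fh.write(
                        f"{c.candidate.chrom}\t{start}\t{end}\t{c.circ_id}.i{i+1}\t0\t"
                        f"{c.candidate.strand}\t{start}\t{end}\t0\t{len(chain)}\t"
                        f"{sizes}\t{starts}\n"
                    )
        with open(outdir / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1, default=list)


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def simulate_truth_set(config: SimConfig) -> Truth:
    """Build genome, annotation, and species truth for one experiment."""
    rng = np.random.default_rng([config.rng_seed, 0])
    lo_e, hi_e = config.exon_count_range
    lo_l, hi_l = config.exon_length_range
    lo_i, hi_i = config.intron_length_range

    # gene layout
    transcripts = []
    chrom_cursor = {f"chr{i + 1}": config.intergenic_gap for i in range(config.n_chroms)}
    gene_meta = []
    for g in range(config.n_genes):
        chrom = f"chr{(g % config.n_chroms) + 1}"
        n_ex = int(rng.integers(lo_e, hi_e + 1))
        ex_lens = rng.integers(lo_l, hi_l + 1, size=n_ex)
        in_lens = rng.integers(lo_i, hi_i + 1, size=n_ex - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = chrom_cursor[chrom]
        exons = []
        for k in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + int(ex_lens[k]), strand))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        chrom_cursor[chrom] = pos + config.intergenic_gap
        gid, tid = f"g{g:04d}", f"t{g:04d}"
        transcripts.append(TranscriptModel(tid, gid, chrom, strand, tuple(exons)))
        gene_meta.append((gid, tid))
    genome = {c: _random_sequence(rng, n) for c, n in sorted(chrom_cursor.items())}
    annotation = Annotation(transcripts)

    def expr_mean() -> float:
        return float(10 ** rng.uniform(*config.expression_log10_range))

    linear: dict[str, LinearTruth] = {}
    for gid, _tid in gene_meta:
        structured = bool(rng.random() < config.structured_fraction)
        ab = config.structured_survival_beta if structured else config.linear_survival_beta
        linear[gid] = LinearTruth(gid, expr_mean(), float(rng.beta(*ab)), structured)

    # circRNAs over internal exons (first and last exon never circularize)
    eligible = [
        (gid, tid) for gid, tid in gene_meta
        if len(annotation.transcripts[tid].exons) >= 4
    ]
    n_hosts = int(round(config.circ_gene_fraction * config.n_genes))
    host_idx = rng.choice(len(eligible), size=min(n_hosts, len(eligible)), replace=False)
    circs: list[CircTruth] = []

    def make_circ(t: TranscriptModel, i: int, j: int) -> CircTruth:
        chain = t.exons[i : j + 1]
        acc, don = chain[0].start, chain[-1].end
        cand = CircCandidate(
            f"circ|{t.chrom}:{acc}-{don}({t.strand})", t.chrom, acc, don, t.strand,
            host_transcript=t.transcript_id,
        )
        chains = [tuple(chain)]
        middles = list(range(1, len(chain) - 1))
        n_iso = 1
        if middles:
            n_iso = int(rng.integers(1, min(config.max_isoforms_per_circ, 1 + len(middles)) + 1))
        rng.shuffle(middles)
        for skip in middles[: n_iso - 1]:
            chains.append(tuple(e for k, e in enumerate(chain) if k != skip))
        w = rng.dirichlet(np.full(len(chains), 3.0))
        order = np.argsort(-w)
        chains = [chains[k] for k in order]
        weights = [float(w[k]) for k in order]
        seqs = []
        for ch in chains:
            s = "".join(genome[t.chrom][e.start : e.end] for e in ch)
            seqs.append(revcomp(s) if t.strand == "-" else s)
        return CircTruth(
            cand, t.gene_id, chains, weights, seqs, expr_mean(),
            float(rng.beta(*config.circ_survival_beta)),
        )

    seen_junctions: set[tuple] = set()
    for idx in sorted(host_idx):
        gid, tid = eligible[idx]
        t = annotation.transcripts[tid]
        n_ex = len(t.exons)
        i = int(rng.integers(1, n_ex - 2))
        j = int(rng.integers(i, n_ex - 1))
        c = make_circ(t, i, j)
        if c.candidate.key in seen_junctions:
            continue
        seen_junctions.add(c.candidate.key)
        circs.append(c)
        if rng.random() < config.cluster_frequency:
            # alternative circularization sharing the acceptor
            alts = [jj for jj in range(i, n_ex - 1) if jj != j]
            if alts:
                j2 = int(rng.choice(alts))
                c2 = make_circ(t, i, j2)
                if c2.candidate.key not in seen_junctions:
                    seen_junctions.add(c2.candidate.key)
                    circs.append(c2)

    # chimeric (template-switching) artifact junctions on + strand hosts
    artifacts: list[ArtifactTruth] = []
    n_art = int(round(config.artifact_fraction * config.n_genes))
    plus_genes = [
        (gid, tid) for gid, tid in gene_meta
        if annotation.transcripts[tid].strand == "+"
    ]
    rng.shuffle(plus_genes)
    for gid, tid in plus_genes:
        if len(artifacts) >= n_art:
            break
        t = annotation.transcripts[tid]
        big = [e for e in t.exons if e.length >= 300]
        if not big:
            continue
        exon = big[int(rng.integers(0, len(big)))]
        L = exon.length
        v_off = int(rng.integers(10, L - 290 + 1))
        u_off = int(rng.integers(v_off + 140, L + 1))
        acc_g, don_g = exon.start + v_off, exon.start + u_off
        key = (t.chrom, acc_g, don_g, "+")
        if key in seen_junctions:
            continue
        seen_junctions.add(key)
        mrna_offset = sum(e.length for e in t.exons if e.end <= exon.start)
        artifacts.append(
            ArtifactTruth(
                CircCandidate(
                    f"circ|{t.chrom}:{acc_g}-{don_g}(+)", t.chrom, acc_g, don_g, "+",
                    host_transcript=tid,
                ),
                gid,
                mrna_offset + u_off,
                mrna_offset + v_off,
                float(rng.uniform(*config.artifact_mean_range)),
                linear[gid].survival,
            )
        )

    return Truth(config, genome, annotation, linear, circs, artifacts)


# ----------------------------------------------------------------- reads


@dataclass
class SimLibraries:
    reads: dict[str, list[tuple[str, str, str]]]  # library -> (fragment_id, r1, r2)
    truth_table: pd.DataFrame
    expected_fragments: dict[str, dict[str, float]] = field(default_factory=dict)

    def write(self, outdir, compress: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, frags in self.reads.items():
            opener = gzip.open if compress else open
            suffix = ".fastq.gz" if compress else ".fastq"
            for mate in (1, 2):
                with opener(outdir / f"{lib}_R{mate}{suffix}", "wt") as fh:
                    for fid, r1, r2 in frags:
                        seq = r1 if mate == 1 else r2
                        fh.write(f"@{fid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
        self.truth_table.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _tile(seq: str, start: int, length: int) -> str:
    """Substring of the infinite circular repetition of ``seq``."""
    L = len(seq)
    reps = (start + length) // L + 2
    return (seq * reps)[start : start + length]


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    arr = bytearray(seq, "ascii")
    for pos in rng.choice(len(seq), size=n, replace=False):
        alts = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = alts[int(rng.integers(0, 3))]
    return arr.decode("ascii")


def simulate_libraries(truth: Truth, config: Optional[SimConfig] = None) -> SimLibraries:
    """Draw paired-end fragments for the control and A-tailing libraries.

    Fragment counts per species are gamma-Poisson (negative binomial) around
    depth-scaled means; the A-tailing library multiplies each species' mean
    by its survival fraction before rescaling to the common library size
    (both libraries are sequenced to the same depth).  Circular fragments
    start uniformly on the circle and may cross the back-splice junction
    (probability ~ fragment length / circle length).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.rng_seed, 1])
    rl = config.read_length

    mrna = {
        gid: truth.annotation.transcripts[
            truth.annotation.genes[gid][0]
        ].spliced_sequence(truth.genome)
        for gid in truth.linear
    }

    species: list[tuple[str, str, object]] = [
        ("linear", lt.gene_id, lt) for lt in truth.linear.values()
    ]
    species += [("circ", c.circ_id, c) for c in truth.circs]
    species += [("artifact", a.circ_id, a) for a in truth.artifacts]

    reads: dict[str, list[tuple[str, str, str]]] = {}
    expected: dict[str, dict[str, float]] = {}
    rows = []
    frag_counter = 0
    # biological (gamma) component drawn per species per library up front, so
    # it is independent of sequencing depth: a deeper library is the same
    # sample with fresh Poisson counting noise only
    shape = 1.0 / config.nb_dispersion
    rel_factor = {
        lib: rng.gamma(shape, 1.0 / shape, size=len(species))
        for lib in ("control", "atail")
    }
    for lib in ("control", "atail"):
        masses = np.array(
            [
                s[2].mean_expression * (s[2].survival if lib == "atail" else 1.0)
                for s in species
            ]
        )
        scale = config.library_size / masses.sum()
        lam = masses * scale
        expected[lib] = {s[1]: float(l) for s, l in zip(species, lam)}
        # NB(mean=lam, var=lam + d*lam^2) as gamma-Poisson with shape 1/d
        counts = rng.poisson(lam * rel_factor[lib])
        lib_reads = []
        for (kind, sid, obj), n in zip(species, counts):
            for _ in range(int(n)):
                f = max(int(round(rng.normal(config.fragment_mean, config.fragment_sd))), rl)
                fid = f"f{frag_counter:07d}"
                frag_counter += 1
                iso = ""
                m1x = m2x = False
                if kind == "linear":
                    T = mrna[sid]
                    f_eff = min(f, len(T))
                    start = int(rng.integers(0, len(T) - f_eff + 1))
                    frag = T[start : start + f_eff]
                elif kind == "circ":
                    k = int(rng.choice(len(obj.isoform_weights), p=obj.isoform_weights))
                    iso = f"i{k + 1}"
                    S = obj.isoform_sequences[k]
                    L = len(S)
                    start = int(rng.integers(0, L))
                    frag = _tile(S, start, f)
                    f_eff = f
                    rl_eff = min(rl, f_eff)
                    m1x = start + rl_eff > L
                    m2x = (start + f_eff - rl_eff) < L < (start + f_eff)
                else:  # chimeric artifact
                    T = mrna[obj.host_gene]
                    u, v = obj.mrna_donor, obj.mrna_acceptor
                    o = int(rng.integers(30, max(f - 30, 31)))
                    o = min(o, u)
                    f_eff = min(f, o + (len(T) - v))
                    frag = T[u - o : u] + T[v : v + (f_eff - o)]
                    rl_eff = min(rl, f_eff)
                    m1x = 0 < o < rl_eff
                    m2x = (f_eff - rl_eff) < o < f_eff
                rl_eff = min(rl, len(frag))
                r1 = _apply_errors(frag[:rl_eff], rng, config.error_rate)
                r2 = _apply_errors(revcomp(frag[-rl_eff:]), rng, config.error_rate)
                lib_reads.append((fid, r1, r2))
                rows.append(
                    (fid, lib, sid, kind, iso, bool(m1x or m2x), bool(m1x), bool(m2x))
                )
        reads[lib] = lib_reads
    table = pd.DataFrame(
        rows,
        columns=[
            "fragment_id", "library", "species_id", "kind", "isoform",
            "crosses_bsj", "mate1_crosses", "mate2_crosses",
        ],
    )
    return SimLibraries(reads, table, expected)


def simulate(config: SimConfig) -> tuple[Truth, SimLibraries]:
    """Truth set plus libraries in one seeded call."""
    truth = simulate_truth_set(config)
    return truth, simulate_libraries(truth, config)
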