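# Methods

## Model and procedure

`atcirc` treats circRNA identification as a two-evidence problem: a read must
(1) cross the back-splice junction cleanly and (2) belong to a molecule that
resists the A-tailing/RNase R treatment.

**Junction evidence.** Every pooled candidate junction gets a
pseudo-reference: the 3′-terminal `flank` nucleotides of the circular body
concatenated with its 5′-terminal `flank` nucleotides (transcript
orientation).  A body shorter than the flank is tiled around the circle, which
is exactly what a read walking a short circle observes.  Reads are matched
ungapped against these references; an alignment validates the junction only
when it covers the whole central seed window (`seed_flank` nt on each side of
the junction) without a single mismatch there.  Mismatches outside the seed
are allowed up to `max_mismatch`; overhang past the reference ends carries no
penalty.  Validated reads that also map end-to-end (no overhang, same
mismatch budget) to the genome or to spliced transcripts are linear-derived
false positives and are removed.

**Resistance evidence.** The treatment degrades linear RNA; circles persist.
The linear host of each gene is quantified on its last exon (last exons
barely circularize, so this signal is uncontaminated), as RPKM per library.
Candidate junctions are quantified as fragment counts (a read pair counts
once, ties across references count for every tied reference) depth-normalized
to counts per million mapped reads.  Each species' ratio
`(atail + pseudocount) / (control + pseudocount)` is compared with a cutoff
placed at the inclusive nearest-rank `quantile` (default 0.95) of the linear
ratios: by construction at least 95 % of linear references fall at or below
it, so calling "confident" only species *strictly above* the cutoff bounds
the expected false discovery rate at 1 − quantile.  Species with fewer than
`min_count` A-tailing fragments are reported as `low_count` and never called.

**Structure.** Mates of junction-validated fragments are matched against
exon–exon junction probes built from the candidate exons inside the
circularized span; a read is a split read for a junction when it crosses the
splice point with ≥ `anchor` nt on both sides.  Junctions supported by more
than two split reads are retained.  Isoforms are maximal acceptor-to-donor
paths through the retained junctions over exons with nonzero body coverage;
each junction's proportion is its count divided by the maximum count over all
junctions and the BSJ, an isoform's inclusion level is the minimum proportion
over its distinguishing junctions, and the dominant isoform maximizes the
minimum supporting count (ties: lexicographically smallest chain).  Isoform
switches are two-sided unpaired Student t-tests on inclusion levels, reported
at p < `switch_alpha` and |mean difference| > `min_inclusion_diff`.

**Clusters, networks, regulation.** circRNAs sharing a donor or an acceptor
coordinate (exact match, same strand; a ±2 nt fuzz window exists behind a
flag, off by default) form clusters whose expression is the member sum and
whose common region is the per-base intersection of member exon chains.  The
built-in cluster differential test — a t-test on log2(normalized count +
pseudocount) of the cluster sum, BH-adjusted across clusters — is an
approximation of a negative-binomial model; the count matrices are exported
for external DE tools, but the approximation reproduces the key phenomenon:
an additive shift spread over members reaches significance at the cluster
level while no member does.  miRNA sites on full-length circular sequences
are the canonical seed classes (8mer, 7mer-m8, 7mer-A1) scanned on the
doubled sequence so junction-spanning sites are found; a miRNA's regulatory
footprint is a t-test of its top targets' log2 fold changes against an
equal-size seeded draw of expressed genes without a site, repeated on
pre-mRNA fold changes to separate transcriptional from post-transcriptional
effects.  Differential A-to-I editing is a per-site t-test on editing
fractions with flanking-intron/Alu intersection and a one-sided binomial
enrichment test against the genome-wide significant-site rate; RBP
candidates require replicate-intersected peaks in *both* flanking introns,
and splicing-factor enrichment among candidates is a 2×2 chi-squared test
without continuity correction (a Fisher exact p is added when an expected
cell is below 5).

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `flank` | 124 nt | pseudo-reference half-length (248 nt total) |
| `seed_flank` | 4 nt | exact-match window on each side of the junction |
| `max_mismatch` | 3 | non-seed mismatch budget per alignment |
| `min_overlap` | 48 nt | minimum read/reference overlap for a placement |
| `min_count` | 2 | minimum A-tailing fragments per reported species |
| `quantile` | 0.95 | linear-ratio quantile defining the resistance cutoff |
| `pseudocount` | 0.5 | ratio stabilizer for zero-control species |
| `min_split_reads` | 3 | split-read support to keep an internal junction |
| `anchor` | 8 nt | minimum matched span on each side of a splice point |
| `switch_alpha`, `min_inclusion_diff` | 0.05, 0.2 | isoform-switch thresholds |
| `context_percentile` | 0.90 | top-target cut on predicted repression strength |
| `editing_alpha`, `min_editing_coverage` | 0.05, 10 | editing test thresholds |

The flank default follows the printed 248-nt reference size; a ±149 nt
variant appears elsewhere in the literature describing this design, so the
flank is an explicit knob rather than a constant.  Context++ scores are more
negative for stronger predicted repression; "top decile" therefore ranks on
−score, strictly above the inclusive empirical 90th percentile.

## Matcher design

Candidate placements come from a k-mer index (default k = 12).  Splitting any
valid overlap into `max_mismatch + 1` blocks shows that whenever
`min_overlap ≥ k·(max_mismatch + 1)` at least one block is mismatch-free and
contributes an exact k-mer on the placement's diagonal — so the indexed path
is *provably identical* to the exhaustive all-offsets scan, and the
implementation falls back to the exhaustive scan whenever the inequality
fails.  Tie-breaking is deterministic: per reference the placement with the
fewest mismatches, then the largest overlap, then forward orientation, then
the smallest offset; across references, every reference tying on the minimum
mismatch count is counted (multi-hit), which slightly over-counts shared
junction flanks and is later absorbed by clustering.  `N` never matches any
base, including `N`.

## The simulator

`SimConfig` defines the study conditions: 240 genes on 4 chromosomes, 4–8
exons of 160–400 nt (every exon at least one flank long, so first-pass
genomic-span pseudo-references are exact around the junction), introns of
200–700 nt, random strands, one transcript per gene.  A quarter of eligible
genes host a circRNA built from internal exons (first/last exons never
circularize); circRNAs carry 1–3 isoforms by skipping distinct middle exons,
and 15 % of hosts gain a second circRNA sharing the acceptor (a cluster).
Expression means are log-uniform (10^0.6–10^2 expected fragments); fragment
counts are negative-binomial (gamma–Poisson, dispersion 0.1) with the gamma
component drawn per species per library *before* depth scaling, so deeper
sequencing of the same sample changes only Poisson noise.  The treatment
multiplies linear means by Beta(1,19) survival (mean 0.05), a 4 % structured
(G4-like) linear fraction by Beta(8,8), and circular means by Beta(40,2);
both libraries are then rescaled to the same size (re-sequencing to equal
depth).  False candidates are template-switching chimeras: fragments joining
a downstream mRNA position back to an upstream one inside a long exon, which
present perfect junction seeds, evade the genome/transcriptome remap, and
deplete with their linear host.  Fragments are ~N(300, 30) nt, reads 2×150 nt
with a 10⁻³ substitution rate; circular fragments start uniformly on the
circle, so the junction-crossing share approximates fragment/circle length.
Truth labels live in a sidecar table keyed by fragment id; FASTQ output stays
standard-conformant.  Seeded runs are bit-reproducible.

What the simulator does *not* model: GC and hexamer bias, position-dependent
coverage, quality-score structure, intron retention inside circles, fusion
junctions across chromosomes, and multi-transcript hosts.  Passing tests
therefore certify the algorithmic contract (geometry, filtering, counting,
statistics, FDR control under the stated degradation model), not performance
on any real library.

## Problem sizes and numerical choices

The benchmark experiments run 240 genes × 8000 fragments per library — sizes
chosen so a full simulate-and-classify cycle completes in well under a minute
per seed on one CPU while keeping ≥ 200 linear references under the cutoff
and dozens of true and false candidates per seed.  The cutoff uses the
inclusive nearest-rank quantile (no interpolation); ties at the cutoff are
classified sensitive (strict inequality for confidence).  Degenerate t-tests
(zero variance in both groups) return p = 1 for equal means and p = 0
otherwise.  Zero-coverage sites, zero-control linear references, and
single-replicate peak sets are excluded with logged counts rather than
guessed at.  Isoform enumeration is capped at 16 chains per circRNA
(longest-support-first, logged).

## Known limitations

- The matcher is ungapped: indels inside a read's overlap are treated as
  mismatch runs, so reads spanning unannotated micro-indels are lost.
- First-pass pseudo-references use the contiguous genomic span; with terminal
  circular exons shorter than the flank on real data, junction-distal
  positions can disagree with the spliced body (overhang tolerance absorbs
  this only beyond the reference window).
- The built-in cluster/member DE test is a labeled approximation; export the
  count matrices for a negative-binomial analysis when replicate structure
  matters.
- Host assignment uses annotated transcripts only; candidates in unannotated
  loci are kept but skipped by structure- and intron-dependent stages.
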