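# Methods

This note records the models, conventions and design choices behind
strainsieve, in the order the pipeline runs them.

## Coordinates and formats

All internal coordinates are 0-based, half-open, on the forward strand
of their target; the single conversion to/from 1-based inclusive
happens at the GFF3 reader/writer. PAF is the canonical alignment
dialect because the pipeline consumes intervals plus identity, never
base-level alignments; SAM support is deliberately minimal (pysam
reader, identity from the NM tag when present, otherwise matches =
block length). When several alignments share a read id, exactly one is
retained: highest match count, ties broken by longer block and then
input order — the single-best-alignment contract that the binning
stage assumes.

## Coverage binning

Per-base depth d(i) counts alignment footprints containing i
(difference-array accumulation; the conservation Σᵢ d(i) = Σ footprint
lengths is a tested invariant). A read's *footprint statistic* is the
median depth over its best alignment's target interval — the median
rather than the mean because footprint ends often hang into
neighbouring depth regimes; the statistic is configurable.

The default bin geometry is a union of explicit depth intervals with
explicit boundary semantics: *high* = (110, ∞); *low* = [25, 120] ∪
(225, ∞). ">" cutoffs are strict and the 25–120 window is inclusive,
so statistics in (110, 120] and everything above 225 enter both bins —
the overlap is intentional: very deeply covered (shared backbone)
regions must feed both strain assemblies. A read may therefore enter
0, 1 or 2 bins, and assignment is a pure function of (statistic,
specs).

**Relative mode.** The absolute cutoffs assume a particular sequencing
depth. In relative mode each bound is divided by an anchor depth of
240× and multiplied by the observed genome-wide median depth M at
assignment time. The anchor is derived from the geometry the bins must
realise on a collapsed two-strain reference whose backbone sits at M:
the minor strain must fall inside the scaled 25–120 window, the
dominant strain between the scaled 120 and 225 cutoffs, and the
backbone above the scaled 225, for dominant:minor mixtures from
~1.75:1 (dominant ≈ 0.64 M) up to 3:1 (dominant = 0.75 M). Anchors in
(225, 300) satisfy the constraints; 240 places the scaled 225 cutoff
at 0.9375 M, three quarters of the way from the 3:1 dominant depth to
the backbone. The asymmetry is deliberate: long-read coverage noise is
autocorrelated over entire footprints, so local high-coverage patches
push whole groups of dominant-strain reads across a nearby cutoff at
once, and every such leak corrupts the minor strain's bin; a backbone
read dropping below the cutoff merely thins shared coverage that the
high bin already duplicates. The leak side therefore gets ~3.7 local
standard deviations of margin at 400× and the backbone side ~1.2.

Refinement partitions a bin's reads around a depth floor (default
100×) measured on the bin's own assembly; contig selection keeps
contigs with mean depth strictly above 190×; low-coverage regions are
maximal runs below 25×, length-filtered (default ≥ 50 bp, no upper
bound). The minimum-length default is exposed because the underlying
size filter of the motivating analysis is not documented.

## Circularization

Overlap lengths from `min_overlap` up to half the sequence are scanned;
a length qualifies when the suffix/prefix mismatch fraction is within
the budget. The longest qualifying overlap wins, and the result is
flagged ambiguous whenever another qualifying length ties the winner's
mismatch fraction (homopolymeric and periodic termini trigger this; no
silent choice is ever made). One overlap copy is trimmed and the
circular sequence canonicalized to its lexicographically smallest
rotation, making the result invariant to where the assembler cut the
circle — a tested property. Junction support is counted on a doubled
representation (genome + its own first bases) so alignment records
stay linear: a read spans the junction when its best alignment covers
junction ± flank contiguously.

## Methylome scoring

Each (position, strand) carries summary statistics of observed log-IPD
values and of an unmethylated control model (explicit control columns
rather than an in-silico kinetic reference — the simulator generates
them and real pipelines can fill them from whole-genome amplified
controls). The score is a one-sided Welch (unequal-variance) two-sample
t-test of obs_mean > ctrl_mean; the modification QV is −10·log₁₀(p)
computed through the log survival function (numerically stable far
into the tail) and capped at 1000. The Phred-like convention makes the
call threshold of QV ≥ 100 (p ≤ 10⁻¹⁰) directly comparable to the
quality values the motivating workflow reports. Calls are typed 6mA on
adenines and 4mC on cytosines; 5mC is never called because no
Tet1-conversion signal is modelled. At ≤ 2·10⁵ sites per genome and
p ≤ 10⁻¹⁰ per site, a fully unmethylated genome yields zero calls in
essentially every run — a tested calibration property.

## Motif discovery

Greedy, specific-to-degenerate, run separately for adenine and
cytosine calls:

1. **Seed.** Strand-oriented contexts (± 11 bp) around the remaining
   called sites are decomposed into exact words of length 4–6 anchored
   at the methylated base; words appearing in at least `min_sites`
   contexts are evaluated genome-wide and the word maximizing the
   number of explained called sites, subject to a methylated fraction
   ≥ `min_frac` (default 0.3), becomes the seed.
2. **Generalize.** One position at a time is widened by one base
   (IUPAC code), keeping at most 3 degenerate positions; a step is
   accepted when it increases explained called sites while the
   genome-wide methylated fraction stays ≥ `min_frac`. Terminal N
   positions are trimmed.
3. **Iterate.** The motif's explained sites are removed and the search
   repeats until fewer than `min_sites` remain. Motifs whose match
   sets contain one another are dropped (non-redundancy).

Seed lengths cap recoverable motifs at six specified positions before
generalization; longer recognition sequences are found only if a
≤ 6-wide core passes the fraction floor first. This bounds runtime and
is the main known limitation of the search.

Occurrence counting resolves IUPAC codes on both strands with
overlapping matches; a self-reverse-complementary (palindromic) match
is reported once per locus by default (`count_per_strand` gives both
strand records — which of the two conventions the motivating table
used is not documented, so both are exposed). The per-motif summary
reports occurrences, occurrences whose methylated base carries a
retained call, % methylated, % intergenic (denominator: detected
occurrences; the methylated base must lie outside every gene model)
and mean per-strand coverage over methylated occurrences.

## Comparative stage

GC% excludes N from the denominator; GC skew is (G−C)/(G+C) per
window, flagged undefined (reported 0) when G+C = 0. Windows anchor at
position 0, non-overlapping; the partial final window is reported but
excluded from the GC-deviant count (|GC_w − GC_genome| ≥ 5 pp over
1 kb windows by default).

ANI cuts both genomes into consecutive 1020 bp fragments (tails
discarded), aligns each fragment against the full partner genome on
both strands by infix edit-distance alignment (edlib, distance bound
from the 70 % identity floor), keeps reciprocal best fragment pairs at
≥ 70 % identity, and averages identity over both directions — so
ANI(A,B) = ANI(B,A) by construction and ANI(G,G) = 100 exactly. The
fragment/identity/coverage constants follow the standard fragment-ANI
definition; infix alignment aligns the entire fragment, so the ≥ 50 %
coverage condition is satisfied whenever an alignment within the
distance bound exists.

Exact local alignment (affine gaps; first gap base scored `gap_open`,
each further `gap_extend`; BLOSUM62 for protein) is backed by
Biopython's PairwiseAligner with deterministic tie-breaking (shortest
alignment, then leftmost start) and a size cap — it generates hit
tables only for small synthetic gene sets; real-proteome searches come
from any external engine as 12-column tabular files. The e-value
attached to built-in hits is a ranking proxy (m·n·2⁻ˢᶜᵒʳᵉ), used only
for tie-breaking.

Hit filtering keeps identity ≥ 90 % and query coverage strictly inside
(0.75, 1.20); coverage is alignment columns / query length, which can
exceed 1 through gap columns — the only reading under which an upper
coverage exclusion is meaningful. Best-bidirectional-hit pairing
applies the identity floor before choosing the best subject (max
bitscore, ties by min e-value then lexicographic subject id; a flag
inverts the filter order, which is otherwise undocumented in the
motivating analysis). Unique genes are queries with zero surviving
hits. Aligned fraction merges query intervals of alignments at ≥ 95 %
identity before summing. Gene presence uses depth ≥ 1 as "covered":
absent = no covered base, partial = uncovered fraction > 0.25, else
present.

## Synthetic community

The generator's defaults are the study conditions every recovery test
runs under:

| parameter | default | rationale |
|---|---|---|
| backbone length | 300 kb | desk-scale stand-in for a ~4.4 Mb chromosome |
| unique regions / strain | 6 × 2 kb (recovery studies: 4 × 8 kb) | regions must hold whole reads for read-level scoring |
| inversions / relocations | 2 / 2, minor strain only | keeps backbone→dominant map monotone for truth projection |
| backbone substitution rate | 0.001 | near-identical strains |
| abundance ratio | 3:1 (dominant 300×, minor 100×) | the two-strain separation regime under test |
| read length | log-normal, median 2 558 bp, σ = 0.55, clipped at 27 kb, < 500 bp discarded | matches the admitted-read length profile of the motivating dataset |
| read errors | rate 0.12: substitutions rate/2, insertions rate/4, deletions rate/4, no context bias | uncorrected long-read error structure |
| GC content | 41 % | anammox-like composition |
| kinetics | baseline 0, σ = 0.5, methylation shift δ = 1.0 (δ/σ = 2), control n = 500, obs n ~ Poisson(depth) | Welch test exactly calibrated: sample SDs drawn from the exact χ distribution |

Reads carry truth alignments against their origin genome (identity =
1 − realized error fraction); `sequences=False` skips residue
realization for coverage-only studies while preserving the length and
error-count distributions. `collapse_reference` emulates how an
assembler collapses the community — the dominant chromosome carries
the shared backbone, each minor-unique region becomes its own contig —
and `project_truth_alignments` lifts truth alignments onto it (largest
wholly-mappable piece; pieces < 200 bp dropped as unmappable). This is
what gives the depth profile its three regimes (backbone = sum of both
strains, dominant-unique, minor-unique) without running an aligner.

What the simulator does **not** model: chimeric reads, context-specific
error or kinetic biases, quality-value string realism, pulse-level
kinetics, repeat-induced mismapping, or more than two strains. Passing
recovery tests therefore demonstrate that the *computations* recover
planted structure under the assumed noise models, not that any real
community will separate as cleanly.

## Evaluation studies and problem sizes

`strainsieve.evaluate` holds the end-to-end recovery studies the
acceptance script and tests run: strain-binning precision/recall on a
300 kb backbone at 300×/100× (relative thresholds, scored on reads
wholly inside unique regions), motif recovery on a 100 kb genome with
planted GATC 6mA at 99 % and GGNCC 4mC at 60 % at 200× per strand
(plus an unmethylated control), ANI self-identity and the 1 %
substitution band on 60 kb, circularization from two cut points of a
20 kb circle with a 500 bp overlap, and junction-spanning read counts
at 50× against the analytic expectation depth·(ℓ̄ − 2·flank)/ℓ̄. These
sizes keep each study in the seconds range while leaving hundreds to
thousands of scored units per estimate.

## Numerical notes

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seed + inputs give
  byte-identical pipeline outputs (tested).
- QV computation uses `t.logsf`, never `sf` followed by `log`, to stay
  exact beyond p ≈ 10⁻³⁰⁸.
- Depth vectors are int64 difference arrays; footprint medians of
  even-length windows follow numpy's midpoint convention, which is why
  bin boundaries accept fractional statistics.
- Degenerate inputs are errors or flagged results, never silent: n < 2
  or SD ≤ 0 kinetics rows refuse to score, non-circularizable
  sequences return a distinct result, ANI on genomes shorter than one
  fragment is undefined rather than 0.
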