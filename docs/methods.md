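# Methods

`paleoline` reconstructs the history and the master sequence of an extinct
LINE-1 (L1) retrotransposon lineage from unassembled shotgun reads, and
ships a forward simulator that generates the same kind of data with known
ground truth so that every stage can be validated by parameter recovery.

## The model of L1 history the pipeline assumes

L1s propagate as *master lineages*: at any time a small set of closely
related active elements ("masters") produces most new genomic insertions.
New copies are usually 5'-truncated (reverse transcription aborts), so the
3' end of the element is the most heavily represented and the best record
of retrotransposition history. After insertion a copy is a dead fossil
evolving neutrally, except that methylated CpG dinucleotides deaminate an
order of magnitude faster, decaying to TpG (coding strand) or CpA
(opposite strand). Copy age is therefore read from percent identity to the
consensus of the copy's subfamily: the higher the identity, the younger
the insertion; a burst of retrotransposition appears as a peak in the
identity distribution.

## Synthetic data generator (`paleoline.simulate`)

`SimulationParams` describes a study: a founding master with canonical
architecture (5'UTR | ORF1 | IGR | ORF2 | 3'UTR | poly-A; segment lengths
configurable, IGR defaulting to 445 bp and coding-strand composition
A-rich at 43%), a chain of families each drifted from its predecessor by a
`spawn_divergence`, and per-family deposition bursts `(age, copy_count)`.

Key modelling choices:

- **Mutation model.** Per-site substitutions with a 4:1
  transition:transversion odds ratio; no indels by default (an optional
  small-indel rate exists for robustness experiments). CpG sites — *all*
  CG dinucleotides of the master, planted and naturally occurring — mutate
  at `cpg_rate_multiplier` (default 10) times the background rate with a
  19:1 transition bias, so decayed sites read TG/CA as in real data.
- **Burst age normalization.** A burst's `age` is defined as the expected
  per-site divergence *within the element's 3' age-defining window*
  (`age_region_length`, default 575 bp — the same window the scanner
  measures). The background rate r solves
  `f*min(m*r, cap) + (1-f)*r = age` with `f` the window's CpG fraction and
  `m` the multiplier. Copy age is estimated from identity in that window,
  so this is the definition that makes the simulation/recovery round trip
  self-consistent; locus-wide divergence fluctuates around the age with
  the element's regional CG density.
- **Master viability.** While copies decay neutrally, a master is by
  definition retrotranspositionally competent, so lineage drift redraws
  any mutation that would create an in-frame stop in ORF1/ORF2 and leaves
  start/stop codons and the poly-A tail untouched. Without this, the
  end-to-end run could not expect the reconstructed element to annotate
  with two open reading frames.
- **Truncation.** Retained 3' length is geometric (mean
  `truncation_mean_retained`, default 1200 bp, floor 100 bp) — most copies
  short, as observed in real genomes — with probability
  `truncation_full_length_prob` (default 0.05) of a full-length insertion.
  The true truncation-length distribution of any particular genome is
  unknown; these defaults are placeholders chosen once, not estimates.
- **Genome and reads.** Loci (half of them reverse-complemented) are
  embedded at random positions in an i.i.d. background (30% A), and reads
  of `read_length` (700 bp) are sampled uniformly from both strands at
  `coverage` (2.0) fold. Every read and locus carries provenance, and a
  fixed `rng_seed` makes all outputs byte-identical.

What the generator deliberately does *not* emulate: sequencing error as a
process distinct from divergence, chimeric reads, gene conversion,
recombination between elements, selection on copies, SINEs, and genome
assembly artifacts. Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated statistical model, not robustness
to every artifact of a real trace archive.

## Detection (`paleoline.scan`)

Each query (default: a 575 bp window at the 3' end of ORF2) is searched
against every read on both strands: exact 12-mer seeds nominate
(read, strand, window) candidates, each scored by affine-gap local
alignment (match +1, mismatch −1, gap open −2, gap extend −1). Because
Smith–Waterman clips low-scoring ends — which inflates percent identity,
increasingly so at higher divergence — the aligned span is then extended
ungapped to the full query/read overlap under an X-drop rule (X=25) that
still stops at genuine homology boundaries such as the flank of a
truncated insertion. Identity is matches / alignment columns with gap
columns counting against it; coverage is the aligned query span over the
query length. Hits below 60% identity or 90% coverage are discarded;
overlapping hits on a read are resolved greedily by identity. An
exhaustive mode (full DP over whole reads, no seeding) exists for
oracle-style cross-checks.

Subfamily assignment takes the consensus of maximal identity (ties to the
lowest index). When all consensuses share the query coordinate frame —
always true inside the discovery loop — identity against every consensus
is computed exactly by column comparison on the stored projection, which
keeps multi-consensus assignment linear in reads.

## Subfamily discovery (`paleoline.coseg`)

Copies descended from one source element share its private mutations.
Within the pooled fragments, the splitter looks for the pair of
polymorphic columns whose minor variants co-occur in the same members far
beyond independence: a one-sided hypergeometric (Fisher) exact test,
Bonferroni-corrected over all tested column pairs (α = 0.05), restricted
to variants with at least `cosegregation_min_count` (10) carriers. The
members carrying both variants split off as a candidate subfamily and the
procedure recurses. Two guard rails:

- Candidate cohorts below `min_subfamily_size` (250 at genome scale, 25 in
  the desk profile) are never split off, and the *remainder* must also
  stay above the floor — otherwise a split would just manufacture an
  undersized subfamily for the size filter to delete.
- Columns showing the CpG-decay fingerprint (high variation, member
  dinucleotides almost all CG/CA/TG/TA with both CA and TG present) are
  excluded from the test. When bursts of different ages coexist, CpG
  columns correlate through per-copy age — a rate-mixture effect, not
  shared ancestry — and otherwise drive spurious splits.

Subfamily consensuses are per-column majorities (ties A>C>G>T) and are
CpG-corrected (below) before clustering and assignment: which way a
near-even decayed column falls is member-set noise that would otherwise
inflate subfamily-to-subfamily distances and bias identities upward.

Discovery alternates with scanning: round 1 scans with the seed query;
further rounds rescan with the refined pooled consensus as the single
query (keeping cost linear in reads) and re-partition from scratch; a
final pass assigns every fragment to its best consensus by projection.
Undersized subfamilies are removed and their members reassigned to the
nearest surviving consensus.

## Families, landscapes, peaks, dispersion (`paleoline.history`)

Subfamily consensuses are clustered into families by complete-linkage
agglomeration stopped strictly below 3.5% pairwise distance
(100 − semiglobal alignment identity), so every within-family pair
respects the threshold; family ids are ordered youngest first. Identities
are binned at 0.5% per family (heights normalized to percent of all
detected elements) and smoothed with a Gaussian kernel of 0.2% bandwidth;
peaks are the local maxima above a prominence floor (0.1% of total
elements), with sub-maxima within 1% identity of a taller peak absorbed
into it — a narrow kernel on a few hundred observations is jagged, and
the separation rule recovers one peak per burst. Relative family age is
100 − peak identity. A neighbor-joining tree of the subfamily distance
matrix is emitted for visualization only.

The Poisson diagnostic: copies deposited instantaneously accumulate
Poisson-distributed substitution counts, so the variance/mean ratio should
be ~1. The per-family report carries the ratio, a χ² overdispersion
verdict ((n−1)·ratio ~ χ²ₙ₋₁, α = 0.01), and mean−peak divergence, so
extended or compound bursts (ratio > 1, mean exceeding the mode) are
flagged. Fragment lengths vary within the 90–100% coverage band, which
adds a small amount of count dispersion of its own; the diagnostic is a
flag, not an estimator.

## Consensus walking (`paleoline.walker`)

From a seed (in production, the conserved 575 bp ORF2 window), reads
matching the current frontier at ≥92% identity — strict enough to keep
older lineages out — with ≥100 bp overhanging it are collected; overhangs
are anchored at the frontier and a per-column majority extends the
consensus by up to 500 bp per step, with a 300–500 bp terminal window
becoming the next frontier seed. Column quality: depth ≥5 and majority
fraction ≥0.7. A column failing the majority rule still receives its
majority base — hypermutated CpG columns routinely dip to ~0.6 and are
repaired later — and only a run of ≥10 consecutive failures (trimmed from
the extension) or a depth collapse stops the walk; chance runs of three
CpG dinucleotides (six columns) occur in random sequence, so the tolerance
must clear them, while beyond the element's boundary every column fails
and termination is immediate. The 3' direction also closes on a poly-A
run (≥15 bp, long enough not to fire inside an A-rich body). The original
e-value prefilter of a BLAST-based search is database-size dependent and
is replaced by the identity filter alone.

After the walk, all reads are mapped back onto the consensus
(best-seeded placement) to give per-column base and member-dinucleotide
counts. This mapping admits reads down to 4 identity points below the
walk's candidate floor: per-copy identity straddles the floor when copy
divergence is near it, and residual consensus errors depress local
identity further — a strict filter would starve exactly the columns that
need correcting. CpG correction rewrites an adjacent column
pair to CG when (a) at least one column is highly variable (majority
< 0.8) and (b) ≥90% of member dinucleotides fall in {CG, CA, TG, TA} with
both CA and TG observed — the two-strand deamination fingerprint.
Verification re-runs the entire pipeline from a pseudo-random internal
500 bp seed (low-complexity windows re-drawn) and reports the identity
between the rerun and the original plus any intervals below the depth
floor. All the hand-editing a manual pipeline would do is replaced by
these logged automatic rules; `--review` dumps the full per-column support
for inspection.

## Annotation and construct utilities (`paleoline.annotate`)

The two longest non-overlapping plus-strand ORFs (by codon count, ties to
the 5'-most start) become ORF1 and ORF2 in positional order; the IGR is
the interval between them; A-content is counted over ORF1+IGR+ORF2 on the
coding strand (UTRs and poly-A excluded) and reported to one decimal.
`alt_orf2_start` finds the nearest in-frame ATG inside the IGR with no
intervening in-frame stop. Note an inherent limit of mechanical
annotation: a *clean* upstream in-frame ATG is necessarily absorbed into
ORF2 by any longest-ORF rule, shortening the reported IGR by the
elongation; the canonical start of a real element is homology-defined and
cannot be recovered from the sequence alone. The simulator therefore does
not plant an alternative start by default, and `alt_orf2_start` is
exercised on elements whose coordinates are fixed independently.

Conservation reports: conserved sites are alignment columns with exactly
one residue among the non-focal taxa (any non-focal gap disqualifies the
column); private changes are conserved columns where the focal, non-gap
residue differs. Construct utilities: `shuffle_igr` is a seeded uniform
permutation (length and composition preserved exactly); `remove_aug`
rewrites every ATG at any offset to AGT until none remain, sparing a
protected suffix such as the ORF2 start context.

## Orchestration, determinism, problem sizes

`PipelineConfig` bundles all stage parameters with an `rng_seed` and a
scale profile (`paper` keeps the 250-member subfamily floor; `desk`
lowers it to 25). Every output file carries the seed and a hash of the
full configuration; a rerun with the same seed is byte-identical. All
outputs are plain text (FASTA wrapped at 70 columns, TSV, JSON, Newick).

The standard desk-scale study sizes, used by the test suite and
`scripts/acceptance.py`, are chosen so a full run completes in minutes on
one CPU: reconstruction on a 6 kb master with 500 copies at 8% divergence
under 2× coverage of a ~1 Mb genome; family/peak recovery on two families
(5% apart) with bursts of 500 copies at 7% and 12%; splitting and
dispersion checks on 600–1000 member pools. Unit tests use 3 kb masters
with 120–150 copies.

## Known limitations

- The identity measure extends alignments ungapped; data dominated by
  long indels would need the (optional) exhaustive DP mode.
- Peak calling at 0.2% bandwidth needs a few hundred copies per burst;
  bursts closer than ~2% divergence merge.
- The co-segregation splitter tests one column pair per recursion level;
  it does not reproduce any particular external tool's partition on real
  data, and the subfamily count on a real genome is tool- and
  parameter-specific.
- Walking across regions with coverage below the depth floor stops rather
  than guessing; promoter-distal 5' UTRs reconstruct only as far as
  full-length copies support them.
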