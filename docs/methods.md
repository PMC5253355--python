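# Methods

`virobench` is a toolkit for benchmarking metagenome assemblers on
virome-like data and for the downstream informatics that virome assemblies
need: duplicate-contig detection, viral/cellular kingdom assignment, and
annotation of small circular Rep-encoding ssDNA (CRESS) virus genomes.
This note describes the models and procedures implemented, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Simulated viromes (`virobench.sim`)

Viromes pose three assembly challenges that generic metagenome simulations
under-represent: strongly skewed abundances, fragmented representation of
larger genomes, and a handful of small circular genomes at coverage orders
of magnitude above the rest (an artifact of rolling-circle genomes and
multiple-displacement amplification). The simulator builds all three
scenarios from a genome set:

* **Skewed abundances.** `sample_abundance_profile(n, sigma, seed)` draws
  lognormal weights (shape `sigma`, normalised to sum 1). `sigma = 1.5`
  is the default used in examples — a realistic virome skew in which the
  top decile of genomes holds most of the mass. A profile weight is a
  genome *copy number*; read sampling weight is copy number × genome
  length, the per-copy convention of standard read simulators.
* **Fragmentation.** `fragment_genomes` cuts each genome into consecutive
  non-overlapping windows of exactly the fragment length (default 2 kb),
  starting at position 0 and discarding a short trailing window. With
  `keep_every_second`, even-indexed windows are kept, so retained
  fragments never abut and any assembled scaffold longer than one fragment
  is an artifact by construction. Which half to discard is arbitrary; the
  even-index rule is fixed for reproducibility.
* **Coverage spikes.** `make_spiked_profile` adds small circular genomes
  at `spike_fold` × the median base weight before renormalising. The
  default `spike_fold = 1000` makes the spiked genomes "exceptionally"
  covered without making the rest of the data vanish; it is configurable
  because the realistic multiple spans orders of magnitude.

**Read model.** `simulate_read_pairs` draws, per pair: a template
(probability ∝ weight × length), an insert length from
N(`insert_mean` = 450 nt, sd = 10% of the mean) rounded and clamped to
[read length, template length], a uniform fragment start (circular
templates wrap), and a strand. Read 2 is the reverse complement of the
fragment end. Substitution errors follow a position-dependent ramp, linear
from 0.5× to 1.5× the target rate along the read so that the mean equals
the configured rate — a first-order stand-in for the rising error profile
of Illumina chemistry. Defaults are 1% for 300 nt reads and 0.9% for 80 nt
reads. No indels or quality-dependent recalibration are modelled; quality
strings encode the per-base error probability exactly (Phred+33, capped at
Q41). All randomness flows from the single `seed` in the configuration;
identical seeds give byte-identical FASTQ output.

**Mock assemblies.** `generate_mock_assembly` plants labelled artifacts —
faithful copies, two-parent chimeras, truncations, and duplicate clusters
(n near-identical copies of one genome with per-copy truncation up to 10%
and substitution mutation, default 0.5%, giving expected pairwise identity
≈ 99%). The truth table makes planted-truth evaluation of the assembly
evaluator and the duplicate-network detector exact rather than
statistical.

**What the generator does not emulate.** Real viromes add strain-level
microdiversity, indel and chimera artifacts of whole-genome amplification,
GC-coverage bias and adapter contamination. Tests passing on these
synthetic data therefore demonstrate correctness of the *rules and
statistics*, not robustness to every artifact of real libraries.

## Assembly evaluation (`virobench.evaluate`)

Scaffolds (≥ 500 nt by default) are aligned to the truth genomes with a
built-in near-identity aligner: exact k-mer anchors (default k = 21) on a
common (genome, strand, diagonal) are chained when ≤ 200 nt apart,
extended gap-free with an x-drop rule (+1 match / −3 mismatch, drop 12),
and reported when block identity ≥ 95%. Circular genomes are aligned
against their self-concatenation with coordinates reported modulo length.
The aligner is substitution-only by design — the simulator plants no
indels — and `load_alignment_coords` accepts show-coords style tabular
files from an external whole-genome aligner when gapped alignment evidence
is preferred.

A scaffold is **correct** iff blocks to a single genome, all same-strand
and collinear, cover ≥ 95% of it; otherwise it is misassembled with a
recorded reason (multi-genome, non-collinear, low-coverage) or unaligned
when no block survives. "Correct" has no standard definition; 0.95/0.95
mirrors the stringent length/similarity fractions used for read mapping in
this kind of benchmarking. In **fragment mode** any scaffold at or beyond
(1 + 5%) × fragment length — 2.1 kb for 2 kb fragments — is misassembled
unconditionally, since no true template of that length exists.

Summary statistics follow the conventions of assembly benchmarking
tables: per-size-bin counts and % misassembled (reported to the integer;
counts are exact), N50 (largest L such that sequences ≥ L hold half the
total length), maximum scaffold, total correctly assembled length (Mb),
**genomes hit** (≥ 1 retained block, i.e. at ≥ 95% identity) and **genomes
recovered**. Recovery is deliberately strict: a single correct scaffold
must cover ≥ 90% of the genome — a genome reassembled in two halves is hit
but not recovered, because multi-scaffold representation forces additional
joining steps that can create chimeras. The 90% fraction is configurable;
"reassembled into one sequence" fixes no fraction by itself.

`map_reads_back` gives simplified read-mapping concordance (% concordant
pairs, % pairs with multiple placements on one scaffold, % pairs split
across scaffolds) by exact 31-mer anchoring with gap-free verification; it
is a diagnostic, not a replacement for a production mapper.

## Duplicate-contig networks (`virobench.dedup`)

Excessively covered genomes are often reconstructed as many near-identical
contigs. The detector aligns all contigs against each other and clusters
the names of "identical" pairs by connected components. Near identity is
operationalised as ≥ 98% identity over ≥ 90% of the shorter contig —
observed duplicate clusters sit near 100% identity, and 98% keeps copies
with ~1% accumulated substitution differences in one cluster while leaving
genuinely distinct sequences out. Candidate pairs are screened by shared
21-mers (canonical, both strands; a full k-mer index probed with ~64
sampled k-mers per contig) and verified with a banded edit-distance
alignment of the shorter within the longer (edlib, infix mode), so the
whole shorter sequence participates: containment semantics. Two unrelated
2 kb sequences share no 21-mer in expectation, so the screen is effectively
exact at these scales.

Supporting operations: `flag_high_coverage` (strictly above the threshold,
default 5000× — contigs that warrant duplicate inspection even when present
as single copies), `partition_reads` (reads to the cluster of their best
placement, ties to the first cluster by representative id; the output is a
disjoint cover of the read ids, so cluster-specific reassembly uses each
read exactly once), and `deduplicate_cluster` (greedy longest-first
retention of members not contained in an already-retained member; the
result is an antichain under containment). The cluster representative is
the longest member, the most complete reconstruction by assumption.

## Kingdom assignment (`virobench.annotate`)

The decision tree compares the top-scoring hit per source — a viral-subset
protein database, NCBI-nr and RefSeq-P — and is described in the module
docstring. The load-bearing choices:

* The viral-subset rule is strict: viral iff bit score **> 50**.
* Rules (b) and (c) require e-value **< 1e-4** and bit score **≥ 45**;
  an e-value exactly at the threshold falls to putative-Viruses.
* A cross-source score *tie* does not fire rule (a); the nr/RefSeq rules
  are then evaluated. "Highest score" with ties resolved against the viral
  call keeps viral assignments conservative.
* Rule (d) (viral domain annotation) is evaluated right after (a), so
  domain evidence can rescue proteins the similarity search misses.
* Bit scores from all sources are treated as the same statistic.

The keyword dictionary is built from the winning viral-subset subject
titles: lower-cased tokens ≥ 3 characters, minus a stoplist of generic
terms (protein, hypothetical, putative, uncharacterized, ...); adjacent
token pairs recurring in ≥ 2 distinct titles are kept as phrases. Matching
is whole-token and case-insensitive, so "macrophage" does not match
"phage". An optional stringency filter (`filter_ambiguous_viral_calls`,
off by default) demotes rule-(a) calls whose viral-subset score is below
half the overall top score on contigs that also carry cellular calls.

LCA assignment follows the MEGAN parameterisation: hits filtered to bit ≥
45 and e-value ≤ 1e-4, retained within top-percent 10 of the best bit
score, minimum support 1, and LCA percent 100 (the returned taxon is an
ancestor of *all* retained hits). `contamination_fraction` reports the
percentage of distinct reads with an rRNA-database hit at bit ≥ 80, to two
decimals.

## Circovirus-like annotation (`virobench.circo`)

**ORFs.** Six-frame prediction of maximal ORFs (first start after the
previous in-frame stop, to the next stop; stop included in the
coordinates, excluded from the protein; standard genetic code, ATG starts
by default). Circular sequences are handled by scanning the doubled
sequence and reporting coordinates modulo length, so origin-spanning ORFs
come out with end < start; the protein multiset is invariant under
rotation of the input. ORFs longer than the sequence itself are not
called. Coordinates are 1-based inclusive with a signed frame label.

**Replication origins.** The rolling-circle origin is modelled as a
conserved nonanucleotide-family motif (defaults `AGTATTAC`, `AGTATTAT`,
`ATTATTAC`; IUPAC degenerate patterns accepted, both strands searched) in
the loop of a stem-loop. "Palindromic repeat" is interpreted as an
*inverted repeat*: the right arm is the reverse complement of the left
arm, "imperfect" meaning ≥ 1 mismatch; the quoted arm length counts one
arm. For each motif occurrence, arms of 8–20 nt are sought within 10 nt of
either motif end, allowing ≤ 2 mismatches by default; the reported site
maximises net matches (arm length − 2 × mismatches), so a perfect planted
arm is never displaced by a mismatch-padded longer one. A minimum arm of
8 keeps the expected number of spurious arm calls per 2 kb of random
sequence below 0.05.

**Rep motifs.** `scan_rep_motifs` matches position-wildcarded amino-acid
patterns, grouped into the shipped profiles for circovirus-like clades —
clade-3 {I: FTINN, II: HLQG, III: YCKKD}, clade-2 {II: H.Q, III: Y.KD /
Y.KE} — and geminivirus-like Reps {I: FLTF, II: HLH, III: YCMKD}. All
(possibly overlapping) matches are reported with 1-based positions.
Profile-based domain detection (PF02407 / PF00910 and relatives) is
consumed from external domain tables, not computed here.

## Numerical and testing choices

* All stochastic operations take an explicit seed; no global random state.
* Coordinates are 0-based half-open internally, 1-based inclusive in all
  human-readable reports.
* Test and acceptance problem sizes are desk-scale by design: 10,000 read
  pairs for simulator fidelity (standard errors ≈ 0.45 nt on the insert
  mean and ≈ 0.004% on the error rate), 100,000 pairs for the multinomial
  sampling check, a 286-member planted duplicate cluster, 500 planted
  origin sites, and 200 random taxonomies for the LCA oracle. These sizes
  make the checks sharp while keeping the full suite to well under a
  minute of simulation time.
* The evaluator's known limitations: gap-free blocks understate coverage
  of indel-rich scaffolds (use an external aligner's coordinates file in
  that case), and `map_reads_back` requires an exact 31-mer anchor, so it
  undercounts placements of reads with dense errors.
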