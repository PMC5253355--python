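# virobench

Virome informatics toolkit: benchmarking metagenome assemblers on
virome-like data, and the downstream analyses a virome assembly needs —
duplicate-contig network detection, viral/cellular kingdom assignment with
LCA, and annotation of small circular Rep-encoding ssDNA (CRESS) virus
genomes.

Viromes are hard on assemblers for reasons that averaged statistics hide:
abundances are strongly skewed, larger genomes are represented in
fragments, and a few small circular genomes (amplified by rolling-circle
replication and whole-genome amplification) arrive at coverage thousands
of times above the rest, which some assemblers reconstruct into hundreds
of near-identical contig copies. `virobench` is for bioinformaticians who
want to (i) build controlled simulated viromes that reproduce exactly
these pathologies, (ii) score assemblies against the truth with
size-stratified misassembly rates rather than dataset-wide averages, and
(iii) clean up and annotate real virome assemblies with the same rules.

## What it computes

* **Simulation** (`virobench.sim`): lognormal abundance profiles; 2 kb
  fragment libraries (with every second fragment discarded); coverage
  spike-ins; paired-end reads with a 450 nt (10% sd) insert model and an
  Illumina-like substitution ramp (1% at 300 nt, 0.9% at 80 nt); mock
  assemblies with planted, labelled chimeras, duplicate clusters and
  truncations; exact-duplicate read-pair removal.
* **Evaluation** (`virobench.evaluate`): built-in near-identity alignment
  of scaffolds to truth genomes (or show-coords style input), per-scaffold
  verdicts (correct / misassembled with reason / unaligned), per-size-bin
  misassembly percentages, N50

  `N50 = max{ L : Σ_{ℓ_i ≥ L} ℓ_i ≥ ½ Σ ℓ_i }`,

  genomes hit and genomes *recovered* (one correct scaffold covering
  ≥ 90% of the genome). In fragment mode every scaffold at or beyond
  (1 + 5%) × fragment length — 2.1 kb for 2 kb fragments — is
  misassembled by definition.
* **Duplicate networks** (`virobench.dedup`): all-vs-all near-identity
  edges (≥ 98% identity over ≥ 90% of the shorter contig), connected
  components, high-coverage flags (> 5000×), cluster-specific read
  partitioning, and containment-based reduction of a cluster to its
  distinct sequences.
* **Annotation** (`virobench.annotate`): score-based kingdom assignment
  comparing a viral-subset database (viral iff bit > 50), NCBI-nr and
  RefSeq-P top hits (rules: viral-subset highest; viral lineage; viral
  keyword; viral domain; each at e-value < 1e-4, bit ≥ 45), the
  putative-Viruses class, a viral keyword dictionary, MEGAN-style LCA
  (min score 45, max e-value 1e-4, top percent 10, LCA percent 100), and
  rRNA contamination fractions (bit ≥ 80).
* **CRESS annotation** (`virobench.circo`): circularity-aware six-frame
  ORF calling, rolling-circle origin detection (nonanucleotide motif in a
  stem-loop of inverted-repeat arms), and Rep motif I/II/III scanning
  (FTINN / HLQG / YCKKD and degenerate relatives).

See `docs/methods.md` for models, parameters and design decisions.

## Worked example

Build a fragmentation scenario (five 16 kb genomes cut into 2 kb pieces,
every second piece discarded), make an "assembly" of 15 faithful fragments
plus one two-fragment join, and evaluate in fragment mode:

```python
from virobench import sim, evaluate
from virobench.evaluate import EvalParams
from virobench.seqio import GenomeRecord

genomes = sim.random_genomes(5, 16_000, seed=11)
lib = sim.fragment_genomes(genomes, 2000, keep_every_second=True)   # 20 fragments
scaffolds = [GenomeRecord(f"scaf{i}", f.sequence) for i, f in enumerate(lib.fragments[:15])]
scaffolds.append(GenomeRecord("join", lib.fragments[15].sequence + lib.fragments[16].sequence))

params = EvalParams(size_bins=[(500, 1000), (1000, 2000), (2000, 2100), (2100, float("inf"))])
summary = evaluate.evaluate_assembly(scaffolds, genomes, params, fragment_mode_length=2000)
for row in summary.to_rows():
    print(row["label"], row["count"], f'{row["pct_misassembled"]}%')
print("N50", summary.n50, "| misassembled", summary.n_misassembled,
      "| genomes hit", summary.genomes_hit, "| recovered", summary.genomes_recovered)
```

prints

```
500-999 nt 0 0%
1-1.999 kb 0 0%
2-2.099 kb 15 0%
>=2.1 kb 1 100%
N50 2000 | misassembled 1 | genomes hit 5 | recovered 0
```

The 15 faithful 2 kb fragments are all correct (0% misassembled in their
bin); the 4 kb join exceeds the 2.1 kb over-length cutoff and is
misassembled by definition (100% of its bin). All five genomes are hit,
but none is recovered: in a fragmentation scenario no single scaffold can
cover 90% of a source genome.

The same operations are available from the shell, e.g.:

```bash
virobench sim fragments --genomes genomes.fa --fragment-length 2000 \
    --out-fasta frags.fa --out-map parents.tsv
virobench eval --scaffolds assembly.fa --genomes genomes.fa --fragment-length 2000
virobench circo ori --contigs contigs.fa --out ori.tsv
```

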