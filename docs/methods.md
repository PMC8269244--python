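# Methods

`shallowmeta` implements the computational core of a homology-based
taxonomic and functional profiler for shallow shotgun metagenomic data
sets (on the order of 100,000 reads), together with the database-curation,
simulation and benchmarking machinery needed to validate it end to end on
synthetic data. This note records the model, the parameters that matter,
the numerical conventions, and what the synthetic test bed does and does
not demonstrate.

## Read classification model

Each read is aligned to a curated nucleotide reference database; the
classifier consumes a bounded list of local-alignment hits (up to
`max_hits = 100`) that passed an E-value gate (`evalue_max = 1e-5`) and a
query-coverage gate (`min_query_cov = 95%`, chosen permissively to absorb
alignment inaccuracy at read ends). Let *I* be the best percent identity
among surviving hits:

* **I > 94%** (`species_min_identity`, the conventional ANI species
  boundary): species-level call. If the equal-best-hit set (hits within
  `identity_tie_epsilon` of *I*; default 0, i.e. exact ties) maps to a
  single species, that species is assigned (`best_hit`). If it maps to
  several species, the read is assigned the least common ancestor (LCA) of
  their taxa (`lca`), and the assignment's rank is the LCA node's rank.
  When every tied hit is viral, LCA is skipped and the highest-bit-score
  species wins (`viral_best_hit`): public viral genomes are so similar
  that LCA would push essentially all viral reads to uninformative ranks.
  Mixed viral/non-viral ties (rare; possible only through database
  contamination) fall back to LCA.
* **20% ≤ I ≤ 94%** (`genus_min_identity` to the species cutoff,
  inclusive on both ends by the strictness convention below): genus-level
  call as an "undefined species" — the read likely derives from a species
  with no representative genome. The low genus floor deliberately admits
  distant homology so novel species still register at genus level.
* **I < 20%**, or no surviving hits: unclassified.

Boundary strictness: the species rule is *strictly greater than* 94, so a
read at exactly 94.0% identity is a genus-level call. Raising
`species_min_identity` can therefore only demote species calls, never add
them (a property the test suite sweeps).

Paired-end mates are classified independently and counted as independent
reads; the profile abundance unit is the read.

### Profiles and genome-size normalization

Species-level counts (with per-genus "undefined species" bins and
higher-rank LCA bins) are converted to relative abundances over classified
reads. Because a genome contributes sequenced fragments in proportion to
its length, read shares over-represent large genomes; the size-normalized
abundance divides each species' count by the mean total genome length of
that species in the database:

    normalized_i = 100 · (c_i / s_i) / Σ_j (c_j / s_j)

Taxa without a size entry (undefined-species bins, higher-rank bins, novel
species) fall back to the database-wide mean genome size; genuinely
missing species trigger a warning.

## Database curation

Curation consumes declared genome metadata plus a precomputed
average-nucleotide-identity (ANI) table and runs four steps in order:

1. **Contig length floors** — contigs shorter than 1 kbp (viral), 5 kbp
   (prokaryotic) or 12 kbp (eukaryotic) are removed; a genome with no
   surviving contig leaves the database. Floors are strict on "shorter
   than" (a contig exactly at the floor survives).
2. **Host decontamination** — contigs aligning to configured host genomes
   at ≥ 90% identity over ≥ 50% of the contig are removed. These two
   thresholds are a design choice (the qualitative criterion is "high
   sequence identity to common hosts") and are config-exposed.
3. **Taxonomic revision** — each non-reference genome is compared with its
   closest reference genome (highest ANI; ties by higher
   min(query, subject) coverage, then accession, for determinism). If
   ANI > 94% with both coverages > 70%, the genome adopts the reference's
   species label. Otherwise, if the closest reference shares the declared
   genus, the declared taxonomy is retained (the species likely lacks a
   reference genome yet); failing that — including genomes with no ANI
   evidence at all — the declared taxonomy is retained and the genome is
   flagged unresolved. A coverage failure never reclassifies, however high
   the ANI: partial-genome evidence is treated as insufficient. Every
   decision is logged with one of three closed reason codes.
4. **Dereplication** — a non-reference genome with ANI > 99% to its own
   (revised) species' reference genome is redundant and dropped. Only the
   species' own reference is consulted, not all-vs-all; genomes whose
   species has no reference are always retained.

Length filtering precedes revision so ANI decisions apply to the sequences
that actually enter the database. The pipeline is idempotent, and raising
the dereplication threshold can only grow the retained set.

The per-species **size table** is the arithmetic mean of retained genomes'
total lengths (mean, not median, so a species' table entry responds to
every genome in it).

## Alignment backends

The profiler is backend-agnostic: it consumes BLAST `outfmt 6` tabular
hits (12 columns, optional 13th `qcovs`; coverage is otherwise derived
from alignment length and supplied query lengths). Two built-in backends
exist:

* `local_align` — exact Smith–Waterman (match +1 / mismatch −1 / gap −2,
  linear gap), deterministic traceback (ties resolved toward the smallest
  query start, then subject start; strand ties prefer `+`). It is the
  small-instance oracle: tests verify it against an independent
  pure-python full-DP recomputation on random pairs.
* `SeedExtendAligner` — the bulk mapper. References are concatenated (with
  `N` spacers so no seed spans two contigs) and indexed as a sorted array
  of 2-bit 21-mer codes; a read is mapped by exact lookup of seeds sampled
  every 12 bp along both strands, clustering seed votes by implied
  alignment start within an indel band (12% of query length), and
  verifying each candidate locus with an infix edit-distance alignment
  (edlib). Identity is `(aln_len − edits) / aln_len`, charging
  substitutions and indels alike. Exhaustive quadratic alignment cannot
  serve whole read sets against megabase references, which is why every
  practical mapper seeds; the seeded backend trades guaranteed optimality
  for that throughput, and the test suite pins its identity estimates to
  the Smith–Waterman oracle on planted cases. With 21-mer seeds at 2%
  substitution error, the chance a 150-bp read has no error-free seed is
  well below 10⁻³.

E-values emitted by built-in backends are the monotone transform
`E = m·n·2^(−score)` — calibrated only for thresholding, not comparable
across scoring schemes; backend-supplied E-values are consumed verbatim.

## Contig classification and GenBank output

Contigs strictly longer than 5 kbp are classified with the read rules,
with two changes: the query-coverage gate is dropped (a long contig rarely
aligns end-to-end to a draft reference) and hits must span ≥ 1 kb. A
contig's hits are reduced to a single best-hit set; segment-wise majority
voting along the contig is a known alternative and deliberately out of
scope. Pools of contigs sharing a taxon are written as one GenBank file
each (one LOCUS per contig) with CDS features from a six-frame maximal
ATG→stop ORF caller (`min_orf_nt = 300`). The ORF caller provides GenBank
structure, not annotation quality.

## Functional profiling

Reads are aligned to labeled functional references (FASTA headers
`>seq_id|family|pw1,pw2`). Gates are separate from the taxonomic ones
(E ≤ 1e-5, coverage ≥ 50%; the laxer coverage accommodates reads spanning
domain boundaries). Each read increments the family of its best passing
hit (bit score; ties broken by lexicographic family so results are
order-independent); pathway counts roll up non-exclusively over the
best-hit reference's pathway list. Searches are nucleotide-space;
a translated-search backend can be plugged in via the same tabular format.

## Synthetic data generator

The generator emulates the artificial-data-set design used to validate
the pipeline:

* **Genomes** — i.i.d. bases at a chosen GC fraction. Real genomes have
  repeats, skew and shared ancestry; i.i.d. genomes are essentially
  orthogonal, which makes cross-mapping between synthetic species
  vanishingly rare.
* **Illumina-like reads** — 150-bp paired-end, fragment positions uniform,
  fragment strand equiprobable, insert ~ Normal(400, 40), substitution
  errors at `base_error_rate = 0.02`, constant Q30 quality strings (truth
  lives in the manifest, not the qualities).
* **Nanopore-like reads** — fixed 8 kbp length with per-base error events
  at 0.003, split evenly between substitutions, insertions and deletions
  (the indel-dominated regime); no homopolymer bias or quality model.
* **ANI fixtures** — planted (query, subject, ANI, coverages) relations,
  optionally symmetric, for exercising the curation rules.

Every read carries a manifest row (species, genome, coordinates, strand);
the expected profile is the per-species read fraction. All generators are
byte-identical for a fixed seed.

Because synthetic species are orthogonal and errors are uniform, passing
the recovery tests demonstrates the correctness of the pipeline's
bookkeeping and thresholds — not robustness to conserved regions,
horizontal transfer, strain mixtures or real error profiles, which
require real reference genomes.

## Evaluation statistics

* **DExA** (Deviation from Expected Abundance) = half the L1 distance
  between observed and expected percent profiles over the union of their
  species; 0% = identical, 100% = disjoint. The halving prevents
  double-counting (mass missing from one species necessarily surfaces as
  surplus elsewhere); DExA is symmetric, bounded and satisfies the
  triangle inequality. Observed profiles are renormalized over classified
  reads by default; alternatively unclassified mass can be carried
  explicitly, where it counts as pure deviation. "Undefined species" bins
  count as non-matching species at species level (strictest reading).
* **Confusion under database ablation** — reads from species kept in the
  database score TP when called to their true species and FP otherwise
  (including unclassified); reads from ablated species score TN when
  rejected or pushed above species rank and FN when confidently
  mis-assigned to a concrete species. This follows the ablation
  convention in which the interesting failure is a confident wrong call
  on an out-of-database read; the textbook relabelling is also emitted.
  Rates are conditioned on their read-origin totals, so the four counts
  partition the read set.
* **Depth titration** — seeded subsamples at a ladder of depths, each
  profiled and scored by DExA against truth.

## Problem sizes and numerical conventions

The test suite exercises the full recovery path at 5 species (genome
lengths 0.5–2 Mb), 20,000 read pairs at 2% error, classified with the
built-in seeded aligner against the source-genome database; the measured
DExA against truth is ~0.3%, and the suite asserts < 5%. Even-design
generator checks use 10 species × 20-kb genomes and 1,000 species × 2-kb
genomes (100,000 reads each); the checked quantity — exact manifest read
allocation — does not depend on genome length. Error-rate calibration
checks use ≥ 10⁵ simulated bases and 3σ binomial/Poisson bands.

Profiles must sum to 100 ± 1e-6 before DExA is computed; relative and
normalized abundances sum to 100 ± 1e-9 by construction. All stochastic
components (genomes, reads, subsampling) take explicit integer seeds, and
child seeds are drawn below 2³¹.

## Known limitations

* The seeded mapper is not guaranteed-optimal alignment; reads whose every
  sampled seed is disrupted go unmapped (negligible at the default error
  rates, unbounded in principle).
* The taxonomy derived from database metadata is a minimal
  root–superkingdom–genus–species skeleton; LCA across it is coarser than
  against a full reference taxonomy.
* No strain-level resolution, no abundance re-estimation beyond genome-size
  normalization, no assembly (contigs are consumed, not produced), and no
  translated functional search in the built-in backend.
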