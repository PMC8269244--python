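# shallowmeta

Homology-based taxonomic and functional profiling of **shallow shotgun
metagenomic data sets** — sequencing runs analyzed at ~100,000 reads, the
cost-effective successor to 16S amplicon profiling that still resolves
species. The package implements the full computational core of such a
profiler: curated reference-database construction, best-hit/LCA read and
contig classification, genome-size-corrected abundance profiles,
CAZy-style functional family profiling, benchmark statistics, and the
synthetic-data generators used to validate all of it — no external
downloads required.

## The model in brief

A read is classified from its filtered local-alignment hits
(E ≤ 10⁻⁵, query coverage ≥ 95%, best 100 hits). With *I* the best-hit
percent nucleotide identity:

| condition | call |
|---|---|
| *I* > 94%, one best species | that species (best hit) |
| *I* > 94%, several equal-best species | LCA of their taxa (skipped for viral hits: best bit score instead) |
| 20% ≤ *I* ≤ 94% | genus of the best hit, as an "undefined species" |
| *I* < 20% or no hits | unclassified |

Species read counts *c_i* are reported raw and corrected for mean genome
size *s_i* (larger genomes shed proportionally more fragments):

    normalized_i = 100 · (c_i / s_i) / Σ_j (c_j / s_j)

Profiler accuracy is summarized by the **DExA index** (Deviation from
Expected Abundance): half the L1 distance between observed and expected
percent profiles — 0% for identical profiles, 100% for disjoint ones.

The reference database behind the classifier is curated from declared
genome metadata plus an average-nucleotide-identity (ANI) table: genomes
are relabelled to their closest reference genome when ANI > 94% with both
coverages > 70%, near-duplicates (ANI > 99% to their species reference)
are dropped, contigs below 1/5/12 kbp (viral/prokaryotic/eukaryotic) and
host-like contigs are removed, and a per-species mean genome-length table
is derived for normalization.

## Worked example

Simulate a three-species mock community (150-bp paired-end reads, 2%
error), build a database from the source genomes, and profile the reads
with the built-in seed-and-extend aligner:

```python
from shallowmeta import benchmark, pipeline, refdb, simdata
from shallowmeta.readprofiler import profile_to_frame

species = (
    simdata.SpeciesSpec("Lactobacillus helveticus", 500_000, gc=0.37,
                        reads=6_000, genus="Lactobacillus"),
    simdata.SpeciesSpec("Streptococcus thermophilus", 1_800_000, gc=0.39,
                        reads=10_000, genus="Streptococcus"),
    simdata.SpeciesSpec("Bifidobacterium breve", 2_300_000, gc=0.59,
                        reads=4_000, genus="Bifidobacterium"),
)
spec = simdata.SimSpec(species=species, base_error_rate=0.02, seed=11)
genomes = simdata.simulate_genomes(spec)
r1, r2, truth = simdata.simulate_illumina(spec, genomes)

records = {
    name: refdb.GenomeRecord(name, name, sp.genus, "prokaryotic", True,
                             ((name, seq),))
    for (name, seq), sp in zip(genomes.items(), species)
}
db = refdb.curate(records, [])

profile, _ = pipeline.profile_sample(r1 + r2, db, seed=0, apply_qc=False)
print(profile_to_frame(profile).to_string(index=False))
print("unclassified reads:", profile.unclassified_count)
print(f"DExA vs truth: {benchmark.dexa(profile.relative, truth.expected_profile):.2f}%")
```

Output:

```
                            taxon  count  relative_pct  normalized_pct
       Streptococcus thermophilus   9955     49.782467       28.698283
         Lactobacillus helveticus   5979     29.899485       62.050559
            Bifidobacterium breve   3988     19.942991        8.997347
  Streptococcus undefined species     43      0.215032        0.145519
  Lactobacillus undefined species     20      0.100015        0.067683
Bifidobacterium undefined species     12      0.060009        0.040610
unclassified reads: 3
DExA vs truth: 0.38%
```

Reading this: of 20,000 reads, 19,922 were recovered at species level
within 0.5% of their true share (DExA 0.38%); the few reads pushed below
94% identity by clustered simulated errors fall into per-genus
"undefined species" bins rather than being mis-assigned. The
`normalized_pct` column re-weights shares by genome size — the 0.5-Mb
*L. helveticus* genome contributed few reads per cell, so its normalized
(cell-proportional) share is the largest.

A command-line interface mirrors the library
(`shallowmeta simulate | curate-db | profile-reads | classify-contigs |
profile-function | dexa`); see `shallowmeta --help`.

### Node table format

Taxonomies load from a flat TSV with columns `taxid`, `parent_taxid`,
`rank`, `name` (ranks: root, superkingdom, phylum, class, order, family,
genus, species; the root is its own parent; intermediate ranks may be
omitted).

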