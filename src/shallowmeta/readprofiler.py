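"""Read-based taxonomic profiling.

The profiling pipeline for a shallow shotgun data set:

1. quality filter (mean Phred >= 25, length >= 150 bp);
2. optional host-DNA depletion;
3. seeded subsampling to the working depth (default 100,000 reads);
4. per-read homology classification against the curated database: reads
   whose best-hit nucleotide identity exceeds 94% are assigned at species
   level, equal best hits to multiple species are resolved by LCA (disabled
   for viral matches, where inter-genome identity is too high for LCA to be
   informative), and reads between 20% and 94% identity become genus-level
   "undefined species";
5. aggregation into per-rank profiles, with relative abundances optionally
   corrected for species genome size (larger genomes shed proportionally
   more fragments into the library, biasing raw read counts).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentHit, filter_hits
from .taxonomy import TaxonomyTree

UNDEFINED_SPECIES = "undefined species"


class ProfilerError(ValueError):
    pass


class Read(NamedTuple):
    """One FASTQ record (Phred+33 qualities)."""

    id: str
    seq: str
    qual: str


def read_fastq(path) -> list[Read]:
    with open(path) as fh:
        return [Read(t.split()[0], s, q) for t, s, q in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable cutoffs for per-read classification.

    ``species_min_identity`` is strict (identity must exceed it) while
    ``genus_min_identity`` is inclusive, so a read exactly at the species
    cutoff is a genus-level call.  ``identity_tie_epsilon`` widens the
    "equal best hits" set by that many percentage points (0 = exact ties).
    """

    species_min_identity: float = 94.0
    genus_min_identity: float = 20.0
    evalue_max: float = 1e-5
    min_query_cov: float = 95.0
    max_hits: int = 100
    sample_size: int = 100_000
    viral_lca_disabled: bool = True
    identity_tie_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.genus_min_identity > self.species_min_identity:
            raise ProfilerError("genus_min_identity must be <= species_min_identity")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    taxid: str | None
    assigned_rank: str  # species | genus | higher | unclassified
    method: str  # best_hit | lca | viral_best_hit | none
    best_identity: float
    species_label: str | None
    genus_label: str | None = None
    taxon_name: str | None = None


@dataclass
class Profile:
    """Per-taxon read counts with raw and genome-size-normalized abundances."""

    counts: dict[str, int]
    relative: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)
    unclassified_count: int = 0
    rank_tables: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total_classified(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# QC / host depletion / subsampling


def mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def quality_filter(
    reads: Sequence[Read], min_mean_q: float = 25.0, min_length: int = 150
) -> tuple[list[Read], dict[str, int]]:
    """Retain reads with mean Phred >= ``min_mean_q`` and length >= ``min_length``."""
    kept: list[Read] = []
    stats = {"input": len(reads), "removed_quality": 0, "removed_length": 0}
    for r in reads:
        if len(r.seq) != len(r.qual):
            raise ProfilerError(f"read {r.id!r}: sequence/quality length mismatch")
        if len(r.seq) < min_length:
            stats["removed_length"] += 1
        elif mean_phred(r.qual) < min_mean_q:
            stats["removed_quality"] += 1
        else:
            kept.append(r)
    stats["retained"] = len(kept)
    return kept, stats


def quality_filter_pairs(
    reads1: Sequence[Read],
    reads2: Sequence[Read],
    min_mean_q: float = 25.0,
    min_length: int = 150,
) -> tuple[list[Read], list[Read], dict[str, int]]:
    """Paired mode: both mates are dropped when either fails the filter."""
    if len(reads1) != len(reads2):
        raise ProfilerError("mate files differ in read count")
    k1, k2 = [], []
    stats = {"input_pairs": len(reads1), "removed_pairs": 0}
    for r1, r2 in zip(reads1, reads2):
        a, _ = quality_filter([r1], min_mean_q, min_length)
        b, _ = quality_filter([r2], min_mean_q, min_length)
        if a and b:
            k1.append(r1)
            k2.append(r2)
        else:
            stats["removed_pairs"] += 1
    stats["retained_pairs"] = len(k1)
    return k1, k2, stats


def deplete_host(
    reads: Sequence[Read],
    host_hits: Mapping[str, Sequence[AlignmentHit]] | None,
    params: ClassifierParams = ClassifierParams(),
) -> list[Read]:
    """Remove reads with a confident host-genome hit.

    A read is depleted iff some host hit passes the E-value and coverage
    gates with identity at or above the species cutoff.  With no host
    configured (``host_hits`` None) the input is returned unchanged.
    """
    if host_hits is None:
        return list(reads)
    kept = []
    for r in reads:
        hits = host_hits.get(r.id, ())
        is_host = any(
            h.evalue <= params.evalue_max
            and h.query_cov >= params.min_query_cov
            and h.percent_identity >= params.species_min_identity
            for h in hits
        )
        if not is_host:
            kept.append(r)
    return kept


def subsample(
    reads: Sequence[Read],
    n: int = 100_000,
    seed: int = 0,
    mates: Sequence[Read] | None = None,
):
    """Uniform sample without replacement of ``min(n, total)`` reads.

    With ``mates`` given, sampling operates on pair units (``n`` counts
    pairs) and both mates travel together.  Seeded and reproducible.
    """
    if n < 1:
        raise ProfilerError("subsample size must be >= 1")
    rng = random.Random(seed)
    if mates is not None:
        if len(mates) != len(reads):
            raise ProfilerError("mate files differ in read count")
        idx = range(len(reads))
        take = sorted(rng.sample(idx, min(n, len(reads))))
        return [reads[i] for i in take], [mates[i] for i in take]
    take = sorted(rng.sample(range(len(reads)), min(n, len(reads))))
    return [reads[i] for i in take]


# ---------------------------------------------------------------------------
# Per-read classification


@dataclass(frozen=True)
class SubjectLabel:
    """Taxonomic identity of one database accession."""

    genus: str
    species: str
    taxid: str
    kingdom: str


def classify_read(
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    labels: Mapping[str, SubjectLabel],
    params: ClassifierParams = ClassifierParams(),
    read_id: str | None = None,
) -> ReadClassification:
    """Assign one read from its (already filtered) hit list.

    The "equal best hits" set contains every hit within
    ``identity_tie_epsilon`` percentage points of the top identity.  Above
    the species cutoff, a single species in that set is a direct call;
    several species trigger LCA — unless the matches are viral, in which
    case the highest-bit-score species wins (LCA across viral genomes is
    uninformative).  Between the genus and species cutoffs the read is a
    genus-level "undefined species"; below the genus cutoff it stays
    unclassified.
    """
    rid = read_id if read_id is not None else (hits[0].query_id if hits else "read")
    if not hits:
        return ReadClassification(rid, None, "unclassified", "none", 0.0, None)
    for h in hits:
        if h.subject_accession not in labels:
            raise ProfilerError(
                f"read {rid!r}: hit to accession {h.subject_accession!r} absent from labels"
            )
    best_identity = max(h.percent_identity for h in hits)
    if best_identity < params.genus_min_identity:
        return ReadClassification(rid, None, "unclassified", "none", best_identity, None)

    tied = [
        h for h in hits
        if h.percent_identity >= best_identity - params.identity_tie_epsilon
    ]
    if best_identity > params.species_min_identity:
        tied_species = {labels[h.subject_accession].species for h in tied}
        if len(tied_species) == 1:
            lab = labels[tied[0].subject_accession]
            return ReadClassification(
                rid, lab.taxid, "species", "best_hit", best_identity,
                lab.species, lab.genus, lab.species,
            )
        all_viral = all(labels[h.subject_accession].kingdom == "viral" for h in tied)
        if all_viral and params.viral_lca_disabled:
            top = min(tied, key=lambda h: (-h.bit_score, h.subject_accession))
            lab = labels[top.subject_accession]
            return ReadClassification(
                rid, lab.taxid, "species", "viral_best_hit", best_identity,
                lab.species, lab.genus, lab.species,
            )
        node_id = tree.lca([labels[h.subject_accession].taxid for h in tied])
        node = tree[node_id]
        if node.rank == "species":
            rank = "species"
            species_label = node.name
        elif node.rank == "genus":
            rank = "genus"
            species_label = UNDEFINED_SPECIES
        else:
            rank = "higher"
            species_label = None
        genus_label = node.name if node.rank == "genus" else None
        return ReadClassification(
            rid, node_id, rank, "lca", best_identity, species_label, genus_label, node.name
        )
    # genus_min_identity <= best_identity <= species_min_identity
    top = min(tied, key=lambda h: (-h.percent_identity, -h.bit_score, h.subject_accession))
    lab = labels[top.subject_accession]
    genus_taxid = _genus_taxid(tree, lab.taxid)
    return ReadClassification(
        rid, genus_taxid or lab.taxid, "genus", "best_hit", best_identity,
        UNDEFINED_SPECIES, lab.genus, lab.genus,
    )


def _genus_taxid(tree: TaxonomyTree, taxid: str) -> str | None:
    for rank, _name, tid in reversed(tree.lineage(taxid)):
        if rank == "genus":
            return tid
    return None


def classify_reads(
    reads: Sequence[Read],
    aligner,
    tree: TaxonomyTree,
    labels: Mapping[str, SubjectLabel],
    params: ClassifierParams = ClassifierParams(),
) -> list[ReadClassification]:
    """Map and classify a batch of reads with any ``map_read``-style backend."""
    out = []
    for r in reads:
        hits = filter_hits(
            aligner.map_read(r.seq, r.id),
            evalue_max=params.evalue_max,
            min_query_cov=params.min_query_cov,
            max_hits=params.max_hits,
        )
        out.append(classify_read(hits, tree, labels, params, read_id=r.id))
    return out


# ---------------------------------------------------------------------------
# Profile aggregation and normalization


def _undefined_bin(genus: str | None) -> str:
    return f"{genus} {UNDEFINED_SPECIES}" if genus else UNDEFINED_SPECIES


def aggregate_profile(
    classifications: Sequence[ReadClassification],
    tree: TaxonomyTree | None = None,
) -> Profile:
    """Fold per-read assignments into a species-level profile.

    Genus-level calls are counted in per-genus "undefined species" bins;
    higher-rank LCA calls are counted under the LCA node's name.  When a
    taxonomy is supplied, per-rank roll-up tables (genus and above) are
    derived by walking each assignment's lineage.
    """
    counts: dict[str, int] = {}
    unclassified = 0
    rank_tables: dict[str, dict[str, int]] = {}
    for c in classifications:
        if c.assigned_rank == "unclassified" or c.taxid is None:
            unclassified += 1
            continue
        if c.assigned_rank == "species":
            key = c.species_label or c.taxon_name or c.taxid
        elif c.assigned_rank == "genus":
            key = _undefined_bin(c.genus_label)
        else:
            key = c.taxon_name or c.taxid
        counts[key] = counts.get(key, 0) + 1
        if tree is not None and c.taxid in tree:
            for rank, name, _tid in tree.lineage(c.taxid):
                if rank in ("root",):
                    continue
                rank_tables.setdefault(rank, {})
                rank_tables[rank][name] = rank_tables[rank].get(name, 0) + 1
    total = sum(counts.values())
    relative = {k: 100.0 * v / total for k, v in counts.items()} if total else {}
    return Profile(
        counts=counts,
        relative=relative,
        unclassified_count=unclassified,
        rank_tables=rank_tables,
    )


def normalize_by_genome_size(
    profile: Profile, size_table: Mapping[str, float]
) -> Profile:
    """Correct relative abundances for species genome size.

    ``normalized_i = 100 * (count_i / size_i) / sum_j (count_j / size_j)``.
    Taxa missing from the size table (undefined-species bins, higher-rank
    calls, novel species) are normalized with the database-wide mean genome
    size, with a warning.
    """
    if not profile.counts:
        profile.normalized = {}
        return profile
    sizes = dict(size_table)
    if any(s <= 0 for s in sizes.values()):
        raise ProfilerError("size table contains a non-positive genome size")
    default = sum(sizes.values()) / len(sizes) if sizes else 1.0
    # genus-level "undefined species" bins have no genome of their own and
    # silently take the mean size; warn only for genuinely missing species
    missing = [
        k for k in profile.counts if k not in sizes and UNDEFINED_SPECIES not in k
    ]
    if missing:
        warnings.warn(
            f"{len(missing)} taxa missing from size table; using database mean "
            f"genome size ({default:.0f} b) for: {', '.join(sorted(missing)[:5])}"
            + ("..." if len(missing) > 5 else ""),
            stacklevel=2,
        )
    weights = {k: v / sizes.get(k, default) for k, v in profile.counts.items()}
    z = sum(weights.values())
    profile.normalized = {k: 100.0 * w / z for k, w in weights.items()}
    return profile


def profile_to_frame(profile: Profile) -> pd.DataFrame:
    """Tidy per-taxon table: taxon, count, relative %, normalized %."""
    rows = [
        {
            "taxon": k,
            "count": profile.counts[k],
            "relative_pct": profile.relative.get(k, 0.0),
            "normalized_pct": profile.normalized.get(k, float("nan")),
        }
        for k in sorted(profile.counts, key=lambda k: -profile.counts[k])
    ]
    return pd.DataFrame(rows, columns=["taxon", "count", "relative_pct", "normalized_pct"])
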