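"""End-to-end glue: wire a curated database, a taxonomy and an aligner
into the read- and contig-level pipelines."""

from __future__ import annotations

from typing import Mapping, Sequence

from .align import SeedExtendAligner
from .readprofiler import (
    ClassifierParams,
    Profile,
    Read,
    ReadClassification,
    SubjectLabel,
    aggregate_profile,
    classify_reads,
    normalize_by_genome_size,
    quality_filter,
    subsample,
)
from .refdb import ReferenceDB
from .taxonomy import TaxonomyTree, TaxonomyNode

ROOT_TAXID = "1"

_KINGDOM_NAMES = {
    "viral": "Viruses",
    "prokaryotic": "Prokaryotes",
    "eukaryotic": "Eukaryota",
}


def taxonomy_from_db(db: ReferenceDB) -> tuple[TaxonomyTree, dict[str, SubjectLabel]]:
    """Derive a minimal taxonomy and per-accession labels from database metadata.

    The tree has root → superkingdom (one per kingdom present) → genus →
    species; intermediate ranks are omitted, which the taxonomy contract
    permits.  Taxids are synthesized deterministically from names.
    """
    nodes: dict[str, TaxonomyNode] = {
        ROOT_TAXID: TaxonomyNode(ROOT_TAXID, "root", "root", ROOT_TAXID)
    }
    labels: dict[str, SubjectLabel] = {}

    def ensure(taxid: str, name: str, rank: str, parent: str) -> str:
        if taxid not in nodes:
            nodes[taxid] = TaxonomyNode(taxid, name, rank, parent)
        return taxid

    for acc in sorted(db.genomes):
        g = db.genomes[acc]
        lab = db.labels[acc]
        king_id = ensure(f"k:{g.kingdom}", _KINGDOM_NAMES[g.kingdom], "superkingdom", ROOT_TAXID)
        genus_id = ensure(f"g:{lab.genus}", lab.genus, "genus", king_id)
        species_id = ensure(f"s:{lab.species}", lab.species, "species", genus_id)
        labels[acc] = SubjectLabel(
            genus=lab.genus, species=lab.species, taxid=species_id, kingdom=g.kingdom
        )
    return TaxonomyTree(nodes.values()), labels


def aligner_from_db(db: ReferenceDB, k: int = 21, **kwargs) -> SeedExtendAligner:
    refs = [
        (acc, cid, seq)
        for acc in sorted(db.genomes)
        for cid, seq in db.genomes[acc].contigs
    ]
    return SeedExtendAligner(refs, k=k, **kwargs)


def profile_sample(
    reads: Sequence[Read],
    db: ReferenceDB,
    params: ClassifierParams = ClassifierParams(),
    seed: int = 0,
    aligner: SeedExtendAligner | None = None,
    apply_qc: bool = True,
    normalize: bool = True,
) -> tuple[Profile, list[ReadClassification]]:
    """QC → subsample → classify → aggregate (→ genome-size normalize)."""
    if apply_qc:
        reads, _stats = quality_filter(reads)
    if len(reads) > params.sample_size:
        reads = subsample(reads, n=params.sample_size, seed=seed)
    tree, labels = taxonomy_from_db(db)
    if aligner is None:
        aligner = aligner_from_db(db)
    classifications = classify_reads(reads, aligner, tree, labels, params)
    profile = aggregate_profile(classifications, tree)
    if normalize and profile.counts:
        normalize_by_genome_size(profile, db.size_table)
    return profile, classifications
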