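"""Curated reference-database construction.

Public genome repositories accumulate species-level misclassifications, and
homology-based profilers inherit them.  This module builds a taxonomically
revised, dereplicated reference set from declared genome metadata plus a
precomputed ANI (average nucleotide identity) table:

1. **Taxonomic revision** — a genome is relabelled to its closest NCBI-style
   *reference genome* when ANI exceeds the species threshold (default 94%)
   with both query and subject coverage above 70%; otherwise its declared
   taxonomy is retained when the closest reference shares the declared
   genus (the species likely lacks a reference yet), and flagged
   unresolved when it does not.
2. **Dereplication** — genomes with ANI above 99% to their own species'
   reference genome are redundant and dropped.
3. **Contig length floors** — contigs shorter than 1 / 5 / 12 kbp are
   removed from viral / prokaryotic / eukaryotic genomes respectively.
4. **Host decontamination** — contigs aligning strongly to configured host
   genomes (identity >= 90% over >= 50% of the contig by default) are
   removed as alien DNA.

A per-species mean genome length table is derived from the curated set and
later drives genome-size normalization of read profiles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentHit

KINGDOMS = ("viral", "prokaryotic", "eukaryotic")

#: change_log reason codes
REASON_RECLASSIFIED = "ani_reclassified"
REASON_GENUS_RETAINED = "genus_retained"
REASON_UNRESOLVED = "unresolved"


class CurationError(ValueError):
    """Inconsistent curation inputs (unknown accessions, bad thresholds)."""


@dataclass(frozen=True)
class GenomeRecord:
    accession: str
    declared_species: str
    declared_genus: str
    kingdom: str
    is_reference: bool
    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise CurationError(
                f"{self.accession}: kingdom {self.kingdom!r} not in {KINGDOMS}"
            )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _cid, seq in self.contigs)


@dataclass(frozen=True)
class ANIRecord:
    query: str
    subject: str
    ani: float
    query_cov: float
    subject_cov: float

    def __post_init__(self) -> None:
        for name in ("ani", "query_cov", "subject_cov"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise CurationError(f"{self.query}->{self.subject}: {name}={v} outside [0,100]")


@dataclass(frozen=True)
class CurationParams:
    ani_species_threshold: float = 94.0
    min_ani_coverage: float = 70.0
    derep_threshold: float = 99.0
    min_contig_length: Mapping[str, int] = field(
        default_factory=lambda: {"viral": 1_000, "prokaryotic": 5_000, "eukaryotic": 12_000}
    )
    host_identity_min: float = 90.0
    host_coverage_min: float = 50.0

    def __post_init__(self) -> None:
        for name in ("ani_species_threshold", "min_ani_coverage", "derep_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 100.0:
                raise CurationError(f"{name}={v} outside (0,100]")
        if self.derep_threshold < self.ani_species_threshold:
            raise CurationError("derep_threshold must be >= ani_species_threshold")


@dataclass(frozen=True)
class Label:
    genus: str
    species: str
    taxid: str | None = None


@dataclass(frozen=True)
class ChangeLogEntry:
    accession: str
    old_label: str
    new_label: str
    reason: str


@dataclass
class ReferenceDB:
    """Curated genome set: sequences, labels, size table and audit trail."""

    genomes: dict[str, GenomeRecord]
    labels: dict[str, Label]
    size_table: dict[str, float]
    change_log: list[ChangeLogEntry]

    def species(self) -> set[str]:
        return {lab.species for lab in self.labels.values() if lab.species}


# ---------------------------------------------------------------------------
# Taxonomic revision


def _closest_reference(
    records: Sequence[ANIRecord],
) -> ANIRecord | None:
    """Best ANI record: highest ANI, ties by higher min coverage, then accession."""
    if not records:
        return None
    return min(
        records,
        key=lambda r: (-r.ani, -min(r.query_cov, r.subject_cov), r.subject),
    )


def revise_taxonomy(
    genomes: Mapping[str, GenomeRecord],
    ani: Sequence[ANIRecord],
    params: CurationParams = CurationParams(),
) -> tuple[dict[str, Label], list[ChangeLogEntry]]:
    """Relabel genomes to their closest reference genome where ANI supports it.

    Reference genomes always keep their declared labels.  Every
    non-reference genome receives one change-log entry stating the outcome:
    ``ani_reclassified`` (gate passed, label adopted from the reference),
    ``genus_retained`` (gate failed but the closest reference shares the
    declared genus) or ``unresolved`` (no ANI evidence, or the closest
    reference belongs to a different genus).
    """
    known = set(genomes)
    for rec in ani:
        if rec.query not in known or rec.subject not in known:
            raise CurationError(
                f"ANI record cites unknown accession: {rec.query!r} -> {rec.subject!r}"
            )
    references = {acc for acc, g in genomes.items() if g.is_reference}
    by_query: dict[str, list[ANIRecord]] = {}
    for rec in ani:
        if rec.subject in references:
            by_query.setdefault(rec.query, []).append(rec)

    labels: dict[str, Label] = {}
    change_log: list[ChangeLogEntry] = []
    for acc in sorted(genomes):
        g = genomes[acc]
        declared = Label(genus=g.declared_genus, species=g.declared_species)
        if g.is_reference:
            labels[acc] = declared
            continue
        closest = _closest_reference(by_query.get(acc, []))
        if (
            closest is not None
            and closest.ani > params.ani_species_threshold
            and closest.query_cov > params.min_ani_coverage
            and closest.subject_cov > params.min_ani_coverage
        ):
            ref = genomes[closest.subject]
            new = Label(genus=ref.declared_genus, species=ref.declared_species)
            labels[acc] = new
            change_log.append(
                ChangeLogEntry(acc, declared.species, new.species, REASON_RECLASSIFIED)
            )
        elif closest is not None and genomes[closest.subject].declared_genus == g.declared_genus:
            labels[acc] = declared
            change_log.append(
                ChangeLogEntry(acc, declared.species, declared.species, REASON_GENUS_RETAINED)
            )
        else:
            labels[acc] = declared
            change_log.append(
                ChangeLogEntry(acc, declared.species, declared.species, REASON_UNRESOLVED)
            )
    return labels, change_log


# ---------------------------------------------------------------------------
# Dereplication


def dereplicate(
    genomes: Mapping[str, GenomeRecord],
    labels: Mapping[str, Label],
    ani: Sequence[ANIRecord],
    params: CurationParams = CurationParams(),
) -> set[str]:
    """Drop non-reference genomes nearly identical to their species reference.

    A genome is removed iff its ANI to its own (revised) species' reference
    genome exceeds ``derep_threshold``.  Genomes whose species has no
    reference genome are always retained, as are all reference genomes.
    """
    species_reference: dict[str, str] = {}
    for acc in sorted(genomes):
        if genomes[acc].is_reference:
            species_reference.setdefault(labels[acc].species, acc)
    pair_ani: dict[tuple[str, str], float] = {}
    for rec in ani:
        pair_ani[(rec.query, rec.subject)] = rec.ani
        pair_ani.setdefault((rec.subject, rec.query), rec.ani)
    retained = set()
    for acc, g in genomes.items():
        if g.is_reference:
            retained.add(acc)
            continue
        ref = species_reference.get(labels[acc].species)
        if ref is None or ref == acc:
            retained.add(acc)
            continue
        value = pair_ani.get((acc, ref))
        if value is None or value <= params.derep_threshold:
            retained.add(acc)
    return retained


# ---------------------------------------------------------------------------
# Contig filters


def filter_contigs_by_length(
    genome: GenomeRecord, params: CurationParams = CurationParams()
) -> GenomeRecord | None:
    """Remove contigs below the kingdom-specific length floor.

    Returns ``None`` when no contig survives (the genome leaves the
    database).  The floor is strict on "shorter than": a contig exactly at
    the floor is kept.
    """
    floor = params.min_contig_length[genome.kingdom]
    kept = tuple((cid, seq) for cid, seq in genome.contigs if len(seq) >= floor)
    if not kept:
        return None
    return replace(genome, contigs=kept)


def remove_host_contigs(
    genome: GenomeRecord,
    host_hits: Sequence[AlignmentHit],
    params: CurationParams = CurationParams(),
) -> GenomeRecord | None:
    """Drop contigs with strong similarity to configured host genomes.

    ``host_hits`` are alignments with the genome's contigs as *queries*
    against a host genome set; a contig is removed iff some hit reaches
    ``host_identity_min`` identity covering ``host_coverage_min`` percent of
    the contig.  Returns ``None`` if no contig survives.
    """
    contig_ids = {cid for cid, _seq in genome.contigs}
    flagged: set[str] = set()
    for hit in host_hits:
        if hit.query_id not in contig_ids:
            raise CurationError(
                f"{genome.accession}: host hit cites unknown contig {hit.query_id!r}"
            )
        if (
            hit.percent_identity >= params.host_identity_min
            and hit.query_cov >= params.host_coverage_min
        ):
            flagged.add(hit.query_id)
    kept = tuple((cid, seq) for cid, seq in genome.contigs if cid not in flagged)
    if not kept:
        return None
    return replace(genome, contigs=kept)


# ---------------------------------------------------------------------------
# Size table and assembly of the full database


def build_size_table(
    genomes: Mapping[str, GenomeRecord], labels: Mapping[str, Label]
) -> dict[str, float]:
    """Mean total genome length per (revised) species over retained genomes."""
    sums: dict[str, list[int]] = {}
    for acc, g in genomes.items():
        sums.setdefault(labels[acc].species, []).append(g.total_length)
    return {sp: sum(v) / len(v) for sp, v in sums.items()}


def curate(
    genomes: Mapping[str, GenomeRecord],
    ani: Sequence[ANIRecord],
    params: CurationParams = CurationParams(),
    host_hits: Mapping[str, Sequence[AlignmentHit]] | None = None,
) -> ReferenceDB:
    """Full curation pipeline: length filter, host removal, revision, dereplication.

    Length filtering runs first so ANI-based decisions apply to the
    sequences that will actually enter the database; host hits are keyed by
    genome accession.
    """
    filtered: dict[str, GenomeRecord] = {}
    for acc, g in genomes.items():
        fg = filter_contigs_by_length(g, params)
        if fg is None:
            continue
        if host_hits and acc in host_hits:
            fg = remove_host_contigs(fg, host_hits[acc], params)
            if fg is None:
                continue
        filtered[acc] = fg
    usable_ani = [r for r in ani if r.query in filtered and r.subject in filtered]
    labels, change_log = revise_taxonomy(filtered, usable_ani, params)
    retained = dereplicate(filtered, labels, usable_ani, params)
    final = {acc: filtered[acc] for acc in sorted(retained)}
    final_labels = {acc: labels[acc] for acc in final}
    size_table = build_size_table(final, final_labels)
    return ReferenceDB(
        genomes=final, labels=final_labels, size_table=size_table, change_log=change_log
    )


# ---------------------------------------------------------------------------
# On-disk format


def write_database(db: ReferenceDB, path) -> None:
    """Write a curated database as FASTA + labels/size/change-log TSVs."""
    os.makedirs(path, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=f"{acc}|{cid}", description="")
        for acc in sorted(db.genomes)
        for cid, seq in db.genomes[acc].contigs
    ]
    SeqIO.write(records, os.path.join(path, "genomes.fasta"), "fasta")
    meta = pd.DataFrame(
        [
            {
                "accession": acc,
                "species": db.labels[acc].species,
                "genus": db.labels[acc].genus,
                "taxid": db.labels[acc].taxid or "",
                "kingdom": db.genomes[acc].kingdom,
                "is_reference": int(db.genomes[acc].is_reference),
                "declared_species": db.genomes[acc].declared_species,
                "declared_genus": db.genomes[acc].declared_genus,
            }
            for acc in sorted(db.genomes)
        ],
        columns=[
            "accession", "species", "genus", "taxid", "kingdom",
            "is_reference", "declared_species", "declared_genus",
        ],
    )
    meta.to_csv(os.path.join(path, "labels.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(db.size_table.items()), columns=["species", "mean_genome_length"]
    ).to_csv(os.path.join(path, "size_table.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"accession": e.accession, "old_label": e.old_label,
             "new_label": e.new_label, "reason": e.reason}
            for e in db.change_log
        ],
        columns=["accession", "old_label", "new_label", "reason"],
    ).to_csv(os.path.join(path, "change_log.tsv"), sep="\t", index=False)


def read_database(path) -> ReferenceDB:
    """Read back a database written by :func:`write_database`."""
    contigs_by_acc: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(os.path.join(path, "genomes.fasta"), "fasta"):
        if "|" not in rec.id:
            raise CurationError(f"FASTA header {rec.id!r} lacks 'accession|contig' form")
        acc, cid = rec.id.split("|", 1)
        contigs_by_acc.setdefault(acc, []).append((cid, str(rec.seq)))
    meta = pd.read_csv(os.path.join(path, "labels.tsv"), sep="\t", dtype=str).fillna("")
    genomes: dict[str, GenomeRecord] = {}
    labels: dict[str, Label] = {}
    for row in meta.to_dict("records"):
        acc = row["accession"]
        genomes[acc] = GenomeRecord(
            accession=acc,
            declared_species=row["declared_species"],
            declared_genus=row["declared_genus"],
            kingdom=row["kingdom"],
            is_reference=bool(int(row["is_reference"])),
            contigs=tuple(contigs_by_acc.get(acc, ())),
        )
        labels[acc] = Label(
            genus=row["genus"], species=row["species"], taxid=row["taxid"] or None
        )
    sizes = pd.read_csv(os.path.join(path, "size_table.tsv"), sep="\t")
    size_table = dict(zip(sizes["species"], sizes["mean_genome_length"].astype(float)))
    log_df = pd.read_csv(os.path.join(path, "change_log.tsv"), sep="\t", dtype=str)
    change_log = [
        ChangeLogEntry(r["accession"], r["old_label"], r["new_label"], r["reason"])
        for r in log_df.to_dict("records")
    ]
    return ReferenceDB(genomes=genomes, labels=labels, size_table=size_table, change_log=change_log)


def read_genomes_fasta(fasta_path, meta_path) -> dict[str, GenomeRecord]:
    """Load raw (pre-curation) genomes: FASTA with ``accession|contig`` headers
    plus a metadata TSV (accession, species, genus, kingdom, is_reference)."""
    contigs_by_acc: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if "|" in rec.id:
            acc, cid = rec.id.split("|", 1)
        else:
            acc = cid = rec.id
        contigs_by_acc.setdefault(acc, []).append((cid, str(rec.seq)))
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    genomes = {}
    for row in meta.to_dict("records"):
        acc = row["accession"]
        genomes[acc] = GenomeRecord(
            accession=acc,
            declared_species=row["species"],
            declared_genus=row["genus"],
            kingdom=row["kingdom"],
            is_reference=bool(int(row["is_reference"])),
            contigs=tuple(contigs_by_acc.get(acc, ())),
        )
    return genomes


def read_ani_table(path) -> list[ANIRecord]:
    """ANI table TSV: query, subject, ani, query_cov, subject_cov."""
    df = pd.read_csv(path, sep="\t")
    return [
        ANIRecord(
            query=str(r["query"]),
            subject=str(r["subject"]),
            ani=float(r["ani"]),
            query_cov=float(r["query_cov"]),
            subject_cov=float(r["subject_cov"]),
        )
        for r in df.to_dict("records")
    ]
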