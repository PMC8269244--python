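"""Assembly-side analysis: contig classification, per-species pooling,
ORF calling and GenBank emission.

Assembled contigs longer than 5 kbp are taxonomically classified with the
same best-hit / LCA rules used for reads; the query-coverage gate is
replaced by a minimum hit span (a long contig rarely aligns end-to-end to
a draft reference).  Contigs sharing a taxon are pooled, genes are
predicted with a minimal six-frame ORF caller, and each pool is written as
one GenBank flat file — one LOCUS per contig with CDS features — ready for
genome browsers.

The ORF caller is deliberately simple (maximal ATG→stop open reading
frames on six frames); it delivers the GenBank structure, not
production-grade annotation.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .align import AlignmentHit, reverse_complement
from .readprofiler import ClassifierParams, ReadClassification, SubjectLabel, classify_read
from .taxonomy import TaxonomyTree

_STOPS = ("TAA", "TAG", "TGA")


class ContigError(ValueError):
    pass


@dataclass(frozen=True)
class ContigClassification:
    contig_id: str
    length: int
    taxid: str | None
    assigned_rank: str  # species | genus | higher | unclassified | too_short
    best_identity: float
    taxon_name: str | None = None


@dataclass(frozen=True)
class GeneFeature:
    contig_id: str
    start: int  # 1-based inclusive, on the plus strand
    end: int
    strand: str
    frame: int
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3:
            raise ContigError(
                f"{self.contig_id}:{self.start}-{self.end}: ORF length not divisible by 3"
            )


# ---------------------------------------------------------------------------
# Classification


def classify_contigs(
    contigs: Mapping[str, str],
    hits_by_contig: Mapping[str, Sequence[AlignmentHit]],
    tree: TaxonomyTree,
    labels: Mapping[str, SubjectLabel],
    params: ClassifierParams = ClassifierParams(),
    contig_min_length: int = 5_000,
    min_hit_span: int = 1_000,
) -> list[ContigClassification]:
    """Classify contigs with the read rules (coverage gate replaced by span).

    Contigs at or below ``contig_min_length`` are reported ``too_short``.
    Hits shorter than ``min_hit_span`` are discarded; survivors feed the
    same best-hit / LCA / identity-cutoff logic as read classification.
    """
    results = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        if len(seq) <= contig_min_length:
            results.append(ContigClassification(cid, len(seq), None, "too_short", 0.0))
            continue
        hits = [
            h
            for h in hits_by_contig.get(cid, ())
            if h.align_length >= min_hit_span and h.evalue <= params.evalue_max
        ]
        hits = sorted(
            hits, key=lambda h: (-h.bit_score, -h.percent_identity, h.subject_accession)
        )[: params.max_hits]
        rc: ReadClassification = classify_read(hits, tree, labels, params, read_id=cid)
        results.append(
            ContigClassification(
                cid, len(seq), rc.taxid, rc.assigned_rank, rc.best_identity, rc.taxon_name
            )
        )
    return results


def classified_length_fraction(
    contigs: Mapping[str, str], classifications: Sequence[ContigClassification]
) -> float:
    """Percent of total contig length (above the size floor) that was classified."""
    eligible = [c for c in classifications if c.assigned_rank != "too_short"]
    total = sum(c.length for c in eligible)
    classified = sum(c.length for c in eligible if c.assigned_rank != "unclassified")
    return 100.0 * classified / total if total else 0.0


def bin_by_taxon(
    contigs: Mapping[str, str], classifications: Sequence[ContigClassification]
) -> dict[str, dict[str, str]]:
    """Partition classified contigs by assigned taxon.

    Keys are taxon names (or taxids when unnamed); unclassified contigs
    pool under ``"unclassified"``; too-short contigs are excluded.
    """
    pools: dict[str, dict[str, str]] = {}
    for c in classifications:
        if c.assigned_rank == "too_short":
            continue
        if c.assigned_rank == "unclassified" or c.taxid is None:
            key = "unclassified"
        else:
            key = c.taxon_name or c.taxid
        pools.setdefault(key, {})[c.contig_id] = contigs[c.contig_id]
    return pools


# ---------------------------------------------------------------------------
# ORF calling


def _orfs_in_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """Maximal ATG→stop ORFs in one forward frame; 0-based [start, end)."""
    orfs = []
    start_candidate = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if start_candidate is not None:
                orfs.append((start_candidate, pos + 3))
                start_candidate = None
        elif codon == "ATG" and start_candidate is None:
            start_candidate = pos
    return orfs


def call_orfs(sequence: str, min_orf_nt: int = 300, contig_id: str = "contig") -> list[GeneFeature]:
    """All maximal ATG→stop open reading frames >= ``min_orf_nt`` on six frames.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next stop (inclusive).  Reverse-strand ORFs are reported in plus-strand
    coordinates with ``strand='-'``.  Ambiguous bases never form a start or
    stop codon, so poly-N stretches yield nothing.
    """
    seq = sequence.upper()
    n = len(seq)
    features = []
    for frame in range(3):
        for s, e in _orfs_in_frame(seq, frame):
            if e - s >= min_orf_nt:
                features.append(GeneFeature(contig_id, s + 1, e, "+", frame))
    rc = reverse_complement(seq)
    for frame in range(3):
        for s, e in _orfs_in_frame(rc, frame):
            if e - s >= min_orf_nt:
                features.append(GeneFeature(contig_id, n - e + 1, n - s, "-", frame))
    features.sort(key=lambda f: (f.start, f.end, f.strand))
    return features


# ---------------------------------------------------------------------------
# GenBank emission


def _locus_name(contig_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", contig_id)[:20]


def write_genbank(
    pool: Mapping[str, str],
    features: Sequence[GeneFeature],
    path,
    organism: str = "unclassified organism",
    lineage: Sequence[str] = (),
) -> str | None:
    """Write one taxon pool as a GenBank flat file (one LOCUS per contig).

    Features must reference contigs in the pool and lie within bounds.
    Returns the path written, or ``None`` for an empty pool.
    """
    if not pool:
        return None
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        if f.contig_id not in pool:
            raise ContigError(f"feature references unknown contig {f.contig_id!r}")
        if f.start < 1 or f.end > len(pool[f.contig_id]):
            raise ContigError(
                f"feature {f.contig_id}:{f.start}-{f.end} outside contig bounds"
            )
        by_contig.setdefault(f.contig_id, []).append(f)
    records = []
    for cid in sorted(pool):
        rec = SeqRecord(
            Seq(pool[cid]),
            id=cid,
            name=_locus_name(cid),
            description=f"{organism} metagenomic contig",
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["organism"] = organism
        rec.annotations["taxonomy"] = list(lineage)
        for f in by_contig.get(cid, []):
            loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1)
            rec.features.append(
                SeqFeature(loc, type="CDS", qualifiers={"product": [f.product]})
            )
        records.append(rec)
    SeqIO.write(records, path, "genbank")
    return str(path)


def write_pools(
    pools: Mapping[str, Mapping[str, str]],
    out_dir,
    tree: TaxonomyTree | None = None,
    taxids: Mapping[str, str] | None = None,
    min_orf_nt: int = 300,
) -> dict[str, str]:
    """Call ORFs and write one GenBank file per taxon pool."""
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for taxon, pool in pools.items():
        features = [
            f
            for cid, seq in sorted(pool.items())
            for f in call_orfs(seq, min_orf_nt=min_orf_nt, contig_id=cid)
        ]
        lineage: list[str] = []
        if tree is not None and taxids and taxon in taxids and taxids[taxon] in tree:
            lineage = [name for _r, name, _t in tree.lineage(taxids[taxon])[1:]]
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", taxon)
        path = os.path.join(out_dir, f"{safe}.gbk")
        if write_genbank(pool, features, path, organism=taxon, lineage=lineage):
            written[taxon] = path
    return written


def classifications_to_frame(classifications: Sequence[ContigClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "length": c.length,
                "taxid": c.taxid or "",
                "assigned_rank": c.assigned_rank,
                "best_identity": c.best_identity,
                "taxon": c.taxon_name or "",
            }
            for c in classifications
        ],
        columns=["contig_id", "length", "taxid", "assigned_rank", "best_identity", "taxon"],
    )
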