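"""Read-level functional profiling against labeled reference sequences.

Reads are aligned to a functional reference set — carbohydrate-active
enzyme (CAZy-style GH/GT/PL/CE/CBM) families and/or pathway-annotated
enzymes — and each read increments the family of its best passing hit.
Pathway counts roll up non-exclusively: a read whose best-hit reference
participates in several pathways counts once for each.

The functional gates are configured separately from the taxonomic ones;
the coverage gate defaults to 50% because reads frequently span domain or
gene boundaries in functional references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .align import AlignmentHit


class FunctionError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledReference:
    """One functional reference sequence with its family and pathway labels."""

    seq_id: str
    sequence: str
    family: str
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.family:
            raise FunctionError(f"{self.seq_id}: empty family label")


@dataclass(frozen=True)
class FunctionParams:
    evalue_max: float = 1e-5
    min_query_cov: float = 50.0


@dataclass
class FunctionProfile:
    family_counts: dict[str, int]
    family_relative: dict[str, float]
    pathway_counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    best_refs: dict[str, str] = field(default_factory=dict)  # read_id -> seq_id

    @property
    def assigned(self) -> int:
        return sum(self.family_counts.values())


def read_labeled_fasta(path) -> dict[str, LabeledReference]:
    """Parse functional references from FASTA with ``>seq_id|family|pw1,pw2``
    headers (the pathway field is optional)."""
    refs = {}
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise FunctionError(f"header {rec.id!r} lacks '|family' label")
        seq_id, family = parts[0], parts[1]
        pathways = tuple(p for p in parts[2].split(",") if p) if len(parts) > 2 else ()
        refs[seq_id] = LabeledReference(seq_id, str(rec.seq), family, pathways)
    return refs


def write_labeled_fasta(refs: Iterable[LabeledReference], path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            header = f"{r.seq_id}|{r.family}"
            if r.pathways:
                header += "|" + ",".join(r.pathways)
            fh.write(f">{header}\n{r.sequence}\n")


def _best_hit(
    hits: Sequence[AlignmentHit],
    refs: Mapping[str, LabeledReference],
    params: FunctionParams,
) -> AlignmentHit | None:
    passing = [
        h for h in hits if h.evalue <= params.evalue_max and h.query_cov >= params.min_query_cov
    ]
    if not passing:
        return None
    for h in passing:
        if h.subject_accession not in refs:
            raise FunctionError(f"hit to unknown reference {h.subject_accession!r}")
    # best bit score; ties broken by the lexicographically smallest family
    return min(
        passing,
        key=lambda h: (-h.bit_score, refs[h.subject_accession].family, h.subject_accession),
    )


def profile_families(
    hits_by_read: Mapping[str, Sequence[AlignmentHit]],
    refs: Mapping[str, LabeledReference],
    params: FunctionParams = FunctionParams(),
) -> FunctionProfile:
    """Count each read toward the family of its best passing hit."""
    family_counts: dict[str, int] = {}
    best_refs: dict[str, str] = {}
    unassigned = 0
    for read_id in sorted(hits_by_read):
        best = _best_hit(hits_by_read[read_id], refs, params)
        if best is None:
            unassigned += 1
            continue
        family = refs[best.subject_accession].family
        family_counts[family] = family_counts.get(family, 0) + 1
        best_refs[read_id] = best.subject_accession
    total = sum(family_counts.values())
    family_relative = (
        {f: 100.0 * c / total for f, c in family_counts.items()} if total else {}
    )
    profile = FunctionProfile(
        family_counts=family_counts,
        family_relative=family_relative,
        unassigned=unassigned,
        best_refs=best_refs,
    )
    profile.pathway_counts = rollup_pathways(profile, refs)
    return profile


def rollup_pathways(
    profile: FunctionProfile, refs: Mapping[str, LabeledReference]
) -> dict[str, int]:
    """Non-exclusive pathway counts: each assigned read increments every
    pathway listed on its best-hit reference."""
    counts: dict[str, int] = {}
    for _read_id, seq_id in profile.best_refs.items():
        for pw in refs[seq_id].pathways:
            counts[pw] = counts.get(pw, 0) + 1
    return counts


def family_frame(profile: FunctionProfile) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"family": f, "count": c, "relative_pct": profile.family_relative[f]}
            for f, c in sorted(profile.family_counts.items(), key=lambda kv: -kv[1])
        ],
        columns=["family", "count", "relative_pct"],
    )


def pathway_frame(profile: FunctionProfile) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(profile.pathway_counts.items(), key=lambda kv: -kv[1]),
        columns=["pathway", "count"],
    )
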