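"""Synthetic genomes, read sets and ANI fixtures with ground truth.

Artificial data sets with known taxonomic composition are the test bed for
the whole pipeline: random genomes at chosen lengths and GC content,
Illumina-style 150-bp paired-end reads with a uniform substitution error
rate (default 0.02), and Nanopore-like fixed-length long reads (default
8 kbp) with a mixed substitution/insertion/deletion error rate (default
0.003).  Every emitted read carries a truth-manifest row (source species,
genome, coordinates, strand), and the manifest's expected profile is the
per-species read fraction.

The short-read error model is substitution-only — adequate for an
Illumina-like instrument and for exercising identity cutoffs; the long-read
model splits errors evenly between substitutions, insertions and deletions,
the indel-dominated regime of nanopore sequencing.  Quality strings are a
constant Q30: truth is carried by the manifest, not by qualities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .readprofiler import Read

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_Q30 = chr(30 + 33)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    """One synthetic species: genome size, GC content and read abundance."""

    name: str
    genome_length: int
    gc: float = 0.5
    reads: int = 0
    genus: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise SimulationError(f"{self.name}: gc {self.gc} outside [0,1]")
        if self.reads < 0:
            raise SimulationError(f"{self.name}: negative read count")


@dataclass(frozen=True)
class SimSpec:
    species: tuple[SpeciesSpec, ...]
    read_length: int = 150
    base_error_rate: float = 0.02
    long_read_length: int = 8_000
    long_read_error_rate: float = 0.003
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.base_error_rate, self.long_read_error_rate):
            if not 0.0 <= rate < 1.0:
                raise SimulationError(f"error rate {rate} outside [0,1)")
        if not self.species:
            raise SimulationError("at least one species required")


@dataclass
class TruthManifest:
    """Per-read ground truth plus the expected relative-abundance profile."""

    rows: pd.DataFrame  # read_id, species, genome, start, end, strand
    expected_profile: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.expected_profile and len(self.rows):
            counts = self.rows["species"].value_counts()
            total = counts.sum()
            self.expected_profile = {
                sp: 100.0 * n / total for sp, n in counts.items()
            }

    def reads_per_species(self) -> dict[str, int]:
        return self.rows["species"].value_counts().to_dict()


def even_spec(
    n_species: int,
    total_reads: int,
    genome_length: int = 100_000,
    gc: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> SimSpec:
    """Even-abundance design: ``n_species`` species splitting ``total_reads``
    equally (total must divide evenly)."""
    if total_reads % n_species:
        raise SimulationError("total_reads must divide evenly across species")
    per = total_reads // n_species
    species = tuple(
        SpeciesSpec(
            name=f"Species_{i:04d}",
            genome_length=genome_length,
            gc=gc,
            reads=per,
            genus=f"Genus_{i:04d}",
        )
        for i in range(n_species)
    )
    return SimSpec(species=species, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Genomes


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random i.i.d. genome with P(G) + P(C) = ``gc``; deterministic per seed."""
    if length < 1_000:
        raise SimulationError("genome length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise SimulationError(f"gc {gc} outside [0,1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode()


def simulate_genomes(spec: SimSpec) -> dict[str, str]:
    """One genome per species, seeded independently from the spec seed."""
    root = np.random.default_rng(spec.seed)
    genomes = {}
    for sp in spec.species:
        sub = int(root.integers(0, 2**31 - 1))
        genomes[sp.name] = simulate_genome(sp.genome_length, sp.gc, seed=sub)
    return genomes


# ---------------------------------------------------------------------------
# Short paired-end reads

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _revcomp_rows(mat: np.ndarray) -> np.ndarray:
    return _COMP[mat[:, ::-1]]


def _apply_substitutions(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    # replace with a uniformly chosen *different* base: shift 1..3 in A<C<G<T order
    idx = np.searchsorted(_BASES, mat)
    shift = rng.integers(1, 4, size=mat.shape)
    new = _BASES[(idx + shift) % 4]
    return np.where(mask, new, mat)


def simulate_illumina(
    spec: SimSpec, genomes: dict[str, str] | None = None
) -> tuple[list[Read], list[Read], TruthManifest]:
    """Paired-end short reads with uniform substitution errors.

    Per species exactly ``reads`` manifest reads (= ``reads/2`` pairs,
    counts must be even) are drawn: fragment positions uniform over the
    genome, fragment strand equiprobable, mates read inward from the two
    fragment ends.  Insert sizes are Normal(``insert_mean``,
    ``insert_sd``), clipped to fit the read length and the genome.
    """
    if genomes is None:
        genomes = simulate_genomes(spec)
    rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length
    reads1: list[Read] = []
    reads2: list[Read] = []
    manifest_rows = []
    for sp in spec.species:
        if sp.reads == 0:
            continue
        if sp.reads % 2:
            raise SimulationError(f"{sp.name}: read count must be even (paired-end)")
        genome = genomes[sp.name]
        glen = len(genome)
        n_pairs = sp.reads // 2
        inserts = rng.normal(spec.insert_mean, spec.insert_sd, size=n_pairs)
        inserts = np.clip(np.rint(inserts).astype(np.int64), L, glen)
        if glen < max(2 * L, int(spec.insert_mean)):
            raise SimulationError(f"{sp.name}: genome shorter than the insert size")
        starts = rng.integers(0, glen - inserts + 1)
        flip = rng.random(n_pairs) < 0.5
        garr = np.frombuffer(genome.encode(), dtype=np.uint8)
        window = np.arange(L)
        r1 = garr[starts[:, None] + window]
        r2 = garr[(starts + inserts - L)[:, None] + window]
        r2 = _revcomp_rows(r2)
        # flipping the fragment strand swaps which end yields mate 1;
        # each end is already oriented (r1 plus-strand, r2 minus-strand)
        r1o = np.where(flip[:, None], r2, r1)
        r2o = np.where(flip[:, None], r1, r2)
        r1e = _apply_substitutions(r1o, spec.base_error_rate, rng)
        r2e = _apply_substitutions(r2o, spec.base_error_rate, rng)
        qual = _Q30 * L
        for i in range(n_pairs):
            rid = f"{sp.name}:{i}"
            reads1.append(Read(f"{rid}/1", r1e[i].tobytes().decode(), qual))
            reads2.append(Read(f"{rid}/2", r2e[i].tobytes().decode(), qual))
            s, ins = int(starts[i]), int(inserts[i])
            strand1, strand2 = ("-", "+") if flip[i] else ("+", "-")
            e1 = (s, s + L) if not flip[i] else (s + ins - L, s + ins)
            e2 = (s + ins - L, s + ins) if not flip[i] else (s, s + L)
            manifest_rows.append(
                (f"{rid}/1", sp.name, sp.name, e1[0] + 1, e1[1], strand1)
            )
            manifest_rows.append(
                (f"{rid}/2", sp.name, sp.name, e2[0] + 1, e2[1], strand2)
            )
    rows = pd.DataFrame(
        manifest_rows, columns=["read_id", "species", "genome", "start", "end", "strand"]
    )
    return reads1, reads2, TruthManifest(rows=rows)


# ---------------------------------------------------------------------------
# Long reads


def _apply_long_errors(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base error events split evenly: substitution / insertion / deletion."""
    if rate <= 0:
        return seq
    events = rng.random(seq.shape[0])
    kind = rng.integers(0, 3, size=seq.shape[0])  # 0 sub, 1 ins, 2 del
    out = []
    for i, base in enumerate(seq):
        if events[i] >= rate:
            out.append(base)
            continue
        if kind[i] == 0:
            idx = int(np.searchsorted(_BASES, base))
            out.append(_BASES[(idx + int(rng.integers(1, 4))) % 4])
        elif kind[i] == 1:
            out.append(base)
            out.append(_BASES[int(rng.integers(0, 4))])
        # deletion: emit nothing
    return np.asarray(out, dtype=np.uint8)


def simulate_nanopore(
    spec: SimSpec, genomes: dict[str, str] | None = None
) -> tuple[list[Read], TruthManifest]:
    """Fixed-length long reads (default 8 kbp) with indel-inclusive errors.

    Per species ``reads`` single-end reads are drawn uniformly over
    positions and strands; error events occur per source base at
    ``long_read_error_rate``, a third each substitution, insertion,
    deletion, so emitted read lengths drift slightly around the nominal
    length.
    """
    if genomes is None:
        genomes = simulate_genomes(spec)
    rng = np.random.default_rng(spec.seed + 2)
    L = spec.long_read_length
    reads: list[Read] = []
    manifest_rows = []
    for sp in spec.species:
        if sp.reads == 0:
            continue
        genome = genomes[sp.name]
        if len(genome) < L:
            raise SimulationError(f"{sp.name}: genome shorter than the read length")
        garr = np.frombuffer(genome.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(genome) - L + 1, size=sp.reads)
        flips = rng.random(sp.reads) < 0.5
        for i in range(sp.reads):
            s = int(starts[i])
            frag = garr[s : s + L]
            strand = "+"
            if flips[i]:
                frag = _COMP[frag[::-1]]
                strand = "-"
            frag = _apply_long_errors(frag, spec.long_read_error_rate, rng)
            rid = f"{sp.name}:long:{i}"
            seq = frag.tobytes().decode()
            reads.append(Read(rid, seq, _Q30 * len(seq)))
            manifest_rows.append((rid, sp.name, sp.name, s + 1, s + L, strand))
    rows = pd.DataFrame(
        manifest_rows, columns=["read_id", "species", "genome", "start", "end", "strand"]
    )
    return reads, TruthManifest(rows=rows)


# ---------------------------------------------------------------------------
# ANI fixtures


def make_ani_fixture(
    accessions: Sequence[str],
    planted_relations: Sequence[tuple[str, str, float, float, float]],
    symmetric: bool = False,
) -> pd.DataFrame:
    """Fabricate an ANI table (query, subject, ani, query_cov, subject_cov).

    Stands in for a precomputed all-vs-reference ANI matrix; relations are
    planted by the test or simulation scenario.  Unknown accessions are
    rejected so fixtures stay consistent with their genome set.
    """
    known = set(accessions)
    rows = []
    for query, subject, ani, qcov, scov in planted_relations:
        if query not in known or subject not in known:
            raise SimulationError(f"ANI relation cites unknown accession {query!r}/{subject!r}")
        rows.append((query, subject, ani, qcov, scov))
        if symmetric:
            rows.append((subject, query, ani, scov, qcov))
    return pd.DataFrame(rows, columns=["query", "subject", "ani", "query_cov", "subject_cov"])


# ---------------------------------------------------------------------------
# On-disk emission


def write_manifest(manifest: TruthManifest, rows_path, profile_path=None) -> None:
    manifest.rows.to_csv(rows_path, sep="\t", index=False)
    if profile_path is not None:
        pd.DataFrame(
            sorted(manifest.expected_profile.items()),
            columns=["species", "expected_relative_pct"],
        ).to_csv(profile_path, sep="\t", index=False)


def write_spec(spec: SimSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2)


def read_spec(path) -> SimSpec:
    with open(path) as fh:
        d = json.load(fh)
    d["species"] = tuple(SpeciesSpec(**s) for s in d["species"])
    return SimSpec(**d)
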