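"""Shared fixtures: small taxonomies, genome sets and alignment helpers."""

from __future__ import annotations

import random

import pytest

from shallowmeta.refdb import GenomeRecord
from shallowmeta.taxonomy import RANKS, TaxonomyNode, TaxonomyTree


def make_linear_tree() -> TaxonomyTree:
    """One node per canonical rank, root to species."""
    nodes = []
    parent = "n0"
    for i, rank in enumerate(RANKS):
        taxid = f"n{i}"
        nodes.append(TaxonomyNode(taxid, f"{rank}_name", rank, parent))
        parent = taxid
    return TaxonomyTree(nodes)


@pytest.fixture
def linear_tree() -> TaxonomyTree:
    return make_linear_tree()


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """Two superkingdoms; bacteria-side genus with two species, a second
    genus, and a viral species."""
    nodes = [
        TaxonomyNode("1", "root", "root", "1"),
        TaxonomyNode("2", "Bacteria", "superkingdom", "1"),
        TaxonomyNode("10", "Viruses", "superkingdom", "1"),
        TaxonomyNode("20", "Lactobacillaceae", "family", "2"),
        TaxonomyNode("30", "Lactobacillus", "genus", "20"),
        TaxonomyNode("31", "Lactobacillus A", "species", "30"),
        TaxonomyNode("32", "Lactobacillus B", "species", "30"),
        TaxonomyNode("40", "Bifidobacterium", "genus", "20"),
        TaxonomyNode("41", "Bifidobacterium C", "species", "40"),
        TaxonomyNode("50", "Siphovirus", "genus", "10"),
        TaxonomyNode("51", "Phage X", "species", "50"),
        TaxonomyNode("52", "Phage Y", "species", "50"),
    ]
    return TaxonomyTree(nodes)


def make_random_tree(n_nodes: int = 500, seed: int = 11) -> TaxonomyTree:
    """Random tree whose ranks stay consistent with node depth."""
    rng = random.Random(seed)
    nodes = [TaxonomyNode("t0", "root", "root", "t0")]
    depths = {"t0": 0}
    for i in range(1, n_nodes):
        parent = f"t{rng.randrange(i)}"
        # pick a rank strictly deeper than the parent's rank
        parent_rank_idx = RANKS.index(nodes[int(parent[1:])].rank)
        if parent_rank_idx >= len(RANKS) - 1:
            parent = "t0"
            parent_rank_idx = 0
        rank = RANKS[rng.randrange(parent_rank_idx + 1, len(RANKS))]
        taxid = f"t{i}"
        nodes.append(TaxonomyNode(taxid, f"node{i}", rank, parent))
        depths[taxid] = depths[parent] + 1
    return TaxonomyTree(nodes)


def genome(accession, species, genus, kingdom="prokaryotic", is_reference=False, contigs=None):
    if contigs is None:
        contigs = (("c1", "ACGT" * 2_000),)  # 8 kb, above the prokaryotic floor
    return GenomeRecord(
        accession=accession,
        declared_species=species,
        declared_genus=genus,
        kingdom=kingdom,
        is_reference=is_reference,
        contigs=tuple(contigs),
    )


def random_seq(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def sw_score_oracle(q: str, s: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Independent full-DP Smith–Waterman score (pure-python recurrence)."""
    n, m = len(q), len(s)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        qi = q[i - 1]
        for j in range(1, m + 1):
            sub = match if qi == s[j - 1] else mismatch
            v = max(0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best
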