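"""In-memory taxonomy with lineage and least-common-ancestor (LCA) queries.

The classifier resolves reads with equal best hits to multiple species by
walking them up to their least common ancestor.  The taxonomy is a plain
rooted tree loaded from a flat node table (TSV with columns ``taxid``,
``parent_taxid``, ``rank``, ``name``); the root is its own parent.  Ranks
follow the canonical eight-level hierarchy, but intermediate ranks may be
missing (a species may hang directly under a family) — LCA operates on the
tree structure, not on rank names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Canonical ranks from the root down.  Gaps along a lineage are allowed.
RANKS = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Malformed node table or unknown taxid."""


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: str
    name: str
    rank: str
    parent: str

    def __post_init__(self) -> None:
        if self.rank not in _RANK_DEPTH:
            raise TaxonomyError(
                f"unknown rank {self.rank!r} for taxid {self.taxid!r}; "
                f"expected one of {', '.join(RANKS)}"
            )


class TaxonomyTree:
    """Rooted taxonomy supporting lineage extraction and LCA.

    Depths are precomputed at load time so that LCA of a pair is the
    classic walk-up in O(depth); set-LCA folds pairwise.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._index: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self._index:
                raise TaxonomyError(f"duplicate taxid {node.taxid!r}")
            self._index[node.taxid] = node
        roots = [n for n in self._index.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self._index.values():
            if node.parent not in self._index:
                raise TaxonomyError(
                    f"node {node.taxid!r} references missing parent {node.parent!r}"
                )
        self._depth: dict[str, int] = {self.root.taxid: 0}
        self._compute_depths()
        self._check_rank_order()

    def _compute_depths(self) -> None:
        for taxid in self._index:
            chain = []
            cursor = taxid
            while cursor not in self._depth:
                chain.append(cursor)
                cursor = self._index[cursor].parent
                if cursor in chain:
                    raise TaxonomyError(f"cycle detected at taxid {cursor!r}")
            base = self._depth[cursor]
            for offset, tid in enumerate(reversed(chain), start=1):
                self._depth[tid] = base + offset

    def _check_rank_order(self) -> None:
        for node in self._index.values():
            if node.taxid == self.root.taxid:
                continue
            parent = self._index[node.parent]
            if _RANK_DEPTH[node.rank] <= _RANK_DEPTH[parent.rank]:
                raise TaxonomyError(
                    f"rank {node.rank!r} of {node.taxid!r} does not descend from "
                    f"parent rank {parent.rank!r}"
                )

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._index

    def __getitem__(self, taxid: str) -> TaxonomyNode:
        try:
            return self._index[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid!r}") from None

    def nodes(self) -> Iterable[TaxonomyNode]:
        return self._index.values()

    def depth(self, taxid: str) -> int:
        self[taxid]
        return self._depth[taxid]

    def lineage(self, taxid: str) -> list[tuple[str, str, str]]:
        """Root-to-node path as ``(rank, name, taxid)`` triples."""
        node = self[taxid]
        path = [node]
        while node.taxid != self.root.taxid:
            node = self._index[node.parent]
            path.append(node)
        return [(n.rank, n.name, n.taxid) for n in reversed(path)]

    def lca(self, taxids: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input taxid."""
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("lca of an empty taxid set is undefined")
        current = taxids[0]
        self[current]
        for other in taxids[1:]:
            current = self._lca_pair(current, other)
        return current

    def _lca_pair(self, a: str, b: str) -> str:
        self[a], self[b]
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self._index[a].parent
            da -= 1
        while db > da:
            b = self._index[b].parent
            db -= 1
        while a != b:
            a = self._index[a].parent
            b = self._index[b].parent
        return a


def build_taxonomy(records: Sequence[Mapping[str, str]] | pd.DataFrame) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from tabular node rows.

    ``records`` may be a DataFrame or an iterable of mappings carrying
    ``taxid``, ``parent_taxid``, ``rank`` and ``name``.
    """
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict("records")
    else:
        rows = list(records)
    nodes = [
        TaxonomyNode(
            taxid=str(r["taxid"]),
            name=str(r["name"]),
            rank=str(r["rank"]),
            parent=str(r["parent_taxid"]),
        )
        for r in rows
    ]
    return TaxonomyTree(nodes)


def read_taxonomy(path) -> TaxonomyTree:
    """Load a taxonomy from a node-table TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"taxid", "parent_taxid", "rank", "name"} - set(df.columns)
    if missing:
        raise TaxonomyError(f"node table missing columns: {sorted(missing)}")
    return build_taxonomy(df)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    rows = [
        {"taxid": n.taxid, "parent_taxid": n.parent, "rank": n.rank, "name": n.name}
        for n in tree.nodes()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
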