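"""Taxonomy trees and taxon-labelled marker reference databases.

The taxonomic substrate of the pipeline: a rooted taxonomy (NCBI-style,
but loaded from a plain 4-column TSV) with lowest-common-ancestor
queries, and marker reference sets (SSU/LSU rRNA, psbO) indexed by
k-mers for seed-and-extend alignment.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Default ordered rank list, most inclusive first.
DEFAULT_RANKS: tuple[str, ...] = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Recognised marker-gene labels for reference sequences.
MARKERS = ("SSU", "LSU", "psbO", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy file (cycle, orphan, duplicate...)."""


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy; the root is its own parent."""

    taxon_id: int
    parent_id: int
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy with ancestor and lowest-common-ancestor queries.

    Validates on construction: unique ids, exactly one root
    (``parent_id == taxon_id``), no cycles, every node reachable from the
    root, and child ranks never more inclusive than their parent's rank.
    """

    def __init__(self, nodes: Iterable[TaxonNode], ranks: Sequence[str] = DEFAULT_RANKS):
        self.ranks = tuple(ranks)
        self._rank_index = {r: i for i, r in enumerate(self.ranks)}
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self._nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id}")
            if node.taxon_id <= 0:
                raise TaxonomyError(f"taxon_id must be positive, got {node.taxon_id}")
            if node.rank not in self._rank_index:
                raise TaxonomyError(
                    f"unknown rank {node.rank!r} for taxon {node.taxon_id}"
                )
            self._nodes[node.taxon_id] = node
        if not self._nodes:
            raise TaxonomyError("empty taxonomy")

        roots = [n.taxon_id for n in self._nodes.values() if n.parent_id == n.taxon_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]

        # Resolve depths iteratively; detects orphans and cycles.
        self._depth: dict[int, int] = {self.root: 0}
        for tid in self._nodes:
            path = []
            cur = tid
            while cur not in self._depth:
                path.append(cur)
                parent = self._nodes[cur].parent_id
                if parent not in self._nodes:
                    raise TaxonomyError(
                        f"orphan node {cur}: parent {parent} not in taxonomy"
                    )
                if parent in path:
                    raise TaxonomyError(f"cycle detected at node {cur}")
                cur = parent
            base = self._depth[cur]
            for i, node_id in enumerate(reversed(path), start=1):
                self._depth[node_id] = base + i

        for node in self._nodes.values():
            parent = self._nodes[node.parent_id]
            if self._rank_index[node.rank] < self._rank_index[parent.rank]:
                raise TaxonomyError(
                    f"rank of {node.taxon_id} ({node.rank}) is more inclusive than "
                    f"its parent's ({parent.rank})"
                )

    # -- basic queries -------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxon_id: int) -> TaxonNode:
        try:
            return self._nodes[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon_id {taxon_id}") from None

    def name(self, taxon_id: int) -> str:
        return self.node(taxon_id).name

    def rank(self, taxon_id: int) -> str:
        return self.node(taxon_id).rank

    def parent(self, taxon_id: int) -> int:
        return self.node(taxon_id).parent_id

    def depth(self, taxon_id: int) -> int:
        self.node(taxon_id)
        return self._depth[taxon_id]

    def root_path(self, taxon_id: int) -> list[int]:
        """Path root → taxon, inclusive on both ends."""
        path = []
        cur = taxon_id
        self.node(cur)
        while cur != self.root:
            path.append(cur)
            cur = self._nodes[cur].parent_id
        path.append(self.root)
        path.reverse()
        return path

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is an ancestor-or-self of ``b``."""
        return a in set(self.root_path(b))

    def ancestor_at(self, taxon_id: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxon_id`` at exactly ``rank``, or None."""
        if rank not in self._rank_index:
            raise ValueError(f"unknown rank {rank!r}")
        for tid in self.root_path(taxon_id):
            if self._nodes[tid].rank == rank:
                return tid
        return None

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxa.

        The deepest node that lies on the root path of every member;
        ancestor-or-self, so ``lca({x}) == x``.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        common = self.root_path(taxa[0])
        for tid in taxa[1:]:
            other = self.root_path(tid)
            limit = min(len(common), len(other))
            i = 0
            while i < limit and common[i] == other[i]:
                i += 1
            if i == 0:  # pragma: no cover - both paths start at root
                raise TaxonomyError("disjoint root paths")
            common = common[:i]
        return common[-1]

    def nodes(self) -> list[TaxonNode]:
        return list(self._nodes.values())


def load_taxonomy(path: str | Path, ranks: Sequence[str] = DEFAULT_RANKS) -> TaxonomyTree:
    """Load a taxonomy from a TSV with columns taxon_id, parent_id, rank, name."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": int, "parent_id": int})
    required = {"taxon_id", "parent_id", "rank", "name"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"taxonomy file missing columns: {sorted(missing)}")
    nodes = [
        TaxonNode(int(r.taxon_id), int(r.parent_id), str(r.rank), str(r.name))
        for r in df.itertuples(index=False)
    ]
    return TaxonomyTree(nodes, ranks=ranks)


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    rows = [
        (n.taxon_id, n.parent_id, n.rank, n.name)
        for n in sorted(tree.nodes(), key=lambda n: n.taxon_id)
    ]
    pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Reference databases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSequence:
    """A taxon-labelled marker sequence (uppercase A/C/G/T, length >= 50)."""

    ref_id: str
    taxon_id: int
    marker: str
    sequence: str


class ReferenceDB:
    """Marker reference set with a forward-strand k-mer index.

    Only the forward strand is indexed; queries are searched as given and
    reverse-complemented, and the better strand is kept (halves the index).
    """

    def __init__(
        self,
        sequences: Iterable[ReferenceSequence],
        tree: TaxonomyTree,
        k: int = 12,
    ):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.k = k
        self.tree = tree
        self.sequences: dict[str, ReferenceSequence] = {}
        for seq in sequences:
            if seq.ref_id in self.sequences:
                raise ValueError(f"duplicate ref_id {seq.ref_id}")
            if seq.taxon_id not in tree:
                raise ValueError(
                    f"reference {seq.ref_id}: taxon {seq.taxon_id} not in taxonomy"
                )
            if seq.marker not in MARKERS:
                raise ValueError(f"reference {seq.ref_id}: unknown marker {seq.marker}")
            if len(seq.sequence) < 50:
                raise ValueError(f"reference {seq.ref_id}: shorter than 50 bp")
            if set(seq.sequence) - set("ACGT"):
                raise ValueError(
                    f"reference {seq.ref_id}: ambiguous or lowercase bases"
                )
            self.sequences[seq.ref_id] = seq
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref_id, seq in self.sequences.items():
            s = seq.sequence
            for off in range(len(s) - self.k + 1):
                self._index[s[off : off + self.k]].append((ref_id, off))

    def __len__(self) -> int:
        return len(self.sequences)

    def kmer_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def seed_counts(self, query: str) -> dict[str, int]:
        """Number of distinct shared k-mer seeds per ref_id for one query strand."""
        counts: dict[str, int] = defaultdict(int)
        seen: set[tuple[str, str]] = set()
        for off in range(len(query) - self.k + 1):
            kmer = query[off : off + self.k]
            for ref_id, _ in self._index.get(kmer, ()):
                if (ref_id, kmer) not in seen:
                    seen.add((ref_id, kmer))
                    counts[ref_id] += 1
        return dict(counts)


def load_references(
    path: str | Path, tree: TaxonomyTree, k: int = 12
) -> tuple[ReferenceDB, int]:
    """Load a reference FASTA with headers ``>ref_id taxid=<int> marker=<label>``.

    Sequences containing ambiguity codes are rejected (not loaded); the
    count of rejected entries is returned and surfaced as a warning.
    """
    sequences = []
    rejected = 0
    for record in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            part.split("=", 1) for part in record.description.split()[1:] if "=" in part
        )
        if "taxid" not in fields or "marker" not in fields:
            raise ValueError(f"reference {record.id}: header missing taxid=/marker=")
        seq = str(record.seq).upper()
        if set(seq) - set("ACGT"):
            rejected += 1
            continue
        sequences.append(
            ReferenceSequence(record.id, int(fields["taxid"]), fields["marker"], seq)
        )
    if rejected:
        warnings.warn(f"{rejected} reference sequence(s) rejected for ambiguous bases")
    return ReferenceDB(sequences, tree, k=k), rejected


def write_references(db: ReferenceDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in db.sequences.values():
            fh.write(f">{ref.ref_id} taxid={ref.taxon_id} marker={ref.marker}\n")
            fh.write(ref.sequence + "\n")


def merge_databases(dbs: Sequence[ReferenceDB]) -> ReferenceDB:
    """Union of several marker databases over one shared taxonomy.

    Mirrors combining SSU and LSU marker sets into a single alignment
    target. ref_id collisions across inputs are resolved by prefixing the
    colliding id with its marker label; the k-mer index is rebuilt.
    """
    if not dbs:
        raise ValueError("merge_databases needs at least one database")
    tree = dbs[0].tree
    for db in dbs[1:]:
        if db.tree is not tree and set(db.tree.nodes()) != set(tree.nodes()):
            raise ValueError("databases do not share one taxonomy")
    merged: dict[str, ReferenceSequence] = {}
    for db in dbs:
        for ref in db.sequences.values():
            ref_id = ref.ref_id
            if ref_id in merged:
                ref_id = f"{ref.marker}:{ref.ref_id}"
            if ref_id in merged:
                raise ValueError(f"unresolvable ref_id collision for {ref.ref_id}")
            merged[ref_id] = ReferenceSequence(
                ref_id, ref.taxon_id, ref.marker, ref.sequence
            )
    return ReferenceDB(merged.values(), tree, k=dbs[0].k)


def apply_alias_table(names: Mapping[str, str], label: str) -> str:
    """Map a taxon display label through a user-supplied alias/synonym table.

    Repeated labels such as 'X incertae sedis' / 'X environmental sample'
    can be grouped under one canonical label; the table is user data, not
    built in.
    """
    return names.get(label, label)
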