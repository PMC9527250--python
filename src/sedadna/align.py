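"""Semiglobal seed-and-extend alignment and naive-LCA taxonomic assignment.

Reads are aligned end-to-end (no clipping) against a local window of each
candidate reference — the semiglobal contract — with candidates chosen by
exact shared k-mers on either strand. Filtered hits are collapsed to one
taxon per read by the naive lowest-common-ancestor rule with the
more-specific-match refinement: a hit whose taxon is a strict ancestor of
another hit's taxon is ignored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .qc import Read
from .taxonomy import ReferenceDB, TaxonomyTree, revcomp

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2
DEFAULT_MIN_PID = 0.95      # minimum percent identity for a significant hit
DEFAULT_TOP_PERCENT = 0.10  # score window below the best hit

#: Sentinel for reads with no surviving hits.
UNASSIGNED = None


@njit(cache=True)
def _semiglobal_fill(query, ref, match, mismatch, gap):  # pragma: no cover - numba
    n = query.shape[0]
    m = ref.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap
        ptr[i, 0] = 1
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            s = match if qi == ref[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            code = 0
            up = H[i - 1, j] + gap
            if up > best:
                best = up
                code = 1
            left = H[i, j - 1] + gap
            if left > best:
                best = left
                code = 2
            H[i, j] = best
            ptr[i, j] = code
    return H, ptr


class _RawAlignment(NamedTuple):
    score: int
    matches: int
    mismatches: list  # (query_pos, ref_base, query_base)
    gaps: int
    insertions: list  # query positions aligned to a reference gap
    ref_start: int
    ref_end: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def semiglobal_align(
    query: str,
    ref: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> _RawAlignment:
    """Semiglobal dynamic programming: query global, reference local.

    Linear gap penalties. Ties prefer diagonal moves over read-gap over
    reference-gap, and the leftmost maximal end column, making the
    traceback deterministic.
    """
    q = _encode(query)
    r = _encode(ref)
    H, ptr = _semiglobal_fill(q, r, match, mismatch, gap)
    n = len(q)
    j = int(np.argmax(H[n, :]))  # leftmost maximum
    score = int(H[n, j])
    ref_end = j
    i = n
    matches = 0
    gaps = 0
    mismatches: list[tuple[int, str, str]] = []
    insertions: list[int] = []
    while i > 0:
        code = ptr[i, j]
        if code == 0:
            qb = query[i - 1]
            rb = ref[j - 1]
            if qb == rb:
                matches += 1
            else:
                mismatches.append((i - 1, rb, qb))
            i -= 1
            j -= 1
        elif code == 1:
            insertions.append(i - 1)
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    mismatches.reverse()
    insertions.reverse()
    return _RawAlignment(score, matches, mismatches, gaps, insertions, j, ref_end)


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-reference semiglobal alignment.

    Mismatch positions are 0-based from the read's 5' end in read
    orientation; for minus-strand hits bases are complemented before
    recording, so deamination on the opposite strand surfaces with the
    expected polarity (e.g. genomic C→T appears as G→A at the read 3').
    """

    read_id: str
    ref_id: str
    taxon_id: int
    strand: str
    score: int
    columns: int
    matches: int
    mismatches: tuple[tuple[int, str, str], ...]
    gaps: int
    read_insertions: tuple[int, ...] = ()
    ref_start: int = 0
    ref_end: int = 0

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def read_length(self) -> int:
        return self.matches + len(self.mismatches) + len(self.read_insertions)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _hit_from_raw(
    read: Read, ref_id: str, taxon_id: int, strand: str, raw: _RawAlignment
) -> AlignmentHit:
    L = len(read.sequence)
    if strand == "+":
        mismatches = tuple(raw.mismatches)
        insertions = tuple(raw.insertions)
    else:
        # The reverse complement of the read was aligned; map positions
        # back to read orientation and complement both bases.
        mismatches = tuple(
            sorted(
                (L - 1 - pos, _COMP[rb], _COMP[qb]) for pos, rb, qb in raw.mismatches
            )
        )
        insertions = tuple(sorted(L - 1 - pos for pos in raw.insertions))
    columns = raw.matches + len(raw.mismatches) + raw.gaps
    return AlignmentHit(
        read_id=read.read_id,
        ref_id=ref_id,
        taxon_id=taxon_id,
        strand=strand,
        score=raw.score,
        columns=columns,
        matches=raw.matches,
        mismatches=mismatches,
        gaps=raw.gaps,
        read_insertions=insertions,
        ref_start=raw.ref_start,
        ref_end=raw.ref_end,
    )


def align_read(
    read: Read,
    db: ReferenceDB,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
    min_seed: int = 1,
) -> list[AlignmentHit]:
    """Align one read against every reference sharing >= min_seed k-mers.

    Both strands are seeded; per reference the better-scoring strand is
    kept (ties resolved to '+'). Hits are sorted by score descending,
    ties by ref_id.
    """
    seq = read.sequence
    if len(seq) < db.k:
        warnings.warn(f"read {read.read_id} shorter than seed length {db.k}; skipped")
        return []
    rc = revcomp(seq)
    fwd_seeds = db.seed_counts(seq)
    rev_seeds = db.seed_counts(rc)
    candidates = {r for r, c in fwd_seeds.items() if c >= min_seed}
    candidates |= {r for r, c in rev_seeds.items() if c >= min_seed}
    hits = []
    for ref_id in candidates:
        ref = db.sequences[ref_id]
        best = None
        if fwd_seeds.get(ref_id, 0) >= min_seed:
            raw = semiglobal_align(seq, ref.sequence, match, mismatch, gap)
            best = ("+", raw)
        if rev_seeds.get(ref_id, 0) >= min_seed:
            raw_rc = semiglobal_align(rc, ref.sequence, match, mismatch, gap)
            if best is None or raw_rc.score > best[1].score:
                best = ("-", raw_rc)
        strand, raw = best
        hits.append(_hit_from_raw(read, ref_id, ref.taxon_id, strand, raw))
    hits.sort(key=lambda h: (-h.score, h.ref_id))
    return hits


def filter_hits(
    hits: Sequence[AlignmentHit],
    min_pid: float = DEFAULT_MIN_PID,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> list[AlignmentHit]:
    """Keep hits at identity >= min_pid within the top score window.

    The score window is relative to the best hit before identity
    filtering: score >= (1 - top_percent) * best_score.
    """
    if not hits:
        return []
    best = hits[0].score
    cutoff = (1.0 - top_percent) * best
    return [h for h in hits if h.identity >= min_pid and h.score >= cutoff]


def assign_read(hits: Sequence[AlignmentHit], tree: TaxonomyTree):
    """Naive LCA with the more-specific-match rule.

    Hits whose taxon is a strict ancestor of another hit's taxon are
    dropped, then the LCA of the remaining taxa is returned;
    no hits → :data:`UNASSIGNED`.
    """
    taxa = {h.taxon_id for h in hits}
    if not taxa:
        return UNASSIGNED
    kept = {
        t
        for t in taxa
        if not any(o != t and tree.is_ancestor(t, o) for o in taxa)
    }
    return tree.lca(kept)


class Assignment(NamedTuple):
    sample_id: str
    read_id: str
    taxon_id: int | None  # None == unassigned


def align_batch(
    reads: Iterable[Read],
    db: ReferenceDB,
    tree: TaxonomyTree,
    min_pid: float = DEFAULT_MIN_PID,
    top_percent: float = DEFAULT_TOP_PERCENT,
    min_seed: int = 1,
) -> tuple[list["Assignment"], list[AlignmentHit]]:
    """Align, filter and LCA-assign a batch of reads.

    Returns one assignment per read plus the best surviving hit per read
    (for downstream damage analysis).
    """
    assignments = []
    best_hits = []
    for read in reads:
        hits = filter_hits(
            align_read(read, db, min_seed=min_seed),
            min_pid=min_pid,
            top_percent=top_percent,
        )
        if hits:
            best_hits.append(hits[0])
        assignments.append(
            Assignment(read.sample_id, read.read_id, assign_read(hits, tree))
        )
    return assignments, best_hits


class TaxonProfile:
    """Sample × taxon count matrix with rank projection.

    ``counts`` is an integer DataFrame indexed by sample_id with taxon_id
    columns. ``unclassified`` marks columns that act as
    "unclassified-at-rank" buckets after projection (their taxon sits
    above the projected rank).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        unassigned: pd.Series | None = None,
        unclassified: frozenset[int] = frozenset(),
        rank: str | None = None,
    ):
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts in profile")
        self.counts = counts.astype(int)
        self.counts.index.name = "sample_id"
        if unassigned is None:
            unassigned = pd.Series(0, index=counts.index, dtype=int)
        self.unassigned = unassigned.reindex(counts.index, fill_value=0).astype(int)
        self.unclassified = unclassified
        self.rank = rank

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[int]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def copy(self) -> "TaxonProfile":
        return TaxonProfile(
            self.counts.copy(), self.unassigned.copy(), self.unclassified, self.rank
        )

    def column_label(self, taxon_id: int, tree: TaxonomyTree | None = None) -> str:
        name = tree.name(taxon_id) if tree is not None else str(taxon_id)
        if taxon_id in self.unclassified:
            return f"{name} (not further classified)"
        return name

    def to_tsv(self, path: str | Path, tree: TaxonomyTree | None = None) -> None:
        out = self.counts.copy()
        out.columns = [self.column_label(t, tree) for t in out.columns]
        out["__unassigned__"] = self.unassigned
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        unassigned = None
        if "__unassigned__" in df.columns:
            unassigned = df.pop("__unassigned__")
        df.columns = [int(c) for c in df.columns]
        return cls(df, unassigned)


def build_profile(
    assignments: Iterable[Assignment],
    tree: TaxonomyTree,
    min_support_percent: float = 0.0,
) -> TaxonProfile:
    """Count assigned reads per (sample, taxon).

    ``min_support_percent`` is in percent units (0–100): taxa whose share
    of a sample's assigned reads falls below it have their reads moved to
    the parent taxon, deepest taxa first, until every retained taxon meets
    the threshold. At 0.0 (the default, 'off') counts equal the raw
    assignments. Unassigned reads are tracked separately.
    """
    counts: dict[str, dict[int, int]] = {}
    unassigned: dict[str, int] = {}
    for a in assignments:
        counts.setdefault(a.sample_id, {})
        unassigned.setdefault(a.sample_id, 0)
        if a.taxon_id is UNASSIGNED:
            unassigned[a.sample_id] += 1
        else:
            counts[a.sample_id][a.taxon_id] = counts[a.sample_id].get(a.taxon_id, 0) + 1

    if min_support_percent > 0.0:
        # Single pass against the raw shares: each weak taxon's reads move
        # one level up. (No cascade: the parent keeps them even if its own
        # share stays under the threshold.)
        for sample_id, row in counts.items():
            total = sum(row.values())
            if total == 0:
                continue
            weak = [
                t
                for t, c in row.items()
                if c > 0 and t != tree.root and 100.0 * c / total < min_support_percent
            ]
            for t in sorted(weak, key=lambda t: (-tree.depth(t), t)):
                parent = tree.parent(t)
                row[parent] = row.get(parent, 0) + row.pop(t)

    taxa = sorted({t for row in counts.values() for t in row})
    df = pd.DataFrame(0, index=sorted(counts), columns=taxa, dtype=int)
    for sample_id, row in counts.items():
        for t, c in row.items():
            df.loc[sample_id, t] = c
    una = pd.Series(unassigned, dtype=int).reindex(df.index, fill_value=0)
    return TaxonProfile(df, una)


def project_rank(profile: TaxonProfile, tree: TaxonomyTree, rank: str) -> TaxonProfile:
    """Project a profile to a higher rank, conserving per-sample totals.

    A taxon with no ancestor at the requested rank (assigned above that
    rank, or on a lineage that skips it) is bucketed under its deepest
    ancestor above the rank and marked "not further classified" rather
    than dropped.
    """
    if rank not in tree.ranks:
        raise ValueError(f"unknown rank {rank!r}")
    target_index = tree.ranks.index(rank)
    mapping: dict[int, int] = {}
    unclassified: set[int] = set()
    for taxon in profile.taxa:
        at_rank = tree.ancestor_at(taxon, rank)
        if at_rank is not None:
            mapping[taxon] = at_rank
        else:
            anchor = tree.root
            for tid in tree.root_path(taxon):
                if tree.ranks.index(tree.rank(tid)) < target_index:
                    anchor = tid
            mapping[taxon] = anchor
            unclassified.add(anchor)
    projected = profile.counts.T.groupby(
        profile.counts.columns.map(mapping)
    ).sum().T
    projected = projected[sorted(projected.columns)]
    return TaxonProfile(
        projected, profile.unassigned.copy(), frozenset(unclassified), rank
    )


# ---------------------------------------------------------------------------
# BLAST-like tabular output
# ---------------------------------------------------------------------------

_BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def hits_to_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as blastn -outfmt 6 columns plus a JSON mismatch sidecar."""
    rows = []
    sidecar = []
    for h in hits:
        rows.append(
            (
                h.read_id, h.ref_id, round(100.0 * h.identity, 3), h.columns,
                len(h.mismatches), h.gaps, 1, h.read_length,
                h.ref_start + 1, h.ref_end, 0.0, h.score,
            )
        )
        sidecar.append(
            {
                "read_id": h.read_id,
                "ref_id": h.ref_id,
                "taxon_id": h.taxon_id,
                "strand": h.strand,
                "mismatches": [list(m) for m in h.mismatches],
                "read_insertions": list(h.read_insertions),
            }
        )
    pd.DataFrame(rows, columns=_BLAST6_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh)
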