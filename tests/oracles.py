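"""Independent reference implementations used to cross-check the package.

Deliberately simple and structurally different from the production code:
the alignment oracle is a score-only vectorised DP (no seeding, no
traceback, every reference examined), and the assignment oracle works by
explicit root-path intersection over the post-ancestor-drop taxa.
"""

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def semiglobal_score(query: str, ref: str, match=1, mismatch=-1, gap=-2) -> int:
    """Best semiglobal score (query global / reference local), full DP.

    Linear gap penalties allow the in-row (reference-gap) recursion to be
    folded into a running prefix maximum, so each row is one vector pass.
    """
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    m = len(r)
    js = np.arange(m + 1)
    prev = np.zeros(m + 1)
    for ch in query.encode():
        sub = np.where(r == ch, match, mismatch)
        a = np.empty(m + 1)
        a[0] = prev[0] + gap
        a[1:] = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        cur = np.maximum.accumulate(a - gap * js) + gap * js
        prev = cur
    return int(prev.max())


def best_score_all_refs(query: str, refs: dict[str, str], match=1, mismatch=-1, gap=-2):
    """Exhaustive best (score, ref_id) over every reference and strand."""
    best = None
    for ref_id in sorted(refs):
        for q in (query, revcomp(query)):
            s = semiglobal_score(q, refs[ref_id], match, mismatch, gap)
            if best is None or s > best[0]:
                best = (s, ref_id)
    return best


def root_path(parents: dict[int, int], node: int) -> list[int]:
    path = [node]
    while parents[path[-1]] != path[-1]:
        path.append(parents[path[-1]])
    return path[::-1]


def lca_oracle(parents: dict[int, int], taxa) -> int:
    """Plain lowest common ancestor by root-path intersection."""
    paths = [root_path(parents, t) for t in taxa]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    depth = {n: len(root_path(parents, n)) for n in common}
    return max(common, key=lambda n: (depth[n], n))


def assign_oracle(parents: dict[int, int], hit_taxa: list[int]):
    """Ancestor-drop then root-path-intersection LCA; None if no hits."""
    taxa = set(hit_taxa)
    if not taxa:
        return None
    ancestors_of = {t: set(root_path(parents, t)) for t in taxa}
    kept = {
        t
        for t in taxa
        if not any(o != t and t in ancestors_of[o] for o in taxa)
    }
    paths = [root_path(parents, t) for t in kept]
    common = set(paths[0]).intersection(*map(set, paths[1:])) if paths else set()
    # deepest member of the intersection
    depth = {n: len(root_path(parents, n)) for n in common}
    return max(common, key=lambda n: (depth[n], n))
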