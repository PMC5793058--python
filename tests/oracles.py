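"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different computational route from the
code it checks: exhaustive enumeration instead of dynamic programming,
codon walking instead of frame translation, least-squares topology
fitting instead of agglomeration.
"""

from __future__ import annotations

import itertools
from math import inf

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gap_cost(k: int, gap_open: float, gap_extend: float) -> float:
    return 0.0 if k == 0 else gap_open + (k - 1) * gap_extend


def brute_force_global_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = False,
) -> float:
    """Optimal affine-gap global score by exhaustive matching enumeration.

    Every alignment corresponds to a monotone matching of residue
    positions; for a fixed matching the cheapest gap arrangement keeps
    each inter-anchor deletion/insertion block contiguous, so maximising
    over matchings with contiguous gap runs yields the DP optimum.
    """
    best = -inf
    la, lb = len(a), len(b)
    for k in range(min(la, lb) + 1):
        for ia in itertools.combinations(range(la), k):
            for ib in itertools.combinations(range(lb), k):
                s = sum(_BLOSUM62[a[i], b[j]] for i, j in zip(ia, ib))
                anchors = list(zip(ia, ib)) + [(la, lb)]
                prev_i = prev_j = -1
                for idx, (i, j) in enumerate(anchors):
                    ga, gb = i - prev_i - 1, j - prev_j - 1
                    ca = gap_cost(ga, gap_open, gap_extend)
                    cb = gap_cost(gb, gap_open, gap_extend)
                    terminal = idx == 0 or idx == len(anchors) - 1
                    if free_end_gaps and terminal:
                        # overhangs of both sequences at the same end cannot
                        # both be terminal: one run precedes the other, and
                        # the second is an internal gap — free the dearer one
                        s -= min(ca, cb)
                    else:
                        s -= ca + cb
                    prev_i, prev_j = i, j
                best = max(best, s)
    return best


def hamming_scan(seq: str, pattern: str, max_mismatch: int):
    """All (start_1based, n_mismatch) windows within the mismatch budget."""
    out = []
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        mm = sum(1 for x, y in zip(seq[i : i + k], pattern) if x != y)
        if mm <= max_mismatch:
            out.append((i + 1, mm))
    return out


def brute_force_longest_orf(nt: str, min_aa: int):
    """Longest start-to-stop ORF by walking codons from every ATG.

    Returns (aa_sequence, frame) or None.  Ties break by frame order
    +1, +2, +3, -1, -2, -3 then earliest start.
    """
    nt = nt.upper().replace("U", "T")
    stops = {"TAA", "TAG", "TGA"}
    candidates = []
    for rank, (frame, tmpl) in enumerate(
        [
            (1, nt),
            (2, nt),
            (3, nt),
            (-1, str(Seq(nt).reverse_complement())),
            (-2, str(Seq(nt).reverse_complement())),
            (-3, str(Seq(nt).reverse_complement())),
        ]
    ):
        off = abs(frame) - 1
        blocked_until = -1
        for start in range(off, len(tmpl) - 2, 3):
            if tmpl[start : start + 3] != "ATG" or start <= blocked_until:
                continue
            pos = start
            codons = []
            while pos + 3 <= len(tmpl):
                codon = tmpl[pos : pos + 3]
                if codon in stops:
                    break
                codons.append(codon)
                pos += 3
            blocked_until = pos  # nested ATGs give shorter ORFs; skip them
            aa = str(Seq("".join(codons)).translate(table=1))
            if len(aa) >= min_aa:
                candidates.append((-len(aa), rank, start, aa, frame))
    if not candidates:
        return None
    candidates.sort()
    _, _, _, aa, frame = candidates[0]
    return aa, frame


def tree_splits(tree) -> set[frozenset]:
    """Non-trivial bipartitions of a (scikit-bio) tree's leaf set."""
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(tips) - 1:
            out.add(frozenset((s, tips - s)))
    return out


def five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 labels, as split sets."""
    labels = list(labels)
    seen = []
    for cherry1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            key = frozenset((frozenset(cherry1), frozenset(cherry2)))
            if key in [k for k, _ in seen]:
                continue
            full = frozenset(labels)
            splits = {
                frozenset((frozenset(cherry1), full - frozenset(cherry1))),
                frozenset((frozenset(cherry2), full - frozenset(cherry2))),
            }
            seen.append((key, splits))
    return [s for _, s in seen]


def additive_topologies(d: np.ndarray, labels) -> list[set[frozenset]]:
    """5-taxon topologies whose branch lengths exactly fit the matrix.

    For each candidate topology the 10 pairwise distances are linear in
    the 7 branch lengths; a topology fits iff least squares leaves no
    residual (and lengths are non-negative).
    """
    n = len(labels)
    assert n == 5 and d.shape == (5, 5)
    fits = []
    idx = {lab: i for i, lab in enumerate(labels)}
    for cherry1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in cherry1]
        for c2_idx, cherry2 in enumerate(itertools.combinations(rest, 2)):
            key = frozenset((frozenset(cherry1), frozenset(cherry2)))
            middle = [x for x in rest if x not in cherry2][0]
            # branch order: leaf branches in `labels` order, then x (cherry1
            # node to centre), y (cherry2 node to centre)
            rows, rhs = [], []
            a, b = cherry1
            c, e = cherry2

            def leafvec(*leaves):
                v = np.zeros(7)
                for leaf in leaves:
                    v[idx[leaf]] = 1
                return v

            paths = {
                (a, b): leafvec(a, b),
                (c, e): leafvec(c, e),
                (a, c): leafvec(a, c) + np.array([0] * 5 + [1, 1]),
                (a, e): leafvec(a, e) + np.array([0] * 5 + [1, 1]),
                (b, c): leafvec(b, c) + np.array([0] * 5 + [1, 1]),
                (b, e): leafvec(b, e) + np.array([0] * 5 + [1, 1]),
                (a, middle): leafvec(a, middle) + np.array([0] * 5 + [1, 0]),
                (b, middle): leafvec(b, middle) + np.array([0] * 5 + [1, 0]),
                (c, middle): leafvec(c, middle) + np.array([0] * 5 + [0, 1]),
                (e, middle): leafvec(e, middle) + np.array([0] * 5 + [0, 1]),
            }
            for (u, v), vec in paths.items():
                rows.append(vec)
                rhs.append(d[idx[u], idx[v]])
            A = np.array(rows)
            y = np.array(rhs)
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            if np.allclose(A @ sol, y, atol=1e-8) and np.all(sol >= -1e-8):
                full = frozenset(labels)
                fits.append(
                    {
                        frozenset((frozenset(cherry1), full - frozenset(cherry1))),
                        frozenset((frozenset(cherry2), full - frozenset(cherry2))),
                    }
                )
    # deduplicate identical split sets
    unique = []
    for f in fits:
        if f not in unique:
            unique.append(f)
    return unique
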