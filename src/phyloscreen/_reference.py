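"""Brute-force reference implementations used for validation.

These deliberately share no code with the production paths: the local
aligner enumerates alignment paths recursively instead of running dynamic
programming, and the Dollo reference enumerates every single-gain labeling
(gain node x loss-edge subset) instead of using the MRCA/maximal-absent-
subtree recursion.  They are exponential-time and only meant for tiny
instances, as ground truth in tests and in the acceptance checks.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trees import SpeciesTree


# ---------------------------------------------------------------------------
# exhaustive local alignment
# ---------------------------------------------------------------------------

def brute_force_local_score(
    scores: np.ndarray,
    seq_codes: Sequence[int],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Maximum over all local alignments, enumerated explicitly.

    An alignment is a chain of match pairs (profile column, sequence
    position), strictly increasing in both coordinates; between consecutive
    matches either profile columns or sequence residues (not both) may be
    skipped, a run of g skips costing ``gap_open + g * gap_extend``.  The
    empty alignment scores 0.
    """
    L = scores.shape[0]
    n = len(seq_codes)
    best = 0.0

    def match(i: int, j: int) -> float:
        c = seq_codes[j]
        return 0.0 if c >= 20 else float(scores[i, c])

    def extend(i: int, j: int, cur: float) -> None:
        nonlocal best
        if cur > best:
            best = cur
        for i2 in range(i + 1, L):
            for j2 in range(j + 1, n):
                gi = i2 - i - 1
                gj = j2 - j - 1
                if gi and gj:
                    continue  # adjacent gap runs in both sequences disallowed
                cost = (gap_open + gi * gap_extend) if gi else 0.0
                cost += (gap_open + gj * gap_extend) if gj else 0.0
                extend(i2, j2, cur + match(i2, j2) - cost)

    for i in range(L):
        for j in range(n):
            extend(i, j, match(i, j))
    return best


# ---------------------------------------------------------------------------
# exhaustive Dollo minimisation
# ---------------------------------------------------------------------------

def all_rooted_binary_trees(tips: Sequence[str]) -> List[str]:
    """Newick strings of every rooted binary tree on the given labeled tips,
    built by attaching each new tip on every edge (including above the root)."""
    tips = list(tips)
    trees: List[object] = [tips[0]]
    for tip in tips[1:]:
        nxt: List[object] = []
        for t in trees:
            nxt.extend(_attach_everywhere(t, tip))
        trees = nxt
    def to_newick(t) -> str:
        if isinstance(t, str):
            return t
        return f"({to_newick(t[0])},{to_newick(t[1])})"
    return [to_newick(t) + ";" for t in trees]


def _attach_everywhere(tree, tip) -> List[object]:
    out = [(tree, tip)]  # new root above the old one
    if not isinstance(tree, str):
        left, right = tree
        out.extend((sub, right) for sub in _attach_everywhere(left, tip))
        out.extend((left, sub) for sub in _attach_everywhere(right, tip))
    return out


def dollo_min_losses_all_patterns(tree: SpeciesTree) -> Dict[int, int]:
    """Minimum loss count for every non-empty presence pattern on a tree.

    Patterns are bitmasks over ``tree.tip_labels`` (bit k = tip k present).
    For every candidate gain node, every subset of edges strictly below it is
    tried as the loss set; the resulting tip pattern is ``tips(gain) minus
    tips under any loss edge``.  Returns pattern -> minimal number of losses
    over all single-gain labelings realising it.
    """
    tips = tree.tip_labels
    n = len(tips)
    tip_bit = {t: 1 << k for k, t in enumerate(tips)}

    node_mask: Dict[str, int] = {}
    for nid in tree.node_ids():
        m = 0
        for t in tree.tips_below(nid):
            m |= tip_bit[t]
        node_mask[nid] = m

    best = np.full(1 << n, np.iinfo(np.int64).max, dtype=np.int64)
    for gain in tree.node_ids():
        below = [nid for nid in tree.node_ids() if nid != gain and _is_below(tree, nid, gain)]
        m = len(below)
        masks = np.array([node_mask[b] for b in below], dtype=np.int64)
        n_sub = 1 << m
        union = np.zeros(n_sub, dtype=np.int64)
        pop = np.zeros(n_sub, dtype=np.int64)
        for b in range(m):
            step = 1 << b
            idx = np.nonzero((np.arange(n_sub) >> b) & 1)[0]
            union[idx] |= masks[b]
            pop[idx] += 1
        result = node_mask[gain] & ~union
        np.minimum.at(best, result, pop)
    return {p: int(best[p]) for p in range(1, 1 << n) if best[p] < np.iinfo(np.int64).max}


def _is_below(tree: SpeciesTree, node_id: str, anc_id: str) -> bool:
    cur = tree.parent(node_id)
    while cur is not None:
        if cur == anc_id:
            return True
        cur = tree.parent(cur)
    return False
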