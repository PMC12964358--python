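"""Exhaustive enumeration of small latent states.

Used for exact posterior computation on toy instances: all outlier
subsets, all set partitions of the remaining blocks, and all rooted
labelled forests over the resulting clusters.  Only feasible for a
handful of blocks.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .tree_model import ROOT, CloneTree, ModelConfig


def set_partitions(items: Sequence) -> Iterator[List[List]]:
    """All set partitions of ``items`` (Bell(n) of them)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def rooted_forests(num_nodes: int) -> Iterator[Dict[int, int]]:
    """All rooted labelled forests on nodes 0..K-1 as parent maps
    (parent :data:`ROOT` marks a root).  There are (K+1)^(K-1)."""
    k = num_nodes
    if k == 0:
        yield {}
        return
    options = [[ROOT] + [j for j in range(k) if j != i] for i in range(k)]
    for combo in product(*options):
        ok = True
        for i in range(k):
            seen = {i}
            u = combo[i]
            while u != ROOT:
                if u in seen:
                    ok = False
                    break
                seen.add(u)
                u = combo[u]
            if not ok:
                break
        if ok:
            yield {i: combo[i] for i in range(k)}


def enumerate_trees(
    blocks: Sequence[int], allow_outliers: bool = False
) -> Iterator[CloneTree]:
    """All clone trees over the given block ids."""
    blocks = list(blocks)
    max_out = len(blocks) if allow_outliers else 0
    for n_out in range(max_out + 1):
        for out in combinations(blocks, n_out):
            rest = [b for b in blocks if b not in out]
            if not rest:
                yield CloneTree(parent={}, clusters={}, outliers=frozenset(out))
                continue
            for part in set_partitions(rest):
                clusters = {i: frozenset(c) for i, c in enumerate(part)}
                for parent in rooted_forests(len(part)):
                    yield CloneTree(
                        parent=parent, clusters=clusters, outliers=frozenset(out)
                    )


def exact_posterior(
    bd, config: ModelConfig, allow_outliers: bool = False
) -> Tuple[List[Tuple[CloneTree, float]], Dict[object, float]]:
    """Exact posterior over all enumerable states of a small instance.

    Returns the (tree, log joint) list and a map from canonical tree
    key to normalized posterior probability.
    """
    from .inference import block_joint

    states = list(
        enumerate_trees(range(bd.num_blocks), allow_outliers=allow_outliers)
    )
    logps = np.array([block_joint(t, bd, config) for t in states])
    norm = logsumexp(logps)
    probs = np.exp(logps - norm)
    table: Dict[object, float] = {}
    for t, p in zip(states, probs):
        table[t.canonical_key()] = table.get(t.canonical_key(), 0.0) + float(p)
    return list(zip(states, logps)), table
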