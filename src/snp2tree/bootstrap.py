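"""Nonparametric bootstrap support for internal edges.

Alignment columns are resampled with replacement (column count
preserved); each replicate tree is rebuilt with the same
distance + neighbor-joining procedure as the main tree (optionally with
NNI refinement, or full per-replicate branch-length ML).  The support of
an internal edge of the reference tree is the percentage of replicate
trees containing the same bipartition of the taxa, in [0, 100].

Replicate r draws from ``numpy.random.default_rng([seed, r])``, a
deterministic per-replicate stream, so results do not depend on
execution order and a fixed seed reproduces the support vector exactly.
"""

from __future__ import annotations

import numpy as np

from .encode import Alignment
from .errors import Snp2TreeError
from .models import SubstitutionModel
from .tree import Node, Tree


def _resample(al: Alignment, rng: np.random.Generator) -> Alignment:
    n = al.n_sites
    idx = rng.integers(0, n, size=n)
    seqs = ["".join(seq[i] for i in idx) for seq in al.sequences]
    site_map = [al.site_map[i] for i in idx] if al.site_map else []
    return Alignment(list(al.sample_ids), seqs, site_map)


def build_replicate_tree(al: Alignment, model: SubstitutionModel,
                         nni: bool = False, full_ml: bool = False) -> Tree:
    """One bootstrap-replicate tree: NJ on JC distances, optionally
    NNI-refined or with full ML branch lengths."""
    from .distance import distance_matrix, neighbor_joining
    from .likelihood import nni_search, optimize_branch_lengths

    tree = neighbor_joining(distance_matrix(al))
    if nni:
        tree = nni_search(tree, al, model)
    elif full_ml:
        tree = optimize_branch_lengths(tree, al, model)
    return tree


def bootstrap_support(best_tree: Tree, al: Alignment, model: SubstitutionModel,
                      n_reps: int, seed: int, nni: bool = False,
                      full_ml: bool = False) -> Tree:
    """Annotate a copy of ``best_tree`` with bootstrap supports.

    Each internal edge's support is the integer percentage of replicate
    trees whose bipartition set contains that edge's leaf split.
    """
    if n_reps < 1:
        raise Snp2TreeError(f"n_reps must be >= 1, got {n_reps}")
    counts: dict[frozenset, int] = {}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        rep = build_replicate_tree(_resample(al, rng), model, nni=nni, full_ml=full_ml)
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    out = best_tree.copy()
    all_leaves = frozenset(out.leaf_labels())
    anchor = min(all_leaves)
    below: dict[Node, frozenset] = {}
    for n in out.postorder():
        if n.is_leaf:
            below[n] = frozenset([n.label])
            continue
        below[n] = frozenset().union(*(below[c] for c in n.children))
        if n.parent is not None:
            side = below[n] if anchor not in below[n] else all_leaves - below[n]
            if 1 < len(side) < len(all_leaves) - 1:
                n.support = round(100.0 * counts.get(side, 0) / n_reps)
    return out


def support_table(tree: Tree) -> list[tuple[str, int]]:
    """Bipartitions with supports as (sorted 'a,b,c' label string, pct)."""
    out = []
    for n in tree.internal_edges():
        if n.support is not None:
            labels = sorted(l.label for l in Tree(n).leaves())
            out.append((",".join(labels), n.support))
    return sorted(out)
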