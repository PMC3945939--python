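"""Pairwise distances between IUPAC pseudo-sequences and neighbor-joining.

The mismatch fraction p between two sequences is computed over columns
where neither symbol is N, scoring IUPAC ambiguity codes as the expected
mismatch under a random draw of one allele from each genotype: identical
symbols match (0), a heterozygote against a compatible homozygote is a
half mismatch (0.5), disjoint symbols fully mismatch (1).  p is then
mapped to substitutions/site with the Jukes-Cantor correction
``d = -(3/4) ln(1 - 4p/3)``, capped at a saturation value when p
approaches the 0.75 domain boundary.

The neighbor-joining implementation is the classical Saitou-Nei
agglomeration with Q-matrix selection; it is exact on additive distance
matrices and serves as the starting tree for likelihood optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encode import ALPHABET, SYMBOL_BASES, Alignment
from .errors import Snp2TreeError
from .tree import Node, Tree

#: JC correction is undefined for p >= 0.75; saturated pairs get this value.
DEFAULT_SATURATION_D = 5.0
_P_EPS = 1e-6


def _mismatch_table() -> np.ndarray:
    """Symbol x symbol expected-mismatch scores (N handled by masking)."""
    k = len(ALPHABET)
    tab = np.zeros((k, k))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == b:
                tab[i, j] = 0.0
            else:
                sa, sb = SYMBOL_BASES[a], SYMBOL_BASES[b]
                tab[i, j] = 1.0 - len(sa & sb) / (len(sa) * len(sb))
    return tab

_MISMATCH = _mismatch_table()
_SYM_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
_N_INDEX = _SYM_INDEX["N"]


def encode_symbols(seq: str) -> np.ndarray:
    try:
        return np.array([_SYM_INDEX[ch] for ch in seq], dtype=np.int8)
    except KeyError as exc:
        raise Snp2TreeError(f"sequence contains non-IUPAC symbol {exc}") from exc


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in substitutions/site."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and nonnegative")


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean mismatch score over comparable (non-N) columns."""
    ok = (a != _N_INDEX) & (b != _N_INDEX)
    n = int(ok.sum())
    if n == 0:
        raise Snp2TreeError("zero comparable columns between a sequence pair")
    return float(_MISMATCH[a[ok], b[ok]].mean())


def jc_correct(p: float, saturation_d: float = DEFAULT_SATURATION_D) -> float:
    """Jukes-Cantor distance; saturated (p >= 0.75 - eps) maps to the cap."""
    if p >= 0.75 - _P_EPS:
        return saturation_d
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def distance_matrix(al: Alignment, saturation_d: float = DEFAULT_SATURATION_D) -> DistanceMatrix:
    """JC-corrected pairwise distances between all alignment sequences."""
    if al.n_samples < 2:
        raise Snp2TreeError("need >= 2 sequences for a distance matrix")
    enc = [encode_symbols(s) for s in al.sequences]
    n = al.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p = p_distance(enc[i], enc[j])
            except Snp2TreeError:
                raise Snp2TreeError(
                    f"zero comparable columns between {al.sample_ids[i]!r} "
                    f"and {al.sample_ids[j]!r}") from None
            d[i, j] = d[j, i] = jc_correct(p, saturation_d)
    return DistanceMatrix(list(al.sample_ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q matrix are broken by the lexicographically smallest
    (label_i, label_j) pair, where a cluster is identified by the
    smallest leaf label it contains; negative branch lengths are clamped
    to zero with the deficit shifted to the sibling edge.  Exact on
    additive matrices.
    """
    n = len(dm.labels)
    if n < 3:
        raise Snp2TreeError(f"neighbor joining needs >= 3 taxa, got {n}")
    nodes: list[Node] = [Node(lbl) for lbl in dm.labels]
    keys: list[str] = list(dm.labels)       # tie-break identity per cluster
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cand if a < b
        )
        ai, bi = best[1], best[2]
        i, j = active[ai], active[bi]

        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Node()
        a_node, b_node = nodes[i], nodes[j]
        a_node.length, b_node.length = li, lj
        parent.add(a_node)
        parent.add(b_node)

        # distances from the new cluster to the remaining ones
        rest = [k for k in active if k != i and k != j]
        newd = 0.5 * (D[i, rest] + D[j, rest] - dij)
        D[i, rest] = newd
        D[rest, i] = newd
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # join the last three clusters at a central node (three-point formula)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(0.0, lk)
        root.add(nodes[k])
    return Tree(root)


def two_taxon_tree(dm: DistanceMatrix) -> Tree:
    """Trivial single-edge tree for a 2-sample input."""
    if len(dm.labels) != 2:
        raise Snp2TreeError("two_taxon_tree needs exactly 2 taxa")
    root = Node()
    root.add(Node(dm.labels[0], dm.d[0, 1] / 2.0))
    root.add(Node(dm.labels[1], dm.d[0, 1] / 2.0))
    return Tree(root)
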