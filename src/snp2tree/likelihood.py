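"""Felsenstein-pruning likelihood, branch-length optimization, NNI search.

The likelihood of a tree given an IUPAC alignment is computed by the
pruning algorithm: per-site conditional (partial) likelihood vectors are
combined post-order, with leaf vectors set to indicators for unambiguous
bases and to the compatibility mask for ambiguity codes (a heterozygote
code R is treated as the partial observation "A or G"; N as "any").
Identical alignment columns are collapsed into weighted patterns first.

Branch lengths are fitted coordinate-wise: for each edge, the likelihood
as a function of that edge's length alone is L(t) = sum_i S_i (P(t) D)_i
per pattern, where D is the post-order partial below the edge and S the
pi-weighted partial of everything above it, and the scalar t is found by
bounded Brent search.  Sweeps repeat until the log-likelihood gain drops
below a tolerance.  The optional topology search evaluates both
nearest-neighbor-interchange alternatives around every internal edge and
accepts strictly improving moves until a local optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .encode import ALPHABET, SYMBOL_BASES, Alignment
from .errors import LikelihoodError
from .models import BASES, SubstitutionModel
from .tree import Node, Tree

#: Branch-length optimization defaults (substitutions/site, log-units).
B_MAX = 10.0
LL_TOL = 1e-6
MAX_SWEEPS = 20

_LEAF_PARTIALS = np.zeros((len(ALPHABET), 4))
for _i, _sym in enumerate(ALPHABET):
    for _b in SYMBOL_BASES[_sym]:
        _LEAF_PARTIALS[_i, BASES.index(_b)] = 1.0


def compress_patterns(al: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Collapse identical alignment columns.

    Returns (per-sample pattern codes, pattern weights): codes[s] is an
    int array over unique columns, weights the column multiplicities.
    """
    from .distance import encode_symbols

    mat = np.stack([encode_symbols(s) for s in al.sequences])  # samples x sites
    cols, counts = np.unique(mat, axis=1, return_counts=True)
    return ({name: cols[i] for i, name in enumerate(al.sample_ids)},
            counts.astype(np.float64))


class _Engine:
    """Shared state for likelihood computations on one (tree, alignment,
    model) triple.  The tree is mutated in place by the optimizers."""

    def __init__(self, tree: Tree, al: Alignment, model: SubstitutionModel,
                 codes: dict[str, np.ndarray] | None = None,
                 weights: np.ndarray | None = None):
        leaf_set = set(tree.leaf_labels())
        if leaf_set != set(al.sample_ids):
            missing = leaf_set ^ set(al.sample_ids)
            raise LikelihoodError(f"tree leaves and alignment samples differ: {sorted(missing)}")
        self.tree = tree
        self.model = model
        if codes is None:
            codes, weights = compress_patterns(al)
        self.codes = codes
        self.weights = weights
        self.pi = model.base_frequencies

    # ------------------------------------------------------ passes
    def _down(self) -> dict[Node, np.ndarray]:
        """Post-order partials: down[v][p, i] = P(data below v | state i at v)."""
        down: dict[Node, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                down[node] = _LEAF_PARTIALS[self.codes[node.label]]
            else:
                acc = None
                for c in node.children:
                    P = self.model.transition_matrix(c.length)
                    contrib = down[c] @ P.T
                    acc = contrib if acc is None else acc * contrib
                down[node] = acc
        return down

    def _up(self, down: dict[Node, np.ndarray]) -> dict[Node, np.ndarray]:
        """Pre-order outside partials.

        S[v][p, i] = pi_i * P(data outside subtree(v) | state i at
        parent(v)), so the site likelihood factors through edge v as
        sum_i S[v]_i (P(t_v) down[v])_i.
        """
        npat = len(self.weights)
        A: dict[Node, np.ndarray] = {self.tree.root: np.ones((npat, 4))}
        S: dict[Node, np.ndarray] = {}
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            contribs = []
            for c in node.children:
                P = self.model.transition_matrix(c.length)
                contribs.append(down[c] @ P.T)
            for k, c in enumerate(node.children):
                other = A[node].copy()
                for kk, contrib in enumerate(contribs):
                    if kk != k:
                        other *= contrib
                S[c] = other * self.pi
                if not c.is_leaf:
                    A[c] = other @ self.model.transition_matrix(c.length)
        return S

    # -------------------------------------------------- likelihood
    def log_likelihood(self) -> float:
        down = self._down()
        site_l = down[self.tree.root] @ self.pi
        if (site_l <= 0).any() or not np.isfinite(site_l).all():
            raise LikelihoodError("non-positive or non-finite site likelihood")
        return float(np.log(site_l) @ self.weights)

    def _edge_ll(self, S_v: np.ndarray, down_v: np.ndarray, t: float) -> float:
        P = self.model.transition_matrix(t)
        site_l = np.einsum("pi,ij,pj->p", S_v, P, down_v)
        if (site_l <= 0).any() or not np.isfinite(site_l).all():
            return -np.inf
        return float(np.log(site_l) @ self.weights)

    # ------------------------------------------------ optimization
    def optimize_branch_lengths(self, tol: float = LL_TOL, max_sweeps: int = MAX_SWEEPS,
                                b_max: float = B_MAX) -> float:
        """Coordinate-ascent sweeps over all edges; returns final lnL.
        The log-likelihood trace across sweeps is non-decreasing."""
        current = self.log_likelihood()
        for _ in range(max_sweeps):
            start = current
            for v in self.tree.edges():
                down = self._down()
                S = self._up(down)
                f = lambda t: -self._edge_ll(S[v], down[v], t)
                res = minimize_scalar(f, bounds=(0.0, b_max), method="bounded",
                                      options={"xatol": 1e-8})
                if not np.isfinite(res.fun):
                    raise LikelihoodError(
                        f"non-finite likelihood optimizing edge above "
                        f"{v.label or 'an internal node'}")
                best_t, best_ll = float(res.x), -res.fun
                at_zero = -f(0.0)  # bounded Brent cannot reach the boundary
                if at_zero >= best_ll:
                    best_t, best_ll = 0.0, at_zero
                if best_ll > current:
                    v.length = best_t
                    current = best_ll
            if current - start < tol:
                break
        self.tree.log_likelihood = current
        return current


def log_likelihood(tree: Tree, al: Alignment, model: SubstitutionModel) -> float:
    """Pruning-algorithm log-likelihood with site-pattern compression."""
    return _Engine(tree, al, model).log_likelihood()


def optimize_branch_lengths(tree: Tree, al: Alignment, model: SubstitutionModel,
                            tol: float = LL_TOL, max_sweeps: int = MAX_SWEEPS,
                            b_max: float = B_MAX) -> Tree:
    """Fit branch lengths by per-edge bounded scalar ascent (tree copied,
    input left untouched); the returned tree carries its log-likelihood."""
    out = tree.copy()
    _Engine(out, al, model).optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps, b_max=b_max)
    return out


# ------------------------------------------------------------- NNI

def _nni_alternatives(tree: Tree, edge_child: Node) -> list[Tree]:
    """The two NNI rearrangements around one internal edge.

    The tree is re-hung at the edge's parent so both of its other
    neighbors are children; each alternative swaps one child of the edge
    child with one of those neighbors.
    """
    alts = []
    for swap_idx in (0, 1):
        t = tree.rerooted_at(edge_child.parent)
        # find the corresponding edge child in the copy via its leaf set
        target = _find_by_leafset(t, _leafset(edge_child))
        u = target.parent
        neighbors = [c for c in u.children if c is not target]
        x = target.children[swap_idx]
        y = neighbors[0]
        # swap x and y between target and u
        target.children[swap_idx] = y
        u.children[u.children.index(y)] = x
        x.parent, y.parent = u, target
        alts.append(t)
    return alts


def _leafset(node: Node) -> frozenset[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return frozenset(out)


def _find_by_leafset(tree: Tree, leafset: frozenset[str]) -> Node:
    total = frozenset(tree.leaf_labels())
    for n in tree.postorder():
        if n.parent is None or n.is_leaf:
            continue
        if _leafset(n) in (leafset, total - leafset):
            return n
    raise LikelihoodError("internal edge not found after rerooting")


def nni_search(tree: Tree, al: Alignment, model: SubstitutionModel,
               tol: float = LL_TOL, candidate_sweeps: int = 3,
               max_rounds: int = 20) -> Tree:
    """Hill-climbing NNI: evaluate both alternatives at every internal
    edge (with branch-length re-optimization), take the best strictly
    improving move, repeat until a local optimum."""
    codes, weights = compress_patterns(al)
    best = tree.copy()
    eng = _Engine(best, al, model, codes, weights)
    best_ll = eng.optimize_branch_lengths()
    for _ in range(max_rounds):
        champion = None
        champion_ll = best_ll
        for edge in best.internal_edges():
            for alt in _nni_alternatives(best, edge):
                ll = _Engine(alt, al, model, codes, weights).optimize_branch_lengths(
                    max_sweeps=candidate_sweeps)
                if ll > champion_ll + 1e-9:
                    champion, champion_ll = alt, ll
        if champion is None:
            break
        best = champion
        best_ll = _Engine(best, al, model, codes, weights).optimize_branch_lengths()
    best.log_likelihood = best_ll
    return best
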