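"""Felsenstein pruning likelihood, branch optimization, NNI search."""

import itertools

import numpy as np
import pytest

import snp2tree as st
from snp2tree.encode import SYMBOL_BASES
from snp2tree.errors import LikelihoodError
from snp2tree.likelihood import compress_patterns
from snp2tree.models import BASES
from snp2tree.simulate import simulate_alignment


def brute_force_ll(tree, al, model):
    """Independent oracle: explicit sum over all internal-node state
    assignments; leaf contributions sum over the bases compatible with
    the observed IUPAC symbol."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    seqs = dict(zip(al.sample_ids, al.sequences))
    pi = model.base_frequencies
    P = {id(n): model.transition_matrix(n.length) for n in nodes if n.parent is not None}
    total = 0.0
    for col in range(al.n_sites):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip(map(id, internals), assign))
            p = pi[amap[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                if n.is_leaf:
                    compat = [BASES.index(b) for b in SYMBOL_BASES[seqs[n.label][col]]]
                    p *= sum(P[id(n)][amap[id(n.parent)], b] for b in compat)
                else:
                    p *= P[id(n)][amap[id(n.parent)], amap[id(n)]]
            site += p
        total += np.log(site)
    return total


def random_alignment(labels, n_sites, rng, alphabet="ACGTRYN"):
    return st.Alignment(list(labels),
                        ["".join(rng.choice(list(alphabet), n_sites)) for _ in labels], [])


MODELS = [st.jc69(), st.f81([0.1, 0.2, 0.3, 0.4]), st.f84([0.3, 0.2, 0.3, 0.2], kappa=2.0)]


class TestLogLikelihood:
    def test_single_site_zero_branches_gives_stationary_frequency(self):
        t = st.parse_newick("((a:0,b:0):0,c:0,d:0);")
        al = st.Alignment(list("abcd"), ["A"] * 4, [])
        assert st.log_likelihood(t, al, st.jc69()) == pytest.approx(np.log(0.25))

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.name)
    def test_matches_brute_force_enumeration(self, model):
        rng = np.random.default_rng(2024)
        for n_taxa in (3, 4, 5):
            for rep in range(3):
                t = st.simulate_tree(n_taxa, int(rng.integers(2**31)))
                for e in t.edges():
                    e.length = float(rng.uniform(0.01, 0.9))
                al = random_alignment(t.leaf_labels(), int(rng.integers(1, 4)), rng)
                mine = st.log_likelihood(t, al, model)
                oracle = brute_force_ll(t, al, model)
                assert abs(mine - oracle) / abs(oracle) < 1e-10

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.name)
    def test_rerooting_invariance(self, model):
        rng = np.random.default_rng(5)
        t = st.simulate_tree(7, 5)
        al = random_alignment(t.leaf_labels(), 30, rng)
        ref = st.log_likelihood(t, al, model)
        for node in [n for n in t.postorder() if not n.is_leaf]:
            assert abs(st.log_likelihood(t.rerooted_at(node), al, model) - ref) < 1e-8

    def test_pattern_compression_soundness(self):
        rng = np.random.default_rng(6)
        t = st.simulate_tree(6, 6)
        al = random_alignment(t.leaf_labels(), 60, rng, alphabet="ACGT")
        codes, weights = compress_patterns(al)
        assert weights.sum() == al.n_sites
        per_column = sum(
            st.log_likelihood(t, st.Alignment(al.sample_ids,
                                              [s[j] for s in al.sequences], []), st.jc69())
            for j in range(al.n_sites))
        assert st.log_likelihood(t, al, st.jc69()) == pytest.approx(per_column)

    def test_leaf_sample_mismatch(self):
        t = st.simulate_tree(4, 1)
        al = st.Alignment(["x", "y", "z", "w"], ["A", "C", "G", "T"], [])
        with pytest.raises(LikelihoodError, match="differ"):
            st.log_likelihood(t, al, st.jc69())


class TestOptimizeBranchLengths:
    def test_ascent_and_fixed_point(self):
        t = st.simulate_tree(6, 11)
        al = simulate_alignment(t, 1500, seed=11)
        m = st.jc69()
        before = st.log_likelihood(t, al, m)
        fit = st.optimize_branch_lengths(t, al, m)
        assert fit.log_likelihood >= before
        again = st.optimize_branch_lengths(fit, al, m)
        assert again.log_likelihood - fit.log_likelihood < 1e-4
        for a, b in zip(fit.edges(), again.edges()):
            assert b.length == pytest.approx(a.length, abs=1e-3)

    def test_perturbed_edge_recovered(self):
        t = st.simulate_tree(8, 7)
        al = simulate_alignment(t, 10_000, seed=7)
        work = t.copy()
        edges = work.internal_edges()
        target = max(edges, key=lambda e: e.length)
        generating = target.length
        target.length = 3.0 * generating
        fit = st.optimize_branch_lengths(work, al, st.jc69())
        est = fit.internal_edges()[edges.index(target)].length
        assert est == pytest.approx(generating, rel=0.10)

    def test_input_tree_untouched(self):
        t = st.simulate_tree(5, 3)
        al = simulate_alignment(t, 200, seed=3)
        lengths = [e.length for e in t.edges()]
        st.optimize_branch_lengths(t, al, st.jc69())
        assert [e.length for e in t.edges()] == lengths


class TestNNISearch:
    def _nni_neighbor(self, tree):
        from snp2tree.likelihood import _nni_alternatives
        edge = tree.internal_edges()[0]
        return _nni_alternatives(tree, edge)[0]

    def test_returns_to_generating_topology(self):
        true = st.simulate_tree(8, 11)
        al = simulate_alignment(true, 5_000, seed=11)
        start = self._nni_neighbor(true)
        assert start.rf_distance(true) > 0
        found = st.nni_search(start, al, st.jc69())
        assert found.rf_distance(true) == 0

    def test_no_move_accepted_at_optimum(self):
        true = st.simulate_tree(7, 12)
        al = simulate_alignment(true, 4_000, seed=12)
        m = st.jc69()
        found = st.nni_search(true, al, m)
        assert found.rf_distance(true) == 0

    def test_ascent_contract(self):
        true = st.simulate_tree(6, 13)
        al = simulate_alignment(true, 800, seed=13)
        m = st.jc69()
        start = self._nni_neighbor(true)
        before = st.log_likelihood(start, al, m)
        after = st.nni_search(start, al, m)
        assert after.log_likelihood >= before
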