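"""Composite-LD r² and greedy window pruning."""

import numpy as np
import pytest

import snp2tree as st
from snp2tree.matrix import MISSING as M


def reference_r2(d1, d2, min_shared=2):
    """Independent oracle: textbook Pearson correlation (sum formulas)
    over complete cases, squared."""
    pairs = [(a, b) for a, b in zip(d1, d2) if a != M and b != M]
    n = len(pairs)
    if n < min_shared:
        return None
    x = [float(a) for a, _ in pairs]
    y = [float(b) for _, b in pairs]
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    if vx <= 1e-12 or vy <= 1e-12:
        return None
    r = (sxy - sx * sy / n) / (vx * vy) ** 0.5
    return r * r


class TestCompositeR2:
    def test_self_correlation(self):
        d = [0, 1, 2, 2, 0]
        assert st.composite_r2(d, d) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert st.composite_r2([0, 0, 2, 2], [2, 2, 0, 0]) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        d1, d2 = [0, 1, 2, 0, 1, 2], [0, 2, 1, 1, 0, 2]
        assert st.composite_r2(d1, d2) == pytest.approx(reference_r2(d1, d2), abs=1e-12)

    def test_constant_vector_undefined(self):
        assert st.composite_r2([0, 1, 2, 0], [1, 1, 1, 1]) is None

    def test_too_few_shared_undefined(self):
        assert st.composite_r2([0, M, M, 1], [M, 1, 2, M]) is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            st.composite_r2([0, 1], [0, 1, 2])

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(150):
            n = int(rng.integers(4, 21))
            d1 = rng.integers(0, 3, n)
            d2 = rng.integers(0, 3, n)
            d1[rng.random(n) < 0.15] = M
            d2[rng.random(n) < 0.15] = M
            mine = st.composite_r2(d1, d2)
            ref = reference_r2(list(d1), list(d2))
            if ref is None:
                assert mine is None
            else:
                assert mine == pytest.approx(ref, abs=1e-12)
                checked += 1
        assert checked >= 100


def gm_with_positions(columns, positions, chrom="chr1"):
    cols = np.array(columns, dtype=np.int8).T
    sites = [st.SiteRecord(chrom, p, f"{chrom}:{p}", "A", "G") for p in positions]
    return st.GenotypeMatrix([f"x{i}" for i in range(cols.shape[0])], sites, cols)


class TestPruneChromosome:
    def test_duplicate_site_removed(self):
        col = [0, 1, 2, 2, 0, 1]
        gm = gm_with_positions([col, col], [1000, 2000])
        kept = st.prune_chromosome(gm, "chr1", st.LDConfig(ld_threshold=0.5, window_bp=10_000))
        assert kept == [0]

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(3)
        cols = [list(rng.integers(0, 3, 8)) for _ in range(6)]
        gm = gm_with_positions(cols, [1000 * (i + 1) for i in range(6)])
        kept = st.prune_chromosome(gm, "chr1", st.LDConfig(ld_threshold=1.0, window_bp=10_000))
        assert kept == list(range(6))

    def test_out_of_window_pair_never_compared(self):
        col = [0, 1, 2, 2, 0, 1]
        gm = gm_with_positions([col, col], [1000, 900_000])
        kept = st.prune_chromosome(gm, "chr1", st.LDConfig(ld_threshold=0.1, window_bp=500_000))
        assert kept == [0, 1]

    def test_absent_chromosome(self):
        gm = gm_with_positions([[0, 1, 2]], [100])
        with pytest.raises(KeyError):
            st.prune_chromosome(gm, "chrX", st.LDConfig())


class TestPruneAll:
    def test_one_site_per_noise_free_block(self):
        tree = st.simulate_tree(10, 2)
        gm, truth = st.simulate_genotypes(tree, st.SimConfig(
            n_taxa=10, n_sites=500, ld_block_size=50, seed=2))
        pruned, report = st.prune_all(gm, st.LDConfig(ld_threshold=0.1))
        # duplicate columns give r^2 = 1 inside each block; blocks are
        # separated by more than the window
        assert pruned.n_sites == 10
        kept_pos = {(s.chrom, s.pos) for s in pruned.sites}
        for start, stop in truth.block_bounds:
            block = {(gm.sites[j].chrom, gm.sites[j].pos) for j in range(start, stop)}
            assert len(block & kept_pos) == 1

    def test_independent_sites_survive_near_ceiling_threshold(self):
        rng = np.random.default_rng(11)
        cols = [list(rng.integers(0, 3, 50)) for _ in range(20)]
        gm = gm_with_positions(cols, [1000 * (i + 1) for i in range(20)])
        pruned, _ = st.prune_all(gm, st.LDConfig(ld_threshold=0.99, window_bp=10**6))
        assert pruned.n_sites == 20

    def test_empty_matrix(self):
        gm = st.GenotypeMatrix(["a", "b"], [], np.zeros((2, 0), np.int8))
        pruned, report = st.prune_all(gm, st.LDConfig())
        assert pruned.n_sites == 0 and report.removed == []

    def test_post_prune_audit(self):
        # after pruning, no retained within-window pair exceeds the threshold
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_sites = 40
            cols = [list(rng.integers(0, 3, 12)) for _ in range(n_sites)]
            for c in cols:
                for i in range(len(c)):
                    if rng.random() < 0.1:
                        c[i] = M
            gm = gm_with_positions(cols, [500 * (i + 1) for i in range(n_sites)])
            cfg = st.LDConfig(ld_threshold=0.3, window_bp=2_000)
            pruned, _ = st.prune_all(gm, cfg)
            pos = [s.pos for s in pruned.sites]
            for i in range(pruned.n_sites):
                for j in range(i + 1, pruned.n_sites):
                    if pos[j] - pos[i] <= cfg.window_bp:
                        r2 = st.composite_r2(pruned.calls[:, i], pruned.calls[:, j])
                        assert r2 is None or r2 <= cfg.ld_threshold

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        cols = [list(rng.integers(0, 3, 10)) for _ in range(30)]
        gm = gm_with_positions(cols, [400 * (i + 1) for i in range(30)])
        counts = []
        for thr in (0.05, 0.2, 0.5, 0.9, 1.0):
            pruned, _ = st.prune_all(gm, st.LDConfig(ld_threshold=thr, window_bp=10_000))
            counts.append(pruned.n_sites)
        assert counts == sorted(counts)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        cols = [list(rng.integers(0, 3, 10)) for _ in range(25)]
        gm = gm_with_positions(cols, [300 * (i + 1) for i in range(25)])
        a, _ = st.prune_all(gm, st.LDConfig(ld_threshold=0.3, window_bp=5_000))
        b, _ = st.prune_all(gm, st.LDConfig(ld_threshold=0.3, window_bp=5_000))
        assert a.equals(b)

    def test_report_lists_blocking_partner(self, tmp_path):
        col = [0, 1, 2, 2, 0, 1]
        gm = gm_with_positions([col, col], [1000, 2000])
        _, report = st.prune_all(gm, st.LDConfig(ld_threshold=0.5, window_bp=10_000))
        assert report.removed == [("chr1:2000", "chr1:1000", pytest.approx(1.0))]
        report.to_tsv(tmp_path / "pruned.tsv")
        assert "blocking_site_id" in (tmp_path / "pruned.tsv").read_text()
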