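"""Synthetic diploid SNP datasets with known ground truth.

Genotypes are evolved on a known (or random) tree so that every pipeline
stage — filtering, LD pruning, encoding, tree inference, bootstrap — can
be tested against the generating truth without any external download.

Model: each site draws an ancestral base at the root; two gene copies
per taxon evolve independently down the tree under JC69 (so derived taxa
can be heterozygous, as in an outcrossing diploid; ``inbred=True``
duplicates a single copy instead, giving fully homozygous lines as in
selfing panels).  Sites whose leaf alleles are not biallelic, or whose
minor allele frequency falls below ``maf_floor``, are rejected and
redrawn.  Linkage disequilibrium is induced mechanically: each kept site
is duplicated into ``ld_block_size`` adjacent columns (optionally with
per-copy genotype noise), giving blocks of within-block r² near 1 with
exactly known boundaries.  Missing calls are injected uniformly at
``missing_rate``; positions are laid out with fixed spacing on one or
more synthetic chromosomes so window-based pruning is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import Snp2TreeError
from .matrix import MISSING, GenotypeMatrix, SiteRecord
from .models import BASES, jc69
from .tree import Node, Tree

#: Branch lengths of random trees: MIN_BRANCH + Exp(MEAN_BRANCH - MIN_BRANCH).
#: The floor keeps internal edges above the resolution limit of the
#: alignment sizes used for validation; edges shorter than ~1/sqrt(n_sites)
#: are statistically unresolvable at finite data regardless of method.
MEAN_BRANCH = 0.05
MIN_BRANCH = 0.01
#: Gap between successive independent sites/blocks: larger than typical
#: pruning windows, since independently simulated sites are in linkage
#: equilibrium and real equilibrium sites lie beyond the LD decay scale.
BLOCK_GAP_BP = 1_000_000
#: Spacing of the tightly linked copies inside one LD block.
WITHIN_BLOCK_BP = 100
#: Synthetic chromosomes are capped at a plant-like span.
MAX_CHROM_SPAN_BP = 100_000_000
_RETRY_FACTOR = 200


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    n_sites counts output columns (after LD-block duplication);
    ld_block_size consecutive columns share one underlying site.
    maf_floor drives rejection sampling of the underlying sites;
    missing_rate injects no-calls uniformly at random.
    """

    n_taxa: int = 10
    n_sites: int = 1_000
    ld_block_size: int = 1
    ld_block_noise: float = 0.0
    missing_rate: float = 0.0
    maf_floor: float = 0.05
    inbred: bool = False
    #: None = split into as many ~100 Mb chromosomes as needed.
    n_chromosomes: int | None = None
    block_gap_bp: int = BLOCK_GAP_BP
    within_block_bp: int = WITHIN_BLOCK_BP
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.ld_block_size * self.within_block_bp >= self.block_gap_bp:
            raise ValueError("block_gap_bp must exceed the span of one block "
                             "(ld_block_size * within_block_bp)")


@dataclass
class GroundTruth:
    """What the generator knows: the tree and the LD-block layout."""

    tree: Tree
    newick: str
    #: [start, stop) column index of each LD block.
    block_bounds: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"newick": self.newick, "block_bounds": self.block_bounds}, fh)


def simulate_tree(n_taxa: int, seed: int, mean_branch: float = MEAN_BRANCH,
                  min_branch: float = MIN_BRANCH) -> Tree:
    """Random binary unrooted topology by iterated random joins; branch
    lengths are min_branch + exponential (overall mean = mean_branch).
    Seed-deterministic; min_branch=0 gives a plain exponential."""
    if n_taxa < 2:
        raise Snp2TreeError("n_taxa must be >= 2")
    if not 0 <= min_branch < mean_branch:
        raise Snp2TreeError("need 0 <= min_branch < mean_branch")
    rng = np.random.default_rng(seed)
    draw = lambda: float(min_branch + rng.exponential(mean_branch - min_branch))
    width = len(str(n_taxa))
    nodes = [Node(f"t{i + 1:0{width}d}") for i in range(n_taxa)]
    if n_taxa == 2:
        root = Node()
        for n in nodes:
            n.length = draw()
            root.add(n)
        return Tree(root)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        for n in (nodes[i], nodes[j]):
            n.length = draw()
            parent.add(n)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        n.length = draw()
        root.add(n)
    return Tree(root)


def _evolve_copies(tree: Tree, n_sites: int, rng: np.random.Generator,
                   inbred: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Evolve 2 gene copies per leaf for n_sites independent sites under
    JC69.  Returns (roots, leaf_states, leaf_labels); leaf_states has
    shape (n_leaves, 2, n_sites) of base indices."""
    n_copies = 1 if inbred else 2
    roots = rng.integers(0, 4, size=n_sites)
    states: dict[Node, np.ndarray] = {tree.root: np.tile(roots, (n_copies, 1))}
    leaves: list[Node] = []
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            parent_state = states[node.parent]
            # exact JC69: with prob e^(-4t/3) no event, else uniform redraw
            stay = np.exp(-4.0 * node.length / 3.0)
            redraw = rng.random(parent_state.shape) >= stay
            new = parent_state.copy()
            new[redraw] = rng.integers(0, 4, size=int(redraw.sum()))
            states[node] = new
        if node.is_leaf:
            leaves.append(node)
    leaf_states = np.stack([states[n] for n in leaves])  # (L, copies, sites)
    if inbred:
        leaf_states = np.repeat(leaf_states, 2, axis=1)
    return roots, leaf_states, [n.label for n in leaves]


def simulate_genotypes(tree: Tree, sim: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Evolve a diploid genotype matrix on a tree; see the module docstring
    for the generative model.  Deterministic for a fixed SimConfig."""
    rng = np.random.default_rng(sim.seed)
    n_blocks = -(-sim.n_sites // sim.ld_block_size)

    kept_dosage: list[np.ndarray] = []   # each (n_taxa,) batch of columns
    kept_ref: list[np.ndarray] = []
    kept_alt: list[np.ndarray] = []
    n_kept = 0
    labels: list[str] | None = None
    attempts = 0
    while n_kept < n_blocks:
        attempts += 1
        if attempts > _RETRY_FACTOR:
            raise Snp2TreeError(
                f"rejection sampling exhausted after {attempts} batches; "
                f"lower maf_floor (currently {sim.maf_floor})")
        batch = max(256, 2 * (n_blocks - n_kept))
        roots, leaf_states, labels = _evolve_copies(tree, batch, rng, sim.inbred)
        n_taxa = leaf_states.shape[0]
        # per-site allele accounting, vectorized over the batch
        counts = np.stack([(leaf_states == b).sum(axis=(0, 1)) for b in range(4)])
        cols = np.arange(batch)
        n_observed = (counts > 0).sum(axis=0)
        root_present = counts[roots, cols] > 0
        masked = counts.copy()
        masked[roots, cols] = 0
        alt = masked.argmax(axis=0)                       # non-root observed base
        # monomorphic-at-root sites have MAF 0 and no real alternate;
        # synthesize one so that ref != alt (kept only when maf_floor <= 0)
        mono = n_observed == 1
        alt[mono] = (roots[mono] + 1 + rng.integers(0, 3, size=int(mono.sum()))) % 4
        dosage = (leaf_states == alt[None, None, :]).sum(axis=1).astype(np.int8)
        f = dosage.sum(axis=0) / (2.0 * n_taxa)
        keep = (n_observed <= 2) & root_present & (np.minimum(f, 1.0 - f) >= sim.maf_floor)
        sel = np.flatnonzero(keep)[: n_blocks - n_kept]
        if sel.size:
            kept_dosage.append(dosage[:, sel])
            kept_ref.append(roots[sel])
            kept_alt.append(alt[sel])
            n_kept += sel.size

    base = np.concatenate(kept_dosage, axis=1)            # (n_taxa, n_blocks)
    base_ref = np.concatenate(kept_ref)
    base_alt = np.concatenate(kept_alt)

    # expand blocks: each kept site fills ld_block_size adjacent columns
    calls = np.repeat(base, sim.ld_block_size, axis=1)[:, : sim.n_sites]
    refs = np.repeat(base_ref, sim.ld_block_size)[: sim.n_sites]
    alts = np.repeat(base_alt, sim.ld_block_size)[: sim.n_sites]
    block_bounds = [(b * sim.ld_block_size, min((b + 1) * sim.ld_block_size, sim.n_sites))
                    for b in range(n_blocks)]
    if sim.ld_block_noise > 0 and sim.ld_block_size > 1:
        flip = rng.random(calls.shape) < sim.ld_block_noise
        calls = calls.copy()
        calls[flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.int8)

    if sim.missing_rate > 0:
        miss = rng.random(calls.shape) < sim.missing_rate
        calls[miss] = MISSING

    # positions: blocks spread block_gap_bp apart (linkage equilibrium
    # between blocks), members within_block_bp apart inside each block;
    # whole blocks are split across chromosomes
    if sim.n_chromosomes is None:
        per_chrom_blocks = min(n_blocks, max(1, MAX_CHROM_SPAN_BP // sim.block_gap_bp))
    else:
        per_chrom_blocks = -(-n_blocks // sim.n_chromosomes)
        if per_chrom_blocks * sim.block_gap_bp > 2**31 - 1:
            raise Snp2TreeError(
                "chromosome span would overflow 32-bit coordinates; "
                "raise n_chromosomes or lower block_gap_bp")
    sites = []
    for j in range(sim.n_sites):
        bi, k = divmod(j, sim.ld_block_size)
        chrom = f"chr{bi // per_chrom_blocks + 1}"
        local_block = bi % per_chrom_blocks
        pos = local_block * sim.block_gap_bp + k * sim.within_block_bp + 1
        sites.append(SiteRecord(chrom, pos, f"{chrom}:{pos}", BASES[refs[j]], BASES[alts[j]]))

    gm = GenotypeMatrix(list(labels), sites, calls)
    truth = GroundTruth(tree=tree, newick=tree.to_newick(), block_bounds=block_bounds)
    return gm, truth


def simulate_alignment(tree: Tree, n_sites: int, seed: int, model=None):
    """Evolve plain (haploid) nucleotide sequences on a tree, with no SNP
    ascertainment: every site is kept, monomorphic or not.

    SNP genotype data keep only segregating biallelic sites, which
    discards multi-hit columns and systematically compresses estimated
    branch lengths; this unfiltered simulator is the right input for
    validating the likelihood machinery itself (branch-length recovery,
    topology search), while :func:`simulate_genotypes` exercises the
    genotype pipeline.
    """
    from .encode import Alignment
    from .models import BASES as _B

    if model is None:
        model = jc69()
    rng = np.random.default_rng(seed)
    root_states = rng.choice(4, size=n_sites, p=model.base_frequencies)
    states: dict[Node, np.ndarray] = {tree.root: root_states}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = model.transition_matrix(node.length)
        cdf = P.cumsum(axis=1)
        parent = states[node.parent]
        u = rng.random(n_sites)
        new = np.empty(n_sites, dtype=np.int64)
        for s in range(4):
            sel = parent == s
            new[sel] = np.searchsorted(cdf[s], u[sel], side="right")
        states[node] = np.minimum(new, 3)
    leaves = tree.leaves()
    seqs = ["".join(_B[i] for i in states[n]) for n in leaves]
    return Alignment([n.label for n in leaves], seqs, [])


def write_fixture(gm: GenotypeMatrix, fmt: str, path: str | Path) -> None:
    """Write a matrix in one of the reader dialects (vcf/hapmap/simple)."""
    from . import io as gio

    writers = {"vcf": gio.write_vcf, "hapmap": gio.write_hapmap, "simple": gio.write_simple}
    if fmt not in writers:
        raise Snp2TreeError(f"unsupported fixture format {fmt!r}; choose vcf, hapmap or simple")
    writers[fmt](gm, path)
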