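# Methods

This note documents the models and procedures behind `snp2tree`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Pipeline overview

A run executes six stages; a JSON manifest records the site count
entering and leaving each one (the counts must be conserved between
consecutive stages, which the pipeline asserts):

1. **Parse** — VCF (GT subfield only), HapMap tabular (11 fixed columns
   + samples), simple tabular (chrom, pos, dosages), or the binary
   genotype cache. Only biallelic SNPs are kept; multiallelic records,
   indels and symbolic alleles are skipped and counted in a parse
   report. All readers normalize to alt-allele dosages {0, 1, 2} with a
   missing marker and sort sites by (chromosome, position).
2. **Qualify** — per-site missing-rate ceiling, then MAF floor, so that
   every removal has a single attributed cause. A cache input skips
   stages 1–2: the cache stores an already-qualified matrix.
3. **LD-prune** — greedy per-chromosome scan (below).
4. **Encode** — one IUPAC pseudo-sequence per sample. Concatenated SNP
   genotypes are equal-length by construction, so the sequences form a
   multiple alignment without any alignment step; the pipeline asserts
   the equal-length invariant instead of invoking an aligner.
5. **Tree** — JC distance matrix → neighbor joining → per-edge ML
   branch lengths (optional NNI topology search).
6. **Bootstrap** — column resampling, replicate trees, bipartition
   supports.

## Site qualification

* Missing rate = fraction of samples without a call at the site;
  retained iff ≤ `max_missing_fraction` (CLI `-p`, a percentage at the
  CLI boundary only). Default 0.05.
* MAF = min(f, 1−f) where f is the alt-allele frequency counted over
  non-missing calls only (complete case, no imputation); retained iff
  ≥ `min_maf` (`-m`). Default 0.1. Both bounds are inclusive.
* A site with no calls at all has no defined MAF; such sites can only
  survive the missing-rate rule when the ceiling is 1.0, and are then
  attributed to the MAF rule (no data can never establish the floor).

## LD pruning

The LD measure is the composite r²: the squared Pearson correlation of
two sites' dosage vectors over samples where both are called. It
requires no haplotype phase and is the natural measure on genotype
matrices. r² is *undefined* when fewer than `min_shared` (default 2)
complete pairs exist or either vector is constant over them; undefined
pairs never cause removal — absence of evidence of linkage is not
evidence of linkage.

Pruning is a greedy left-to-right scan per chromosome: the first site
is retained, and each later site is kept iff its r² with **every**
already-retained site within `window_bp` upstream is ≤ `ld_threshold`.
Keep-first tie-breaking makes the result a pure function of input and
configuration. Defaults: `ld_threshold` 0.1, `window_bp` 500,000 —
both conventions rather than derived quantities, and both exposed
(`-l`, `--window-bp`).

A small-sample caveat worth knowing: between truly independent sites
the *sampled* r² has expectation ≈ 1/(n−1) for n samples, so with n
below ~12 the default 0.1 ceiling will also prune some unlinked sites
that happen to correlate by chance. That is a property of the
statistic, not a defect of the scan; raise `-l` for very small panels.

## Sequence encoding

Dosage 0 → ref base, 2 → alt base, missing → N, and a heterozygote →
the two-base IUPAC ambiguity code of {ref, alt} (R=A/G, Y=C/T, S=C/G,
W=A/T, K=G/T, M=A/C). The encoding is lossless given ref/alt: decoding
a column with its site record recovers the dosage exactly. The
alternative conventions (random-allele draw, major-allele collapse)
discard the heterozygosity signal and were rejected.

Outputs: FASTA with original sample ids, and sequential PHYLIP with
strict 10-character names for PHYLIP-suite interoperability. Names that
fit and stay unique are padded; the rest get collision-proof aliases
(`s0001`, ...) with a TSV mapping written next to the alignment.

The *simple* input format carries no nucleotide identities, so its
reader synthesizes placeholder alleles ref=A/alt=G; downstream
sequences are internally consistent but their letters are not real
nucleotides. The format itself (chrom, pos, one dosage column per
sample, optional header naming samples) is this package's
reconstruction of a common minimal dialect and is documented here
precisely because no external standard pins it down.

## Distances and neighbor joining

Pairwise mismatch fraction p is computed over columns where neither
symbol is N. Symbols are scored by expected mismatch under one random
allele draw per genotype: identical symbols 0; het vs compatible
homozygote 0.5; disjoint symbols 1. p maps to substitutions/site by the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p at or beyond the
0.75 domain boundary (minus 1e-6) is capped at d = 5.0 (configurable)
to keep the matrix finite.

Neighbor joining is the classical Saitou–Nei algorithm with Q-matrix
selection. Ties in Q (e.g. ultrametric inputs) are broken by the
lexicographically smallest label pair, a cluster being identified by
the smallest leaf label it contains — deterministic and order-stable.
Negative intermediate branch lengths are clamped to zero with the
deficit shifted to the sibling edge, preserving the pair distance. NJ
is exact on additive matrices (validated to 1e-9 in the tests). Two
samples are handled as a trivial single-edge tree.

## Likelihood

Models: JC69 (default), F81, F84 — DNAML's family. Each model's rate
matrix is scaled to one expected substitution per site per unit branch
length; P(t) = exp(Qt) is computed from a spectral decomposition of the
π-symmetrized rate matrix (reversible ⇒ real spectrum), so each
evaluation is a 4×4 reconstruction. For F81/F84, base frequencies are
counted empirically from the alignment (ambiguity codes contribute half
counts, N nothing); F84's κ is fixed by configuration (default 2.0),
not optimized — this keeps every optimization one-dimensional and is a
documented divergence from DNAML's joint estimation.

The likelihood is Felsenstein's pruning algorithm over site patterns
(identical columns collapsed and weighted). Leaf partial vectors are
indicators for A/C/G/T and compatibility masks for ambiguity codes: a
heterozygote R enters as the partial observation "this sequence carries
A or G". Because all models are reversible, the likelihood is invariant
under the choice of traversal root (verified to 1e-8; the Newick
serialization's rooting is cosmetic).

Branch lengths are fitted coordinate-wise. For an edge e the site
likelihood factors as Σᵢ Sᵢ (P(t) D)ᵢ with D the post-order partial
below e and S the π-weighted partial of everything above it, so the
1-D profile is cheap; each edge is optimized by bounded Brent search on
[0, 10] substitutions/site (the boundary t = 0 is evaluated explicitly,
since bounded Brent cannot reach it), and sweeps repeat until the gain
is below 1e-6 log-units or 20 sweeps. Updates are accepted only if they
improve the total, making the log-likelihood trace non-decreasing by
construction.

The optional NNI search evaluates both nearest-neighbor interchanges at
every internal edge, re-optimizing candidate branch lengths with a
reduced sweep budget (3), accepts the best strictly improving move
(ΔlnL > 1e-9), re-optimizes fully, and repeats until a local optimum.
It is off by default: the NJ starting tree is already consistent, and
the search multiplies run time by the edge count.

No numerical scaling of partial products is performed; with float64
this is safe to roughly 300 taxa, far beyond the intended panel sizes
(tens of samples).

## Bootstrap

Replicate r resamples alignment columns with replacement (column count
preserved) using `numpy.random.default_rng([seed, r])` — a
deterministic per-replicate stream, so results are independent of
execution order and byte-reproducible for a fixed seed. Each replicate
tree is rebuilt by the same distance+NJ route as the main tree
(optionally NNI-refined, or with full ML branch lengths via a flag;
distance replicates are the default, matching common distance-bootstrap
practice — per-replicate branch lengths do not affect bipartition
supports). The support of an internal edge is the integer percentage of
replicates containing its leaf bipartition; a binary unrooted tree on n
taxa has n−3 of them.

## The synthetic-data generator

The generator exists so every stage can be tested against known ground
truth without external data.

* **Genotypes** (`simulate_genotypes`): each site draws a uniform
  ancestral base; two gene copies per taxon evolve independently down
  the tree under JC69 (exact transition sampling), modeling an
  outcrossing diploid and producing realistic heterozygous calls;
  `inbred=True` duplicates a single copy instead (fully homozygous
  lines, as in selfing panels such as rice or soybean cultivars).
  Sites that are not biallelic-with-ancestral-allele at the leaves, or
  that fall below `maf_floor` (default 0.05), are rejected and redrawn;
  with `maf_floor=0`, monomorphic sites pass (MAF 0 ≥ 0) and receive a
  placeholder alternate allele.
* **LD structure** is mechanical, not coalescent: each kept site is
  duplicated into `ld_block_size` adjacent columns (optional per-copy
  noise), giving blocks with within-block r² = 1 and exactly known
  boundaries — directly assertable pruning targets.
* **Positions** are two-scale: block members sit 100 bp apart, while
  successive independent sites/blocks are 1 Mb apart, beyond the
  default pruning window. This is deliberate model consistency: the
  generator simulates sites in linkage *equilibrium*, and equilibrium
  sites on real genomes lie beyond the LD decay scale; placing them
  inside the window would misrepresent sampling noise as linkage.
  Chromosomes are capped at a plant-like ~100 Mb and split
  automatically unless `n_chromosomes` is pinned.
* **Random trees** (`simulate_tree`): random joins give a uniform-ish
  binary unrooted shape; branch lengths are 0.01 + Exp(0.04)
  substitutions/site (mean 0.05). The floor matters: edges shorter than
  about 1/√(sites) are statistically unresolvable at finite data, so an
  unfloored exponential (which puts ~25% of trees below that limit at
  the validation sizes used here) would make topology-recovery
  experiments measure data limits rather than correctness. With the
  floor, the full pipeline recovers the generating 8-taxon topology in
  20/20 seeded replicates at 5,000 sites.
* **Sequences** (`simulate_alignment`): unascertained nucleotide
  alignments under any of the implemented models, with every site kept.
  This is the right input for validating the likelihood machinery
  itself — see the ascertainment caveat below.

What the generator does **not** emulate: coalescent or recombination
processes, population structure beyond the tree, selection, genotyping
error models (missingness is uniform), or reference bias. Passing tests
therefore demonstrate algorithmic correctness under the stated
generative model, not robustness to every artifact of real
resequencing data.

## Ascertainment bias — a limitation users should know

SNP matrices contain only segregating biallelic sites. Fitting a
substitution model to such data compresses *all* branch-length
estimates, because the discarded sites (invariant ones, and multi-hit
sites showing >2 alleles) carry a disproportionate share of the
substitution signal: on generator defaults the fitted tree is uniformly
~20% shorter than the generating tree, and its likelihood genuinely
exceeds that of the generating lengths — no unbiased estimate is
recoverable from the ascertained data alone. Topology and support are
far more robust (the recovery experiments above all use ascertained
genotype data). Branch-length *recovery* is therefore validated on
unascertained `simulate_alignment` data, where a perturbed edge is
re-estimated within 1% at 10,000 sites. Treat branch lengths from
SNP-only alignments as relative, not absolute, divergences.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 100+ random matrices
(≤ 20 samples × ≤ 50 sites) for the r² oracle; 50 random additive
matrices (4–8 taxa) for NJ exactness; all-model brute-force likelihood
enumeration on 3–5 taxa × 1–3 sites; 10,000 sites for branch-length
recovery; 100–200 bootstrap replicates; 20 seeded replicates of
8 taxa × 5,000 sites for end-to-end topology recovery; and one
20-sample × 100,000-site end-to-end run. These sizes were chosen as the
smallest at which each property is sharply testable.

## Other defaults

| parameter | default | unit / domain | note |
|---|---|---|---|
| `-p` max missing | 5% | percent of samples | loosen (e.g. 25) for sparse data |
| `-m` MAF floor | 0.1 | allele frequency | inclusive bound |
| `-l` LD ceiling | 0.1 | r² | raise (e.g. 0.4) for high-LD genomes |
| `window_bp` | 500,000 | bp | pruning comparison window |
| `-b` bootstrap | 100 | replicates | 0 skips supports; studies often use 1,000 |
| model | JC69 | — | F81/F84 with empirical frequencies |
| `kappa` | 2.0 | — | F84 only, fixed (not optimized) |
| saturation cap | 5.0 | subst/site | JC distance at p ≥ 0.75 − 1e-6 |
| `b_max` | 10 | subst/site | branch-length search upper bound |
| NNI | off | — | `--nni` enables |

## Known limitations

* No rate heterogeneity (Γ), no GTR, no partitioned models.
* κ is fixed, not estimated; no model selection.
* Topology search is NJ + optional NNI; no SPR/TBR or global
  rearrangements. With informative data the NJ tree is already in the
  right basin, but pathological distance matrices can leave NNI at a
  local optimum.
* Trees are unrooted; displayed rooting is arbitrary.
* Genotype likelihoods (GL/PL), imputation, indels and bgzip/tabix
  random access are out of scope.
* The diploid heterozygote enters the likelihood as an ambiguous single
  observation ("A or G"), a composite-likelihood treatment of the
  two-copy reality; it is exact for homozygous (inbred) panels and a
  documented approximation otherwise.
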