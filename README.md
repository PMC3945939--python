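# snp2tree

Maximum-likelihood phylogenetic trees from large diploid SNP genotype
matrices — in one command, with the statistical hygiene the problem
needs.

## The problem

Resequencing projects routinely call millions of SNPs across dozens of
accessions, cultivars or strains. Turning that matrix into a reliable
phylogeny is not just "concatenate and run a tree program":

* **low-quality sites** (high missing rate) and **near-monomorphic
  sites** (low minor allele frequency, MAF) add noise, not signal;
* **linkage disequilibrium (LD)** makes nearby SNPs statistically
  redundant, so dense clusters of linked sites over-weight their genomic
  region and bias the tree;
* heterozygous diploid calls must be carried into the sequence world
  without being silently discarded.

`snp2tree` implements the whole path natively: parse (VCF / HapMap /
simple tabular / binary cache) → qualify sites (missing-rate ceiling
`-p`, MAF floor `-m`) → LD-prune (composite-r² ceiling `-l` in a
sliding base-pair window) → encode each sample as one IUPAC
pseudo-sequence (heterozygote = ambiguity code, missing = N) →
neighbor-joining starting tree → maximum-likelihood branch lengths by
Felsenstein's pruning algorithm (JC69 / F81 / F84, optional NNI topology
search) → nonparametric bootstrap supports → Newick.

## The statistics inside

* **Composite LD r²** between sites *i*, *j*: the squared Pearson
  correlation of their dosage vectors (0/1/2 copies of the alternate
  allele) over samples where both are called — no haplotype phase
  needed. Greedy left-to-right pruning keeps a site iff r² ≤ `-l`
  against every retained site within `window_bp` upstream.
* **Jukes–Cantor distances** d = −(3/4)·ln(1 − 4p/3) from pairwise
  mismatch fractions (heterozygote vs compatible homozygote scores a
  half mismatch), feeding Saitou–Nei **neighbor joining** — exact on
  additive matrices.
* **Pruning-algorithm likelihood**: per-site partial likelihood vectors
  combined post-order; IUPAC ambiguity codes enter as partial
  observations ("A or G"); site patterns are compressed. Branch lengths
  are fitted by bounded per-edge scalar ascent; likelihood never
  decreases.
* **Bootstrap support** of an internal edge: the percentage of trees
  built from column-resampled alignments that contain the same leaf
  bipartition.

## Worked example

`examples/01_pipeline_from_vcf.py` simulates a 12-accession panel
(2,000 SNPs in 5-site LD blocks, 3% missing calls) on a known tree,
writes it as VCF and runs the pipeline:

```
stage            sites_in -> sites_out
  read_vcf           2000 -> 2000
  filter             2000 -> 833
  ld_prune            833 -> 70
  encode               70 -> 70
  tree                 70 -> 70
  bootstrap            70 -> 70

log-likelihood: -140.47
tree: ((t07:0,t02:0)90:0,(((t10:0,t01:0.0328749)81:0,t09:0.00436682)57:0.0102449,...);

Robinson-Foulds distance to the generating tree: 0 (0 = identical topology)
```

Reading the output: the filter removed sites breaching the 5%
missing-rate ceiling or the 0.1 MAF floor; LD pruning collapsed each
linked block to roughly one representative; the integer labels after
parentheses are bootstrap percentages (100 replicates); and the final
tree has the same unrooted topology as the tree the data were simulated
on. Zero branch lengths are genuine ML estimates — at 70 sites many
short edges carry no observed substitutions.

The same run from a shell:

```bash
snp2tree run -i panel.vcf -p 5 -m 0.1 -l 0.1 -b 100 --seed 42 -o panel
# -> panel.nwk, panel.fasta, panel.phylip (+ name map), panel.manifest.json,
#    panel.filter_removed.tsv, panel.prune_removed.tsv
```

`snp2tree cache -i panel.vcf -o panel.cache` converts any text input
into a compact binary genotype cache (2 bits/call + missing mask);
running from a cache skips the parse-and-qualify stages entirely
(`examples/04_genotype_cache.py` shows a ~30x reload speedup).

The other examples demonstrate LD-block collapsing
(`02_ld_pruning.py`) and the likelihood/bootstrap machinery on
sequence data (`03_likelihood_and_bootstrap.py`).

## Scope

Biallelic SNPs only; JC69/F81/F84 substitution models (no rate
heterogeneity or GTR); NJ + optional NNI topology search (no SPR/TBR);
unrooted trees. See `docs/methods.md` for the model details, parameter
defaults, the synthetic-data generator, and known limitations.
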