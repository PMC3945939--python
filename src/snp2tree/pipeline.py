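"""End-to-end orchestration: genotype file -> ML tree with supports.

Stages mirror the classical SNP-to-phylogeny workflow: parse the input
(VCF / HapMap / simple / binary cache), qualify sites by missing rate
and MAF, LD-prune, encode IUPAC pseudo-sequences, build an NJ starting
tree, fit branch lengths by maximum likelihood (optionally NNI-refine
the topology), and attach bootstrap supports.  A cache input skips the
parse-and-qualify stages, the same shortcut a pre-built genotype
container gives the original workflow.

Every run writes <prefix>.fasta, <prefix>.phylip (+ name map),
<prefix>.nwk, <prefix>.manifest.json, and TSV filter/prune reports, and
returns a RunManifest with conserved per-stage site counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import bootstrap_support
from .distance import distance_matrix, neighbor_joining, two_taxon_tree
from .encode import build_alignment, write_fasta, write_phylip
from .errors import EmptyAfterPruneError, FormatDetectionError
from .filtering import FilterConfig, filter_sites
from .io import CACHE_MAGIC, read_cache, read_hapmap, read_simple, read_vcf
from .ld import LDConfig, prune_all
from .likelihood import nni_search, optimize_branch_lengths
from .models import make_model
from .tree import write_newick

logger = logging.getLogger(__name__)

FORMATS = ("vcf", "hapmap", "simple", "cache")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline thresholds.

    max_missing_fraction is a proportion here; the CLI's -p flag takes a
    percentage and converts at the boundary.  bootstrap_reps = 0 skips
    support computation.
    """

    input_path: str
    format: str | None = None
    max_missing_fraction: float = 0.05
    min_maf: float = 0.1
    ld_threshold: float = 0.1
    window_bp: int = 500_000
    bootstrap_reps: int = 100
    model: str = "jc69"
    kappa: float = 2.0
    nni_enabled: bool = False
    seed: int = 1
    output_prefix: str = "snp2tree_out"

    def __post_init__(self):
        if self.format is not None and self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}, got {self.format!r}")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    seed: int = 0
    version: str = __version__
    log_likelihood: float | None = None
    newick: str | None = None

    def add_stage(self, name: str, sites_in: int, sites_out: int, seconds: float) -> None:
        if self.stages and self.stages[-1]["sites_out"] != sites_in:
            raise AssertionError(
                f"stage {name}: sites_in {sites_in} != previous sites_out "
                f"{self.stages[-1]['sites_out']}")
        self.stages.append({"stage": name, "sites_in": sites_in,
                            "sites_out": sites_out, "seconds": round(seconds, 3)})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed, "version": self.version,
                       "stages": self.stages, "log_likelihood": self.log_likelihood,
                       "newick": self.newick}, fh, indent=2)


def detect_format(path: str | Path) -> str:
    """Sniff vcf / hapmap / cache / simple from file content."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(4096)
    if head[: len(CACHE_MAGIC)] == CACHE_MAGIC:
        return "cache"
    try:
        text = head.decode("utf-8", errors="strict")
    except UnicodeDecodeError:
        raise FormatDetectionError(
            f"{path}: binary content without cache magic; tried cache, vcf, hapmap, simple")
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
        return "vcf"
    cols = first.split("\t")
    if cols and cols[0] in ("rs#", "rs") and len(cols) >= 12:
        return "hapmap"
    if len(cols) >= 3:
        return "simple"
    raise FormatDetectionError(
        f"{path}: unrecognized content; tried cache magic, VCF sentinel, "
        f"HapMap header, simple tabular")


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    fmt = cfg.format or detect_format(cfg.input_path)
    prefix = Path(cfg.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={**asdict(cfg), "format": fmt}, seed=cfg.seed)

    def timed(stage, fn):
        t0 = time.perf_counter()
        out = fn()
        return out, time.perf_counter() - t0

    # ---- stage 1-2: parse (and qualify, unless reading a cache)
    readers = {"vcf": read_vcf, "hapmap": read_hapmap, "simple": read_simple}
    if fmt == "cache":
        (gm), dt = timed("read", lambda: read_cache(cfg.input_path))
        manifest.add_stage("read_cache", gm.n_sites, gm.n_sites, dt)
        logger.info("read cache: %d samples x %d sites", gm.n_samples, gm.n_sites)
    else:
        (gm, parse_report), dt = timed("read", lambda: readers[fmt](cfg.input_path))
        manifest.add_stage(f"read_{fmt}", parse_report.records_in, gm.n_sites, dt)
        logger.info("read %s: %d samples, %d/%d records retained", fmt,
                    gm.n_samples, parse_report.records_retained, parse_report.records_in)

        t0 = time.perf_counter()
        fcfg = FilterConfig(max_missing_fraction=cfg.max_missing_fraction, min_maf=cfg.min_maf)
        raw = gm
        gm, filter_report = filter_sites(gm, fcfg)
        manifest.add_stage("filter", filter_report.n_input_sites, gm.n_sites,
                           time.perf_counter() - t0)
        filter_report.to_tsv(raw, f"{prefix}.filter_removed.tsv")
        logger.info("filter: %d retained (%d missing-rate, %d MAF removals)",
                    filter_report.n_retained, filter_report.n_removed_missing,
                    filter_report.n_removed_maf)

    # ---- stage 3: LD pruning
    t0 = time.perf_counter()
    ldcfg = LDConfig(ld_threshold=cfg.ld_threshold, window_bp=cfg.window_bp)
    pruned, prune_report = prune_all(gm, ldcfg)
    if pruned.n_sites == 0:
        raise EmptyAfterPruneError(
            f"LD pruning at r2<={cfg.ld_threshold} within {cfg.window_bp} bp removed all sites")
    manifest.add_stage("ld_prune", gm.n_sites, pruned.n_sites, time.perf_counter() - t0)
    prune_report.to_tsv(f"{prefix}.prune_removed.tsv")
    logger.info("LD prune: %d -> %d sites", gm.n_sites, pruned.n_sites)

    # ---- stages 4-5: encode (equal-length by construction)
    t0 = time.perf_counter()
    al = build_alignment(pruned)
    assert len({len(s) for s in al.sequences}) == 1
    write_fasta(al, f"{prefix}.fasta")
    write_phylip(al, f"{prefix}.phylip")
    manifest.add_stage("encode", pruned.n_sites, al.n_sites, time.perf_counter() - t0)

    # ---- stage 6: tree inference
    t0 = time.perf_counter()
    model = make_model(cfg.model, al, kappa=cfg.kappa)
    dm = distance_matrix(al)
    if al.n_samples == 2:
        tree = two_taxon_tree(dm)
    else:
        tree = neighbor_joining(dm)
        tree = optimize_branch_lengths(tree, al, model)
        if cfg.nni_enabled:
            tree = nni_search(tree, al, model)
    manifest.add_stage("tree", al.n_sites, al.n_sites, time.perf_counter() - t0)
    manifest.log_likelihood = tree.log_likelihood
    logger.info("tree: lnL = %s", tree.log_likelihood)

    # ---- bootstrap
    with_support = cfg.bootstrap_reps > 0 and al.n_samples > 3
    if with_support:
        t0 = time.perf_counter()
        tree = bootstrap_support(tree, al, model, cfg.bootstrap_reps, cfg.seed,
                                 nni=cfg.nni_enabled)
        manifest.add_stage("bootstrap", al.n_sites, al.n_sites, time.perf_counter() - t0)

    write_newick(tree, f"{prefix}.nwk", include_support=with_support)
    manifest.newick = tree.to_newick(include_support=with_support)
    manifest.to_json(f"{prefix}.manifest.json")
    return manifest
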