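"""Linkage-disequilibrium pruning of a genotype matrix.

Nearby SNPs in strong LD are statistically redundant: keeping all of
them over-weights their genomic region in a concatenated phylogenetic
analysis.  Pruning greedily selects, per chromosome, a subset in which
no retained pair within a base-pair window exceeds an r-squared ceiling.

The LD measure is the composite (Burrows-style) r²: the squared Pearson
correlation of the two sites' diploid dosage vectors over samples where
both calls are present.  It needs no haplotype phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import MISSING, GenotypeMatrix

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class LDConfig:
    """Pruning parameters.

    ld_threshold: r² ceiling (-l); a candidate site is discarded when its
    r² with any retained site within window_bp upstream exceeds it.
    window_bp: comparison window in base pairs.
    min_shared: minimum complete pairs for r² to be defined; pairs with
    undefined r² never cause removal.
    """

    ld_threshold: float = 0.1
    window_bp: int = 500_000
    min_shared: int = 2

    def __post_init__(self):
        if not 0.0 <= self.ld_threshold <= 1.0:
            raise ValueError(f"ld_threshold must be in [0,1], got {self.ld_threshold}")
        if self.window_bp < 1:
            raise ValueError(f"window_bp must be >= 1, got {self.window_bp}")
        if self.min_shared < 2:
            raise ValueError(f"min_shared must be >= 2, got {self.min_shared}")


@dataclass
class PruneReport:
    n_input_sites: int = 0
    n_retained: int = 0
    #: (removed site_id, retained blocking site_id, r²)
    removed: list[tuple[str, str, float]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\tblocking_site_id\tr2\n")
            for sid, blocker, r2 in self.removed:
                fh.write(f"{sid}\t{blocker}\t{r2:.6g}\n")


def composite_r2(d1, d2, min_shared: int = 2) -> float | None:
    """Composite-LD r² between two dosage vectors over {0,1,2,MISSING}.

    Complete-case squared Pearson correlation of the genotype scores.
    Returns None (undefined) when fewer than ``min_shared`` samples have
    both calls, or either vector is constant over the complete cases.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    if d1.shape != d2.shape:
        raise ValueError(f"length mismatch: {d1.shape} vs {d2.shape}")
    ok = (d1 != MISSING) & (d2 != MISSING)
    n = int(ok.sum())
    if n < min_shared:
        return None
    x = d1[ok].astype(np.float64)
    y = d2[ok].astype(np.float64)
    x -= x.mean()
    y -= y.mean()
    vx = x @ x
    vy = y @ y
    if vx <= _VAR_EPS or vy <= _VAR_EPS:
        return None
    r = (x @ y) / np.sqrt(vx * vy)
    return float(r * r)


def _block_r2(y: np.ndarray, ymask: np.ndarray, X: np.ndarray, Xmask: np.ndarray,
              min_shared: int) -> np.ndarray:
    """Complete-case r² of column y against each column of X; NaN where
    undefined.  Masks are True where the call is present."""
    valid = ymask[:, None] & Xmask
    n = valid.sum(axis=0).astype(np.float64)
    Xv = np.where(valid, X, 0.0)
    yv = np.where(valid, y[:, None], 0.0)
    sx = Xv.sum(axis=0)
    sy = yv.sum(axis=0)
    sxx = (Xv * Xv).sum(axis=0)
    syy = (yv * yv).sum(axis=0)
    sxy = (Xv * yv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[(n < min_shared) | (vx <= _VAR_EPS) | (vy <= _VAR_EPS)] = np.nan
    return r2


def prune_chromosome(gm: GenotypeMatrix, chrom: str, cfg: LDConfig,
                     report: PruneReport | None = None) -> list[int]:
    """Greedy left-to-right LD pruning of one chromosome.

    The first site is retained; each later site is retained iff its r²
    with every already-retained site within window_bp upstream is at or
    below the threshold.  Returns retained site indices into ``gm.sites``
    (strictly increasing).
    """
    idx = [j for j, s in enumerate(gm.sites) if s.chrom == chrom]
    if not idx:
        raise KeyError(f"chromosome {chrom!r} absent from matrix")
    pos = np.array([gm.sites[j].pos for j in idx], dtype=np.int64)
    X = gm.calls[:, idx].astype(np.float64)
    present = gm.calls[:, idx] != MISSING

    retained: list[int] = []           # positions into idx
    retained_pos: list[int] = []
    for k in range(len(idx)):
        lo = int(np.searchsorted(np.asarray(retained_pos), pos[k] - cfg.window_bp))
        window = retained[lo:]
        keep = True
        if window:
            r2 = _block_r2(X[:, k], present[:, k], X[:, window], present[:, window],
                           cfg.min_shared)
            bad = np.where(np.nan_to_num(r2, nan=-1.0) > cfg.ld_threshold)[0]
            if bad.size:
                keep = False
                if report is not None:
                    b = window[int(bad[0])]
                    report.removed.append((gm.sites[idx[k]].site_id,
                                           gm.sites[idx[b]].site_id, float(r2[bad[0]])))
        if keep:
            retained.append(k)
            retained_pos.append(int(pos[k]))
    return [idx[k] for k in retained]


def prune_all(gm: GenotypeMatrix, cfg: LDConfig) -> tuple[GenotypeMatrix, PruneReport]:
    """LD-prune every chromosome independently; retained sites keep their
    (chrom, pos) order.  Inter-chromosomal LD is ignored."""
    report = PruneReport(n_input_sites=gm.n_sites)
    if gm.n_sites == 0:
        return gm, report
    kept: list[int] = []
    for chrom in gm.chromosomes():
        kept.extend(prune_chromosome(gm, chrom, cfg, report))
    kept.sort()
    report.n_retained = len(kept)
    return gm.subset_sites(kept), report


def write_retained_bed(gm: GenotypeMatrix, path: str | Path) -> None:
    """Retained sites as BED (0-based half-open) for interoperability."""
    with open(path, "w") as fh:
        for s in gm.sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.site_id}\n")
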