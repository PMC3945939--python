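"""Per-site qualification: missing-rate ceiling and MAF floor.

Sites with too many no-calls carry little information and inflate the
ambiguity content of the concatenated sequences; near-monomorphic sites
(low minor allele frequency) carry almost no phylogenetic signal.  Both
rules are applied per site, missing-rate first, so every removal has a
single attributed cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyAfterFilterError, UndefinedMAFError
from .matrix import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site qualification.

    max_missing_fraction is the missing-rate ceiling as a proportion
    (the CLI's -p percentage divided by 100); min_maf is the minor
    allele frequency floor.  Both bounds are inclusive: a site is kept
    when missing_rate <= max_missing_fraction and maf >= min_maf.
    """

    max_missing_fraction: float = 0.05
    min_maf: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError(f"max_missing_fraction must be in [0,1], got {self.max_missing_fraction}")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError(f"min_maf must be in [0,0.5], got {self.min_maf}")


@dataclass
class FilterReport:
    n_input_sites: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    removed_missing_ids: list[str] = field(default_factory=list)
    removed_maf_ids: list[str] = field(default_factory=list)

    def conserved(self) -> bool:
        return self.n_input_sites == self.n_removed_missing + self.n_removed_maf + self.n_retained

    def to_tsv(self, gm: GenotypeMatrix, path: str | Path) -> None:
        """Removal report: site_id, chrom, pos, rule, value."""
        by_id = {s.site_id: s for s in gm.sites}
        rates = _missing_rates(gm)
        mafs = _mafs(gm)
        idx = {s.site_id: j for j, s in enumerate(gm.sites)}
        with open(path, "w") as fh:
            fh.write("site_id\tchrom\tpos\trule\tvalue\n")
            for sid in self.removed_missing_ids:
                s, j = by_id[sid], idx[sid]
                fh.write(f"{sid}\t{s.chrom}\t{s.pos}\tmissing_rate\t{rates[j]:.6g}\n")
            for sid in self.removed_maf_ids:
                s, j = by_id[sid], idx[sid]
                fh.write(f"{sid}\t{s.chrom}\t{s.pos}\tmaf\t{mafs[j]:.6g}\n")


def _missing_rates(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.calls == MISSING).mean(axis=0)


def _mafs(gm: GenotypeMatrix) -> np.ndarray:
    """Complete-case minor allele frequency per site; NaN where all calls
    are missing."""
    present = gm.calls != MISSING
    n_alleles = 2 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(present, gm.calls, 0).sum(axis=0) / n_alleles
    maf = np.minimum(alt, 1.0 - alt)
    maf[n_alleles == 0] = np.nan
    return maf


def site_missing_rate(gm: GenotypeMatrix, site_index: int) -> float:
    """Fraction of samples with a missing call at one site."""
    if not 0 <= site_index < gm.n_sites:
        raise IndexError(f"site index {site_index} out of range [0, {gm.n_sites})")
    return float((gm.calls[:, site_index] == MISSING).mean())


def site_maf(gm: GenotypeMatrix, site_index: int) -> float:
    """Minor allele frequency over non-missing calls at one site."""
    if not 0 <= site_index < gm.n_sites:
        raise IndexError(f"site index {site_index} out of range [0, {gm.n_sites})")
    col = gm.calls[:, site_index]
    present = col != MISSING
    if not present.any():
        raise UndefinedMAFError(
            f"site {gm.sites[site_index].site_id}: all calls missing, MAF undefined")
    f = col[present].sum() / (2 * present.sum())
    return float(min(f, 1.0 - f))


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain sites passing both rules; order and samples unchanged.

    All-missing sites that survive the missing-rate ceiling (possible
    only when the ceiling is 1.0) have no defined MAF and are attributed
    to the MAF rule.
    """
    rates = _missing_rates(gm)
    mafs = _mafs(gm)
    fail_missing = rates > cfg.max_missing_fraction
    maf_val = np.where(np.isnan(mafs), -1.0, mafs)  # undefined MAF can never pass the floor
    fail_maf = ~fail_missing & (maf_val < cfg.min_maf)
    keep = ~fail_missing & ~fail_maf

    report = FilterReport(
        n_input_sites=gm.n_sites,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        removed_missing_ids=[gm.sites[j].site_id for j in np.flatnonzero(fail_missing)],
        removed_maf_ids=[gm.sites[j].site_id for j in np.flatnonzero(fail_maf)],
    )
    if report.n_retained == 0:
        raise EmptyAfterFilterError(
            f"no site passed max_missing_fraction={cfg.max_missing_fraction} "
            f"and min_maf={cfg.min_maf}")
    return gm.subset_sites(np.flatnonzero(keep)), report
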