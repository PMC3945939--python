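"""Central genotype containers.

A :class:`GenotypeMatrix` holds diploid genotypes as alt-allele dosages
(0, 1, 2) with ``MISSING`` (-1) marking no-calls, one row per sample and
one column per biallelic SNP.  Sites are kept sorted by (chromosome,
position); every reader and every pipeline stage preserves that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel dosage for a missing call.  Stored as -1 in the int8 call matrix.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP locus.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    pos : int
        1-based base-pair coordinate.
    site_id : str
        Locus identifier; synthesized as ``chrom:pos`` when the source
        format carries none.
    ref, alt : str
        Single-nucleotide reference and alternate alleles (A/C/G/T,
        ``ref != alt``).
    """

    chrom: str
    pos: int
    site_id: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(
                f"site {self.site_id}: alleles must be single nucleotides, "
                f"got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"site {self.site_id}: ref and alt alleles are identical ({self.ref})")


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosage matrix.

    ``calls[i, j]`` counts copies of ``sites[j].alt`` carried by
    ``samples[i]``: 0, 1, 2 or :data:`MISSING`.
    """

    samples: list[str]
    sites: list[SiteRecord]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        ok = (self.calls >= 0) & (self.calls <= 2) | (self.calls == MISSING)
        if not ok.all():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")
        prev: tuple[str, int] | None = None
        for s in self.sites:
            key = (s.chrom, s.pos)
            if prev is not None and prev[0] == s.chrom and s.pos <= prev[1]:
                raise ValueError(
                    f"sites not strictly increasing within chromosome {s.chrom} near pos {s.pos}"
                )
            prev = key

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in indices],
            calls=self.calls[:, indices].copy(),
        )

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Field-for-field equality (used by cache round-trip contracts)."""
        return (
            self.samples == other.samples
            and self.sites == other.sites
            and np.array_equal(self.calls, other.calls)
        )


def sort_sites(samples: list[str], sites: list[SiteRecord], calls: np.ndarray) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix, stably sorting sites by (chrom, pos)."""
    order = sorted(range(len(sites)), key=lambda j: (sites[j].chrom, sites[j].pos))
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        samples=list(samples),
        sites=[sites[j] for j in order],
        calls=calls[:, order],
    )
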