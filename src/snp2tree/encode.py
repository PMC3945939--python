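"""Concatenate retained SNP genotypes into IUPAC pseudo-sequences.

Each sample becomes one sequence with one character per retained site:
homozygous reference -> ref base, homozygous alternate -> alt base,
heterozygous -> the two-base IUPAC ambiguity code for {ref, alt}, and a
missing call -> N.  All sequences are equal length by construction, so
the result is already a multiple alignment; no aligner is involved.

Writers emit FASTA and sequential PHYLIP; PHYLIP names are padded or
aliased to the strict 10-character convention with a mapping table so
downstream PHYLIP-suite tools interoperate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import Snp2TreeError
from .matrix import MISSING, GenotypeMatrix, SiteRecord

#: Two-base IUPAC ambiguity codes, keyed by the unordered base pair.
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: Base set each alignment symbol stands for.
SYMBOL_BASES = {b: frozenset(b) for b in "ACGT"}
SYMBOL_BASES.update({code: pair for pair, code in IUPAC_PAIR.items()})
SYMBOL_BASES["N"] = frozenset("ACGT")

ALPHABET = "ACGTRYSWKMN"


@dataclass
class Alignment:
    """Equal-length IUPAC pseudo-sequences, one per sample.

    site_map records the SNP locus behind each alignment column.
    """

    sample_ids: list[str]
    sequences: list[str]
    site_map: list[SiteRecord]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in alignment")
        if len(self.sequences) != len(self.sample_ids):
            raise ValueError("one sequence required per sample")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not equal length: {sorted(lengths)}")
        if self.site_map and len(self.site_map) != self.n_sites:
            raise ValueError("site_map length does not match sequence length")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def iupac_code(ref: str, alt: str, dosage: int) -> str:
    """Alignment symbol for one genotype call at a ref/alt SNP."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid allele pair {ref!r}/{alt!r}")
    if dosage == MISSING:
        return "N"
    if dosage == 0:
        return ref
    if dosage == 2:
        return alt
    if dosage == 1:
        return IUPAC_PAIR[frozenset((ref, alt))]
    raise ValueError(f"invalid dosage {dosage!r}")


def decode_symbol(site: SiteRecord, symbol: str) -> int:
    """Inverse of :func:`iupac_code` given the site's ref/alt (N -> MISSING)."""
    if symbol == site.ref:
        return 0
    if symbol == site.alt:
        return 2
    if symbol == IUPAC_PAIR[frozenset((site.ref, site.alt))]:
        return 1
    if symbol == "N":
        return MISSING
    raise ValueError(f"symbol {symbol!r} impossible at site {site.site_id} "
                     f"({site.ref}/{site.alt})")


def build_alignment(gm: GenotypeMatrix) -> Alignment:
    """Encode a (post-pruning) genotype matrix as IUPAC pseudo-sequences."""
    if gm.n_sites == 0:
        raise Snp2TreeError("cannot build an alignment from zero sites")
    # per-site symbol table indexed by dosage+1: [N, ref, het, alt]
    table = np.empty((gm.n_sites, 4), dtype="S1")
    for j, s in enumerate(gm.sites):
        table[j] = [b"N", s.ref.encode(), iupac_code(s.ref, s.alt, 1).encode(), s.alt.encode()]
    chars = table[np.arange(gm.n_sites)[None, :], gm.calls.astype(np.int16) + 1]
    sequences = [row.tobytes().decode("ascii") for row in chars]
    return Alignment(list(gm.samples), sequences, list(gm.sites))


# ------------------------------------------------------------- writers

def write_fasta(al: Alignment, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in zip(al.sample_ids, al.sequences)]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Alignment:
    from Bio.SeqIO import parse

    names, seqs = [], []
    for rec in parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return Alignment(names, seqs, [])


def phylip_names(sample_ids: list[str]) -> dict[str, str]:
    """Strict 10-character PHYLIP aliases.

    Names that fit in 10 characters and stay unique are kept (padded on
    write); the rest get collision-proof aliases s0001, s0002, ...
    """
    mapping: dict[str, str] = {}
    used: set[str] = set()
    needs_alias = []
    for name in sample_ids:
        short = name[:10]
        if len(name) <= 10 and short not in used:
            mapping[name] = short
            used.add(short)
        else:
            needs_alias.append(name)
    k = 0
    for name in needs_alias:
        while True:
            k += 1
            alias = f"s{k:04d}"
            if alias not in used:
                break
        mapping[name] = alias
        used.add(alias)
    return mapping


def write_phylip(al: Alignment, path: str | Path) -> dict[str, str]:
    """Write sequential PHYLIP; returns the name mapping and writes it
    alongside as ``<path>.names.tsv``."""
    path = Path(path)
    mapping = phylip_names(al.sample_ids)
    with open(path, "w") as fh:
        fh.write(f"{al.n_samples} {al.n_sites}\n")
        for name, seq in zip(al.sample_ids, al.sequences):
            fh.write(f"{mapping[name]:<10}{seq}\n")
    with open(path.with_suffix(path.suffix + ".names.tsv"), "w") as fh:
        fh.write("phylip_name\tsample_id\n")
        for name in al.sample_ids:
            fh.write(f"{mapping[name]}\t{name}\n")
    return mapping
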