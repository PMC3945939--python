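"""Genotype file I/O: VCF, HapMap, simple tabular, and a binary cache.

Readers return a :class:`~snp2tree.matrix.GenotypeMatrix` plus a
:class:`ParseReport` accounting for every input record.  Only biallelic
SNPs are retained; multiallelic records, indels and symbolic alleles are
skipped and counted.  The binary cache plays the role a packed genotype
container (such as GDS) plays in SNP pipelines: re-reading it skips the
raw-parse and per-site qualification stages entirely.

Cache layout (little-endian), version 1::

    bytes 0-7    magic  b"S2TCACHE"
    bytes 8-9    uint16 format version
    bytes 10-13  uint32 JSON header length H
    bytes 14..   H bytes of UTF-8 JSON: {"samples": [...],
                 "sites": [[chrom, pos, id, ref, alt], ...]}
    then         ceil(n_samples*n_sites/4) bytes of 2-bit dosages,
                 row-major, missing packed as 0
    then         ceil(n_samples*n_sites/8) bytes of 1-bit missing mask
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CacheError, EmptyInputError, FormatError
from .matrix import MISSING, GenotypeMatrix, SiteRecord, sort_sites

logger = logging.getLogger(__name__)

CACHE_MAGIC = b"S2TCACHE"
CACHE_VERSION = 1

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_SIMPLE_MISSING = {".", "NA"}
_HAPMAP_MISSING = {"NN", "N", "--"}


@dataclass
class ParseReport:
    """Per-file accounting: every input record is retained or attributed
    to exactly one skip reason (records_in = retained + skipped)."""

    records_in: int = 0
    records_retained: int = 0
    multiallelic: int = 0
    not_snp: int = 0
    bad_genotype: int = 0
    skipped_ids: list[str] = field(default_factory=list)

    @property
    def records_skipped(self) -> int:
        return self.multiallelic + self.not_snp + self.bad_genotype

    def conserved(self) -> bool:
        return self.records_in == self.records_retained + self.records_skipped


# ----------------------------------------------------------------- VCF

def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, ParseReport]:
    """Parse a VCF (v4.x) into a dosage matrix using the GT subfield.

    ``0/0 -> 0``, ``0/1``/``1/0`` -> 1, ``1/1 -> 2``; ``./.`` and
    half-calls -> MISSING.  Phase separators are ignored.  Records that
    are not biallelic SNPs are skipped and counted in the report; a
    record whose GT indexes an allele other than 0/1/. is skipped with a
    warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises on a missing/broken header
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise FormatError(f"{path}: VCF #CHROM header names {len(samples)} samples; need >= 2")

    report = ParseReport()
    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        report.records_in += 1
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        alts = var.ALT
        if len(alts) != 1:
            report.multiallelic += 1
            report.skipped_ids.append(sid)
            continue
        ref, alt = var.REF, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            report.not_snp += 1
            report.skipped_ids.append(sid)
            continue
        # genotypes: one [allele_a, allele_b, phased] triple per sample
        geno = np.array([g[:2] for g in var.genotypes], dtype=np.int64)
        if geno.max(initial=0) > 1:
            warnings.warn(f"{path}: record {sid} has GT allele index > 1; skipped")
            report.bad_genotype += 1
            report.skipped_ids.append(sid)
            continue
        dosage = geno.sum(axis=1).astype(np.int8)
        dosage[(geno < 0).any(axis=1)] = MISSING  # ./., ./1 half-calls
        sites.append(SiteRecord(var.CHROM, var.POS, sid, ref, alt))
        columns.append(dosage)
        report.records_retained += 1
    vcf.close()

    if not columns:
        raise EmptyInputError(f"{path}: no biallelic SNP records retained")
    calls = np.stack(columns, axis=1)
    return sort_sites(samples, sites, calls), report


# -------------------------------------------------------------- HapMap

def read_hapmap(path: str | Path) -> tuple[GenotypeMatrix, ParseReport]:
    """Parse HapMap tabular format (11 fixed columns + one per sample).

    Genotype cells are two-letter diploid calls ("AA", "AG", ...) or a
    single letter (homozygous); "NN"/"N"/"--" are missing.  The alleles
    column (e.g. "A/G") fixes ref = first listed allele.  Rows whose
    observed alleles exceed two are skipped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as tab-delimited HapMap ({exc})") from exc
    if df.shape[1] < 12:
        raise FormatError(
            f"{path}: HapMap requires 11 fixed columns plus >= 1 sample column, "
            f"found {df.shape[1]}"
        )
    samples = list(df.columns[11:])
    if "-" in set(df.iloc[:, 4]):
        warnings.warn(f"{path}: '-' strand entries present; strand is read but ignored")

    report = ParseReport()
    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    for row in df.itertuples(index=False):
        report.records_in += 1
        rsid, alleles, chrom, pos = row[0], row[1], row[2], int(row[3])
        sid = rsid if rsid and rsid != "." else f"{chrom}:{pos}"
        pair = alleles.split("/")
        if len(pair) != 2 or any(a not in "ACGT" for a in pair):
            report.not_snp += 1
            report.skipped_ids.append(sid)
            continue
        ref, alt = pair
        cells = row[11:]
        observed = {b for c in cells if c not in _HAPMAP_MISSING for b in c}
        if len(observed) > 2:
            report.multiallelic += 1
            report.skipped_ids.append(sid)
            continue
        dosage = np.full(len(samples), MISSING, dtype=np.int8)
        for i, cell in enumerate(cells):
            if cell in _HAPMAP_MISSING:
                continue
            letters = cell if len(cell) == 2 else cell * 2
            if any(b not in (ref, alt) for b in letters):
                warnings.warn(f"{path}: site {sid} sample {samples[i]}: genotype {cell!r} "
                              f"not in alleles {ref}/{alt}; set to missing")
                continue
            dosage[i] = letters.count(alt)
        sites.append(SiteRecord(str(chrom), pos, sid, ref, alt))
        columns.append(dosage)
        report.records_retained += 1

    if not columns:
        raise EmptyInputError(f"{path}: no biallelic SNP rows retained")
    calls = np.stack(columns, axis=1)
    return sort_sites(samples, sites, calls), report


# -------------------------------------------------------------- simple

def read_simple(path: str | Path) -> tuple[GenotypeMatrix, ParseReport]:
    """Parse the simple tabular format: chrom, pos, one dosage column per
    sample (cells 0/1/2, missing "." or "NA").

    The format carries no nucleotide identities, so placeholder alleles
    ref=A / alt=G are synthesized; downstream IUPAC sequences are
    internally consistent but the letters are not real nucleotides.
    An optional header line names the samples; without one they are
    named ``sample_1..sample_k``.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty file")
    first = lines[0].split("\t")
    if len(first) < 3:
        raise FormatError(f"{path}: simple format needs >= 3 tab-separated columns")

    def is_cell(tok: str) -> bool:
        return tok in _SIMPLE_MISSING or tok.isdigit()

    has_header = not all(is_cell(t) for t in first[2:]) or not first[1].isdigit()
    if has_header:
        samples = first[2:]
        body = lines[1:]
        offset = 2
    else:
        samples = [f"sample_{i + 1}" for i in range(len(first) - 2)]
        body = lines
        offset = 1

    report = ParseReport()
    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    for k, ln in enumerate(body):
        report.records_in += 1
        toks = ln.split("\t")
        if len(toks) != len(samples) + 2:
            raise FormatError(f"{path}, line {k + offset}: expected {len(samples) + 2} columns, "
                              f"got {len(toks)}")
        chrom, pos_s = toks[0], toks[1]
        if not pos_s.isdigit():
            raise FormatError(f"{path}, line {k + offset}: position {pos_s!r} is not an integer")
        dosage = np.empty(len(samples), dtype=np.int8)
        for i, cell in enumerate(toks[2:]):
            if cell in _SIMPLE_MISSING:
                dosage[i] = MISSING
            elif cell in ("0", "1", "2"):
                dosage[i] = int(cell)
            else:
                raise FormatError(f"{path}, line {k + offset}: dosage cell {cell!r} "
                                  f"is not 0/1/2 or a missing code")
        pos = int(pos_s)
        sites.append(SiteRecord(chrom, pos, f"{chrom}:{pos}", "A", "G"))
        columns.append(dosage)
        report.records_retained += 1

    if not columns:
        raise EmptyInputError(f"{path}: no records")
    calls = np.stack(columns, axis=1)
    return sort_sites(samples, sites, calls), report


# --------------------------------------------------------------- cache

def _pack2(vals: np.ndarray) -> bytes:
    v = vals.astype(np.uint8)
    pad = (-len(v)) % 4
    if pad:
        v = np.concatenate([v, np.zeros(pad, np.uint8)])
    v = v.reshape(-1, 4)
    return (v[:, 0] | v[:, 1] << 2 | v[:, 2] << 4 | v[:, 3] << 6).tobytes()


def _unpack2(buf: bytes, n: int) -> np.ndarray:
    b = np.frombuffer(buf, dtype=np.uint8)
    out = np.empty((len(b), 4), np.uint8)
    out[:, 0] = b & 3
    out[:, 1] = (b >> 2) & 3
    out[:, 2] = (b >> 4) & 3
    out[:, 3] = (b >> 6) & 3
    return out.reshape(-1)[:n]


def write_cache(gm: GenotypeMatrix, path: str | Path) -> None:
    """Serialize a genotype matrix to the versioned binary cache."""
    header = json.dumps({
        "samples": gm.samples,
        "sites": [[s.chrom, s.pos, s.site_id, s.ref, s.alt] for s in gm.sites],
    }).encode()
    flat = gm.calls.reshape(-1)
    miss = flat == MISSING
    with open(path, "wb") as fh:
        fh.write(CACHE_MAGIC)
        fh.write(int(CACHE_VERSION).to_bytes(2, "little"))
        fh.write(len(header).to_bytes(4, "little"))
        fh.write(header)
        fh.write(_pack2(np.where(miss, 0, flat)))
        fh.write(np.packbits(miss).tobytes())


def read_cache(path: str | Path) -> GenotypeMatrix:
    """Read a cache written by :func:`write_cache` (lossless round trip)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:8] != CACHE_MAGIC:
        raise CacheError(f"{path}: not a snp2tree genotype cache (bad magic)")
    version = int.from_bytes(blob[8:10], "little")
    if version != CACHE_VERSION:
        raise CacheError(f"{path}: cache version {version} is incompatible with "
                         f"reader version {CACHE_VERSION}")
    hlen = int.from_bytes(blob[10:14], "little")
    try:
        header = json.loads(blob[14:14 + hlen])
        samples = header["samples"]
        sites = [SiteRecord(c, p, i, r, a) for c, p, i, r, a in header["sites"]]
    except Exception as exc:
        raise CacheError(f"{path}: corrupt cache header ({exc})") from exc
    n = len(samples) * len(sites)
    dbytes = (n + 3) // 4
    mbytes = (n + 7) // 8
    body = blob[14 + hlen:]
    if len(body) < dbytes + mbytes:
        raise CacheError(f"{path}: truncated cache (expected {dbytes + mbytes} data bytes, "
                         f"found {len(body)})")
    calls = _unpack2(body[:dbytes], n).astype(np.int8)
    miss = np.unpackbits(np.frombuffer(body[dbytes:dbytes + mbytes], np.uint8))[:n].astype(bool)
    calls[miss] = MISSING
    return GenotypeMatrix(samples, sites, calls.reshape(len(samples), len(sites)))


# ----------------------------------------------------- fixture writers

def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal sites+GT VCF that read_vcf parses back losslessly."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            maxpos = max(s.pos for s in gm.sites if s.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, s in enumerate(gm.sites):
            cells = "\t".join(gt[int(c)] for c in gm.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{cells}\n")


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write HapMap tabular text that read_hapmap parses back losslessly."""
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + gm.samples) + "\n")
        for j, s in enumerate(gm.sites):
            cell = {0: s.ref * 2, 1: s.ref + s.alt, 2: s.alt * 2, MISSING: "NN"}
            row = [s.site_id, f"{s.ref}/{s.alt}", s.chrom, str(s.pos), "+",
                   "NA", "NA", "NA", "NA", "NA", "NA"]
            row += [cell[int(c)] for c in gm.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def write_simple(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write simple tabular text (dosages only; allele identity is lost)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos"] + gm.samples) + "\n")
        for j, s in enumerate(gm.sites):
            cells = ["." if c == MISSING else str(int(c)) for c in gm.calls[:, j]]
            fh.write(f"{s.chrom}\t{s.pos}\t" + "\t".join(cells) + "\n")
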