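"""Biallelic SNP panels for inbred (haploid-coded) accessions.

The central data structure is :class:`SnpMatrix`, a sites x samples matrix of
haploid genotype codes (0 = reference allele, 1 = alternate allele,
``MISSING`` = no call).  Inbred selfing accessions are modelled as haploid:
homozygous diploid calls collapse to a single code and heterozygous calls are
treated according to a configurable policy (missing by default).

Coordinates: per-site positions are stored 1-based (as in VCF); interval
queries (gene bodies, neighborhood spans) use 0-based half-open intervals
(as in BED) and are converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateLocusError,
    DuplicateSiteError,
    FormatError,
    GnselectError,
    UndefinedFrequencyError,
)

#: Genotype code for a missing call.
MISSING: int = -1

_ALLOWED_CODES = frozenset({-1, 0, 1})


@dataclass
class SnpMatrix:
    """A panel of biallelic SNPs over haploid-coded samples.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_sites,)
    pos : np.ndarray of int, shape (n_sites,)
        1-based physical positions, strictly increasing within a chromosome.
    ref_allele, alt_allele : np.ndarray of str, shape (n_sites,)
    genotypes : np.ndarray of int8, shape (n_sites, n_samples)
        Codes in {0, 1, MISSING}.
    sample_ids : list of str
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            self.genotypes = self.genotypes.reshape(len(self.pos), -1)
        self.validate()

    # ------------------------------------------------------------------ #

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.genotypes.shape[1])

    def validate(self) -> None:
        n = self.n_sites
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref_allele, "ref_allele"),
                          (self.alt_allele, "alt_allele")):
            if len(arr) != n:
                raise GnselectError(f"{name} length {len(arr)} != n_sites {n}")
        codes = np.unique(self.genotypes) if n else np.array([], dtype=np.int8)
        bad = set(codes.tolist()) - _ALLOWED_CODES
        if bad:
            raise GnselectError(f"invalid genotype codes: {sorted(bad)}")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise GnselectError(
                    f"positions not strictly increasing on chromosome {c}")

    # ------------------------------------------------------------------ #

    def allele_frequency(self, site_index: int) -> float:
        """Alternate-allele frequency among non-missing calls at a site."""
        g = self.genotypes[site_index]
        called = g != MISSING
        n = int(called.sum())
        if n == 0:
            raise UndefinedFrequencyError(
                f"all calls missing at site index {site_index}")
        return float(g[called].sum()) / n

    def minor_allele_frequency(self, site_index: int) -> float:
        f = self.allele_frequency(site_index)
        return min(f, 1.0 - f)

    def missingness(self, site_index: int) -> float:
        g = self.genotypes[site_index]
        return float((g == MISSING).mean()) if self.n_samples else 0.0

    def sites_in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites whose 0-based position lies in [start, end)."""
        zero_based = self.pos - 1
        mask = (self.chrom == chrom) & (zero_based >= start) & (zero_based < end)
        return np.flatnonzero(mask)

    def take_sites(self, indices) -> "SnpMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return SnpMatrix(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            genotypes=self.genotypes[idx],
            sample_ids=list(self.sample_ids),
        )

    # ------------------------------------------------------------------ #

    def write_tsv(self, path) -> None:
        """Write the panel in the transparent sites-by-samples TSV dialect.

        Header: ``chrom pos ref alt <sample...>``; codes 0/1/NA.
        """
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(self.sample_ids) + "\n")
            for i in range(self.n_sites):
                row = [
                    str(self.chrom[i]), str(self.pos[i]),
                    str(self.ref_allele[i]), str(self.alt_allele[i]),
                ]
                row.extend("NA" if g == MISSING else str(int(g))
                           for g in self.genotypes[i])
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------- #
# loading

def _sorted_unique_check(chrom: np.ndarray, pos: np.ndarray):
    order = np.lexsort((pos, chrom.astype(str)))
    c, p = chrom[order], pos[order]
    dup = (c[1:] == c[:-1]) & (p[1:] == p[:-1])
    if np.any(dup):
        k = int(np.flatnonzero(dup)[0])
        raise DuplicateSiteError(f"duplicated site ({c[k + 1]}, {p[k + 1]})")
    return order


def load_variants(path, het_policy: str = "missing") -> SnpMatrix:
    """Load a SNP panel from a VCF (plain or bgzipped) or the TSV dialect.

    Diploid homozygous calls collapse to haploid codes; heterozygous calls
    follow ``het_policy`` ("missing", "ref" or "alt").  Only biallelic SNP
    records are kept from VCF input.  Sites are sorted by (chrom, pos).
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith((".vcf.gz", ".vcf.bgz")):
        return _load_vcf(path, het_policy=het_policy)
    return _load_tsv(path)


def _collapse_gt(gt, het_policy: str) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if any(a > 1 for a in alleles):
        return MISSING  # call references a dropped (non-first) ALT
    first = alleles[0]
    if all(a == first for a in alleles):
        return int(first)
    if het_policy == "ref":
        return 0
    if het_policy == "alt":
        return 1
    return MISSING


def _load_vcf(path: Path, het_policy: str) -> SnpMatrix:
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    chroms, positions, refs, alts, rows = [], [], [], [], []
    try:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic or ALT-less records are dropped
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue  # indels are out of scope
            row = np.empty(len(samples), dtype=np.int8)
            for j, s in enumerate(samples):
                row[j] = _collapse_gt(rec.samples[s].get("GT", (None,)),
                                      het_policy)
            chroms.append(rec.chrom)
            positions.append(rec.pos)  # pysam gives the 1-based VCF POS
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            rows.append(row)
    except (OSError, ValueError) as exc:
        raise FormatError(
            f"unparseable VCF record after {len(rows)} records in {path}: {exc}"
        ) from exc
    finally:
        vf.close()

    chrom = np.asarray(chroms, dtype=object)
    pos = np.asarray(positions, dtype=np.int64)
    order = _sorted_unique_check(chrom, pos)
    geno = (np.vstack(rows) if rows
            else np.empty((0, len(samples)), dtype=np.int8))
    return SnpMatrix(
        chrom=chrom[order], pos=pos[order],
        ref_allele=np.asarray(refs, dtype=object)[order],
        alt_allele=np.asarray(alts, dtype=object)[order],
        genotypes=geno[order], sample_ids=samples,
    )


def _load_tsv(path: Path) -> SnpMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str,
                                                "alt": str}, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    required = ["chrom", "pos", "ref", "alt"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"TSV {path} missing column '{col}'")
    samples = [c for c in df.columns if c not in required]
    geno = df[samples].to_numpy(dtype=object) if samples else \
        np.empty((len(df), 0), dtype=object)
    out = np.empty(geno.shape, dtype=np.int8)
    for i in range(geno.shape[0]):
        for j in range(geno.shape[1]):
            v = geno[i, j]
            if pd.isna(v) or str(v).upper() == "NA":
                out[i, j] = MISSING
            else:
                try:
                    out[i, j] = int(v)
                except (TypeError, ValueError) as exc:
                    raise FormatError(
                        f"bad genotype '{v}' at data row {i + 1}, "
                        f"sample '{samples[j]}' in {path}") from exc
    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    order = _sorted_unique_check(chrom, pos)
    return SnpMatrix(
        chrom=chrom[order], pos=pos[order],
        ref_allele=df["ref"].to_numpy(dtype=object)[order],
        alt_allele=df["alt"].to_numpy(dtype=object)[order],
        genotypes=out[order], sample_ids=samples,
    )


# ---------------------------------------------------------------------- #
# site filtering

def filter_sites(m: SnpMatrix, maf_min: float = 0.0,
                 biallelic_only: bool = True,
                 max_missing: float = 0.1) -> SnpMatrix:
    """Apply the standard pre-analysis site filters.

    Retains sites with minor allele frequency >= ``maf_min`` among
    non-missing calls, drops sites with missingness > ``max_missing``, and
    (when ``biallelic_only``) drops sites that do not show exactly two
    observed alleles among non-missing calls.  Idempotent.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise GnselectError(f"maf_min {maf_min} outside [0, 0.5]")
    if m.n_sites == 0:
        return m
    g = m.genotypes
    called = g != MISSING
    n_called = called.sum(axis=1)
    n_samples = m.n_samples or 1
    miss_frac = 1.0 - n_called / n_samples
    keep = miss_frac <= max_missing
    keep &= n_called > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, g, 0).sum(axis=1)
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    if biallelic_only:
        keep &= (alt > 0) & (alt < n_called)
    keep &= ~np.isnan(maf) & (maf >= maf_min)
    return m.take_sites(np.flatnonzero(keep))


def allele_frequency(m: SnpMatrix, site_index: int) -> float:
    """Module-level alias for :meth:`SnpMatrix.allele_frequency`."""
    return m.allele_frequency(site_index)


# ---------------------------------------------------------------------- #
# locus tables (BED)

@dataclass(frozen=True)
class Locus:
    """A gene-body interval: 0-based half-open, optional group label."""

    locus_id: str
    chrom: str
    start: int
    end: int
    group_label: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise GnselectError(
                f"locus {self.locus_id}: start {self.start} >= end {self.end}")


class LocusTable:
    """An ordered collection of loci with unique ids."""

    def __init__(self, loci: Iterable[Locus]):
        self.loci = list(loci)
        seen = set()
        for loc in self.loci:
            if loc.locus_id in seen:
                raise DuplicateLocusError(f"duplicate locus_id {loc.locus_id}")
            seen.add(loc.locus_id)

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, i):
        return self.loci[i]

    def by_chrom(self) -> dict:
        out: dict[str, list[Locus]] = {}
        for loc in self.loci:
            out.setdefault(loc.chrom, []).append(loc)
        for v in out.values():
            v.sort(key=lambda l: (l.start, l.end))
        return out


def read_loci_bed(path) -> LocusTable:
    """Read a 4-5 column BED: chrom, start, end, name[, group label]."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: BED needs >= 4 columns, got {len(parts)}")
            label = parts[4] if len(parts) > 4 and parts[4] else None
            try:
                loci.append(Locus(locus_id=parts[3], chrom=parts[0],
                                  start=int(parts[1]), end=int(parts[2]),
                                  group_label=label))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return LocusTable(loci)
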