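"""Genomic-neighborhood LD enrichment.

Pipeline: merge tandem focal loci into genomic neighborhoods (gene bodies
plus fixed flanks), evaluate r-squared linkage disequilibrium between every
pair of biallelic sites inside each neighborhood, keep pairs above a
threshold, count them per neighborhood, and compare clustered versus
non-clustered neighborhood groups with a pooled-variance t-test.  A tricube
local-linear smoother summarises LD decay with inter-site distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateVarianceError,
    GnselectError,
    InsufficientDataError,
    LabelConflictError,
    MonomorphicSiteError,
)
from .snp_matrix import MISSING, LocusTable, SnpMatrix, read_loci_bed

__all__ = [
    "GenomicNeighborhood", "LdPairTable", "GroupComparison",
    "r_squared", "fisher_association", "build_neighborhoods",
    "window_ld_pairs", "gn_ld_count", "compare_gn_groups", "ld_decay_loess",
    "osc_locus_inventory", "nucleotide_diversity",
]


@dataclass(frozen=True)
class GenomicNeighborhood:
    """A focal locus (or merged tandem set) extended by flanking windows."""

    gn_id: str
    chrom: str
    focal_loci: tuple
    start: int  # 0-based half-open span including flanks
    end: int
    group_label: str | None = None

    @property
    def span(self) -> tuple:
        return (self.start, self.end)


@dataclass
class LdPairTable:
    """Retained LD pairs for one neighborhood.

    ``df`` columns: site_i, site_j, pos_i, pos_j, distance_bp, r2, fisher_p
    (site indices refer to the SnpMatrix the table was computed from; i < j).
    """

    df: pd.DataFrame
    gn_id: str = ""
    r2_threshold: float = 0.1

    def __len__(self):
        return len(self.df)


@dataclass(frozen=True)
class GroupComparison:
    n_clustered: int
    n_nonclustered: int
    mean_clustered: float
    mean_nonclustered: float
    t_statistic: float
    df: int
    p_two_sided: float


# ---------------------------------------------------------------------- #
# pairwise statistics

def _paired_counts(hap_a, hap_b):
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise GnselectError("haplotype vectors differ in length")
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep].astype(np.int64), b[keep].astype(np.int64)
    if a.size < 2:
        raise MonomorphicSiteError("fewer than 2 shared non-missing calls")
    if a.min() == a.max() or b.min() == b.max():
        raise MonomorphicSiteError("monomorphic site after pairwise deletion")
    return a, b


def r_squared(hap_a, hap_b) -> float:
    """Squared allele-frequency correlation between two biallelic sites.

    Computed on haplotype counts after pairwise deletion of missing calls:
    r2 = D^2 / (pa (1-pa) pb (1-pb)) with D = p_ab - pa*pb.  Equals the
    squared Pearson correlation of the 0/1 vectors.
    """
    a, b = _paired_counts(hap_a, hap_b)
    n = a.size
    pa = a.sum() / n
    pb = b.sum() / n
    pab = (a & b).sum() / n
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def fisher_association(hap_a, hap_b) -> float:
    """Two-sided Fisher exact p on the 2x2 haplotype count table."""
    a, b = _paired_counts(hap_a, hap_b)
    n11 = int((a & b).sum())
    n10 = int((a & (1 - b)).sum())
    n01 = int(((1 - a) & b).sum())
    n00 = int(((1 - a) & (1 - b)).sum())
    return float(stats.fisher_exact([[n11, n10], [n01, n00]],
                                    alternative="two-sided")[1])


# ---------------------------------------------------------------------- #
# neighborhoods

def osc_locus_inventory() -> LocusTable:
    """The built-in 13-gene Col-0 oxidosqualene-cyclase locus table."""
    ref = resources.files("gnselect") / "data" / "osc_col0.bed"
    with resources.as_file(ref) as path:
        return read_loci_bed(path)


def build_neighborhoods(loci: LocusTable, flank_bp: int = 50_000,
                        tandem_merge_bp: int = 50_000) -> list:
    """Merge tandem loci and extend by flanks into genomic neighborhoods.

    Loci on the same chromosome whose gene bodies lie within
    ``tandem_merge_bp`` of each other merge transitively into one
    neighborhood; the span is the merged bodies extended by ``flank_bp`` on
    each side (clamped at 0).  Merged loci must agree on group label.
    """
    if flank_bp <= 0:
        raise GnselectError("flank_bp must be positive")
    out = []
    for chrom, locs in sorted(loci.by_chrom().items()):
        cluster = [locs[0]]
        for loc in locs[1:]:
            gap = loc.start - max(l.end for l in cluster)
            if gap <= tandem_merge_bp:
                cluster.append(loc)
            else:
                out.append(_make_gn(chrom, cluster, flank_bp))
                cluster = [loc]
        out.append(_make_gn(chrom, cluster, flank_bp))
    return out


def _make_gn(chrom, cluster, flank_bp) -> GenomicNeighborhood:
    labels = {l.group_label for l in cluster}
    if len(labels) > 1:
        raise LabelConflictError(
            f"conflicting group labels {sorted(map(str, labels))} in merged "
            f"loci {[l.locus_id for l in cluster]}")
    start = min(l.start for l in cluster)
    end = max(l.end for l in cluster)
    return GenomicNeighborhood(
        gn_id="+".join(l.locus_id for l in cluster),
        chrom=chrom,
        focal_loci=tuple(l.locus_id for l in cluster),
        start=max(0, start - flank_bp),
        end=end + flank_bp,
        group_label=labels.pop(),
    )


# ---------------------------------------------------------------------- #
# within-neighborhood LD scan

def _pairwise_r2_matrix(g: np.ndarray):
    """All-pairs r2 for a sites x samples 0/1/MISSING matrix.

    Returns (r2, valid) square matrices; ``valid`` is False where a pair has
    < 2 shared calls or a site is monomorphic after pairwise deletion.
    """
    called = (g != MISSING)
    v = np.where(called, g, 0).astype(np.float64)
    c = called.astype(np.float64)
    n = c @ c.T
    sa = v @ c.T           # sum of site-i alleles over shared samples
    sb = c @ v.T
    sab = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = sa / n
        pb = sb / n
        pab = sab / n
        d = pab - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = d * d / denom
    valid = (n >= 2) & (denom > 0)
    return r2, valid


def window_ld_pairs(m: SnpMatrix, gn: GenomicNeighborhood,
                    r2_threshold: float = 0.1, maf_min: float = 0.05,
                    top_k_per_site: int | None = None) -> LdPairTable:
    """Evaluate every unordered site pair inside a neighborhood span.

    Sites are restricted to the span, to minor allele frequency >= maf_min
    and to polymorphic-in-sample; rows are retained where r2 > r2_threshold
    and carry r2, two-sided Fisher exact p and inter-site distance.
    """
    idx = m.sites_in_interval(gn.chrom, gn.start, gn.end)
    usable = []
    for i in idx:
        g = m.genotypes[i]
        called = g != MISSING
        if called.sum() < 2:
            continue
        f = g[called].mean()
        if 0.0 < f < 1.0 and min(f, 1 - f) >= maf_min:
            usable.append(i)
    cols = ["site_i", "site_j", "pos_i", "pos_j", "distance_bp", "r2",
            "fisher_p"]
    if len(usable) < 2:
        return LdPairTable(pd.DataFrame(columns=cols), gn_id=gn.gn_id,
                           r2_threshold=r2_threshold)
    usable = np.asarray(usable)
    sub = m.genotypes[usable]
    r2, valid = _pairwise_r2_matrix(sub)
    iu, ju = np.triu_indices(len(usable), k=1)
    keep = valid[iu, ju] & (r2[iu, ju] > r2_threshold)
    iu, ju = iu[keep], ju[keep]
    rows = []
    for a, b in zip(iu, ju):
        i, j = int(usable[a]), int(usable[b])
        rows.append((i, j, int(m.pos[i]), int(m.pos[j]),
                     abs(int(m.pos[j]) - int(m.pos[i])),
                     float(r2[a, b]),
                     fisher_association(m.genotypes[i], m.genotypes[j])))
    df = pd.DataFrame(rows, columns=cols)
    if top_k_per_site is not None and len(df):
        df = _apply_top_k(df, top_k_per_site)
    return LdPairTable(df.reset_index(drop=True), gn_id=gn.gn_id,
                       r2_threshold=r2_threshold)


def _apply_top_k(df: pd.DataFrame, k: int) -> pd.DataFrame:
    # keep a row iff it ranks in the top-k r2 values for either of its sites
    keep = np.zeros(len(df), dtype=bool)
    for col in ("site_i", "site_j"):
        for _, grp in df.groupby(col):
            top = grp.sort_values("r2", ascending=False).head(k).index
            keep[df.index.get_indexer(top)] = True
    return df[keep]


def gn_ld_count(table: LdPairTable) -> int:
    """Number of retained LD pairs — the per-neighborhood scan statistic."""
    return len(table.df)


# ---------------------------------------------------------------------- #
# group comparison and decay

def compare_gn_groups(counts, labels) -> GroupComparison:
    """Pooled-variance two-sample two-sided Student t-test on per-GN counts.

    ``labels`` must contain exactly two values, "clustered" and
    "non_clustered", each with at least 2 neighborhoods.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=object)
    x = counts[labels == "clustered"]
    y = counts[labels == "non_clustered"]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(
            f"need >= 2 neighborhoods per group, got {len(x)} and {len(y)}")
    dof = len(x) + len(y) - 2
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    if ss == 0:
        if x.mean() == y.mean():
            return GroupComparison(len(x), len(y), float(x.mean()),
                                   float(y.mean()), 0.0, dof, 1.0)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal group means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(len(x), len(y), float(x.mean()), float(y.mean()),
                           float(t), dof, float(p))


def ld_decay_loess(table: LdPairTable, span: float = 0.75,
                   grid_points: int = 100):
    """Tricube-weighted local linear regression of r2 on distance.

    Returns (grid, fitted) evaluated on an evenly spaced distance grid; the
    fit is clamped to [0, 1].
    """
    if not 0.0 < span <= 1.0:
        raise GnselectError(f"span {span} outside (0, 1]")
    d = table.df["distance_bp"].to_numpy(dtype=float)
    r = table.df["r2"].to_numpy(dtype=float)
    if len(d) < 10:
        raise InsufficientDataError(f"need >= 10 pairs, got {len(d)}")
    grid = np.linspace(d.min(), d.max(), grid_points)
    k = max(2, int(np.ceil(span * len(d))))
    fitted = np.empty(grid_points)
    for gi, x0 in enumerate(grid):
        dist = np.abs(d - x0)
        h = np.partition(dist, k - 1)[k - 1]
        if h == 0:
            fitted[gi] = r[dist == 0].mean()
            continue
        w = (1 - np.minimum(dist / h, 1.0) ** 3) ** 3
        sw = w.sum()
        xm = (w * d).sum() / sw
        ym = (w * r).sum() / sw
        sxx = (w * (d - xm) ** 2).sum()
        if sxx <= 0:
            fitted[gi] = ym
        else:
            beta = (w * (d - xm) * (r - ym)).sum() / sxx
            fitted[gi] = ym + beta * (x0 - xm)
    return grid, np.clip(fitted, 0.0, 1.0)


# ---------------------------------------------------------------------- #
# diversity helper (used by sweep diagnostics)

def nucleotide_diversity(m: SnpMatrix, chrom: str, start: int, end: int) -> float:
    """Sum over sites in [start, end) of unbiased pairwise heterozygosity."""
    idx = m.sites_in_interval(chrom, start, end)
    pi = 0.0
    for i in idx:
        g = m.genotypes[i]
        called = g != MISSING
        n = int(called.sum())
        if n < 2:
            continue
        f = g[called].mean()
        pi += 2.0 * f * (1.0 - f) * n / (n - 1)
    return pi
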