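import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnselect import (
    GenomicNeighborhood, Locus, LocusTable, SnpMatrix, build_neighborhoods,
    compare_gn_groups, fisher_association, gn_ld_count, ld_decay_loess,
    osc_locus_inventory, r_squared, window_ld_pairs,
)
from gnselect.ld_neighborhood import LdPairTable
from gnselect.exceptions import (
    DegenerateVarianceError, InsufficientDataError, LabelConflictError,
    MonomorphicSiteError,
)

from conftest import random_panel
from oracles import naive_r_squared


class TestRSquared:
    def test_identical_columns(self):
        assert r_squared([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_balanced_independent(self):
        assert r_squared([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # oracle: naive squared Pearson correlation of the two 0/1 vectors
        a = [0, 0, 0, 1, 1, 1, 1, 1]
        b = [0, 0, 1, 1, 1, 1, 1, 0]
        assert naive_r_squared(a, b) == pytest.approx(49 / 225)
        assert r_squared(a, b) == pytest.approx(49 / 225, abs=1e-12)

    def test_symmetry_and_label_swap(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, 12)
            b = rng.integers(0, 2, 12)
            if a.min() == a.max() or b.min() == b.max():
                continue
            v = r_squared(a, b)
            assert r_squared(b, a) == pytest.approx(v)
            assert r_squared(1 - a, b) == pytest.approx(v)
            assert r_squared(a, 1 - b) == pytest.approx(v)

    def test_missing_pairwise_deletion(self):
        a = [0, 0, 1, 1, -1]
        b = [0, 0, 1, 1, 1]
        assert r_squared(a, b) == pytest.approx(1.0)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicSiteError):
            r_squared([0, 0, 0, 0], [0, 1, 0, 1])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=4, max_size=40))
    def test_matches_naive_pearson(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        if len(set(a)) < 2 or len(set(b)) < 2:
            return
        assert r_squared(a, b) == pytest.approx(naive_r_squared(a, b),
                                                abs=1e-12)


class TestFisher:
    def test_two_by_two_diagonal(self):
        # enumeration over hypergeometric support {0,1,2}: p = 1/6 + 1/6
        assert fisher_association([1, 1, 0, 0], [1, 1, 0, 0]) == \
            pytest.approx(1 / 3)

    def test_no_association(self):
        a = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        b = [1] * 5 + [1] * 5 + [0] * 5 + [0] * 5
        assert fisher_association(a, b) == pytest.approx(1.0)

    def test_in_unit_interval_and_swap_invariant(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, 16)
            b = rng.integers(0, 2, 16)
            if a.min() == a.max() or b.min() == b.max():
                continue
            p = fisher_association(a, b)
            assert 0 < p <= 1
            assert fisher_association(1 - a, b) == pytest.approx(p)
            assert fisher_association(b, a) == pytest.approx(p)


class TestBuildNeighborhoods:
    def test_inventory_gives_nine_neighborhoods(self):
        gns = build_neighborhoods(osc_locus_inventory())
        assert len(gns) == 9
        labels = [g.group_label for g in gns]
        assert labels.count("clustered") == 4
        assert labels.count("non_clustered") == 5
        merged = {g.gn_id for g in gns if len(g.focal_loci) > 1}
        assert merged == {"At4g15340+At4g15370",
                          "At1g78950+At1g78955+At1g78960+At1g78970"}

    def test_single_locus_flank(self):
        table = LocusTable([Locus("g", "1", 100_000, 104_000)])
        gn, = build_neighborhoods(table, flank_bp=50_000)
        assert gn.span == (50_000, 154_000)

    def test_distant_loci_not_merged(self):
        table = LocusTable([Locus("a", "1", 0, 1000),
                            Locus("b", "1", 1_000_000, 1_001_000)])
        assert len(build_neighborhoods(table, tandem_merge_bp=50_000)) == 2

    def test_label_conflict(self):
        table = LocusTable([
            Locus("a", "1", 0, 1000, "clustered"),
            Locus("b", "1", 2000, 3000, "non_clustered"),
        ])
        with pytest.raises(LabelConflictError):
            build_neighborhoods(table, tandem_merge_bp=50_000)


def _panel_from_columns(columns, positions):
    geno = np.array(columns, dtype=np.int8)
    return SnpMatrix(chrom=np.full(len(positions), "1", dtype=object),
                     pos=positions,
                     ref_allele=np.full(len(positions), "A", dtype=object),
                     alt_allele=np.full(len(positions), "T", dtype=object),
                     genotypes=geno,
                     sample_ids=[f"s{i}" for i in range(geno.shape[1])])


class TestWindowLdPairs:
    def test_three_identical_sites(self):
        col = [0, 0, 0, 0, 1, 1, 1, 1]
        m = _panel_from_columns([col, col, col], [100, 200, 300])
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 1000, None)
        table = window_ld_pairs(m, gn, r2_threshold=0.1, maf_min=0.05)
        assert gn_ld_count(table) == 3
        assert np.allclose(table.df["r2"], 1.0)

    def test_orthogonal_sites_yield_nothing(self):
        cols = [[0, 0, 0, 0, 1, 1, 1, 1],
                [0, 0, 1, 1, 0, 0, 1, 1],
                [0, 1, 0, 1, 0, 1, 0, 1],
                [0, 1, 1, 0, 0, 1, 1, 0]]
        m = _panel_from_columns(cols, [100, 200, 300, 400])
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 1000, None)
        assert gn_ld_count(window_ld_pairs(m, gn, 0.1, 0.05)) == 0

    def test_too_few_sites_is_empty_not_error(self):
        m = _panel_from_columns([[0, 1, 0, 1]], [100])
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 1000, None)
        assert gn_ld_count(window_ld_pairs(m, gn)) == 0

    def test_matches_brute_force_all_pairs(self, rng):
        m = random_panel(rng, n_sites=40, n_samples=24, missing_rate=0.05)
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 10**6, None)
        thr, maf = 0.1, 0.05
        table = window_ld_pairs(m, gn, r2_threshold=thr, maf_min=maf)
        # independent recomputation: per-site filter then all-pairs loop
        usable = []
        for i in range(m.n_sites):
            calls = [g for g in m.genotypes[i] if g != -1]
            f = sum(calls) / len(calls)
            if 0 < f < 1 and min(f, 1 - f) >= maf:
                usable.append(i)
        expected = 0
        for x in range(len(usable)):
            for y in range(x + 1, len(usable)):
                i, j = usable[x], usable[y]
                a, b = m.genotypes[i], m.genotypes[j]
                keep = (a != -1) & (b != -1)
                aa, bb = a[keep], b[keep]
                if len(aa) < 2 or aa.min() == aa.max() or bb.min() == bb.max():
                    continue
                if naive_r_squared(aa, bb) > thr:
                    expected += 1
        assert gn_ld_count(table) == expected

    def test_count_monotone_in_threshold(self, rng):
        m = random_panel(rng, n_sites=30, n_samples=16)
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 10**6, None)
        counts = [gn_ld_count(window_ld_pairs(m, gn, thr, 0.05))
                  for thr in (0.05, 0.1, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_distance_column(self):
        col = [0, 0, 0, 0, 1, 1, 1, 1]
        m = _panel_from_columns([col, col], [100, 350])
        gn = GenomicNeighborhood("g", "1", ("g",), 0, 1000, None)
        table = window_ld_pairs(m, gn)
        assert table.df["distance_bp"].tolist() == [250]


class TestCompareGroups:
    def test_df_follows_group_sizes(self):
        res = compare_gn_groups([5, 7, 6, 9, 1, 2, 3, 1, 2],
                                ["clustered"] * 4 + ["non_clustered"] * 5)
        assert res.df == 7
        assert res.n_clustered == 4 and res.n_nonclustered == 5

    def test_equal_constant_groups(self):
        res = compare_gn_groups([3, 3, 3, 3, 3, 3],
                                ["clustered"] * 3 + ["non_clustered"] * 3)
        assert res.t_statistic == 0.0
        assert res.p_two_sided == 1.0
        assert res.df == 4

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVarianceError):
            compare_gn_groups([10, 10, 0, 0],
                              ["clustered", "clustered",
                               "non_clustered", "non_clustered"])

    def test_matches_scipy(self, rng):
        x = rng.poisson(20, 6).astype(float)
        y = rng.poisson(10, 5).astype(float)
        from scipy import stats
        t, p = stats.ttest_ind(x, y, equal_var=True)
        res = compare_gn_groups(np.concatenate([x, y]),
                                ["clustered"] * 6 + ["non_clustered"] * 5)
        assert res.t_statistic == pytest.approx(t)
        assert res.p_two_sided == pytest.approx(p)


def _table(distances, r2s):
    df = pd.DataFrame({
        "site_i": range(len(distances)), "site_j": range(len(distances)),
        "pos_i": 0, "pos_j": distances, "distance_bp": distances, "r2": r2s,
        "fisher_p": 1.0})
    return LdPairTable(df, gn_id="t")


class TestLoess:
    def test_constant_response(self, rng):
        d = rng.uniform(0, 50_000, 60)
        grid, fit = ld_decay_loess(_table(d, np.full(60, 0.4)))
        assert np.allclose(fit, 0.4, atol=1e-9)

    def test_recovers_noiseless_decay(self, rng):
        d = np.sort(rng.uniform(0, 100_000, 200))
        r2 = 1.0 / (1.0 + d / 10_000)
        # narrow span: local-linear bias on this sharply curved response
        # exceeds 0.02 for span >= 0.15 (checked against the generator)
        grid, fit = ld_decay_loess(_table(d, r2), span=0.1)
        truth = 1.0 / (1.0 + grid / 10_000)
        interior = (grid > np.quantile(d, 0.05)) & (grid < np.quantile(d, 0.95))
        assert np.max(np.abs(fit[interior] - truth[interior])) < 0.02

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            ld_decay_loess(_table(np.arange(5), np.full(5, 0.2)))

    def test_output_clamped(self, rng):
        d = rng.uniform(0, 1000, 30)
        grid, fit = ld_decay_loess(_table(d, rng.uniform(0, 1, 30)))
        assert fit.min() >= 0 and fit.max() <= 1
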