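import math

import numpy as np
import pandas as pd
import pytest

from crispmeth import simulate_all
from crispmeth.dmr import (
    annotate_dmrs,
    call_dmrs,
    find_dmrs,
    fisher_two_sided,
    fold_change,
    pool_counts,
    pool_replicates,
    promoter_dmgs,
    scan_windows,
)
from crispmeth.io_formats import AnnotationSet, GeneModel

from conftest import make_calls, small_config


def fisher_oracle(a, b, c, d):
    """Exact-rational brute-force two-sided Fisher p (independent oracle)."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - r2), min(r1, k)
    weights = {aa: math.comb(r1, aa) * math.comb(r2, k - aa)
               for aa in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return num / math.comb(n, k)


class TestFisher:
    def test_five_vs_zero_split(self):
        # C(10,5)=252 tables conditioned on margins; the two extremes weigh 1
        assert fisher_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-12)

    def test_balanced_table_is_one(self):
        assert fisher_two_sided(3, 3, 3, 3) == 1.0

    def test_all_zero_table_convention(self):
        assert fisher_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_matches_exact_enumeration_on_random_tables(self, rng):
        for _ in range(400):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            assert fisher_two_sided(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-10
            )

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, 4))
            ref = fisher_exact([[a, b], [c, d]])[1]
            assert fisher_two_sided(a, b, c, d) == pytest.approx(ref, rel=1e-7)

    def test_symmetry_under_row_and_column_swaps(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            p = fisher_two_sided(a, b, c, d)
            assert fisher_two_sided(c, d, a, b) == pytest.approx(p, abs=1e-12)
            assert fisher_two_sided(b, a, d, c) == pytest.approx(p, abs=1e-12)


class TestPooling:
    def test_two_replicates_pool_to_summed_counts(self):
        r1 = make_calls([("chr1", 100, "+", "CG", 3, 4)])
        r2 = make_calls([("chr1", 100, "+", "CG", 1, 6)])
        pooled = pool_replicates([r1, r2])
        assert pooled.iloc[0].meth == 4 and pooled.iloc[0].total == 10

    def test_cg_strands_merge_to_forward_unit(self):
        df = make_calls(
            [("chr1", 100, "+", "CG", 2, 5), ("chr1", 101, "-", "CG", 3, 5),
             ("chr1", 200, "+", "CHH", 1, 5)]
        )
        pooled = pool_replicates([df])
        cg = pooled[pooled.context == "CG"]
        assert len(cg) == 1 and cg.iloc[0].pos == 100
        assert cg.iloc[0].meth == 5 and cg.iloc[0].total == 10
        assert (pooled[pooled.context == "CHH"].pos == 200).all()

    def test_empty_interval_pools_to_zero(self):
        a = pool_replicates([make_calls([("chr1", 100, "+", "CG", 3, 8)])])
        b = pool_replicates([make_calls([("chr1", 100, "+", "CG", 1, 8)])])
        assert pool_counts(a, b, "chr1", 5000, 6000) == (0, 0, 0, 0, 0)

    def test_interval_pooling_matches_enumeration_oracle(self, rng):
        n = 300
        pos = np.sort(rng.choice(20_000, n, replace=False))
        rows_a, rows_b = [], []
        for p in pos:
            ta, tb = int(rng.integers(4, 30)), int(rng.integers(4, 30))
            rows_a.append(("chr1", int(p), "+", "CG", int(rng.integers(0, ta + 1)), ta))
            rows_b.append(("chr1", int(p), "+", "CG", int(rng.integers(0, tb + 1)), tb))
        pa = pool_replicates([make_calls(rows_a)])
        pb = pool_replicates([make_calls(rows_b)])
        for _ in range(200):
            s = int(rng.integers(0, 19_000))
            e = s + int(rng.integers(100, 2000))
            got = pool_counts(pa, pb, "chr1", s, e)
            # brute-force site enumeration
            ma = ta = mb = tb = nc = 0
            for ra, rb in zip(rows_a, rows_b):
                if s <= ra[1] < e:
                    ma += ra[4]; ta += ra[5]; mb += rb[4]; tb += rb[5]; nc += 1
            assert got == (ma, ta, mb, tb, nc)

    def test_coverage_floor_applies_in_both_groups(self):
        a = pool_replicates([make_calls([("chr1", 100, "+", "CG", 3, 10)])])
        b = pool_replicates([make_calls([("chr1", 100, "+", "CG", 1, 3)])])
        assert pool_counts(a, b, "chr1", 0, 1000, min_total=4)[4] == 0


def _window_fixture(level_a, level_b, n_sites=8, depth=25, start=0):
    rows_a, rows_b = [], []
    for i in range(n_sites):
        p = start + 10 + i * 40
        rows_a.append(("chr1", p, "+", "CG", int(round(level_a * depth)), depth))
        rows_b.append(("chr1", p, "+", "CG", int(round(level_b * depth)), depth))
    return make_calls(rows_a), make_calls(rows_b)


class TestScanWindows:
    def test_identical_groups_are_null(self):
        a, _ = _window_fixture(0.5, 0.5)
        w = scan_windows([a], [a], width=400, step=400)
        assert (w.fold_change == 1.0).all() and (w.p_value == 1.0).all()

    def test_strong_contrast_is_significant(self):
        a, b = _window_fixture(0.9, 0.1, n_sites=5, depth=10)
        w = scan_windows([a], [b], width=400, step=400, min_cpg=5)
        assert len(w) == 1
        row = w.iloc[0]
        # pooled counts give the 2x2 table (45,5 / 5,45): levels 0.9 vs 0.1
        # at a pooled depth of 50 per group
        assert (row.meth_a, row.total_a, row.meth_b, row.total_b) == (45, 50, 5, 50)
        assert row.p_value == pytest.approx(fisher_oracle(45, 5, 5, 45), abs=1e-12)
        assert row.p_value < 0.05 and row.fold_change == pytest.approx(9.0)

    def test_min_cpg_filter_drops_sparse_windows(self):
        a, b = _window_fixture(0.9, 0.1, n_sites=4)
        w = scan_windows([a], [b], width=400, step=400, min_cpg=5)
        assert len(w) == 0

    def test_bad_geometry_rejected(self):
        a, b = _window_fixture(0.5, 0.5)
        with pytest.raises(ValueError):
            scan_windows([a], [b], width=0, step=10)

    def test_step_larger_than_width_warns(self):
        a, b = _window_fixture(0.5, 0.5)
        with pytest.warns(UserWarning, match="gaps"):
            scan_windows([a], [b], width=100, step=400)


class TestCallDmrs:
    def test_no_significant_windows_gives_empty_list(self):
        a, _ = _window_fixture(0.5, 0.5)
        w = scan_windows([a], [a], width=400, step=200)
        assert len(call_dmrs(w)) == 0

    def test_overlapping_same_direction_windows_merge(self):
        a, b = _window_fixture(0.9, 0.1, n_sites=30, depth=25)
        w = scan_windows([a], [b], width=400, step=200,
                         chrom_lengths={"chr1": 1400})
        dmrs = call_dmrs(w, pooled_a=pool_replicates([a]),
                         pooled_b=pool_replicates([b]))
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d.n_windows > 1
        assert d.start == w.start.min() and d.end == w.end.max()
        # merged stats recomputed over the merged span: all 30 sites
        assert d.n_cpg == 30

    def test_opposite_directions_do_not_merge(self):
        a1, b1 = _window_fixture(0.9, 0.1, n_sites=8, start=0)
        a2, b2 = _window_fixture(0.1, 0.9, n_sites=8, start=400)
        a = pd.concat([a1, a2], ignore_index=True)
        b = pd.concat([b1, b2], ignore_index=True)
        w = scan_windows([a], [b], width=400, step=400,
                         chrom_lengths={"chr1": 800})
        dmrs = call_dmrs(w)
        assert len(dmrs) == 2
        assert set(dmrs.direction) == {"hyper_in_A", "hypo_in_A"}

    def test_merge_is_idempotent(self):
        a, b = _window_fixture(0.9, 0.1, n_sites=30, depth=25)
        w = scan_windows([a], [b], width=400, step=200,
                         chrom_lengths={"chr1": 1400})
        pa, pb = pool_replicates([a]), pool_replicates([b])
        once = call_dmrs(w, pooled_a=pa, pooled_b=pb)
        # re-scan restricted to the called region reproduces the same span
        again = call_dmrs(once.assign(q_value=0.0), pooled_a=pa, pooled_b=pb)
        assert len(again) == 1
        assert (again.iloc[0].start, again.iloc[0].end) == (
            once.iloc[0].start, once.iloc[0].end
        )

    def test_fold_change_pseudocount_keeps_zero_levels_callable(self):
        assert fold_change(0.4, 0.0) == pytest.approx(0.4 / 1e-6)


class TestRecovery:
    def test_planted_dmrs_recovered_on_small_genome(self, small_bundle):
        ta, tb = small_bundle.group_tables()
        lengths = {c: len(s) for c, s in small_bundle.sequences.items()}
        dmrs, _ = find_dmrs(ta, tb, chrom_lengths=lengths)
        truth = small_bundle.truth.dmr_intervals()
        called = list(zip(dmrs.chrom, dmrs.start, dmrs.end))

        def hit(x, y):
            return x[0] == y[0] and x[1] < y[2] and x[2] > y[1]

        recall = np.mean([any(hit(c, t) for c in called) for t in truth])
        precision = np.mean([any(hit(c, t) for t in truth) for c in called])
        assert recall >= 0.9 and precision >= 0.9

    def test_recall_non_decreasing_in_effect_size(self):
        recalls = []
        for delta in (0.15, 0.3, 0.5):
            b = simulate_all(small_config(seed=23, dmr_effect=delta))
            ta, tb = b.group_tables()
            dmrs, _ = find_dmrs(
                ta, tb, chrom_lengths={c: len(s) for c, s in b.sequences.items()}
            )
            truth = b.truth.dmr_intervals()
            called = list(zip(dmrs.chrom, dmrs.start, dmrs.end))
            recalls.append(
                np.mean([
                    any(c[0] == t[0] and c[1] < t[2] and c[2] > t[1]
                        for c in called)
                    for t in truth
                ])
            )
        assert recalls[0] <= recalls[1] <= recalls[2]

    def test_recall_non_decreasing_in_coverage(self):
        recalls = []
        for cov in (2.0, 6.0, 20.0):
            b = simulate_all(small_config(seed=29, mean_coverage=cov))
            ta, tb = b.group_tables()
            dmrs, _ = find_dmrs(
                ta, tb, chrom_lengths={c: len(s) for c, s in b.sequences.items()}
            )
            truth = b.truth.dmr_intervals()
            called = list(zip(dmrs.chrom, dmrs.start, dmrs.end))
            recalls.append(
                np.mean([
                    any(c[0] == t[0] and c[1] < t[2] and c[2] > t[1]
                        for c in called)
                    for t in truth
                ])
            )
        assert recalls[0] <= recalls[1] <= recalls[2]


class TestAnnotation:
    def _annotation(self):
        genes = [
            GeneModel("gP", "chr1", "+", ((5000, 5500), (6000, 6500)),
                      chrom_length=50_000),
            GeneModel("gM", "chr1", "-", ((20_000, 20_400),),
                      chrom_length=50_000),
        ]
        return AnnotationSet(genes=genes, chrom_lengths={"chr1": 50_000})

    def _dmr(self, chrom, start, end):
        return pd.DataFrame(
            [{"chrom": chrom, "start": start, "end": end, "n_cpg": 6,
              "level_a": 0.9, "level_b": 0.2, "fold_change": 4.5,
              "p_value": 1e-4, "direction": "hyper_in_A", "context": "CG",
              "n_windows": 1}]
        )

    def test_dmr_inside_promoter_is_promoter_hit(self):
        ann = self._annotation()
        hits = annotate_dmrs(self._dmr("chr1", 3500, 4200), ann)
        assert {(h.gene_id, h.feature) for h in hits} == {("gP", "promoter")}
        assert promoter_dmgs(hits) == {"gP"}

    def test_zero_length_touch_is_not_a_hit(self):
        # promoter of gP is [3000, 5000): a DMR ending exactly at 3000
        # shares no base under half-open intersection
        ann = self._annotation()
        hits = annotate_dmrs(self._dmr("chr1", 2500, 3000), ann)
        assert promoter_dmgs(hits) == set()
        assert annotate_dmrs(self._dmr("chr1", 5000, 5001), ann)

    def test_minus_strand_promoter_is_downstream_of_gene_end(self):
        ann = self._annotation()
        hits = annotate_dmrs(self._dmr("chr1", 20_500, 21_000), ann)
        assert ("gM", "promoter") in {(h.gene_id, h.feature) for h in hits}

    def test_unknown_chromosome_left_unannotated(self):
        ann = self._annotation()
        assert annotate_dmrs(self._dmr("chrZ", 0, 1000), ann) == []

    def test_matches_quadratic_overlap_oracle(self, rng):
        ann = self._annotation()
        feature_map = []
        for g in ann.genes:
            feature_map.append((g.gene_id, "promoter", *g.promoter))
            feature_map.append((g.gene_id, "downstream", *g.downstream_region))
            for s, e in g.exons:
                feature_map.append((g.gene_id, "exon", s, e))
            for s, e in g.introns:
                feature_map.append((g.gene_id, "intron", s, e))
        rows = []
        for _ in range(100):
            s = int(rng.integers(0, 48_000))
            rows.append({"chrom": "chr1", "start": s,
                         "end": s + int(rng.integers(50, 3000)),
                         "n_cpg": 5, "level_a": 0.5, "level_b": 0.1,
                         "fold_change": 5.0, "p_value": 0.01,
                         "direction": "hyper_in_A", "context": "CG",
                         "n_windows": 1})
        dmrs = pd.DataFrame(rows)
        got = {(h.dmr_index, h.gene_id, h.feature)
               for h in annotate_dmrs(dmrs, ann)}
        expected = set()
        for i, r in dmrs.iterrows():
            for gid, feat, fs, fe in feature_map:
                if r.start < fe and r.end > fs:
                    expected.add((i, gid, feat))
        assert got == expected
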