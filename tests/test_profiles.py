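"""Activity matrices, hierarchical clustering, enrichment, 2D-vs-3D."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import qscreen as q

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_merges(dist, method):
    """Naive O(n^3) agglomeration; returns the sequence of merged leaf-sets
    with merge heights.  Independent of scipy's linkage implementation."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            pair_d = [dist[i, j] for i in clusters[a] for j in clusters[b]]
            d = max(pair_d) if method == "complete" else min(pair_d)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[n + len(merges)] = merged
        merges.append((merged, d))
    return merges


def linkage_merges(z, n):
    """Convert a scipy linkage matrix to the same (leaf-set, height) form."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, d, _) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        merges.append((merged, float(d)))
    return merges


def hypergeom_tail_exact(k, N, K, n):
    """P(X >= k) by exact rational enumeration."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(total)


def rand_index(labels_a, labels_b):
    n = len(labels_a)
    agree = sum(
        (labels_a[i] == labels_a[j]) == (labels_b[i] == labels_b[j])
        for i, j in combinations(range(n), 2)
    )
    return agree / math.comb(n, 2)


# ---------------------------------------------------------------------------
# matrix building
# ---------------------------------------------------------------------------


def summary_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "cell_line", "is_active",
                                       "auc", "log10_ic50"])


class TestBuildMatrix:
    def test_inactive_row_is_zero_for_auc(self):
        df = summary_frame([("c1", "L1", False, np.nan, np.nan),
                            ("c1", "L2", False, np.nan, np.nan)])
        mat = q.build_matrix(df, "auc")
        assert (mat.loc["c1"] == 0).all()

    def test_inactive_row_is_missing_for_potency(self):
        df = summary_frame([("c1", "L1", False, np.nan, np.nan),
                            ("c1", "L2", False, np.nan, np.nan),
                            ("c2", "L1", True, 40.0, -7.0),
                            ("c2", "L2", True, 55.0, -7.5)])
        mat = q.build_matrix(df, "log_ic50")
        assert mat.loc["c1"].isna().all()
        assert mat.loc["c2"].notna().all()

    def test_dimensions_match_universe(self, series11):
        lib = q.generate_library(8, seed=3)
        plates = q.simulate_viability_screen(lib, ["L1", "L2", "L3"], series11,
                                             seed=4)
        result = q.analyze_viability_screen(plates)
        mat = q.build_matrix(result.consensus, "auc")
        assert mat.shape == (8, 3)

    def test_duplicate_cells_rejected(self):
        df = summary_frame([("c1", "L1", True, 40.0, -7.0),
                            ("c1", "L1", True, 41.0, -7.0)])
        with pytest.raises(q.DataIntegrityError):
            q.build_matrix(df, "auc")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class TestClustering:
    def test_identical_rows_are_adjacent_at_distance_zero(self):
        mat = pd.DataFrame(
            [[10, 0, 5], [0, 9, 1], [10, 0, 5]],
            index=["a", "b", "c"], columns=["L1", "L2", "L3"], dtype=float,
        )
        res = q.hierarchical_cluster(mat, cluster_columns=False)
        i, j = res.row_order.index("a"), res.row_order.index("c")
        assert abs(i - j) == 1
        assert res.row_linkage[0, 2] == 0.0

    @pytest.mark.parametrize("method", ["complete", "single"])
    @pytest.mark.parametrize("n_rows", [3, 5, 6])
    def test_merge_order_matches_brute_force(self, method, n_rows):
        rng = np.random.default_rng(n_rows)
        x = rng.normal(size=(n_rows, 4))
        mat = pd.DataFrame(x, index=[f"r{i}" for i in range(n_rows)],
                           columns=list("abcd"))
        res = q.hierarchical_cluster(mat, linkage_method=method,
                                     cluster_columns=False)
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        expected = brute_force_merges(dist, method)
        got = linkage_merges(res.row_linkage, n_rows)
        for (set_a, d_a), (set_b, d_b) in zip(expected, got):
            assert set_a == set_b
            assert d_a == pytest.approx(d_b, abs=1e-9)

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(5)
        block1 = 80.0 + rng.normal(0, 2, size=(10, 6))
        block2 = rng.normal(0, 2, size=(10, 6))
        x = np.vstack([block1, block2])
        ids = [f"hot{i}" for i in range(10)] + [f"cold{i}" for i in range(10)]
        mat = pd.DataFrame(x, index=ids, columns=[f"L{j}" for j in range(6)])
        res = q.hierarchical_cluster(mat, cluster_columns=False)
        labels = q.cut_clusters(res, 2)
        truth = {i: (0 if i.startswith("hot") else 1) for i in ids}
        ri = rand_index([truth[i] for i in ids], [labels[i] for i in ids])
        assert ri == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 5))
        ids = [f"r{i}" for i in range(8)]
        mat = pd.DataFrame(x, index=ids, columns=list("abcde"))
        shuffled = mat.sample(frac=1, random_state=1)
        a = q.hierarchical_cluster(mat, cluster_columns=False)
        b = q.hierarchical_cluster(shuffled, cluster_columns=False)
        assert a.row_order == b.row_order

    def test_all_missing_row_excluded_with_warning(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 0.5], [np.nan, np.nan, np.nan], [1.1, 2.2, 0.4],
             [5.0, 6.0, 7.0]],
            index=list("abcd"), columns=["L1", "L2", "L3"],
        )
        with pytest.warns(UserWarning, match="all-missing"):
            res = q.hierarchical_cluster(mat, cluster_columns=False)
        assert "b" not in res.row_order
        assert len(res.row_order) == 3

    def test_sparse_overlap_uses_max_observed_distance(self):
        mat = pd.DataFrame(
            [
                [1.0, 1.0, 1.0, 1.0],
                [1.1, 1.2, 0.9, 1.0],
                [np.nan, np.nan, np.nan, 5.0],
            ],
            index=list("abc"), columns=["L1", "L2", "L3", "L4"],
        )
        res = q.hierarchical_cluster(mat, min_overlap=3, cluster_columns=False)
        # c shares only one finite cell with a and b -> pushed out at the
        # maximum observed distance, so a and b merge first
        got = linkage_merges(res.row_linkage, 3)
        assert got[0][0] == frozenset([0, 1])


def test_heatmap_export_writes_file(tmp_path):
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.uniform(0, 100, size=(6, 4)),
                       index=[f"c{i}" for i in range(6)],
                       columns=[f"L{j}" for j in range(4)])
    mat.iloc[0, 0] = np.nan  # missing cell renders grey, must not crash
    res = q.hierarchical_cluster(mat.fillna(mat.mean().mean()))
    out = tmp_path / "heatmap.png"
    q.plot_activity_heatmap(mat, res, out)
    assert out.stat().st_size > 0


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


class TestEnrichment:
    def test_hits_equal_background_p_is_one(self):
        bg = [f"c{i}" for i in range(12)]
        cats = {c: ("kinase" if i % 3 else "HDAC") for i, c in enumerate(bg)}
        for r in q.enrichment_test(bg, bg, cats):
            assert r.p_value == 1.0

    def test_closed_form_full_overlap(self):
        bg = [f"c{i}" for i in range(20)]
        cats = {c: ("topo" if i < 5 else "other") for i, c in enumerate(bg)}
        hits = bg[:5]
        res = {r.category: r for r in q.enrichment_test(hits, bg, cats)}
        assert res["topo"].p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 31))
        bg = [f"c{i}" for i in range(N)]
        cats = {c: f"cat{rng.integers(0, 3)}" for c in bg}
        hits = list(rng.choice(bg, size=int(rng.integers(1, N)), replace=False))
        for r in q.enrichment_test(hits, bg, cats):
            assert r.p_value == pytest.approx(
                hypergeom_tail_exact(r.k, r.N, r.K, r.n), abs=1e-12
            )

    def test_bh_q_values_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        bg = [f"c{i}" for i in range(40)]
        cats = {c: f"cat{rng.integers(0, 6)}" for c in bg}
        hits = list(rng.choice(bg, size=12, replace=False))
        res = q.enrichment_test(hits, bg, cats)
        ps = [r.p_value for r in res]
        qs = [r.q_value for r in res]
        assert all(0 < v <= 1 for v in ps + qs)
        assert sorted(ps) == ps  # results sorted by p
        assert sorted(qs) == qs  # BH preserves the p ordering

    def test_label_exchangeability_mean_p(self):
        """Permuting hit labels gives p-values with the exchangeable mean."""
        rng = np.random.default_rng(8)
        N, n, K = 30, 10, 8
        bg = [f"c{i}" for i in range(N)]
        cats = {c: ("A" if i < K else "B") for i, c in enumerate(bg)}
        # E[p] under the null by enumeration over k
        expected = sum(
            (hypergeom_tail_exact(k, N, K, n) - hypergeom_tail_exact(k + 1, N, K, n))
            * hypergeom_tail_exact(k, N, K, n)
            for k in range(0, min(K, n) + 1)
        )
        ps = []
        for _ in range(500):
            hits = list(rng.choice(bg, size=n, replace=False))
            res = {r.category: r for r in q.enrichment_test(hits, bg, cats)}
            ps.append(res["A"].p_value)
        assert np.mean(ps) == pytest.approx(expected, abs=0.05)

    def test_empty_background_rejected(self):
        with pytest.raises(q.InvalidParameterError):
            q.enrichment_test([], [], {})

    def test_hits_outside_background_rejected(self):
        with pytest.raises(q.InvalidParameterError):
            q.enrichment_test(["x"], ["a", "b"], {"a": "t", "b": "t"})

    def test_unannotated_compounds_drop_from_background(self):
        bg = ["a", "b", "c", "d"]
        cats = {"a": "t", "b": "t", "c": "", "d": "t"}
        res = q.enrichment_test(["a"], bg, cats)
        assert res[0].N == 3


# ---------------------------------------------------------------------------
# 2D vs 3D comparison
# ---------------------------------------------------------------------------


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["compound_id", "cell_line", "ic50_2d",
                                       "ic50_3d"])


class TestCompare2D3D:
    def test_identical_potencies(self):
        rows = [(f"c{i}", "L1", v, v) for i, v in enumerate([1e-8, 1e-7, 1e-6, 5e-6])]
        corr, conc = q.compare_2d_3d(pairs_frame(rows))
        assert corr.loc[0, "rank_correlation"] == pytest.approx(1.0)
        assert (conc["label"] == "concordant_active").all()

    def test_3d_only_label(self):
        rows = [("acyclovir-like", "L1", np.nan, 1e-6),
                ("x1", "L1", 1e-7, 1e-7), ("x2", "L1", 1e-8, 1e-8),
                ("x3", "L1", 1e-6, 1e-6), ("dead-in-2d", "L1", 1e-7, np.nan)]
        _, conc = q.compare_2d_3d(pairs_frame(rows))
        lab = conc.set_index("compound_id")["label"]
        assert lab["acyclovir-like"] == "3d_only"
        assert lab["dead-in-2d"] == "2d_only"

    def test_censored_potency_counts_as_inactive(self):
        rows = [("c1", "L1", 50e-6, 50e-6)]  # >10 uM in both formats
        with pytest.warns(UserWarning):
            _, conc = q.compare_2d_3d(pairs_frame(rows))
        assert conc.loc[0, "label"] == "concordant_inactive"

    def test_too_few_pairs_omits_correlation(self):
        rows = [("c1", "L1", 1e-7, 1e-7), ("c2", "L1", 1e-6, 1e-6)]
        with pytest.warns(UserWarning, match="correlation omitted"):
            corr, conc = q.compare_2d_3d(pairs_frame(rows))
        assert np.isnan(corr.loc[0, "rank_correlation"])
        assert len(conc) == 2

    def test_known_3d_shift_preserves_ranking(self, series11):
        """2D and 3D screens of the same compounds correlate strongly."""
        lib = q.generate_library(25, {"complete_full": 1.0},
                                 ic50_range=(5e-9, 3e-6), seed=41)
        p2d = q.simulate_viability_screen(lib, ["TC32"], series11,
                                          noise_cv=0.05, seed=42)
        res2d = q.analyze_viability_screen(p2d)
        cp = q.SpheroidCoupling(noise_cv=0.05)
        p3d = q.simulate_spheroid_plate(lib, "TC32", series11, replicates=3,
                                        coupling=cp, seed=43)
        lum = [p for p in p3d if p.readout == "luminescence"]
        fits3d, calls3d = q.fit_series_table(q.ctg_viability(lum))
        cons3d, _ = q.consensus_table(fits3d, calls3d)
        merged = res2d.consensus.merge(cons3d, on="compound_id",
                                       suffixes=("_2d", "_3d"))
        rows = pairs_frame([
            (r.compound_id, "TC32", r.ic50_molar_2d, r.ic50_molar_3d)
            for r in merged.itertuples()
        ])
        corr, _ = q.compare_2d_3d(rows)
        assert corr.loc[0, "rank_correlation"] >= 0.9
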