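import itertools

import numpy as np
import pandas as pd
import pytest

from regscan.enrichment import PeakExperiment
from regscan.similarity import (
    TargetGeneSet,
    build_regulatory_matrix,
    build_target_sets,
    gene_distance,
    gsea_batch,
    gsea_signal_integration,
    overrepresentation,
    pca_project,
    preranked_gsea,
    set_overlap_compare,
)


def peaks(factor, starts, ends, scores, eid="E0"):
    return PeakExperiment(eid, factor, "t", np.asarray(starts), np.asarray(ends), np.asarray(scores))


def tss_table(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


class TestBuildTargetSets:
    TSS = tss_table([("GENE1", "chr1", 5_000, "+")])

    def test_promoter_peak_above_threshold_is_target(self):
        sets = build_target_sets([peaks("TF1", [4_500], [4_700], [60.0])], self.TSS)
        assert sets[0].genes == ["GENE1"]

    def test_score_filter_boundary_excludes(self):
        sets = build_target_sets([peaks("TF1", [4_500], [4_700], [40.0])], self.TSS)
        assert sets[0].genes == []

    def test_mean_score_across_experiments_then_threshold(self):
        exps = [
            peaks("TF1", [4_500], [4_700], [40.0], eid="E0"),
            peaks("TF1", [4_600], [4_800], [80.0], eid="E1"),
        ]
        sets = build_target_sets(exps, self.TSS)
        assert sets[0].genes == ["GENE1"]
        assert sets[0].mean_scores["GENE1"] == pytest.approx(60.0)

    def test_peak_outside_promoter_window_ignored(self):
        # promoter is [4000, 6000); a peak ending at 4000 does not overlap
        sets = build_target_sets([peaks("TF1", [3_900], [4_000], [99.0])], self.TSS)
        assert sets[0].genes == []

    def test_missing_strand_warns_and_defaults(self):
        tss = pd.DataFrame([("GENE1", "chr1", 5_000)], columns=["gene", "chrom", "tss"])
        with pytest.warns(UserWarning, match="strand"):
            sets = build_target_sets([peaks("TF1", [4_500], [4_700], [60.0])], tss)
        assert sets[0].genes == ["GENE1"]

    def test_duplicate_tss_rejected(self):
        tss = tss_table([("GENE1", "chr1", 5_000, "+"), ("GENE1", "chr1", 9_000, "+")])
        with pytest.raises(ValueError, match="one representative TSS"):
            build_target_sets([peaks("TF1", [1], [2], [60.0])], tss)


class TestGeneDistance:
    def matrix(self, rows):
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=["f1", "f2", "f3"]
        )

    def test_single_bit_difference_is_distance_one(self):
        m = self.matrix([[1, 1, 0], [1, 0, 0]])
        m.index = ["FOCAL", "g"]
        d = gene_distance(m, "FOCAL", bin_width=40)
        assert d.loc["g", "distance"] == pytest.approx(1.0)

    def test_identical_rows_distance_zero(self):
        m = self.matrix([[1, 0, 1], [1, 0, 1]])
        m.index = ["FOCAL", "twin"]
        assert gene_distance(m, "FOCAL").loc["twin", "distance"] == 0.0

    def test_matches_bruteforce_on_random_binary_rows(self, rng):
        rows = rng.integers(0, 2, size=(50, 12))
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(50)])
        d = gene_distance(m, "g0")
        for g in m.index[1:]:
            brute = np.sqrt(((m.loc[g] - m.loc["g0"]) ** 2).sum())
            assert d.loc[g, "distance"] == pytest.approx(brute)

    def test_forty_gene_bins_consecutive(self, rng):
        rows = rng.integers(0, 2, size=(130, 8))
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(130)])
        d = gene_distance(m, "g0", bin_width=40)
        counts = d["distance_bin"].value_counts().sort_index()
        assert counts.loc[0] == 40 and counts.loc[1] == 40 and counts.loc[2] == 40
        assert counts.loc[3] == 129 - 120
        # bins ordered by distance: max of bin b <= min of bin b+1
        for b in range(3):
            assert (
                d[d.distance_bin == b]["distance"].max()
                <= d[d.distance_bin == b + 1]["distance"].min() + 1e-12
            )

    def test_focal_excluded_by_default(self):
        m = self.matrix([[1, 1, 0], [0, 1, 0]])
        m.index = ["FOCAL", "g"]
        assert "FOCAL" not in gene_distance(m, "FOCAL").index
        assert "FOCAL" in gene_distance(m, "FOCAL", include_focal=True).index


class TestPcaProject:
    def test_collinear_points_put_all_variance_on_pc1(self):
        m = pd.DataFrame(
            [[1, 2], [2, 4], [3, 6], [4, 8]], index=list("abcd"), dtype=float
        )
        proj, evr = pca_project(m)
        assert evr[0] == pytest.approx(1.0)
        assert np.allclose(proj["PC2"], 0.0, atol=1e-12)

    def test_three_point_toy_matches_hand_eigendecomposition(self):
        # points (1,0), (3,0), (1,2): centered covariance is [[4/3,-2/3],[-2/3,4/3]]
        # eigenvalues 2 and 2/3, leading axis along (1,-1)/sqrt(2)
        m = pd.DataFrame([[1.0, 0.0], [3.0, 0.0], [1.0, 2.0]], index=list("abc"))
        proj, evr = pca_project(m)
        assert evr[0] == pytest.approx(2.0 / (2.0 + 2.0 / 3.0))
        # the leading axis is (1,−1)/√2 whose loadings tie in magnitude, so
        # the hand oracle pins the projection only up to component sign
        expected_pc1 = np.array([0.0, np.sqrt(2.0), -np.sqrt(2.0)])
        got = proj["PC1"].to_numpy()
        assert np.allclose(got, expected_pc1, atol=1e-9) or np.allclose(
            got, -expected_pc1, atol=1e-9
        )

    def test_duplicated_rows_identical_projections(self, rng):
        base = rng.integers(0, 2, size=(6, 5)).astype(float)
        base[0] = base[1]
        m = pd.DataFrame(base, index=[f"g{i}" for i in range(6)])
        m = m.loc[m.var(axis=1) > 0]
        proj, _ = pca_project(m)
        if "g0" in proj.index and "g1" in proj.index:
            assert np.allclose(proj.loc["g0"], proj.loc["g1"])

    def test_zero_variance_genes_removed_with_warning(self, rng):
        rows = rng.integers(0, 2, size=(10, 6)).astype(float)
        rows[3] = 1.0
        m = pd.DataFrame(rows, index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="zero-variance"):
            proj, _ = pca_project(m)
        assert "g3" not in proj.index

    def test_sign_convention_is_deterministic(self, rng):
        m = pd.DataFrame(rng.integers(0, 2, size=(20, 7)).astype(float))
        m = m.loc[m.var(axis=1) > 0]
        p1, _ = pca_project(m)
        p2, _ = pca_project(m)
        pd.testing.assert_frame_equal(p1, p2)


def brute_force_es(scores: pd.Series, members: set, weight: float = 1.0) -> float:
    """Oracle: explicit running-sum over the full descending ranking."""
    order = scores.sort_values(ascending=False, kind="stable")
    hits = np.array([g in members for g in order.index])
    w = np.abs(order.to_numpy()) ** weight
    w = np.where(hits, w, 0.0)
    if w.sum() == 0:
        w = hits.astype(float)
    inc = np.where(hits, w / w.sum(), -1.0 / (len(order) - hits.sum()))
    run = np.cumsum(inc)
    return float(run[np.argmax(np.abs(run))])


class TestPrerankedGsea:
    def scores(self, n=8, seed=0):
        r = np.random.default_rng(seed)
        return pd.Series(r.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_singleton_top_gene_has_es_one(self):
        s = pd.Series([5.0, 1.0, 0.5, -2.0], index=list("abcd"))
        r = preranked_gsea(s, ["a"], n_perm=100, rng=0)
        assert r.es == pytest.approx(1.0)

    def test_es_matches_bruteforce_oracle(self, rng):
        for seed in range(5):
            s = self.scores(n=30, seed=seed)
            members = list(rng.choice(s.index, size=8, replace=False))
            r = preranked_gsea(s, members, n_perm=50, rng=0)
            assert r.es == pytest.approx(brute_force_es(s, set(members)), abs=1e-12)

    def test_exhaustive_p_matches_enumeration_universe8_set3(self):
        s = self.scores(n=8, seed=4)
        members = ["g0", "g3", "g5"]
        r = preranked_gsea(s, members, exhaustive=True)
        null = np.array(
            [brute_force_es(s, set(c)) for c in itertools.combinations(s.index, 3)]
        )
        side = null[null > 0] if r.es >= 0 else null[null < 0]
        expected = float((np.abs(side) >= abs(r.es)).sum()) / side.size
        assert r.p == pytest.approx(expected)

    def test_unweighted_es_invariant_to_monotone_rescale(self):
        s = self.scores(n=20, seed=1)
        members = [f"g{i}" for i in (0, 4, 9, 13)]
        r1 = preranked_gsea(s, members, n_perm=50, rng=0, weight=0.0)
        r2 = preranked_gsea(np.exp(s / 2), members, n_perm=50, rng=0, weight=0.0)
        assert r1.es == pytest.approx(r2.es, abs=1e-12)

    def test_whole_universe_set_degenerates_with_warning(self):
        s = self.scores(n=6)
        with pytest.warns(UserWarning, match="whole ranking"):
            r = preranked_gsea(s, list(s.index), n_perm=50, rng=0)
        assert r.es == 0.0

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            preranked_gsea(self.scores(), ["absent"], n_perm=50, rng=0)

    def test_nes_sign_matches_es_sign(self, rng):
        s = self.scores(n=40, seed=2)
        for _ in range(5):
            members = list(rng.choice(s.index, size=6, replace=False))
            r = preranked_gsea(s, members, n_perm=500, rng=1)
            if np.isfinite(r.nes) and r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)

    def test_leading_edge_within_set(self):
        s = self.scores(n=30, seed=3)
        members = [f"g{i}" for i in (1, 5, 11, 20)]
        r = preranked_gsea(s, members, n_perm=50, rng=0)
        assert set(r.leading_edge) <= set(members)
        assert len(r.leading_edge) >= 1

    def test_batch_applies_bh_across_sets(self):
        s = self.scores(n=50, seed=6)
        sets = {f"S{i}": list(s.sample(8, random_state=i).index) for i in range(4)}
        table = gsea_batch(s, sets, n_perm=200, rng=0)
        assert (table["fdr"] >= table["p"] - 1e-12).all()


class TestOverrepresentation:
    def test_hypergeometric_worked_example(self):
        # universe 10, term 4, set 5, overlap 4: p = C(4,4)C(6,1)/C(10,5)
        universe = [f"u{i}" for i in range(10)]
        term = universe[:4]
        query = universe[:4] + [universe[9]]
        out = overrepresentation(query, {"T": term}, universe)
        assert out.loc["T", "p"] == pytest.approx(6 / 252)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        out = overrepresentation(universe[5:], {"T": universe[:3]}, universe[3:])
        assert out.loc["T", "p"] == pytest.approx(1.0)

    def test_term_equal_to_universe_p_one(self):
        universe = [f"u{i}" for i in range(8)]
        out = overrepresentation(universe[:3], {"ALL": universe}, universe)
        assert out.loc["ALL", "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(["a"], {"T": ["a"]}, [])


class TestSetOverlapCompare:
    def ts(self, factor, genes):
        return TargetGeneSet(factor, genes, pd.Series(60.0, index=genes))

    def test_pairwise_intersection_counts(self):
        sets = [self.ts("A", ["a", "b", "c"]), self.ts("B", ["b", "c", "d"])]
        scores = pd.Series(0.0, index=list("abcdefgh"))
        out = set_overlap_compare(sets, scores)
        assert out["pairwise"][("A", "B")] == 2
        assert out["full_intersection"] == ["b", "c"]

    def test_rank_sum_null_calibration(self):
        # identical distributions: two-sided p should be roughly uniform
        ps = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(120)]
            scores = pd.Series(r.normal(size=120), index=genes)
            sets = [self.ts("A", genes[:25]), self.ts("B", genes[15:40])]
            out = set_overlap_compare(sets, scores, group_genes=genes[15:25])
            ps.append(out["comparison"]["p"])
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) < 0.35 and max(ps) > 0.65

    def test_group_covering_everything_skipped_with_warning(self):
        genes = list("abcdef")
        scores = pd.Series(0.0, index=genes)
        sets = [self.ts("A", genes), self.ts("B", genes)]
        with pytest.warns(UserWarning, match="skipped"):
            out = set_overlap_compare(sets, scores, group_genes=genes)
        assert out["comparison"] is None

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_compare([self.ts("A", ["a"])], pd.Series(0.0, index=["a"]))


class TestGseaSignalIntegration:
    def gsea_table(self, n=8, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame(
            {"es": r.normal(size=n), "nes": r.normal(size=n), "fdr": r.uniform(0.01, 1, size=n)},
            index=[f"TF{i}" for i in range(n)],
        )

    def test_monotone_signal_gives_rho_one(self):
        g = self.gsea_table()
        combined = g["nes"] * -np.log10(g["fdr"])
        signal = pd.Series(np.exp(combined), index=g.index)
        rho, p, table = gsea_signal_integration(g, signal)
        assert rho == pytest.approx(1.0)
        assert list(table.index) == list(table["gsea_score"].sort_values(ascending=False).index)

    def test_independent_tables_have_small_rho(self):
        rhos = [
            gsea_signal_integration(
                self.gsea_table(n=60, seed=s),
                pd.Series(
                    np.random.default_rng(1000 + s).normal(size=60),
                    index=[f"TF{i}" for i in range(60)],
                ),
            )[0]
            for s in range(10)
        ]
        assert abs(np.mean(rhos)) < 0.15

    def test_fewer_than_four_shared_factors_rejected(self):
        g = self.gsea_table(n=3)
        with pytest.raises(ValueError, match="≥4 required"):
            gsea_signal_integration(g, pd.Series(1.0, index=g.index))

    def test_mismatched_factors_dropped_with_warning(self):
        g = self.gsea_table(n=6)
        signal = pd.Series(1.0 + np.arange(5), index=[f"TF{i}" for i in range(1, 6)])
        with pytest.warns(UserWarning, match="dropped"):
            rho, p, table = gsea_signal_integration(g, signal)
        assert len(table) == 5


class TestDistanceCorrelationCoupling:
    def test_coregulated_neighborhood_couples_distance_to_median_z(self):
        """Genes co-targeted with the focal gene by the planted factors sit in
        the nearest distance bins and carry elevated median z, so bin-median z
        decreases with bin index."""
        from scipy import stats

        from regscan.coexpression import pan_cancer_median, spearman_to_focal, z_transform
        from regscan.synthetic import SimulationConfig, simulate_cohorts, simulate_target_sets

        regs = [(f"REG{i:03d}", 0.6) for i in range(120)]
        cfg = SimulationConfig(
            n_cohorts=4, samples_per_cohort=100, n_genes=600,
            planted_regulators=regs, n_factors=12,
            planted_factors=[(f"TF{i:03d}", 3.0) for i in range(6)],
            co_membership=1.0, target_set_size=200, seed=1,
        )
        cohorts, _ = simulate_cohorts(cfg)
        zs = [z_transform(spearman_to_focal(c, "FOCAL")) for c in cohorts]
        score = pan_cancer_median(zs)
        sets, universe, _ = simulate_target_sets(cfg)
        matrix = build_regulatory_matrix(sets, universe)
        dist = gene_distance(matrix, "FOCAL", bin_width=40)
        merged = dist.join(score.median_z, how="inner").dropna()
        bin_median = merged.groupby("distance_bin")["median_z"].median()
        rho, _ = stats.spearmanr(bin_median.index.to_numpy(), bin_median.to_numpy())
        assert rho < 0


class TestRegulatoryMatrix:
    def test_membership_encoded_as_binary(self):
        sets = [
            TargetGeneSet("A", ["g1", "g2"], pd.Series(60.0, index=["g1", "g2"])),
            TargetGeneSet("B", ["g2"], pd.Series(70.0, index=["g2"])),
        ]
        m = build_regulatory_matrix(sets, ["g1", "g2", "g3"])
        assert m.loc["g1"].tolist() == [1, 0]
        assert m.loc["g2"].tolist() == [1, 1]
        assert m.loc["g3"].tolist() == [0, 0]
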