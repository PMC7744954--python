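"""Normalisation, classification, differential tests, trajectory and subgroup."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oomt import transcriptome as tr
from oomt.synthetic_data import SimulationConfig, simulate_expression


def _clean_config(**overrides):
    """Study conditions with only the named effects planted."""
    base = dict(
        n_de=0, n_dv=0, n_signature=0, n_coupled=0, n_maternal=0,
        young_like_fraction=0.0, diversity_loss_fraction=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# size factors / normalisation
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        m = pd.DataFrame({"c1": [5, 3, 8], "c2": [5, 3, 8]}, index=list("abc"))
        np.testing.assert_allclose(tr.size_factors(m), [1.0, 1.0])

    def test_doubled_cell_recovers_scaling(self):
        m = pd.DataFrame({"c1": [5, 3, 8], "c2": [10, 6, 16]}, index=list("abc"))
        f = tr.size_factors(m)
        assert f["c2"] / f["c1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_hand_computed_median_of_ratios(self):
        m = pd.DataFrame(
            [[10, 20, 5, 8], [4, 8, 2, 3], [100, 180, 60, 90], [1, 2, 1, 1], [7, 15, 3, 6]],
            index=list("abcde"), columns=["c1", "c2", "c3", "c4"],
        )
        # brute-force oracle: ratios to the per-gene geometric mean
        X = m.to_numpy(dtype=float)
        gm = np.exp(np.mean(np.log(X), axis=1))
        raw = np.median(X / gm[:, None], axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(tr.size_factors(m), expected)

    def test_fallback_when_no_common_gene(self):
        m = pd.DataFrame({"c1": [5, 0], "c2": [0, 7]}, index=list("ab"))
        with pytest.warns(UserWarning, match="total-count"):
            f = tr.size_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_scaled_dataset_recovers_scaling_invariant(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, size=50).astype(float) + 1
        scale = np.array([0.5, 1.0, 2.0, 1.5, 0.8, 1.2])
        m = pd.DataFrame(base[:, None] * scale, columns=[f"c{i}" for i in range(6)])
        f = tr.size_factors(m)
        np.testing.assert_allclose(f / f.iloc[0], scale / scale[0], rtol=1e-9)


class TestTranscriptDiversity:
    def test_exact_counts(self):
        m = pd.DataFrame({"c1": [0, 1, 5], "c2": [0, 0, 0], "c3": [2, 0, 1]})
        assert tr.transcript_diversity(m).tolist() == [2, 0, 2]

    def test_aged_diversity_loss_detected(self):
        """An aged detection deficit shows up in the rank-sum group test."""
        from oomt.methylome import group_compare

        hits = 0
        for s in range(5):
            cfg = _clean_config(seed=800 + s, diversity_loss_fraction=0.06)
            counts, ann, _ = simulate_expression(cfg)
            g = ann.set_index("cell_id")["age_group"]
            div = tr.transcript_diversity(counts)
            _, p = group_compare(div[g == "young"], div[g == "aged"])
            hits += p < 0.01
        assert hits >= 5 * 0.9


# ---------------------------------------------------------------------------
# chromatin-state classification
# ---------------------------------------------------------------------------

class TestClassifyChromatinState:
    def test_degenerate_identical_cells_all_nsn(self):
        m = pd.DataFrame(np.full((6, 4), 7), index=[f"g{i}" for i in range(6)],
                         columns=list("abcd"))
        with pytest.warns(UserWarning, match="identical"):
            labels = tr.classify_chromatin_state(m, [f"g{i}" for i in range(6)])
        assert (labels == "NSN").all()

    def test_cell_order_invariance(self):
        cfg = _clean_config(seed=21, n_signature=100)
        counts, _, truth = simulate_expression(cfg)
        l1 = tr.classify_chromatin_state(counts, truth.signature_genes)
        shuffled = counts.sample(frac=1, axis=1, random_state=0)
        l2 = tr.classify_chromatin_state(shuffled, truth.signature_genes)
        pd.testing.assert_series_equal(l1.sort_index(), l2.sort_index())

    def test_too_few_signature_genes_rejected(self):
        m = pd.DataFrame(np.arange(12).reshape(3, 4), index=list("abc"))
        with pytest.raises(ValueError, match="resolvable"):
            tr.classify_chromatin_state(m, ["a", "b", "nope"])

    def test_unresolvable_ids_warned(self):
        cfg = _clean_config(seed=22, n_signature=100)
        counts, _, truth = simulate_expression(cfg)
        with pytest.warns(UserWarning, match="not in matrix"):
            tr.classify_chromatin_state(counts, truth.signature_genes + ["missing_gene"])


class TestFisherProportionTest:
    def test_symmetric_table_p_one(self):
        assert tr.fisher_proportion_test([[5, 5], [5, 5]]) == 1.0

    def test_zero_margin_p_one(self):
        assert tr.fisher_proportion_test([[0, 0], [3, 7]]) == 1.0

    def test_matches_enumeration_oracle(self):
        """Exact two-sided p equals full enumeration over all tables with the
        observed margins (sum of hypergeometric probabilities <= observed)."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum() == 0:
                continue
            r1, r2 = t.sum(axis=1)
            c1 = t[:, 0].sum()
            n = t.sum()
            probs = []
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs.append((a, stats.hypergeom.pmf(a, n, r1, c1)))
            p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
            expected = sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))
            got = tr.fisher_proportion_test(t)
            assert got == pytest.approx(min(expected, 1.0), rel=1e-9)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            tr.fisher_proportion_test(np.array([[0.5, 1], [2, 3]]))


# ---------------------------------------------------------------------------
# PCA associations
# ---------------------------------------------------------------------------

class TestPcaWithAssociations:
    def test_self_association(self):
        cfg = _clean_config(seed=23)
        counts, ann, _ = simulate_expression(cfg)
        cov = pd.DataFrame(index=counts.columns)
        scores0, _ = tr.pca_with_associations(counts, cov.assign(dummy=1.0 * np.arange(len(cov))))
        cov["pc1_copy"] = scores0["PC1"]
        _, pmat = tr.pca_with_associations(counts, cov[["pc1_copy"]])
        assert pmat.loc["pc1_copy", "PC1"] < 1e-10

    def test_constant_covariate_flagged(self):
        cfg = _clean_config(seed=24, n_genes=300)
        counts, _, _ = simulate_expression(cfg)
        cov = pd.DataFrame({"const": 1.0}, index=counts.columns)
        with pytest.warns(UserWarning, match="constant"):
            _, pmat = tr.pca_with_associations(counts, cov)
        assert pmat.loc["const"].isna().all()

    def test_signature_drives_pc1_age_a_later_pc(self):
        """With a strong SN signature plus an age effect, the chromatin
        covariate dominates PC1 while age is still associated with an early
        component."""
        cfg = SimulationConfig(seed=25, n_dv=0, n_coupled=0, n_maternal=0,
                               young_like_fraction=0.0, sn_fold=4.0)
        counts, ann, _ = simulate_expression(cfg)
        cov = ann.set_index("cell_id")[["age_group", "chromatin_state"]]
        _, pmat = tr.pca_with_associations(counts, cov)
        assert pmat.loc["chromatin_state", "PC1"] < 1e-6
        assert pmat.loc["chromatin_state", "PC1"] <= pmat.loc["age_group", "PC1"]
        assert pmat.loc["age_group"].min() < 1e-4

    def test_cell_order_invariance(self):
        cfg = _clean_config(seed=26, n_genes=300)
        counts, _, _ = simulate_expression(cfg)
        cov = pd.DataFrame({"x": np.arange(counts.shape[1], dtype=float)},
                           index=counts.columns)
        _, p1 = tr.pca_with_associations(counts, cov)
        order = np.random.default_rng(1).permutation(counts.columns)
        _, p2 = tr.pca_with_associations(counts[order], cov.loc[order])
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), rtol=1e-6)


# ---------------------------------------------------------------------------
# differential mean / variability
# ---------------------------------------------------------------------------

class TestDifferentialMean:
    def test_planted_lfc_recovered(self):
        """The rank-sum stand-in recovers the bulk of two-fold planted
        effects at the study's cell numbers."""
        recs = []
        for s in range(3):
            cfg = _clean_config(seed=27 + s, n_de=100)
            counts, ann, truth = simulate_expression(cfg)
            g = ann.set_index("cell_id")["age_group"]
            res = tr.differential_mean_test(counts, g)
            sig = set(res[res["q"] < 0.05]["gene"])
            true_de = set(truth.de_genes["gene"])
            recs.append(len(sig & true_de) / len(true_de))
        assert np.mean(recs) >= 0.6

    def test_lfc_sign_matches_truth(self):
        cfg = _clean_config(seed=29, n_de=100)
        counts, ann, truth = simulate_expression(cfg)
        g = ann.set_index("cell_id")["age_group"]
        res = tr.differential_mean_test(counts, g).set_index("gene")
        sig = res[res["q"] < 0.05]
        joined = truth.de_genes.set_index("gene").join(sig, how="inner")
        agree = (np.sign(joined["lfc"]) == np.sign(joined["log2_fc"])).mean()
        assert agree > 0.95

    def test_null_calibration(self):
        """Under the null the rank-sum p-values are roughly uniform and BH
        controls the rejection count (2,000 null genes give the >=200 null
        instances needed for a stable type-I estimate)."""
        cfg = _clean_config(seed=30)
        counts, ann, _ = simulate_expression(cfg)
        g = ann.set_index("cell_id")["age_group"]
        res = tr.differential_mean_test(counts, g)
        assert (res["p"] < 0.05).mean() < 0.075  # 1.5x nominal
        assert (res["q"] < 0.05).sum() <= 3

    def test_all_zero_genes_excluded(self):
        m = pd.DataFrame(np.ones((4, 8), dtype=int), index=list("abcd"))
        m.loc["c"] = 0
        groups = pd.Series(["x"] * 4 + ["y"] * 4, index=m.columns)
        res = tr.differential_mean_test(m, groups)
        assert "c" not in set(res["gene"])
        assert res.attrs["excluded"] == ["c"]


class TestDifferentialVariability:
    def test_planted_inflation_recovered_with_aged_direction(self):
        cfg = _clean_config(seed=31, n_dv=300)
        counts, ann, truth = simulate_expression(cfg)
        g = ann.set_index("cell_id")["age_group"]
        res = tr.differential_variability_test(counts, g, n_permutations=50, seed=1)
        sig = res[res["q"] < 0.10]
        rec = len(set(sig["gene"]) & set(truth.dv_genes)) / len(truth.dv_genes)
        assert rec >= 0.5
        assert (sig["statistic"] > 0).mean() > 0.9

    def test_statistic_invariant_to_joint_cell_scaling(self):
        """Multiplying a cell's counts by c while the size factor absorbs c
        leaves the dispersion statistic unchanged (normalisation
        consistency)."""
        cfg = _clean_config(seed=32, n_genes=200)
        counts, ann, _ = simulate_expression(cfg)
        g = ann.set_index("cell_id")["age_group"]
        res1 = tr.differential_variability_test(counts, g, n_permutations=10, seed=2)
        scaled = counts.astype(float).copy()
        scaled.iloc[:, 0] *= 4.0  # size-factor estimation absorbs the scaling
        res2 = tr.differential_variability_test(scaled, g, n_permutations=10, seed=2)
        diff = np.abs(res1["statistic"].to_numpy() - res2["statistic"].to_numpy())
        # re-estimated size factors absorb the scaling up to median jitter
        assert np.median(diff) < 0.02
        assert (diff < 0.2).mean() > 0.95

    def test_null_rejections_at_nominal_rate(self):
        cfg = _clean_config(seed=33)
        counts, ann, _ = simulate_expression(cfg)
        g = ann.set_index("cell_id")["age_group"]
        res = tr.differential_variability_test(counts, g, n_permutations=50, seed=3)
        assert (res["q"] < 0.10).sum() <= 3


class TestPairwiseDistance:
    def test_identical_cells_zero_distance(self):
        m = pd.DataFrame(np.tile([[4], [7]], (1, 6)), index=["g1", "g2"],
                         columns=[f"c{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=m.columns)
        out = tr.pairwise_distance_stat(m, ["g1", "g2"], groups)
        assert all((d == 0).all() for d in out["distances"].values())

    def test_two_cells_equal_direct_euclidean(self):
        m = pd.DataFrame({"c1": [1, 2], "c2": [3, 5], "c3": [2, 2], "c4": [4, 1]},
                         index=["g1", "g2"])
        groups = pd.Series(["a", "a", "b", "b"], index=m.columns)
        out = tr.pairwise_distance_stat(m, ["g1", "g2"], groups)
        logn = tr.log_normalize(m)
        expected = np.linalg.norm(logn["c1"] - logn["c2"])
        assert out["distances"]["a"][0] == pytest.approx(expected)

    def test_aged_profiles_further_apart_under_inflation(self):
        hits = 0
        for s in range(5):
            cfg = _clean_config(seed=900 + s, n_dv=300)
            counts, ann, truth = simulate_expression(cfg)
            g = ann.set_index("cell_id")["age_group"]
            out = tr.pairwise_distance_stat(counts, truth.dv_genes, g)
            hits += np.median(out["distances"]["aged"]) > np.median(out["distances"]["young"])
        assert hits == 5

    def test_missing_genes_rejected(self):
        m = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"])
        groups = pd.Series(["a", "a", "b", "b"], index=m.columns)
        with pytest.raises(ValueError, match="not in matrix"):
            tr.pairwise_distance_stat(m, ["g1", "nope"], groups)


class TestClusterTrajectory:
    def test_perfect_trend_gene(self):
        rng = np.random.default_rng(5)
        cells = [f"c{i}" for i in range(20)]
        cl = pd.Series(np.repeat([1, 2, 3, 4], 5), index=cells)
        m = pd.DataFrame(rng.poisson(20, (30, 20)), columns=cells)
        m.loc[0] = (cl * 40).to_numpy()  # expression == cluster trend
        res, _ = tr.cluster_trajectory_test(m, cl)
        assert res.set_index("gene").loc[0, "p_bonferroni"] < 1e-6

    def test_maternal_enrichment_recovered(self):
        cfg = SimulationConfig(seed=34, n_de=0, n_dv=0, n_coupled=0,
                               diversity_loss_fraction=0.0)
        counts, ann, truth = simulate_expression(cfg)
        cl = ann.set_index("cell_id")["cluster_id"]
        _, enrich_p = tr.cluster_trajectory_test(counts, cl, truth.maternal_genes)
        assert enrich_p < 0.01

    def test_shuffled_clusters_lose_enrichment(self):
        cfg = SimulationConfig(seed=35, n_de=0, n_dv=0, n_coupled=0,
                               diversity_loss_fraction=0.0)
        counts, ann, truth = simulate_expression(cfg)
        cl = ann.set_index("cell_id")["cluster_id"]
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(5):
            shuffled = pd.Series(rng.permutation(cl.to_numpy()), index=cl.index)
            _, p = tr.cluster_trajectory_test(counts, shuffled, truth.maternal_genes)
            ps.append(p)
        assert min(ps) > 1e-4  # no systematic enrichment under label noise


class TestYoungLikeSubgroup:
    def test_planted_subgroup_recovered(self):
        cfg = SimulationConfig(seed=36, n_dv=0, n_coupled=0, n_maternal=0,
                               n_signature=0, young_like_fraction=16 / 45,
                               diversity_loss_fraction=0.0)
        counts, ann, truth = simulate_expression(cfg)
        flags = tr.young_like_subgroup(counts, list(truth.de_genes["gene"]), ann)
        true_yl = set(truth.young_like)
        pred_yl = set(flags[flags].index)
        inter = len(true_yl & pred_yl)
        assert inter / len(true_yl) >= 0.9
        aged_nsn_affected = set(
            ann[(ann["age_group"] == "aged") & ~ann["young_like"]]["cell_id"]
        )
        assert len(pred_yl & aged_nsn_affected) / max(len(pred_yl), 1) <= 0.2

    def test_aged_identical_to_young_all_flagged(self):
        m = pd.DataFrame(np.tile([[10], [4], [7]], (1, 8)),
                         index=["g1", "g2", "g3"],
                         columns=[f"c{i}" for i in range(8)])
        ann = pd.DataFrame({"cell_id": m.columns,
                            "age_group": ["young"] * 4 + ["aged"] * 4})
        flags = tr.young_like_subgroup(m, ["g1", "g2", "g3"], ann)
        assert flags[[f"c{i}" for i in range(4, 8)]].all()
        assert not flags[[f"c{i}" for i in range(4)]].any()

    def test_cell_order_invariance(self):
        cfg = SimulationConfig(seed=37, n_dv=0, n_coupled=0, n_maternal=0,
                               n_signature=0, young_like_fraction=0.3,
                               diversity_loss_fraction=0.0)
        counts, ann, truth = simulate_expression(cfg)
        degs = list(truth.de_genes["gene"])
        f1 = tr.young_like_subgroup(counts, degs, ann)
        order = np.random.default_rng(2).permutation(counts.columns)
        f2 = tr.young_like_subgroup(counts[order], degs, ann)
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())

    def test_too_few_aged_cells_skipped(self):
        m = pd.DataFrame(np.arange(12).reshape(3, 4), index=["g1", "g2", "g3"],
                         columns=list("abcd"))
        ann = pd.DataFrame({"cell_id": list("abcd"),
                            "age_group": ["young"] * 3 + ["aged"]})
        with pytest.warns(UserWarning, match="fewer than 4"):
            flags = tr.young_like_subgroup(m, ["g1"], ann)
        assert not flags.any()
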