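"""ICA factors, Ward states, composite pseudotime, and the 2-D depiction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from thrombotraj import trajectory
from thrombotraj.trajectory import (
    ClusterAssignment,
    LatentFactors,
    assemble_pseudotime,
    choose_k,
    cluster_cells,
    embed_2d,
    fit_ica,
    label_clusters,
    orient_factors,
    regress_path,
    spearman,
)


def _mixture(n_sources, n_samples=400, n_features=60, noise=0.02, seed=0):
    """Linear mixture of independent non-Gaussian (Laplace) sources."""
    rng = np.random.default_rng(seed)
    s = rng.laplace(size=(n_samples, n_sources))
    a = rng.normal(size=(n_sources, n_features))
    x = s @ a + noise * rng.normal(size=(n_samples, n_features))
    return pd.DataFrame(
        x,
        index=[f"c{i:04d}" for i in range(n_samples)],
        columns=[f"g{j}" for j in range(n_features)],
    ), s


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.arange(10.0)
        assert spearman(x, x) == pytest.approx(1.0)
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_hand_formula(self):
        # 5 points with one tie in y; average ranks computed by hand:
        # y = (1, 2, 2, 4, 5) -> ranks (1, 2.5, 2.5, 4, 5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        rx = np.array([1, 2, 3, 4, 5])
        ry = np.array([1, 2.5, 2.5, 4, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestChooseK:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        x = np.outer(rng.laplace(size=100), rng.normal(size=20))
        assert choose_k(pd.DataFrame(x)) == 1

    @pytest.mark.parametrize("k_true", [2, 4])
    def test_elbow_recovers_source_count(self, k_true):
        x, _ = _mixture(k_true, seed=k_true)
        assert choose_k(x, k_max=8) == k_true

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            choose_k(pd.DataFrame(np.ones((10, 5))))


class TestFitIca:
    def test_recovers_independent_sources(self):
        x, s = _mixture(4, seed=1)
        factors = fit_ica(x, k=4, seed=0)
        # brute-force matching over factor permutations and signs
        got = factors.values.to_numpy()
        for j in range(4):
            best = max(
                abs(np.corrcoef(s[:, j], got[:, i])[0, 1]) for i in range(4)
            )
            assert best >= 0.99

    def test_deterministic_given_seed(self):
        x, _ = _mixture(3, seed=2)
        f1 = fit_ica(x, k=3, seed=7)
        f2 = fit_ica(x, k=3, seed=7)
        pd.testing.assert_frame_equal(f1.values, f2.values)

    def test_row_order_invariance(self):
        x, _ = _mixture(3, seed=3)
        perm = np.random.default_rng(0).permutation(len(x))
        f1 = fit_ica(x, k=3, seed=7)
        f2 = fit_ica(x.iloc[perm], k=3, seed=7)
        pd.testing.assert_frame_equal(
            f1.values, f2.values.loc[f1.values.index], atol=1e-8
        )


class TestOrientFactors:
    def _factors(self, values):
        idx = [f"c{i}" for i in range(len(values))]
        return LatentFactors(pd.DataFrame({"IC1": values}, index=idx))

    def test_anticorrelated_factor_flipped(self, rng):
        fl = pd.Series(np.arange(50.0), index=[f"c{i}" for i in range(50)])
        f = self._factors(-np.arange(50.0) + rng.normal(0, 5, 50))
        rho_before = stats.spearmanr(f.values["IC1"], fl).statistic
        out = orient_factors(f, fl)
        assert stats.spearmanr(out.values["IC1"], fl).statistic == pytest.approx(
            -rho_before
        )

    def test_positive_factor_unchanged_and_idempotent(self):
        fl = pd.Series(np.arange(20.0), index=[f"c{i}" for i in range(20)])
        f = self._factors(np.arange(20.0) * 0.5)
        once = orient_factors(f, fl)
        twice = orient_factors(once, fl)
        pd.testing.assert_frame_equal(once.values, f.values)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_zero_variance_factor_warns(self):
        fl = pd.Series(np.arange(5.0), index=[f"c{i}" for i in range(5)])
        f = self._factors(np.ones(5))
        with pytest.warns(UserWarning):
            orient_factors(f, fl)


class TestClusterCells:
    def test_planted_blobs_fully_recovered(self, rng):
        centers = rng.normal(0, 8, size=(6, 4))
        labels = np.repeat(np.arange(6), 20)
        x = centers[labels] + rng.normal(0, 0.3, size=(120, 4))
        f = LatentFactors(
            pd.DataFrame(x, index=[f"c{i:03d}" for i in range(120)])
        )
        got = cluster_cells(f, 6).partition
        assert adjusted_rand_score(labels, got) == pytest.approx(1.0)

    def test_singletons_when_clusters_equal_cells(self, rng):
        f = LatentFactors(pd.DataFrame(rng.normal(size=(7, 3))))
        part = cluster_cells(f, 7).partition
        assert part.nunique() == 7

    def test_duplicated_points_co_cluster(self, rng):
        x = rng.normal(size=(10, 3))
        x[1] = x[0]
        f = LatentFactors(pd.DataFrame(x))
        part = cluster_cells(f, 5).partition
        assert part.iloc[0] == part.iloc[1]

    def test_more_clusters_than_cells_rejected(self, rng):
        f = LatentFactors(pd.DataFrame(rng.normal(size=(4, 2))))
        with pytest.raises(ValueError):
            cluster_cells(f, 5)


def _stage_world(rng, sizes=(20, 20, 20, 20, 20, 3)):
    """Hand-built factor space: five fluorescence-ordered blobs + outliers."""
    n = sum(sizes)
    idx = [f"c{i:03d}" for i in range(n)]
    lab = np.repeat(np.arange(6), sizes)
    vals = pd.DataFrame(
        rng.normal(0, 0.1, size=(n, 4)), index=idx,
        columns=["IC1", "IC2", "IC3", "IC4"],
    )
    vals["IC1"] += np.where(lab < 3, lab * 2.0, 0.0)  # within_small
    vals["IC2"] += np.where(lab == 4, 4.0, 0.0)  # within_large
    vals["IC4"] += lab * 1.0  # difference (tracks fluorescence)
    vals.loc[lab == 5, "IC3"] = 9.0  # outlier loading
    fluor = pd.Series(np.exp(lab.astype(float)), index=idx)
    factors = LatentFactors(
        vals,
        roles={
            "within_small": "IC1",
            "within_large": "IC2",
            "outlier": "IC3",
            "difference": "IC4",
        },
    )
    return factors, fluor, lab


class TestLabelClusters:
    def test_planted_stages_named_in_order(self, rng):
        factors, fluor, lab = _stage_world(rng)
        part = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index)
        )
        out = label_clusters(part, factors, fluor)
        expect = np.array(["1a", "1b", "2", "3", "4", "outlier"], object)[lab]
        assert (out.stages.to_numpy() == expect).all()

    def test_extreme_outlier_cluster_labeled_outlier(self, rng):
        factors, fluor, lab = _stage_world(rng, sizes=(30, 30, 30, 30, 30, 3))
        part = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index)
        )
        out = label_clusters(part, factors, fluor)
        assert (out.stages[lab == 5] == "outlier").all()
        assert (out.stages == "outlier").sum() == 3

    def test_tied_fluorescence_deterministic(self, rng):
        factors, _, lab = _stage_world(rng)
        flat_fluor = pd.Series(1.0, index=factors.values.index)
        part = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index)
        )
        a = label_clusters(part, factors, flat_fluor)
        b = label_clusters(part, factors, flat_fluor)
        pd.testing.assert_series_equal(a.stages, b.stages)


class TestAssemblePseudotime:
    def test_single_cluster_sorts_by_factor(self, rng):
        idx = ["a", "b", "c"]
        vals = pd.DataFrame(
            {"IC1": [0.3, -1.0, 2.0], "IC2": 0.0, "IC3": 0.0, "IC4": 0.0},
            index=idx,
        )
        factors = LatentFactors(
            vals,
            roles={
                "within_small": "IC1",
                "difference": "IC2",
                "within_large": "IC3",
                "outlier": "IC4",
            },
        )
        stages = pd.Series(["1a", "1a", "1a"], index=idx)
        assign = ClusterAssignment(
            partition=pd.Series([1, 1, 1], index=idx), stages=stages
        )
        fluor = pd.Series(1.0, index=idx)
        ranks = assemble_pseudotime(assign, factors, fluor)
        assert ranks.to_dict() == {"a": 1, "b": 0, "c": 2}

    def test_matches_brute_force_lexicographic_sort(self, rng):
        factors, fluor, lab = _stage_world(rng, sizes=(3, 3, 3, 3, 3, 2))
        stages_map = np.array(["1a", "1b", "2", "3", "4", "outlier"], object)
        stages = pd.Series(stages_map[lab], index=factors.values.index)
        assign = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index),
            stages=stages,
        )
        ranks = assemble_pseudotime(assign, factors, fluor)
        stage_key = {"1a": 0, "1b": 1, "2": 2, "3": 3, "4": 4}
        fac_col = {"1a": "IC1", "1b": "IC1", "2": "IC1", "3": "IC4", "4": "IC2"}
        rows = sorted(
            (
                stage_key[stages[c]],
                factors.values.loc[c, fac_col[stages[c]]],
                fluor[c],
                c,
            )
            for c in stages.index
            if stages[c] != "outlier"
        )
        expected = {c: i for i, (_, _, _, c) in enumerate(rows)}
        assert ranks.to_dict() == expected

    def test_outliers_excluded(self, rng):
        factors, fluor, lab = _stage_world(rng)
        stages_map = np.array(["1a", "1b", "2", "3", "4", "outlier"], object)
        assign = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index),
            stages=pd.Series(stages_map[lab], index=factors.values.index),
        )
        ranks = assemble_pseudotime(assign, factors, fluor)
        assert len(ranks) == (lab != 5).sum()
        assert sorted(ranks) == list(range(len(ranks)))

    def test_missing_stage_labels_rejected(self, rng):
        factors, fluor, lab = _stage_world(rng)
        assign = ClusterAssignment(
            partition=pd.Series(lab + 1, index=factors.values.index)
        )
        with pytest.raises(ValueError):
            assemble_pseudotime(assign, factors, fluor)


class TestEmbed2d:
    def _factors(self, rng, n=60):
        return LatentFactors(
            pd.DataFrame(rng.normal(size=(n, 4)), index=[f"c{i}" for i in range(n)])
        )

    def test_shape_and_determinism(self, rng):
        f = self._factors(rng)
        e1 = embed_2d(f, perplexity=10, seed=1)
        e2 = embed_2d(f, perplexity=10, seed=1)
        assert e1.shape == (60, 2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_distant_blobs_stay_separated(self, rng):
        x = rng.normal(size=(60, 4)) * 0.2
        x[30:] += 25.0
        f = LatentFactors(pd.DataFrame(x))
        emb = embed_2d(f, perplexity=10, seed=0).to_numpy()
        c0, c1 = emb[:30].mean(0), emb[30:].mean(0)
        intra = np.linalg.norm(emb[:30] - c0, axis=1).mean()
        assert np.linalg.norm(c0 - c1) > intra

    def test_perplexity_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(self._factors(rng, n=20), perplexity=30, seed=0)


class TestRegressPath:
    def test_constant_embedding_gives_constant_path(self):
        idx = [f"c{i}" for i in range(20)]
        pt = pd.Series(range(20), index=idx)
        emb = pd.DataFrame({"tsne1": 3.0, "tsne2": -1.0}, index=idx)
        path = regress_path(pt, emb)
        np.testing.assert_allclose(path, np.tile([3.0, -1.0], (len(path), 1)))

    def test_endpoints_near_rank_extremes(self, rng):
        idx = [f"c{i}" for i in range(100)]
        pt = pd.Series(range(100), index=idx)
        t = np.linspace(0, 1, 100)
        emb = pd.DataFrame(
            {"tsne1": 10 * t + rng.normal(0, 0.2, 100), "tsne2": t**2},
            index=idx,
        )
        path = regress_path(pt, emb)
        start = emb.iloc[:10].mean().to_numpy()
        end = emb.iloc[-10:].mean().to_numpy()
        assert np.linalg.norm(path[0] - start) < 1.0
        assert np.linalg.norm(path[-1] - end) < 1.0

    def test_polyline_at_least_straight_line(self, rng):
        idx = [f"c{i}" for i in range(50)]
        pt = pd.Series(range(50), index=idx)
        emb = pd.DataFrame(rng.normal(size=(50, 2)), index=idx, columns=["tsne1", "tsne2"])
        path = regress_path(pt, emb)
        seglen = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
        assert seglen >= np.linalg.norm(path[-1] - path[0]) - 1e-9


class TestFullOrdering:
    def test_pipeline_deterministic(self, processed, ordered):
        proc, meta, _ = processed
        pt2, _, _ = trajectory.order_cells(proc, meta)
        pd.testing.assert_series_equal(ordered[0], pt2)

    def test_pseudotime_correlates_with_fluorescence(self, processed, ordered):
        _, meta, _ = processed
        pt = ordered[0]
        assert spearman(pt, meta.loc[pt.index, "fluorescence"]) >= 0
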