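from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from trophicniche import community_stats as cs


def _dm(values, metric="bray_curtis"):
    return cs.distance_matrix(pd.DataFrame(np.asarray(values, dtype=float)), metric)


class TestDistanceMatrix:
    def test_bray_curtis_arithmetic(self):
        d = _dm([[2, 2], [1, 1], [2, 2], [0, 3]])
        assert d.values[0, 2] == 0.0
        assert d.values[0, 1] == pytest.approx(1 / 3)
        d2 = _dm([[1, 0], [0, 1]])
        assert d2.values[0, 1] == pytest.approx(1.0)  # disjoint supports

    def test_bray_curtis_bounds_and_symmetry(self, rng):
        d = _dm(rng.uniform(0, 5, size=(10, 6)))
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            _dm([[0, 0], [1, 2]])


from oracles import pseudo_f as _oracle_pseudo_f  # noqa: E402


class TestPermanova:
    def test_exhaustive_p_equals_full_enumeration_oracle(self, rng):
        """6 samples, 2 groups of 3: p over all 20 assignments, exactly."""
        from itertools import permutations

        data = rng.normal(size=(6, 4))
        data[:3] += 1.5
        dist = cs.distance_matrix(pd.DataFrame(np.abs(data)), "bray_curtis")
        codes = [0, 0, 0, 1, 1, 1]
        result = cs.permanova(dist, codes, exhaustive=True)
        all_f = [
            _oracle_pseudo_f(dist.values, perm)
            for perm in sorted(set(permutations(codes)))
        ]
        assert len(all_f) == 20
        obs = _oracle_pseudo_f(dist.values, codes)
        p_oracle = sum(f >= obs - 1e-12 for f in all_f) / 20
        assert result.observed == pytest.approx(obs)
        assert result.p_value == pytest.approx(p_oracle)
        assert result.n_perm == 20

    def test_univariate_euclidean_pseudo_f_equals_anova_f(self, rng):
        values = rng.normal(size=18) + np.repeat([0.0, 1.0, 2.0], 6)
        dist = cs.distance_matrix(pd.DataFrame(values[:, None]), "euclidean")
        codes = np.repeat([0, 1, 2], 6)
        res = cs.permanova(dist, codes, n_perm=9, seed=0, exhaustive=False)
        f_classic = f_oneway(values[:6], values[6:12], values[12:]).statistic
        assert res.observed == pytest.approx(f_classic, rel=1e-10)
        assert res.df == (2, 15)

    def test_separated_groups_reach_minimal_p(self, rng):
        data = rng.normal(size=(12, 3))
        data[6:] += 50.0
        dist = cs.distance_matrix(pd.DataFrame(data), "euclidean")
        res = cs.permanova(dist, np.repeat([0, 1], 6), n_perm=199, seed=1,
                           exhaustive=False)
        assert res.p_value == pytest.approx(1 / 200)

    def test_seed_reproducibility(self, rng):
        data = pd.DataFrame(rng.uniform(0.1, 3, size=(14, 5)))
        dist = cs.distance_matrix(data, "bray_curtis")
        codes = np.repeat([0, 1], 7)
        r1 = cs.permanova(dist, codes, n_perm=99, seed=42, exhaustive=False)
        r2 = cs.permanova(dist, codes, n_perm=99, seed=42, exhaustive=False)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 100

    def test_singleton_group_is_named_in_error(self, rng):
        dist = _dm(rng.uniform(0.1, 1, size=(5, 3)))
        with pytest.raises(ValueError, match="lonely"):
            cs.permanova(dist, ["a", "a", "a", "a", "lonely"])

    def test_matches_scikit_bio_statistic(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        data = rng.uniform(0, 4, size=(16, 6))
        dist = cs.distance_matrix(pd.DataFrame(data), "bray_curtis")
        codes = list(np.repeat(["a", "b"], 8))
        ours = cs.permanova(dist, codes, n_perm=9, seed=0, exhaustive=False)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dist.values), codes, permutations=9
        )
        assert ours.observed == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestPairwisePermanova:
    def test_pair_count_and_bh_monotonicity(self, rng):
        data = rng.uniform(0.1, 3, size=(20, 5))
        codes = np.repeat(["a", "b", "c", "d"], 5)
        dist = cs.distance_matrix(pd.DataFrame(data), "bray_curtis")
        results = cs.pairwise_permanova(dist, codes, n_perm=99, seed=3)
        assert len(results) == 6  # k(k-1)/2 for k=4
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-12


def _oracle_anosim_r(dist, codes):
    """Hand-rolled ANOSIM R from average-ranked distances."""
    n = len(codes)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dist[i, j] for i, j in pairs]
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):
        tied = [order[k]]
        while k + len(tied) < len(order) and values[order[k + len(tied)]] == values[order[k]]:
            tied.append(order[k + len(tied)])
        avg = sum(range(k + 1, k + len(tied) + 1)) / len(tied)
        for idx in tied:
            ranks[idx] = avg
        k += len(tied)
    within = [r for r, (i, j) in zip(ranks, pairs) if codes[i] == codes[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if codes[i] != codes[j]]
    m = n * (n - 1) / 2
    return (np.mean(between) - np.mean(within)) / (m / 2)


class TestAnosim:
    def test_toy_matches_hand_ranked_oracle(self, rng):
        data = rng.uniform(0.2, 4, size=(5, 3))
        dist = cs.distance_matrix(pd.DataFrame(data), "bray_curtis")
        codes = [0, 0, 1, 1, 1]
        res = cs.anosim(dist, codes, exhaustive=True)
        assert res.observed == pytest.approx(_oracle_anosim_r(dist.values, codes))

    def test_complete_separation_gives_r_of_one(self, rng):
        data = rng.normal(size=(10, 2))
        data[5:] += 100.0
        dist = cs.distance_matrix(pd.DataFrame(data), "euclidean")
        res = cs.anosim(dist, np.repeat([0, 1], 5), n_perm=99, seed=0,
                        exhaustive=False)
        assert res.observed == pytest.approx(1.0)

    def test_random_labels_centre_r_near_zero(self, rng):
        values = []
        data = rng.uniform(0.1, 2, size=(12, 4))
        dist = cs.distance_matrix(pd.DataFrame(data), "bray_curtis")
        for rep in range(60):
            codes = rng.permutation(np.repeat([0, 1], 6))
            values.append(cs.anosim(dist, codes, n_perm=9, seed=rep,
                                    exhaustive=False).observed)
        assert abs(np.mean(values)) < 0.05

    def test_matches_scikit_bio_statistic(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        data = rng.uniform(0, 4, size=(12, 5))
        dist = cs.distance_matrix(pd.DataFrame(data), "bray_curtis")
        codes = list(np.repeat(["a", "b", "c"], 4))
        ours = cs.anosim(dist, codes, n_perm=9, seed=0, exhaustive=False)
        theirs = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(dist.values), codes, permutations=9
        )
        assert ours.observed == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestSimper:
    def test_toy_matrix_matches_hand_decomposition(self):
        samples = pd.DataFrame(
            [[4.0, 1.0, 0.0], [3.0, 2.0, 1.0], [0.0, 5.0, 2.0], [1.0, 4.0, 3.0]],
            columns=["t1", "t2", "t3"],
        )
        groups = ["a", "a", "b", "b"]
        (result,) = cs.simper(samples, groups)
        # hand decomposition over the four between-group pairs
        expected = np.zeros(3)
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        for i, j in pairs:
            xa, xb = samples.iloc[i].to_numpy(), samples.iloc[j].to_numpy()
            expected += np.abs(xa - xb) / (xa + xb).sum()
        expected /= len(pairs)
        mean_bc = np.mean(
            [squareform(pdist(samples, "braycurtis"))[i, j] for i, j in pairs]
        )
        assert result.average_dissimilarity == pytest.approx(mean_bc)
        got = result.contributions.set_index("taxon")["mean_contribution_pct"]
        for k, taxon in enumerate(samples.columns):
            assert got[taxon] == pytest.approx(100 * expected[k] / expected.sum())

    def test_contributions_sum_to_100_and_cumulative_monotone(self, rng):
        samples = pd.DataFrame(rng.uniform(0, 5, size=(8, 6)))
        (result,) = cs.simper(samples, np.repeat(["x", "y"], 4))
        contrib = result.contributions
        assert contrib["mean_contribution_pct"].sum() == pytest.approx(100.0)
        assert (np.diff(contrib["cumulative_pct"]) >= -1e-9).all()

    def test_exclusive_dominant_taxa_explain_everything(self):
        samples = pd.DataFrame(
            [[50, 0, 0.1], [45, 0, 0.2], [0, 60, 0.1], [0, 55, 0.3]],
            columns=["only_a", "only_b", "shared"],
        )
        (result,) = cs.simper(samples, ["a", "a", "b", "b"])
        top2 = result.contributions.head(2)
        assert set(top2["taxon"]) == {"only_a", "only_b"}
        assert top2["mean_contribution_pct"].sum() > 99.0
        assert set(result.cutoff_set) <= {"only_a", "only_b"}


def _oracle_upgma_heights(dist):
    """Naive UPGMA agglomeration returning sorted merge heights."""
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return sorted(heights)


class TestUpgmaSimprof:
    def test_merge_heights_match_hand_upgma(self, rng):
        samples = pd.DataFrame(rng.uniform(0.2, 5, size=(6, 4)))
        part = cs.upgma_simprof(samples, n_perm=19, seed=0)
        dist = squareform(pdist(samples, "braycurtis"))
        np.testing.assert_allclose(
            sorted(part.linkage[:, 2]), _oracle_upgma_heights(dist)
        )

    def test_planted_two_block_structure_is_recovered(self, rng):
        # node alpha 0.01: recursion tests several homogeneous nodes, so
        # the per-node false-split rate is kept small
        block_a = rng.poisson([30, 25, 1, 1, 1], size=(7, 5)).astype(float)
        block_b = rng.poisson([1, 1, 30, 25, 20], size=(7, 5)).astype(float)
        samples = pd.DataFrame(np.vstack([block_a, block_b]))
        part = cs.upgma_simprof(samples, n_perm=299, alpha=0.01, seed=5)
        assert part.n_groups == 2
        labels = part.group_assignments.to_numpy()
        assert len(set(labels[:7])) == 1 and len(set(labels[7:])) == 1
        assert labels[0] != labels[7]

    def test_homogeneous_data_forms_one_group(self, rng):
        samples = pd.DataFrame(
            rng.dirichlet(np.full(5, 30.0), size=10) * 100
        )
        part = cs.upgma_simprof(samples, n_perm=299, alpha=0.01, seed=6)
        assert part.n_groups == 1


class TestRdaVarpart:
    def test_exact_linear_response_gives_adjusted_r2_near_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 4)))
        res = cs.rda_varpart(Y, X, n_perm=199, seed=0)
        assert set(res.selected_covariates) == {"a", "b"}
        assert res.constrained_variance_fraction == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.axis_eigenvalues) <= 1e-12).all()

    def test_independent_noise_explains_nothing(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        Y = pd.DataFrame(rng.normal(size=(200, 4)))
        res = cs.rda_varpart(Y, X, n_perm=99, seed=1)
        assert abs(res.constrained_variance_fraction) < 0.05

    def test_identical_sets_share_all_explained_variance(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        Y = pd.DataFrame(
            X.to_numpy() @ rng.normal(size=(2, 3)) + 0.3 * rng.normal(size=(80, 3))
        )
        res = cs.rda_varpart(
            Y, X, covariate_sets={"s1": ["a", "b"], "s2": ["a", "b"]},
            n_perm=99, seed=2,
        )
        vp = res.varpart_fractions
        assert vp["unique_s1"] == pytest.approx(0.0, abs=1e-9)
        assert vp["unique_s2"] == pytest.approx(0.0, abs=1e-9)
        assert vp["shared"] == pytest.approx(vp["total"])

    def test_collinear_covariate_is_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        X["twin"] = X["a"] * 2.0
        Y = pd.DataFrame(X[["a", "b"]].to_numpy() @ rng.normal(size=(2, 3)))
        with pytest.warns(UserWarning, match="twin"):
            res = cs.rda_varpart(Y, X, n_perm=49, seed=3)
        assert "twin" not in res.selected_covariates

    def test_normalize_covariates_centres_and_scales(self):
        raw = pd.DataFrame({"flow": [0.5, 4.1, 10.7, 37.9], "area": [13, 222, 340, 2516]})
        out = cs.normalize_covariates(raw)
        assert np.allclose(out.mean(), 0.0)
        assert np.allclose(out.std(ddof=1), 1.0)
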