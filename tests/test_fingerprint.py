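import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from svpangut import fingerprint, synthio


class TestClassifyPairs:
    def _rates(self, samples):
        rows = [
            {"species": "sp", "sample_a": a, "sample_b": b, "rate_per_mb": 1.0}
            for a, b in itertools.combinations(samples, 2)
        ]
        return pd.DataFrame(rows)

    def test_two_samples_same_individual(self):
        t = fingerprint.classify_pairs(self._rates(["a", "b"]), {"a": "I1", "b": "I1"})
        assert list(t["comparison_class"]) == ["intra_individual"]

    def test_three_individuals_all_inter(self):
        t = fingerprint.classify_pairs(
            self._rates(["a", "b", "c"]), {"a": "I1", "b": "I2", "c": "I3"}
        )
        assert (t["comparison_class"] == "inter_individual").sum() == 3

    def test_mixed_two_plus_two_design(self):
        t = fingerprint.classify_pairs(
            self._rates(["a1", "a2", "b1", "b2"]),
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        assert (t["comparison_class"] == "intra_individual").sum() == 2
        assert (t["comparison_class"] == "inter_individual").sum() == 4

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            fingerprint.classify_pairs(self._rates(["a", "b"]), {"a": "I1"})


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning):
            _, p = fingerprint.wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert p == 1.0

    def test_two_vs_two_exact(self):
        _, p = fingerprint.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    @pytest.mark.parametrize("nx,ny,seed", [(3, 4, 0), (5, 5, 1), (6, 6, 2)])
    def test_exact_matches_enumeration_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1, nx + ny + 1)).astype(float)
        x, y = pooled[:nx], pooled[nx:]
        _, p = fingerprint.wilcoxon_rank_sum(x, y)
        # enumerate all C(nx+ny, nx) group assignments of the ranks
        ranks = np.arange(1, nx + ny + 1)
        obs_u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        n = nx * ny
        us = [
            sum(1 for i in combo for j in set(range(nx + ny)) - set(combo)
                if ranks[i] > ranks[j])
            for combo in itertools.combinations(range(nx + ny), nx)
        ]
        us = np.array(us, dtype=float)
        p_oracle = np.mean(np.minimum(us, n - us) <= min(obs_u, n - obs_u))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_approximation_close_to_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        _, p = fingerprint.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        n = len(x)
        obs = abs(np.sum(pooled[:n]))  # use rank-sum of x under label permutation
        from scipy.stats import rankdata

        r = rankdata(pooled)
        obs_stat = abs(r[:n].sum() - n * (len(pooled) + 1) / 2)
        sims = np.empty(100_000)
        for i in range(100_000):
            perm = rng.permutation(r)
            sims[i] = abs(perm[:n].sum() - n * (len(pooled) + 1) / 2)
        p_mc = np.mean(sims >= obs_stat - 1e-9)
        assert p == pytest.approx(p_mc, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fingerprint.wilcoxon_rank_sum([], [1.0])


class TestJaccard:
    def test_examples(self):
        m = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [1, 1, 0]],
            index=["a", "b", "c"],
            columns=["f1", "f2", "f3"],
        )
        d = fingerprint.jaccard_distance_matrix(m)
        assert d.loc["a", "c"] == 0.0
        assert d.loc["a", "b"] == pytest.approx(1 - 1 / 3)

    def test_disjoint_rows_distance_one(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert fingerprint.jaccard_distance_matrix(m).loc["a", "b"] == 1.0

    def test_empty_pair_conventions(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=["a", "b", "c"])
        assert fingerprint.jaccard_distance_matrix(m).loc["a", "b"] == 0.0
        dna = fingerprint.jaccard_distance_matrix(m, empty_pair="na")
        assert np.isnan(dna.loc["a", "b"])
        assert dna.loc["a", "c"] == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            fingerprint.jaccard_distance_matrix(pd.DataFrame([[0.5, 1]]))

    def test_metric_axioms_exhaustive_six_features(self):
        # all 64 possible presence rows over 6 features; every triple obeys
        # the triangle inequality
        rows = np.array(list(itertools.product([0, 1], repeat=6)), dtype=bool)
        d = squareform(pdist(rows, metric="jaccard"))
        m = pd.DataFrame(rows.astype(int))
        ours = fingerprint.jaccard_distance_matrix(m).to_numpy()
        assert np.allclose(ours, d)
        assert np.allclose(ours, ours.T) and np.allclose(np.diag(ours), 0)
        viol = ours[:, :, None] > ours[:, None, :] + ours[None, :, :] + 1e-12
        assert not viol.any()


class TestPcoa:
    def test_three_collinear_points(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ordn = fingerprint.pcoa(d, k=1)
        x = ordn.coordinates[:, 0]
        gaps = sorted(abs(v) for v in (x[0] - x[1], x[1] - x[2], x[0] - x[2]))
        assert gaps == pytest.approx([1.0, 1.0, 2.0])

    def test_all_zero_distances(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ordn = fingerprint.pcoa(np.zeros((4, 4)), k=2)
        assert np.allclose(ordn.coordinates, 0.0)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        ordn = fingerprint.pcoa(d, k=2)
        d2 = squareform(pdist(ordn.coordinates))
        assert np.allclose(d, d2, atol=1e-8)
        assert np.allclose(ordn.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert (np.diff(ordn.eigenvalues) <= 1e-12).all()

    def test_k_reduced_with_warning(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            ordn = fingerprint.pcoa(d, k=5)
        assert ordn.coordinates.shape[1] == 1

    def test_matches_skbio_on_random_distances(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        ours = fingerprint.pcoa(d, k=3)
        theirs = skbio_pcoa(d, number_of_dimensions=3)
        ref = theirs.samples.to_numpy()
        for j in range(3):  # eigenvectors are sign-arbitrary
            col = ours.coordinates[:, j]
            assert np.allclose(col, ref[:, j], atol=1e-6) or np.allclose(
                col, -ref[:, j], atol=1e-6
            )


class TestProtest:
    def test_rotation_recovers_floor_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(25, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        y = x @ rot
        res = fingerprint.protest(x, y, n_perm=999, seed=1)
        assert res.correlation == pytest.approx(1.0, abs=1e-10)
        assert res.m2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(0.001)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 2))
        y = rng.normal(size=(15, 2))
        a = fingerprint.protest(x, y, n_perm=199, seed=2)
        b = fingerprint.protest(x, 2.0 * y, n_perm=199, seed=2)
        assert a.m2 == pytest.approx(b.m2)
        assert a.correlation == pytest.approx(b.correlation)
        assert a.p == b.p

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fingerprint.protest(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_matches_vegan_protest_statistic(self):
        # oracle: m2 = 1 - (sum of singular values)^2 on unit-trace
        # configurations, computed independently per the textbook formula
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 2))
        y = 0.8 * x + 0.3 * rng.normal(size=(20, 2))
        res = fingerprint.protest(x, y, n_perm=99, seed=3)
        xc = (x - x.mean(0)) / np.sqrt(((x - x.mean(0)) ** 2).sum())
        yc = (y - y.mean(0)) / np.sqrt(((y - y.mean(0)) ** 2).sum())
        ev = np.clip(np.linalg.eigvalsh(yc.T @ xc @ xc.T @ yc), 0.0, None)
        t = np.sqrt(ev).sum()
        assert res.m2 == pytest.approx(1 - t**2, abs=1e-8)


class TestInterVsIntraDominance:
    def test_inter_rates_dominate_intra(self):
        profiles, mapping = synthio.simulate_sv_profiles(
            n_individuals=10, samples_per_individual=3, seed=12
        )
        rates = fingerprint.pairwise_sv_rates(profiles, 2_000_000)
        table = fingerprint.classify_pairs(rates, mapping)
        inter = table.loc[table["comparison_class"] == "inter_individual", "rate_per_mb"]
        intra = table.loc[table["comparison_class"] == "intra_individual", "rate_per_mb"]
        assert inter.median() > intra.median()
        _, p = fingerprint.wilcoxon_rank_sum(inter, intra)
        assert p < 0.01
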