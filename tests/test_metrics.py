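"""Integration metrics against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
import scipy.stats

from sida.datatypes import Embedding
from sida.metrics import (
    _kbet_chi2,
    ari,
    asw,
    evaluate_all,
    f1_asw,
    f1_lisi,
    kbet,
    knn_indices,
    lisi,
    positive_rate,
    true_positive_rate,
)


def blobs(rng, centers, n_per, scale=1.0):
    X, lab = [], []
    for i, c in enumerate(centers):
        c = np.atleast_1d(np.asarray(c, dtype=float))
        X.append(c + scale * rng.normal(size=(n_per, len(c))))
        lab += [f"t{i}"] * n_per
    return np.vstack(X), np.array(lab, dtype=object)


# ---------------------------------------------------------------------------
# brute-force oracles


def naive_knn(coords, k):
    n = len(coords)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        d = np.round(np.sum((coords - coords[i]) ** 2, axis=1), 9)
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[j], j))
        out[i] = order[:k]
    return out


def naive_silhouette(coords, labels):
    n = len(coords)
    D = np.sqrt(np.sum((coords[:, None] - coords[None]) ** 2, axis=2))
    s = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i]) & (np.arange(n) != i)
        if own.sum() == 0:
            s[i] = 0.0
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == l].mean() for l in set(labels) if l != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def naive_ari(x, y):
    """Closed-form pair-counting adjusted Rand index."""
    from math import comb

    n = len(x)
    cx, cy = sorted(set(x)), sorted(set(y))
    cont = np.array([[np.sum((x == a) & (y == b)) for b in cy] for a in cx])
    sum_ij = sum(comb(int(v), 2) for v in cont.flat)
    sum_a = sum(comb(int(v), 2) for v in cont.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in cont.sum(axis=0))
    total = comb(n, 2)
    exp = sum_a * sum_b / total
    mx = (sum_a + sum_b) / 2
    return (sum_ij - exp) / (mx - exp)


# ---------------------------------------------------------------------------


class TestKnn:
    def test_matches_naive_with_index_tiebreak(self, rng):
        coords = rng.integers(0, 4, size=(60, 2)).astype(float)  # many exact ties
        np.testing.assert_array_equal(knn_indices(coords, 7), naive_knn(coords, 7))

    def test_no_self_neighbor(self, rng):
        coords = rng.normal(size=(30, 3))
        knn = knn_indices(coords, 5)
        assert not np.any(knn == np.arange(30)[:, None])

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            knn_indices(rng.normal(size=(5, 2)), 5)


class TestPositiveRate:
    def test_two_pure_far_blobs(self, rng):
        X, lab = blobs(rng, [np.zeros(4), np.full(4, 100.0)], 60)
        rate, flags = positive_rate(X, lab, k=50)
        assert rate == 1.0 and flags.all()

    def test_random_labels_unreachable_purity(self, rng):
        X = rng.normal(size=(120, 4))
        lab = np.array(["a", "b"] * 60, dtype=object)
        rate, _ = positive_rate(X, lab, k=50)
        assert rate == 0.0

    def test_matches_naive_recomputation(self, rng):
        X = rng.normal(size=(200, 3))
        lab = np.array([f"t{i%3}" for i in range(200)], dtype=object)
        k = 20
        knn = naive_knn(X, k)
        naive_flags = np.array(
            [(lab[knn[i]] == lab[i]).mean() >= 0.95 for i in range(200)]
        )
        rate, flags = positive_rate(X, lab, k=k)
        assert rate == naive_flags.mean()
        np.testing.assert_array_equal(flags, naive_flags)


class TestTruePositiveRate:
    def test_three_sigma_interval_accepts_balanced_split(self):
        # two batches with p = (0.5, 0.5), k=50: bounds ~[14.39, 35.61]
        p = 0.5
        lo = 50 * p - 3 * np.sqrt(50 * p * (1 - p))
        hi = 50 * p + 3 * np.sqrt(50 * p * (1 - p))
        assert lo == pytest.approx(14.39, abs=0.01)
        assert hi == pytest.approx(35.61, abs=0.01)

    def _tpr_fixture(self, rng, n_from_b0):
        """One positive cell whose 50 neighbors split n_from_b0 / (50 - n_from_b0)."""
        # cluster of 101 same-type cells; first 51 in b0, rest in b1 -> p ~ 0.5
        n = 102
        coords = np.zeros((n, 2))
        coords[0] = [0, 0]
        # neighbors of cell 0: closest 50 cells
        for i in range(1, n):
            coords[i] = [0.01 * i, 0]
        types = np.array(["t"] * n, dtype=object)
        batch = np.array(["b1"] * n, dtype=object)
        batch[: n // 2] = "b0"
        # force neighbor composition of cell 0: its 50 nearest are cells 1..50
        nb = np.arange(1, 51)
        batch[nb] = "b1"
        batch[nb[:n_from_b0]] = "b0"
        # rebalance global counts to p=(0.5,0.5)
        rest = np.arange(51, n)
        need_b0 = n // 2 - n_from_b0 - (1 if batch[0] == "b0" else 0)
        batch[rest] = "b1"
        batch[rest[:need_b0]] = "b0"
        batch[0] = "b0"
        return coords, types, batch

    @pytest.mark.parametrize("split,expected", [(20, True), (10, False)])
    def test_direct_interval_evaluation(self, rng, split, expected):
        coords, types, batch = self._tpr_fixture(rng, split)
        _, flags = positive_rate(coords, types, k=50)
        assert flags[0]
        tpr = true_positive_rate(coords, types, batch, _first_only(flags), k=50)
        assert (tpr > 0) == expected

    def test_single_batch_every_positive_is_true(self, rng):
        X, lab = blobs(rng, [np.zeros(4), np.full(4, 50.0)], 60)
        batch = np.array(["only"] * len(X), dtype=object)
        rate, flags = positive_rate(X, lab, k=50)
        assert true_positive_rate(X, lab, batch, flags, k=50) == rate

    def test_never_exceeds_positive_rate(self, rng):
        X = rng.normal(size=(150, 3))
        lab = np.array([f"t{i%2}" for i in range(150)], dtype=object)
        batch = np.array([f"b{i%3}" for i in range(150)], dtype=object)
        rate, flags = positive_rate(X, lab, k=30)
        assert true_positive_rate(X, lab, batch, flags, k=30) <= rate


def _first_only(flags):
    out = np.zeros_like(flags)
    out[0] = flags[0]
    return out


class TestKbet:
    def test_chi2_statistic_hand_toy(self):
        # neighborhood counts (30, 10, 10) vs expected (25, 15, 10)
        stat = _kbet_chi2(np.array([30.0, 10, 10]), np.array([25.0, 15, 10]))
        assert stat == pytest.approx((5**2) / 25 + (5**2) / 15 + 0.0)

    def test_disjoint_batches_score_zero(self, rng):
        X = np.vstack([rng.normal(size=(100, 3)), 50.0 + rng.normal(size=(100, 3))])
        batch = np.array(["b0"] * 100 + ["b1"] * 100, dtype=object)
        assert kbet(X, batch, k=50, seed=0) == 0.0

    def test_well_mixed_blob_high_score(self, rng):
        X = rng.normal(size=(600, 3))
        batch = rng.choice(["b0", "b1", "b2"], size=600)
        assert kbet(X, batch.astype(object), k=50, seed=0) > 0.8

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            kbet(rng.normal(size=(60, 2)), np.array(["b"] * 60, dtype=object), k=10)

    def test_null_calibration(self, rng):
        """i.i.d. batch labels in one blob: rejection rate ~ alpha (3 MC SEs)."""
        alpha = 0.05
        n = 1000
        X = rng.normal(size=(n, 5))
        rejections, tested = 0, 0
        for seed in range(20):
            labels = rng.choice(["b0", "b1", "b2"], size=n).astype(object)
            score = kbet(X, labels, k=50, sample_fraction=0.10, alpha=alpha, seed=seed)
            n_s = round(n * 0.10)
            rejections += (1.0 - score) * n_s
            tested += n_s
        rate = rejections / tested
        se = np.sqrt(alpha * (1 - alpha) / tested)
        assert abs(rate - alpha) <= 3 * se + 1e-12


class TestLisi:
    def test_single_category_neighborhood_is_one(self, rng):
        X, _ = blobs(rng, [np.zeros(3)], 80)
        lab = np.array(["only"] * 80, dtype=object)
        scores = lisi(X, lab, perplexity=20)
        np.testing.assert_allclose(scores, 1.0, atol=1e-9)

    def test_uniform_mixture_approaches_B(self, rng):
        X = rng.normal(size=(400, 2))
        lab = np.array([f"b{i%4}" for i in range(400)], dtype=object)
        scores = lisi(X, lab, perplexity=30)
        assert scores.mean() > 3.5  # near the maximum diversity of B=4

    def test_f1_endpoints(self):
        assert f1_lisi(ilisi_rescaled=1.0, clisi_rescaled=0.0) == 1.0
        assert f1_lisi(ilisi_rescaled=0.7, clisi_rescaled=1.0) == 0.0

    def test_perplexity_bounds(self, rng):
        with pytest.raises(ValueError):
            lisi(rng.normal(size=(10, 2)), np.array(["a"] * 10, dtype=object), perplexity=10)


class TestAsw:
    def test_ideal_separation(self, rng):
        X, lab = blobs(rng, [np.zeros(3), np.full(3, 200.0)], 50, scale=0.01)
        assert asw(X, lab) > 0.99

    def test_equidistant_point_zero_silhouette(self):
        # point 0 exactly between its own cluster-mate and the other pair
        coords = np.array([[0.0, 0], [2.0, 0], [-2.0, 0], [-2.0, 0.1]])
        lab = np.array(["a", "a", "b", "b"], dtype=object)
        from sklearn.metrics import silhouette_samples

        s = silhouette_samples(coords, lab.astype(str))
        assert s[0] == pytest.approx(0.0, abs=0.03)

    def test_matches_naive_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        lab = np.array([f"t{i%3}" for i in range(30)], dtype=object)
        assert asw(X, lab) == pytest.approx(naive_silhouette(X, lab), abs=1e-8)

    def test_single_label_raises(self, rng):
        with pytest.raises(ValueError):
            asw(rng.normal(size=(10, 2)), np.array(["x"] * 10, dtype=object))

    def test_f1_form(self):
        assert f1_asw(0.5, 1.0) == pytest.approx(2 * 0.5 * 1.0 / (0.5 + 1.0))


class TestAri:
    def test_perfect_clustering(self, rng):
        X, lab = blobs(rng, [np.zeros(3), np.full(3, 100.0)], 40, scale=0.1)
        batch = np.array(["b0", "b1"] * 40, dtype=object)
        f1, ari_ct, ari_b = ari(X, lab, batch, seed=0)
        assert ari_ct == pytest.approx(1.0)
        assert f1 > 0.9

    def test_label_permutation_invariance(self, rng):
        from sklearn.metrics import adjusted_rand_score

        x = rng.integers(0, 3, size=50)
        perm = np.array([2, 0, 1])[x]
        assert adjusted_rand_score(x, perm) == 1.0

    def test_printed_toy_contingency(self):
        x = np.array(["1", "1", "2", "2"])
        y = np.array(["1", "2", "2", "2"])
        from sklearn.metrics import adjusted_rand_score

        expected = naive_ari(x, y)
        assert adjusted_rand_score(x, y) == pytest.approx(expected, abs=1e-12)

    def test_kmeans_ari_matches_naive_formula(self, rng):
        X = rng.normal(size=(60, 3))
        lab = np.array([f"t{i%3}" for i in range(60)], dtype=object)
        batch = np.array([f"b{i%2}" for i in range(60)], dtype=object)
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        pred = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(X)
        assert adjusted_rand_score(lab, pred) == pytest.approx(
            naive_ari(lab, pred.astype(str)), abs=1e-12
        )

    def test_too_few_cells_or_types(self, rng):
        with pytest.raises(ValueError):
            ari(rng.normal(size=(5, 2)), np.array(["a"] * 5, dtype=object),
                np.array(["b"] * 5, dtype=object))


class TestEvaluateAll:
    def _embedding(self, rng, separated=True, mixed=True):
        shift = 30.0 if separated else 0.5
        X, lab = blobs(rng, [np.zeros(4), np.full(4, shift)], 150)
        if mixed:
            batch = rng.choice(["b0", "b1"], size=len(X)).astype(object)
        else:
            # both types occur in both batches, but the batches sit apart
            batch = np.array(["b0", "b1"] * 150, dtype=object)
            X = X + np.where(batch == "b1", 15.0, 0.0)[:, None]
        return Embedding(
            X,
            np.array([f"c{i}" for i in range(len(X))], dtype=object),
            lab,
            batch,
        )

    def test_well_integrated_fixture_near_optima(self, rng):
        rep = evaluate_all(self._embedding(rng), seed=0)
        assert rep.positive_rate >= 0.95
        assert rep.true_positive_rate >= 0.8
        assert rep.kbet >= 0.8
        assert rep.f1_ari >= 0.9
        assert rep.f1_lisi >= 0.5

    def test_batch_separated_fixture_scores_low(self, rng):
        rep = evaluate_all(self._embedding(rng, mixed=False), seed=0)
        assert rep.kbet <= 0.05
        assert rep.true_positive_rate <= 0.05

    def test_all_scores_in_unit_interval_and_deterministic(self, rng):
        emb = self._embedding(rng)
        rep1 = evaluate_all(emb, seed=3)
        rep2 = evaluate_all(emb, seed=3)
        for v in rep1.headline().values():
            assert 0.0 <= v <= 1.0
        assert rep1.headline() == rep2.headline()

    def test_rigid_motion_invariance(self, rng):
        from scipy.stats import ortho_group

        emb = self._embedding(rng)
        R = ortho_group.rvs(emb.dim, random_state=1)
        moved = Embedding(emb.coords @ R + 7.0, emb.cell_ids, emb.cell_types, emb.batch_ids)
        a = evaluate_all(emb, seed=0)
        b = evaluate_all(moved, seed=0)
        assert a.positive_rate == b.positive_rate
        assert a.true_positive_rate == b.true_positive_rate
        assert a.kbet == b.kbet
        assert abs(a.f1_lisi - b.f1_lisi) < 0.02

    def test_uniform_scaling_invariance(self, rng):
        emb = self._embedding(rng)
        scaled = Embedding(emb.coords * 3.7, emb.cell_ids, emb.cell_types, emb.batch_ids)
        a = evaluate_all(emb, seed=0)
        b = evaluate_all(scaled, seed=0)
        assert a.positive_rate == b.positive_rate
        assert a.kbet == b.kbet
        assert abs(a.f1_lisi - b.f1_lisi) < 1e-6
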