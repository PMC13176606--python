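"""Evaluation metrics against independently coded brute-force oracles."""

import math

import numpy as np
import pytest

from stimpute.data import SpatialCoordinates, ValidationError
from stimpute.evaluation import (
    clustering_scores,
    evaluate_imputation,
    js_divergence,
    moran_shift_summary,
    morans_i,
    neighborhood_recall,
    pcc,
    rmse_z,
    ssim,
    svg_recovery_auprc,
    wasserstein_z,
)


# --- brute-force oracles (independent transcriptions of the definitions) ---

def brute_pcc(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    if sx == 0 or sy == 0:
        return 0.0
    return cov / (sx * sy)


def brute_ssim(x, y, c1=0.01, c2=0.03):
    def norm(v):
        lo, hi = min(v), max(v)
        if hi == lo:
            return [0.0] * len(v)
        return [(a - lo) / (hi - lo) for a in v]

    xn, yn = norm(x), norm(y)
    n = len(xn)
    mx, my = sum(xn) / n, sum(yn) / n
    vx = sum((a - mx) ** 2 for a in xn) / n
    vy = sum((b - my) ** 2 for b in yn) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(xn, yn)) / n
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def brute_z(v):
    n = len(v)
    mu = sum(v) / n
    sd = math.sqrt(sum((a - mu) ** 2 for a in v) / n)
    return [(a - mu) / sd for a in v]


def brute_rmse_z(x, y):
    zx, zy = brute_z(x), brute_z(y)
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(zx, zy)) / len(x))


def brute_wasserstein_z(x, y):
    zx, zy = sorted(brute_z(x)), sorted(brute_z(y))
    return sum(abs(a - b) for a, b in zip(zx, zy)) / len(x)


def brute_js(x, y):
    sx, sy = sum(x), sum(y)
    p = [a / sx for a in x]
    q = [b / sy for b in y]
    m = [(a + b) / 2 for a, b in zip(p, q)]

    def kl(a, b):
        return sum(ai * math.log2(ai / bi) for ai, bi in zip(a, b) if ai > 0)

    return 0.5 * kl(q, m) + 0.5 * kl(p, m)


def brute_morans_i(values, xy, k):
    n = len(values)
    mu = sum(values) / n
    z = [v - mu for v in values]
    w = [[0.0] * n for _ in range(n)]
    for i in range(n):
        d = [(xy[i, 0] - xy[j, 0]) ** 2 + (xy[i, 1] - xy[j, 1]) ** 2 for j in range(n)]
        order = sorted(range(n), key=lambda j: (d[j], j))
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            w[i][j] = 1.0 / k
    sw = sum(sum(row) for row in w)
    num = sum(w[i][j] * z[i] * z[j] for i in range(n) for j in range(n))
    den = sum(v**2 for v in z)
    if den == 0:
        return 0.0
    return (n / sw) * num / den


def brute_ari(a, b):
    from itertools import combinations

    n = len(a)
    s_both = s_a = s_b = 0
    for i, j in combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s_both += same_a and same_b
        s_a += same_a
        s_b += same_b
    pairs = n * (n - 1) / 2
    expected = s_a * s_b / pairs
    max_index = (s_a + s_b) / 2
    if max_index == expected:
        return 1.0
    return (s_both - expected) / (max_index - expected)


# --- tests ---

class TestMetricOracles:
    def test_hand_cases(self):
        assert pcc([1, 2, 3, 4], [2, 4, 5, 9]) == pytest.approx(
            brute_pcc([1, 2, 3, 4], [2, 4, 5, 9]), abs=1e-12)
        assert ssim([0, 1, 2], [2, 1, 0]) == pytest.approx(
            brute_ssim([0, 1, 2], [2, 1, 0]), abs=1e-12)
        assert rmse_z([1, 2, 3], [1, 3, 2]) == pytest.approx(
            brute_rmse_z([1, 2, 3], [1, 3, 2]), abs=1e-10)

    @pytest.mark.parametrize("trial", range(25))
    def test_random_instances_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 200))
        x = rng.gamma(2.0, 1.0, size=n)
        y = rng.gamma(2.0, 1.0, size=n)
        assert pcc(x, y) == pytest.approx(brute_pcc(x, y), abs=1e-8)
        assert ssim(x, y) == pytest.approx(brute_ssim(x, y), abs=1e-8)
        assert rmse_z(x, y) == pytest.approx(brute_rmse_z(x, y), abs=1e-8)
        assert wasserstein_z(x, y) == pytest.approx(brute_wasserstein_z(x, y), abs=1e-8)
        assert js_divergence(x, y) == pytest.approx(brute_js(x, y), abs=1e-8)

    def test_affine_invariance_of_rmse_z(self, rng):
        x = rng.normal(size=30)
        assert rmse_z(x, 5.0 * x + 3.0) == pytest.approx(0.0, abs=1e-9)

    def test_js_disjoint_supports_is_one(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.gamma(2.0, 1.0, size=40), rng.gamma(2.0, 1.0, size=40)
        assert js_divergence(x, y) == pytest.approx(js_divergence(y, x), abs=1e-12)
        assert wasserstein_z(x, y) == pytest.approx(wasserstein_z(y, x), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(10):
            x, y = rng.gamma(2.0, 1.0, size=25), rng.gamma(2.0, 1.0, size=25)
            assert -1.0 <= pcc(x, y) <= 1.0
            assert 0.0 <= js_divergence(x, y) <= 1.0
            assert rmse_z(x, y) >= 0.0 and wasserstein_z(x, y) >= 0.0

    def test_constant_vector_policy(self):
        assert pcc([1, 1, 1], [1, 2, 3]) == 0.0
        assert ssim([2, 2, 2], [2, 2, 2]) == pytest.approx(1.0 * (0.01 / 0.01) * (0.03 / 0.03))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pcc([1, 2], [1, 2, 3])


class TestMoransI:
    def test_constant_vector_is_zero(self, rng):
        coords = SpatialCoordinates(rng.uniform(size=(20, 2)))
        assert morans_i(np.ones(20), coords, 6) == 0.0

    def test_matches_brute_force_on_constructed_layout(self, rng):
        coords = rng.uniform(size=(20, 2))
        values = np.sin(3 * coords[:, 0]) + rng.normal(0, 0.1, 20)
        mine = morans_i(values, SpatialCoordinates(coords), 5)
        assert mine == pytest.approx(brute_morans_i(list(values), coords, 5), abs=1e-10)

    def test_two_blob_layout_positive(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(1, 0.05, (10, 2))])
        values = np.array([1.0] * 10 + [-1.0] * 10) + rng.normal(0, 0.01, 20)
        assert morans_i(values, SpatialCoordinates(coords), 4) > 0.5

    def test_permutation_reduces_autocorrelation(self, rng):
        coords = rng.uniform(size=(100, 2))
        smooth = np.sin(4 * coords[:, 0]) * np.cos(4 * coords[:, 1])
        i_smooth = morans_i(smooth, SpatialCoordinates(coords), 6)
        i_perm = morans_i(rng.permutation(smooth), SpatialCoordinates(coords), 6)
        assert i_smooth > i_perm

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValidationError):
            morans_i(np.ones(5), SpatialCoordinates(rng.uniform(size=(5, 2))), 6)


class TestMoranShift:
    def test_identical_matrices_zero_shift(self, rng):
        coords = SpatialCoordinates(rng.uniform(size=(30, 2)))
        m = rng.gamma(2.0, 1.0, size=(30, 4))
        summary = moran_shift_summary(m, m, coords, [f"g{i}" for i in range(4)])
        assert np.allclose(summary.delta, 0.0)
        assert summary.fraction_within == 1.0 and summary.band == 0.10

    def test_spatial_smoothing_raises_moran(self, rng):
        coords = rng.uniform(size=(60, 2))
        noisy = rng.normal(size=(60, 1))
        # neighbor-averaged (smoothed) version of the same field
        from sklearn.neighbors import NearestNeighbors

        idx = NearestNeighbors(n_neighbors=6).fit(coords).kneighbors(coords)[1]
        smoothed = noisy[idx].mean(axis=1)
        summary = moran_shift_summary(noisy, smoothed, SpatialCoordinates(coords), ["g"])
        assert summary.delta[0] > 0


class TestNeighborhoodRecall:
    def test_identity_mapping_full_recall(self, rng):
        z = rng.normal(size=(80, 10))
        res = neighborhood_recall(z, z, k=5, m=15)
        assert res.mean == 1.0 and np.all(res.per_cell == 1.0)

    def test_random_permutation_matches_chance_level(self):
        rng = np.random.default_rng(0)
        n, k, m = 400, 5, 45
        z = rng.normal(size=(n, 8))
        perm = rng.permutation(n)
        res = neighborhood_recall(z, z[perm], k=k, m=m)
        assert res.mean == pytest.approx(m / (n - 1), abs=0.05)

    def test_defaults_and_validation(self, rng):
        z = rng.normal(size=(100, 6))
        res = neighborhood_recall(z, z)
        assert res.k == 15 and res.m == 45
        with pytest.raises(ValidationError):
            neighborhood_recall(z[:40], z[:40], k=15, m=45)


class TestClustering:
    def test_identical_labelings(self):
        labels = [0, 0, 1, 1, 2, 2]
        scores = clustering_scores(labels, labels)
        assert scores["ari"] == 1.0 and scores["nmi"] == 1.0

    def test_label_permutation_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [2, 2, 0, 0, 1, 1]
        assert clustering_scores(a, b)["ari"] == 1.0

    def test_ari_matches_exhaustive_pair_oracle(self, rng):
        a = rng.integers(0, 3, size=25)
        b = rng.integers(0, 3, size=25)
        assert clustering_scores(a, b)["ari"] == pytest.approx(
            brute_ari(list(a), list(b)), abs=1e-10)

    def test_macro_silhouette(self, rng):
        emb = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(3, 0.2, (20, 2))])
        labels = np.array([0] * 10 + [1] * 20)
        scores = clustering_scores(labels, labels, embedding=emb)
        from sklearn.metrics import silhouette_samples

        s = silhouette_samples(emb, labels)
        expected = (s[:10].mean() + s[10:].mean()) / 2
        assert scores["silhouette"] == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_silhouette_errors(self, rng):
        with pytest.raises(ValidationError):
            clustering_scores([0, 0, 0], [0, 0, 0], embedding=rng.normal(size=(3, 2)))


class TestEvaluateImputation:
    def test_perfect_imputation_identity_suite(self, rng):
        m = rng.gamma(2.0, 1.0, size=(30, 5))
        report = evaluate_imputation(m, m.copy(), [f"g{i}" for i in range(5)])
        assert report.averages["pcc"] == pytest.approx(1.0, abs=1e-12)
        assert report.averages["ssim"] == pytest.approx(1.0, abs=1e-12)
        assert report.averages["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert report.averages["wasserstein"] == pytest.approx(0.0, abs=1e-12)
        assert report.averages["js"] == pytest.approx(0.0, abs=1e-12)

    def test_table_matches_individual_metrics(self, rng):
        m = rng.gamma(2.0, 1.0, size=(20, 3))
        p = rng.gamma(2.0, 1.0, size=(20, 3))
        report = evaluate_imputation(m, p, ["a", "b", "c"])
        for j, g in enumerate(["a", "b", "c"]):
            assert report.per_gene.loc[g, "pcc"] == pytest.approx(pcc(m[:, j], p[:, j]))
            assert report.per_gene.loc[g, "js"] == pytest.approx(
                js_divergence(m[:, j], p[:, j]))
        for col in report.per_gene.columns:
            assert report.averages[col] == pytest.approx(report.per_gene[col].mean())

    def test_all_zero_measured_gene_excluded(self, rng):
        m = rng.gamma(2.0, 1.0, size=(15, 3))
        m[:, 1] = 0.0
        report = evaluate_imputation(m, m + 0.1, ["a", "b", "c"])
        assert list(report.per_gene.index) == ["a", "c"]
        assert report.diagnostics["excluded_genes"] == ["b"]

    def test_no_evaluable_genes_errors(self):
        with pytest.raises(ValidationError):
            evaluate_imputation(np.zeros((5, 2)), np.ones((5, 2)), ["a", "b"])


def test_svg_auprc_prefers_correct_ranking():
    scores_good = {"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.05}
    scores_bad = {"a": 0.1, "b": 0.05, "c": 0.9, "d": 0.8}
    ref = ["a", "b"]
    assert svg_recovery_auprc(scores_good, ref) == 1.0
    assert svg_recovery_auprc(scores_good, ref) > svg_recovery_auprc(scores_bad, ref)


class TestMetricPropertiesHypothesis:
    """Invariant checks over generated inputs (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    vectors = st.lists(st.floats(0.0, 1e3, allow_nan=False), min_size=3, max_size=40)

    @given(x=vectors, y=vectors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_symmetric_nonnegative(self, x, y):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n]), np.asarray(y[:n])
        assert -1.0 - 1e-12 <= pcc(x, y) <= 1.0 + 1e-12
        j = js_divergence(x, y)
        assert -1e-12 <= j <= 1.0 + 1e-12
        assert j == pytest.approx(js_divergence(y, x), abs=1e-9)
        assert rmse_z(x, y) >= 0.0
        w = wasserstein_z(x, y)
        assert w >= 0.0 and w == pytest.approx(wasserstein_z(y, x), abs=1e-9)

    @given(x=vectors, a=st.floats(0.1, 50), b=st.floats(-10, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rmse_z_affine_invariance(self, x, a, b):
        x = np.asarray(x)
        if x.std() == 0:
            return
        assert rmse_z(x, a * x + b) == pytest.approx(0.0, abs=1e-6)
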