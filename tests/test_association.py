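import numpy as np
import pytest
from scipy import stats

from lagmine.association import (
    SeriesPair,
    cca_score,
    ccf_score,
    delay_embed,
    dtw_distance,
    dtw_score,
    pearson_score,
    score_all_genes,
    spearman_score,
)
from lagmine.io import PipelineConfig


def pearson_oracle(x, y):
    """Textbook product-moment formula, coded independently of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def midrank(v):
    """Average ranks with ties, brute force."""
    v = np.asarray(v, float)
    out = np.empty(v.size)
    for i, value in enumerate(v):
        less = np.sum(v < value)
        equal = np.sum(v == value)
        out[i] = less + (equal + 1) / 2.0
    return out


def dtw_oracle(x, y):
    """Independent full-DP table, plain python."""
    n, m = len(x), len(y)
    INF = float("inf")
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            D[i][j] = c + min(D[i - 1][j], D[i][j - 1], D[i - 1][j - 1])
    return D[n][m]


class TestPearson:
    def test_perfect_positive(self):
        assert pearson_score(SeriesPair([1, 2, 3], [2, 4, 6])).score == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_score(SeriesPair([1, 2, 3], [3, 2, 1])).score == pytest.approx(-1.0)

    def test_constant_degenerate(self):
        s = pearson_score(SeriesPair([1, 1, 1], [1, 2, 3]))
        assert s.degenerate and s.score == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=20), rng.normal(size=20)
            got = pearson_score(SeriesPair(x, y)).score
            assert got == pytest.approx(pearson_oracle(x, y), abs=1e-12)


class TestSpearman:
    def test_monotone(self):
        assert spearman_score(SeriesPair([1, 2, 3, 4], [1, 8, 27, 64])).score == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman_score(SeriesPair([1, 2, 3, 4], [64, 27, 8, 1])).score == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 3]
        got = spearman_score(SeriesPair(x, y)).score
        assert got == pytest.approx(pearson_oracle(midrank(x), midrank(y)), abs=1e-12)

    def test_random_matches_oracle(self, rng):
        for _ in range(100):
            x = rng.integers(0, 5, size=15).astype(float)  # ties likely
            y = rng.integers(0, 5, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            got = spearman_score(SeriesPair(x, y)).score
            assert got == pytest.approx(pearson_oracle(midrank(x), midrank(y)), abs=1e-10)


class TestDelayEmbed:
    def test_E2_tau1(self):
        vec, anchors = delay_embed(np.array([1.0, 2, 3, 4]), 2, 1)
        np.testing.assert_array_equal(anchors, [1, 2, 3])
        np.testing.assert_array_equal(vec, [[2, 1], [3, 2], [4, 3]])

    def test_E1_is_series(self):
        vec, anchors = delay_embed(np.array([1.0, 2, 3]), 1, 1)
        np.testing.assert_array_equal(vec[:, 0], [1, 2, 3])
        np.testing.assert_array_equal(anchors, [0, 1, 2])

    def test_E3_tau2(self):
        vec, anchors = delay_embed(np.arange(1.0, 7), 3, 2)
        np.testing.assert_array_equal(anchors, [4, 5])
        np.testing.assert_array_equal(vec, [[5, 3, 1], [6, 4, 2]])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            delay_embed(np.arange(3.0), 4, 1)


class TestCCA:
    def test_identity_lag0(self):
        x = np.arange(10.0)
        assert cca_score(SeriesPair(x, x), 0).score == pytest.approx(1.0)

    def test_exact_lagged_map(self, rng):
        x = rng.normal(size=30)
        y = np.roll(x, 1)
        y[0] = 0.0
        assert cca_score(SeriesPair(x, y), 1).score >= 0.999

    def test_matches_sqrt_r2_oracle(self, rng):
        for _ in range(100):
            T, L = 25, 2
            x, y = rng.normal(size=T), rng.normal(size=T)
            got = cca_score(SeriesPair(x, y), L).score
            # independent least-squares oracle via normal equations
            rows = np.arange(L, T)
            X = np.column_stack([np.ones(rows.size)] + [x[rows - j] for j in range(L + 1)])
            beta = np.linalg.solve(X.T @ X, X.T @ y[rows])
            resid = y[rows] - X @ beta
            tss = np.sum((y[rows] - y[rows].mean()) ** 2)
            want = np.sqrt(max(1 - resid @ resid / tss, 0.0))
            assert got == pytest.approx(want, abs=1e-8)

    def test_score_in_unit_interval(self, rng):
        for _ in range(20):
            s = cca_score(SeriesPair(rng.normal(size=15), rng.normal(size=15)), 1).score
            assert 0.0 <= s <= 1.0


class TestDTW:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=12)
        assert dtw_distance(x, x) == 0.0
        assert dtw_score(SeriesPair(x, x)).score == pytest.approx(1.0)

    def test_hand_example(self):
        # 3x2 table: D(2,2)=1, D(3,2)=1
        assert dtw_distance([1, 2, 3], [1, 3]) == 1.0

    def test_matches_full_dp_oracle(self, rng):
        for _ in range(25):
            x, y = rng.normal(size=30), rng.normal(size=30)
            assert dtw_distance(x, y) == pytest.approx(dtw_oracle(list(x), list(y)), abs=1e-12)

    def test_band_restricts_warping(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert dtw_distance(x, y, band=1) >= dtw_distance(x, y) - 1e-12


class TestCCF:
    def test_exact_lag2(self):
        x = np.sin(np.linspace(0, 6, 30))
        y = np.empty_like(x)
        y[2:] = x[:-2]
        y[:2] = 0.0
        s = ccf_score(SeriesPair(x, y), 4)
        assert s.score == pytest.approx(1.0, abs=1e-9)
        assert s.best_lag == 2

    def test_identity_lag0(self):
        x = np.arange(10.0)
        s = ccf_score(SeriesPair(x, x), 4)
        assert s.score == pytest.approx(1.0)
        assert s.best_lag == 0

    def test_matches_max_over_lags_oracle(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)
        L = 5
        s = ccf_score(SeriesPair(x, y), L)
        cands = []
        for lag in range(L + 1):
            xs = x[: len(x) - lag] if lag else x
            cands.append((abs(pearson_oracle(xs, y[lag:])), lag, pearson_oracle(xs, y[lag:])))
        best = max(cands, key=lambda c: (c[0], -c[1]))
        assert s.score == pytest.approx(best[2], abs=1e-12)
        assert s.best_lag == best[1]

    def test_all_degenerate(self):
        s = ccf_score(SeriesPair(np.ones(10), np.arange(10.0)), 2)
        assert s.degenerate and s.score == 0.0


class TestScaleOffsetInvariance:
    """x -> a*x + b (a > 0) must leave these estimators unchanged."""

    @pytest.mark.parametrize("method", ["pearson", "spearman", "ccf", "cca", "dtw"])
    def test_invariance(self, method, rng):
        from lagmine import association as assoc

        x, y = rng.normal(size=40), rng.normal(size=40)
        pair1 = SeriesPair(x, y)
        pair2 = SeriesPair(3.7 * x + 11.0, y)
        fn = {
            "pearson": lambda p: assoc.pearson_score(p).score,
            "spearman": lambda p: assoc.spearman_score(p).score,
            "ccf": lambda p: assoc.ccf_score(p, 3).score,
            "cca": lambda p: assoc.cca_score(p, 2).score,
            "dtw": lambda p: assoc.dtw_score(p).score,
        }[method]
        assert fn(pair1) == pytest.approx(fn(pair2), abs=1e-8)

    def test_ccm_invariance(self, rng):
        from lagmine.association import EmbeddingParams, ccm_score
        from lagmine.synthetic import gen_coupled_logistic

        x, y = gen_coupled_logistic(150, beta_xy=0.7, seed=4)
        s1 = ccm_score(SeriesPair(x, y), EmbeddingParams(2, 1), 0).score
        s2 = ccm_score(SeriesPair(5.0 * x + 2.0, y), EmbeddingParams(2, 1), 0).score
        assert s1 == pytest.approx(s2, abs=1e-8)


class TestScoreAllGenes:
    def test_all_finite(self, small_aligned, default_cfg):
        scores = score_all_genes(small_aligned, default_cfg)
        assert len(scores) == len(small_aligned.gene_ids)
        assert all(np.isfinite(s.score) for s in scores.values())

    def test_gene_equal_to_target_scores_one_with_pearson(self, small_aligned):
        import copy

        study = copy.deepcopy(small_aligned)
        target = study.metabolite("met_target")
        study.gene_series[0] = target
        cfg = PipelineConfig(target_metabolite="met_target", method="pearson")
        scores = score_all_genes(study, cfg)
        assert scores[study.gene_ids[0]].score == pytest.approx(1.0)

    def test_unknown_target_lists_near_matches(self, small_aligned, default_cfg):
        import dataclasses

        cfg = dataclasses.replace(default_cfg, target_metabolite="met_targett")
        with pytest.raises(KeyError, match="met_target"):
            score_all_genes(small_aligned, cfg)

    def test_results_independent_of_gene_order(self, small_aligned, default_cfg):
        import copy

        study = copy.deepcopy(small_aligned)
        perm = np.random.default_rng(0).permutation(len(study.gene_ids))
        study.gene_ids = [small_aligned.gene_ids[i] for i in perm]
        study.gene_series = small_aligned.gene_series[perm]
        a = score_all_genes(small_aligned, default_cfg)
        b = score_all_genes(study, default_cfg)
        for g in a:
            assert a[g].score == pytest.approx(b[g].score, abs=1e-12)

    def test_degenerate_gene_kept_with_flag(self, small_aligned, default_cfg):
        import copy

        study = copy.deepcopy(small_aligned)
        study.gene_series[3] = 7.0
        scores = score_all_genes(study, default_cfg)
        g = study.gene_ids[3]
        assert scores[g].degenerate and scores[g].score == 0.0
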