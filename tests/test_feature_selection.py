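import numpy as np
import pytest
from scipy import stats as sps

from fabo.feature_selection import (
    REDUNDANCY_FLOOR,
    FeatureSubset,
    choose_k,
    f_statistic_relevance,
    mrmr_order,
    mrmr_select,
    random_select,
    spearman_scores,
    spearman_select,
)


# ---------------------------------------------------------------- oracles

def oracle_f_stat(x, y):
    """F of the univariate regression slope = squared t-statistic."""
    res = sps.linregress(x, y)
    t = res.slope / res.stderr
    return t**2


def oracle_spearman(x, y):
    """Definition-level: Pearson correlation of average-rank vectors."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def oracle_mrmr(X, y, k, seed_first_two=True):
    """Exhaustive re-scoring of every candidate at every greedy step."""
    n, p = X.shape

    def rel(j):
        r = np.corrcoef(X[:, j], y)[0, 1]
        r2 = min(r**2, 1 - 1e-12)
        return (n - 2) * r2 / (1 - r2)

    relevance = np.array([rel(j) for j in range(p)])
    selected = []
    n_seed = min(2 if seed_first_two else 1, k)
    for _ in range(n_seed):
        best, best_score = None, -np.inf
        for j in range(p):
            if j not in selected and relevance[j] > best_score:
                best, best_score = j, relevance[j]
        selected.append(best)
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            mean_corr = np.mean(
                [abs(np.corrcoef(X[:, j], X[:, s])[0, 1]) for s in selected]
            )
            score = relevance[j] / max(REDUNDANCY_FLOOR, mean_corr)
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
    return selected


# ------------------------------------------------------------- relevance

class TestFStatistic:
    def test_matches_squared_t_oracle(self, rng):
        X = rng.standard_normal((10, 5))
        y = X[:, 0] + rng.standard_normal(10)
        F = f_statistic_relevance(X, y)
        for j in range(5):
            assert F[j] == pytest.approx(oracle_f_stat(X[:, j], y), rel=1e-9)

    def test_perfect_predictor_capped_and_first(self, rng):
        X = rng.standard_normal((8, 3))
        y = X[:, 1].copy()
        F = f_statistic_relevance(X, y)
        assert np.isfinite(F).all()
        assert F.argmax() == 1
        assert F[1] > 1e10  # capped, not infinite

    def test_orthogonal_feature_scores_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        F = f_statistic_relevance(np.column_stack([x, y]), y)
        assert F[0] == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            f_statistic_relevance(np.ones((2, 1)), np.ones(2))


# ------------------------------------------------------------------ mRMR

class TestMRMR:
    def test_k1_is_top_relevance(self, rng):
        X = rng.standard_normal((15, 6))
        y = 2 * X[:, 3] + 0.1 * rng.standard_normal(15)
        sub = mrmr_select(X, y, 1)
        assert list(sub.indices) == [int(f_statistic_relevance(X, y).argmax())]

    def test_exact_duplicate_suppressed_by_redundancy(self, rng):
        """After f is selected, its copy scores worse than a distinct
        informative feature (single-seed mode, where redundancy applies
        from the second pick onward)."""
        f = rng.standard_normal(30)
        g = rng.standard_normal(30)
        y = f + 0.8 * g
        X = np.column_stack([f, f.copy(), g])
        sub = mrmr_select(X, y, 3, seed_first_two_by_relevance=False)
        # the duplicate (column 1) must come last
        assert list(sub.indices) == [0, 2, 1]

    def test_duplicate_enters_second_under_first_two_by_relevance(self, rng):
        """Under the first-two-by-relevance seeding rule an exact duplicate
        of the top feature legitimately takes the second slot (relevance
        tie, lower index first)."""
        f = rng.standard_normal(30)
        g = rng.standard_normal(30)
        y = f + 0.8 * g
        X = np.column_stack([f, f.copy(), g])
        sub = mrmr_select(X, y, 3, seed_first_two_by_relevance=True)
        assert list(sub.indices) == [0, 1, 2]

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for trial in range(50):
            X = rng.standard_normal((20, 6))
            w = rng.standard_normal(6) * (rng.random(6) < 0.5)
            y = X @ w + rng.standard_normal(20)
            got = mrmr_select(X, y, 3)
            assert list(got.indices) == oracle_mrmr(X, y, 3), f"instance {trial}"

    def test_first_two_by_relevance_rule_changes_result(self, rng):
        """Verified on instances where seeding with two relevance picks
        differs from seeding with one."""
        seen_difference = 0
        for trial in range(200):
            X = rng.standard_normal((20, 6))
            # near-duplicate of the top feature plus a strong uncorrelated
            # feature: the two seeding rules pick different second features
            X[:, 1] = 0.97 * X[:, 0] + 0.05 * rng.standard_normal(20)
            y = X[:, 0] + 0.9 * X[:, 2] + 0.3 * rng.standard_normal(20)
            two = mrmr_select(X, y, 3, seed_first_two_by_relevance=True)
            one = mrmr_select(X, y, 3, seed_first_two_by_relevance=False)
            if list(two.indices) != list(one.indices):
                seen_difference += 1
                assert list(two.indices) == oracle_mrmr(X, y, 3, True)
                assert list(one.indices) == oracle_mrmr(X, y, 3, False)
            if seen_difference >= 5:
                break
        assert seen_difference >= 5

    def test_order_is_prefix_nested(self, rng):
        X = rng.standard_normal((25, 8))
        y = X[:, 0] - X[:, 4] + 0.2 * rng.standard_normal(25)
        idx, _ = mrmr_order(X, y, 6)
        for k in (1, 3, 6):
            assert list(mrmr_select(X, y, k).indices) == list(idx[:k])

    def test_redundancy_disabled_equals_topk_relevance(self, rng):
        """Raising the redundancy floor far above any attainable mean
        correlation reduces mRMR to top-k by relevance."""
        X = rng.standard_normal((30, 6))
        y = X @ rng.standard_normal(6) + 0.3 * rng.standard_normal(30)
        sub = mrmr_select(X, y, 5, redundancy_floor=1e12)
        F = f_statistic_relevance(X, y)
        assert list(sub.indices) == list(np.argsort(-F)[:5])

    def test_k_exceeding_features_errors(self, rng):
        with pytest.raises(ValueError):
            mrmr_select(rng.standard_normal((10, 3)), rng.standard_normal(10), 4)

    def test_zero_relevance_falls_back_to_random(self):
        X = np.column_stack([[1.0, -1, 1, -1, 1, -1], [1.0, 1, -1, -1, 1, -1]])
        y = np.array([1.0, 1, 1, -1, -1, -1])
        # construct exactly orthogonal columns vs y
        X[:, 0] = [1, -1, 1, -1, 1, -1]
        y = np.array([0.0, 0, 0, 0, 0, 0])  # constant target: all r = 0
        sub = mrmr_select(X, y, 1, rng=np.random.default_rng(0))
        assert sub.method == "random" and sub.k == 1

    def test_pure_function_of_inputs(self, rng):
        X = rng.standard_normal((20, 6))
        y = X[:, 2] + rng.standard_normal(20)
        a = mrmr_select(X, y, 4)
        b = mrmr_select(X, y, 4)
        assert list(a.indices) == list(b.indices)
        np.testing.assert_array_equal(a.scores, b.scores)


# -------------------------------------------------------------- Spearman

class TestSpearman:
    def test_monotone_increasing_ranked_first(self, rng):
        X = rng.standard_normal((12, 4))
        X[:, 2] = np.exp(rng.standard_normal(12))  # any values
        y = np.sort(rng.standard_normal(12))
        X[:, 2] = np.sort(X[:, 2])  # strictly increasing with sorted y
        sub = spearman_select(X, y, 4)
        assert sub.indices[0] == 2
        assert sub.scores[0] == pytest.approx(1.0)

    def test_anti_monotone_equally_top_ranked(self):
        y = np.arange(10.0)
        X = np.column_stack([-y, np.random.default_rng(1).standard_normal(10)])
        sub = spearman_select(X, y, 2)
        assert sub.indices[0] == 0 and sub.scores[0] == pytest.approx(1.0)

    def test_tied_data_matches_rank_pearson_oracle(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0])
        y = rng.standard_normal(8)
        got = spearman_scores(x[:, None], y)[0]
        assert got == pytest.approx(abs(oracle_spearman(x, y)), rel=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        X = rng.integers(0, 5, size=(20, 6)).astype(float)  # plenty of ties
        y = rng.standard_normal(20)
        got = spearman_scores(X, y)
        for j in range(6):
            want = abs(sps.spearmanr(X[:, j], y).statistic)
            assert got[j] == pytest.approx(want, rel=1e-12)

    def test_selection_order_and_tie_to_lower_index(self, rng):
        y = np.arange(9.0)
        x = rng.standard_normal(9)
        X = np.column_stack([x, y, y.copy()])  # columns 1, 2 tie at rho=1
        sub = spearman_select(X, y, 2)
        assert list(sub.indices) == [1, 2]


# ---------------------------------------------------------------- random

class TestRandomSelect:
    def test_k_equals_p_returns_all(self):
        sub = random_select(5, 5, 0)
        assert sorted(sub.indices) == list(range(5))

    def test_seed_determinism(self):
        a = random_select(10, 3, 42)
        b = random_select(10, 3, 42)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_inclusion_frequency_binomial(self):
        """Each of p=10 features appears with frequency ~ k/p = 0.3."""
        rng = np.random.default_rng(7)
        counts = np.zeros(10)
        n_draws = 10_000
        for _ in range(n_draws):
            counts[random_select(10, 3, rng).indices] += 1
        freq = counts / n_draws
        se = np.sqrt(0.3 * 0.7 / n_draws)
        assert (np.abs(freq - 0.3) < 3 * se).all()

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            random_select(3, 4, 0)


# --------------------------------------------------------------- choose_k

class TestChooseK:
    def test_ramp_clipped_by_n_labeled(self):
        assert choose_k(10, 5, 40, "ramp", ramp_alpha=1.0) == 8

    def test_constant_bounds_any_strategy(self):
        assert choose_k(50, 7, 7, "ramp") == 7
        assert choose_k(50, 7, 7, "loo_grid") == 7

    def test_never_exceeds_n_minus_2(self):
        assert choose_k(6, 5, 40, "ramp", ramp_alpha=10.0) == 4

    def test_infeasible_bounds(self):
        with pytest.raises(ValueError):
            choose_k(50, 10, 5, "ramp")

    def test_loo_grid_prefers_true_support_size(self):
        """With exactly 5 informative features, the leave-one-out schedule
        picks sizes far closer to 5 than to the 40-feature cap."""
        from fabo.data_model import fit_standardizer
        from fabo.surrogate import fit_gp, gp_loo_log_density
        from fabo.feature_selection import mrmr_order

        chosen = []
        for s in range(10):
            rng = np.random.default_rng(2000 + s)
            X = rng.standard_normal((60, 60))
            y = X[:, :5].sum(axis=1) + 0.1 * rng.standard_normal(60)
            order, _ = mrmr_order(X, y, 40)

            def ev(kk, X=X, y=y, order=order):
                cols = order[:kk]
                st = fit_standardizer(X[:, cols], y)
                post = fit_gp(st.transform_X(X[:, cols]), st.transform_y(y),
                              "shared", 1, 0)
                return gp_loo_log_density(post)

            chosen.append(choose_k(60, 5, 40, "loo_grid", ev,
                                   p_available=60, grid_size=4))
        mean_k = np.mean(chosen)
        assert abs(mean_k - 5) < abs(40 - mean_k)

    def test_loo_grid_returns_grid_argmax(self):
        calls = []

        def ev(k):
            calls.append(k)
            return -((k - 12) ** 2)  # peak at 12

        k = choose_k(100, 5, 40, "loo_grid", ev, grid_size=5)
        assert k == min(calls, key=lambda kk: (kk - 12) ** 2)
        assert all(5 <= kk <= 40 for kk in calls)


class TestSubsetInvariants:
    def test_unique_indices_enforced(self):
        with pytest.raises(ValueError):
            FeatureSubset(np.array([1, 1]), np.zeros(2), "random", 2)

    def test_selection_excludes_masked_features_by_construction(self, rng):
        """Selection operates on the non-degenerate submatrix, so masked
        features can never appear in the output."""
        from fabo.data_model import drop_degenerate_features

        X = rng.standard_normal((20, 5))
        X[:, 3] = 2.0  # degenerate
        y = X[:, 0] + rng.standard_normal(20)
        keep = drop_degenerate_features(X)
        avail = np.flatnonzero(keep)
        sub = mrmr_select(X[:, avail], y, 3)
        assert 3 not in set(avail[sub.indices])
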