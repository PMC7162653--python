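"""Connection-probability estimation, exact tests, bootstrap controls, GLM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st_hyp
from scipy.stats import binom, hypergeom

from clonal_circuits import connectivity as conn
from conftest import make_pairs


class TestClopperPearson:
    def test_closed_form_zero_successes(self):
        lo, hi = conn.clopper_pearson(0, 20, alpha=0.05)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-12)

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = conn.clopper_pearson(20, 20)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 20), abs=1e-12)

    def test_matches_binomial_tail_grid_inversion(self):
        # independent oracle: invert the binomial tails on a fine p-grid
        k, n, alpha = 7, 62, 0.05
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        lo_oracle = grid[np.searchsorted(binom.sf(k - 1, n, grid), alpha / 2) ]
        upper_ok = binom.cdf(k, n, grid) > alpha / 2
        hi_oracle = grid[np.flatnonzero(upper_ok)[-1]]
        lo, hi = conn.clopper_pearson(k, n, alpha)
        assert lo == pytest.approx(lo_oracle, abs=1e-4)
        assert hi == pytest.approx(hi_oracle, abs=1e-4)

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            conn.clopper_pearson(5, 3)

    @given(
        n=st_hyp.integers(1, 200),
        frac=st_hyp.floats(0, 1),
        alpha=st_hyp.floats(0.001, 0.5),
    )
    def test_interval_brackets_point_estimate(self, n, frac, alpha):
        k = int(round(frac * n))
        lo, hi = conn.clopper_pearson(k, n, alpha)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestConnectionProbability:
    def test_vertical_pooled_rate(self):
        pairs = make_pairs(464, 0, connected=np.arange(464) < 28)
        est = conn.connection_probability(pairs, relation="related")
        assert est.p_hat == pytest.approx(28 / 464)
        assert est.k == 28 and est.n == 464

    def test_zero_connections_ci_low_zero(self):
        pairs = make_pairs(98, 0, connected=np.zeros(98, bool))
        est = conn.connection_probability(pairs)
        assert est.p_hat == 0.0 and est.ci_low == 0.0

    def test_empty_selection_raises_not_zero_div(self):
        pairs = make_pairs(10, 0.5)
        with pytest.raises(conn.EmptySelectionError):
            conn.connection_probability(pairs, relation="unrelated")

    def test_invariant_to_row_order_and_pooling(self):
        rng = np.random.default_rng(3)
        pairs = make_pairs(200, 0.1, rng=rng)
        shuffled = pairs.sample(frac=1, random_state=1)
        a = conn.connection_probability(pairs)
        b = conn.connection_probability(shuffled)
        halves = conn.CPEstimate.from_counts(
            int(pairs.iloc[:97]["connected"].sum()) + int(pairs.iloc[97:]["connected"].sum()),
            200,
        )
        assert a == b == halves

    def test_vertical_lateral_classification(self):
        assert conn.connection_class("L4", "L5") == "vertical"
        assert conn.connection_class("L4", "L4") == "lateral"
        pairs = pd.concat(
            [make_pairs(5, 1.0), make_pairs(5, 0.0, pre_layer="L5", post_layer="L5")]
        )
        vert = conn.select_pairs(pairs, conn_class="vertical")
        assert (vert["pre_layer"] != vert["post_layer"]).all()


class TestFisherExact:
    def test_vertical_comparison_p_value(self):
        # 28/464 related vs 19/711 unrelated vertical connections
        assert conn.fisher_exact(28, 464, 19, 711) == pytest.approx(0.0056, abs=5e-4)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert conn.fisher_exact(0, 1, 0, 1) == 1.0

    def test_symmetric_under_group_swap(self):
        assert conn.fisher_exact(5, 40, 2, 55) == pytest.approx(
            conn.fisher_exact(2, 55, 5, 40)
        )

    @pytest.mark.parametrize("k1,k2", [(0, 3), (2, 2), (5, 1), (4, 0)])
    def test_matches_exhaustive_enumeration(self, k1, k2):
        # enumerate all 2x2 tables at the observed margins (n1 = n2 = 5)
        n1 = n2 = 5
        K = k1 + k2
        probs = {a: hypergeom.pmf(a, n1 + n2, K, n1) for a in range(max(0, K - n2), min(K, n1) + 1)}
        p_obs = probs[k1]
        oracle = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
        assert conn.fisher_exact(k1, n1, k2, n2) == pytest.approx(oracle, rel=1e-9)


class TestChiSquared:
    def test_table_at_expectation_gives_zero(self):
        stat, p = conn.chi_squared_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # expected cells are all 15; sum (O-E)^2/E = 4 * 25/15
        stat, _ = conn.chi_squared_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(4 * 25 / 15)

    def test_bonferroni_caps_at_one(self):
        _, p_raw = conn.chi_squared_test([[12, 9], [10, 11]])
        _, p_adj = conn.chi_squared_test([[12, 9], [10, 11]], bonferroni_m=13)
        assert p_adj == min(p_raw * 13, 1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            conn.chi_squared_test([[0, 0], [5, 3]])


class TestLogRatios:
    def test_fig_style_counts(self):
        # 7/62 related vs 2/89 unrelated: log2((8/63)/(3/90))
        assert conn.smoothed_log_ratio(7, 62, 2, 89) == pytest.approx(1.9296, abs=1e-4)

    def test_equal_smoothed_rates_give_zero(self):
        assert conn.smoothed_log_ratio(4, 9, 4, 9) == 0.0

    def test_heatmap_cis_cover_point_estimate(self):
        pairs = pd.concat(
            [
                make_pairs(62, 0, connected=np.arange(62) < 7),
                make_pairs(89, 0, relation="unrelated", connected=np.arange(89) < 2),
            ]
        )
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            row = conn.log_ratio_heatmap(pairs, B_reps=200, seed=seed).iloc[0]
            hits += row.ci_low <= row.log2_ratio <= row.ci_high
        assert hits / n_seeds >= 0.94

    def test_heatmap_reports_counts_per_type(self):
        pairs = pd.concat(
            [
                make_pairs(30, 0.2),
                make_pairs(30, 0.1, relation="unrelated"),
                make_pairs(30, 0.2, pre_layer="L5", post_layer="L5"),
                make_pairs(30, 0.1, relation="unrelated", pre_layer="L5", post_layer="L5"),
            ]
        )
        out = conn.log_ratio_heatmap(pairs, B_reps=50, seed=0)
        assert len(out) == 2
        assert set(out["B"]) == {30} and set(out["D"]) == {30}


class TestDistanceMatchedBootstrap:
    def test_identical_controls_null(self):
        rng = np.random.default_rng(5)
        rel = make_pairs(120, 0.3, rng=rng)
        ctl = rel.copy()
        ctl["relation"] = "unrelated"
        res = conn.distance_matched_bootstrap(pd.concat([rel, ctl]), B=400, seed=1)
        assert res.p_value > 0.5
        assert abs(res.mean_difference) < 0.05

    def test_no_matchable_related_raises(self):
        rel = make_pairs(10, 0.5, tangential=50.0)
        ctl = make_pairs(10, 0.5, relation="unrelated", tangential=500.0)
        with pytest.raises(conn.EmptySelectionError):
            conn.distance_matched_bootstrap(pd.concat([rel, ctl]), seed=0)

    def test_unmatched_related_are_dropped(self):
        rng = np.random.default_rng(2)
        rel_near = make_pairs(20, 0.5, tangential=50.0, rng=rng)
        rel_far = make_pairs(7, 0.5, tangential=900.0, rng=rng)
        ctl = make_pairs(40, 0.5, relation="unrelated", tangential=55.0, rng=rng)
        res = conn.distance_matched_bootstrap(
            pd.concat([rel_near, rel_far, ctl]), B=10, seed=0
        )
        assert res.n_related_used == 20
        assert res.n_related_dropped == 7

    def test_single_rep_degenerate_p(self):
        rng = np.random.default_rng(4)
        rel = make_pairs(30, 0.4, rng=rng)
        ctl = make_pairs(30, 0.4, relation="unrelated", rng=rng)
        res = conn.distance_matched_bootstrap(pd.concat([rel, ctl]), B=1, seed=0)
        assert len(res.related_cp) == 1
        assert res.p_value in (0.0, 1.0)

    def test_detects_threefold_excess(self):
        # Monte-Carlo power oracle: related 3x more connected at fixed distances
        detected = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            rel = make_pairs(500, 0.15, rng=rng)
            ctl = make_pairs(1500, 0.05, relation="unrelated", rng=rng)
            res = conn.distance_matched_bootstrap(
                pd.concat([rel, ctl]), B=200, seed=rep
            )
            detected += res.p_value < 0.05
        assert detected >= 9


class TestConnectivityGLM:
    def test_intercept_only_recovers_logit_rate(self):
        pairs = make_pairs(
            400, 0, relation="unrelated", pre_layer="L4", post_layer="L4",
            tangential=0.0, vertical=0.0, rostrocaudal=3,
            connected=np.arange(400) < 60,
        )
        pairs["rostrocaudal"] = 0  # zero out every predictor
        pairs["euclidean_um"] = 0.0
        coefs = conn.connectivity_glm(pairs)
        assert coefs.loc["const", "estimate"] == pytest.approx(
            np.log((60 / 400) / (1 - 60 / 400)), abs=1e-6
        )

    def test_loglik_improves_over_null(self, small_sim):
        pairs = small_sim["pairs"]
        coefs = conn.connectivity_glm(pairs)
        k = pairs["connected"].sum()
        n = len(pairs)
        p0 = k / n
        ll_null = k * np.log(p0) + (n - k) * np.log(1 - p0)
        assert coefs.attrs["llf"] >= ll_null - 1e-9
        assert coefs.attrs["df_resid"] == len(pairs) - 11

    def test_separation_is_flagged(self):
        pairs = pd.concat(
            [
                make_pairs(50, 0, relation="related", connected=np.ones(50, bool)),
                make_pairs(50, 0, relation="unrelated", connected=np.zeros(50, bool)),
            ]
        )
        with pytest.raises(conn.GLMFitError):
            conn.connectivity_glm(pairs)


class TestStratification:
    def test_single_stratum_matches_unstratified(self):
        rng = np.random.default_rng(8)
        pairs = pd.concat(
            [make_pairs(100, 0.1, rng=rng), make_pairs(100, 0.05, relation="unrelated", rng=rng)]
        )
        out = conn.stratify_by_rostrocaudal(pairs, split_rule=lambda r: "all")
        assert len(out) == 1
        row = out.iloc[0]
        assert row.p_related == conn.connection_probability(pairs, relation="related").p_hat
        assert row.fisher_p == conn.fisher_exact(
            row.k_related, row.n_related, row.k_unrelated, row.n_unrelated
        )

    def test_equal_probabilities_show_no_stratum_effect(self):
        detected = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(200 + rep)
            parts = []
            for rc in (1, 4):
                parts.append(make_pairs(1200, 0.06, rostrocaudal=rc, rng=rng))
                parts.append(
                    make_pairs(1200, 0.06, relation="unrelated", rostrocaudal=rc, rng=rng)
                )
            out = conn.stratify_by_rostrocaudal(pd.concat(parts))
            by = out.set_index("stratum")
            p = conn.fisher_exact(
                by.loc["rostral", "k_related"], by.loc["rostral", "n_related"],
                by.loc["caudal", "k_related"], by.loc["caudal", "n_related"],
            )
            detected += p < 0.05
        assert detected <= 1

    def test_twofold_stratum_difference_detected(self):
        detected = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(300 + rep)
            parts = [
                make_pairs(2500, 0.10, rostrocaudal=1, rng=rng),
                make_pairs(2500, 0.05, rostrocaudal=4, rng=rng),
                make_pairs(500, 0.05, relation="unrelated", rostrocaudal=1, rng=rng),
                make_pairs(500, 0.05, relation="unrelated", rostrocaudal=4, rng=rng),
            ]
            out = conn.stratify_by_rostrocaudal(pd.concat(parts)).set_index("stratum")
            p = conn.fisher_exact(
                out.loc["rostral", "k_related"], out.loc["rostral", "n_related"],
                out.loc["caudal", "k_related"], out.loc["caudal", "n_related"],
            )
            detected += p < 0.05
        assert detected >= 9

    def test_missing_group_stratum_skipped_with_warning(self):
        pairs = pd.concat(
            [
                make_pairs(50, 0.1, rostrocaudal=1),
                make_pairs(50, 0.1, relation="unrelated", rostrocaudal=1),
                make_pairs(50, 0.1, rostrocaudal=5),  # no unrelated here
            ]
        )
        with pytest.warns(UserWarning):
            out = conn.stratify_by_rostrocaudal(pairs)
        assert set(out["stratum"]) == {"rostral"}


class TestBidirectional:
    def test_fraction_of_reciprocally_connected_pairs(self):
        pairs = pd.concat([make_pairs(3, 0), make_pairs(3, 0)], ignore_index=True)
        pairs["pair_id"] = [0, 1, 2, 0, 1, 2]
        pairs["bidirectional_tested"] = True
        pairs["connected"] = [True, True, False, True, False, False]
        est = conn.bidirectional_probability(pairs)
        assert (est.k, est.n) == (1, 3)
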