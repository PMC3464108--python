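"""Scoring statistics against independent closed-form oracles, and the
dual-threshold calling logic."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from sgascore import (
    InteractionScorer,
    ScoringConfig,
    adjust_p,
    call_hits,
    fisher_combine,
    intersect_screens,
    paired_t,
)
from sgascore.scoring import STATUS_DEGENERATE, STATUS_INSUFFICIENT, STATUS_OK, score_genes


def oracle_paired_t(c, t):
    """Closed form: t = mean(d) / (sd(d)/sqrt(n)), p two-sided from t_{n-1}."""
    d = np.asarray(c, float) - np.asarray(t, float)
    n = len(d)
    tval = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return tval, 2.0 * stats.t.sf(abs(tval), n - 1)


def oracle_bh(p):
    """BH step-up by hand: adjusted_(i) = min_{j>=i} m*p_(j)/j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestPairedT:
    def test_identical_pairs_degenerate_with_p_one(self):
        r = paired_t([100.0] * 4, [100.0] * 4)
        assert (r.diff, r.p_value, r.status) == (0.0, 1.0, STATUS_DEGENERATE)

    def test_constant_shift_degenerate_with_p_zero(self):
        r = paired_t([102.0, 98.0, 101.0, 99.0], [52.0, 48.0, 51.0, 49.0])
        assert r.diff == 50.0
        assert r.p_value == 0.0
        assert r.status == STATUS_DEGENERATE

    def test_six_pair_closed_form(self):
        c = [110.0, 95.0, 105.0, 100.0, 90.0, 100.0]
        t = [60.0, 55.0, 70.0, 50.0, 45.0, 60.0]
        r = paired_t(c, t)
        t_exp, p_exp = oracle_paired_t(c, t)
        assert r.t_stat == pytest.approx(t_exp, abs=1e-12)
        assert r.p_value == pytest.approx(p_exp, abs=1e-12)
        assert r.diff == pytest.approx(np.mean(np.subtract(c, t)), abs=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = rng.integers(3, 13)
            c = rng.normal(100, 10, n)
            t = rng.normal(90, 10, n)
            r = paired_t(c, t)
            t_exp, p_exp = oracle_paired_t(c, t)
            assert abs(r.t_stat - t_exp) < 1e-12 * max(1, abs(t_exp))
            assert abs(r.p_value - p_exp) < 1e-12

    def test_single_pair_insufficient(self):
        assert paired_t([100.0], [50.0]).status == STATUS_INSUFFICIENT

    def test_nonfinite_pairs_dropped(self):
        r = paired_t([100.0, 101.0, np.nan, 99.0], [90.0, 91.0, 95.0, 89.0])
        assert r.n_pairs == 3

    def test_one_sided_is_upper_tail(self):
        c, t = [110.0, 95.0, 105.0, 100.0], [60.0, 55.0, 70.0, 50.0]
        two = paired_t(c, t, sided="two")
        one = paired_t(c, t, sided="one")
        assert one.p_value == pytest.approx(two.p_value / 2, abs=1e-12)


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        x2, df, p = fisher_combine([1.0, 1.0])
        assert (x2, df, p) == (0.0, 4, 1.0)

    def test_two_equal_pvalues_closed_form(self):
        x2, df, p = fisher_combine([0.05, 0.05])
        x2_exp = -4.0 * math.log(0.05)
        assert x2 == pytest.approx(x2_exp, abs=1e-12)
        assert df == 4
        # df=4 survival: e^{-x/2} (1 + x/2)
        assert p == pytest.approx(math.exp(-x2_exp / 2) * (1 + x2_exp / 2),
                                  abs=1e-12)

    def test_single_p_passes_through(self):
        for p in (0.003, 0.2, 0.97):
            assert fisher_combine([p])[2] == pytest.approx(p, abs=1e-12)

    def test_matches_df4_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            pair = rng.uniform(1e-12, 1.0, size=2)
            x2, _, p = fisher_combine(pair)
            x2_exp = -2.0 * np.log(pair).sum()
            p_exp = math.exp(-x2_exp / 2) * (1 + x2_exp / 2)
            assert abs(x2 - x2_exp) < 1e-12 * max(1, x2_exp)
            assert abs(p - p_exp) < 1e-12

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            x2, _, p = fisher_combine([0.0, 0.5])
        assert np.isfinite(x2) and 0.0 <= p < 1e-250

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 1.5])
        with pytest.raises(ValueError):
            fisher_combine([])


class TestAdjustP:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_p([0.01, 0.02, 0.04], "BH"), [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert adjust_p([0.013], "BH")[0] == pytest.approx(0.013, abs=1e-12)

    def test_adjustment_never_decreases(self):
        p = np.full(10, 0.5)
        for method in ("BH", "bonferroni", "none"):
            assert np.all(adjust_p(p, method) >= 0.5 - 1e-15)

    def test_bonferroni_is_m_times_p_clipped(self):
        p = [0.001, 0.2, 0.9]
        np.testing.assert_allclose(
            adjust_p(p, "bonferroni"), [0.003, 0.6, 1.0], atol=1e-12)

    def test_bh_matches_hand_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(adjust_p(p, "BH"), oracle_bh(p),
                                       atol=1e-12)

    def test_empty_input(self):
        assert adjust_p([], "BH").size == 0


def _result_row(gene="g1", p_combined=0.01, diff=30.0, linked=False,
                sign_consistent=True, status=STATUS_OK):
    return dict(gene=gene, n_pairs=4, n_dead_control=0, n_dead_test=0,
                mean_control=100.0, mean_test=100.0 - diff, diff=diff,
                t_stat=5.0, p_raw=p_combined, x2=np.nan,
                p_combined=p_combined, p_adjusted=np.nan,
                sign_consistent=sign_consistent, status=status,
                linked=linked, call="none")


class TestCallHits:
    @pytest.mark.parametrize(
        "p,diff,linked,expected",
        [
            (0.01, 30.0, False, "sick"),      # passes both thresholds
            (0.01, 30.0, True, "none"),       # linkage veto
            (0.2, 100.0, False, "none"),      # fails alpha
            (0.01, 20.0, False, "none"),      # fails size threshold
            (0.01, 25.0, False, "none"),      # threshold is strict
            (0.01, -30.0, False, "rescue"),   # rescue direction
        ],
    )
    def test_dual_threshold_rules(self, p, diff, linked, expected):
        results = pd.DataFrame([_result_row(p_combined=p, diff=diff,
                                            linked=linked)])
        called = call_hits(results)
        assert called.loc[0, "call"] == expected

    def test_sign_inconsistent_gene_never_called(self):
        results = pd.DataFrame(
            [_result_row(p_combined=1e-6, diff=40.0, sign_consistent=False)])
        assert call_hits(results).loc[0, "call"] == "none"

    def test_linked_genes_leave_the_adjustment_universe(self):
        rows = [
            _result_row("a", p_combined=0.01),
            _result_row("b", p_combined=0.01, linked=True),
            _result_row("c", p_combined=0.04),
        ]
        called = call_hits(pd.DataFrame(rows)).set_index("gene")
        assert np.isnan(called.loc["b", "p_adjusted"])
        # BH with m=2, not m=3
        np.testing.assert_allclose(
            called.loc[["a", "c"], "p_adjusted"], adjust_p([0.01, 0.04], "BH"))

    def test_insufficient_data_never_called(self):
        results = pd.DataFrame(
            [_result_row(p_combined=1e-9, status=STATUS_INSUFFICIENT)])
        called = call_hits(results)
        assert called.loc[0, "call"] == "none"
        assert np.isnan(called.loc[0, "p_adjusted"])


class TestIntersect:
    def test_identical_hit_lists(self):
        res = call_hits(pd.DataFrame([_result_row("a"), _result_row("b")]))
        both = intersect_screens(res, res)
        assert both["gene"].tolist() == ["a", "b"]

    def test_disjoint_hits_empty(self):
        a = call_hits(pd.DataFrame([_result_row("a")]))
        b = call_hits(pd.DataFrame([_result_row("b")]))
        with pytest.warns(UserWarning, match="disjoint"):
            assert intersect_screens(a, b).empty

    def test_shared_planted_sick_genes_recovered_in_both_screens(self):
        # two screens of the same library sharing 10 true sick genes: the
        # intersection of their sick calls recovers nearly all of them
        from sgascore import SimulationConfig, score_screen, simulate_screen

        config = SimulationConfig(n_genes=200, replicates_per_gene=12,
                                  n_experiments=2, sick_fraction=0.05,
                                  rescue_fraction=0.0, seed=19)
        scr = simulate_screen(config)
        results = []
        for exp in ("exp1", "exp2"):
            part = scr.colonies[scr.colonies["experiment_id"] == exp]
            results.append(
                score_screen(part, scr.annotations, scr.windows).results)
        shared = intersect_screens(results[0], results[1], call="sick")
        truth_sick = set(scr.truth.loc[
            scr.truth["interaction"] == "sick", "gene"])
        assert len(truth_sick) == 10
        assert len(truth_sick & set(shared["gene"])) >= 9

    def test_disjoint_universes_warn(self):
        a = call_hits(pd.DataFrame([_result_row("a")]))
        b = call_hits(pd.DataFrame([_result_row("b")]))
        with pytest.warns(UserWarning, match="disjoint"):
            intersect_screens(a, b)


class TestScoreGenes:
    def test_raw_sizes_warn_without_normalization(self, small_screen):
        with pytest.warns(UserWarning, match="size_normalized"):
            results, _ = score_genes(small_screen.colonies)
        assert len(results) == 96

    def test_dead_spots_counted_and_excluded_from_pairs(self):
        frames = []
        for cond, sizes in (("control", [100.0, 100.0, 100.0, 0.0]),
                            ("test", [50.0, 50.0, 0.0, 50.0])):
            frames.append(pd.DataFrame({
                "screen_id": "s", "experiment_id": "e1", "condition": cond,
                "temperature": "25C", "plate_id": "p1", "row": 1,
                "col": np.arange(1, 5), "gene": "g1",
                "replicate": np.arange(1, 5), "size": sizes,
                "size_normalized": sizes,
            }))
        results, _ = score_genes(pd.concat(frames, ignore_index=True))
        rec = results.iloc[0]
        assert rec["n_pairs"] == 2
        assert rec["n_dead_control"] == 1 and rec["n_dead_test"] == 1
        assert rec["status"] == STATUS_DEGENERATE  # both surviving diffs are 50

    def test_monotonic_t_in_effect_size_with_fixed_noise(self):
        # with the noise realization held fixed, a stronger planted effect
        # never weakens the statistic
        rng = np.random.default_rng(5)
        u = 100.0 * np.exp(rng.normal(0, 0.1, 8))
        v = 100.0 * np.exp(rng.normal(0, 0.1, 8))
        tstats = [abs(paired_t(u, effect * v).t_stat)
                  for effect in (0.9, 0.7, 0.5, 0.3)]
        assert np.all(np.diff(tstats) > 0)

    def test_scorer_recovers_planted_genes(self, small_screen):
        from sgascore import PlateNormalizer

        normalized = PlateNormalizer().fit_transform(small_screen.colonies)
        scorer = InteractionScorer().fit(normalized)
        truth = small_screen.truth
        sick = set(truth.loc[truth["interaction"] == "sick", "gene"])
        assert sick <= set(scorer.hits("sick"))

    def test_sklearn_estimator_protocol(self):
        scorer = InteractionScorer(alpha=0.01)
        cloned = clone(scorer)
        assert cloned.get_params()["alpha"] == 0.01
        cloned.set_params(diff_threshold=10.0)
        assert cloned.diff_threshold == 10.0


class TestScoringConfig:
    @pytest.mark.parametrize(
        "kw", [dict(alpha=0.0), dict(alpha=1.0), dict(diff_threshold=-1),
               dict(adjust_method="holm"), dict(sided="both")])
    def test_invalid_config_rejected(self, kw):
        from sgascore import ConfigurationError

        with pytest.raises(ConfigurationError):
            ScoringConfig(**kw)
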