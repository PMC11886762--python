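import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ditchflux.data_model import FluxObservation
from ditchflux.group_stats import (
    kruskal_wallis,
    mann_whitney,
    pairwise_wilcoxon,
    run_comparison_battery,
    spearman,
)


def brute_force_mw_p(x, y):
    """Exact two-sided Mann–Whitney p by full enumeration of assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = stats.rankdata(pooled)[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        ranks = stats.rankdata(pooled)[list(combo)]
        us.append(ranks.sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(cdf, sf))


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        # rank sums 6, 15, 24 -> H = 12/90 * (12+75+192) - 30 = 7.2
        res = kruskal_wallis(
            [1, 2, 3, 4, 5, 6, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        )
        assert res.statistic == pytest.approx(7.2)
        assert res.p == pytest.approx(stats.chi2.sf(7.2, 2))
        assert res.df == 2

    def test_identical_values_degenerate(self):
        res = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_fewer_than_two_groups_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_two_group_case_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 20)
        y = rng.lognormal(0.5, 1, 20)
        kw = kruskal_wallis(
            np.concatenate([x, y]), ["a"] * 20 + ["b"] * 20
        )
        mw = mann_whitney(x, y)
        assert kw.p == pytest.approx(mw.p, abs=0.02)

    def test_two_group_h_equals_wilcoxon_quadratic_form(self):
        # without ties, H reduces to the normalized squared rank-sum deviate
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 8)
        n1, n2 = len(x), len(y)
        n = n1 + n2
        r1 = stats.rankdata(np.concatenate([x, y]))[:n1].sum()
        h_closed = (
            12.0 / (n * (n + 1)) * (r1**2 / n1 + (n * (n + 1) / 2 - r1) ** 2 / n2)
            - 3 * (n + 1)
        )
        res = kruskal_wallis(np.concatenate([x, y]), ["a"] * n1 + ["b"] * n2)
        assert res.statistic == pytest.approx(h_closed, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(0, 1, 30)
        labs = np.array(["a", "b", "c"] * 10)
        perm = rng.permutation(30)
        r1 = kruskal_wallis(vals, labs)
        r2 = kruskal_wallis(vals[perm], labs[perm])
        assert r1.statistic == pytest.approx(r2.statistic) and r1.p == pytest.approx(r2.p)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2/20 assignments as extreme
        assert "exact" in res.test

    def test_identical_multisets_are_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p >= 0.99

    def test_shifted_lognormal_is_detected(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, 50)
        y = rng.lognormal(1.0, 1, 50)
        assert mann_whitney(x, y).p < 0.01

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1, n2", [(2, 2), (2, 4), (3, 3), (3, 4), (4, 4)])
    def test_exact_p_matches_brute_force_enumeration(self, n1, n2):
        """Exhaustive check over every tie-free rank configuration."""
        n = n1 + n2
        for combo in itertools.combinations(range(n), n1):
            x = np.array(combo, dtype=float)
            y = np.array(sorted(set(range(n)) - set(combo)), dtype=float)
            res = mann_whitney(x, y, exact=True)
            assert res.p == pytest.approx(brute_force_mw_p(x, y), rel=1e-12), (
                x, y,
            )


class TestPairwiseWilcoxon:
    def test_bonferroni_is_raw_times_m_capped(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 1, 45)
        labs = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        frame = pairwise_wilcoxon(vals, labs, adjust="bonferroni")
        m = len(frame)
        assert m == 3
        np.testing.assert_allclose(
            frame["p_adj"], np.minimum(1.0, frame["p_raw"] * m)
        )

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [rng.lognormal(0, 1, 15), rng.lognormal(1, 1, 15), rng.lognormal(2, 1, 15)]
        )
        labs = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        holm = pairwise_wilcoxon(vals, labs, adjust="holm")
        bonf = pairwise_wilcoxon(vals, labs, adjust="bonferroni")
        assert (holm["p_adj"] <= bonf["p_adj"] + 1e-15).all()
        assert (holm["p_adj"] >= holm["p_raw"] - 1e-15).all()

    def test_null_groups_stay_nonsignificant(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 1, 90)
        labs = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        frame = pairwise_wilcoxon(vals, labs)
        assert (frame["p_adj"] > 0.05).all()

    def test_unknown_adjust_method_is_error(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon([1, 2, 3, 4], ["a", "a", "b", "b"], adjust="fishing")


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [math.exp(v) for v in x]).rho == pytest.approx(1.0)
        assert spearman(x, sorted(x, reverse=True)).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # d^2 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.rho == pytest.approx(0.8)
        assert res.n == 5

    def test_pairwise_complete_and_small_n(self):
        res = spearman([1.0, None, 3.0, 4.0], [2.0, 5.0, None, 8.0])
        assert res.rho is None and res.n == 2

    def test_zero_rank_variance_reported_absent(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.rho is None and res.n == 4

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y**3).rho == pytest.approx(base)


class TestBattery:
    @staticmethod
    def _records_with_climate_effect(seed=1, ratio=5.0, n=25):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(2 * n):
            climate = "temperate" if i < n else "continental"
            mult = ratio if climate == "temperate" else 1.0
            records.append(
                FluxObservation(
                    site_id=f"s{i}", climate=climate,
                    n2o_flux=float(rng.lognormal(np.log(0.5), 1.2) * mult),
                )
            )
        return records

    def test_injected_climate_effect_is_detected(self):
        report = run_comparison_battery(
            self._records_with_climate_effect(), gases=("N2O",)
        )
        row = report.tests.query("kind == 'factor' and name == 'climate'").iloc[0]
        assert row.p < 0.05

    def test_fixture_battery_runs_all_factor_tests(self, default_records):
        report = run_comparison_battery(default_records)
        factor_rows = report.tests.query("kind == 'factor'")
        assert len(factor_rows) == 14  # 7 factors x 2 gases
        corr = report.tests.query("kind == 'correlation'")
        assert set(corr.gas) == {"CO2", "N2O"}
        assert (report.tests.p.dropna() <= 1).all()
        assert (report.tests.n >= 3).all()

    def test_null_type_one_error_is_controlled(self):
        """Without injected effects, at most 1 of 7 CO2 factor tests comes out
        significant in >=80% of seeds."""
        from ditchflux.synthetic_data import GeneratorConfig, generate

        cfg = GeneratorConfig(effects_enabled=False)
        good = 0
        n_seeds = 50
        for seed in range(n_seeds):
            tests = run_comparison_battery(
                generate(cfg, seed=3000 + seed), gases=("CO2",)
            ).tests
            n_sig = int(tests.query("kind == 'factor'").significant.sum())
            good += n_sig <= 1
        assert good >= 0.8 * n_seeds
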