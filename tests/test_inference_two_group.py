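"""Two-group test statistics, p-values, adjustment, simultaneous CIs."""

import numpy as np
import pytest
from scipy.stats import norm

from ancombc.bias_correction import (DeltaSeries, MixtureFit, VarEstimate,
                                     em_fit)
from ancombc.inference_two_group import (TwoGroupTestConfig, adjust_pvalues,
                                         choose_statistic, pvalues_ci)
from ancombc.inference_two_group import test_statistics as taxon_statistics
from ancombc.pipeline import run_two_group
from ancombc.synthetic_data import SimulationConfig, generate


def _fit(delta=1.0, pi=(0.9, 0.05, 0.05)):
    m = 4
    return MixtureFit(delta_em=delta, pi=np.array(pi), l1=-1.0, l2=1.0,
                      kappa1=0.1, kappa2=0.1,
                      responsibilities=np.tile([1, 0, 0], (m, 1)).astype(float),
                      classes=np.zeros(m, dtype=int), loglik_trace=[0.0])


def _series():
    return DeltaSeries(np.array([1.0, 1.5, 0.2, 3.0]),
                       np.array([0.04, 0.09, 0.01, 0.25]))


class TestTestStatistics:
    def test_null_centered_effect_gives_zero(self):
        s = _series()
        fit = _fit(delta=1.0)
        ve = VarEstimate(1.0, 0.0)
        st = taxon_statistics(s, s.nu0_2, ve, fit,
                             TwoGroupTestConfig(statistic="W"))
        assert st.W[0] == pytest.approx(0.0, abs=1e-12)

    def test_w_is_effect_over_se(self):
        s = _series()
        fit = _fit(delta=0.0)
        st = taxon_statistics(s, s.nu0_2, VarEstimate(0.0, 0.0), fit,
                             TwoGroupTestConfig(statistic="W"))
        np.testing.assert_allclose(st.W, s.delta_i / np.sqrt(s.nu0_2))
        # effect = 1.96 se gives W = 1.96
        s2 = DeltaSeries(np.array([1.96, 0.5, 0.1]), np.array([1.0, 1.0, 1.0]))
        st2 = taxon_statistics(s2, s2.nu0_2, VarEstimate(0.0, 0.0),
                              _fit(delta=0.0),
                              TwoGroupTestConfig(statistic="W"))
        assert st2.W[0] == pytest.approx(1.96)

    def test_w_star_never_exceeds_w_at_equal_numerator(self):
        rng = np.random.default_rng(0)
        s = DeltaSeries(rng.normal(size=50), rng.uniform(0.01, 0.2, size=50))
        fit = _fit(delta=0.3)
        ve = VarEstimate(0.3, 0.05)  # same center so numerators match
        w = taxon_statistics(s, s.nu0_2, ve, fit,
                            TwoGroupTestConfig(statistic="W"))
        ws = taxon_statistics(s, s.nu0_2, ve, fit,
                             TwoGroupTestConfig(statistic="W_star"))
        assert np.all(np.abs(ws.W) <= np.abs(w.W) + 1e-12)
        # the denominator identity: sqrt(a) + sqrt(b) form
        np.testing.assert_allclose(
            ws.se, np.sqrt(s.nu0_2) + np.sqrt(ve.var_wls), rtol=1e-12)

    def test_zero_se_yields_nan(self):
        s = DeltaSeries(np.array([1.0, 2.0, 0.3]), np.array([0.0, 0.1, 0.1]))
        st = taxon_statistics(s, s.nu0_2, VarEstimate(0.0, 0.0), _fit(0.0),
                             TwoGroupTestConfig(statistic="W"))
        assert np.isnan(st.W[0]) and np.isfinite(st.W[1])

    def test_auto_switch_rules(self):
        cfg = TwoGroupTestConfig(statistic="auto")
        assert choose_statistic(cfg, 20, 50, _fit()) == "W_star"
        assert choose_statistic(cfg, 50, 50, _fit()) == "W"
        heavy = _fit(pi=(0.3, 0.4, 0.3))
        assert choose_statistic(cfg, 50, 50, heavy) == "W_star"


class TestPvaluesCI:
    def test_zero_statistic_gives_p_one_and_symmetric_ci(self):
        s = DeltaSeries(np.array([1.0, 1.0, 1.0]), np.array([0.1, 0.1, 0.1]))
        st = taxon_statistics(s, s.nu0_2, VarEstimate(1.0, 0.0), _fit(1.0),
                             TwoGroupTestConfig(statistic="W"))
        p, p_adj, lo, hi = pvalues_ci(st, TwoGroupTestConfig(), m=3)
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(hi - st.effect, st.effect - lo)

    def test_single_taxon_quantile(self):
        s = DeltaSeries(np.array([1.959964, 2.0, 3.0]),
                        np.array([1.0, 1.0, 1.0]))
        st = taxon_statistics(s, s.nu0_2, VarEstimate(0.0, 0.0), _fit(0.0),
                             TwoGroupTestConfig(statistic="W"))
        p, _, lo, hi = pvalues_ci(st, TwoGroupTestConfig(), m=1)
        assert p[0] == pytest.approx(0.05, abs=1e-6)
        assert hi[0] - st.effect[0] == pytest.approx(1.959964, abs=1e-5)

    def test_simultaneous_multiplier_m10(self):
        s = DeltaSeries(np.zeros(10), np.ones(10))
        st = taxon_statistics(s, s.nu0_2, VarEstimate(0.0, 0.0), _fit(0.0),
                             TwoGroupTestConfig(statistic="W"))
        _, _, lo, hi = pvalues_ci(st, TwoGroupTestConfig(alpha=0.05), m=10)
        assert (hi[0] - lo[0]) / 2 == pytest.approx(2.8070, abs=1e-3)

    def test_ci_excludes_zero_iff_bonferroni_significant(self):
        rng = np.random.default_rng(3)
        s = DeltaSeries(rng.normal(0, 1, 40), np.full(40, 0.04))
        cfg = TwoGroupTestConfig(statistic="W", adjust="bonferroni")
        st = taxon_statistics(s, s.nu0_2, VarEstimate(0.0, 0.0), _fit(0.0), cfg)
        p, p_adj, lo, hi = pvalues_ci(st, cfg, m=40)
        excludes = (lo > 0) | (hi < 0)
        np.testing.assert_array_equal(excludes, p_adj <= cfg.alpha)


class TestAdjustPvalues:
    def test_bonferroni_multiplies_by_m(self):
        p = np.array([0.01] + [0.5] * 9)
        assert adjust_pvalues(p, "bonferroni")[0] == pytest.approx(0.1)

    def test_holm_step_down(self):
        p = np.array([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adjust_pvalues(p, "holm"),
                                   [0.03, 0.06, 0.06], atol=1e-12)

    def test_bh_step_up(self):
        p = np.array([0.01, 0.02, 0.9])
        np.testing.assert_allclose(adjust_pvalues(p, "bh"),
                                   [0.03, 0.03, 0.9], atol=1e-12)

    def test_clipped_at_one_and_monotone_vs_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        for method in ("bonferroni", "holm", "bh"):
            q = adjust_pvalues(p, method)
            assert np.all(q <= 1.0 + 1e-15)
            assert np.all(q >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5, 1.2]), "bh")


class TestCalibration:
    def test_type_one_error_under_global_null(self):
        """Per-taxon unadjusted type-I error near 0.05 under a global null
        with group-confounded sampling fractions (n = 30, m = 200)."""
        hits = tot = 0
        for rep in range(6):
            cfg = SimulationConfig(m=200, n=(30, 30), prop_da=0.0,
                                   scenario="large", seed=300 + rep)
            ds = generate(cfg)
            res = run_two_group(ds.table, ds.design, statistic="W")
            p = np.array([r.p for r in res.results if np.isfinite(r.p)])
            hits += int((p <= 0.05).sum())
            tot += p.size
        rate = hits / tot
        band = 3 * np.sqrt(0.05 * 0.95 / tot)
        assert abs(rate - 0.05) < band

    def test_bonferroni_familywise_error_under_null(self):
        any_rej = 0
        reps = 40
        for rep in range(reps):
            cfg = SimulationConfig(m=100, n=(30, 30), prop_da=0.0,
                                   scenario="large", seed=700 + rep)
            ds = generate(cfg)
            res = run_two_group(ds.table, ds.design)
            any_rej += any(
                r.decided_by_structural_zero
                or (np.isfinite(r.p_adj) and r.p_adj <= 0.05)
                for r in res.results)
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        assert any_rej / reps <= bound

    def test_simultaneous_ci_coverage(self):
        covered = 0
        reps = 30
        for rep in range(reps):
            cfg = SimulationConfig(m=150, n=(20, 30), prop_da=0.1,
                                   scenario="large", seed=400 + rep)
            ds = generate(cfg)
            res = run_two_group(ds.table, ds.design)
            truth = np.log(ds.true_mu[:, 0]) - np.log(ds.true_mu[:, 1])
            tid = {t: i for i, t in enumerate(ds.table.taxon_ids)}
            ok = all(
                r.ci_lo <= truth[tid[r.taxon_id]] <= r.ci_hi
                for r in res.results if np.isfinite(r.ci_lo))
            covered += ok
        assert covered / reps >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_w_and_w_star_agree_at_large_n(self):
        cfg = SimulationConfig(m=300, n=(200, 200), prop_da=0.0,
                               scenario="large", seed=9)
        ds = generate(cfg)
        r_w = run_two_group(ds.table, ds.design, statistic="W")
        r_ws = run_two_group(ds.table, ds.design, statistic="W_star")
        assert np.nanmean(np.abs(r_w.stats.W - r_ws.stats.W)) < 0.1
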