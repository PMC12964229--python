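"""Correlated sampling, PSA, CEAC/EVPI, deterministic SA and scenarios."""

import numpy as np
import pandas as pd
import pytest

import psmcea
from psmcea import (ceac, cholesky_sample, evpi, one_way_dsa, run_psa,
                    sample_all, two_way_price_map)
from psmcea.sensitivity import PSASamples, run_scenarios, make_trial_ipd


class TestCholeskySample:
    def test_identity_vcov_reproduces_unit_covariance(self):
        draws = cholesky_sample(np.zeros(2), np.eye(2), 20000, 1)
        cov = np.cov(draws.T)
        assert np.allclose(cov, np.eye(2), atol=3 / np.sqrt(20000) * 3)

    def test_published_vcov_monte_carlo(self, config):
        block = config.strategies["EC+mFOLFOX6"].survival["os"]
        V = block.vcov_array()
        draws = cholesky_sample(block.coefs, V, 50000, 2)
        cov = np.cov(draws.T)
        assert np.allclose(cov, V, rtol=0.05)

    def test_factor_reconstructs_vcov_to_machine_precision(self, config):
        for strat in config.strategies.values():
            for block in strat.survival.values():
                V = block.vcov_array()
                L = np.linalg.cholesky(V)
                assert np.allclose(L @ L.T, V, atol=1e-12)

    def test_degenerate_draw_returns_mean(self):
        class ZeroRng:
            def standard_normal(self, shape):
                return np.zeros(shape)
        out = cholesky_sample([1.5, -2.0], np.eye(2), 1, ZeroRng())
        assert np.allclose(out, [[1.5, -2.0]])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            cholesky_sample([0, 0], [[1, 0.5], [0.2, 1]], 10, 0)


class TestSampleAll:
    def test_beta_utility_draws_centre_on_published_mean(self, config):
        p = config.utilities["pfs"]
        rng = np.random.default_rng(3)
        draws = p.sample(rng, 10000)
        assert np.mean(draws) == pytest.approx(0.80, abs=0.005)

    def test_gamma_cost_draws_have_expected_cv(self, config):
        p = config.drugs["encorafenib"].cost
        draws = p.sample(np.random.default_rng(4), 20000)
        assert np.mean(draws) == pytest.approx(91.03, rel=0.01)
        assert np.std(draws) / np.mean(draws) == pytest.approx(
            1 / np.sqrt(384.16), rel=0.05)

    def test_degenerate_config_reproduces_base_case_exactly(self, config):
        frozen = config.model_copy(deep=True)
        for p in frozen._all_params():
            p.dist = "fixed"
        for strat in frozen.strategies.values():
            for block in strat.survival.values():
                block.vcov = (1e-30 * np.eye(len(block.coefs))).tolist()
        draw = sample_all(frozen, np.random.default_rng(0))
        base = psmcea.run_all(config)
        redrawn = psmcea.run_all(draw)
        for s in base:
            assert redrawn[s].total_cost == pytest.approx(
                base[s].total_cost, abs=1e-6)
            assert redrawn[s].total_qalys == pytest.approx(
                base[s].total_qalys, abs=1e-9)

    def test_probabilities_stay_in_unit_interval(self, config):
        rng = np.random.default_rng(7)
        for _ in range(5):
            draw = sample_all(config, rng)
            for strat in draw.strategies.values():
                for p in strat.ae_incidence.values():
                    assert 0.0 <= p.value <= 1.0
            assert 0.0 <= draw.utilities["pfs"].value <= 1.0


@pytest.fixture(scope="module")
def psa_small(config):
    return run_psa(config, n=250, seed=42)


class TestPSA:
    def test_fixed_seed_reproducibility(self, config):
        a = run_psa(config, n=40, seed=5)
        b = run_psa(config, n=40, seed=5)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_summary_interval_brackets_base_case_increment(self, psa_small,
                                                           base_results):
        s = psa_small.summary("EC+mFOLFOX6", "SOC")
        dq_base = (base_results["EC+mFOLFOX6"].total_qalys
                   - base_results["SOC"].total_qalys)
        lo, hi = s["ci_delta_qaly"]
        assert lo < dq_base < hi

    def test_ceac_probabilities_partition(self, psa_small):
        curves = ceac(psa_small, [0, 50000, 150000, 500000])
        probs = curves[list(psa_small.strategies)].to_numpy()
        assert np.all((0 <= probs) & (probs <= 1))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_zero_wtp_prefers_cheapest_strategy(self, psa_small):
        curves = ceac(psa_small, [0, 1])
        cheapest = psa_small.strategies[int(np.argmin(
            psa_small.costs.mean(axis=0)))]
        assert curves.iloc[0][cheapest] == pytest.approx(1.0)

    def test_soc_dominates_at_threshold(self, psa_small):
        curves = ceac(psa_small, [1, 150000])
        assert curves.iloc[1]["SOC"] > 0.95


class TestEVPI:
    def test_dominating_strategy_gives_zero_evpi(self):
        s = PSASamples(strategies=("a", "b"),
                       costs=np.array([[0.0, 100.0], [0.0, 100.0]]),
                       qalys=np.array([[2.0, 1.0], [2.0, 1.0]]),
                       wtp=1000.0, seed=0)
        assert evpi(s) == 0.0

    def test_two_iteration_hand_enumeration(self):
        # NMB vectors (1,3) and (3,1): E[max]=3, max E = 2 -> EVPI = 1
        s = PSASamples(strategies=("a", "b"),
                       costs=np.array([[0.0, 0.0], [0.0, 0.0]]),
                       qalys=np.array([[1.0, 3.0], [3.0, 1.0]]),
                       wtp=1.0, seed=0)
        assert evpi(s) == pytest.approx(1.0)

    def test_evpi_nonnegative_on_psa(self, psa_small):
        for lam in (0, 150000, 500000, 1000000):
            assert evpi(psa_small, lam) >= 0.0


class TestDeterministicSA:
    def test_zero_width_bounds_give_zero_swing(self, config):
        cfg = config.model_copy(deep=True)
        p = cfg.monitoring_costs["braf_test"]
        p.low = p.high = p.value
        df = one_way_dsa(cfg, ("EC", "SOC"), include_survival=False)
        row = df[df.parameter == "monitoring_costs.braf_test"].iloc[0]
        assert row.swing == pytest.approx(0.0, abs=1e-6)

    def test_intervention_drug_price_moves_icer_monotonically(self, config):
        df = one_way_dsa(config, ("EC+mFOLFOX6", "SOC"), include_survival=False)
        row = df[df.parameter == "drugs.encorafenib.cost"].iloc[0]
        assert row.icer_low < row.base_icer < row.icer_high

    def test_longer_horizon_reduces_icer(self, config):
        df = one_way_dsa(config, ("EC+mFOLFOX6", "SOC"), include_survival=False)
        row = df[df.parameter == "settings.horizon_years"].iloc[0]
        # low bound = 5 years, high = 30 years
        assert row.icer_low > row.icer_high

    def test_survival_parameters_lead_the_tornado(self, config):
        df = one_way_dsa(config, ("EC+mFOLFOX6", "SOC"))
        top = set(df.head(6).parameter)
        assert any("survival" in p or "horizon" in p or "discount" in p
                   for p in top)


class TestTwoWayPriceMap:
    def test_current_prices_prefer_soc(self, config):
        grid = two_way_price_map(config, fractions_a=[1.0], fractions_b=[1.0])
        assert grid.preferred.iloc[0] == "SOC"

    def test_free_targeted_drugs_do_not_rescue_doublet(self, config):
        # zero-priced encorafenib and cetuximab still leave EC non-optimal
        grid = two_way_price_map(config, fractions_a=[0.0], fractions_b=[0.0])
        assert grid.preferred.iloc[0] != "EC"

    def test_preferred_region_downward_closed(self, config):
        grid = two_way_price_map(config, fractions_a=[0.0, 0.5, 1.0],
                                 fractions_b=[0.0, 0.5, 1.0])
        tab = grid.pivot(index="fraction_encorafenib",
                         columns="fraction_cetuximab", values="preferred")
        wins = (tab == "EC+mFOLFOX6").to_numpy()
        # if the combination wins at a price point it wins at all cheaper ones
        for i in range(wins.shape[0]):
            for j in range(wins.shape[1]):
                if wins[i, j]:
                    assert wins[: i + 1, : j + 1].all()


class TestScenarios:
    def test_progression_only_utilities_icer(self, config):
        df = run_scenarios(config, scenarios=("progression-utilities-only",))
        icer = df[(df.kind == "pair")
                  & (df.name == "EC+mFOLFOX6 vs SOC")].icer.iloc[0]
        assert icer == pytest.approx(504038, rel=0.02)

    def test_excluding_rdi_raises_costs_and_icer(self, config, base_results):
        df = run_scenarios(config, scenarios=("no-rdi",))
        strat = df[(df.kind == "strategy")].set_index("name")
        for s in ("EC+mFOLFOX6", "EC"):
            assert strat.loc[s, "cost"] >= base_results[s].total_cost
        icer = df[(df.kind == "pair")
                  & (df.name == "EC+mFOLFOX6 vs SOC")].icer.iloc[0]
        assert icer == pytest.approx(534036, rel=0.02)

    def test_refit_scenarios_require_ipd(self, config):
        with pytest.raises(ValueError, match="pseudo-IPD"):
            run_scenarios(config, scenarios=("spline",))

    def test_refit_scenarios_run_end_to_end(self, config):
        ipd = make_trial_ipd(config, n_subjects=250, seed=11)
        df = run_scenarios(config, ipd_map=ipd,
                           scenarios=("spline", "aic-average", "bic-average"))
        pairs = df[(df.kind == "pair") & (df.name == "EC+mFOLFOX6 vs SOC")]
        assert len(pairs) == 3
        # survival benefit and cost burden both persist under refitting
        assert (pairs.qaly > 0).all()
        assert (pairs.icer > 150000).all()
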