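"""Smoking-model structure: multipliers, flows, aging chain, feedback signs."""

import numpy as np
import pytest

from smokesim import (
    BehaviorParams,
    Cohort,
    EnvInputs,
    InitialConditions,
    TimeGrid,
    averaged_prevalence,
    build_model,
    run_simulation,
    simulate,
    smoking_prevalence,
)
from smokesim.engine import EXTERNAL, StepSeries
from smokesim.model import (
    RISK_STOCK,
    STATES,
    availability_multiplier,
    compute_flows,
    compute_multipliers,
    marketing_index,
    monthly_smoking_quantity,
    quantity_and_price_multipliers,
    real_price,
    risk_perception_multiplier,
    risk_perception_state,
    shs_dependence_multiplier,
    social_pressure_multiplier,
    stock_name,
)


def feedback_free(params: BehaviorParams) -> BehaviorParams:
    """All loop strengths off: dynamics governed by base hazards and aging."""
    return params.with_values(
        s_social=0.0,
        s_shs=0.0,
        s_avail=0.0,
        s_risk=0.0,
        eps_q=0.0,
        s_q_init=0.0,
        s_q_prog=0.0,
        eps_cess=0.0,
        s_nd=0.0,
        m_msa=0.0,
        s_fund=0.0,
        s_fund_risk=0.0,
    )


def stocks_with(cohort_values: dict) -> dict:
    """Build a full stock dict; unspecified stocks get 0 (risk stock 0.1)."""
    stocks = {stock_name(s, c): 0.0 for s in STATES for c in Cohort}
    stocks[RISK_STOCK] = 0.1
    stocks.update(cohort_values)
    return stocks


class TestElementaryOps:
    @pytest.mark.parametrize(
        "freq,cpd,expected", [(20, 5, 100), (0, 12, 0), (30, 20, 600)]
    )
    def test_monthly_quantity_is_product(self, freq, cpd, expected):
        assert monthly_smoking_quantity(freq, cpd) == expected

    @pytest.mark.parametrize("freq,cpd", [(32, 5), (-1, 5), (10, -2)])
    def test_monthly_quantity_range_errors(self, freq, cpd):
        with pytest.raises(ValueError):
            monthly_smoking_quantity(freq, cpd)

    def test_prevalence_counts_current_users(self):
        stocks = stocks_with(
            {
                stock_name("never", Cohort.MIDDLE): 800.0,
                stock_name("current_experimenters", Cohort.MIDDLE): 60.0,
                stock_name("former_experimenters", Cohort.MIDDLE): 40.0,
                stock_name("current_smokers", Cohort.MIDDLE): 40.0,
                stock_name("ex_smokers", Cohort.MIDDLE): 60.0,
            }
        )
        assert smoking_prevalence(stocks, Cohort.MIDDLE) == pytest.approx(0.10)

    def test_prevalence_limits(self):
        all_never = stocks_with({stock_name("never", Cohort.HIGH): 500.0})
        assert smoking_prevalence(all_never, Cohort.HIGH) == 0.0
        all_smoking = stocks_with({stock_name("current_smokers", Cohort.HIGH): 500.0})
        assert smoking_prevalence(all_smoking, Cohort.HIGH) == 1.0

    def test_prevalence_zero_population_raises(self):
        with pytest.raises(ZeroDivisionError):
            smoking_prevalence(stocks_with({}), Cohort.MIDDLE)

    def test_averaged_prevalence_is_unweighted_mean(self):
        stocks = stocks_with(
            {
                stock_name("never", Cohort.MIDDLE): 920.0,
                stock_name("current_smokers", Cohort.MIDDLE): 80.0,
                stock_name("never", Cohort.HIGH): 880.0,
                stock_name("current_smokers", Cohort.HIGH): 120.0,
            }
        )
        assert averaged_prevalence(stocks) == pytest.approx(0.10)

    def test_real_price_income_adjustment(self):
        assert real_price(3.56, 0.44, 1.0) == pytest.approx(4.00)
        assert real_price(3.56, 0.44, 1.25) == pytest.approx(3.20)
        assert real_price(5.0, 0.0, 1.0) == 5.0
        with pytest.raises(ValueError):
            real_price(3.56, 0.44, 0.0)


class TestMultipliers:
    def test_social_pressure_reference_normalization(self, params):
        sp_ref = params.sp_ref_middle
        peer = (sp_ref - (1 - params.w_peer) * 0.2) / params.w_peer
        m = social_pressure_multiplier(peer, 0.2, params, Cohort.MIDDLE)
        assert m == pytest.approx(1.0)

    def test_social_pressure_power_form(self):
        p = BehaviorParams(s_social=0.8, w_peer=1.0, sp_ref_middle=0.15)
        m = social_pressure_multiplier(0.30, 0.0, p, Cohort.MIDDLE)
        assert m == pytest.approx(2**0.8, rel=1e-6)

    def test_social_pressure_vanishes_without_exposure(self, params):
        assert social_pressure_multiplier(0.0, 0.0, params, Cohort.HIGH) == 0.0

    def test_shs_multiplier_linear_gain(self):
        p = BehaviorParams(s_shs=0.5, w_peer=1.0)
        assert shs_dependence_multiplier(0.0, 0.0, p) == 1.0
        assert shs_dependence_multiplier(0.2, 0.0, p) == pytest.approx(1.10)
        off = BehaviorParams(s_shs=0.0)
        assert shs_dependence_multiplier(0.9, 0.9, off) == 1.0

    def test_price_channel_reference_and_elasticity(self, params):
        q, mi, mp, mc = quantity_and_price_multipliers(params.p_ref, params)
        assert (q, mi, mp, mc) == (params.q_ref, 1.0, 1.0, 1.0)
        p = params.with_values(eps_q=-1.0)
        q2, *_ = quantity_and_price_multipliers(2 * p.p_ref, p)
        assert q2 == pytest.approx(p.q_ref / 2)
        off = params.with_values(eps_q=0.0, s_q_init=0.0, s_q_prog=0.0, eps_cess=0.0)
        assert quantity_and_price_multipliers(3 * off.p_ref, off) == (
            off.q_ref,
            1.0,
            1.0,
            1.0,
        )

    def test_availability_reference_and_example(self):
        p = BehaviorParams(s_avail=0.3, compliance_ref_middle=0.73)
        assert availability_multiplier(0.73, Cohort.MIDDLE, p) == pytest.approx(1.0)
        m = availability_multiplier(0.95, Cohort.MIDDLE, p)
        assert m == pytest.approx((0.05 / 0.27) ** 0.3, rel=1e-6)
        off = BehaviorParams(s_avail=0.0)
        assert availability_multiplier(0.95, Cohort.HIGH, off) == 1.0

    def test_availability_floor_keeps_finite(self):
        p = BehaviorParams(s_avail=0.3)
        assert availability_multiplier(1.0, Cohort.MIDDLE, p) > 0.0
        with pytest.raises(ValueError):
            availability_multiplier(1.2, Cohort.MIDDLE, p)

    def test_risk_smoothing_derivative(self):
        assert risk_perception_state(0.1, 0.1, 3.0) == 0.0
        assert risk_perception_state(0.0, 0.3, 3.0) == pytest.approx(0.1)
        # first-order step response: smoothed reaches p (1 - e^(-dt/tau))
        tau, p_target, dt = 2.0, 0.2, 1.0
        s, n = 0.0, 20000
        h = dt / n
        for _ in range(n):
            s += h * risk_perception_state(s, p_target, tau)
        assert s == pytest.approx(p_target * (1 - np.exp(-dt / tau)), rel=1e-3)

    def test_risk_multiplier_reference_and_funding(self):
        p = BehaviorParams(s_fund_risk=0.2, f_ref=9.80, s_risk=0.0)
        assert risk_perception_multiplier(p.risk_ref, 9.80, p) == 1.0
        m = risk_perception_multiplier(p.risk_ref, 20.0, p)
        assert m == pytest.approx(1.0 / (1.0 + 0.2 * (20.0 / 9.80 - 1.0)), rel=1e-6)
        off = BehaviorParams(s_risk=0.0, s_fund_risk=0.0)
        assert risk_perception_multiplier(0.9, 50.0, off) == 1.0

    def test_marketing_msa_step_and_funding(self, env):
        p = BehaviorParams(m_msa=0.4, s_fund=0.0)
        assert marketing_index(1995.0, 9.80, p, env) == pytest.approx(p.m0)
        assert marketing_index(2000.0, 9.80, p, env) == pytest.approx(0.6 * p.m0)
        off = BehaviorParams(m_msa=0.0, s_fund=0.0)
        assert marketing_index(2030.0, 99.0, off, env) == off.m0


class TestFlows:
    def test_initiation_reduces_to_base_hazard(self, params, env):
        stocks = stocks_with(
            {
                stock_name("never", Cohort.MIDDLE): 1000.0,
                stock_name("never", Cohort.HIGH): 1000.0,
            }
        )
        mult = {k: 1.0 for k in (
            "m_risk", "m_init_q", "m_prog_q", "m_cess_p", "marketing",
            "quantity_ratio", "prev_avg",
            "m_social_middle", "m_shs_middle", "m_avail_middle",
            "m_social_high", "m_shs_high", "m_avail_high",
        )}
        flows = {f.name: f for f in compute_flows(stocks, mult, params, env, 1992.0)}
        assert flows["initiation_middle"].rate == pytest.approx(
            params.h_init * 1000.0
        )

    def test_empty_stocks_produce_zero_behavior_flows(self, params, env, init, grid):
        stocks = stocks_with(
            {
                stock_name("never", Cohort.MIDDLE): 1.0,
                stock_name("never", Cohort.HIGH): 1.0,
            }
        )
        mult = compute_multipliers(1995.0, stocks, params, env)
        flows = {f.name: f for f in compute_flows(stocks, mult, params, env, 1995.0)}
        assert flows["cessation_middle"].rate == 0.0
        assert flows["progression_high"].rate == 0.0

    def test_aging_chain_quarter_per_year(self, params, env):
        stocks = stocks_with(
            {
                stock_name("never", Cohort.MIDDLE): 1000.0,
                stock_name("current_experimenters", Cohort.MIDDLE): 1000.0,
                stock_name("former_experimenters", Cohort.MIDDLE): 1000.0,
                stock_name("current_smokers", Cohort.MIDDLE): 500.0,
                stock_name("ex_smokers", Cohort.MIDDLE): 500.0,
                stock_name("never", Cohort.HIGH): 100.0,
            }
        )
        mult = compute_multipliers(1995.0, stocks, params, env)
        flows = compute_flows(stocks, mult, params, env, 1995.0)
        graduation = sum(f.rate for f in flows if f.name.startswith("graduate_"))
        assert graduation == pytest.approx(4000.0 / 4.0)

    def test_no_flow_returns_smokers_to_experimenter_side(self, base_traj):
        experimenter_side = {
            stock_name(s, c)
            for s in ("never", "current_experimenters", "former_experimenters")
            for c in Cohort
        }
        smoker_side = {
            stock_name(s, c) for s in ("current_smokers", "ex_smokers") for c in Cohort
        }
        for name, (source, sink) in base_traj.flow_graph.items():
            assert not (source in smoker_side and sink in experimenter_side), name


class TestModelRuns:
    def test_default_run_completes_and_stays_physical(self, base_traj):
        for name, series in base_traj.stocks.items():
            assert np.all(series >= 0.0), name
        prev = base_traj.aux["prev_avg"]
        assert np.all((prev >= 0.0) & (prev <= 1.0))

    def test_population_accounting_closes(self, base_traj, init, grid):
        person_stocks = [stock_name(s, c) for s in STATES for c in Cohort]
        total = sum(base_traj.stocks[n] for n in person_stocks)
        net_in = base_traj.flows["entry"] - sum(
            base_traj.flows[f"exit_{s}"] for s in STATES
        )
        expected = total[0] + grid.dt * np.concatenate(([0.0], np.cumsum(net_in[:-1])))
        assert np.max(np.abs(total / expected - 1.0)) < 1e-6

    def test_rise_peak_decline_shape(self, base_traj):
        years = np.arange(1992, 2033)
        prev = np.array([base_traj.at("prev_avg", float(y)) for y in years])
        peak = int(years[np.argmax(prev)])
        assert 1994 <= peak <= 2000
        assert prev[np.argmax(prev)] > prev[0]
        assert prev[-1] < 0.6 * prev[0]

    def test_halving_dt_changes_final_stocks_under_half_percent(
        self, params, env, init
    ):
        t1 = simulate(params, env, init, TimeGrid(dt=0.125))
        t2 = simulate(params, env, init, TimeGrid(dt=0.0625))
        for name in t1.stocks:
            a, b = t1.stocks[name][-1], t2.stocks[name][-1]
            assert a == pytest.approx(b, rel=5e-3), name

    def test_feedback_free_model_approaches_linear_equilibrium(self, env, init):
        # with all loops off the system is linear; run far past the horizon
        # and compare against the analytic fixed point of the rate matrix
        params = feedback_free(BehaviorParams())
        grid = TimeGrid(t_start=1992, t_end=2192, dt=0.25)
        traj = simulate(params, env, init, grid)

        names = [stock_name(s, c) for c in Cohort for s in STATES]
        idx = {n: i for i, n in enumerate(names)}
        A = np.zeros((10, 10))
        b = np.zeros(10)
        b[idx[stock_name("never", Cohort.MIDDLE)]] = env.entry_rate(2192.0)
        for c in Cohort:
            n_, ce, fe, cs, ex = (stock_name(s, c) for s in STATES)
            A[idx[n_], idx[n_]] -= params.h_init
            A[idx[ce], idx[n_]] += params.h_init
            A[idx[fe], idx[ce]] += params.h_quit_exp
            A[idx[ce], idx[ce]] -= params.h_quit_exp
            A[idx[ce], idx[fe]] += params.h_rel_exp
            A[idx[fe], idx[fe]] -= params.h_rel_exp
            A[idx[cs], idx[ce]] += params.h_prog
            A[idx[ce], idx[ce]] -= params.h_prog
            A[idx[ex], idx[cs]] += params.h_quit_smk
            A[idx[cs], idx[cs]] -= params.h_quit_smk
            A[idx[cs], idx[ex]] += params.h_rel_smk
            A[idx[ex], idx[ex]] -= params.h_rel_smk
        for s in STATES:
            mid, high = stock_name(s, Cohort.MIDDLE), stock_name(s, Cohort.HIGH)
            A[idx[mid], idx[mid]] -= 0.25
            A[idx[high], idx[mid]] += 0.25
            A[idx[high], idx[high]] -= 0.25
        equilibrium = np.linalg.solve(A, -b)
        final = np.array([traj.stocks[n][-1] for n in names])
        assert np.max(np.abs(final - equilibrium) / equilibrium.max()) < 1e-3

    def test_social_loop_amplifies_impulse(self, env, init, coarse_grid):
        # an impulse of extra current smokers in 1992 echoes louder five
        # years on when the reinforcing social loop is active
        bumped = init.to_stocks()
        for c in Cohort:
            bumped[stock_name("current_smokers", c)] += 1500.0

        def gain(params):
            ref = simulate(params, env, init, coarse_grid)
            hit = simulate(params, env, bumped, coarse_grid)
            return hit.at("prev_avg", 1997.0) - ref.at("prev_avg", 1997.0)

        with_loop = gain(BehaviorParams())
        without = gain(BehaviorParams().with_values(s_social=0.0))
        assert with_loop > without

    def test_build_model_rejects_incomplete_initial_stocks(self, params, env):
        with pytest.raises(ValueError):
            build_model(params, env, {"never_middle": 100.0})


class TestInitialConditions:
    def test_decomposition_sums_to_population(self, init):
        stocks = init.to_stocks()
        for c, pop in ((Cohort.MIDDLE, init.pop_middle), (Cohort.HIGH, init.pop_high)):
            total = sum(stocks[stock_name(s, c)] for s in STATES)
            assert total == pytest.approx(pop)
        assert smoking_prevalence(stocks, Cohort.MIDDLE) == pytest.approx(
            init.prev_middle
        )
        assert smoking_prevalence(stocks, Cohort.HIGH) == pytest.approx(init.prev_high)

    def test_overfull_decomposition_rejected(self):
        with pytest.raises(ValueError):
            InitialConditions(prev_middle=0.5, former_per_current_exp=5.0).to_stocks()


class TestEnvInputs:
    def test_missing_series_raises(self):
        with pytest.raises(KeyError):
            EnvInputs(
                retail_price=None,
                excise_tax=0.44,
                income_index=1.0,
                entry_rate=8000.0,
                parental_prevalence=0.25,
                funding_per_capita=9.80,
            )

    def test_copy_is_independent(self, env):
        c = env.copy()
        c.excise_tax = StepSeries(env.excise_tax, 2015.0, 2.20)
        assert env.excise_tax(2020.0) == pytest.approx(0.44)
        assert c.excise_tax(2020.0) == pytest.approx(2.20)
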