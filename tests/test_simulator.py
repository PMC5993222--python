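"""Tendency assembly, vertical transport, and time integration."""

import dataclasses

import numpy as np
import pytest

from cocycle import (BoundaryForcing, CoParams, ColumnGrid, RunResult,
                     ScenarioConfig, TracerState, apply_transport,
                     make_scenario, mass_total, run, tendency)
from cocycle.kinetics import dissol_specific_rate, scav_specific_rate
from cocycle.params import PM_M_TO_MOL_M2

from conftest import make_linear_box_env


class TestTendency:
    def test_zero_state_zero_boundary(self, closed_box_cfg):
        grid, env, _ = make_scenario("closed_box")
        tend, rates = tendency(TracerState.zeros(1), env, CoParams(),
                               closed_box_cfg, grid=grid)
        for name, arr in tend.items():
            assert np.all(arr == 0.0), name

    def test_closed_box_pools_cancel_pairwise(self, closed_box_cfg):
        grid, env, _ = make_scenario("closed_box")
        st = TracerState.zeros(1)
        st.dco[:], st.scco[:] = 80.0, 10.0
        st.phyco_d[:], st.phyco_n[:] = 3.0, 4.0
        st.pco_s[:], st.pco_b[:], st.zoo_co[:] = 2.0, 5.0, 1.0
        tend, _ = tendency(st, env, CoParams(), closed_box_cfg, grid=grid)
        total = sum(arr.sum() for arr in tend.values())
        scale = sum(abs(arr).sum() for arr in tend.values())
        assert abs(total) <= 1e-12 * max(scale, 1.0)

    def test_dissolution_only_transfer(self, closed_box_cfg):
        # low-O2, dark forcing with only scCo present: pure scCo -> dCo return
        grid, env, _ = make_scenario("closed_box")
        env = env.copy()
        env.o2[:] = 10.0
        env.par[:] = 0.0
        env.nano_biomass[:] = env.diat_biomass[:] = 0.0
        st = TracerState.zeros(1)
        st.scco[:] = 40.0
        p = CoParams(col_min=0.0)
        lam = float(dissol_specific_rate(0.0, 10.0, p))
        tend, _ = tendency(st, env, p, closed_box_cfg, grid=grid)
        assert tend["dco"][0] == pytest.approx(lam * 40.0)
        assert tend["scco"][0] == pytest.approx(-lam * 40.0)

    def test_negative_tracer_rejected(self, closed_box_cfg):
        grid, env, _ = make_scenario("closed_box")
        st = TracerState.zeros(1)
        st.dco[0] = -5.0
        with pytest.raises(ValueError, match="negative"):
            tendency(st, env, CoParams(), closed_box_cfg, grid=grid)


class TestTransport:
    def test_diffusion_of_uniform_profile_is_identity(self):
        grid = ColumnGrid.uniform(100.0, 10, kz=20.0)
        st = TracerState.uniform(10, 20.0)
        st.scco[:] = 7.0
        p = CoParams(w_scco=0.0, w_pcos=0.0, w_pcob=0.0)
        out, burial = apply_transport(st, grid, p, dt=1.0)
        assert np.allclose(out.dco, 20.0)
        assert np.allclose(out.scco, 7.0)
        assert all(v == 0.0 for v in burial.values())

    def test_upwind_advection_of_top_layer(self):
        # 10 pM scCo in the top 10 m layer, w = 1 m/day, dt = 1 day:
        # one tenth of the mass moves down one layer
        grid = ColumnGrid.uniform(50.0, 5, kz=0.0)
        st = TracerState.zeros(5)
        st.scco[0] = 10.0
        p = CoParams(w_pcos=0.0, w_pcob=0.0)
        out, _ = apply_transport(st, grid, p, dt=1.0, substeps=1)
        assert out.scco[0] == pytest.approx(9.0)
        assert out.scco[1] == pytest.approx(1.0)

    def test_mass_conserved_up_to_burial(self):
        rng = np.random.default_rng(0)
        grid = ColumnGrid.uniform(100.0, 10, kz=5.0)
        st = TracerState.zeros(10)
        st.scco[:] = rng.uniform(0, 50, 10)
        st.pco_b[:] = rng.uniform(0, 10, 10)
        st.dco[:] = rng.uniform(0, 100, 10)
        p = CoParams()
        m0 = mass_total(st, grid)
        out, burial = apply_transport(st, grid, p, dt=0.25)
        m1 = mass_total(out, grid)
        buried = sum(burial.values()) * PM_M_TO_MOL_M2
        assert m1 + buried == pytest.approx(m0, rel=1e-12)

    def test_stability_violation_raises(self):
        grid = ColumnGrid.uniform(50.0, 5, kz=0.0)
        st = TracerState.zeros(5)
        with pytest.raises(ValueError, match="sub-step"):
            apply_transport(st, grid, CoParams(), dt=1.0, substeps=1)

    def test_auto_substepping_matches_manual(self):
        grid = ColumnGrid.uniform(50.0, 5, kz=0.0)
        st = TracerState.zeros(5)
        st.pco_b[2] = 10.0
        p = CoParams()
        auto, _ = apply_transport(st, grid, p, dt=1.0)
        manual = st
        for _ in range(5):
            manual, _ = apply_transport(manual, grid, p, dt=0.2, substeps=1)
        assert np.allclose(auto.pco_b, manual.pco_b)


class TestRun:
    def test_no_active_process_preserves_state(self):
        cfg = ScenarioConfig(scenario_name="closed_box", years=1.0, dt=0.5,
                             kinetics_on=False)
        res = run(cfg)
        assert np.array_equal(res.final_state.dco, res.states[0].dco)
        assert res.max_step_closure_error < 1e-12

    def test_linear_box_reaches_source_over_lambda(self, box_grid, linear_box_env):
        p = CoParams(col_min=0.0)
        cfg = ScenarioConfig(scenario_name="closed_box", years=8.0, dt=0.1)
        res = run(cfg, p, grid=box_grid, env=linear_box_env)
        lam = float(scav_specific_rate(20.0, 1e6, 1e6, 0.0, p))
        s_pm = res.cumulative_inputs["dust"] / res.duration_days / PM_M_TO_MOL_M2 / 50.0
        expected = s_pm / lam
        assert res.final_state.dco[0] == pytest.approx(expected, rel=1e-3)

    def test_steady_input_burial_balance(self, box_grid, linear_box_env):
        # at steady state the scavenged export through the floor equals the input
        p = CoParams(col_min=0.0)
        cfg = ScenarioConfig(scenario_name="closed_box", years=8.0, dt=0.1)
        res = run(cfg, p, grid=box_grid, env=linear_box_env)
        input_rate = res.boundary_fluxes["dust"].iloc[-1]
        burial_rate = res.boundary_fluxes["burial_rate"].iloc[-1]
        assert burial_rate == pytest.approx(input_rate, rel=1e-2)

    def test_dt_convergence_is_first_order(self):
        # Co-rich box with an active transient: truncation error should halve
        # (first-order splitting) when dt halves
        finals = {}
        for dt in (1.0, 0.5, 0.25):
            cfg = ScenarioConfig(scenario_name="closed_box", years=1.0, dt=dt,
                                 initial_dco=80.0)
            finals[dt] = run(cfg).final_state.dco[0]
        e1 = abs(finals[1.0] - finals[0.5])
        e2 = abs(finals[0.5] - finals[0.25])
        assert e2 < e1  # halving dt shrinks the change
        assert e2 <= 0.75 * e1

    def test_mass_closure_short_runs(self):
        for name in ("omz_margin", "arctic_shelf", "closed_box"):
            cfg = ScenarioConfig(scenario_name=name, years=1.0, dt=0.25)
            res = run(cfg)
            assert res.max_step_closure_error < 1e-10, name
            assert res.mass_closure() < 1e-10, name

    def test_deterministic(self):
        cfg = ScenarioConfig(scenario_name="arctic_shelf", years=0.5, dt=0.5, seed=4)
        r1, r2 = run(cfg), run(cfg)
        assert np.array_equal(r1.final_state.dco, r2.final_state.dco)

    def test_snapshot_count_matches_times(self):
        cfg = ScenarioConfig(scenario_name="closed_box", years=1.0, dt=0.25,
                             output_interval=36.5)
        res = run(cfg)
        assert len(res.states) == len(res.times) == len(res.rates)
        for st in res.states:
            st.validate()

    def test_netcdf_round_trip(self, tmp_path):
        cfg = ScenarioConfig(scenario_name="arctic_shelf", years=0.5, dt=0.5)
        res = run(cfg)
        path = str(tmp_path / "run.nc")
        res.to_netcdf(path)
        back = RunResult.from_netcdf(path)
        assert np.array_equal(back.times, res.times)
        assert np.array_equal(back.final_state.dco, res.final_state.dco)
        assert back.cumulative_inputs == pytest.approx(res.cumulative_inputs)
        assert back.config == res.config
        assert back.params.lambda_co == res.params.lambda_co

    def test_csv_export(self, tmp_path):
        import pandas as pd
        cfg = ScenarioConfig(scenario_name="closed_box", years=0.5, dt=0.5)
        res = run(cfg)
        path = str(tmp_path / "run.csv")
        res.to_csv(path)
        df = pd.read_csv(path)
        assert {"time", "depth", "dco", "scav_co"} <= set(df.columns)
        assert len(df) == len(res.times) * res.grid.n_layers
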