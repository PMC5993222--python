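"""Rate-law unit tests and invariant properties for the process kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocycle import (CoParams, co_prime, dissol_specific_rate, k_bact,
                     k_o2_scav, k_par, ligand_conc, remin_flux,
                     scav_loss, scav_specific_rate, temp_factor, uptake_rate,
                     xi_zn, zn_from_si, zoo_excretion)

nonneg = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestZnProxy:
    @pytest.mark.parametrize("si,expected", [(0.0, 0.183), (10.0, 0.833), (100.0, 6.683)])
    def test_linear_proxy(self, si, expected):
        assert zn_from_si(si) == pytest.approx(expected)

    def test_negative_si_rejected(self):
        with pytest.raises(ValueError):
            zn_from_si(-1.0)


class TestXiZn:
    def test_zn_zero_gives_ceiling(self):
        assert xi_zn(0.0) == pytest.approx(1.3)

    def test_high_zn_gives_floor(self):
        # 90% reduction of diatom Co uptake in the high-Zn limit
        assert xi_zn(1e9) == pytest.approx(0.1, rel=1e-6)

    def test_at_half_saturation(self):
        assert xi_zn(0.5) == pytest.approx(0.65)

    @settings(deadline=None, derandomize=True)
    @given(zn=nonneg)
    def test_bounded_and_decreasing(self, zn):
        p = CoParams()
        v = float(xi_zn(zn, p))
        assert p.xi_floor <= v <= p.xi_scale
        assert float(xi_zn(zn + 1.0, p)) <= v + 1e-12


class TestLigandsAndSpeciation:
    def test_capped_at_dco(self):
        assert ligand_conc(1.0, 1.0, 20.0) == 20.0  # no excess ligand

    def test_floor_when_no_nano(self):
        assert ligand_conc(0.0, 1.0, 100.0) == 25.0

    def test_nano_fraction(self):
        assert ligand_conc(0.8, 1.0, 100.0) == 80.0

    def test_zero_biomass_means_floor(self):
        assert ligand_conc(0.0, 0.0, 100.0) == 25.0

    @pytest.mark.parametrize("dco,col,expected", [(50, 25, 25), (25, 25, 0), (20, 25, 0)])
    def test_co_prime_clamped(self, dco, col, expected):
        assert co_prime(dco, col) == expected

    @settings(deadline=None, derandomize=True)
    @given(nano=nonneg, total=nonneg, dco=nonneg)
    def test_ligand_bounds(self, nano, total, dco):
        p = CoParams()
        nano = min(nano, total)
        col = float(ligand_conc(nano, total, dco, p))
        assert col <= dco + 1e-9
        assert col >= min(dco, p.col_min) - 1e-9
        assert co_prime(dco, col) <= dco


class TestUptake:
    def test_quota_full_stops_uptake(self):
        assert uptake_rate("nano", 100.0, 150.0, 1.0, 1.0, 0.0) == 0.0

    def test_no_substrate_no_uptake(self):
        assert uptake_rate("diatom", 0.0, 0.0, 1.0, 1.0, 0.0) == 0.0

    def test_half_saturated_empty_quota(self):
        # 150 * 0.5 * (1/1.05) for nano at bco = kdco_nano, theta = 0
        v = uptake_rate("nano", 50.0, 0.0, 1.0, 1.0, 0.0)
        assert v == pytest.approx(150.0 * 0.5 / 1.05)

    def test_xi_applies_to_diatoms_only(self):
        p = CoParams()
        high_zn = 1e9
        d = uptake_rate("diatom", 80.0, 0.0, 1.0, 1.0, high_zn, p)
        d0 = uptake_rate("diatom", 80.0, 0.0, 1.0, 1.0, 0.0, p)
        n = uptake_rate("nano", 50.0, 0.0, 1.0, 1.0, high_zn, p)
        n0 = uptake_rate("nano", 50.0, 0.0, 1.0, 1.0, 0.0, p)
        assert d / d0 == pytest.approx(0.1 / 1.3, rel=1e-6)
        assert n == n0

    def test_over_quota_clamps_to_zero(self):
        assert uptake_rate("nano", 100.0, 200.0, 1.0, 1.0, 0.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(bco=nonneg, theta=st.floats(0.0, 150.0), mu=st.floats(0.0, 2.0),
           p_biomass=st.floats(0.0, 1.0))
    def test_monotone_in_bco_and_bounded(self, bco, theta, mu, p_biomass):
        p = CoParams()
        v = float(uptake_rate("nano", bco, theta, mu, p_biomass, 0.0, p))
        v2 = float(uptake_rate("nano", bco + 10.0, theta, mu, p_biomass, 0.0, p))
        assert v2 >= v - 1e-12
        bound = mu * p.theta_max_nano * p_biomass / p.quota_denom_const
        assert v <= bound + 1e-9


class TestTemperature:
    def test_reference(self):
        assert temp_factor(20.0) == 1.0

    def test_plus_ten_is_q10(self):
        assert temp_factor(30.0) == pytest.approx(2.75)

    def test_minus_ten(self):
        assert temp_factor(10.0) == pytest.approx(1 / 2.75)

    @settings(deadline=None, derandomize=True)
    @given(t=st.floats(-5.0, 40.0))
    def test_log_linearity(self, t):
        assert temp_factor(t + 10.0) == pytest.approx(2.75 * float(temp_factor(t)), rel=1e-12)


class TestSaturationFactors:
    @pytest.mark.parametrize("func,arg,expected", [
        (k_o2_scav, 100.0, 0.0),
        (k_o2_scav, 125.0, 0.5),
        (k_o2_scav, 200.0, 100.0**2 / (100.0**2 + 25.0**2)),
        (k_bact, 0.0, 0.0),
        (k_bact, 2.5, 0.5),
        (k_bact, 7.5, 0.9),
        (k_par, 0.0, 0.0),
        (k_par, 15.0, 0.5),
        (k_par, 45.0, 0.9),
    ])
    def test_printed_points(self, func, arg, expected):
        assert func(arg) == pytest.approx(expected)

    def test_o2_one_sided(self):
        # clamped: no revival of scavenging at very low oxygen
        assert k_o2_scav(0.0) == 0.0
        assert k_o2_scav(50.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(x=nonneg, dx=nonneg)
    @pytest.mark.parametrize("func", [k_o2_scav, k_bact, k_par])
    def test_in_unit_interval_and_monotone(self, func, x, dx):
        v, v2 = float(func(x)), float(func(x + dx))
        assert 0.0 <= v < 1.0
        assert v2 >= v - 1e-12


class TestScavenging:
    def test_at_threshold_only_minimum(self):
        assert scav_specific_rate(20.0, 100.0, 5.0, 0.0) == pytest.approx(1e-4)

    def test_saturated_limit(self):
        lam = scav_specific_rate(20.0, 1e9, 1e9, 0.0)
        assert lam == pytest.approx(0.0101, rel=1e-4)

    def test_bright_light_shuts_off_variable_term(self):
        lam = scav_specific_rate(20.0, 1e9, 1e9, 1e9)
        assert lam == pytest.approx(1e-4, rel=1e-4)

    def test_toggles_replace_factors_with_one(self):
        # SCAV1: oxygen effect off -> full rate even at zero O2
        lam = scav_specific_rate(20.0, 0.0, 1e9, 0.0, o2_effect=False)
        assert lam == pytest.approx(0.0101, rel=1e-4)
        lam = scav_specific_rate(20.0, 1e9, 0.0, 0.0, bact_effect=False)
        assert lam == pytest.approx(0.0101, rel=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(t=st.floats(-2.0, 35.0), o2=nonneg, bact=nonneg, par=nonneg,
           d=st.floats(0.0, 1e3))
    def test_bounds_and_monotonicity(self, t, o2, bact, par, d):
        p = CoParams()
        lam = float(scav_specific_rate(t, o2, bact, par, p))
        q = float(temp_factor(t, p))
        assert p.lambda_co_min - 1e-15 <= lam <= p.lambda_co_min + p.lambda_co * q + 1e-12
        assert float(scav_specific_rate(t, o2 + d, bact, par, p)) >= lam - 1e-12
        assert float(scav_specific_rate(t, o2, bact + d, par, p)) >= lam - 1e-12
        assert float(scav_specific_rate(t, o2, bact, par + d, p)) <= lam + 1e-12

    def test_loss_linear_below_threshold(self):
        assert scav_loss(0.0, 0.01) == 0.0
        assert scav_loss(50.0, 0.01) == pytest.approx(0.5)

    def test_elevated_rate_above_threshold(self):
        # saturated factors: variable part 0.01 -> 10x above 100 pM Co'
        lam = 1e-4 + 0.01
        expected = (1e-4 + 10 * 0.01) * 150.0
        assert scav_loss(150.0, lam) == pytest.approx(expected)

    def test_optional_smoothing_is_continuous(self):
        p = CoParams(elevated_smooth_pm=5.0)
        lam = 1e-4 + 0.01
        below = scav_loss(94.999, lam, p) / 94.999
        above = scav_loss(105.001, lam, p) / 105.001
        mid = scav_loss(100.0, lam, p) / 100.0
        assert below == pytest.approx(lam, rel=1e-6)
        assert above == pytest.approx(1e-4 + 0.1, rel=1e-6)
        assert below < mid < above


class TestDissolution:
    def test_both_factors_at_threshold(self):
        assert dissol_specific_rate(0.0, 50.0) == 0.0

    def test_half_saturated_light(self):
        assert dissol_specific_rate(15.0, 100.0) == pytest.approx(0.05)

    def test_half_saturated_low_oxygen(self):
        assert dissol_specific_rate(0.0, 25.0) == pytest.approx(0.05)

    def test_one_sided_in_oxygen(self):
        # dissolution must not revive at very high O2
        assert dissol_specific_rate(0.0, 500.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(par=nonneg, o2=nonneg, scco=nonneg)
    def test_flux_bounded_by_max_rate(self, par, o2, scco):
        p = CoParams()
        lam = float(dissol_specific_rate(par, o2, p))
        assert 0.0 <= lam <= p.lambda_max_dissol
        assert lam * scco <= p.lambda_max_dissol * scco + 1e-12


class TestReminAndExcretion:
    def test_remin_scaling(self):
        assert remin_flux(0.0, 0.1) == 0.0
        assert remin_flux(10.0, 0.1) == pytest.approx(1.5)
        assert remin_flux(10.0, 0.1, CoParams(phi=1.0)) == pytest.approx(1.0)

    def test_excretion_of_excess_only(self):
        # prey Co/P exactly at the zooplankton quota: nothing excreted
        assert zoo_excretion(20.0, 1.0) == 0.0
        # prey Co/P twice the quota: half the grazed Co excreted
        assert zoo_excretion(40.0, 1.0) == pytest.approx(20.0)
        # no P demand: everything excreted
        assert zoo_excretion(5.0, 0.0) == 5.0

    @settings(deadline=None, derandomize=True)
    @given(gc=nonneg, gp=st.floats(0.0, 100.0))
    def test_excretion_never_exceeds_grazed(self, gc, gp):
        e = float(zoo_excretion(gc, gp))
        assert 0.0 <= e <= gc
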